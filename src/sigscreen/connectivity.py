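"""Build-02 style connectivity scoring of ranked compound profiles.

A reference compendium holds, per *instance* (one compound-treatment
profile), a permutation of ranks 1..n over a shared gene universe with rank
1 the most up-regulated gene.  A query signature's up- and down-tag sets are
scored against each instance with the tag-set Kolmogorov-Smirnov statistic

    a = max_j (j/t - V(j)/n),  b = max_j (V(j)/n - (j-1)/t),
    ks = a if a > b else -b,

where V(1) < ... < V(t) are the sorted tag ranks.  The raw instance score is
s = ks_up - ks_down when the two statistics have opposite signs and 0
otherwise (the null-instance rule); raw scores are scaled by the compendium
maximum p = max s (positives) and |q| = |min s| (negatives) so that scaled
scores span [-1, +1].  Per compound we report the mean scaled score, a
permutation p-value against random tag sets of matched sizes, the percent of
sign-concordant nonzero instances, and optionally a specificity against
decoy signatures.  The final table ranks compounds by permutation p
ascending, ties by mean scaled score descending (positive connectivity
preferred), then name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError
from .signature import QuerySignature

logger = logging.getLogger(__name__)


@dataclass
class RankedProfile:
    """One instance: a compound label plus a rank permutation over the universe."""

    instance_id: str
    compound: str
    ranks: pd.Series  # gene -> rank, a bijection onto 1..n

    def __post_init__(self) -> None:
        r = np.sort(self.ranks.to_numpy())
        n = len(r)
        if not np.array_equal(r, np.arange(1, n + 1)):
            raise FormatError(
                f"instance {self.instance_id!r}: ranks are not a permutation of 1..{n}"
            )


@dataclass
class ReferenceCompendium:
    """Rank matrix (genes x instances) with instance -> compound metadata."""

    ranks: pd.DataFrame
    meta: pd.DataFrame  # columns: instance_id, compound

    def __post_init__(self) -> None:
        if list(self.meta.columns[:2]) != ["instance_id", "compound"]:
            self.meta = self.meta.rename(
                columns=dict(zip(self.meta.columns[:2], ["instance_id", "compound"]))
            )
        if set(self.meta["instance_id"]) != set(self.ranks.columns):
            raise FormatError("instance metadata does not match rank-matrix columns")
        self.meta = self.meta.set_index("instance_id").loc[list(self.ranks.columns)].reset_index()
        self.ranks.index.name = "gene"
        self.ranks.columns.name = None
        R = self.ranks.to_numpy()
        n = R.shape[0]
        expected = np.arange(1, n + 1)
        for j, inst in enumerate(self.ranks.columns):
            if not np.array_equal(np.sort(R[:, j]), expected):
                raise FormatError(f"instance {inst!r}: ranks are not a permutation of 1..{n}")

    @property
    def universe(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[0]

    @property
    def instances(self) -> list[str]:
        return list(self.ranks.columns)

    @property
    def compounds(self) -> list[str]:
        return list(dict.fromkeys(self.meta["compound"]))

    def compound_instances(self, compound: str) -> list[str]:
        return list(self.meta.loc[self.meta["compound"] == compound, "instance_id"])

    def profile(self, instance_id: str) -> RankedProfile:
        compound = self.meta.set_index("instance_id").loc[instance_id, "compound"]
        return RankedProfile(instance_id, compound, self.ranks[instance_id])


@dataclass
class ConnectivityReport:
    """Per-instance and per-compound connectivity results."""

    instances: pd.DataFrame  # instance_id, compound, ks_up, ks_down, raw, scaled
    compounds: pd.DataFrame  # indexed by compound: mean_score, p_perm, percent_nonnull, [specificity], rank

    def to_json(self) -> str:
        return json.dumps(
            {
                "instances": self.instances.to_dict(orient="records"),
                "compounds": self.compounds.reset_index().to_dict(orient="records"),
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# KS tag statistic
# ---------------------------------------------------------------------------

def _ks_from_sorted(V: np.ndarray, n: int) -> np.ndarray:
    """Vectorized tag-KS on sorted rank columns.

    ``V`` has shape (t, m): m instances' sorted tag ranks.  Returns the m
    signed statistics.
    """
    t = V.shape[0]
    j = np.arange(1, t + 1, dtype=float)[:, None]
    a = (j / t - V / n).max(axis=0)
    b = (V / n - (j - 1) / t).max(axis=0)
    return np.where(a > b, a, -b)


def ks_tag_statistic(tags, profile: RankedProfile) -> float:
    """Signed KS statistic of a tag set against one ranked profile."""
    tags = list(tags)
    n = len(profile.ranks)
    if not 1 <= len(tags) < n:
        raise ValueError(f"need 1 <= t < n, got t={len(tags)}, n={n}")
    missing = [g for g in tags if g not in profile.ranks.index]
    if missing:
        raise KeyError(f"tags outside the profile universe: {missing[:5]}")
    V = np.sort(profile.ranks.loc[tags].to_numpy(dtype=float))[:, None]
    return float(_ks_from_sorted(V, n)[0])


def _tag_ks_matrix(ranks: pd.DataFrame, tags) -> np.ndarray:
    """KS statistic of one tag set against every instance column."""
    idx = ranks.index.get_indexer(list(tags))
    if (idx < 0).any():
        missing = [t for t, i in zip(tags, idx) if i < 0]
        raise KeyError(f"tags outside the compendium universe: {missing[:5]}")
    V = np.sort(ranks.to_numpy()[idx, :].astype(float), axis=0)
    return _ks_from_sorted(V, ranks.shape[0])


def instance_raw_score(up, down, profile: RankedProfile) -> float:
    """ks_up - ks_down when the signs differ, else 0 (null instance)."""
    if set(up) & set(down):
        raise FormatError("up and down tags overlap")
    ks_up = ks_tag_statistic(up, profile)
    ks_down = ks_tag_statistic(down, profile)
    return _raw_from_ks(np.array([ks_up]), np.array([ks_down]))[0]


def _raw_from_ks(ks_up: np.ndarray, ks_down: np.ndarray) -> np.ndarray:
    s = ks_up - ks_down
    null = np.sign(ks_up) == np.sign(ks_down)
    return np.where(null, 0.0, s)


def scale_connectivity_scores(raw, warn_all_zero: bool = True) -> np.ndarray:
    """Scale raw scores so the extremes hit exactly +1 and -1.

    s > 0 -> s / max(s);  s < 0 -> s / |min(s)|;  s = 0 stays 0.
    """
    s = np.asarray(raw, dtype=float)
    if s.size < 1:
        raise InsufficientDataError("need at least one instance")
    out = np.zeros_like(s)
    p = s.max()
    q = s.min()
    if p > 0:
        out = np.where(s > 0, s / p, out)
    if q < 0:
        out = np.where(s < 0, s / abs(q), out)
    if p == 0 and q == 0 and warn_all_zero:
        logger.warning("all raw connectivity scores are 0")
    return out


def _score_instances(compendium: ReferenceCompendium, up, down) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ks_up = _tag_ks_matrix(compendium.ranks, up)
    ks_down = _tag_ks_matrix(compendium.ranks, down)
    return ks_up, ks_down, _raw_from_ks(ks_up, ks_down)


def compound_summary(scaled: pd.Series, compendium: ReferenceCompendium) -> pd.Series:
    """Mean scaled score per compound (arithmetic mean over its instances)."""
    by = compendium.meta.set_index("instance_id")["compound"]
    return scaled.groupby(by).mean().reindex(compendium.compounds)


def percent_nonnull(scores, mean_score: float) -> float:
    """Percent of instances whose nonzero score sign matches the mean's sign."""
    s = np.asarray(scores, dtype=float)
    if mean_score == 0:
        return 0.0
    concordant = (s != 0) & (np.sign(s) == np.sign(mean_score))
    return 100.0 * concordant.sum() / s.size


# ---------------------------------------------------------------------------
# Permutation p-values
# ---------------------------------------------------------------------------

def _null_compound_means(
    compendium: ReferenceCompendium,
    n_up: int,
    n_down: int,
    B: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """B replicates of per-compound mean scaled scores under random tag sets.

    Each replicate draws disjoint up/down tag sets uniformly without
    replacement from the universe, rescans the whole compendium, and rescales
    compendium-wide exactly as the observed statistic is computed.  One
    matrix serves every compound.
    """
    n = compendium.n_genes
    if n_up + n_down > n:
        raise InsufficientDataError("universe smaller than |up| + |down|")
    R = compendium.ranks.to_numpy().astype(float)
    by_compound = compendium.meta.groupby("compound", sort=False).indices
    compounds = compendium.compounds
    means = np.empty((B, len(compounds)))
    for b in range(B):
        pick = rng.choice(n, size=n_up + n_down, replace=False)
        Vu = np.sort(R[pick[:n_up], :], axis=0)
        Vd = np.sort(R[pick[n_up:], :], axis=0)
        raw = _raw_from_ks(_ks_from_sorted(Vu, n), _ks_from_sorted(Vd, n))
        # an all-null replicate is an ordinary draw here, not a data problem
        scaled = scale_connectivity_scores(raw, warn_all_zero=False)
        for c, comp in enumerate(compounds):
            means[b, c] = scaled[by_compound[comp]].mean()
    return pd.DataFrame(means, columns=compounds)


def permutation_pvalues(
    signature: QuerySignature,
    compendium: ReferenceCompendium,
    observed_means: pd.Series,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Add-one permutation p per compound: (1 + #{|null| >= |obs|}) / (B + 1)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = _null_compound_means(compendium, len(signature.up_tags),
                                len(signature.down_tags), B, rng)
    ps = {}
    for comp in compendium.compounds:
        obs = abs(observed_means[comp])
        ps[comp] = (1.0 + int((null[comp].abs() >= obs).sum())) / (B + 1.0)
    return pd.Series(ps)


def permutation_pvalue(
    compound: str,
    signature: QuerySignature,
    compendium: ReferenceCompendium,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p for a single compound (shares the full-compendium null)."""
    _, _, raw = _score_instances(compendium, signature.up_tags, signature.down_tags)
    scaled = pd.Series(scale_connectivity_scores(raw), index=compendium.instances)
    observed = compound_summary(scaled, compendium)
    return float(permutation_pvalues(signature, compendium, observed, B=B, seed=seed)[compound])


def specificity_score(
    compound: str,
    signature: QuerySignature,
    decoy_signatures,
    compendium: ReferenceCompendium,
) -> float:
    """Fraction of decoy signatures scoring at least as strongly (|mean|).

    0 means no decoy matches the observed connectivity (most specific);
    1 means every decoy ties or beats it.
    """
    decoys = list(decoy_signatures)
    if not decoys:
        raise InsufficientDataError("need at least one decoy signature")
    _, _, raw = _score_instances(compendium, signature.up_tags, signature.down_tags)
    scaled = pd.Series(scale_connectivity_scores(raw), index=compendium.instances)
    obs = abs(compound_summary(scaled, compendium)[compound])
    hits = 0
    for decoy in decoys:
        _, _, raw_d = _score_instances(compendium, decoy.up_tags, decoy.down_tags)
        scaled_d = pd.Series(scale_connectivity_scores(raw_d), index=compendium.instances)
        if abs(compound_summary(scaled_d, compendium)[compound]) >= obs:
            hits += 1
    return hits / len(decoys)


def rank_small_molecules(compounds: pd.DataFrame) -> pd.DataFrame:
    """Order compounds by (p_perm asc, mean_score desc, name asc) and number them.

    Positive connectivity is preferred at equal significance because the
    screen seeks compounds that mimic, not invert, the query signature.
    """
    out = compounds.copy()
    out["_name"] = out.index
    out = out.sort_values(by=["p_perm", "mean_score", "_name"],
                          ascending=[True, False, True], kind="stable")
    out = out.drop(columns="_name")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Full screen
# ---------------------------------------------------------------------------

def score_compendium(
    signature: QuerySignature,
    compendium: ReferenceCompendium,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    decoy_signatures=None,
) -> ConnectivityReport:
    """Score every instance and compound, attach permutation p-values and rank."""
    ks_up, ks_down, raw = _score_instances(compendium, signature.up_tags, signature.down_tags)
    scaled = scale_connectivity_scores(raw)
    inst = pd.DataFrame(
        {
            "instance_id": compendium.instances,
            "compound": list(compendium.meta["compound"]),
            "ks_up": ks_up,
            "ks_down": ks_down,
            "raw": raw,
            "scaled": scaled,
        }
    )
    scaled_s = pd.Series(scaled, index=compendium.instances)
    means = compound_summary(scaled_s, compendium)
    ps = permutation_pvalues(signature, compendium, means, B=B, seed=seed)
    pn = {
        comp: percent_nonnull(
            scaled_s[compendium.compound_instances(comp)].to_numpy(), means[comp]
        )
        for comp in compendium.compounds
    }
    table = pd.DataFrame(
        {"mean_score": means, "p_perm": ps, "percent_nonnull": pd.Series(pn)}
    )
    if decoy_signatures:
        table["specificity"] = [
            specificity_score(c, signature, decoy_signatures, compendium)
            for c in table.index
        ]
    table = rank_small_molecules(table)
    table.index.name = "compound"
    return ConnectivityReport(inst, table)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_compendium(ranks_path, meta_path, break_ties: bool = False) -> ReferenceCompendium:
    """Read a rank-matrix TSV (genes x instances) and instance metadata TSV.

    Rank ties are forbidden; ``break_ties`` converts a general score-like
    matrix into ranks by stable input order with a logged warning.
    """
    ranks = pd.read_csv(ranks_path, sep="\t", comment="#", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str)
    if break_ties:
        logger.warning("breaking rank ties by stable input order")
        arr = np.empty_like(ranks.to_numpy(), dtype=int)
        for j in range(arr.shape[1]):
            order = np.argsort(ranks.to_numpy()[:, j], kind="stable")
            arr[order, j] = np.arange(1, arr.shape[0] + 1)
        ranks = pd.DataFrame(arr, index=ranks.index, columns=ranks.columns)
    else:
        ranks = ranks.astype(int)
    return ReferenceCompendium(ranks, meta)


def write_compendium(compendium: ReferenceCompendium, ranks_path, meta_path) -> None:
    compendium.ranks.to_csv(ranks_path, sep="\t", index_label="gene")
    compendium.meta.to_csv(meta_path, sep="\t", index=False)
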