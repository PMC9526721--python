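"""Two-group differential expression and up/down query-signature extraction.

The signature is the set of genes differentially expressed below a raw
p-value threshold (default 0.005, no multiplicity correction), split by the
sign of the mean difference and ordered by ascending p.  Signatures are
persisted as GRP files: one gene per line, ``#`` comments, one file per
direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySignatureError, FormatError, InsufficientDataError
from .expression import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class DifferentialResult:
    """Per-gene two-sample test results (treated minus reference)."""

    table: pd.DataFrame  # columns: diff, t, p
    treated: str
    reference: str

    def with_direction(self, alpha: float = 0.005) -> pd.DataFrame:
        tab = self.table.copy()
        direction = np.where(
            (tab["p"] < alpha) & (tab["diff"] > 0), "up",
            np.where((tab["p"] < alpha) & (tab["diff"] < 0), "down", "none"),
        )
        tab["direction"] = direction
        return tab


@dataclass
class QuerySignature:
    """Ordered up- and down-regulated tag lists with their threshold."""

    up_tags: list[str]
    down_tags: list[str]
    alpha: float = 0.005

    def __post_init__(self) -> None:
        overlap = set(self.up_tags) & set(self.down_tags)
        if overlap:
            raise FormatError(f"tags in both lists: {sorted(overlap)[:5]}")

    @property
    def tags(self) -> set[str]:
        return set(self.up_tags) | set(self.down_tags)


def _pick_reference(labels: list[str], reference: str | None) -> str:
    if reference is not None:
        if reference not in labels:
            raise ValueError(f"reference group {reference!r} not among {labels}")
        return reference
    for candidate in ("vehicle", "control", "ctrl"):
        if candidate in labels:
            return candidate
    return sorted(labels)[0]


def differential_expression(
    ds: ExpressionDataset,
    reference: str | None = None,
    welch: bool = False,
) -> DifferentialResult:
    """Per-gene two-sided t-test between the two sample groups.

    Pooled-variance Student t by default; Welch via ``welch=True``.  The
    mean difference is treated minus reference, where the reference group is
    ``reference`` if given, else a conventional control label ("vehicle",
    "control"), else the alphabetically first group.  Genes with exactly
    zero pooled variance get t = 0, p = 1.
    """
    groups = ds.group_vector()
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise InsufficientDataError(f"expected exactly 2 groups, got {labels}")
    ref = _pick_reference(labels, reference)
    trt = next(l for l in labels if l != ref)
    Xt = ds.values.loc[:, groups[groups == trt].index].to_numpy()
    Xr = ds.values.loc[:, groups[groups == ref].index].to_numpy()
    if Xt.shape[1] < 2 or Xr.shape[1] < 2:
        raise InsufficientDataError("each group needs >=2 samples")
    diff = Xt.mean(axis=1) - Xr.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(Xt, Xr, axis=1, equal_var=not welch)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = (Xt.var(axis=1) == 0) & (Xr.var(axis=1) == 0)
    t[zero_var] = 0.0
    p[zero_var] = 1.0
    bad = ~np.isfinite(t)
    t[bad] = 0.0
    p[bad] = 1.0
    table = pd.DataFrame({"diff": diff, "t": t, "p": p}, index=ds.values.index)
    return DifferentialResult(table, treated=trt, reference=ref)


def build_query_signature(de: DifferentialResult, alpha: float = 0.005) -> QuerySignature:
    """Threshold the DE table into an ordered up/down signature.

    up_tags: p < alpha and positive difference, ascending p (stable order);
    down_tags analogously.  Raises :class:`EmptySignatureError` when either
    list would be empty.
    """
    tab = de.table
    up = tab[(tab["p"] < alpha) & (tab["diff"] > 0)].sort_values("p", kind="stable")
    down = tab[(tab["p"] < alpha) & (tab["diff"] < 0)].sort_values("p", kind="stable")
    if up.empty or down.empty:
        raise EmptySignatureError(
            f"signature empty at alpha={alpha} "
            f"(up={len(up)}, down={len(down)}); try a larger alpha"
        )
    return QuerySignature(list(up.index), list(down.index), alpha=alpha)


# ---------------------------------------------------------------------------
# GRP round-trip
# ---------------------------------------------------------------------------

def write_signature(sig: QuerySignature, up_path, down_path) -> None:
    for path, tags in ((up_path, sig.up_tags), (down_path, sig.down_tags)):
        with open(path, "w") as fh:
            for g in tags:
                fh.write(f"{g}\n")


def _read_grp(path) -> list[str]:
    tags = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                tags.append(line)
    return tags


def read_signature(up_path, down_path, alpha: float = 0.005) -> QuerySignature:
    """Read GRP tag lists; overlapping or empty lists are errors."""
    up = _read_grp(up_path)
    down = _read_grp(down_path)
    if not up or not down:
        raise EmptySignatureError("a GRP tag list is empty")
    if set(up) & set(down):
        raise FormatError(f"genes present in both lists: {sorted(set(up) & set(down))[:5]}")
    return QuerySignature(up, down, alpha=alpha)
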