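"""Seeded generators for every input the screen consumes, with ground truth.

The expression generator emulates a summarized two-group microarray
experiment on a log-like intensity scale: planted co-expression modules are
driven by latent per-sample eigengenes, trait-linked modules receive a
treatment shift of the eigengene (half the trait modules shift up, half
down, so the derived signature has both directions), and background genes
are pure noise.  The compendium generator emulates a build-02 style
reference: random rank permutations, plus planted "mimic" instances whose
ranks are exponentially tilted so the planted up-genes concentrate at the
top (Gumbel noise plus lambda on the tilted genes, i.e. Plackett-Luce
sampling with weights e^lambda), and "reverser" instances with the roles
swapped.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .connectivity import ReferenceCompendium

logger = logging.getLogger(__name__)


@dataclass
class SyntheticExpressionConfig:
    """Conditions of the emulated two-group microarray study.

    Defaults mirror the study design the pipeline targets: ~10,000 genes
    after variance filtering, 3 vs 3 samples, several planted modules of
    which 4 are trait-linked, within-module gene-eigengene correlation 0.8,
    and a 2-SD eigengene treatment shift.
    """

    n_genes: int = 10000
    n_modules: int = 6
    module_size: int = 150
    n_trait_modules: int = 4
    within_module_correlation: float = 0.8
    treatment_effect: float = 2.0
    samples_per_group: int = 3
    noise_sd: float = 1.0
    outlier_sample: bool = False
    orthogonal_latents: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("n_modules * module_size must be <= n_genes")
        if self.n_trait_modules > self.n_modules:
            raise ValueError("n_trait_modules must be <= n_modules")
        if not 0 <= self.within_module_correlation < 1:
            raise ValueError("within_module_correlation must be in [0, 1)")
        if self.orthogonal_latents and self.n_modules > 2 * self.samples_per_group - 1:
            raise ValueError("orthogonal latents need n_modules <= n_samples - 1")


@dataclass
class SyntheticCompendiumConfig:
    """Shape of the synthetic reference compendium.

    ``mimic_compounds`` / ``reverser_compounds`` map compound name to the
    tilt strength lambda (lambda = 0 is indistinguishable from random).
    ``n_compounds`` is the total compound count including the planted ones.
    """

    n_compounds: int = 50
    instances_per_compound: int = 3
    universe: list[str] = field(default_factory=list)
    mimic_compounds: dict[str, float] = field(default_factory=lambda: {"mimic": 3.0})
    reverser_compounds: dict[str, float] = field(default_factory=lambda: {"reverser": 3.0})
    seed: int = 0

    def __post_init__(self) -> None:
        planted = len(self.mimic_compounds) + len(self.reverser_compounds)
        if self.n_compounds < planted:
            raise ValueError("n_compounds must cover the planted compounds")


@dataclass
class GroundTruth:
    """What the generators planted, for recovery checks."""

    module_assignment: dict[str, str] = field(default_factory=dict)
    trait_modules: dict[str, int] = field(default_factory=dict)  # label -> +1/-1 shift sign
    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)
    outlier_sample: str | None = None
    mimic_compounds: dict[str, float] = field(default_factory=dict)
    reverser_compounds: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


BACKGROUND = "background"


def generate_expression_dataset(
    cfg: SyntheticExpressionConfig,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a module-structured two-group expression matrix plus ground truth.

    Gene g in module m is rho * e_m + sqrt(1 - rho^2) * noise (noise SD
    ``noise_sd``); trait-linked module eigengenes are shifted by
    +/-``treatment_effect`` in treated samples; background genes are pure
    noise.  A per-gene baseline offset puts values on a log-intensity-like
    scale without touching variances or correlations.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = 2 * cfg.samples_per_group
    samples = [f"vehicle_{i + 1}" for i in range(cfg.samples_per_group)] + [
        f"treated_{i + 1}" for i in range(cfg.samples_per_group)
    ]
    groups = {s: ("vehicle" if s.startswith("vehicle") else "treated") for s in samples}
    treated = np.array([groups[s] == "treated" for s in samples], dtype=float)

    width = len(str(cfg.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    X = np.empty((cfg.n_genes, n_samples))

    truth = GroundTruth()
    rho = cfg.within_module_correlation
    latents = rng.standard_normal((cfg.n_modules, n_samples))
    if cfg.orthogonal_latents:
        # Gram-Schmidt: exactly uncorrelated module drivers (unit sample SD)
        latents = latents - latents.mean(axis=1, keepdims=True)
        Q, _ = np.linalg.qr(latents.T)
        latents = (Q.T * np.sqrt(n_samples - 1))[: cfg.n_modules]
    row = 0
    for m in range(cfg.n_modules):
        label = f"P{m + 1}"
        e = latents[m].copy()
        if m < cfg.n_trait_modules:
            sign = 1 if m % 2 == 0 else -1  # alternate up/down trait modules
            e = e + sign * cfg.treatment_effect * treated
            truth.trait_modules[label] = sign
        block = genes[row: row + cfg.module_size]
        noise = rng.standard_normal((cfg.module_size, n_samples)) * cfg.noise_sd
        X[row: row + cfg.module_size] = rho * e + np.sqrt(1 - rho ** 2) * noise
        for g in block:
            truth.module_assignment[g] = label
        if label in truth.trait_modules:
            if truth.trait_modules[label] > 0:
                truth.up_genes.extend(block)
            else:
                truth.down_genes.extend(block)
        row += cfg.module_size
    n_background = cfg.n_genes - row
    X[row:] = rng.standard_normal((n_background, n_samples)) * cfg.noise_sd
    for g in genes[row:]:
        truth.module_assignment[g] = BACKGROUND

    baseline = rng.uniform(6.0, 12.0, size=cfg.n_genes)[:, None]
    X = X + baseline

    if cfg.outlier_sample:
        # scramble one treated sample within-column: kills its correlation
        # with every other sample without changing its marginal distribution
        target = samples.index(f"treated_{cfg.samples_per_group}")
        X[:, target] = rng.permutation(X[:, target])
        truth.outlier_sample = samples[target]

    values = pd.DataFrame(X, index=genes, columns=samples)
    return ExpressionDataset(values, groups), truth


def generate_null_dataset(
    n_genes: int = 1000,
    samples_per_group: int = 3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionDataset:
    """Pure-noise two-group dataset (no modules, no treatment effect)."""
    cfg = SyntheticExpressionConfig(
        n_genes=n_genes, n_modules=1, module_size=2, n_trait_modules=0,
        within_module_correlation=0.0, treatment_effect=0.0,
        samples_per_group=samples_per_group, noise_sd=noise_sd, seed=seed,
    )
    ds, _ = generate_expression_dataset(cfg)
    return ds


def generate_de_dataset(
    n_genes: int = 1000,
    n_up: int = 50,
    n_down: int = 50,
    effect: float = 2.0,
    samples_per_group: int = 3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Dataset with individually planted differential genes (no modules).

    The first ``n_up`` genes gain ``effect`` (in noise-SD units) in treated
    samples, the next ``n_down`` lose it; the rest are null.
    """
    rng = np.random.default_rng(seed)
    n_samples = 2 * samples_per_group
    samples = [f"vehicle_{i + 1}" for i in range(samples_per_group)] + [
        f"treated_{i + 1}" for i in range(samples_per_group)
    ]
    groups = {s: ("vehicle" if s.startswith("vehicle") else "treated") for s in samples}
    treated = np.array([groups[s] == "treated" for s in samples], dtype=float)
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    shift = np.zeros(n_genes)
    shift[:n_up] = effect * noise_sd
    shift[n_up: n_up + n_down] = -effect * noise_sd
    X = rng.standard_normal((n_genes, n_samples)) * noise_sd + shift[:, None] * treated
    X += rng.uniform(6.0, 12.0, size=n_genes)[:, None]
    truth = GroundTruth(
        module_assignment={g: BACKGROUND for g in genes},
        up_genes=genes[:n_up],
        down_genes=genes[n_up: n_up + n_down],
    )
    return ExpressionDataset(pd.DataFrame(X, index=genes, columns=samples), groups), truth


def generate_reference_compendium(
    cfg: SyntheticCompendiumConfig, truth: GroundTruth
) -> ReferenceCompendium:
    """Draw ranked profiles: random permutations plus tilted mimics/reversers.

    A mimic instance samples gene scores as Gumbel(0,1) + lambda on planted
    up-genes and - lambda on planted down-genes, then ranks by descending
    score (rank 1 = most up-regulated); a reverser swaps the roles.
    """
    if not cfg.universe:
        raise ValueError("compendium config needs a gene universe")
    universe = list(cfg.universe)
    n = len(universe)
    idx = pd.Index(universe)
    up_idx = idx.get_indexer([g for g in truth.up_genes if g in idx])
    down_idx = idx.get_indexer([g for g in truth.down_genes if g in idx])
    up_idx = up_idx[up_idx >= 0]
    down_idx = down_idx[down_idx >= 0]

    planted = list(cfg.mimic_compounds) + list(cfg.reverser_compounds)
    n_random = cfg.n_compounds - len(planted)
    compounds = planted + [f"cmpd_{i + 1:03d}" for i in range(n_random)]

    rng = np.random.default_rng(cfg.seed)
    cols, meta_rows = {}, []
    for comp in compounds:
        lam = cfg.mimic_compounds.get(comp, 0.0) + cfg.reverser_compounds.get(comp, 0.0)
        reverse = comp in cfg.reverser_compounds
        for i in range(cfg.instances_per_compound):
            inst = f"{comp}.{i + 1}"
            if lam > 0:
                score = rng.gumbel(size=n)
                top, bottom = (down_idx, up_idx) if reverse else (up_idx, down_idx)
                score[top] += lam
                score[bottom] -= lam
                order = np.argsort(-score, kind="stable")
            else:
                order = rng.permutation(n)
            ranks = np.empty(n, dtype=int)
            ranks[order] = np.arange(1, n + 1)
            cols[inst] = ranks
            meta_rows.append((inst, comp))
    ranks = pd.DataFrame(cols, index=universe)
    meta = pd.DataFrame(meta_rows, columns=["instance_id", "compound"])
    truth.mimic_compounds = dict(cfg.mimic_compounds)
    truth.reverser_compounds = dict(cfg.reverser_compounds)
    return ReferenceCompendium(ranks, meta)


def make_extreme_instance_compendium(
    n_genes: int = 100,
    n_up: int = 10,
    n_down: int = 10,
    n_random: int = 4,
    concordant: bool = True,
    seed: int = 0,
):
    """A compendium with one extreme instance among random ones, plus its query.

    The extreme instance places every up-tag above all other genes and every
    down-tag below them (``concordant=True``), or the reverse placement
    (``concordant=False``).  Returns (compendium, signature, instance_id).
    Useful for exercising the scaling bounds: after compendium-wide scaling
    the concordant construction scores exactly +1 and the reversed one -1.
    """
    from .connectivity import ReferenceCompendium
    from .signature import QuerySignature

    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:03d}" for i in range(n_genes)]
    up, down = genes[:n_up], genes[n_genes - n_down:]
    rest = genes[n_up: n_genes - n_down]
    ordered = (list(up) + rest + list(down)) if concordant else (
        list(down) + rest + list(up))
    cols = {"extreme.1": pd.Series({g: i + 1 for i, g in enumerate(ordered)})}
    meta = [("extreme.1", "extreme")]
    for i in range(n_random):
        order = rng.permutation(n_genes)
        ranks = np.empty(n_genes, dtype=int)
        ranks[order] = np.arange(1, n_genes + 1)
        inst = f"rand{i + 1}.1"
        cols[inst] = pd.Series(ranks, index=genes)
        meta.append((inst, f"rand{i + 1}"))
    compendium = ReferenceCompendium(
        pd.DataFrame(cols, index=genes),
        pd.DataFrame(meta, columns=["instance_id", "compound"]),
    )
    return compendium, QuerySignature(list(up), list(down)), "extreme.1"


def random_signature(universe, n_up: int, n_down: int, rng: np.random.Generator):
    """Disjoint random up/down tag lists drawn uniformly from the universe."""
    from .signature import QuerySignature

    pick = rng.choice(len(universe), size=n_up + n_down, replace=False)
    universe = list(universe)
    return QuerySignature(
        [universe[i] for i in pick[:n_up]],
        [universe[i] for i in pick[n_up:]],
        alpha=float("nan"),
    )
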