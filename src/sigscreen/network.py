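"""Weighted gene co-expression network analysis, implemented from scratch.

Pipeline: Pearson correlation -> soft-thresholded adjacency (signed or
unsigned, power beta) -> topological overlap matrix (TOM) -> average-linkage
hierarchical clustering of 1 - TOM -> static cut at a fraction of the maximal
merge height -> minimum-size filter -> module eigengenes -> iterative merging
of modules whose eigengenes correlate above ``1 - merge_diss_threshold``.

Module eigengenes are the first right-singular vector of the standardized
module submatrix (unit norm, sign-oriented to correlate non-negatively with
the module's mean standardized profile), and module-trait association is the
Pearson correlation of each eigengene with a per-sample trait vector, with
Bonferroni correction over the assigned modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import InsufficientDataError, ZeroVarianceError
from .expression import ExpressionDataset

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class NetworkParams:
    """Knobs of the co-expression network construction.

    beta is the soft-threshold power applied to the (signed or unsigned)
    correlation; min_module_size is the smallest cluster kept as a module;
    cut_height_fraction positions the static dendrogram cut relative to the
    maximal merge height; merge_diss_threshold is the eigengene
    dissimilarity (1 - cor) below which modules are merged.
    """

    beta: int = 16
    adjacency_type: str = "signed"
    min_module_size: int = 100
    cut_height_fraction: float = 0.95
    merge_diss_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.adjacency_type not in ("signed", "unsigned"):
            raise ValueError("adjacency_type must be 'signed' or 'unsigned'")
        if not 0 < self.cut_height_fraction <= 1:
            raise ValueError("cut_height_fraction must be in (0, 1]")


@dataclass
class ModuleDecomposition:
    """Gene -> module assignment plus per-module eigengenes and merge history."""

    assignment: dict[str, str]
    eigengenes: dict[str, np.ndarray]
    merge_log: list[tuple[str, str, float]] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)

    @property
    def modules(self) -> list[str]:
        return sorted(self.eigengenes)

    def module_genes(self, label: str) -> list[str]:
        return [g for g, m in self.assignment.items() if m == label]

    def eigengene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {m: self.eigengenes[m] for m in self.modules},
            index=self.samples or None,
        ).T


# ---------------------------------------------------------------------------
# Adjacency and topological overlap
# ---------------------------------------------------------------------------

def adjacency_matrix(ds: ExpressionDataset, params: NetworkParams,
                     dtype=np.float64) -> np.ndarray:
    """Soft-thresholded co-expression adjacency.

    signed:   a_ij = ((1 + cor_ij) / 2) ** beta
    unsigned: a_ij = |cor_ij| ** beta

    The diagonal is 1 and entries live in [0, 1].  ``dtype`` lets large
    networks run in float32, where the rounding is far below the scale the
    downstream clustering resolves.
    """
    if ds.n_samples < 3:
        raise InsufficientDataError("adjacency needs >=3 samples")
    X = ds.values.to_numpy()
    sds = X.std(axis=1)
    if np.any(sds == 0):
        gene = ds.genes[int(np.argmax(sds == 0))]
        raise ZeroVarianceError(f"gene {gene!r} has zero variance")
    base = np.corrcoef(X).astype(dtype, copy=False)
    np.clip(base, -1.0, 1.0, out=base)
    if params.adjacency_type == "signed":
        base += 1.0
        base *= 0.5
    else:
        np.abs(base, out=base)
    A = _int_power(base, params.beta)
    np.fill_diagonal(A, 1.0)
    np.clip(A, 0.0, 1.0, out=A)
    return A


def _int_power(base: np.ndarray, beta: int) -> np.ndarray:
    """Elementwise base**beta by repeated squaring (fast for large matrices).

    Values below 1e-30 are flushed to zero after each multiply: high powers
    of near-zero correlations otherwise land in the subnormal float range,
    which is orders of magnitude slower on common hardware and numerically
    irrelevant at the adjacency scale.
    """
    if not float(beta).is_integer():
        return base ** beta
    tiny = 1e-30

    def _flush(x: np.ndarray) -> np.ndarray:
        x[x < tiny] = 0.0
        return x

    beta = int(beta)
    result = np.ones_like(base)
    square = _flush(base.copy())
    while beta:
        if beta & 1:
            result = _flush(result * square)
        beta >>= 1
        if beta:
            square = _flush(square * square)
    return result


def topological_overlap(A: np.ndarray, validate: bool = True) -> np.ndarray:
    """Topological overlap matrix of a [0,1] adjacency with unit diagonal.

    TOM_ij = (sum_{u != i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij)
    with k_i the connectivity excluding the diagonal.  Pairs with a
    non-positive denominator (fully isolated) get TOM 0.  ``validate=False``
    skips the symmetry check for adjacencies the caller built itself.
    """
    A = np.asarray(A)
    if not np.issubdtype(A.dtype, np.floating):
        A = A.astype(float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if validate and not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    k = A.sum(axis=1) - np.diag(A)
    # (A @ A)_ij counts u = i and u = j once each as A_ij (diag is 1), so
    # subtracting one A_ij leaves sum_{u != i,j} A_iu A_uj + A_ij
    numer = A @ A
    numer -= A
    denom = np.minimum.outer(k, k)
    denom += 1.0
    denom -= A
    bad = denom <= 0
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        logger.warning("TOM: %d isolated pairs set to 0", n_bad // 2)
        denom[bad] = 1.0
    T = numer
    T /= denom
    if n_bad:
        T[bad] = 0.0
    np.fill_diagonal(T, 1.0)
    T += T.T.copy()
    T *= 0.5
    np.clip(T, 0.0, 1.0, out=T)
    return T


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------

def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ZeroVarianceError("cannot standardize a zero-variance gene")
    return (X - mu) / sd


def module_eigengene(ds: ExpressionDataset, genes, return_variance: bool = False):
    """First principal component of a module's standardized expression.

    Returns a unit-norm vector over samples whose correlation with the mean
    standardized module profile is >= 0.  With ``return_variance`` the
    fraction of variance explained by the component is returned too.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise InsufficientDataError("a module needs >= 2 genes")
    X = _standardize_rows(ds.values.loc[genes].to_numpy())
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if S[0] == 0:
        raise ZeroVarianceError("rank-0 module submatrix")
    v = Vt[0]
    mean_profile = X.mean(axis=0)
    c = float(np.dot(v, mean_profile))
    if c < 0:
        v = -v
    elif c == 0:
        # orthogonal to the mean profile: orient by first nonzero entry
        nz = np.flatnonzero(v)
        if nz.size and v[nz[0]] < 0:
            v = -v
    if return_variance:
        return v, float(S[0] ** 2 / np.sum(S ** 2))
    return v


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def _size_sorted_labels(clusters: dict[int, list[str]]) -> list[int]:
    """Cluster keys ordered by decreasing size, ties by smallest member gene."""
    return sorted(clusters, key=lambda c: (-len(clusters[c]), min(clusters[c])))


def detect_modules(ds: ExpressionDataset, params: NetworkParams | None = None) -> ModuleDecomposition:
    """Full module-detection pipeline on a filtered, normalized dataset."""
    params = params or NetworkParams()
    # float32 keeps the O(n^3) TOM matmul and the elementwise passes
    # tractable for ~10^4 genes; the ~1e-7 rounding is far below the
    # dissimilarity scale the clustering resolves
    A = adjacency_matrix(ds, params, dtype=np.float32)
    T = topological_overlap(A, validate=False)
    D = 1.0 - T.astype(np.float64)
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method="average")
    cut = params.cut_height_fraction * float(Z[:, 2].max())
    flat = fcluster(Z, t=cut, criterion="distance")

    genes = ds.genes
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, flat):
        clusters.setdefault(int(c), []).append(g)

    assignment: dict[str, str] = {g: UNASSIGNED for g in genes}
    members: dict[str, list[str]] = {}
    for i, key in enumerate(c for c in _size_sorted_labels(clusters)
                            if len(clusters[c]) >= params.min_module_size):
        label = f"M{i + 1}"
        members[label] = clusters[key]
        for g in clusters[key]:
            assignment[g] = label

    eigengenes = {m: module_eigengene(ds, gs) for m, gs in members.items()}
    merge_log: list[tuple[str, str, float]] = []

    # iterative closure: merge the closest eligible eigengene pair, recompute,
    # repeat until no pair is closer than the merge threshold
    while len(eigengenes) >= 2:
        labels = sorted(eigengenes)
        E = np.array([eigengenes[m] for m in labels])
        C = np.corrcoef(E)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(int(np.argmax(C)), C.shape)
        diss = 1.0 - C[i, j]
        if diss >= params.merge_diss_threshold:
            break
        a, b = labels[i], labels[j]
        keep, gone = (a, b) if len(members[a]) >= len(members[b]) else (b, a)
        merge_log.append((keep, gone, float(diss)))
        members[keep] = members[keep] + members[gone]
        del members[gone], eigengenes[gone]
        for g in members[keep]:
            assignment[g] = keep
        eigengenes[keep] = module_eigengene(ds, members[keep])

    # relabel by decreasing size for order-independent, deterministic names
    order = sorted(members, key=lambda m: (-len(members[m]), min(members[m])))
    rename = {old: f"M{i + 1}" for i, old in enumerate(order)}
    assignment = {g: rename.get(m, UNASSIGNED) for g, m in assignment.items()}
    eigengenes = {rename[m]: v for m, v in eigengenes.items()}
    merge_log = [(rename.get(a, a), b, d) for a, b, d in merge_log]
    return ModuleDecomposition(assignment, eigengenes, merge_log, samples=ds.samples)


# ---------------------------------------------------------------------------
# Module-trait association and enrichment
# ---------------------------------------------------------------------------

def _pearson_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def module_trait_relationships(decomp: ModuleDecomposition, trait) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a per-sample trait.

    Returns a DataFrame indexed by module with columns r, p, p_bonf and
    significant (adjusted p < 0.05).  Bonferroni is over the assigned
    modules.  A constant trait is an error.
    """
    trait = np.asarray(trait, dtype=float)
    modules = decomp.modules
    if not modules:
        return pd.DataFrame(columns=["r", "p", "p_bonf", "significant"])
    n = len(trait)
    if n != len(next(iter(decomp.eigengenes.values()))):
        raise ValueError("trait length must equal the sample count")
    if np.std(trait) == 0:
        raise ZeroVarianceError("trait vector is constant")
    m = len(modules)
    rows = []
    for mod in modules:
        e = decomp.eigengenes[mod]
        r = float(np.corrcoef(e, trait)[0, 1])
        p = _pearson_p(r, n)
        p_adj = min(1.0, m * p)
        rows.append((mod, r, p, p_adj, p_adj < 0.05))
    return pd.DataFrame(rows, columns=["module", "r", "p", "p_bonf", "significant"]
                        ).set_index("module")


def module_enrichment(module_genes, gene_sets: dict, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``module_genes`` in named sets.

    One-sided upper-tail p per set, Benjamini-Hochberg adjusted across sets.
    Gene sets are intersected with the universe first.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes) & universe
    names, ps, overlaps = [], [], []
    M, n_draw = len(universe), len(module)
    for name, genes in gene_sets.items():
        K = len(set(genes) & universe)
        k = len(set(genes) & module)
        p = float(stats.hypergeom.sf(k - 1, M, K, n_draw)) if K else 1.0
        names.append(name)
        ps.append(min(1.0, p))
        overlaps.append(k)
    if not names:
        return pd.DataFrame(columns=["overlap", "p", "p_bh"])
    p_bh = stats.false_discovery_control(ps, method="bh")
    out = pd.DataFrame({"overlap": overlaps, "p": ps, "p_bh": p_bh}, index=names)
    return out.sort_values(["p", "overlap"], ascending=[True, False])


def read_gene_sets_gmt(path) -> dict[str, list[str]]:
    """Read GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
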