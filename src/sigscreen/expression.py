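"""Expression-matrix I/O, sample QC, quantile normalization and gene filtering.

The in-memory container is :class:`ExpressionDataset`: a genes x samples
matrix (pandas DataFrame) plus a sample -> group annotation.  All operations
are pure functions returning new datasets; nothing mutates its input.

The file dialect is plain TSV (UTF-8, header row of sample IDs, first column
gene IDs, ``#``-prefixed comment lines ignored) so that fixtures stay
text-only and diffable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    FormatError,
    InsufficientDataError,
    MappingError,
    ZeroVarianceError,
)

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """A gene-by-sample real-valued expression matrix with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene/probe ID with sample IDs as columns.
        All entries must be finite.
    groups
        Mapping sample ID -> group label covering every sample.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise AnnotationError(f"samples missing from annotation: {missing}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise FormatError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_vector(self) -> pd.Series:
        """Group label per sample, in column order."""
        return pd.Series([self.groups[s] for s in self.samples], index=self.samples)

    def subset_genes(self, genes) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[list(genes)], dict(self.groups))

    def drop_samples(self, samples) -> "ExpressionDataset":
        keep = [s for s in self.samples if s not in set(samples)]
        groups = {s: self.groups[s] for s in keep}
        return ExpressionDataset(self.values[keep], groups)


@dataclass
class SampleQCReport:
    """Outcome of correlation-based sample QC.

    ``outliers`` holds every sample whose mean correlation with all other
    samples falls more than ``k`` sample standard deviations below the
    average of those means (single pass, no re-estimation after removal).
    """

    mean_correlation: dict[str, float]
    mean: float
    sd: float
    k: float
    outliers: set[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean_correlation": self.mean_correlation,
                "mean": self.mean,
                "sd": self.sd,
                "k": self.k,
                "outliers": sorted(self.outliers),
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    return df


def read_expression_matrix(path, annotation_path) -> ExpressionDataset:
    """Read a TSV expression matrix and a two-column sample annotation.

    The matrix has a header row of sample IDs and gene IDs in the first
    column; the annotation is ``sample<TAB>group`` with an arbitrary header.
    Raises :class:`FormatError` for duplicates or non-numeric cells and
    :class:`AnnotationError` when a sample lacks a group label.
    """
    try:
        mat = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                          float_precision="round_trip").astype(float)
    except ValueError:
        raw = _read_tsv(path)
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise FormatError(
                f"non-numeric value {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
                f"sample {raw.columns[j]!r}"
            ) from None
        raise FormatError(f"could not parse expression matrix {path}") from None
    if mat.isna().to_numpy().any():
        i, j = np.argwhere(mat.isna().to_numpy())[0]
        raise FormatError(f"missing value at gene {mat.index[i]!r}, sample {mat.columns[j]!r}")
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)

    ann = pd.read_csv(annotation_path, sep="\t", comment="#", dtype=str)
    if ann.shape[1] < 2:
        raise FormatError("annotation must have two columns: sample<TAB>group")
    groups = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
    missing = [s for s in mat.columns if s not in groups]
    if missing:
        raise AnnotationError(f"samples missing from annotation: {missing}")
    return ExpressionDataset(mat, {s: groups[s] for s in mat.columns})


def write_expression_matrix(ds: ExpressionDataset, path, annotation_path=None) -> None:
    """Write the matrix (and optionally the annotation) in the TSV dialect.

    Floats are written with 17 significant digits so a write/read round trip
    is bitwise exact.
    """
    ds.values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")
    if annotation_path is not None:
        ann = pd.DataFrame({"sample": ds.samples,
                            "group": [ds.groups[s] for s in ds.samples]})
        ann.to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def sample_qc(ds: ExpressionDataset, k: float = 3.0) -> SampleQCReport:
    """Flag samples whose mean inter-sample correlation is > k SD below average.

    Computed once on the full matrix; the flagged set is not re-estimated
    after removal.  Requires >= 3 samples and at least some within-sample
    variance (all-constant columns make Pearson correlation undefined).
    """
    if ds.n_samples < 3:
        raise InsufficientDataError(f"sample QC needs >=3 samples, got {ds.n_samples}")
    X = ds.values.to_numpy()
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = ds.samples[int(np.argmax(sds == 0))]
        raise ZeroVarianceError(f"sample {bad!r} has zero variance; correlation undefined")
    C = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(C, np.nan)
    mean_corr = np.nanmean(C, axis=1)
    mean = float(np.mean(mean_corr))
    sd = float(np.std(mean_corr, ddof=1))
    if sd == 0:
        # all samples equally correlated (e.g. identical columns): the
        # k-SD rule has no scale to work with
        raise ZeroVarianceError("inter-sample mean correlations are all identical; "
                                "outlier rule is undefined")
    thresh = mean - k * sd
    outliers = {s for s, m in zip(ds.samples, mean_corr) if m < thresh}
    return SampleQCReport(
        mean_correlation={s: float(m) for s, m in zip(ds.samples, mean_corr)},
        mean=mean,
        sd=sd,
        k=float(k),
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# Normalization and filtering
# ---------------------------------------------------------------------------

def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Force every sample onto the per-rank mean of the sorted columns.

    Tied values within a column receive the mean of the reference values
    across their tied ranks, so the within-column rank order (with ties)
    is preserved exactly.  Idempotent for tie-free matrices.
    """
    if ds.n_samples < 2:
        raise InsufficientDataError("quantile normalization needs >=2 samples")
    X = ds.values.to_numpy()
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # ties -> mean of the reference values at the tied ranks
        s = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    values = pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns)
    return ExpressionDataset(values, dict(ds.groups))


def select_most_variable_genes(ds: ExpressionDataset, n: int = 10000) -> ExpressionDataset:
    """Keep the ``n`` genes with the largest sample variance (ddof=1).

    Ties are broken by input order; if the dataset has fewer than ``n``
    genes, everything is kept and a warning is logged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ds.n_genes <= n:
        if ds.n_genes < n:
            logger.warning("requested %d genes but dataset has only %d; keeping all",
                           n, ds.n_genes)
        return ExpressionDataset(ds.values.copy(), dict(ds.groups))
    var = ds.values.to_numpy().var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")[:n]
    keep = np.sort(order)  # preserve input row order
    return ExpressionDataset(ds.values.iloc[keep], dict(ds.groups))


def collapse_probes_to_genes(ds: ExpressionDataset, mapping: dict[str, str]) -> ExpressionDataset:
    """Collapse probe rows to gene rows, keeping the max-variance probe per gene.

    ``mapping`` maps probe ID -> gene symbol.  Probes absent from the mapping
    are dropped (count logged).  Raises :class:`MappingError` when the mapping
    covers no probe in the dataset.
    """
    present = [p for p in ds.genes if p in mapping]
    if not present:
        raise MappingError("probe-to-gene mapping does not cover any probe in the dataset")
    dropped = ds.n_genes - len(present)
    if dropped:
        logger.info("dropping %d probes absent from the mapping", dropped)
    var = ds.values.loc[present].to_numpy().var(axis=1, ddof=1)
    best: dict[str, tuple[float, int, str]] = {}
    for i, probe in enumerate(present):
        gene = mapping[probe]
        v = var[i]
        # max variance wins; ties keep the earliest probe (stable policy)
        if gene not in best or v > best[gene][0]:
            best[gene] = (v, i, probe)
    chosen = sorted(best.values(), key=lambda t: t[1])
    rows = ds.values.loc[[c[2] for c in chosen]].copy()
    rows.index = pd.Index([mapping[c[2]] for c in chosen], name=ds.values.index.name)
    return ExpressionDataset(rows, dict(ds.groups))
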