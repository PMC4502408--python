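"""Expression-matrix container and preprocessing helpers.

The algorithms in this package operate on *linear-scale* (non-log)
intensities, because pairwise differences and pairwise fold changes are
defined on raw expression values.  The helpers here therefore accept and
return linear-scale matrices; log2 is used internally only (quantile
normalisation and probe collapsing are performed on the log2 scale, as is
conventional for microarray intensities, and back-transformed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPES = ("R", "S")


class MatrixLoadError(ValueError):
    """Raised when an expression matrix or annotation fails validation."""


@dataclass
class ExpressionMatrix:
    """A genes x samples table of non-negative linear-scale intensities.

    Parameters
    ----------
    values
        DataFrame with gene IDs as the index and sample IDs as columns.
        Entries are linear (non-log) intensities, all >= 0 and finite.
    phenotype
        Mapping from every sample ID to ``"R"`` (drug-resistant) or
        ``"S"`` (drug-sensitive).
    """

    values: pd.DataFrame
    phenotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise MatrixLoadError(f"duplicate gene IDs: {dupes[:5]}")
        if df.columns.has_duplicates:
            raise MatrixLoadError("duplicate sample IDs in header")
        arr = df.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            bad = df.index[~np.isfinite(arr).all(axis=1)][0]
            raise MatrixLoadError(f"non-finite value in gene row {bad!r}")
        if arr.size and (arr < 0).any():
            bad = df.index[(arr < 0).any(axis=1)][0]
            raise MatrixLoadError(f"negative intensity in gene row {bad!r}")
        missing = [s for s in df.columns if s not in self.phenotype]
        if missing:
            raise MatrixLoadError(f"samples without phenotype annotation: {missing}")
        bad_ph = {s: p for s, p in self.phenotype.items() if p not in PHENOTYPES}
        if bad_ph:
            raise MatrixLoadError(f"phenotype must be one of {PHENOTYPES}, got {bad_ph}")

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def samples_of(self, phenotype: str) -> list[str]:
        """Sample IDs carrying the given phenotype, in column order."""
        return [s for s in self.values.columns if self.phenotype.get(s) == phenotype]

    def column(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.columns:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return self.values[sample_id]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, dict(self.phenotype))


def read_annotation(source: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>phenotype`` table, or pass a mapping through."""
    if isinstance(source, Mapping):
        return dict(source)
    ann = pd.read_csv(source, sep="\t", header=None, names=["sample_id", "phenotype"],
                      dtype=str, comment="#")
    return dict(zip(ann["sample_id"].str.strip(), ann["phenotype"].str.strip()))


def read_matrix(path: str | Path,
                annotation: str | Path | Mapping[str, str]) -> ExpressionMatrix:
    """Load an expression matrix (TSV/CSV, header = sample IDs, first column = gene IDs).

    Rows with any missing value are dropped (with a logged count); duplicate
    gene IDs are collapsed by the arithmetic mean of their log2 values.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # malformed header / ragged rows
        raise MatrixLoadError(f"cannot parse {path}: {exc}") from exc
    if df.columns.empty:
        raise MatrixLoadError(f"{path}: header row contains no sample IDs")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise MatrixLoadError(f"{path}: non-numeric expression value ({exc})") from exc

    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d gene rows with missing values", n_missing)
        df = df.dropna(axis=0)

    if (df.to_numpy() < 0).any():
        bad = df.index[(df.to_numpy() < 0).any(axis=1)][0]
        raise MatrixLoadError(f"{path}: negative intensity in gene row {bad!r}")

    if df.index.has_duplicates:
        # collapse duplicate gene IDs: arithmetic mean on the log2 scale
        with np.errstate(divide="ignore"):
            logdf = np.log2(df)
        df = 2.0 ** logdf.groupby(level=0, sort=False).mean()

    phenotype = read_annotation(annotation)
    unknown = [s for s in phenotype if s not in df.columns]
    if unknown:
        raise MatrixLoadError(f"annotation names unknown samples: {unknown}")
    phenotype = {s: phenotype[s] for s in df.columns if s in phenotype}
    return ExpressionMatrix(df, phenotype)


def write_matrix(m: ExpressionMatrix, path: str | Path,
                 annotation_path: str | Path | None = None) -> None:
    """Write the matrix as TSV; optionally write the phenotype annotation alongside."""
    m.values.to_csv(path, sep="\t", index_label="gene_id")
    if annotation_path is not None:
        with open(annotation_path, "w") as fh:
            for s in m.sample_ids:
                fh.write(f"{s}\t{m.phenotype[s]}\n")


def floor_values(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Replace every intensity below ``floor`` by ``floor`` (guards fold changes)."""
    if not floor > 0:
        raise ValueError(f"floor must be positive, got {floor}")
    return m.with_values(m.values.clip(lower=floor))


def quantile_normalize_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalise on the log2 scale; return on the linear scale.

    After normalisation every sample shares the identical sorted
    distribution of log2 intensities, equal to the per-rank mean across
    samples.  Ties share the mean of the ranks they occupy (average-rank
    convention).
    """
    if (m.values.to_numpy() <= 0).any():
        raise ValueError("zero or negative value present; apply floor_values first")
    log = np.log2(m.values.to_numpy(dtype=float))
    order = np.sort(log, axis=0)
    mean_dist = order.mean(axis=1)  # per-rank mean across samples
    out = np.empty_like(log)
    for j in range(log.shape[1]):
        col = log[:, j]
        ranks = pd.Series(col).rank(method="average").to_numpy() - 1.0
        # fractional ranks (ties) interpolate between adjacent rank means
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        frac = ranks - lo
        out[:, j] = mean_dist[lo] * (1 - frac) + mean_dist[hi] * frac
    values = pd.DataFrame(2.0 ** out, index=m.values.index, columns=m.values.columns)
    return m.with_values(values)


def collapse_probes(m: ExpressionMatrix,
                    probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe rows to gene rows by arithmetic mean of log2 values.

    Probes absent from the mapping are dropped with a logged count.  A gene
    measured by a single probe keeps its value exactly.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    keep = [p for p in m.values.index if p in probe_to_gene]
    n_dropped = m.n_genes - len(keep)
    if n_dropped:
        logger.warning("dropping %d probes without gene mapping", n_dropped)
    if not keep:
        raise ValueError("no probes left after applying mapping")
    sub = m.values.loc[keep]
    genes = pd.Index([probe_to_gene[p] for p in keep], name="gene_id")
    counts = pd.Series(1, index=genes).groupby(level=0, sort=False).sum()
    with np.errstate(divide="ignore"):
        logsub = np.log2(sub.set_axis(genes, axis=0))
    collapsed = 2.0 ** logsub.groupby(level=0, sort=False).mean()
    # exact preservation for single-probe genes (avoid log round-trip error)
    single = counts.index[counts == 1]
    collapsed.loc[single] = sub.set_axis(genes, axis=0).loc[single]
    return m.with_values(collapsed)
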