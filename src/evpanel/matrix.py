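"""Protein-by-sample abundance matrices and label-free quantification primitives.

The central container is :class:`AbundanceMatrix`: a nonnegative protein-by-
sample table (rows keyed by gene symbol) together with a case/control label
per sample and a scale tag (``linear`` spectral-count-like values or
``log2``-transformed intensities).  Everything downstream — differential
expression, clustering, NSAF, panel fitting — consumes this object.

The quantification primitives implemented here:

* identifier collapsing: accessions mapping to the same gene symbol are
  summed on the linear scale (spectral counts are additive evidence);
* log2 transform with a pseudocount so undetected proteins (exact zeros)
  map to log2 value 0;
* high/low abundance partitioning at a log2-intensity cutoff (default 12),
  where *high* means the per-protein mean is strictly above the cutoff;
* NSAF, the normalized spectral abundance factor
  ``NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)`` per sample, with ``L_i``
  the protein length in amino acids.  NSAF values sum to 1 within a sample.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CASE = "case"
CTRL = "ctrl"
VALID_GROUPS = frozenset({CASE, CTRL})

__all__ = [
    "CASE",
    "CTRL",
    "AbundanceMatrix",
    "AbundancePartition",
    "NsafTable",
    "MatrixFormatError",
    "read_abundance_matrix",
    "write_abundance_matrix",
    "collapse_by_gene",
    "log2_transform",
    "partition_by_abundance",
    "compute_nsaf",
]


class MatrixFormatError(ValueError):
    """Raised when an abundance table violates the format contract."""


@dataclasses.dataclass
class AbundanceMatrix:
    """Nonnegative protein-by-sample quantification table with group labels.

    Parameters
    ----------
    data
        ``genes x samples`` table; the index holds unique gene symbols.
    groups
        Mapping ``sample -> {"case", "ctrl"}`` aligned with ``data.columns``.
    scale
        ``"linear"`` (raw nonnegative abundances) or ``"log2"``.
    """

    data: pd.DataFrame
    groups: pd.Series
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data).astype(float)
        self.groups = pd.Series(self.groups).reindex(self.data.columns)
        if self.scale not in ("linear", "log2"):
            raise MatrixFormatError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate gene symbols: {dups}")
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise MatrixFormatError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - VALID_GROUPS
        if bad:
            raise MatrixFormatError(f"unknown group labels: {sorted(bad)}")
        if self.scale == "linear":
            vals = self.data.to_numpy()
            if np.isnan(vals).any() or (vals < 0).any():
                g, s = np.argwhere(np.isnan(vals) | (vals < 0))[0]
                raise MatrixFormatError(
                    "negative or missing value at gene "
                    f"{self.data.index[g]!r}, sample {self.data.columns[s]!r}"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CASE])

    @property
    def ctrl_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CTRL])

    def values_for(self, gene: str, group: str) -> np.ndarray:
        cols = self.case_samples if group == CASE else self.ctrl_samples
        return self.data.loc[gene, cols].to_numpy(dtype=float)

    def detected_genes(self, group: str | None = None) -> set[str]:
        """Genes with a nonzero value in >= 1 sample of ``group`` (or any)."""
        if group is None:
            cols = self.samples
        else:
            cols = self.case_samples if group == CASE else self.ctrl_samples
        sub = self.data[cols]
        return set(sub.index[(sub > 0).any(axis=1)])

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.groups.copy(), self.scale)


@dataclasses.dataclass
class AbundancePartition:
    """Exhaustive, exclusive split of genes at a mean log2-intensity cutoff."""

    cutoff: float
    high: set[str]
    low: set[str]

    @property
    def n_high(self) -> int:
        return len(self.high)

    @property
    def n_low(self) -> int:
        return len(self.low)


@dataclasses.dataclass
class NsafTable:
    """Per-sample NSAF values (genes x samples); columns sum to 1.

    ``length_normalized`` is False when no length table was available and a
    unit length was used for every gene, in which case the values are plain
    normalized spectral fractions.
    """

    values: pd.DataFrame
    lengths: Mapping[str, float] | None
    length_normalized: bool

    def sample_means(self, samples: Iterable[str]) -> pd.Series:
        return self.values[list(samples)].mean(axis=1)


# ---------------------------------------------------------------------------
# I/O — TSV dialect: row 1 sample IDs, row 2 group labels, then gene rows.
# ---------------------------------------------------------------------------

def read_abundance_matrix(path, sep: str = "\t") -> AbundanceMatrix:
    """Read an abundance matrix from the two-header-row TSV dialect.

    Row 1: ``gene<sep>S1<sep>S2...``; row 2: ``group<sep>case<sep>ctrl...``;
    each following row: gene symbol plus one nonnegative value per sample.
    Raises :class:`MatrixFormatError` naming the offending row/column on
    malformed headers, unknown group labels, negative values, or duplicate
    gene rows.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        group_row = fh.readline().rstrip("\n").split(sep)
    if len(header) < 2:
        raise MatrixFormatError(f"{path}: header row has no sample columns")
    if len(group_row) != len(header):
        raise MatrixFormatError(
            f"{path}: group row has {len(group_row)} fields, expected {len(header)}"
        )
    samples = header[1:]
    groups = pd.Series(group_row[1:], index=samples)
    bad = set(groups) - VALID_GROUPS
    if bad:
        raise MatrixFormatError(f"{path}: unknown group labels {sorted(bad)} in row 2")
    body = pd.read_csv(path, sep=sep, skiprows=2, header=None, index_col=0)
    if body.shape[1] != len(samples):
        raise MatrixFormatError(f"{path}: data rows do not match header width")
    body.columns = samples
    body.index.name = "gene"
    body.index = body.index.astype(str)
    try:
        return AbundanceMatrix(body, groups, scale="linear")
    except MatrixFormatError as err:
        raise MatrixFormatError(f"{path}: {err}") from err


def write_abundance_matrix(matrix: AbundanceMatrix, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["gene", *matrix.samples]) + "\n")
        fh.write(sep.join(["group", *matrix.groups.tolist()]) + "\n")
        for gene, row in matrix.data.iterrows():
            fh.write(sep.join([str(gene), *(format(v, ".10g") for v in row)]) + "\n")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def collapse_by_gene(matrix: AbundanceMatrix, id_to_gene: Mapping[str, str]) -> AbundanceMatrix:
    """Sum rows whose identifiers map to the same gene symbol.

    Only valid on the linear scale (sums of log intensities are meaningless).
    Every row identifier must have a mapping entry.
    """
    if matrix.scale != "linear":
        raise ValueError("collapse_by_gene requires a linear-scale matrix")
    missing = [i for i in matrix.data.index if i not in id_to_gene]
    if missing:
        raise KeyError(f"no gene mapping for identifiers: {missing}")
    genes = [id_to_gene[i] for i in matrix.data.index]
    collapsed = matrix.data.groupby(pd.Index(genes, name="gene"), sort=True).sum()
    return AbundanceMatrix(collapsed, matrix.groups, scale="linear")


def log2_transform(matrix: AbundanceMatrix, offset: float = 1.0) -> AbundanceMatrix:
    """``value -> log2(value + offset)``; default pseudocount 1 maps 0 -> 0."""
    if matrix.scale == "log2":
        raise ValueError("matrix is already log2-scaled")
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    return AbundanceMatrix(np.log2(matrix.data + offset), matrix.groups, scale="log2")


def partition_by_abundance(matrix: AbundanceMatrix, cutoff: float = 12.0) -> AbundancePartition:
    """Split genes by mean log2 intensity: strictly above ``cutoff`` -> high,
    equal-or-below -> low."""
    if matrix.scale != "log2":
        raise ValueError("partition_by_abundance requires a log2-scale matrix")
    if matrix.data.empty:
        raise ValueError("cannot partition an empty matrix")
    means = matrix.data.mean(axis=1)
    high = set(means.index[means > cutoff])
    low = set(means.index[means <= cutoff])
    return AbundancePartition(cutoff=cutoff, high=high, low=low)


def compute_nsaf(
    matrix: AbundanceMatrix,
    lengths: Mapping[str, float] | None = None,
) -> NsafTable:
    """Normalized spectral abundance factor per sample.

    For each sample, ``NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)``.  With no
    length table, unit lengths are used and the result is a plain normalized
    spectral fraction (``length_normalized=False``).  A sample whose counts
    are all zero yields all-zero NSAF with a warning.
    """
    if matrix.scale != "linear":
        raise ValueError("compute_nsaf requires linear-scale counts")
    counts = matrix.data
    if lengths is None:
        length_vec = pd.Series(1.0, index=counts.index)
        normalized = False
    else:
        length_vec = pd.Series({g: float(lengths.get(g, np.nan)) for g in counts.index})
        nonzero = (counts > 0).any(axis=1)
        missing = sorted(counts.index[nonzero & length_vec.isna()])
        if missing:
            raise KeyError(f"missing protein length for nonzero-count genes: {missing}")
        if (length_vec.dropna() <= 0).any():
            bad = sorted(length_vec.index[length_vec <= 0])
            raise ValueError(f"nonpositive protein lengths: {bad}")
        length_vec = length_vec.fillna(1.0)  # all-zero genes: length irrelevant
        normalized = True
    rate = counts.div(length_vec, axis=0)
    totals = rate.sum(axis=0)
    zero_samples = list(totals.index[totals == 0])
    if zero_samples:
        warnings.warn(f"samples with all-zero counts get all-zero NSAF: {zero_samples}")
        totals = totals.replace(0, 1.0)
    nsaf = rate.div(totals, axis=1)
    return NsafTable(values=nsaf, lengths=lengths, length_normalized=normalized)
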