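"""Count-matrix containers, CPM transforms, expression filtering and a
paired differential-expression test.

The paired test is a deliberately simple stand-in for a count-model GLM: it
computes per-gene log2CPM differences within subject pairs (case minus
control) and applies a paired t-test, with Benjamini-Hochberg FDR across
genes.  Every downstream stage consumes only ``(log2fc, fdr)`` pairs, so
externally computed differential-expression tables can be substituted via
:func:`load_de_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "filter_low_expression",
    "log2cpm",
    "paired_de",
    "benjamini_hochberg",
    "load_de_table",
]

#: columns expected in a sample-metadata table (indexed by sample id)
META_COLUMNS = ("subject", "cell_type", "dex_group")


@dataclass
class CountMatrix:
    """Gene-by-sample integer counts with optional per-sample metadata.

    ``values`` is a DataFrame whose index are unique gene ids and whose
    columns are unique sample ids.  ``sample_meta``, when present, is indexed
    by sample id with columns ``subject``, ``cell_type``, ``dex_group``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = sorted(self.values.columns[self.values.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("count matrix contains non-integer entries")
            self.values = self.values.round().astype(np.int64)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")
        if self.sample_meta is not None:
            missing = set(self.values.columns) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        """Counts-per-million on the matrix's own library sizes."""
        lib = self.library_sizes.to_numpy(dtype=float)
        if (lib <= 0).any():
            bad = list(self.values.columns[lib <= 0])
            raise ValueError(f"samples with zero library size: {bad}")
        return self.values / lib * 1e6


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log2CPM values (derived from a :class:`CountMatrix`)."""

    values: pd.DataFrame
    pseudocount: float = 1.0
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def read_count_matrix(
    path: str | Path,
    format: str = "tsv",
    meta_path: str | Path | None = None,
) -> CountMatrix:
    """Read a gene-by-sample count matrix from TSV or MatrixMarket.

    TSV layout: gene ids in the first column, sample ids in the header.
    MatrixMarket layout: ``<stem>.mtx`` plus ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` index files (one id per line).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx":
        from scipy.io import mmread

        raw = mmread(path)
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format: {format!r}")
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(df, sample_meta=meta)


def write_count_matrix(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write counts as TSV (genes as rows) or MatrixMarket triplets."""
    path = Path(path)
    if format == "tsv":
        cm.values.to_csv(path, sep="\t")
    elif format == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(cm.values.to_numpy()))
        stem = path.with_suffix("")
        Path(f"{stem}.genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format: {format!r}")
    if cm.sample_meta is not None and format == "tsv":
        cm.sample_meta.to_csv(path.with_suffix(".meta.tsv"), sep="\t")


def filter_low_expression(
    cm: CountMatrix, cpm_min: float = 1.0, min_samples: int = 3
) -> CountMatrix:
    """Remove genes not expressed above ``cpm_min`` CPM in more than
    ``min_samples`` samples.

    A gene is kept iff its CPM exceeds ``cpm_min`` (strictly) in strictly
    more than ``min_samples`` samples, i.e. in at least ``min_samples + 1``.
    CPM is computed on the unfiltered library sizes, so the filter is
    idempotent.
    """
    if cm.values.empty:
        raise ValueError("empty count matrix")
    n_pass = (cm.cpm() > cpm_min).sum(axis=1)
    keep = n_pass > min_samples
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return CountMatrix(cm.values.loc[keep], sample_meta=cm.sample_meta)


def log2cpm(cm: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + pseudocount) per entry, using per-sample library sizes."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = np.log2(cm.cpm() + pseudocount)
    return ExpressionMatrix(vals, pseudocount=pseudocount, sample_meta=cm.sample_meta)


def paired_de(
    em: ExpressionMatrix,
    pairing: Mapping[str, tuple[str, str]],
) -> pd.DataFrame:
    """Paired differential expression on log2CPM.

    ``pairing`` maps subject id to its ``(case_sample, control_sample)``
    columns.  Returns one row per gene with columns ``log2fc`` (mean of
    per-subject case-minus-control differences), ``pvalue`` (two-sided
    paired t-test), ``fdr`` (Benjamini-Hochberg over all genes) and
    ``degenerate`` (True where the differences had zero variance but a
    nonzero mean, for which the p-value is set to the smallest positive
    float).  Genes whose differences are identically zero get p-value 1.
    """
    if len(pairing) < 2:
        raise ValueError("paired test requires at least 2 subject pairs")
    cases, controls = zip(*pairing.values())
    for s in (*cases, *controls):
        if s not in em.values.columns:
            raise KeyError(f"sample {s!r} not in expression matrix")
    diffs = em.values[list(cases)].to_numpy() - em.values[list(controls)].to_numpy()
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    pvalue = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    degenerate = zero_var & (mean != 0)
    pvalue[zero_var & (mean == 0)] = 1.0
    pvalue[degenerate] = np.finfo(float).tiny
    out = pd.DataFrame(
        {
            "log2fc": mean,
            "pvalue": pvalue,
            "fdr": benjamini_hochberg(pvalue),
            "degenerate": degenerate,
        },
        index=em.values.index.rename("gene"),
    )
    return out


def benjamini_hochberg(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def load_de_table(
    path: str | Path,
    gene_col: str,
    log2fc_col: str,
    fdr_col: str,
    pvalue_col: str | None = None,
    sheet: str | int | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Load an externally computed differential-expression table.

    Accepts XLSX (``sheet`` selects the worksheet), CSV or TSV.  The result
    is indexed by gene with columns ``log2fc``, ``fdr`` and optionally
    ``pvalue``/``group`` — the shape :func:`paired_de` produces, so either
    source feeds the attenuation and ranking stages interchangeably.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        raw = pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        raw = pd.read_csv(path, sep=sep)
    cols = {gene_col: "gene", log2fc_col: "log2fc", fdr_col: "fdr"}
    if pvalue_col is not None:
        cols[pvalue_col] = "pvalue"
    missing = set(cols) - set(raw.columns)
    if missing:
        raise KeyError(f"columns not found in {path.name}: {sorted(missing)}")
    out = raw.rename(columns=cols).set_index("gene")[list(cols.values())[1:]]
    if group is not None:
        out["group"] = group
    return out
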