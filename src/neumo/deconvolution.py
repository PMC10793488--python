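"""Guide-matrix construction and semi-supervised (masked) NMF deconvolution.

A guide matrix is a binary gene-by-state table: 1 where a gene is a marker
highly expressed in that state, 0 elsewhere; each retained gene marks
exactly one state.  The deconvolution factorizes a nonnegative linear-scale
expression matrix ``X (genes x samples)`` as ``S @ F`` with ``S`` a
nonnegative signature matrix forced to zero wherever the guide is zero, and
``F`` the per-sample state abundances, reported on the unit simplex.

Fitting minimizes the squared Frobenius reconstruction error with classic
multiplicative updates; because the signature is initialized on the mask
and multiplicative updates preserve zeros, the mask is satisfied exactly at
every iteration (an explicit clamp guards against numerical drift).
Because the mixing scale of each state is not identifiable from ``X``
alone, signature columns are normalized to a common total after fitting and
the compensating scale is absorbed into ``F`` before the simplex
normalization — the convention matching generators whose state signatures
carry equal total signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GuideMatrix",
    "DeconvolutionFit",
    "build_guide_matrix",
    "read_guide_matrix",
    "write_guide_matrix",
    "fit_semisupervised_nmf",
    "state_fraction",
]

_EPS = 1e-12


@dataclass
class GuideMatrix:
    """Binary gene-by-state marker matrix."""

    values: pd.DataFrame  # genes x states, entries in {0, 1}
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("guide entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        rowsum = arr.sum(axis=1)
        if (rowsum != 1).any():
            bad = list(self.values.index[rowsum != 1])
            raise ValueError(f"each gene must mark exactly one state; offenders: {bad}")
        colsum = arr.sum(axis=0)
        if (colsum == 0).any():
            bad = list(self.values.columns[colsum == 0])
            raise ValueError(f"states without markers: {bad}")

    @property
    def states(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def markers(self, state: str) -> frozenset[str]:
        col = self.values[state]
        return frozenset(col.index[col == 1])


def build_guide_matrix(marker_table: pd.DataFrame, cutoff: float = 0.58) -> GuideMatrix:
    """Threshold a per-state log2 fold-enrichment table into a guide matrix.

    A gene gets a 1 for a state iff its enrichment for that state is at
    least ``cutoff``.  Genes passing for more than one state are ambiguous
    markers and dropped with a warning; genes passing for none are dropped
    silently.  A state left without markers is an error.
    """
    if marker_table.shape[1] < 2:
        raise ValueError("marker table must cover at least 2 states")
    passing = (marker_table >= cutoff).astype(np.int8)
    n_pass = passing.sum(axis=1)
    ambiguous = list(marker_table.index[n_pass > 1])
    if ambiguous:
        warnings.warn(f"dropping ambiguous markers (pass cutoff for several states): {ambiguous}",
                      stacklevel=2)
    keep = n_pass == 1
    guide = passing.loc[keep]
    empty = [c for c in guide.columns if guide[c].sum() == 0]
    if empty:
        raise ValueError(f"no marker passes the cutoff for states: {empty}")
    return GuideMatrix(guide, provenance={"cutoff": float(cutoff),
                                          "n_ambiguous_dropped": len(ambiguous)})


def read_guide_matrix(path: str | Path) -> GuideMatrix:
    """Read a guide matrix TSV: gene id column then one 0/1 column per state."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GuideMatrix(df, provenance={"path": str(path)})


def write_guide_matrix(guide: GuideMatrix, path: str | Path) -> None:
    guide.values.to_csv(path, sep="\t")


@dataclass
class DeconvolutionFit:
    """Masked-NMF fit: signatures, simplex fractions and loss traces."""

    signatures: pd.DataFrame  # genes x states, zero where guide is zero
    fractions: pd.DataFrame  # states x samples, columns sum to 1
    loss_traces: list[np.ndarray]  # one per restart
    best_restart: int
    converged: bool
    n_iter: int
    seed: int


def _mu_nmf(
    x: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, int]:
    """One multiplicative-update run from a random masked initialization."""
    n_genes, n_samples = x.shape
    n_states = mask.shape[1]
    s = mask * rng.uniform(0.1, 1.0, size=(n_genes, n_states))
    f = rng.uniform(0.1, 1.0, size=(n_states, n_samples))
    scale = x.mean() or 1.0
    s *= np.sqrt(scale)
    f *= np.sqrt(scale)
    losses = np.empty(max_iter + 1)
    recon = s @ f
    losses[0] = ((x - recon) ** 2).sum()
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        s *= (x @ f.T) / (s @ (f @ f.T) + _EPS)
        s *= mask  # exact mask satisfaction (multiplicative updates keep zeros)
        f *= (s.T @ x) / ((s.T @ s) @ f + _EPS)
        recon = s @ f
        losses[it] = ((x - recon) ** 2).sum()
        denom = losses[it - 1] if losses[it - 1] > 0 else 1.0
        if abs(losses[it - 1] - losses[it]) / denom < tol:
            converged = True
            break
    return s, f, losses[: it + 1], converged, it


def fit_semisupervised_nmf(
    expr: pd.DataFrame,
    guide: GuideMatrix,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> DeconvolutionFit:
    """Fit masked NMF on the guide genes of a nonnegative expression matrix.

    ``expr`` is genes x samples on a linear scale (e.g. CPM), restricted to
    (a subset of) the guide's genes.  The best of ``n_restarts`` seeded
    random restarts by final loss is returned.  Output fractions are
    simplex-normalized per sample after signature columns are scaled to a
    common total.
    """
    missing = set(expr.index) - set(guide.genes)
    if missing:
        raise ValueError(f"expression genes not in the guide: {sorted(missing)}")
    x = expr.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("expression matrix must be nonnegative")
    zero_cols = list(expr.columns[x.sum(axis=0) == 0])
    if zero_cols:
        raise ValueError(f"samples with all-zero expression: {zero_cols}")
    mask = guide.values.loc[expr.index].to_numpy(dtype=float)
    if (mask.sum(axis=0) == 0).any():
        bad = [c for c, tot in zip(guide.states, mask.sum(axis=0)) if tot == 0]
        raise ValueError(f"no marker of states {bad} present in the expression matrix")

    ss = np.random.SeedSequence(seed)
    runs = []
    for child in ss.spawn(max(1, n_restarts)):
        runs.append(_mu_nmf(x, mask, np.random.default_rng(child), max_iter, tol))
    best = int(np.argmin([r[2][-1] for r in runs]))
    s, f, _, converged, n_iter = runs[best]

    # resolve per-state scale: equalize signature column totals, absorb into F
    col_tot = s.sum(axis=0)
    col_tot = np.where(col_tot <= 0, 1.0, col_tot)
    f_scaled = f * col_tot[:, None]
    frac = f_scaled / np.maximum(f_scaled.sum(axis=0, keepdims=True), _EPS)
    sig = s / col_tot

    return DeconvolutionFit(
        signatures=pd.DataFrame(sig, index=expr.index, columns=guide.states),
        fractions=pd.DataFrame(frac, index=guide.states, columns=expr.columns),
        loss_traces=[r[2] for r in runs],
        best_restart=best,
        converged=converged,
        n_iter=n_iter,
        seed=seed,
    )


def state_fraction(fit: DeconvolutionFit, state: str) -> pd.Series:
    """Per-sample mixing fraction of one state."""
    if state not in fit.fractions.index:
        raise KeyError(f"unknown state {state!r}; states: {list(fit.fractions.index)}")
    return fit.fractions.loc[state]
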