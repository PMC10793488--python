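"""Synthetic data generators with known ground truth.

Three generators cover the input types the pipeline consumes:

* :func:`simulate_paired_counts` — paired case/control (MDSC vs monocyte)
  negative-binomial counts for two exposure groups, with planted fold
  changes and a multiplicative attenuation of those fold changes in the
  exposed group;
* :func:`simulate_mixtures` — linear-scale expression profiles mixed from
  guide-respecting state signatures with Dirichlet fractions, for testing
  guided NMF deconvolution;
* :func:`simulate_cells` — toy single-cell counts with discrete planted
  states and disjoint marker sets, for module scores and stability sweeps.

All generators are deterministic given their seed and echo their parameters
so a run can be reproduced from its sidecar alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix, write_count_matrix

if TYPE_CHECKING:  # pragma: no cover
    from .deconvolution import GuideMatrix

__all__ = [
    "SimulatedPairedStudy",
    "SimulatedMixtureSet",
    "SimulatedCellPopulation",
    "simulate_paired_counts",
    "simulate_mixtures",
    "simulate_cells",
]


@dataclass
class SimulatedPairedStudy:
    """Paired-design count simulation with its ground truth.

    Each subject contributes exactly one MDSC and one monocyte sample, and
    belongs to either the DEX-exposed ("Yes") or unexposed ("No") group.
    ``truth`` records, per gene, whether it was planted as differentially
    expressed, its true log2 fold change in each group, and the dispersion
    used.  For non-DE genes the true log2FC is exactly 0.
    """

    counts: pd.DataFrame  # genes x samples, integer
    sample_meta: pd.DataFrame  # indexed by sample id: subject, cell_type, dex_group
    truth: pd.DataFrame  # indexed by gene: is_de, log2fc_no, log2fc_yes, dispersion
    params: dict = field(default_factory=dict)
    seed: int = 0

    def count_matrix(self) -> CountMatrix:
        return CountMatrix(self.counts, sample_meta=self.sample_meta)

    def pairing(self, dex_group: str) -> dict[str, tuple[str, str]]:
        """Subject -> (MDSC sample, Mono sample) map for one exposure group."""
        meta = self.sample_meta[self.sample_meta["dex_group"] == dex_group]
        out: dict[str, tuple[str, str]] = {}
        for subj, grp in meta.groupby("subject"):
            case = grp.index[grp["cell_type"] == "MDSC"][0]
            ctrl = grp.index[grp["cell_type"] == "Mono"][0]
            out[str(subj)] = (case, ctrl)
        return out

    def write(self, outdir: str | Path, format: str = "tsv") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_count_matrix(self.count_matrix(), outdir / f"counts.{format}", format=format)
        self.sample_meta.to_csv(outdir / "sample_meta.tsv", sep="\t")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t")
        sidecar = {"seed": self.seed, **self.params}
        (outdir / "params.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def _check_count(name: str, value: int) -> int:
    if not isinstance(value, (int, np.integer)) or isinstance(value, bool) or value < 0:
        raise ValueError(f"{name} must be a nonnegative integer, got {value!r}")
    return int(value)


def simulate_paired_counts(
    n_genes: int = 2000,
    n_pairs_yes: int = 6,
    n_pairs_no: int = 12,
    de_fraction: float = 0.2,
    mean_abs_log2fc: float = 2.0,
    attenuation_factor: float = 0.5,
    dispersion: float = 0.1,
    lib_size: int = 1_000_000,
    seed: int = 0,
) -> SimulatedPairedStudy:
    """Simulate paired MDSC/monocyte counts with planted attenuated effects.

    Counts follow a negative binomial with mean ``mu`` and variance
    ``mu + dispersion * mu**2``.  A lognormal subject factor multiplies both
    samples of a pair, inducing the within-pair correlation the paired test
    exploits.  DE genes receive a signed log2FC with magnitude drawn
    uniformly in [0.5, 1.5] x ``mean_abs_log2fc`` in the unexposed group;
    the exposed group's log2FC is that value times ``attenuation_factor``.
    The fold change is split symmetrically between MDSC and monocyte means.
    """
    n_genes = _check_count("n_genes", n_genes)
    n_pairs_yes = _check_count("n_pairs_yes", n_pairs_yes)
    n_pairs_no = _check_count("n_pairs_no", n_pairs_no)
    lib_size = _check_count("lib_size", lib_size)
    if lib_size <= 0:
        raise ValueError("lib_size must be positive")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if not 0.0 < attenuation_factor <= 1.0:
        raise ValueError("attenuation_factor must lie in (0, 1]")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]

    # baseline relative abundance: lognormal, normalized to sum 1
    base = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    base /= base.sum()

    n_de = int(round(de_fraction * n_genes))
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[rng.choice(n_genes, size=n_de, replace=False)] = True
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    magnitude = mean_abs_log2fc * rng.uniform(0.5, 1.5, size=n_genes)
    log2fc_no = np.where(is_de, sign * magnitude, 0.0)
    log2fc_yes = log2fc_no * attenuation_factor

    subjects, cell_types, groups, cols = [], [], [], []
    mus = []
    for group, n_pairs, fc in (("Yes", n_pairs_yes, log2fc_yes), ("No", n_pairs_no, log2fc_no)):
        for p in range(n_pairs):
            subj = f"{group}{p:02d}"
            subj_factor = rng.lognormal(mean=0.0, sigma=0.2, size=n_genes)
            for cell, shift in (("MDSC", +0.5), ("Mono", -0.5)):
                rel = base * subj_factor * 2.0 ** (shift * fc)
                mu = rel / rel.sum() * lib_size
                mus.append(mu)
                cols.append(f"{subj}_{cell}")
                subjects.append(subj)
                cell_types.append(cell)
                groups.append(group)
    mu_mat = np.column_stack(mus)
    # NB in (n, p) form: n = 1/dispersion, p = n / (n + mu)
    nb_n = 1.0 / dispersion
    counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu_mat))

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=cols)
    meta = pd.DataFrame(
        {"subject": subjects, "cell_type": cell_types, "dex_group": groups},
        index=pd.Index(cols, name="sample"),
    )
    truth = pd.DataFrame(
        {
            "is_de": is_de,
            "log2fc_no": log2fc_no,
            "log2fc_yes": log2fc_yes,
            "attenuation_factor": np.where(is_de, attenuation_factor, np.nan),
            "dispersion": dispersion,
        },
        index=pd.Index(genes, name="gene"),
    )
    params = dict(
        n_genes=n_genes,
        n_pairs_yes=n_pairs_yes,
        n_pairs_no=n_pairs_no,
        de_fraction=de_fraction,
        mean_abs_log2fc=mean_abs_log2fc,
        attenuation_factor=attenuation_factor,
        dispersion=dispersion,
        lib_size=lib_size,
    )
    return SimulatedPairedStudy(counts_df, meta, truth, params=params, seed=seed)


@dataclass
class SimulatedMixtureSet:
    """Linear-scale mixtures of state signatures with known fractions.

    ``expression = signatures @ true_fractions`` plus truncated Gaussian
    noise; signature columns are scaled to a common total so the mixing
    fractions are identifiable up to the simplex normalization the
    deconvolution reports.
    """

    expression: pd.DataFrame  # genes x samples, nonnegative
    true_fractions: pd.DataFrame  # states x samples, columns on the simplex
    signatures: pd.DataFrame  # genes x states, nonnegative, guide-masked
    noise_sd: float
    seed: int


def simulate_mixtures(
    guide: "GuideMatrix",
    n_samples: int = 50,
    alpha: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    fractions: np.ndarray | None = None,
) -> SimulatedMixtureSet:
    """Generate mixture expression from guide-respecting signatures.

    Signatures are drawn uniform-positive where the guide allows a marker
    and are exactly zero elsewhere; each signature column is rescaled to the
    same total signal so fractions are recoverable.  Fractions are
    Dirichlet(``alpha``) unless given explicitly (states x samples).
    """
    n_samples = _check_count("n_samples", n_samples)
    mask = guide.values.to_numpy(dtype=float)
    if mask.shape[1] < 2:
        raise ValueError("guide must define at least 2 states")
    if (mask.sum(axis=1) == 0).any():
        raise ValueError("guide contains a gene marking no state")
    if (mask.sum(axis=0) == 0).any():
        raise ValueError("guide contains a state with no marker genes")
    rng = np.random.default_rng(seed)
    n_genes, n_states = mask.shape
    sig = mask * rng.uniform(1.0, 10.0, size=mask.shape)
    sig = sig / sig.sum(axis=0, keepdims=True) * n_genes  # equal column totals
    if fractions is None:
        frac = rng.dirichlet(np.full(n_states, float(alpha)), size=n_samples).T
    else:
        frac = np.asarray(fractions, dtype=float)
        if frac.shape != (n_states, n_samples):
            raise ValueError(f"fractions must have shape {(n_states, n_samples)}")
        if (frac < 0).any() or not np.allclose(frac.sum(axis=0), 1.0, atol=1e-12):
            raise ValueError("fraction columns must be on the unit simplex")
    expr = sig @ frac
    if noise_sd > 0:
        expr = np.clip(expr + rng.normal(0.0, noise_sd, size=expr.shape), 0.0, None)
    samples = [f"M{j:03d}" for j in range(n_samples)]
    return SimulatedMixtureSet(
        expression=pd.DataFrame(expr, index=guide.values.index, columns=samples),
        true_fractions=pd.DataFrame(frac, index=guide.values.columns, columns=samples),
        signatures=pd.DataFrame(sig, index=guide.values.index, columns=guide.values.columns),
        noise_sd=float(noise_sd),
        seed=seed,
    )


@dataclass
class SimulatedCellPopulation:
    """Toy single-cell counts with planted discrete states."""

    counts: pd.DataFrame  # cells x genes, integer
    true_state: pd.Series  # cell -> state label
    marker_sets: dict[str, frozenset[str]]
    seed: int


def simulate_cells(
    n_cells: int = 500,
    state_props: Sequence[float] = (0.5, 0.5),
    n_marker_genes_per_state: int = 20,
    n_noise_genes: int = 200,
    fold_up: float = 8.0,
    seed: int = 0,
) -> SimulatedCellPopulation:
    """Simulate cells from a finite set of states with disjoint markers.

    Every gene has Poisson counts around a baseline mean; marker genes of a
    cell's own state have mean ``fold_up`` times baseline.  Cells of the
    same state therefore share an expected expression profile.
    """
    n_cells = _check_count("n_cells", n_cells)
    props = np.asarray(state_props, dtype=float)
    if props.size < 2:
        raise ValueError("need at least 2 states")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("state_props must sum to 1")
    if fold_up <= 1:
        raise ValueError("fold_up must exceed 1")
    rng = np.random.default_rng(seed)
    n_states = props.size
    state_names = [f"state{k}" for k in range(n_states)]
    labels = rng.choice(n_states, size=n_cells, p=props)

    genes: list[str] = []
    marker_sets: dict[str, frozenset[str]] = {}
    for k, name in enumerate(state_names):
        ms = [f"MK{k}_{i:03d}" for i in range(n_marker_genes_per_state)]
        marker_sets[name] = frozenset(ms)
        genes.extend(ms)
    genes.extend(f"NS_{i:04d}" for i in range(n_noise_genes))

    baseline = rng.uniform(0.5, 2.0, size=len(genes))
    mean = np.tile(baseline, (n_cells, 1))
    for k, name in enumerate(state_names):
        cols = [genes.index(g) for g in sorted(marker_sets[name])]
        mean[np.ix_(labels == k, cols)] *= fold_up
    counts = rng.poisson(mean)
    cells = [f"C{i:04d}" for i in range(n_cells)]
    return SimulatedCellPopulation(
        counts=pd.DataFrame(counts, index=pd.Index(cells, name="cell"), columns=genes),
        true_state=pd.Series([state_names[k] for k in labels], index=cells, name="state"),
        marker_sets=marker_sets,
        seed=seed,
    )
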