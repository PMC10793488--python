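"""Consensus metagene construction, sample/cell scoring, group comparison
and meta-analytic pooling.

The NeuMo signature is built in two steps: within each exposure group, take
the genes present in at least half of the enriched gene sets' leading edges
(:func:`majority_leading_edge`); then intersect the two groups' majority
sets (:func:`consensus_signature`).  A sample's signature score is the
unweighted mean log2CPM over the signature genes.  Scores from several
cohorts are pooled as inverse-variance-weighted mean differences, with a
DerSimonian-Laird between-study variance under the random-effects model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = [
    "MetageneSignature",
    "ScoreVector",
    "StudyEffect",
    "PooledEstimate",
    "majority_leading_edge",
    "consensus_signature",
    "score_samples",
    "expand_signature",
    "compare_scores",
    "pool_mean_differences",
    "module_score_cells",
]


@dataclass(frozen=True)
class MetageneSignature:
    """A named gene set with enough provenance to regenerate it."""

    name: str
    genes: frozenset[str]
    provenance: dict = field(default_factory=dict, hash=False, compare=False)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ScoreVector:
    """Per-sample signature scores (mean log2CPM over signature genes)."""

    scores: pd.Series
    signature: str
    n_genes_used: int


@dataclass(frozen=True)
class StudyEffect:
    """Two-group summary statistics of a score within one study."""

    label: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be nonnegative")

    @property
    def mean_difference(self) -> float:
        return self.mean1 - self.mean2

    @property
    def variance(self) -> float:
        return self.sd1**2 / self.n1 + self.sd2**2 / self.n2


@dataclass
class PooledEstimate:
    """Inverse-variance pooled mean difference with a 95% CI."""

    effect: float
    ci_low: float
    ci_high: float
    se: float
    weights: dict[str, float]
    tau2: float
    model: str


def majority_leading_edge(
    leading_edges: Sequence[Iterable[str]],
    threshold: float = 0.5,
    strict: bool = False,
) -> frozenset[str]:
    """Genes present in at least ``threshold`` of the given leading edges.

    With the default reading, a gene qualifies when its membership count is
    >= ``threshold * n_sets`` (so "in >=50% of 6 sets" means in at least 3).
    ``strict=True`` requires the count to exceed that bound instead.
    """
    if not leading_edges:
        raise ValueError("need at least one leading edge")
    n = len(leading_edges)
    counts: dict[str, int] = {}
    for le in leading_edges:
        for g in set(le):
            counts[g] = counts.get(g, 0) + 1
    bound = threshold * n
    if strict:
        return frozenset(g for g, c in counts.items() if c > bound)
    return frozenset(g for g, c in counts.items() if c >= bound)


def consensus_signature(
    majority_yes: Iterable[str],
    majority_no: Iterable[str],
    name: str = "NeuMo",
    provenance: dict | None = None,
) -> MetageneSignature:
    """Intersection of the two exposure groups' majority leading-edge sets."""
    genes = frozenset(majority_yes) & frozenset(majority_no)
    if not genes:
        warnings.warn(f"consensus signature {name!r} is empty", stacklevel=2)
    return MetageneSignature(name=name, genes=genes, provenance=provenance or {})


def score_samples(
    em: ExpressionMatrix,
    sig: MetageneSignature,
    missing_policy: str = "intersect_warn",
) -> ScoreVector:
    """Per-sample unweighted mean expression over the signature genes.

    Signature genes missing from the matrix are dropped with a warning
    (``intersect_warn``) or raise (``error``); the number of genes actually
    used is recorded.
    """
    present = sorted(sig.genes & set(em.values.index))
    missing = sorted(sig.genes - set(em.values.index))
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in the matrix")
    if missing:
        if missing_policy == "error":
            raise ValueError(f"signature genes missing from matrix: {missing}")
        if missing_policy == "intersect_warn":
            warnings.warn(
                f"{len(missing)} of {len(sig)} signature genes missing; "
                f"scoring on {len(present)}",
                stacklevel=2,
            )
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
    scores = em.values.loc[present].mean(axis=0)
    return ScoreVector(scores=scores.rename(sig.name), signature=sig.name,
                       n_genes_used=len(present))


def expand_signature(
    em: ExpressionMatrix,
    scores: ScoreVector,
    r_min: float = 0.7,
) -> frozenset[str]:
    """Genes whose expression correlates with the score at Pearson r >= r_min.

    Genes with zero variance across samples are excluded (their correlation
    is undefined).  Requires at least 3 samples.
    """
    if em.values.shape[1] < 3:
        raise ValueError("correlation-based expansion needs >= 3 samples")
    s = scores.scores.reindex(em.values.columns).to_numpy(dtype=float)
    if np.isnan(s).any():
        raise ValueError("score vector does not cover all samples")
    x = em.values.to_numpy(dtype=float)
    xm = x - x.mean(axis=1, keepdims=True)
    sm = s - s.mean()
    gene_sd = np.sqrt((xm**2).sum(axis=1))
    s_sd = np.sqrt((sm**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xm @ sm) / (gene_sd * s_sd)
    keep = np.isfinite(r) & (r >= r_min)
    return frozenset(em.values.index[keep])


def compare_scores(
    scores: ScoreVector,
    groups: Mapping[str, str] | pd.Series,
    paired_by: Mapping[str, str] | pd.Series | None = None,
) -> tuple[float, float, str]:
    """Compare signature scores between two groups.

    Unpaired data use a two-sided Wilcoxon rank-sum (Mann-Whitney) test;
    when ``paired_by`` maps samples to subjects, a Wilcoxon signed-rank test
    on within-subject differences is used.  Returns ``(delta, p, test)``
    where ``delta`` is mean(first group) - mean(second group) with groups
    ordered by sorted label.
    """
    g = pd.Series(groups)
    s = scores.scores
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly 2 groups required, got {labels}")
    a = s[g[g == labels[0]].index].to_numpy(dtype=float)
    b = s[g[g == labels[1]].index].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    delta = float(a.mean() - b.mean())
    if paired_by is None:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return delta, float(res.pvalue), "wilcoxon_rank_sum"
    pb = pd.Series(paired_by)
    subj_a = pb[g[g == labels[0]].index]
    subj_b = pb[g[g == labels[1]].index]
    common = sorted(set(subj_a) & set(subj_b))
    if len(common) != len(subj_a) or len(common) != len(subj_b):
        raise ValueError("pairing must be complete across both groups")
    ai = pd.Series(subj_a.index, index=subj_a.values)
    bi = pd.Series(subj_b.index, index=subj_b.values)
    d = s[ai[common].values].to_numpy() - s[bi[common].values].to_numpy()
    if np.all(d == 0):
        return delta, 1.0, "wilcoxon_signed_rank"
    res = stats.wilcoxon(d, alternative="two-sided")
    return delta, float(res.pvalue), "wilcoxon_signed_rank"


def pool_mean_differences(
    studies: Sequence[StudyEffect],
    model: str = "random",
) -> PooledEstimate:
    """Pool per-study mean differences by inverse-variance weighting.

    The random-effects model adds a DerSimonian-Laird between-study
    variance tau^2 to each study's sampling variance; with tau^2 = 0 the
    random and fixed models coincide.  The 95% CI is effect +/- 1.96 SE.
    """
    if model not in {"fixed", "random"}:
        raise ValueError("model must be 'fixed' or 'random'")
    if not studies:
        raise ValueError("need at least one study")
    labels = [s.label for s in studies]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate study labels")
    y = np.array([s.mean_difference for s in studies], dtype=float)
    v = np.array([s.variance for s in studies], dtype=float)
    if (v == 0).all():
        raise ValueError("every study has zero variance; pooling degenerate")
    v = np.where(v == 0, np.finfo(float).tiny, v)
    w_fixed = 1.0 / v
    tau2 = 0.0
    if model == "random" and len(studies) > 1:
        mu_f = (w_fixed * y).sum() / w_fixed.sum()
        q = (w_fixed * (y - mu_f) ** 2).sum()
        c = w_fixed.sum() - (w_fixed**2).sum() / w_fixed.sum()
        tau2 = max(0.0, (q - (len(studies) - 1)) / c) if c > 0 else 0.0
    w = 1.0 / (v + tau2)
    effect = float((w * y).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    wn = w / w.sum()
    return PooledEstimate(
        effect=effect,
        ci_low=effect - 1.96 * se,
        ci_high=effect + 1.96 * se,
        se=se,
        weights={lab: float(x) for lab, x in zip(labels, wn)},
        tau2=float(tau2),
        model=model,
    )


def module_score_cells(
    cell_expr: pd.DataFrame,
    gene_set: Iterable[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell gene-module score with expression-matched background.

    ``cell_expr`` is cells x genes.  In the default mode, genes are binned
    by their average expression into ``n_bins`` bins and ``n_ctrl`` control
    genes per module gene are drawn from the module gene's bin; the score is
    the mean expression over module genes minus the mean over the sampled
    controls.  With ``n_ctrl = 0`` the score is the plain mean over the
    module genes.
    """
    gene_set = sorted(frozenset(gene_set) & set(cell_expr.columns))
    if not gene_set:
        raise ValueError("no module gene present in the expression matrix")
    if n_ctrl == 0:
        return cell_expr[gene_set].mean(axis=1).rename("module_score")
    rng = np.random.default_rng(seed)
    gene_means = cell_expr.mean(axis=0)
    # bin genes by average expression rank (equal-occupancy bins)
    order = gene_means.rank(method="first")
    bins = pd.cut(order, bins=n_bins, labels=False)
    ctrl_genes: list[str] = []
    for g in gene_set:
        pool = bins.index[(bins == bins[g]) & (bins.index != g)]
        if len(pool) == 0:
            pool = bins.index[bins.index != g]
        ctrl_genes.extend(rng.choice(pool, size=n_ctrl, replace=True))
    score = cell_expr[gene_set].mean(axis=1) - cell_expr[list(ctrl_genes)].mean(axis=1)
    return score.rename("module_score")
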