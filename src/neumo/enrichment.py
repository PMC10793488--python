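"""Preranked gene-set enrichment analysis and over-representation tests.

The enrichment score is the classic weighted Kolmogorov-Smirnov running
statistic over a ranked gene list: walking the list from top to bottom, a
hit (in-set gene) moves the running sum up by |score|^weight normalized by
the sum over in-set hits, a miss moves it down by 1/(N - N_hit); the
enrichment score (ES) is the running-sum value of maximal absolute
deviation, and the leading edge is the in-set genes at or before the peak
for positive ES (at or after it for negative ES).

Significance is assessed by permuting which genes carry the set labels
(equivalently: placing a same-size random set on the ranking) — the only
null available for preranked input.  The normalized enrichment score (NES)
divides the observed ES by the mean |null ES| of matching sign, and FDR is
the pooled-NES procedure of the original GSEA method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedList",
    "GeneSetCollection",
    "rank_genes",
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "preranked_gsea",
    "select_enriched",
    "hypergeometric_ora",
]


@dataclass(frozen=True)
class RankedList:
    """Gene ids with real scores, sorted descending.

    Ties in score are broken by lexicographic gene id so serialization and
    permutation nulls are reproducible.
    """

    genes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list contains duplicate gene ids")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be sorted descending")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(scores: Mapping[str, float] | pd.Series) -> RankedList:
    """Build a :class:`RankedList` from gene -> score (e.g. log2FC)."""
    s = pd.Series(scores, dtype=float)
    s = s.sort_index().sort_values(ascending=False, kind="stable")
    return RankedList(genes=tuple(s.index), scores=tuple(s.to_numpy()))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2..."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path.name}:{lineno}: GMT line needs name, description and >=1 gene")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path.name}: duplicate gene-set name {name!r}")
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise ValueError(f"{path.name}:{lineno}: gene set {name!r} is empty")
        sets[name] = genes
    return GeneSetCollection(sets, source=source or path.name)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.source or "na", *sorted(genes)])
        for name, genes in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _step_vectors(scores: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    """Per-position running-sum increments for hit matrix rows.

    ``hits`` is boolean, shape (n_rows, N); all rows share the score vector.
    """
    n = scores.size
    n_hit = hits.sum(axis=1, keepdims=True)
    if (n_hit == n).any():
        raise ValueError("gene set covers the whole ranked list (miss step undefined)")
    w = np.abs(scores) ** weight
    hit_w = hits * w
    denom = hit_w.sum(axis=1, keepdims=True)
    # a set whose hits all carry score 0 at weight>0 degenerates; fall back
    # to unweighted steps for those rows
    zero = denom[:, 0] == 0
    if zero.any():
        hit_w[zero] = hits[zero].astype(float)
        denom[zero] = n_hit[zero]
    steps = hit_w / denom - (~hits) / (n - n_hit)
    return steps


def _es_from_steps(steps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    run = np.cumsum(steps, axis=1)
    peak = np.abs(run).argmax(axis=1)
    es = run[np.arange(run.shape[0]), peak]
    return es, peak


def enrichment_score(
    rl: RankedList,
    gene_set: Iterable[str],
    weight: float = 1.0,
) -> tuple[float, int, frozenset[str]]:
    """ES, peak index and leading edge for one gene set.

    Returns ``(es, peak_index, leading_edge)``.  The leading edge is empty
    when the ES is exactly zero.
    """
    genes = np.asarray(rl.genes)
    scores = np.asarray(rl.scores, dtype=float)
    members = frozenset(gene_set) & set(rl.genes)
    if not members:
        warnings.warn("gene set has no overlap with the ranked list; skipping", stacklevel=2)
        return 0.0, 0, frozenset()
    hits = np.isin(genes, list(members))[None, :]
    steps = _step_vectors(scores, hits, weight)
    es_arr, peak_arr = _es_from_steps(steps)
    es, peak = float(es_arr[0]), int(peak_arr[0])
    if es > 0:
        le = frozenset(genes[: peak + 1][hits[0, : peak + 1]])
    elif es < 0:
        le = frozenset(genes[peak:][hits[0, peak:]])
    else:
        le = frozenset()
    return es, peak, le


def preranked_gsea(
    rl: RankedList,
    col: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection.

    Returns a DataFrame indexed by set name with columns ``es``, ``nes``,
    ``pvalue``, ``fdr``, ``set_size_used``, ``leading_edge`` (frozenset) and
    ``boundary`` (True when nes/fdr sit exactly on common selection
    thresholds, so either inclusive or exclusive readings can be audited).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable FDR estimates", stacklevel=2)
    genes = np.asarray(rl.genes)
    scores = np.asarray(rl.scores, dtype=float)
    n = genes.size
    rng = np.random.default_rng(seed)

    used: list[tuple[str, frozenset[str]]] = []
    for name, gs in sorted(col.items()):
        members = frozenset(gs) & set(rl.genes)
        if not (min_size <= len(members) <= max_size):
            continue
        if len(members) == n:
            raise ValueError(f"gene set {name!r} covers the whole ranked list")
        used.append((name, members))
    if not used:
        raise ValueError("no gene set within the size bounds overlaps the ranking")

    rows = []
    null_nes_pool: list[np.ndarray] = []
    obs_nes: list[float] = []
    for name, members in used:
        k = len(members)
        hits = np.isin(genes, list(members))[None, :]
        es, peak, le = enrichment_score(rl, members, weight=weight)

        # null: the set occupies k random positions of the ranking
        null_hits = np.zeros((n_perm, n), dtype=bool)
        cols = np.argpartition(rng.random((n_perm, n)), k - 1, axis=1)[:, :k]
        null_hits[np.arange(n_perm)[:, None], cols] = True
        null_es, _ = _es_from_steps(_step_vectors(scores, null_hits, weight))

        pos = null_es[null_es > 0]
        neg = null_es[null_es < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        if es >= 0:
            nes = es / mean_pos if pos.size else np.nan
            pvalue = (1 + int((pos >= es).sum())) / (pos.size + 1)
            null_nes = np.concatenate([pos / mean_pos if pos.size else pos,
                                       -np.abs(neg) / mean_neg if neg.size else neg])
        else:
            nes = es / mean_neg if neg.size else np.nan
            pvalue = (1 + int((neg <= es).sum())) / (neg.size + 1)
            null_nes = np.concatenate([pos / mean_pos if pos.size else pos,
                                       -np.abs(neg) / mean_neg if neg.size else neg])
        null_nes_pool.append(null_nes)
        obs_nes.append(nes)
        rows.append(
            dict(name=name, es=es, nes=nes, pvalue=pvalue, set_size_used=k,
                 leading_edge=le, peak=peak)
        )

    pooled = np.concatenate(null_nes_pool)
    obs = np.asarray(obs_nes, dtype=float)
    fdrs = []
    for nes in obs:
        if not np.isfinite(nes):
            fdrs.append(np.nan)
            continue
        if nes >= 0:
            num = (pooled >= nes).sum() / max((pooled >= 0).sum(), 1)
            den = (obs >= nes).sum() / max((obs >= 0).sum(), 1)
        else:
            num = (pooled <= nes).sum() / max((pooled < 0).sum(), 1)
            den = (obs <= nes).sum() / max((obs < 0).sum(), 1)
        fdrs.append(min(1.0, num / den) if den > 0 else 1.0)

    out = pd.DataFrame(rows).set_index("name")
    out["fdr"] = fdrs
    out["boundary"] = (out["nes"].abs() == 2.5) | (out["fdr"] == 0.05)
    return out[["es", "nes", "pvalue", "fdr", "set_size_used", "leading_edge", "peak", "boundary"]]


def select_enriched(
    results: pd.DataFrame,
    nes_min: float = 2.5,
    fdr_max: float = 0.05,
    direction: str = "positive",
) -> pd.DataFrame:
    """Filter GSEA results by NES magnitude and FDR (inclusive bounds)."""
    if direction not in {"positive", "negative", "both"}:
        raise ValueError("direction must be 'positive', 'negative' or 'both'")
    nes = results["nes"]
    if direction == "positive":
        keep = nes >= nes_min
    elif direction == "negative":
        keep = nes <= -nes_min
    else:
        keep = nes.abs() >= nes_min
    keep &= results["fdr"] <= fdr_max
    return results.loc[keep]


def hypergeometric_ora(
    query: Iterable[str],
    universe: Iterable[str],
    col: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    p is the probability of drawing at least the observed overlap when
    |query| genes are drawn from the universe without replacement.
    """
    query = frozenset(query)
    universe = frozenset(universe)
    offenders = query - universe
    if offenders:
        raise ValueError(f"query genes outside the universe: {sorted(offenders)}")
    m = len(universe)
    q = len(query)
    rows = []
    for name, gs in sorted(col.items()):
        gs_u = gs & universe
        k = len(query & gs_u)
        p = float(stats.hypergeom.sf(k - 1, m, len(gs_u), q)) if q else 1.0
        rows.append(dict(name=name, set_size=len(gs_u), overlap=k, pvalue=min(1.0, p)))
    return pd.DataFrame(rows).set_index("name")
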