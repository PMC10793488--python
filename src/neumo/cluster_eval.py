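"""Clustering agreement, reseeded stability sweeps and gene-set overlap.

The resolution-selection procedure runs a caller-supplied clustering
function over a grid of resolution values; at each resolution the labeling
obtained at a base seed is compared (adjusted Rand index) against many
reseeded runs, and the chosen resolution is the one immediately before the
mean ARI first strictly decreases along the grid — the end of the stability
plateau.  The clustering function is a contract ``(data, resolution, seed)
-> labeling``; a reference implementation based on a k-nearest-neighbor
graph and Leiden modularity communities ships for testing, but the sweep is
algorithm-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "StabilityTrace",
    "adjusted_rand_index",
    "stability_sweep",
    "knn_leiden",
    "overlap_coefficient",
    "pairwise_overlap",
]

DEFAULT_RESOLUTIONS = tuple(np.round(np.arange(0.10, 0.501, 0.05), 2))


def _as_labeling(x: Mapping | pd.Series | Sequence) -> pd.Series:
    s = pd.Series(x)
    if s.index.duplicated().any():
        raise ValueError("labeling contains duplicate item ids")
    return s


def adjusted_rand_index(a: Mapping | pd.Series | Sequence, b: Mapping | pd.Series | Sequence) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings.

    Labels are opaque: the index is invariant to relabeling clusters.  Both
    labelings must cover exactly the same items.
    """
    sa, sb = _as_labeling(a), _as_labeling(b)
    if set(sa.index) != set(sb.index):
        raise ValueError("labelings cover different item sets")
    sb = sb.reindex(sa.index)
    return float(adjusted_rand_score(sa.to_numpy(), sb.to_numpy()))


@dataclass
class StabilityTrace:
    """Mean reseeded ARI per resolution and the selected resolution."""

    trace: pd.DataFrame  # index: resolution; columns: mean_ari, sd_ari, n_reseeds
    chosen_resolution: float
    never_decreased: bool
    base_seed: int


def stability_sweep(
    cluster_fn: Callable[[object, float, int], pd.Series],
    data: object,
    resolutions: Sequence[float] = DEFAULT_RESOLUTIONS,
    n_reseeds: int = 100,
    base_seed: int = 0,
) -> StabilityTrace:
    """Reseeded-ARI stability across a resolution grid.

    At each resolution, a reference clustering at ``base_seed`` is compared
    against ``n_reseeds`` runs at seeds ``base_seed + 1 .. base_seed +
    n_reseeds``; the mean ARI against the reference is recorded.  The
    chosen resolution is the grid point immediately before the first strict
    decrease of the mean ARI; if the mean never decreases, the last grid
    point is chosen and flagged via ``never_decreased``.
    """
    res = [float(r) for r in resolutions]
    if any(b <= a for a, b in zip(res, res[1:])):
        raise ValueError("resolutions must be strictly increasing")
    rows = []
    for r in res:
        ref = _as_labeling(cluster_fn(data, r, base_seed))
        aris = []
        for i in range(1, n_reseeds + 1):
            lab = _as_labeling(cluster_fn(data, r, base_seed + i))
            if set(lab.index) != set(ref.index):
                raise ValueError("cluster_fn returned a labeling over a different item set")
            aris.append(adjusted_rand_score(ref.to_numpy(), lab.reindex(ref.index).to_numpy()))
        aris = np.asarray(aris)
        rows.append(dict(resolution=r, mean_ari=aris.mean(),
                         sd_ari=aris.std(ddof=1) if len(aris) > 1 else 0.0,
                         n_reseeds=n_reseeds))
    trace = pd.DataFrame(rows).set_index("resolution")
    means = trace["mean_ari"].to_numpy()
    chosen = res[-1]
    never = True
    for i in range(1, len(res)):
        if means[i] < means[i - 1]:
            chosen = res[i - 1]
            never = False
            break
    return StabilityTrace(trace=trace, chosen_resolution=chosen,
                          never_decreased=never, base_seed=base_seed)


def knn_leiden(
    data: np.ndarray | pd.DataFrame,
    resolution: float,
    seed: int,
    n_neighbors: int = 15,
) -> pd.Series:
    """Reference clustering: k-nearest-neighbor graph + Leiden communities.

    ``resolution`` is the modularity resolution parameter.  Deterministic
    given ``(data, resolution, seed)``.
    """
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    df = pd.DataFrame(data)
    x = df.to_numpy(dtype=float)
    k = min(n_neighbors, len(df) - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(x)
    _, idx = nn.kneighbors(x)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = igraph.Graph(n=len(df), edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=float(resolution),
        seed=int(seed),
        n_iterations=2,
    )
    return pd.Series(part.membership, index=df.index, name="cluster")


def overlap_coefficient(a: Iterable[str], b: Iterable[str]) -> float:
    """|A intersect B| / min(|A|, |B|) for two nonempty sets."""
    sa, sb = frozenset(a), frozenset(b)
    if not sa or not sb:
        raise ValueError("overlap coefficient undefined for an empty set")
    return len(sa & sb) / min(len(sa), len(sb))


def pairwise_overlap(collections: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Symmetric overlap-coefficient matrix over named gene sets."""
    names = list(collections)
    if len(names) != len(set(names)):
        raise ValueError("duplicate set names")
    sets = {n: frozenset(collections[n]) for n in names}
    if any(not s for s in sets.values()):
        empty = [n for n, s in sets.items() if not s]
        raise ValueError(f"empty sets: {empty}")
    mat = pd.DataFrame(1.0, index=names, columns=names)
    for i, ni in enumerate(names):
        for nj in names[i + 1 :]:
            v = overlap_coefficient(sets[ni], sets[nj])
            mat.loc[ni, nj] = v
            mat.loc[nj, ni] = v
    return mat
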