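"""The glucocorticoid (DEX) attenuation statistic and its resampling null.

For a gene differentially expressed in the same direction in both exposure
groups, the statistic is the exposed-group log2 fold change divided by the
unexposed-group log2 fold change.  By construction it is positive; a value
in (0, 1) means the drug attenuated the differential expression, a value
above 1 means it potentiated it.  Whether the number of attenuated genes
among the shared DEGs is surprising is judged against a null distribution
built by repeatedly drawing the same number of genes from all
same-direction analyzed genes and counting ratios in (0, 1).

The equivalent change index (ECI) compares a gene's fold changes across two
studies on a bounded scale: sign(a*b) * min(|a|,|b|) / max(|a|,|b|), which
is 1 for identical nonzero changes and -1 for exactly opposite ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedRatioError",
    "DiscordantError",
    "NullSummary",
    "ratio_of_log2fc",
    "classify_attenuation",
    "class_counts",
    "attenuation_null",
    "attenuation_test",
    "equivalent_change_index",
]

CLASSES = ("attenuated", "potentiated", "neutral", "discordant")


class UndefinedRatioError(ValueError):
    """The denominator fold change is zero."""


class DiscordantError(ValueError):
    """The two fold changes have opposite signs; the ratio is not defined."""


def ratio_of_log2fc(fc_yes: float, fc_no: float) -> float:
    """Ratio of the exposed to the unexposed log2 fold change.

    Defined only for same-direction fold changes (or ``fc_yes == 0``) with a
    nonzero denominator; the result is then nonnegative.
    """
    if fc_no == 0:
        raise UndefinedRatioError("denominator (No-DEX) log2FC is zero")
    if fc_yes * fc_no < 0:
        raise DiscordantError("fold changes have opposite signs")
    return fc_yes / fc_no


def classify_attenuation(
    fold_changes: pd.DataFrame,
    restrict_to: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Classify genes as attenuated / potentiated / neutral / discordant.

    ``fold_changes`` is indexed by gene with columns ``fc_yes`` and
    ``fc_no``.  ``restrict_to`` (typically the DEGs shared by both exposure
    groups) selects the genes to classify; each must be present.  Discordant
    genes (``fc_yes * fc_no <= 0``, where the ratio is undefined) carry
    ``ratio = NaN``.
    """
    if restrict_to is not None:
        restrict = pd.Index(sorted(set(restrict_to)))
        missing = restrict.difference(fold_changes.index)
        if len(missing):
            raise KeyError(f"genes missing fold changes: {list(missing)}")
        fold_changes = fold_changes.loc[restrict]
    fy = fold_changes["fc_yes"].to_numpy(dtype=float)
    fn = fold_changes["fc_no"].to_numpy(dtype=float)
    # a zero fold change in either group leaves the ratio undefined too
    discordant = fy * fn <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(discordant, np.nan, fy / np.where(fn == 0, np.nan, fn))
    klass = np.full(len(fy), "discordant", dtype=object)
    klass[~discordant & (ratio > 0) & (ratio < 1)] = "attenuated"
    klass[~discordant & (ratio > 1)] = "potentiated"
    klass[~discordant & (ratio == 1)] = "neutral"
    return pd.DataFrame(
        {"ratio": ratio, "klass": klass},
        index=fold_changes.index.rename("gene"),
    )


def class_counts(records: pd.DataFrame) -> dict[str, int]:
    """Per-class gene counts for a :func:`classify_attenuation` table."""
    vc = records["klass"].value_counts()
    return {c: int(vc.get(c, 0)) for c in CLASSES}


@dataclass
class NullSummary:
    """Resampling null for the number of attenuated genes among a draw."""

    n_iter: int
    n_draw: int
    counts: np.ndarray  # per-iteration attenuated-gene counts
    seed: int
    with_replacement: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != self.n_iter:
            raise ValueError("counts length must equal n_iter")
        if ((self.counts < 0) | (self.counts > self.n_draw)).any():
            raise ValueError("null counts must lie in [0, n_draw]")

    @property
    def min(self) -> int:
        return int(self.counts.min())

    @property
    def max(self) -> int:
        return int(self.counts.max())

    def quantiles(self, q: Sequence[float] = (0.025, 0.25, 0.5, 0.75, 0.975)) -> dict[float, float]:
        return {float(x): float(v) for x, v in zip(q, np.quantile(self.counts, q))}

    def to_dict(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "n_draw": self.n_draw,
            "seed": self.seed,
            "with_replacement": self.with_replacement,
            "min": self.min,
            "max": self.max,
            "quantiles": {str(k): v for k, v in self.quantiles().items()},
        }


def attenuation_null(
    universe: pd.DataFrame,
    n_draw: int = 666,
    n_iter: int = 100_000,
    seed: int = 0,
    with_replacement: bool = False,
) -> NullSummary:
    """Null distribution of the attenuated-gene count.

    ``universe`` holds all same-direction analyzed genes (columns ``fc_yes``
    and ``fc_no``, ``fc_no`` nonzero).  Each iteration draws ``n_draw``
    genes (without replacement by default) and counts ratios strictly inside
    (0, 1).
    """
    fy = universe["fc_yes"].to_numpy(dtype=float)
    fn = universe["fc_no"].to_numpy(dtype=float)
    if (fn == 0).any():
        raise ValueError("universe contains genes with zero No-DEX log2FC")
    if (fy * fn < 0).any():
        raise ValueError("universe contains discordant-direction genes")
    n_universe = len(fy)
    if n_universe < n_draw and not with_replacement:
        raise ValueError(f"universe size {n_universe} smaller than n_draw {n_draw}")
    ratio = fy / fn
    attenuated = (ratio > 0) & (ratio < 1)

    rng = np.random.default_rng(seed)
    counts = np.empty(n_iter, dtype=np.int64)
    if with_replacement:
        idx = rng.integers(0, n_universe, size=(n_iter, n_draw))
        counts[:] = attenuated[idx].sum(axis=1)
    else:
        # vectorized without-replacement sampling: random keys, take the
        # n_draw smallest per iteration; chunked to bound memory
        chunk = max(1, int(2e7) // n_universe)
        ind = attenuated.astype(np.int64)
        for start in range(0, n_iter, chunk):
            m = min(chunk, n_iter - start)
            keys = rng.random((m, n_universe))
            sel = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]
            counts[start : start + m] = ind[sel].sum(axis=1)
    return NullSummary(n_iter=n_iter, n_draw=n_draw, counts=counts, seed=seed,
                       with_replacement=with_replacement)


def attenuation_test(observed: int, null: NullSummary) -> tuple[float, bool]:
    """Empirical upper-tail p for the observed attenuated count.

    Uses the add-one convention ``p = (1 + #{null >= observed}) /
    (n_iter + 1)`` so p is never zero.  ``outside_range`` is True when the
    observation falls outside the null's min-max range (either side).
    """
    if not 0 <= observed <= null.n_draw:
        raise ValueError("observed count must lie in [0, n_draw]")
    p = (1 + int((null.counts >= observed).sum())) / (null.n_iter + 1)
    outside = observed > null.max or observed < null.min
    return p, outside


def equivalent_change_index(fc_a: float, fc_b: float) -> float:
    """Bounded agreement between two fold changes.

    ``sign(fc_a * fc_b) * min(|fc_a|, |fc_b|) / max(|fc_a|, |fc_b|)``:
    equal nonzero changes give 1, exactly opposite ones give -1, and a zero
    in either argument gives 0.  Undefined when both are zero.
    """
    if fc_a == 0 and fc_b == 0:
        raise ValueError("ECI undefined for two zero fold changes")
    if fc_a == 0 or fc_b == 0:
        return 0.0
    a, b = abs(fc_a), abs(fc_b)
    return float(np.sign(fc_a * fc_b)) * min(a, b) / max(a, b)
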