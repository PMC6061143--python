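"""Rank-based comparison of per-biome consumption rates.

Consumption values are strictly positive, span two orders of magnitude
across biomes and are far from normal, so biome differences are tested
nonparametrically: a tie-corrected Kruskal-Wallis omnibus test followed
by Dunn's pairwise z-tests on the pooled midranks, plus a rank
correlation between per-biome consumption and net primary production.

The Kruskal-Wallis and Dunn statistics are computed directly from their
rank-sum formulas (scipy supplies only the chi-square and normal tails);
this keeps the tie correction explicit and lets degenerate all-tied
input return H = 0 rather than fail.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupedSamples",
    "PairwiseComparison",
    "TestResult",
    "midranks",
    "tie_term",
    "kruskal_wallis",
    "dunn_test",
    "consumption_npp_correlation",
]


@dataclass(frozen=True)
class GroupedSamples:
    """Labeled groups of real values; the unit of both tests."""

    groups: dict[str, np.ndarray]

    @classmethod
    def from_mapping(cls, data: Mapping[str, Sequence[float]]) -> "GroupedSamples":
        groups = {k: np.asarray(v, dtype=float) for k, v in data.items()}
        if len(groups) < 2:
            raise ValueError("at least two groups required")
        for name, values in groups.items():
            if values.size == 0:
                raise ValueError(f"group {name!r} is empty")
            if values.ndim != 1:
                raise ValueError(f"group {name!r} must be one-dimensional")
        return cls(groups)

    @property
    def n_total(self) -> int:
        return sum(v.size for v in self.groups.values())

    def pooled(self) -> np.ndarray:
        return np.concatenate(list(self.groups.values()))


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_value: float  # two-sided, after any adjustment


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    tie_correction: float
    pairwise: tuple[PairwiseComparison, ...] = ()


def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..N with tied values sharing the mean of their span.

    Midranks always sum to N(N+1)/2.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty sequence")
    return stats.rankdata(values, method="average")


def tie_term(values: np.ndarray) -> float:
    """Σ(t³ − t) over tie groups of size t in the pooled sample."""
    _, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def kruskal_wallis(samples: GroupedSamples) -> TestResult:
    """Tie-corrected Kruskal-Wallis one-way analysis of variance by ranks.

    H = [12/(N(N+1)) Σ R_j²/n_j − 3(N+1)] / C with the tie correction
    C = 1 − Σ(t³−t)/(N³−N); p from the chi-square with k−1 df. An
    all-tied pooled sample (C would be 0) is defined as H = 0, p = 1,
    so degenerate synthetic draws never crash a pipeline run.
    """
    pooled = samples.pooled()
    n = pooled.size
    k = len(samples.groups)
    ranks = midranks(pooled)
    h_raw = -3.0 * (n + 1)
    offset = 0
    for values in samples.groups.values():
        r_j = float(ranks[offset : offset + values.size].sum())
        h_raw += 12.0 / (n * (n + 1)) * r_j**2 / values.size
        offset += values.size
    correction = 1.0 - tie_term(pooled) / (n**3 - n) if n > 1 else 1.0
    if correction <= 0.0:  # every pooled observation identical
        return TestResult(statistic=0.0, df=k - 1, p_value=1.0, tie_correction=0.0)
    h = h_raw / correction
    if abs(h) < 1e-12:  # clip the −0.0 from float cancellation
        h = 0.0
    p = float(stats.chi2.sf(h, k - 1))
    return TestResult(statistic=h, df=k - 1, p_value=p, tie_correction=correction)


_P_ADJUSTMENTS = ("none", "holm", "bonferroni")


def dunn_test(samples: GroupedSamples, p_adjust: str = "none") -> TestResult:
    """Dunn's pairwise multiple comparisons on the pooled midranks.

    For groups i, j with mean ranks R̄:

        z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)]

    with two-sided normal p-values, optionally Holm- or
    Bonferroni-adjusted. The omnibus fields of the returned result carry
    the underlying Kruskal-Wallis test.
    """
    if p_adjust not in _P_ADJUSTMENTS:
        raise ValueError(f"p_adjust must be one of {_P_ADJUSTMENTS}")
    omnibus = kruskal_wallis(samples)
    pooled = samples.pooled()
    n = pooled.size
    ranks = midranks(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    offset = 0
    for name, values in samples.groups.items():
        mean_ranks[name] = float(ranks[offset : offset + values.size].mean())
        sizes[name] = values.size
        offset += values.size
    variance = n * (n + 1) / 12.0 - tie_term(pooled) / (12.0 * (n - 1)) if n > 1 else 0.0
    comparisons = []
    for a, b in itertools.combinations(samples.groups, 2):
        denom = np.sqrt(variance * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / denom if denom > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        comparisons.append((a, b, z, p))
    raw_p = [c[3] for c in comparisons]
    adjusted = _adjust_pvalues(raw_p, p_adjust)
    pairwise = tuple(
        PairwiseComparison(a, b, z, p_adj)
        for (a, b, z, _), p_adj in zip(comparisons, adjusted)
    )
    return TestResult(
        statistic=omnibus.statistic,
        df=omnibus.df,
        p_value=omnibus.p_value,
        tie_correction=omnibus.tie_correction,
        pairwise=pairwise,
    )


def _adjust_pvalues(p: Sequence[float], method: str) -> list[float]:
    p = list(p)
    m = len(p)
    if method == "none" or m == 0:
        return p
    if method == "bonferroni":
        return [min(1.0, v * m) for v in p]
    # holm: step-down, enforcing monotonicity
    order = np.argsort(p)
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def consumption_npp_correlation(
    biome_means: Sequence[float],
    npp_values: Sequence[float],
    method: str = "spearman",
) -> float:
    """Correlation between per-biome consumption means and NPP.

    Spearman rank correlation by default (the claim is monotone
    association, and with seven biomes rank methods are the safest);
    Pearson available by flag.
    """
    x = np.asarray(biome_means, dtype=float)
    y = np.asarray(npp_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("biome_means and npp_values must have equal length")
    if x.size < 3:
        raise ValueError("at least three paired values required")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError("method must be 'spearman' or 'pearson'")
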