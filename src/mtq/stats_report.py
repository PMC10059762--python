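"""Statistical layer: Friedman test, one-way ANOVA with Tukey HSD,
min-max normalization and mean +/- SEM summaries.

The Friedman test (nonparametric, within-block ranks) serves repeated
measurements such as cell-count time courses; one-way ANOVA followed by the
Tukey HSD post-test compares two or more independent groups. Significance is
read at alpha = 0.05 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "StatResult",
    "friedman_test",
    "anova_tukey",
    "minmax_normalize",
    "summarize",
]


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    alpha: float = 0.05
    pairwise_p: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def friedman_test(blocked: np.ndarray) -> StatResult:
    """Friedman chi-square test on a blocks x conditions table.

    Ranks are taken within each block with average-rank ties. Requires at
    least 2 complete blocks and 2 conditions; an all-constant table carries
    no rank information and returns statistic 0, p = 1.
    """
    blocked = np.asarray(blocked, dtype=float)
    if blocked.ndim != 2:
        raise ValueError("expected a 2D blocks x conditions table")
    n_blocks, k = blocked.shape
    if n_blocks < 2 or k < 2:
        raise ValueError("need >= 2 blocks and >= 2 conditions")
    if np.isnan(blocked).any():
        raise ValueError("incomplete blocks (NaN entries) are not supported")
    ranks = np.apply_along_axis(stats.rankdata, 1, blocked)
    if np.allclose(ranks.var(axis=1), 0):
        return StatResult("friedman", 0.0, 1.0, (n_blocks,) * k)
    stat, p = stats.friedmanchisquare(*blocked.T)
    return StatResult("friedman", float(stat), float(p), (n_blocks,) * k)


def anova_tukey(groups: list[np.ndarray], alpha: float = 0.05) -> StatResult:
    """One-way ANOVA followed by Tukey HSD over all group pairs.

    ``pairwise_p`` maps group-index pairs (i, j), i < j, to Tukey-adjusted
    p-values from the studentized-range distribution. Degenerate input with
    zero variance everywhere and equal means gives F = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    ns = tuple(len(a) for a in arrays)
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        pairs = {p: 1.0 for p in combinations(range(len(arrays)), 2)}
        return StatResult("anova_tukey", 0.0, 1.0, ns, alpha, pairs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warnings
        f_stat, p = stats.f_oneway(*arrays)
    if np.isnan(f_stat):
        f_stat, p = 0.0, 1.0
    tukey = stats.tukey_hsd(*arrays)
    pairs = {
        (i, j): float(tukey.pvalue[i, j])
        for i, j in combinations(range(len(arrays)), 2)
    }
    return StatResult("anova_tukey", float(f_stat), float(p), ns, alpha, pairs)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Min-max scaling (x - min) / (max - min) onto [0, 1].

    Constant input is returned as all zeros with a warning. Invariant under
    increasing affine transforms of the input.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    rng = values.max() - values.min()
    if rng == 0:
        warnings.warn("constant input to min-max normalization; returning zeros",
                      stacklevel=2)
        return np.zeros_like(values)
    return (values - values.min()) / rng


def summarize(values: np.ndarray) -> tuple[float, float, int]:
    """(mean, SEM, n) with SEM = sd / sqrt(n); SEM is 0 (flagged) at n = 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    n = values.size
    if n == 1:
        warnings.warn("SEM undefined at n=1; reporting 0", stacklevel=2)
        return float(values[0]), 0.0, 1
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(n)), n
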