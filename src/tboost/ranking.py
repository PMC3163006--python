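"""Pooled-variance two-sample t statistic and |t|-descending feature ranking.

The ranking statistic is the classical equal-variance two-sample t:

    t = (xbar_1 - xbar_2) / sqrt( S_c^2 * (1/n_1 + 1/n_2) )

with the pooled variance S_c^2 = ((n_1-1) S_1^2 + (n_2-1) S_2^2) / (n_1+n_2-2)
and nu = n_1 + n_2 - 2 degrees of freedom. Group 1 is the positive class, so
t > 0 means the biomarker is elevated in cases.

Two-sided p-values are reported for interpretation only; candidate-subset
formation uses the |t| rank, never a significance cut, and no
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

from .cohort import CohortTable, GroupSummary, split_by_label
from .exceptions import ConfigurationError, DataError, DegenerateScaleError

__all__ = [
    "RankedFeature",
    "pooled_sd_of_mean_difference",
    "t_statistic",
    "two_sided_p",
    "rank_features",
    "candidate_subset",
]


@dataclass(frozen=True)
class RankedFeature:
    """One biomarker's t statistic, p-value and 1-based |t| rank."""

    name: str
    t_value: float
    df: int
    p_value: float
    rank: int
    degenerate: bool = False

    @property
    def abs_t(self) -> float:
        return abs(self.t_value)


def pooled_sd_of_mean_difference(g1: GroupSummary, g2: GroupSummary) -> float:
    """Standard error of the mean difference under a common variance.

    sqrt( S_c^2 * (1/n1 + 1/n2) ) with the df-weighted pooled variance S_c^2.
    Raises :class:`DegenerateScaleError` when both variances are zero.
    """
    if g1.n < 2 or g2.n < 2:
        raise DataError("both groups need n >= 2 for a pooled variance")
    sc2 = ((g1.n - 1) * g1.variance + (g2.n - 1) * g2.variance) / (g1.n + g2.n - 2)
    if sc2 <= 0.0:
        raise DegenerateScaleError(
            "pooled variance is zero (both groups constant); t is undefined"
        )
    return math.sqrt(sc2 * (1.0 / g1.n + 1.0 / g2.n))


def t_statistic(g1: GroupSummary, g2: GroupSummary) -> tuple[float, int]:
    """Pooled two-sample t and its degrees of freedom n1 + n2 - 2.

    Positive when group 1 (the +1 class) has the larger mean.
    """
    se = pooled_sd_of_mean_difference(g1, g2)
    return (g1.mean - g2.mean) / se, g1.n + g2.n - 2


def two_sided_p(t: float, df: int) -> float:
    """Two-sided tail probability of the central Student-t distribution."""
    if df < 1:
        raise ConfigurationError(f"degrees of freedom must be >= 1, got {df}")
    return float(2.0 * stats.t.sf(abs(t), df))


def rank_features(table: CohortTable) -> list[RankedFeature]:
    """t-test every biomarker and rank by |t|, largest first.

    Ties in |t| keep the original column order (stable sort). A feature that
    is constant in both groups has no defined t; it is ranked last with
    t = 0, p = 1 and a warning rather than aborting the run.
    """
    table.require_both_classes()
    rows: list[tuple] = []
    for j, name in enumerate(table.feature_names):
        g1, g2 = split_by_label(table, name)
        try:
            t, df = t_statistic(g1, g2)
            p = two_sided_p(t, df)
            degen = False
        except DegenerateScaleError:
            warnings.warn(
                f"feature {name!r} is constant within both classes; ranked last",
                stacklevel=2,
            )
            t, df, p, degen = 0.0, g1.n + g2.n - 2, 1.0, True
        rows.append((degen, -abs(t), j, name, t, df, p))

    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    return [
        RankedFeature(name=name, t_value=t, df=df, p_value=p, rank=r + 1,
                      degenerate=degen)
        for r, (degen, _negabs, _j, name, t, df, p) in enumerate(rows)
    ]


def candidate_subset(ranked: list[RankedFeature], k: int = 10) -> list[str]:
    """Top-k biomarker names in rank order."""
    if not 1 <= k <= len(ranked):
        raise ConfigurationError(
            f"k must be in 1..{len(ranked)} (number of ranked features), got {k}"
        )
    return [rf.name for rf in sorted(ranked, key=lambda r: r.rank)[:k]]
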