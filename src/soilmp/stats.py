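"""Inferential toolkit: one-way ANOVA, Pearson correlation, chi-square.

Thin, contract-enforcing layer over ``scipy.stats``: it validates inputs,
attaches degrees of freedom and group labels, and implements the seasonal
comparison workflow (omnibus ANOVA followed by Tukey HSD pairwise
comparisons at alpha = 0.05).  Normality/equal-variance diagnostics are
logged but never gate the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .characterization import _METRICS
from .data_model import FaunaSample, Season, SoilSample, ValidationError

__all__ = [
    "TestResult",
    "SeasonComparison",
    "one_way_anova",
    "pearson_correlation",
    "chi_square_proportions",
    "compare_seasons",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value: must lie in [0, 1]")
        if any(d <= 0 for d in self.df):
            raise ValidationError("df: degrees of freedom must be positive")

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


@dataclass(frozen=True)
class SeasonComparison:
    omnibus: TestResult
    #: (season_a, season_b) -> adjusted p-value; empty if omnibus not significant
    pairwise: Mapping[tuple[str, str], float] = field(default_factory=dict)
    #: seasons whose mean is significantly higher than every other season's
    highest: str | None = None


def one_way_anova(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> TestResult:
    """F = MS_between / MS_within with df (k-1, N-k).

    Identical groups (zero between-group variance with positive
    within-group variance) give F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValidationError("groups: need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("groups: every group needs n >= 2")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df = (k - 1, n_total - k)
    if ssw == 0:
        if ssb == 0:
            raise ValidationError(
                "groups: zero variance both within and between groups"
            )
        f, p = np.inf, 0.0
    else:
        f = (ssb / df[0]) / (ssw / df[1])
        p = float(sps.f.sf(f, *df))
    labels = tuple(labels) if labels else tuple(f"group{i}" for i in range(k))
    # diagnostics are advisory only
    if all(a.size >= 3 for a in arrays) and ssw > 0:
        levene_p = sps.levene(*arrays).pvalue
        if levene_p < 0.05:
            logger.info("Levene test suggests unequal variances (p=%.3g)", levene_p)
    return TestResult("one_way_anova", float(f), df, p, labels)


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> TestResult:
    """Pearson r with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x/y: unequal lengths")
    if x.size < 3:
        raise ValidationError("x/y: need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("x/y: constant vector has undefined correlation")
    r, p = sps.pearsonr(x, y)
    return TestResult("pearson", float(r), (float(x.size - 2),), float(p))


def chi_square_proportions(counts: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square on an r x k contingency table (no continuity
    correction), df = (r-1)(k-1)."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("counts: need an r x k table with r, k >= 2")
    if np.any(table < 0) or np.any(table != np.floor(table)):
        raise ValidationError("counts: entries must be non-negative integers")
    expected = sps.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValidationError("counts: zero expected cell count")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult("chi_square", float(chi2), (float(df),), float(p))


def compare_seasons(
    samples: Sequence[SoilSample | FaunaSample],
    metric: str | Callable[..., float],
    alpha: float = 0.05,
    posthoc: str = "tukey",
) -> SeasonComparison:
    """Omnibus ANOVA of a per-sample metric across seasons; Tukey HSD
    pairwise comparisons when the omnibus test is significant."""
    if isinstance(metric, str):
        try:
            metric_fn = _METRICS[metric][0]
        except KeyError:
            raise ValidationError(f"metric: unknown metric {metric!r}") from None
    else:
        metric_fn = metric
    by_season: dict[Season, list[float]] = {}
    for s in samples:
        by_season.setdefault(s.season, []).append(metric_fn(s))
    if len(by_season) < 2:
        raise ValidationError("samples: need at least two seasons to compare")
    seasons = [s for s in Season if s in by_season]
    groups = [by_season[s] for s in seasons]
    omnibus = one_way_anova(groups, [s.value for s in seasons])
    pairwise: dict[tuple[str, str], float] = {}
    highest = None
    if omnibus.p_value <= alpha:
        if posthoc != "tukey":
            raise ValidationError(f"posthoc: unsupported procedure {posthoc!r}")
        res = sps.tukey_hsd(*[np.asarray(g, dtype=float) for g in groups])
        for i in range(len(seasons)):
            for j in range(i + 1, len(seasons)):
                pairwise[(seasons[i].value, seasons[j].value)] = float(
                    res.pvalue[i, j]
                )
        means = [float(np.mean(g)) for g in groups]
        top = int(np.argmax(means))
        if all(
            res.pvalue[top, j] <= alpha and means[top] > means[j]
            for j in range(len(seasons))
            if j != top
        ):
            highest = seasons[top].value
    return SeasonComparison(omnibus=omnibus, pairwise=pairwise, highest=highest)
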