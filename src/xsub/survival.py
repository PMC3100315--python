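"""Extreme-rank patient selection and Kaplan-Meier / log-rank comparison.

Given a per-dataset ranking of patients by a signature score, the top
and bottom ``floor(fraction * n)`` patients of each dataset (default
fraction one third) are pooled across datasets into a high-score and a
low-score group, whose survival is compared with the product-limit
estimator and the Mantel-Cox log-rank test (chi-square, 1 df).

Conventions (recorded because the arithmetic is sensitive to them):
median survival is the smallest observed event time at which the
Kaplan-Meier estimate falls to 0.5 or below, reported as not-reached if
the curve never gets there; at tied times, events precede censorings in
the risk-set update.  The estimator and test are computed with
lifelines.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .containers import SurvivalRecord

__all__ = [
    "KaplanMeierCurve",
    "StratifiedCohort",
    "StratificationReport",
    "select_extremes",
    "km_curve",
    "logrank_test",
    "stratify_and_compare",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Step-function survival estimate at the distinct observed times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None  # None = median not reached
    n: int

    def at(self, t: float) -> float:
        """S(t): right-continuous step evaluation."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class StratifiedCohort:
    group_high: tuple[SurvivalRecord, ...]
    group_low: tuple[SurvivalRecord, ...]
    per_dataset_counts: Mapping[str, int]  # selected per end, per dataset
    fraction: float


@dataclass(frozen=True)
class StratificationReport:
    cohort: StratifiedCohort
    km_high: KaplanMeierCurve
    km_low: KaplanMeierCurve
    chi_square: float
    p_value: float

    @property
    def median_high(self) -> float | None:
        return self.km_high.median

    @property
    def median_low(self) -> float | None:
        return self.km_low.median


def _records_frame(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def km_curve(records: Sequence[SurvivalRecord]) -> KaplanMeierCurve:
    """Product-limit survival estimate with the median convention above."""
    if not records:
        raise ValueError("no survival records given")
    times, events = _records_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    # event_table carries a t=0 anchor row; observed times are all > 0
    table = kmf.event_table[kmf.event_table.index > 0]
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[grid, "KM_estimate"].to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=int)

    median: float | None = None
    event_times = table.index[table["observed"] > 0].to_numpy(dtype=float)
    for t in event_times:
        if kmf.survival_function_.loc[t, "KM_estimate"] <= 0.5 + 1e-12:
            median = float(t)
            break
    return KaplanMeierCurve(times=grid, survival=surv, at_risk=at_risk,
                            median=median, n=len(records))


def logrank_test(
    group_high: Sequence[SurvivalRecord], group_low: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Mantel-Cox log-rank chi-square (1 df) and p-value for two groups."""
    if not group_high or not group_low:
        raise ValueError("both groups must be non-empty")
    t_h, e_h = _records_frame(group_high)
    t_l, e_l = _records_frame(group_low)
    if e_h.sum() + e_l.sum() == 0:
        raise ValueError("log-rank test needs at least one observed event")
    res = _lifelines_logrank(t_h, t_l, event_observed_A=e_h, event_observed_B=e_l)
    chi2, p = float(res.test_statistic), float(res.p_value)
    if not (np.isfinite(chi2) and np.isfinite(p)):
        raise ValueError("log-rank variance is zero; the test statistic is undefined")
    return chi2, p


def select_extremes(
    ranking: pd.DataFrame,
    records: Iterable[SurvivalRecord],
    fraction: float = 1.0 / 3.0,
) -> StratifiedCohort:
    """Pick the top/bottom ``floor(fraction*n)`` ranked samples per dataset.

    ``ranking`` needs columns ``sample_id``, ``score`` and (optionally)
    ``dataset``; it is the output shape of
    :func:`xsub.gsea.es_difference_ranking`.  Selected samples are
    pooled across datasets into the high- and low-score groups.  A
    dataset too small to contribute (floor = 0) is skipped with a
    warning.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    required = {"sample_id", "score"}
    if not required <= set(ranking.columns):
        raise ValueError(f"ranking must have columns {sorted(required)}")
    ranking = ranking.copy()
    if "dataset" not in ranking.columns:
        ranking["dataset"] = ""

    by_sample = {r.sample_id: r for r in records}
    missing = [s for s in ranking["sample_id"] if s not in by_sample]
    if missing:
        raise ValueError(f"ranked samples without survival records: {missing[:10]}")

    high: list[SurvivalRecord] = []
    low: list[SurvivalRecord] = []
    counts: dict[str, int] = {}
    for ds, block in ranking.groupby("dataset", sort=False):
        block = block.sort_values(["score", "sample_id"], ascending=[False, True], kind="stable")
        k = math.floor(fraction * len(block))
        if k == 0:
            warnings.warn(f"dataset {ds!r} has too few samples ({len(block)}) for fraction "
                          f"{fraction:.3g}; skipped")
            continue
        counts[str(ds)] = k
        high.extend(by_sample[s] for s in block["sample_id"].head(k))
        low.extend(by_sample[s] for s in block["sample_id"].tail(k))
    if not high or not low:
        raise ValueError("no dataset was large enough to contribute to the stratification")
    logger.info("select_extremes: %d per group from %d datasets", len(high), len(counts))
    return StratifiedCohort(group_high=tuple(high), group_low=tuple(low),
                            per_dataset_counts=counts, fraction=fraction)


def stratify_and_compare(
    ranking: pd.DataFrame,
    records: Iterable[SurvivalRecord],
    fraction: float = 1.0 / 3.0,
) -> StratificationReport:
    """End-to-end: select extremes, fit per-group KM, run the log-rank test."""
    records = list(records)
    cohort = select_extremes(ranking, records, fraction)
    km_high = km_curve(cohort.group_high)
    km_low = km_curve(cohort.group_low)
    chi2, p = logrank_test(cohort.group_high, cohort.group_low)
    return StratificationReport(cohort=cohort, km_high=km_high, km_low=km_low,
                                chi_square=chi2, p_value=p)
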