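"""Detection metrics, confidence intervals, lead times and alert burden.

Episode-level crosstabs yield sensitivity (TP / escalations), specificity,
positive predictive value (TP / warnings), the number of warning periods
needed to evaluate per true warning (NNE = 1/PPV), and warnings per patient
admission day.  Confidence intervals are standard-error (Wald) intervals on
proportions; the NNE interval inverts the PPV interval.  Lead time is the
elapsed time from a true-positive period's first alert to its escalation,
summarised by median/IQR and a cumulative detection curve.  The alert-burden
statistic divides alerting minutes by available scored minutes in a window —
the per-patient "fraction of warning minutes" used for gradual risk
assessment — and group contrasts use the Mann-Whitney U test with midranks
and a tie-corrected normal approximation.

Quartiles throughout use linear interpolation between order statistics
(numpy's default), a documented convention choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort import Admission
from .episodes import ContingencyTable, WarningPeriod
from .scoring import ScoreSeries

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; the message names the metric."""


class DegenerateVarianceError(ValueError):
    """All pooled values identical: the rank test has zero variance."""


def proportion_ci(numerator: int, n: int) -> tuple[float, float]:
    """Wald 95% interval ``p +/- 1.96 sqrt(p(1-p)/n)``, clipped to [0, 1]."""
    if n <= 0:
        raise UndefinedMetricError("proportion_ci: n must be positive")
    if not 0 <= numerator <= n:
        raise ValueError("numerator must lie in [0, n]")
    p = numerator / n
    half = Z95 * math.sqrt(p * (1.0 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


@dataclass(frozen=True)
class ValueCI:
    value: float
    lo: float
    hi: float


@dataclass(frozen=True)
class MetricSet:
    """Point estimates with 95% CIs for one scenario."""

    scenario: str
    sensitivity: ValueCI
    specificity: ValueCI
    ppv: ValueCI
    nne: ValueCI
    warnings_per_patient_day: float
    table: ContingencyTable

    def display(self) -> dict[str, object]:
        """Rounded presentation values: whole percentages, PPV to 3 decimals,
        NNE to the nearest integer, warnings/day to 2 decimals."""
        pct = lambda x: int(round(100.0 * x))
        return {
            "scenario": self.scenario,
            "sensitivity_pct": pct(self.sensitivity.value),
            "sensitivity_ci_pct": (pct(self.sensitivity.lo), pct(self.sensitivity.hi)),
            "specificity_pct": pct(self.specificity.value),
            "specificity_ci_pct": (pct(self.specificity.lo), pct(self.specificity.hi)),
            "ppv": round(self.ppv.value, 3),
            "ppv_ci": (round(self.ppv.lo, 3), round(self.ppv.hi, 3)),
            "nne": int(round(self.nne.value)),
            "nne_ci": (int(round(self.nne.lo)), int(round(self.nne.hi))),
            "warnings_per_patient_day": round(self.warnings_per_patient_day, 2),
        }


def contingency_metrics(ct: ContingencyTable, scenario: str = "") -> MetricSet:
    """Sensitivity, specificity, PPV, NNE and warnings/day from episode counts."""
    if ct.n_eoc == 0:
        raise UndefinedMetricError("sensitivity undefined: no escalations (tp + fn = 0)")
    if ct.n_warnings == 0:
        raise UndefinedMetricError("ppv undefined: no warning periods (tp + fp = 0)")
    if ct.tn + ct.fp == 0:
        raise UndefinedMetricError("specificity undefined: tn + fp = 0")
    sens = ct.tp / ct.n_eoc
    spec = ct.tn / (ct.tn + ct.fp)
    ppv = ct.tp / ct.n_warnings
    sens_ci = proportion_ci(ct.tp, ct.n_eoc)
    spec_ci = proportion_ci(ct.tn, ct.tn + ct.fp)
    ppv_ci = proportion_ci(ct.tp, ct.n_warnings)
    if ct.tp == 0:
        raise UndefinedMetricError("nne undefined: tp = 0")
    nne = ct.n_warnings / ct.tp
    nne_ci = (1.0 / ppv_ci[1] if ppv_ci[1] > 0 else math.inf,
              1.0 / ppv_ci[0] if ppv_ci[0] > 0 else math.inf)
    if ct.patient_days <= 0:
        raise UndefinedMetricError("warnings per patient-day undefined: patient_days = 0")
    return MetricSet(
        scenario=scenario,
        sensitivity=ValueCI(sens, *sens_ci),
        specificity=ValueCI(spec, *spec_ci),
        ppv=ValueCI(ppv, *ppv_ci),
        nne=ValueCI(nne, *nne_ci),
        warnings_per_patient_day=ct.n_warnings / ct.patient_days,
        table=ct,
    )


@dataclass
class LeadTimeSummary:
    """Lead times (hours from first alert to escalation) over true positives."""

    leads_h: list[float]
    n_eoc: int
    median_h: float | None
    iqr_h: tuple[float, float] | None
    curve: pd.DataFrame  # columns: hours_before, cum_pct_detected

    @property
    def plateau_pct(self) -> float:
        return float(self.curve["cum_pct_detected"].iloc[-1]) if len(self.curve) else 0.0


def lead_time_summary(tp_periods: Sequence[WarningPeriod], n_eoc: int,
                      max_hours: int | None = None) -> LeadTimeSummary:
    """Median/IQR lead time and the cumulative detection curve.

    The curve at ``x`` hours is the percentage of *all* effective escalations
    whose detecting period's first alert preceded them by at most ``x`` hours;
    it is non-decreasing and plateaus at sensitivity x 100.
    """
    leads = sorted((p.eoc_t - p.start) / 60.0 for p in tp_periods if p.eoc_t is not None)
    hi = max(168, int(math.ceil(max(leads)))) if leads else 168
    if max_hours is not None:
        hi = max_hours
    grid = np.arange(0, hi + 1)
    if n_eoc > 0 and leads:
        cum = 100.0 * np.searchsorted(leads, grid, side="right") / n_eoc
    else:
        cum = np.zeros_like(grid, dtype=float)
    curve = pd.DataFrame({"hours_before": grid, "cum_pct_detected": cum})
    if leads:
        med = float(np.median(leads))
        q1, q3 = (float(q) for q in np.quantile(leads, [0.25, 0.75]))
        return LeadTimeSummary(leads, n_eoc, med, (q1, q3), curve)
    return LeadTimeSummary([], n_eoc, None, None, curve)


#: Largest per-group size at which the exact permutation p-value is used.
EXACT_MW_MAX_N = 8


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Rank-sum U for ``x``, tie-corrected normal Z, and two-sided p.

    Midranks are assigned to ties and ``Z = (U - mx my / 2) / sd`` with the
    tie-corrected standard deviation.  For large samples p comes from the
    normal approximation; when both groups have at most ``EXACT_MW_MAX_N``
    observations the exhaustive permutation p-value
    ``P(|U - mu| >= |U_obs - mu|)`` is returned instead, since the normal
    approximation is unreliable there (desk statistics packages switch the
    same way).  ``Z < 0`` when ``x`` tends to be smaller than ``y``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    mx, my = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise DegenerateVarianceError("all values identical across both samples")
    ranks = rankdata(pooled)
    u = float(ranks[:mx].sum() - mx * (mx + 1) / 2.0)
    n = mx + my
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    var = mx * my / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        raise DegenerateVarianceError("zero variance after tie correction")
    mu = mx * my / 2.0
    z = (u - mu) / math.sqrt(var)
    if mx <= EXACT_MW_MAX_N and my <= EXACT_MW_MAX_N:
        p = _exact_permutation_p(ranks, mx, mu, abs(u - mu))
    else:
        p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return u, z, p


def _exact_permutation_p(ranks: np.ndarray, mx: int, mu: float, dev: float) -> float:
    from itertools import combinations

    offset = mx * (mx + 1) / 2.0
    hits = total = 0
    for idx in combinations(range(len(ranks)), mx):
        total += 1
        if abs(ranks[list(idx)].sum() - offset - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def alerting_fraction(series: ScoreSeries, a: Admission,
                      window_start: int, window_end: int) -> float | None:
    """Alerting minutes over valid scored minutes in ``[window_start, window_end)``.

    Returns ``None`` (undefined) when no valid scored minute falls in the
    window — undefined is a value, not an error.
    """
    if window_start >= window_end:
        raise ValueError("window_start must be < window_end")
    e = series.entries
    in_win = (e["t_min"] >= window_start) & (e["t_min"] < window_end)
    valid = in_win & e["valid"]
    denom = int(valid.sum())
    if denom == 0:
        return None
    num = int((valid & (e["score"] >= series.alert_threshold)).sum())
    return num / denom


def prelude_bins(series: ScoreSeries, a: Admission, eoc_t: int,
                 bin_edges_h: Sequence[int] = (72, 48, 24, 0)) -> tuple[float | None, ...]:
    """Alerting fractions over the last three days before an escalation.

    Default bins: [72, 48), [48, 24) and [24, 0) hours before ``eoc_t``; bins
    reaching before admission are clipped at minute 0.
    """
    if eoc_t <= 0:
        raise ValueError("eoc_t must be positive")
    out = []
    for hi_h, lo_h in zip(bin_edges_h, bin_edges_h[1:]):
        ws = max(0, eoc_t - hi_h * 60)
        we = eoc_t - lo_h * 60
        out.append(alerting_fraction(series, a, ws, we) if ws < we else None)
    return tuple(out)


@dataclass(frozen=True)
class BurdenComparison:
    """Group contrast of per-admission alerting-minute fractions."""

    median: tuple[float, float]          # (group x, group y)
    iqr: tuple[tuple[float, float], tuple[float, float]]
    n: tuple[int, int]
    n_excluded: tuple[int, int]          # undefined fractions, per group
    u: float
    z: float
    p: float


def group_burden_comparison(x_fractions: Sequence[float | None],
                            y_fractions: Sequence[float | None]) -> BurdenComparison:
    """Medians, IQRs and the Mann-Whitney contrast of two burden samples.

    Admissions with undefined fractions are excluded and counted.  With the
    conventional ordering (non-escalation group first), ``z < 0`` indicates a
    higher burden in the escalation group.
    """
    def clean(vals: Sequence[float | None]) -> tuple[np.ndarray, int]:
        kept = np.array([v for v in vals if v is not None], dtype=float)
        return kept, len(vals) - len(kept)

    x, x_drop = clean(x_fractions)
    y, y_drop = clean(y_fractions)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must contain defined fractions")
    u, z, p = mann_whitney(x, y)
    q = lambda v: (float(np.quantile(v, 0.25)), float(np.quantile(v, 0.75)))
    return BurdenComparison(
        median=(float(np.median(x)), float(np.median(y))),
        iqr=(q(x), q(y)),
        n=(len(x), len(y)),
        n_excluded=(x_drop, y_drop),
        u=u, z=z, p=p,
    )
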