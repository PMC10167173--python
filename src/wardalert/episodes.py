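"""Warning-period construction, negative-time segmentation and classification.

This is the episode model at the heart of the comparison.  An alerting score
value opens a *warning period* lasting 4 h; each further alert inside the open
period extends it to 4 h past that alert (greedy left-to-right chaining, with
the half-open convention that an alert exactly at the period's end starts a
new period).  A period containing an effective escalation of care (EOC) is
truncated at the escalation and keeps the escalation on its closed right
endpoint — the escalation "results from" the period.  Monitored time not
covered by warning periods is cut into *negative segments* of at most 8 h,
the regular observation interval for stable patients, so that both scenarios
count comparable evaluation units.

Effective escalations follow the repeat-call rule: the first EOC-eligible
event always counts; after it, only further rapid-response calls at least
24 h after the most recent effective escalation count, and any non-RRT
escalation (ICU transfer, emergency surgery, death) ends follow-up.

Classification is per episode: a warning period is a true positive when it
contains an effective escalation, otherwise a false positive; an escalation
in no warning period is a false negative; a negative segment containing no
escalation is a true negative.  Every effective escalation is matched to at
most one episode, so ``tp + fn`` always equals the number of effective
escalations.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cohort import Admission, ClinicalEvent, EOC_KINDS

NON_RRT_EOC = EOC_KINDS - {"rrt"}


class OrderingError(ValueError):
    """Input events or alerts were not in time order."""


class ConsistencyError(ValueError):
    """Warning periods overlap or are otherwise mutually inconsistent."""


class CoverageError(ValueError):
    """An effective escalation lies outside every episode."""


@dataclass(frozen=True)
class EffectiveEoc:
    t_min: int
    kind: str
    sequence_index: int


@dataclass
class WarningPeriod:
    start: int
    end: int                      # half-open; closed when truncated_by_eoc
    alert_times: list[int]
    truncated_by_eoc: bool = False
    classification: str = "unclassified"  # TP | FP | unclassified
    eoc_t: int | None = None      # matched escalation time (TP only)

    def contains_eoc_time(self, t: int) -> bool:
        return self.start <= t < self.end or (self.truncated_by_eoc and t == self.end)

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class NegativeSegment:
    start: int
    end: int
    classification: str = "unclassified"  # TN | FN


@dataclass(frozen=True)
class ContingencyTable:
    """Episode-level counts for one scenario (warnings are periods)."""

    tp: int
    fp: int
    tn: int
    fn: int
    patient_days: float = 0.0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_eoc(self) -> int:
        return self.tp + self.fn

    @property
    def n_warnings(self) -> int:
        return self.tp + self.fp

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(self.tp + other.tp, self.fp + other.fp,
                                self.tn + other.tn, self.fn + other.fn,
                                self.patient_days + other.patient_days)


def derive_effective_eocs(events: Sequence[ClinicalEvent],
                          rrt_separation_min: int = 1440) -> list[EffectiveEoc]:
    """Reduce raw clinical events to the escalations that count.

    Events after a censoring event (discharge or monitoring stop) are ignored.
    The first EOC-eligible event is always effective; afterwards only RRT
    activations at least ``rrt_separation_min`` after the most recent effective
    escalation are effective, and a non-RRT escalation closes the admission to
    further escalations.
    """
    times = [ev.t_min for ev in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise OrderingError("events must be ordered by t_min")
    effective: list[EffectiveEoc] = []
    censored_at: int | None = None
    closed = False
    for ev in events:
        if censored_at is not None and ev.t_min > censored_at:
            continue
        if ev.kind in ("discharge", "monitoring_stop"):
            censored_at = ev.t_min if censored_at is None else min(censored_at, ev.t_min)
            continue
        if not ev.is_eoc or closed:
            continue
        if not effective:
            effective.append(EffectiveEoc(ev.t_min, ev.kind, 1))
        elif ev.kind == "rrt" and ev.t_min - effective[-1].t_min >= rrt_separation_min:
            effective.append(EffectiveEoc(ev.t_min, ev.kind, len(effective) + 1))
        else:
            continue
        if ev.kind in NON_RRT_EOC:
            closed = True
    return effective


def build_warning_periods(alerts: Sequence[int],
                          eocs: Sequence[EffectiveEoc],
                          window_min: int = 240) -> list[WarningPeriod]:
    """Greedy left-to-right chaining of alerts into warning periods.

    An alert at ``t`` opens a period ending at ``t + window_min``; an alert
    before the current end extends the end to 4 h past itself; an alert at or
    after the end opens a new period.  A period that reaches an effective
    escalation is truncated there (closed right endpoint) and chaining resumes
    after the escalation.  Alerts after the final non-RRT escalation are
    discarded.
    """
    alerts = [int(t) for t in alerts]
    if any(b <= a for a, b in zip(alerts, alerts[1:])):
        raise OrderingError("alerts must be strictly increasing")
    terminal = next((e.t_min for e in eocs if e.kind in NON_RRT_EOC), None)
    if terminal is not None:
        alerts = [t for t in alerts if t <= terminal]
    eoc_times = sorted(e.t_min for e in eocs)

    def first_eoc_in(start: int, end: int) -> int | None:
        i = bisect_left(eoc_times, start)
        if i < len(eoc_times) and eoc_times[i] < end:
            return eoc_times[i]
        return None

    periods: list[WarningPeriod] = []
    i = 0
    while i < len(alerts):
        start = alerts[i]
        end = start + window_min
        times = [start]
        i += 1
        trunc_at = first_eoc_in(start, end)
        while i < len(alerts) and alerts[i] < end and (trunc_at is None or alerts[i] <= trunc_at):
            times.append(alerts[i])
            end = alerts[i] + window_min
            i += 1
            trunc_at = first_eoc_in(start, end)
        if trunc_at is not None:
            periods.append(WarningPeriod(start, trunc_at, times, truncated_by_eoc=True))
        else:
            periods.append(WarningPeriod(start, end, times))
    return periods


def censor_time(a: Admission, eocs: Sequence[EffectiveEoc] | None = None,
                rrt_separation_min: int = 1440) -> int:
    """End of the evaluable timeline: monitoring stop, discharge, final
    non-RRT escalation, or end of stay — whichever comes first."""
    if eocs is None:
        eocs = derive_effective_eocs(a.events, rrt_separation_min)
    t = a.length_of_stay_min
    for ev in a.events:
        if ev.kind in ("discharge", "monitoring_stop"):
            t = min(t, ev.t_min)
    for e in eocs:
        if e.kind in NON_RRT_EOC:
            t = min(t, e.t_min)
    return t


def clip_periods(periods: Iterable[WarningPeriod], censor: int) -> list[WarningPeriod]:
    """Restrict periods to the evaluable timeline ``[0, censor]``."""
    out = []
    for p in periods:
        if p.start > censor:
            continue
        end = min(p.end, censor) if not p.truncated_by_eoc else p.end
        out.append(WarningPeriod(p.start, end, [t for t in p.alert_times if t <= end],
                                 truncated_by_eoc=p.truncated_by_eoc))
    return out


def segment_negative_time(a: Admission,
                          periods: Sequence[WarningPeriod],
                          max_len_min: int = 480,
                          scenario: str = "continuous",
                          rrt_separation_min: int = 1440) -> list[NegativeSegment]:
    """Tile the non-warning part of ``[0, censor)`` into segments of <= 8 h.

    Each gap between warning periods is cut into consecutive half-open
    ``max_len_min`` blocks with one shorter remainder; together with the
    periods these exactly tile the evaluable timeline.
    """
    ordered = sorted(periods, key=lambda p: p.start)
    for p, q in zip(ordered, ordered[1:]):
        if q.start < p.end:
            raise ConsistencyError(f"warning periods overlap at [{q.start}, {p.end})")
    censor = censor_time(a, rrt_separation_min=rrt_separation_min)
    segments: list[NegativeSegment] = []
    cursor = 0
    bounds = [(p.start, min(p.end, censor)) for p in ordered if p.start < censor]
    for ps, pe in bounds + [(censor, censor)]:
        gap_end = min(ps, censor)
        while cursor < gap_end:
            seg_end = min(cursor + max_len_min, gap_end)
            segments.append(NegativeSegment(cursor, seg_end))
            cursor = seg_end
        cursor = max(cursor, pe)
    return segments


def classify(periods: Sequence[WarningPeriod],
             segments: Sequence[NegativeSegment],
             eocs: Sequence[EffectiveEoc],
             patient_days: float = 0.0) -> tuple[ContingencyTable, list[WarningPeriod], list[NegativeSegment]]:
    """Episode-level contingency classification.

    Each effective escalation is matched to the first warning period containing
    it (closed right endpoint for truncated periods); unmatched escalations are
    false negatives and must fall inside a negative segment (a terminal
    escalation abutting the censor boundary is attributed to the last segment
    via its closed end).  Returns the table plus annotated copies.
    """
    periods = [WarningPeriod(p.start, p.end, list(p.alert_times), p.truncated_by_eoc)
               for p in sorted(periods, key=lambda p: p.start)]
    segments = [NegativeSegment(s.start, s.end) for s in sorted(segments, key=lambda s: s.start)]
    tp = 0
    fn_times: list[int] = []
    for e in sorted(eocs, key=lambda e: e.t_min):
        hit = next((p for p in periods if p.contains_eoc_time(e.t_min)), None)
        if hit is not None:
            tp += 1
            hit.classification = "TP"
            if hit.eoc_t is None:
                hit.eoc_t = e.t_min
            continue
        seg = next((s for s in segments if s.start <= e.t_min < s.end
                    or (e.t_min == s.end and not any(s2.start <= e.t_min < s2.end for s2 in segments))),
                   None)
        if seg is None:
            raise CoverageError(f"escalation at t={e.t_min} outside every episode")
        seg.classification = "FN"
        fn_times.append(e.t_min)
    for p in periods:
        if p.classification == "unclassified":
            p.classification = "FP"
    for s in segments:
        if s.classification == "unclassified":
            s.classification = "TN"
    fp = sum(p.classification == "FP" for p in periods)
    tn = sum(s.classification == "TN" for s in segments)
    table = ContingencyTable(tp=tp, fp=fp, tn=tn, fn=len(fn_times), patient_days=patient_days)
    return table, periods, segments


@dataclass
class AdmissionEpisodes:
    """All episode-model outputs for one admission and one scenario."""

    admission_id: str
    scenario: str
    eocs: list[EffectiveEoc]
    periods: list[WarningPeriod]
    segments: list[NegativeSegment]
    table: ContingencyTable
    censor: int


def evaluate_admission(a: Admission,
                       alert_minutes: Sequence[int],
                       scenario: str,
                       window_min: int = 240,
                       max_negative_min: int = 480,
                       rrt_separation_min: int = 1440) -> AdmissionEpisodes:
    """Run the full episode model for one admission and one alert stream."""
    eocs = derive_effective_eocs(a.events, rrt_separation_min)
    censor = censor_time(a, eocs)
    terminal = next((e.t_min for e in eocs if e.kind in NON_RRT_EOC), None)
    alerts = [int(t) for t in alert_minutes if t < censor or (terminal is not None and t == terminal)]
    periods = clip_periods(build_warning_periods(alerts, eocs, window_min), censor)
    segments = segment_negative_time(a, periods, max_negative_min, scenario, rrt_separation_min)
    table, periods, segments = classify(periods, segments, eocs,
                                        patient_days=a.patient_days)
    return AdmissionEpisodes(a.admission_id, scenario, eocs, periods, segments, table, censor)
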