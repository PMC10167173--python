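"""Admission-level data model and CSV round-tripping for ward-monitoring cohorts.

An admission couples three time-aligned records, all indexed by integer minutes
since the start of the stay (minute 0 = admission; intervals are half-open
``[start, end)``):

* per-minute vital-sign samples from a wearable monitor,
* periodic nurse observations (vitals plus oxygen delivery and AVPU level),
* clinical events (escalations of care and censoring events).

Missingness convention: a minute with no sample row means the monitor recorded
nothing that minute (device offline); a sample row with an empty channel means
that sensor alone dropped out.  Per-minute streams are held as DataFrames so
that cohorts of millions of monitored minutes stay cheap; the record dataclasses
(:class:`VitalSample`, :class:`PeriodicObservation`) are the row-level currency
of the scoring functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VITAL_CHANNELS = ("hr", "rr", "spo2", "sbp", "skin_temp")
OBS_CHANNELS = ("hr", "rr", "spo2", "sbp", "temp")
AVPU_LEVELS = ("A", "V", "P", "U")

EOC_KINDS = frozenset({"rrt", "icu_unplanned", "emergency_surgery", "death"})
CENSOR_KINDS = frozenset({"discharge", "monitoring_stop"})
EVENT_KINDS = EOC_KINDS | CENSOR_KINDS

#: Per-channel plausibility bounds; values outside are flagged on read.
PHYSIOLOGIC_BOUNDS = {
    "hr": (10.0, 300.0),
    "rr": (0.0, 80.0),
    "spo2": (30.0, 100.0),
    "sbp": (30.0, 300.0),
    "skin_temp": (25.0, 45.0),
    "temp": (25.0, 45.0),
}

VITALS_COLUMNS = ("admission_id", "t_min") + VITAL_CHANNELS
OBS_COLUMNS = ("admission_id", "t_min") + OBS_CHANNELS + ("oxygen_delivery", "consciousness")
EVENTS_COLUMNS = ("admission_id", "t_min", "kind")


class CohortError(Exception):
    """Base class for cohort I/O and validation failures."""


class SchemaError(CohortError):
    """A CSV is missing required columns or contains unknown categorical codes."""


class DuplicateRecordError(CohortError):
    """Two vital-sign rows claim the same (admission_id, t_min)."""


@dataclass(frozen=True)
class VitalSample:
    """One monitored minute; ``None`` marks a dropped-out channel."""

    t_min: int
    hr: float | None = None
    rr: float | None = None
    spo2: float | None = None
    sbp: float | None = None
    skin_temp: float | None = None

    def present_channels(self) -> tuple[str, ...]:
        return tuple(ch for ch in VITAL_CHANNELS if getattr(self, ch) is not None)


@dataclass(frozen=True)
class PeriodicObservation:
    """One nurse-validated observation set.

    ``oxygen_delivery`` is litres/minute of supplemental oxygen (0 = room air;
    a plain boolean is accepted and coerced).  ``consciousness`` is an AVPU
    level.
    """

    t_min: int
    hr: float | None = None
    rr: float | None = None
    spo2: float | None = None
    sbp: float | None = None
    temp: float | None = None
    oxygen_delivery: float = 0.0
    consciousness: str = "A"

    def present_channels(self) -> tuple[str, ...]:
        return tuple(ch for ch in OBS_CHANNELS if getattr(self, ch) is not None)


@dataclass(frozen=True)
class ClinicalEvent:
    t_min: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SchemaError(f"unknown event kind {self.kind!r}")

    @property
    def is_eoc(self) -> bool:
        return self.kind in EOC_KINDS


@dataclass
class Admission:
    """One patient stay: per-minute streams, periodic observations, events.

    ``samples`` has columns ``t_min`` + the five vital channels; ``observations``
    additionally carries ``oxygen_delivery`` and ``consciousness``.  Both are
    sorted by ``t_min``.
    """

    admission_id: str
    ward: str = "medical"
    length_of_stay_min: int = 0
    samples: pd.DataFrame = field(default_factory=lambda: empty_samples())
    observations: pd.DataFrame = field(default_factory=lambda: empty_observations())
    events: list[ClinicalEvent] = field(default_factory=list)

    def iter_samples(self) -> Iterator[VitalSample]:
        for row in self.samples.itertuples(index=False):
            yield VitalSample(
                t_min=int(row.t_min),
                **{ch: None if pd.isna(getattr(row, ch)) else float(getattr(row, ch)) for ch in VITAL_CHANNELS},
            )

    def iter_observations(self) -> Iterator[PeriodicObservation]:
        for row in self.observations.itertuples(index=False):
            yield PeriodicObservation(
                t_min=int(row.t_min),
                **{ch: None if pd.isna(getattr(row, ch)) else float(getattr(row, ch)) for ch in OBS_CHANNELS},
                oxygen_delivery=0.0 if pd.isna(row.oxygen_delivery) else float(row.oxygen_delivery),
                consciousness=str(row.consciousness),
            )

    @property
    def patient_days(self) -> float:
        return self.length_of_stay_min / 1440.0


def empty_samples() -> pd.DataFrame:
    return pd.DataFrame({"t_min": pd.Series(dtype="int64"),
                         **{ch: pd.Series(dtype="float64") for ch in VITAL_CHANNELS}})


def empty_observations() -> pd.DataFrame:
    df = pd.DataFrame({"t_min": pd.Series(dtype="int64"),
                       **{ch: pd.Series(dtype="float64") for ch in OBS_CHANNELS}})
    df["oxygen_delivery"] = pd.Series(dtype="float64")
    df["consciousness"] = pd.Series(dtype="object")
    return df


def _ward_from_id(admission_id: str) -> str:
    return "surgical" if admission_id[:1] == "S" else "medical"


def _check_header(df: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _flag_bounds(df: pd.DataFrame, channels: Sequence[str], label: str) -> None:
    """Log (never drop) rows whose values fall outside physiologic bounds."""
    for ch in channels:
        lo, hi = PHYSIOLOGIC_BOUNDS[ch]
        bad = df[ch].notna() & ((df[ch] < lo) | (df[ch] > hi))
        if bad.any():
            logger.warning("%s: %d %s value(s) outside [%g, %g]; kept and flagged",
                           label, int(bad.sum()), ch, lo, hi)


def read_cohort(vitals_path: str | Path,
                observations_path: str | Path,
                events_path: str | Path) -> list[Admission]:
    """Load a cohort from the three on-disk CSVs.

    One :class:`Admission` is returned per distinct ``admission_id`` appearing
    in any file.  Out-of-bounds vitals are flagged via logging but never
    dropped; duplicate per-minute rows raise :class:`DuplicateRecordError`.
    """
    vit = pd.read_csv(vitals_path, dtype={"admission_id": str})
    obs = pd.read_csv(observations_path, dtype={"admission_id": str, "consciousness": str})
    evt = pd.read_csv(events_path, dtype={"admission_id": str, "kind": str})
    _check_header(vit, VITALS_COLUMNS, vitals_path)
    _check_header(obs, OBS_COLUMNS, observations_path)
    _check_header(evt, EVENTS_COLUMNS, events_path)

    if len(vit) == 0:
        logger.warning("%s: no vital-sign rows (header only)", vitals_path)
    dup = vit.duplicated(subset=["admission_id", "t_min"])
    if dup.any():
        first = vit.loc[dup, ["admission_id", "t_min"]].iloc[0]
        raise DuplicateRecordError(
            f"duplicate vital row for admission {first['admission_id']} at t_min={int(first['t_min'])}")
    _flag_bounds(vit, VITAL_CHANNELS, "vitals")
    _flag_bounds(obs, OBS_CHANNELS, "observations")
    bad_avpu = obs["consciousness"].notna() & ~obs["consciousness"].isin(AVPU_LEVELS)
    if bad_avpu.any():
        raise SchemaError(f"observations: unknown consciousness code(s) "
                          f"{sorted(obs.loc[bad_avpu, 'consciousness'].unique())}")
    bad_kind = ~evt["kind"].isin(sorted(EVENT_KINDS))
    if bad_kind.any():
        raise SchemaError(f"events: unknown event kind(s) {sorted(evt.loc[bad_kind, 'kind'].unique())}")

    ids = sorted(set(vit["admission_id"]) | set(obs["admission_id"]) | set(evt["admission_id"]))
    vit_by = dict(tuple(vit.groupby("admission_id", sort=False)))
    obs_by = dict(tuple(obs.groupby("admission_id", sort=False)))
    evt_by = dict(tuple(evt.groupby("admission_id", sort=False)))

    admissions: list[Admission] = []
    for aid in ids:
        s = vit_by.get(aid)
        s = (s.sort_values("t_min").reset_index(drop=True)[list(VITALS_COLUMNS)].drop(columns="admission_id")
             if s is not None else empty_samples())
        s["t_min"] = s["t_min"].astype("int64")
        o = obs_by.get(aid)
        o = (o.sort_values("t_min").reset_index(drop=True)[list(OBS_COLUMNS)].drop(columns="admission_id")
             if o is not None else empty_observations())
        o["t_min"] = o["t_min"].astype("int64")
        e = evt_by.get(aid)
        events = ([ClinicalEvent(int(r.t_min), str(r.kind))
                   for r in e.sort_values("t_min", kind="stable").itertuples(index=False)]
                  if e is not None else [])
        terminal = [ev.t_min for ev in events if ev.kind in ("discharge", "death")]
        los = max(terminal) if terminal else int(max(
            [s["t_min"].max() + 1 if len(s) else 0, o["t_min"].max() + 1 if len(o) else 0]
            + [ev.t_min for ev in events] + [0]))
        admissions.append(Admission(admission_id=aid, ward=_ward_from_id(aid),
                                    length_of_stay_min=int(los), samples=s,
                                    observations=o, events=events))
    return admissions


def write_cohort(admissions: Iterable[Admission], out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write ``vitals.csv``, ``observations.csv`` and ``events.csv``.

    Row order is deterministic: admission_id, then t_min.  Missing channel
    values are written as empty strings.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    admissions = sorted(admissions, key=lambda a: a.admission_id)

    def _stack(frames: list[pd.DataFrame], columns: Sequence[str], empty: pd.DataFrame) -> pd.DataFrame:
        if frames:
            return pd.concat(frames, ignore_index=True)[list(columns)]
        out = empty.copy()
        out.insert(0, "admission_id", pd.Series(dtype="object"))
        return out[list(columns)]

    vit = _stack([a.samples.assign(admission_id=a.admission_id) for a in admissions if True],
                 VITALS_COLUMNS, empty_samples())
    obs = _stack([a.observations.assign(admission_id=a.admission_id) for a in admissions],
                 OBS_COLUMNS, empty_observations())
    evt_rows = [(a.admission_id, ev.t_min, ev.kind) for a in admissions for ev in a.events]
    evt = pd.DataFrame(evt_rows, columns=list(EVENTS_COLUMNS))

    paths = (out_dir / "vitals.csv", out_dir / "observations.csv", out_dir / "events.csv")
    vit.to_csv(paths[0], index=False, na_rep="")
    obs.to_csv(paths[1], index=False, na_rep="")
    evt.to_csv(paths[2], index=False, na_rep="")
    return paths


def validate_admission(a: Admission,
                       *,
                       min_stay_min: int = 1440,
                       max_connect_min: int = 720) -> list[str]:
    """Return human-readable rule violations (empty list = valid and eligible).

    Structural invariants (timestamps, ordering, bounds, terminal event) and
    the two eligibility rules — stay of at least ``min_stay_min`` and first
    monitored minute within ``max_connect_min`` of admission — are checked.
    Violations are returned, never raised, so I/O stays lossless.
    """
    v: list[str] = []
    s = a.samples
    if len(s):
        t = s["t_min"].to_numpy()
        if (t < 0).any():
            v.append("sample t_min < 0")
        if not (np.diff(t) > 0).all() if len(t) > 1 else False:
            v.append("samples not strictly increasing in t_min")
        if t.size and t.max() > a.length_of_stay_min:
            v.append("sample timestamp beyond length of stay")
        for ch in VITAL_CHANNELS:
            lo, hi = PHYSIOLOGIC_BOUNDS[ch]
            col = s[ch]
            if ((col < lo) | (col > hi)).any():
                v.append(f"{ch} outside physiologic bounds [{lo:g}, {hi:g}]")
    o = a.observations
    if len(o):
        if (o["t_min"].to_numpy() < 0).any():
            v.append("observation t_min < 0")
        if o["t_min"].max() > a.length_of_stay_min:
            v.append("observation timestamp beyond length of stay")
        if (~o["consciousness"].isin(AVPU_LEVELS)).any():
            v.append("consciousness not an AVPU level")
    terminal = [ev for ev in a.events if ev.kind in ("discharge", "death")]
    if len(terminal) != 1:
        v.append("admission must have exactly one terminal censoring event (discharge or death)")
    elif a.events and a.events[-1].kind not in ("discharge", "death"):
        v.append("terminal censoring event is not last")
    if any(ev.t_min > a.length_of_stay_min or ev.t_min < 0 for ev in a.events):
        v.append("event timestamp outside [0, length of stay]")
    # eligibility
    if a.length_of_stay_min < min_stay_min:
        v.append(f"stay < {min_stay_min / 60:g} h")
    if len(s) == 0 or int(s["t_min"].iloc[0]) > max_connect_min:
        v.append(f"not connected within {max_connect_min / 60:g} h")
    return v


def monitored_minutes(a: Admission, window_start: int, window_end: int) -> int:
    """Count minutes in ``[window_start, window_end)`` with at least one present vital."""
    if window_start >= window_end:
        raise ValueError("window_start must be < window_end")
    s = a.samples
    if not len(s):
        return 0
    in_win = (s["t_min"] >= window_start) & (s["t_min"] < window_end)
    any_present = s[list(VITAL_CHANNELS)].notna().any(axis=1)
    return int((in_win & any_present).sum())


def cohort_summary(admissions: Sequence[Admission]) -> dict:
    """Descriptive rates the generator is expected to reproduce.

    Availability is monitored sample-minutes divided by the monitorable span
    (admission start to monitoring stop, escalation end, or discharge).
    """
    n = len(admissions)
    n_eoc = sum(any(ev.is_eoc for ev in a.events) for a in admissions)
    n_stop = sum(any(ev.kind == "monitoring_stop" for ev in a.events) for a in admissions)
    span = 0
    monitored = 0
    for a in admissions:
        stops = [ev.t_min for ev in a.events if ev.kind == "monitoring_stop"]
        span += min(stops[0] if stops else a.length_of_stay_min, a.length_of_stay_min)
        monitored += len(a.samples)
    los_h = np.array([a.length_of_stay_min / 60.0 for a in admissions]) if n else np.array([np.nan])
    return {
        "n_admissions": n,
        "eoc_fraction": n_eoc / n if n else float("nan"),
        "discontinuation_fraction": n_stop / n if n else float("nan"),
        "availability": monitored / span if span else float("nan"),
        "patient_days": sum(a.patient_days for a in admissions),
        "median_los_h": float(np.median(los_h)),
    }
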