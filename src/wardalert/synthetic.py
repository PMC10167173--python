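"""Synthetic ward cohorts with the statistical structure the analysis assumes.

The generator emulates an eligible general-ward population under continuous
wearable monitoring: about 7% of admissions end in an escalation of care
(EOC: rapid-response call, unplanned ICU admission, emergency surgery, or
death), 79% of monitorable minutes carry a recorded sample, 11% of admissions
have monitoring discontinued early, stays are right-skewed with a median of
120 h, and nurse observations arrive roughly every 8 h.

Vital signs follow a per-patient AR(1) process around a patient-specific
baseline.  Admissions heading for an EOC acquire a gradual drift (tachycardia,
tachypnoea, desaturation, hypotension, falling skin temperature) that ramps up
over roughly the final day before the event.  All admissions additionally
experience occasional transient instability episodes (a few hours, one or two
channels) and rare 1–3-minute spike artifacts, so both score smoothing and
false-positive behaviour are exercised.

No published trajectory model exists for this population; the drift and noise
defaults are explicitly placeholders chosen to be physiologically plausible,
not fitted values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .cohort import (
    Admission,
    ClinicalEvent,
    PHYSIOLOGIC_BOUNDS,
    VITAL_CHANNELS,
    empty_observations,
    empty_samples,
)

__all__ = [
    "CohortParams",
    "TrajectoryModel",
    "ParameterError",
    "default_trajectory_model",
    "generate_cohort",
    "inject_deterioration",
    "apply_missingness",
]


class ParameterError(ValueError):
    """A cohort parameter is outside its admissible range (named in the message)."""


@dataclass(frozen=True)
class TrajectoryModel:
    """Stable-patient dynamics and the deterioration target, per channel.

    ``baseline_sd`` is the between-patient spread of the resting baseline;
    ``noise_sd`` the stationary within-patient minute-to-minute spread;
    ``autocorr`` the AR(1) coefficient shared by all channels; ``shift`` the
    terminal deviation (channel units) reached at the moment of escalation.
    """

    baseline_mean: Mapping[str, float]
    baseline_sd: Mapping[str, float]
    noise_sd: Mapping[str, float]
    shift: Mapping[str, float]
    autocorr: float = 0.97

    def __post_init__(self) -> None:
        if not 0.0 <= self.autocorr < 1.0:
            raise ParameterError("autocorr must lie in [0, 1)")
        for ch in VITAL_CHANNELS:
            lo, hi = PHYSIOLOGIC_BOUNDS[ch]
            if not lo <= self.baseline_mean[ch] <= hi:
                raise ParameterError(f"baseline_mean[{ch}] outside physiologic bounds")


def default_trajectory_model() -> TrajectoryModel:
    return TrajectoryModel(
        baseline_mean={"hr": 78.0, "rr": 16.0, "spo2": 96.5, "sbp": 122.0, "skin_temp": 36.4},
        baseline_sd={"hr": 7.0, "rr": 1.5, "spo2": 1.0, "sbp": 10.0, "skin_temp": 0.4},
        noise_sd={"hr": 3.0, "rr": 1.2, "spo2": 0.8, "sbp": 5.0, "skin_temp": 0.2},
        shift={"hr": 35.0, "rr": 8.0, "spo2": -8.0, "sbp": -25.0, "skin_temp": -0.8},
        autocorr=0.97,
    )


#: Channel value written during a spike artifact (plus small jitter).
_ARTIFACT_VALUE = {"hr": 190.0, "rr": 55.0, "spo2": 45.0, "sbp": 45.0, "skin_temp": 28.0}

#: Nurse re-measurement noise for periodic observations, per channel.
_OBS_NOISE_SD = {"hr": 1.5, "rr": 0.8, "spo2": 0.6, "sbp": 3.0, "skin_temp": 0.15}

_ROUND_DECIMALS = {"hr": 0, "rr": 0, "spo2": 0, "sbp": 0, "skin_temp": 1}


@dataclass(frozen=True)
class CohortParams:
    """Study-level cohort composition and measurement process.

    Defaults are the conditions of the ward population this pipeline models:
    7% EOC admissions, 79% per-minute data availability, 11% monitoring
    discontinuation, 120 h median stay, 8-hourly observations, and vital-sign
    drift beginning on average 24 h before an escalation.
    """

    n_admissions: int
    eoc_fraction: float = 0.07
    availability: float = 0.79
    discontinuation_fraction: float = 0.11
    los_median_h: float = 120.0
    los_dispersion: float = 0.6          # log-scale sd of the stay distribution
    obs_interval_h: float = 8.0
    deterioration_onset_h: float = 24.0  # mean onset of pre-EOC drift
    onset_sd_h: float = 8.0
    trajectory: TrajectoryModel = field(default_factory=default_trajectory_model)
    artifact_rate: float = 0.002         # spike artifacts per monitored minute
    transient_rate_per_day: float = 0.15 # transient instability episodes per day
    mean_gap_min: float = 30.0           # mean length of a monitoring dropout burst
    medical_fraction: float = 0.66
    eoc_kind_probs: Mapping[str, float] = field(
        default_factory=lambda: {"rrt": 0.25, "icu_unplanned": 0.25,
                                 "emergency_surgery": 0.25, "death": 0.25})
    rrt_repeat_prob: float = 0.15        # chance a long stay gets a second RRT call
    rrt_repeat_min: int = 1440
    min_stay_h: float = 26.0             # generator emulates the eligible (>24 h) cohort
    seed: int = 0

    def validate(self) -> None:
        for name in ("eoc_fraction", "availability", "discontinuation_fraction",
                     "artifact_rate", "medical_fraction", "rrt_repeat_prob"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {val}")
        if self.n_admissions < 1:
            raise ParameterError(f"n_admissions must be >= 1, got {self.n_admissions}")
        if self.los_median_h <= 24:
            raise ParameterError(f"los_median_h must exceed 24, got {self.los_median_h}")
        if self.los_dispersion < 0:
            raise ParameterError("los_dispersion must be >= 0")
        if self.obs_interval_h <= 0:
            raise ParameterError("obs_interval_h must be positive")
        if self.deterioration_onset_h <= 0:
            raise ParameterError("deterioration_onset_h must be positive")
        if self.mean_gap_min < 1:
            raise ParameterError("mean_gap_min must be >= 1")
        total = sum(self.eoc_kind_probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ParameterError(f"eoc_kind_probs must sum to 1, got {total}")


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) path of length n with marginal sd ``sd``."""
    if n == 0:
        return np.empty(0)
    e = rng.normal(0.0, sd * math.sqrt(max(1.0 - phi * phi, 0.0)), n)
    e[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], e)


def _availability_mask(rng: np.random.Generator, n: int, availability: float,
                       mean_gap_min: float) -> np.ndarray:
    """Alternating-renewal on/off mask; long-run on-fraction = availability."""
    if availability >= 1.0:
        return np.ones(n, dtype=bool)
    if availability <= 0.0:
        return np.zeros(n, dtype=bool)
    mean_on = availability / (1.0 - availability) * mean_gap_min
    mask = np.zeros(n, dtype=bool)
    t, on = 0, True
    while t < n:
        run = int(rng.geometric(1.0 / mean_on if on else 1.0 / mean_gap_min))
        if on:
            mask[t:t + run] = True
        t += run
        on = not on
    return mask


def _ramp(n: int, start: int, end: int) -> np.ndarray:
    """Linear 0→1 ramp over [start, end) within an array of length n."""
    w = np.zeros(n)
    a, b = max(start, 0), min(end, n)
    if b > a:
        w[a:b] = (np.arange(a, b) - start + 1) / (end - start)
    return w


def generate_cohort(params: CohortParams) -> list[Admission]:
    """Generate a reproducible synthetic cohort (identical seeds, identical cohorts)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    return [_generate_admission(rng, params, i) for i in range(params.n_admissions)]


def _generate_admission(rng: np.random.Generator, p: CohortParams, idx: int) -> Admission:
    tm = p.trajectory
    medical = rng.random() < p.medical_fraction
    aid = f"{'M' if medical else 'S'}{idx:05d}"
    los = int(np.exp(rng.normal(math.log(p.los_median_h * 60.0), p.los_dispersion)))
    los = max(los, int(p.min_stay_h * 60))

    has_eoc = rng.random() < p.eoc_fraction
    stopped = (not has_eoc) and rng.random() < p.discontinuation_fraction / (1.0 - p.eoc_fraction)

    eoc_events: list[tuple[str, int]] = []
    if has_eoc:
        kinds = sorted(p.eoc_kind_probs)
        kind = str(rng.choice(kinds, p=[p.eoc_kind_probs[k] for k in kinds]))
        if kind == "rrt":
            t_e = int(rng.uniform(360, los))
            eoc_events.append(("rrt", t_e))
            if los - t_e > p.rrt_repeat_min + 360 and rng.random() < p.rrt_repeat_prob:
                eoc_events.append(("rrt", int(rng.uniform(t_e + p.rrt_repeat_min, los))))
        else:
            eoc_events.append((kind, los))
    stop_t = int(rng.uniform(720, los)) if stopped else None
    monitor_end = min(stop_t, los) if stop_t is not None else los

    # latent physiology on the full minute grid
    latent = {}
    for ch in VITAL_CHANNELS:
        base = tm.baseline_mean[ch] + rng.normal(0.0, tm.baseline_sd[ch])
        latent[ch] = base + _ar1(rng, los, tm.noise_sd[ch], tm.autocorr)

    # transient instability episodes (both outcome groups)
    for _ in range(rng.poisson(p.transient_rate_per_day * los / 1440.0)):
        dur = int(rng.integers(120, 361))
        start = int(rng.integers(0, max(1, los - dur)))
        n_ch = int(rng.integers(1, 3))
        chans = rng.choice(["hr", "rr", "spo2", "sbp"], size=n_ch, replace=False)
        severity = rng.uniform(0.4, 1.1)
        window = np.sin(np.pi * np.arange(dur) / dur) ** 2
        for ch in chans:
            latent[ch][start:start + dur] += severity * tm.shift[ch] * window

    # gradual deterioration before each escalation
    for _, t_e in eoc_events:
        onset = int(np.clip(rng.normal(p.deterioration_onset_h * 60.0, p.onset_sd_h * 60.0),
                            120, max(t_e, 121)))
        w = _ramp(los, t_e - onset, t_e)
        for ch in VITAL_CHANNELS:
            latent[ch] += tm.shift[ch] * w

    for ch in VITAL_CHANNELS:
        lo, hi = PHYSIOLOGIC_BOUNDS[ch]
        np.clip(latent[ch], lo, hi, out=latent[ch])

    # recorded stream: artifacts, then burst missingness, then channel dropout
    rec = {ch: latent[ch][:monitor_end].copy() for ch in VITAL_CHANNELS}
    for _ in range(rng.poisson(p.artifact_rate * monitor_end)):
        pos = int(rng.integers(0, max(1, monitor_end)))
        dur = int(rng.integers(1, 4))
        ch = str(rng.choice(list(VITAL_CHANNELS)))
        lo, hi = PHYSIOLOGIC_BOUNDS[ch]
        rec[ch][pos:pos + dur] = np.clip(
            _ARTIFACT_VALUE[ch] + rng.normal(0.0, 2.0), lo, hi)

    mask = _availability_mask(rng, monitor_end, p.availability, p.mean_gap_min)
    t_rec = np.nonzero(mask)[0]
    data = {"t_min": t_rec.astype("int64")}
    for ch in VITAL_CHANNELS:
        vals = np.round(rec[ch][t_rec], _ROUND_DECIMALS[ch])
        drop = _availability_mask(rng, monitor_end, 0.97, 15.0)  # sensor-level dropout
        vals = np.where(drop[t_rec], vals, np.nan)
        data[ch] = vals
    samples = pd.DataFrame(data)
    any_present = samples[list(VITAL_CHANNELS)].notna().any(axis=1)
    samples = samples.loc[any_present].reset_index(drop=True)

    # periodic nurse observations from the latent (validated) state
    obs_times: list[int] = []
    t_obs = rng.uniform(30.0, p.obs_interval_h * 60.0)
    while t_obs < monitor_end:
        obs_times.append(int(t_obs))
        t_obs += p.obs_interval_h * 60.0 + rng.uniform(-60.0, 60.0)
    obs_rows = []
    next_eoc = {t: k for k, t in eoc_events}
    for t in obs_times:
        row: dict[str, object] = {"t_min": t}
        for ch in VITAL_CHANNELS:
            lo, hi = PHYSIOLOGIC_BOUNDS[ch]
            val = float(np.clip(latent[ch][t] + rng.normal(0.0, _OBS_NOISE_SD[ch]), lo, hi))
            row["temp" if ch == "skin_temp" else ch] = round(val, _ROUND_DECIMALS[ch])
        spo2_now = latent["spo2"][t]
        row["oxygen_delivery"] = 2.0 if (spo2_now < 93.0 and rng.random() < 0.7) else 0.0
        pre_eoc = any(0 <= t_e - t <= 360 for t_e in next_eoc)
        u = rng.random()
        row["consciousness"] = ("P" if pre_eoc and u < 0.05
                                else "V" if pre_eoc and u < 0.25 else "A")
        obs_rows.append(row)
    observations = (pd.DataFrame(obs_rows)[list(empty_observations().columns)]
                    if obs_rows else empty_observations())

    events: list[ClinicalEvent] = [ClinicalEvent(t, k) for k, t in eoc_events]
    if stop_t is not None:
        events.append(ClinicalEvent(stop_t, "monitoring_stop"))
    terminal_kind = "death" if eoc_events and eoc_events[0][0] == "death" else "discharge"
    if terminal_kind == "discharge":
        events.append(ClinicalEvent(los, "discharge"))
    events.sort(key=lambda ev: (ev.t_min, ev.kind in ("discharge", "monitoring_stop")))

    return Admission(admission_id=aid, ward="medical" if medical else "surgical",
                     length_of_stay_min=los, samples=samples,
                     observations=observations, events=events)


def inject_deterioration(a: Admission, eoc_t_min: int, model: TrajectoryModel,
                         onset_min: int) -> Admission:
    """Superimpose a linear drift toward ``baseline + shift`` over the onset window.

    Channels ramp from 0 at ``eoc_t_min - onset_min`` to the full per-channel
    shift just before ``eoc_t_min``; samples before onset are untouched.  The
    drift is added in expectation (deterministically) on top of whatever noise
    the samples already carry.
    """
    if not onset_min < eoc_t_min:
        raise ParameterError("onset_min must be < eoc_t_min")
    if eoc_t_min > a.length_of_stay_min:
        raise ValueError(f"eoc_t_min={eoc_t_min} beyond stay of {a.length_of_stay_min} min")
    s = a.samples.copy()
    if len(s):
        t = s["t_min"].to_numpy()
        start = eoc_t_min - onset_min
        frac = np.clip((t - start + 1) / onset_min, 0.0, 1.0)
        frac[t < start] = 0.0
        frac[t >= eoc_t_min] = 0.0
        for ch in VITAL_CHANNELS:
            lo, hi = PHYSIOLOGIC_BOUNDS[ch]
            s[ch] = np.clip(s[ch].to_numpy() + model.shift[ch] * frac, lo, hi)
    return replace(a, samples=s)


def apply_missingness(a: Admission, availability: float, seed: int) -> Admission:
    """Drop monitored minutes in contiguous geometric bursts.

    The long-run retained fraction equals ``availability``; the result is
    deterministic given ``seed``.
    """
    if not 0.0 <= availability <= 1.0:
        raise ParameterError(f"availability must lie in [0, 1], got {availability}")
    s = a.samples
    if not len(s) or availability >= 1.0:
        return replace(a, samples=s.copy())
    rng = np.random.default_rng(seed)
    span = int(s["t_min"].max()) + 1
    mask = _availability_mask(rng, span, availability, 30.0)
    keep = mask[s["t_min"].to_numpy()]
    return replace(a, samples=s.loc[keep].reset_index(drop=True))
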