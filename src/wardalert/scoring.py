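"""Score computation for both alerting scenarios.

Periodic scenario: a Modified Early Warning Score (MEWS) is computed from each
nurse observation by summing per-channel band points plus oxygen-delivery and
AVPU consciousness add-ons; an alert fires at a configurable threshold
(default 6).

Continuous scenario: every monitored minute receives a 0-5 instability score.
The raw streams are first median-smoothed so that isolated faulty measurements
are replaced by surrounding reassuring data; the score is then a saturating
monotone map of the root-mean-square standardized deviation of the four
continuous channels (SpO2, respiratory rate, heart rate, systolic pressure)
from a normal-vitals reference, and is valid only when at least three of the
four channels are present.  The scorer is a documented stand-in for the
proprietary index whose interface it reproduces (0-5 range, >=3-of-4 validity,
alert at 3); it makes no claim of numerical fidelity to that product.
Skin temperature is deliberately excluded from the continuous score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    Admission,
    OBS_CHANNELS,
    PHYSIOLOGIC_BOUNDS,
    PeriodicObservation,
    VITAL_CHANNELS,
    VitalSample,
)

logger = logging.getLogger(__name__)

VSI_CHANNELS = ("spo2", "rr", "hr", "sbp")


class TableCoverageError(ValueError):
    """A channel value fell outside every configured band."""


@dataclass(frozen=True)
class EwsTable:
    """Banded point table for the periodic early warning score.

    ``bands`` maps each observation channel to ordered half-open
    ``[lo, hi) -> points`` triples that must tile the physiologic range.
    """

    bands: Mapping[str, tuple[tuple[float, float, int], ...]]
    oxygen_points: int = 2
    avpu_points: Mapping[str, int] = field(
        default_factory=lambda: {"A": 0, "V": 1, "P": 2, "U": 3})
    alert_threshold: int = 6

    def __post_init__(self) -> None:
        if self.alert_threshold < 1:
            raise ValueError("alert_threshold must be >= 1")
        for ch, bands in self.bands.items():
            lo_bound, hi_bound = PHYSIOLOGIC_BOUNDS[ch]
            if not bands:
                raise ValueError(f"{ch}: empty band list")
            if bands[0][0] > lo_bound or bands[-1][1] < hi_bound:
                raise ValueError(f"{ch}: bands do not cover physiologic range")
            for (lo, hi, pts), nxt in zip(bands, bands[1:] + ((None,) * 3,)):
                if hi <= lo or pts < 0:
                    raise ValueError(f"{ch}: malformed band [{lo}, {hi}) -> {pts}")
                if nxt[0] is not None and nxt[0] != hi:
                    raise ValueError(f"{ch}: bands not contiguous at {hi}")

    def points(self, channel: str, value: float) -> int:
        for lo, hi, pts in self.bands[channel]:
            if lo <= value < hi:
                return int(pts)
        # the last band's upper edge is inclusive so the range boundary scores
        last = self.bands[channel][-1]
        if value == last[1]:
            return int(last[2])
        raise TableCoverageError(f"{channel}={value} outside all configured bands")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EwsTable":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            bands={ch: tuple((float(lo), float(hi), int(p)) for lo, hi, p in b)
                   for ch, b in raw["bands"].items()},
            oxygen_points=int(raw["oxygen_points"]),
            avpu_points={k: int(v) for k, v in raw["avpu_points"].items()},
            alert_threshold=int(raw["alert_threshold"]),
        )

    @classmethod
    def default(cls) -> "EwsTable":
        with resources.as_file(resources.files("wardalert.config") / "mews_table.yaml") as p:
            return cls.from_yaml(p)


@dataclass(frozen=True)
class ReferenceVitalsModel:
    """Normal-vitals reference and output mapping for the continuous score.

    ``score = score_max * r / (r + softness)`` where ``r`` is the RMS of
    ``(value - center) / scale`` over present channels; the map is monotone in
    ``r`` and saturates toward ``score_max``.
    """

    center: Mapping[str, float]
    scale: Mapping[str, float]
    softness: float = 1.5
    score_max: float = 5.0
    alert_threshold: float = 3.0
    min_channels: int = 3
    half_window_min: int = 5

    def __post_init__(self) -> None:
        for ch in VSI_CHANNELS:
            if self.scale[ch] <= 0:
                raise ValueError(f"scale[{ch}] must be positive")
        if self.softness <= 0:
            raise ValueError("softness must be positive")

    def map_deviation(self, r: np.ndarray | float) -> np.ndarray | float:
        return self.score_max * r / (r + self.softness)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceVitalsModel":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            center={k: float(v) for k, v in raw["center"].items()},
            scale={k: float(v) for k, v in raw["scale"].items()},
            softness=float(raw["softness"]),
            score_max=float(raw["score_max"]),
            alert_threshold=float(raw["alert_threshold"]),
            min_channels=int(raw["min_channels"]),
            half_window_min=int(raw["half_window_min"]),
        )

    @classmethod
    def default(cls) -> "ReferenceVitalsModel":
        with resources.as_file(resources.files("wardalert.config") / "reference_model.yaml") as p:
            return cls.from_yaml(p)


@dataclass
class ScoreSeries:
    """Ordered per-time score values with validity flags and an alert threshold.

    ``entries`` has columns ``t_min`` (strictly increasing), ``score`` (NaN on
    invalid entries) and ``valid``.
    """

    scenario: str  # "periodic" | "continuous"
    alert_threshold: float
    entries: pd.DataFrame

    def alert_minutes(self) -> np.ndarray:
        e = self.entries
        hit = e["valid"] & (e["score"] >= self.alert_threshold)
        return e.loc[hit, "t_min"].to_numpy(dtype="int64")


def compute_mews(obs: PeriodicObservation, table: EwsTable) -> int:
    """Sum band points over present channels plus oxygen and consciousness points.

    Missing channels contribute zero (and are logged at debug level); an
    observation with no present channel at all is rejected.
    """
    present = obs.present_channels()
    if not present:
        raise ValueError("observation has no present vital-sign channel")
    score = 0
    for ch in OBS_CHANNELS:
        val = getattr(obs, ch)
        if val is None:
            logger.debug("t=%d: channel %s missing, contributes 0", obs.t_min, ch)
            continue
        score += table.points(ch, float(val))
    if obs.oxygen_delivery and float(obs.oxygen_delivery) > 0:
        score += table.oxygen_points
    score += table.avpu_points[obs.consciousness]
    return int(score)


def smooth_vitals(samples: pd.DataFrame, half_window_min: int = 5) -> pd.DataFrame:
    """Per-channel running median over ``[t - w, t + w]`` on the minute grid.

    Minutes without any data stay absent; channels missing at a minute stay
    missing (the median is taken over available values only).  Isolated spikes
    shorter than the half-window are replaced by surrounding values.
    """
    if half_window_min < 1:
        raise ValueError("half_window_min must be >= 1")
    if not len(samples):
        return samples.copy()
    t = samples["t_min"].to_numpy()
    full = np.arange(t.min(), t.max() + 1)
    grid = samples.set_index("t_min").reindex(full)
    med = grid[list(VITAL_CHANNELS)].rolling(
        2 * half_window_min + 1, center=True, min_periods=1).median()
    out = med.loc[t].reset_index(names="t_min")
    return out[list(samples.columns)]


def compute_continuous_score(sample: VitalSample,
                             model: ReferenceVitalsModel) -> tuple[float | None, bool]:
    """Score one (smoothed) minute; invalid when fewer than 3 of 4 channels present."""
    devs = []
    for ch in VSI_CHANNELS:
        val = getattr(sample, ch)
        if val is not None:
            devs.append((float(val) - model.center[ch]) / model.scale[ch])
    if len(devs) < model.min_channels:
        return None, False
    r = float(np.sqrt(np.mean(np.square(devs))))
    return float(model.map_deviation(r)), True


def score_periodic(a: Admission, table: EwsTable | None = None) -> ScoreSeries:
    """One MEWS entry per periodic observation, in time order."""
    table = table or EwsTable.default()
    rows = []
    for obs in a.iter_observations():
        if obs.present_channels():
            rows.append((obs.t_min, float(compute_mews(obs, table)), True))
        else:
            rows.append((obs.t_min, np.nan, False))
    entries = pd.DataFrame(rows, columns=["t_min", "score", "valid"]) if rows else \
        pd.DataFrame({"t_min": pd.Series(dtype="int64"),
                      "score": pd.Series(dtype="float64"),
                      "valid": pd.Series(dtype="bool")})
    return ScoreSeries("periodic", float(table.alert_threshold), entries)


def score_continuous(a: Admission, model: ReferenceVitalsModel | None = None,
                     half_window_min: int | None = None) -> ScoreSeries:
    """Smooth the streams, then score every monitored minute.

    The >=3-of-4 validity rule is applied after smoothing: a minute is
    scoreable when at least ``model.min_channels`` of the four continuous
    channels survive the median filter.
    """
    model = model or ReferenceVitalsModel.default()
    w = model.half_window_min if half_window_min is None else half_window_min
    empty = pd.DataFrame({"t_min": pd.Series(dtype="int64"),
                          "score": pd.Series(dtype="float64"),
                          "valid": pd.Series(dtype="bool")})
    if not len(a.samples):
        return ScoreSeries("continuous", model.alert_threshold, empty)
    sm = smooth_vitals(a.samples, w)
    z2 = np.zeros(len(sm))
    n_present = np.zeros(len(sm), dtype=int)
    for ch in VSI_CHANNELS:
        z = (sm[ch].to_numpy() - model.center[ch]) / model.scale[ch]
        ok = ~np.isnan(z)
        z2[ok] += z[ok] ** 2
        n_present += ok
    valid = n_present >= model.min_channels
    score = np.full(len(sm), np.nan)
    with np.errstate(invalid="ignore"):
        r = np.sqrt(z2[valid] / n_present[valid])
    score[valid] = model.map_deviation(r)
    entries = pd.DataFrame({"t_min": sm["t_min"].astype("int64"),
                            "score": score, "valid": valid})
    return ScoreSeries("continuous", model.alert_threshold, entries)
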