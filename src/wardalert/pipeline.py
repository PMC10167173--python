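"""End-to-end orchestration: simulate/load -> score -> episodes -> metrics.

Both scenarios are always evaluated on the identical cohort object, mirroring
the within-cohort design of the comparison.  Eligibility exclusions (stay of
at least 24 h, monitoring connected within 12 h) are applied once, before
scoring, and excluded admissions are listed in the run log.  Given a fixed
configuration and seed the pipeline is deterministic down to the report bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Admission, cohort_summary, read_cohort, validate_admission, write_cohort
from .episodes import AdmissionEpisodes, ContingencyTable, evaluate_admission
from .evaluation import (
    BurdenComparison,
    UndefinedMetricError,
    alerting_fraction,
    contingency_metrics,
    group_burden_comparison,
    lead_time_summary,
    prelude_bins,
)
from .scoring import EwsTable, ReferenceVitalsModel, ScoreSeries, score_continuous, score_periodic
from .synthetic import CohortParams, generate_cohort

logger = logging.getLogger(__name__)

SCENARIOS = ("periodic", "continuous")


@dataclass(frozen=True)
class PipelineConfig:
    """Every protocol constant of the comparison, in one place.

    Either ``cohort`` (simulation parameters) or the three input paths must be
    set.  Thresholds and windows default to the protocol: periodic alert at a
    score of 6, continuous alert at 3, 4 h warning window, 8 h cap on negative
    segments, 120 h burden window, 72/48/24/0 h prelude bins, and repeat
    rapid-response calls separated by at least 24 h.
    """

    cohort: CohortParams | None = None
    vitals_path: str | None = None
    observations_path: str | None = None
    events_path: str | None = None
    ews_table_path: str | None = None
    reference_model_path: str | None = None
    ews_alert: int | None = None      # overrides the table's alert threshold
    csi_alert: float | None = None    # overrides the model's alert threshold
    window_min: int = 240
    max_negative_min: int = 480
    burden_window_h: int = 120
    prelude_bins_h: tuple[int, ...] = (72, 48, 24, 0)
    rrt_separation_min: int = 1440
    half_window_min: int = 5
    min_stay_min: int = 1440
    max_connect_min: int = 720
    out_dir: str = "results/run"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_min", "max_negative_min", "burden_window_h",
                     "rrt_separation_min", "half_window_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def ews_table(self) -> EwsTable:
        return EwsTable.from_yaml(self.ews_table_path) if self.ews_table_path else EwsTable.default()

    def reference_model(self) -> ReferenceVitalsModel:
        return (ReferenceVitalsModel.from_yaml(self.reference_model_path)
                if self.reference_model_path else ReferenceVitalsModel.default())

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        d = _as_jsonable(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj: object) -> object:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "cohort" in raw and raw["cohort"] is not None:
        raw["cohort"] = CohortParams(**raw["cohort"])
    if "prelude_bins_h" in raw:
        raw["prelude_bins_h"] = tuple(raw["prelude_bins_h"])
    return PipelineConfig(**raw)


def _load_or_simulate(cfg: PipelineConfig) -> list[Admission]:
    if cfg.cohort is not None:
        params = dataclasses.replace(cfg.cohort, seed=cfg.seed)
        logger.info("simulating cohort: n=%d seed=%d", params.n_admissions, params.seed)
        return generate_cohort(params)
    if not (cfg.vitals_path and cfg.observations_path and cfg.events_path):
        raise ValueError("config must provide either cohort parameters or the three input paths")
    return read_cohort(cfg.vitals_path, cfg.observations_path, cfg.events_path)


def filter_eligible(admissions: Sequence[Admission], cfg: PipelineConfig
                    ) -> tuple[list[Admission], dict[str, list[str]]]:
    """Apply the eligibility rules once; report exclusions by admission."""
    kept, excluded = [], {}
    for a in admissions:
        violations = validate_admission(a, min_stay_min=cfg.min_stay_min,
                                        max_connect_min=cfg.max_connect_min)
        if violations:
            excluded[a.admission_id] = violations
        else:
            kept.append(a)
    return kept, excluded


def score_cohort(admissions: Sequence[Admission], cfg: PipelineConfig
                 ) -> dict[str, dict[str, ScoreSeries]]:
    table = cfg.ews_table()
    if cfg.ews_alert is not None:
        table = dataclasses.replace(table, alert_threshold=cfg.ews_alert)
    model = cfg.reference_model()
    if cfg.csi_alert is not None:
        model = dataclasses.replace(model, alert_threshold=cfg.csi_alert)
    return {a.admission_id: {
        "periodic": score_periodic(a, table),
        "continuous": score_continuous(a, model, cfg.half_window_min),
    } for a in admissions}


@dataclass
class ScenarioResult:
    scenario: str
    table: ContingencyTable
    metrics: dict
    lead_times: dict
    episodes: list[AdmissionEpisodes] = field(repr=False, default_factory=list)


def evaluate_scenario(admissions: Sequence[Admission],
                      series: Mapping[str, Mapping[str, ScoreSeries]],
                      scenario: str, cfg: PipelineConfig) -> ScenarioResult:
    episodes = []
    total = ContingencyTable(0, 0, 0, 0, 0.0)
    for a in admissions:
        try:
            ep = evaluate_admission(a, series[a.admission_id][scenario].alert_minutes(),
                                    scenario, cfg.window_min, cfg.max_negative_min,
                                    cfg.rrt_separation_min)
        except Exception as exc:  # surface failing stage with context
            raise RuntimeError(f"episode model failed for admission "
                               f"{a.admission_id} ({scenario}): {exc}") from exc
        episodes.append(ep)
        total = total + ep.table
    try:
        metrics = contingency_metrics(total, scenario).display()
    except UndefinedMetricError as exc:
        metrics = {"scenario": scenario, "undefined": str(exc),
                   "tp": total.tp, "fp": total.fp, "tn": total.tn, "fn": total.fn}
    tp_periods = [p for ep in episodes for p in ep.periods if p.classification == "TP"]
    lt = lead_time_summary(tp_periods, total.n_eoc)
    lead = {"n_tp": len(lt.leads_h), "median_h": lt.median_h,
            "iqr_h": lt.iqr_h, "plateau_pct": lt.plateau_pct}
    return ScenarioResult(scenario, total, metrics, lead, episodes)


def burden_analysis(admissions: Sequence[Admission],
                    series: Mapping[str, Mapping[str, ScoreSeries]],
                    cfg: PipelineConfig) -> dict:
    """Continuous-scenario alert burden: 120 h group contrast + prelude bins."""
    eoc_fr, non_fr = [], []
    bins: list[tuple[float | None, ...]] = []
    for a in admissions:
        s = series[a.admission_id]["continuous"]
        frac = alerting_fraction(s, a, 0, cfg.burden_window_h * 60)
        eoc_times = [ev.t_min for ev in a.events if ev.is_eoc]
        if eoc_times:
            eoc_fr.append(frac)
            bins.append(prelude_bins(s, a, eoc_times[0], cfg.prelude_bins_h))
        else:
            non_fr.append(frac)
    out: dict = {"n_eoc_admissions": len(eoc_fr), "n_non_eoc_admissions": len(non_fr)}
    try:
        cmp = group_burden_comparison(non_fr, eoc_fr)
        out["burden_120h"] = {
            "non_eoc_median_pct": 100.0 * cmp.median[0],
            "eoc_median_pct": 100.0 * cmp.median[1],
            "non_eoc_iqr_pct": [100.0 * v for v in cmp.iqr[0]],
            "eoc_iqr_pct": [100.0 * v for v in cmp.iqr[1]],
            "n": cmp.n, "n_excluded": cmp.n_excluded,
            "mann_whitney": {"u": cmp.u, "z": cmp.z, "p": cmp.p},
        }
    except ValueError as exc:
        out["burden_120h"] = {"undefined": str(exc)}
    labels = [f"{hi}-{lo}h" for hi, lo in zip(cfg.prelude_bins_h, cfg.prelude_bins_h[1:])]
    medians = []
    for i, label in enumerate(labels):
        vals = [b[i] for b in bins if b[i] is not None]
        medians.append({"bin": label,
                        "median_pct": 100.0 * float(np.median(vals)) if vals else None,
                        "n": len(vals)})
    out["prelude_bins"] = medians
    return out


def episodes_frame(results: Mapping[str, ScenarioResult]) -> pd.DataFrame:
    rows = []
    for res in results.values():
        for ep in res.episodes:
            for p in ep.periods:
                rows.append((ep.admission_id, res.scenario, "warning", p.start, p.end,
                             len(p.alert_times), p.classification))
            for s in ep.segments:
                rows.append((ep.admission_id, res.scenario, "negative", s.start, s.end,
                             0, s.classification))
    df = pd.DataFrame(rows, columns=["admission_id", "scenario", "kind",
                                     "start_min", "end_min", "n_alerts", "classification"])
    return df.sort_values(["admission_id", "scenario", "start_min"],
                          kind="stable").reset_index(drop=True)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run both scenarios end to end; write episodes, curves, report and log."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash={cfg.config_hash()}", f"seed={cfg.seed}"]

    admissions = _load_or_simulate(cfg)
    log_lines.append(f"admissions_in={len(admissions)}")
    eligible, excluded = filter_eligible(admissions, cfg)
    log_lines.append(f"admissions_eligible={len(eligible)} admissions_excluded={len(excluded)}")
    for aid, why in excluded.items():
        log_lines.append(f"excluded {aid}: {'; '.join(why)}")

    series = score_cohort(eligible, cfg)
    results = {sc: evaluate_scenario(eligible, series, sc, cfg) for sc in SCENARIOS}
    for sc, res in results.items():
        t = res.table
        log_lines.append(f"{sc}: tp={t.tp} fp={t.fp} tn={t.tn} fn={t.fn} "
                         f"patient_days={t.patient_days:.1f}")

    episodes_frame(results).to_csv(out_dir / "episodes.csv", index=False)
    curves = {}
    for sc, res in results.items():
        tp_periods = [p for ep in res.episodes for p in ep.periods if p.classification == "TP"]
        curve = lead_time_summary(tp_periods, res.table.n_eoc).curve
        name = f"detection_curve_{sc}.csv"
        curve.to_csv(out_dir / name, index=False)
        curves[sc] = name  # relative to the report's directory

    report = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "cohort": cohort_summary(eligible),
        "n_excluded": len(excluded),
        "scenarios": {sc: {"metrics": res.metrics,
                           "counts": {"tp": res.table.tp, "fp": res.table.fp,
                                      "tn": res.table.tn, "fn": res.table.fn,
                                      "patient_days": res.table.patient_days},
                           "lead_times": res.lead_times,
                           "detection_curve_csv": curves[sc]}
                      for sc, res in results.items()},
        "alert_burden": burden_analysis(eligible, series, cfg),
    }
    (out_dir / "report.json").write_text(json.dumps(_as_jsonable(report), indent=2,
                                                    sort_keys=True) + "\n")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    for line in log_lines[:6]:
        logger.info("%s", line)
    return report
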