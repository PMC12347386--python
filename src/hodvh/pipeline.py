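"""End-to-end study orchestration.

``run_full_study`` takes plans either from a cohort manifest on disk or
from the synthetic generator, evaluates the fourteen per-plan indices,
builds the cohort comparison tables (per-arm summaries, normality, paired
Wilcoxon), runs the Monte Carlo resampling study on the cohort's own
(mean, SD) baseline, and writes CSV/JSON/plain-text reports plus a run log
sufficient to reproduce every number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .baseline import ALL_INDICES
from .cohort import CohortConfig, calibrate, generate_cohort
from .dosimetry import compute_dosimetric_panel
from .dvh import Arm, PlanRecord, load_cohort, save_cohort
from .montecarlo import (
    MCConfig,
    MCDistribution,
    export_histograms,
    export_summary,
    run_mc_study,
)
from .radiobiology import DEFAULT_ALPHA, compute_radbio_panel
from .stats import CohortSummary, build_comparison_tables

__all__ = ["RunConfig", "StudyReport", "compute_index_panel", "panels_frame", "run_full_study"]


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of a full study run.

    Exactly one input mode is active: ``manifest`` (plans on disk) or
    ``cohort`` (synthetic generation; the default synthetic cohort is used
    when both are None).
    """

    seed: int = 0
    manifest: Path | None = None
    cohort: CohortConfig | None = None
    calibrate_cohort: bool = False
    alpha: float = DEFAULT_ALPHA
    geud_a: float = 1.0
    mc_samples: int = 10_000
    mc_bins: int = 60
    mc_bin_width: float | None = None
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.manifest is not None and self.cohort is not None:
            raise ValueError("choose one input mode: manifest or synthetic cohort")


@dataclass(frozen=True)
class StudyReport:
    panels: pd.DataFrame
    summary: CohortSummary
    mc_distributions: list[MCDistribution]
    run_log: dict
    written: dict[str, Path] = field(default_factory=dict)


def compute_index_panel(
    plan: PlanRecord, *, alpha: float = DEFAULT_ALPHA, a: float = 1.0
) -> dict:
    """All fourteen evaluated indices for one plan, keyed by index name."""
    row: dict = {"patient_id": plan.patient_id, "arm": plan.arm.value}
    dosi = compute_dosimetric_panel(plan).as_dict()
    dosi["GI"] = np.nan if dosi["GI"] is None else dosi["GI"]
    row.update(dosi)
    row.update(compute_radbio_panel(plan, alpha=alpha, a=a).as_dict())
    return row


def panels_frame(
    plans: Sequence[PlanRecord], *, alpha: float = DEFAULT_ALPHA, a: float = 1.0
) -> pd.DataFrame:
    return pd.DataFrame([compute_index_panel(p, alpha=alpha, a=a) for p in plans])


def _cohort_baseline(panels: pd.DataFrame) -> dict:
    """Per-(index, arm) (mean, sd) of the evaluated cohort — the baseline
    feeding the resampling study."""
    baseline: dict = {}
    for index_name in ALL_INDICES:
        if index_name not in panels.columns:
            continue
        arms = {}
        for arm in (Arm.IC_OFF, Arm.IC_ON):
            values = panels.loc[panels["arm"] == arm.value, index_name].dropna()
            if len(values) >= 2:
                arms[arm] = (float(values.mean()), float(values.std(ddof=1)))
        if arms:
            baseline[index_name] = arms
    return baseline


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k.value if isinstance(k, Arm) else k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, Arm):
        return obj.value
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _config_hash(config: RunConfig) -> str:
    # out_dir is presentation, not science: identical studies written to
    # different directories must hash (and report) identically
    canonical = _jsonable(config)
    canonical.pop("out_dir", None)
    return hashlib.sha256(json.dumps(canonical, sort_keys=True).encode()).hexdigest()


def _frame_records(frame: pd.DataFrame) -> list[dict]:
    records = frame.to_dict(orient="records")
    return [
        {k: (None if isinstance(v, float) and np.isnan(v) else _jsonable(v)) for k, v in r.items()}
        for r in records
    ]


def run_full_study(config: RunConfig) -> StudyReport:
    """Execute every stage and (optionally) write the report bundle.

    Outputs under ``out_dir``: ``panels.csv``, ``comparison_dosimetric.csv``,
    ``comparison_radiobiological.csv``, ``tables.txt``, ``mc_summary.csv``,
    ``mc_histograms.csv``, ``summary.json`` (machine-readable, byte-stable
    across reruns with the same config) and ``run_log.json``.
    """
    stage = "input"
    try:
        if config.manifest is not None:
            plans = load_cohort(config.manifest)
            cohort_cfg = None
            calibration_audit = None
        else:
            cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
            calibration_audit = None
            if config.calibrate_cohort:
                stage = "calibration"
                cohort_cfg, calibration_audit = calibrate(cohort_cfg)
            stage = "generation"
            plans = generate_cohort(cohort_cfg)

        stage = "index panels"
        panels = panels_frame(plans, alpha=config.alpha, a=config.geud_a)

        stage = "cohort comparison"
        summary = build_comparison_tables(panels)

        stage = "monte carlo"
        mc_config = MCConfig(
            seed=config.seed,
            n_samples=config.mc_samples,
            baseline=_cohort_baseline(panels),
            n_bins=config.mc_bins,
            bin_width=config.mc_bin_width,
        )
        mc = run_mc_study(mc_config)
    except Exception as exc:
        raise RuntimeError(f"study aborted in stage '{stage}': {exc}") from exc

    run_log = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "input_mode": "manifest" if config.manifest is not None else "synthetic",
        "n_plans": len(plans),
        "n_patients": summary.n_patients,
        "mc_samples": config.mc_samples,
        "calibrated": bool(config.calibrate_cohort and config.manifest is None),
    }
    if calibration_audit is not None:
        run_log["calibration"] = _jsonable(calibration_audit)

    written: dict[str, Path] = {}
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        panels.to_csv(out / "panels.csv", index=False)
        summary.dosimetric.to_csv(out / "comparison_dosimetric.csv", index=False)
        summary.radiobiological.to_csv(out / "comparison_radiobiological.csv", index=False)
        (out / "tables.txt").write_text(summary.render_text())
        export_summary(mc, out / "mc_summary.csv")
        export_histograms(mc, out / "mc_histograms.csv")
        machine = {
            "panels": _frame_records(panels),
            "dosimetric": _frame_records(summary.dosimetric),
            "radiobiological": _frame_records(summary.radiobiological),
            "mc": [
                {
                    "index": d.index_name,
                    "arm": d.arm.value,
                    "mean": d.summary.mean,
                    "sd": d.summary.sd,
                    "ci_low": d.summary.ci_low,
                    "ci_high": d.summary.ci_high,
                }
                for d in mc
            ],
            "run_log": run_log,
        }
        (out / "summary.json").write_text(json.dumps(machine, sort_keys=True, indent=1))
        (out / "run_log.json").write_text(json.dumps(run_log, sort_keys=True, indent=1))
        if config.manifest is None:
            save_cohort(plans, out / "synthetic_cohort")
            written["synthetic_cohort"] = out / "synthetic_cohort" / "manifest.csv"
        for name in (
            "panels.csv",
            "comparison_dosimetric.csv",
            "comparison_radiobiological.csv",
            "tables.txt",
            "mc_summary.csv",
            "mc_histograms.csv",
            "summary.json",
            "run_log.json",
        ):
            written[name] = out / name

    return StudyReport(
        panels=panels, summary=summary, mc_distributions=mc, run_log=run_log, written=written
    )
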