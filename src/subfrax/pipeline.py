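"""End-to-end experiment orchestration.

One call chains cohort simulation -> shift estimation -> traffic-light
protocol -> plan construction -> intrafraction and interfraction dose
accumulation -> counterfactual re-planning -> cohort reporting, with all
randomness flowing from a single master seed through named substreams and
per-patient failure isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field, fields, is_dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .accumulation import (
    AccumulationResult,
    ConstraintSet,
    accumulate_interfraction,
    accumulate_intrafraction,
    cumulative_shift_table,
    summarize_cohort,
)
from .grid import VoxelGrid
from .motion import CohortConfig, SubgroupMotion
from .phantom import (
    DEFAULT_ANATOMY,
    DEFAULT_GRID,
    SMOKE_ANATOMY,
    SMOKE_GRID,
    AnatomyParams,
    Patient,
    ground_truth_records,
    simulate_cohort,
)
from .planning import PlanSpec, fraction_subplans
from .protocol import (
    ShiftRecord,
    TrafficLightConfig,
    apply_protocol,
    records_to_frame,
)
from .registration import RegistrationSettings, estimate_ctv_shift, register

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """All knobs of one experiment, seedable and serializable."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    registration: RegistrationSettings = field(default_factory=RegistrationSettings)
    traffic: TrafficLightConfig = field(default_factory=TrafficLightConfig)
    plan: PlanSpec = field(default_factory=PlanSpec)
    constraints: ConstraintSet = field(default_factory=ConstraintSet)
    grid: VoxelGrid = DEFAULT_GRID
    anatomy: AnatomyParams = DEFAULT_ANATOMY
    scale: str = "default"
    seed: int = 0
    #: "estimated" runs the DIR for shifts and accumulation; "ground_truth"
    #: uses the simulator's generating motions (fast oracle path)
    shift_source: str = "estimated"
    accumulation_motion: str = "estimated"
    write_volumes: bool = False

    def __post_init__(self) -> None:
        if self.shift_source not in ("estimated", "ground_truth"):
            raise ValueError("shift_source must be 'estimated' or 'ground_truth'")
        if self.accumulation_motion not in ("estimated", "ground_truth"):
            raise ValueError("accumulation_motion must be 'estimated' or 'ground_truth'")
        # the master seed drives every substream
        self.cohort = replace(self.cohort, seed=self.seed)
        self.registration = replace(self.registration, seed=self.seed)


def smoke_config(seed: int = 0, **kwargs) -> ExperimentConfig:
    """Small preset: 2 patients on a 32^3 grid, single-repeat registration."""
    return ExperimentConfig(
        cohort=CohortConfig(n_patients=2, seed=seed),
        registration=RegistrationSettings(n_repeats=1, max_iterations=40),
        grid=SMOKE_GRID,
        anatomy=SMOKE_ANATOMY,
        scale="smoke",
        seed=seed,
        **kwargs,
    )


def default_config(seed: int = 0, **kwargs) -> ExperimentConfig:
    """Default preset: 8 patients on a 48^3 grid, 3-repeat registration."""
    return ExperimentConfig(
        cohort=CohortConfig(n_patients=8, seed=seed),
        registration=RegistrationSettings(n_repeats=3),
        scale="default",
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# config (de)serialization

def config_to_dict(cfg) -> dict:
    if is_dataclass(cfg):
        return {f.name: config_to_dict(getattr(cfg, f.name)) for f in fields(cfg)}
    if isinstance(cfg, np.ndarray):
        return cfg.tolist()
    if isinstance(cfg, (list, tuple)):
        return [config_to_dict(v) for v in cfg]
    if isinstance(cfg, dict):
        return {k: config_to_dict(v) for k, v in cfg.items()}
    return cfg


_NESTED = {
    "cohort": CohortConfig,
    "registration": RegistrationSettings,
    "traffic": TrafficLightConfig,
    "plan": PlanSpec,
    "constraints": ConstraintSet,
    "grid": VoxelGrid,
    "anatomy": AnatomyParams,
    "typical": SubgroupMotion,
    "large": SubgroupMotion,
}


def _build_dataclass(cls, data: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name in _NESTED and isinstance(v, dict):
            v = _build_dataclass(_NESTED[f.name], v)
        elif f.name in ("tight_margins", "large_margins", "margins") and isinstance(
            v, (list, dict)
        ):
            from .protocol import MarginSpec

            v = MarginSpec(*v) if isinstance(v, list) else MarginSpec(**v)
        elif isinstance(v, list) and not isinstance(v, str):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[f.name] = v
    return cls(**kwargs)


def config_from_dict(data: dict) -> ExperimentConfig:
    return _build_dataclass(ExperimentConfig, data)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# shift estimation

def estimated_records(
    patient: Patient, settings: RegistrationSettings
) -> Tuple[List[ShiftRecord], Dict[int, Dict[str, np.ndarray]]]:
    """DIR-estimated shift records and cumulative target positions.

    Registers MR2/MR3/MR4 of every session to its MR1 and reads the CTV
    displacement off the fields; shift 1 and shift 2 are differences of the
    cumulative positions, exactly as the protocol defines them.
    """
    records: List[ShiftRecord] = []
    cumulative: Dict[int, Dict[str, np.ndarray]] = {}
    for session in patient.sessions:
        fixed = session.images["MR1"]
        ctv = session.labels["MR1"]["ctv"]
        t = {}
        for scan in ("MR2", "MR3", "MR4"):
            disp = register(fixed, session.images[scan], settings)
            t[scan] = estimate_ctv_shift(disp, ctv)
        cumulative[session.fraction] = t
        records.append(
            ShiftRecord(
                patient.patient_id, session.fraction, "shift1",
                t["MR3"] - t["MR2"], source="estimated",
            )
        )
        records.append(
            ShiftRecord(
                patient.patient_id, session.fraction, "shift2",
                t["MR4"] - t["MR3"], source="estimated",
            )
        )
    return records, cumulative


def _truth_cumulative(patient: Patient) -> Dict[int, Dict[str, np.ndarray]]:
    return {s.fraction: dict(s.cumulative) for s in patient.sessions}


# ---------------------------------------------------------------------------
# per-patient analysis

@dataclass
class PatientOutcome:
    patient: Patient
    records: List[ShiftRecord]
    protocol_state: object
    actual: AccumulationResult
    counterfactual: AccumulationResult

    @property
    def subgroup(self) -> str:
        return "switched" if self.protocol_state.switched else "tight"


def _accumulate_scenario(
    patient: Patient,
    margins_by_fraction: Dict[int, object],
    cumulative: Dict[int, Dict[str, np.ndarray]],
    cfg: ExperimentConfig,
) -> AccumulationResult:
    use_truth = cfg.accumulation_motion == "ground_truth"
    per_fraction: Dict[int, object] = {}
    for session in patient.sessions:
        k = session.fraction
        ctv = session.labels["MR1"]["ctv"]
        atp_shifts = (cumulative[k]["MR2"], cumulative[k]["MR3"])
        atp1, atp2 = fraction_subplans(
            ctv, session.grid, cfg.plan, margins_by_fraction[k], atp_shifts
        )
        per_fraction[k] = accumulate_intrafraction(
            session, atp1, atp2, cfg.registration,
            use_ground_truth_motion=use_truth,
        )
    return accumulate_interfraction(
        patient, per_fraction, cfg.registration, cfg.constraints,
        use_ground_truth_motion=use_truth,
    )


def analyze_patient(patient: Patient, cfg: ExperimentConfig) -> PatientOutcome:
    """Full per-patient chain: shifts, protocol, both scenarios."""
    if cfg.shift_source == "ground_truth":
        records = ground_truth_records(patient)
        cumulative = _truth_cumulative(patient)
    else:
        records, cumulative = estimated_records(patient, cfg.registration)
    state = apply_protocol(records, cfg.traffic, cfg.cohort.n_fractions)

    actual = _accumulate_scenario(patient, dict(state.margins_by_fraction), cumulative, cfg)
    if state.switched:
        tight_all = {
            f: cfg.traffic.tight_margins
            for f in state.margins_by_fraction
        }
        counterfactual = _accumulate_scenario(patient, tight_all, cumulative, cfg)
    else:
        counterfactual = actual
    return PatientOutcome(patient, records, state, actual, counterfactual)


# ---------------------------------------------------------------------------
# experiment driver

@dataclass
class ExperimentResult:
    outcomes: List[PatientOutcome]
    metrics: pd.DataFrame
    summary: pd.DataFrame
    comparison: Dict[str, pd.DataFrame]
    shift_records: pd.DataFrame
    failed_patients: Dict[int, str]
    outdir: Optional[Path] = None


def compare_scenarios(metrics: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Actual vs counterfactual comparison for switched patients.

    Returns a per-patient panel table (A: as-delivered with the margin
    switch; B: re-planned with the original tight margins) and a subgroup
    summary with threshold-pass counts in both scenarios.
    """
    a = metrics[metrics.scenario == "actual"].set_index("patient")
    b = metrics[metrics.scenario == "counterfactual"].set_index("patient")
    common = a.index.intersection(b.index)
    if len(common) != len(a) or len(common) != len(b):
        raise ValueError("actual and counterfactual patient sets do not match")
    per_patient = pd.DataFrame(
        {
            "subgroup": a.loc[common, "subgroup"],
            "d99_actual": a.loc[common, "ctv_d99"],
            "d99_counterfactual": b.loc[common, "ctv_d99"],
        }
    )
    per_patient["delta_d99"] = (
        per_patient["d99_actual"] - per_patient["d99_counterfactual"]
    )
    threshold = 34.4
    summary_rows = []
    for scenario, col in (("actual", "d99_actual"), ("counterfactual", "d99_counterfactual")):
        sw = per_patient[per_patient.subgroup == "switched"][col]
        summary_rows.append(
            {
                "scenario": scenario,
                "n_switched": len(sw),
                "d99_median": float(sw.median()) if len(sw) else float("nan"),
                "d99_iqr_lo": float(sw.quantile(0.25)) if len(sw) else float("nan"),
                "d99_iqr_hi": float(sw.quantile(0.75)) if len(sw) else float("nan"),
                "n_above_threshold": int((sw >= threshold).sum()),
            }
        )
    return {
        "per_patient": per_patient.reset_index(),
        "summary": pd.DataFrame(summary_rows),
    }


def run_experiment(cfg: ExperimentConfig, outdir=None) -> ExperimentResult:
    """Run the full experiment; write the report bundle if ``outdir`` given."""
    patients = simulate_cohort(cfg.cohort, cfg.anatomy, cfg.grid)
    outcomes: List[PatientOutcome] = []
    failed: Dict[int, str] = {}
    for patient in patients:
        try:
            outcomes.append(analyze_patient(patient, cfg))
        except Exception as exc:  # per-patient isolation
            logger.error("patient %d failed: %s", patient.patient_id, exc)
            failed[patient.patient_id] = "".join(
                traceback.format_exception_only(type(exc), exc)
            ).strip()
    if not outcomes:
        raise RuntimeError("all patients failed")

    rows = []
    for oc in outcomes:
        for scenario, res in (("actual", oc.actual), ("counterfactual", oc.counterfactual)):
            rows.append(
                {
                    "patient": oc.patient.patient_id,
                    "subgroup": oc.subgroup,
                    "scenario": scenario,
                    "switch_fraction": oc.protocol_state.switch_fraction,
                    **res.metrics,
                    **{f"pass_{k}": v for k, v in res.constraints.items()},
                }
            )
    metrics = pd.DataFrame(rows)
    summary = summarize_cohort(rows, cfg.constraints.ctv_d99_min_gy)
    comparison = compare_scenarios(metrics)
    all_records = [r for oc in outcomes for r in oc.records]
    shift_df = records_to_frame(all_records)

    result = ExperimentResult(
        outcomes=outcomes,
        metrics=metrics,
        summary=summary,
        comparison=comparison,
        shift_records=shift_df,
        failed_patients=failed,
    )
    if outdir is not None:
        result.outdir = write_report_bundle(result, cfg, Path(outdir))
    return result


def write_report_bundle(result: ExperimentResult, cfg: ExperimentConfig, outdir: Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.shift_records.to_csv(outdir / "shift_records.csv", index=False)
    cumulative_shift_table(result.shift_records).to_csv(
        outdir / "cumulative_shift_distribution.csv", index=False
    )
    result.metrics.to_csv(outdir / "patient_metrics.csv", index=False)
    result.summary.to_csv(outdir / "cohort_summary.csv", index=False)
    result.comparison["per_patient"].to_csv(
        outdir / "scenario_comparison_per_patient.csv", index=False
    )
    result.comparison["summary"].to_csv(
        outdir / "scenario_comparison_summary.csv", index=False
    )
    traces = []
    with open(outdir / "protocol_log.txt", "w") as fh:
        for oc in result.outcomes:
            df = oc.protocol_state.to_frame()
            df.insert(0, "patient", oc.patient.patient_id)
            traces.append(df)
            fh.write(f"patient {oc.patient.patient_id} ({oc.subgroup}):\n")
            for line in oc.protocol_state.log:
                fh.write(f"  {line}\n")
            if not oc.protocol_state.log:
                fh.write("  no events\n")
    pd.concat(traces).to_csv(outdir / "protocol_traces.csv", index=False)
    if cfg.write_volumes:
        for oc in result.outcomes:
            sio.save_volume(
                oc.actual.total,
                outdir / "doses" / f"patient{oc.patient.patient_id:03d}_total.nii.gz",
            )
    cfg_dict = config_to_dict(cfg)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "seed": cfg.seed,
        "scale": cfg.scale,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_patients": len(result.outcomes),
        "failed_patients": result.failed_patients,
        "versions": _versions(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    save_config(cfg, outdir / "config.yaml")
    return outdir


def _versions() -> Dict[str, str]:
    import nibabel
    import scipy

    from . import __version__

    return {
        "subfrax": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
    }
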