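"""End-to-end orchestration: trial -> cycles -> parameters -> cohort stats.

Thin glue over the stage modules, fixing the analysis order: filter raw
marker coordinates, calibrate on the static trial, compute the per-model
ankle traces, segment into normalized cycles with force-plate (or
provided) events, extract per-cycle parameters and rocker flags, pick one
representative cycle per subject x model x condition, and feed the six
parameter tables to the 3 x 2 factorial analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cycle_analysis import (
    AnkleParameters,
    RockerCriteria,
    classify_rockers,
    extract_parameters,
    lfm,
    select_representative,
)
from .foot_models import CalibrationOffsets, compute_ankle_trace, static_calibration
from .gaitdata_io import Condition, FootModel, GaitEvents, TrialRecording
from .group_stats import CohortTable, FactorialReport, run_factorial_pipeline
from .preprocess import FilterSpec, NormalizedCycle, detect_gait_events, filter_trial
from .preprocess import time_normalize
from .synthetic_gait import SubjectData

__all__ = [
    "PARAMETER_NAMES",
    "TrialResult",
    "CohortAnalysis",
    "calibrate_subject",
    "process_trial",
    "analyze_cohort",
]

#: the six clinical parameters fed to the factorial analysis
PARAMETER_NAMES: tuple[str, ...] = (
    "rom", "angle_at_fc", "peak_df", "t_peak_df", "peak_pf", "t_peak_pf",
)


@dataclass
class TrialResult:
    """All cycles of one trial under one foot model, with per-cycle outcomes."""

    model: FootModel
    condition: Condition
    subject_id: str
    cycles: list[NormalizedCycle]
    parameters: list[AnkleParameters]
    heel_rocker: list[bool]
    premature_forefoot: list[bool]
    representative_index: int | None = None

    @property
    def representative_parameters(self) -> AnkleParameters:
        if self.representative_index is None:
            raise ValueError("no representative cycle selected")
        return self.parameters[self.representative_index]


def calibrate_subject(
    static_trial: TrialRecording,
    filter_spec: FilterSpec = FilterSpec(),
) -> dict[FootModel, CalibrationOffsets]:
    """Static calibration for all three foot models at once."""
    filtered = filter_trial(static_trial, filter_spec)
    return {m: static_calibration(filtered, m) for m in FootModel}


def process_trial(
    trial: TrialRecording,
    offsets: dict[FootModel, CalibrationOffsets],
    *,
    events: GaitEvents | None = None,
    filter_spec: FilterSpec = FilterSpec(),
    criteria: RockerCriteria = RockerCriteria(),
    grf_channel: str = "Fz",
) -> dict[FootModel, TrialResult]:
    """Run one walking trial through every foot model.

    Events default to force-plate threshold detection on ``grf_channel``;
    pass ``events`` to use externally provided gait events instead.
    """
    filtered = filter_trial(trial, filter_spec)
    if events is None:
        if grf_channel not in trial.analog:
            raise ValueError(f"no {grf_channel!r} analog channel and no events given")
        events = detect_gait_events(
            trial.analog[grf_channel], trial.analog_rate, trial.marker_rate
        )
    out: dict[FootModel, TrialResult] = {}
    for model in FootModel:
        trace = compute_ankle_trace(filtered, model, offsets[model])
        cycles = time_normalize(
            trace.values,
            events,
            model=model,
            condition=trial.condition,
            subject_id=trial.subject_id,
            trial_id=trial.trial_id,
        )
        params = [extract_parameters(c) for c in cycles]
        flags = [classify_rockers(c, p, criteria) for c, p in zip(cycles, params)]
        rep = (
            select_representative(cycles).chosen_index if len(cycles) >= 2
            else (0 if cycles else None)
        )
        out[model] = TrialResult(
            model=model,
            condition=trial.condition,
            subject_id=trial.subject_id,
            cycles=cycles,
            parameters=params,
            heel_rocker=[f.heel_rocker for f in flags],
            premature_forefoot=[f.premature_forefoot_rocker for f in flags],
            representative_index=rep,
        )
    return out


@dataclass
class CohortAnalysis:
    """Cohort-level outputs: parameter tables, factorial report, prevalence."""

    parameters: pd.DataFrame          # one row per cycle
    representative: pd.DataFrame      # one row per subject x model x condition
    tables: dict[str, CohortTable]
    report: FactorialReport
    prevalence: pd.DataFrame          # rocker prevalence per model x condition
    lfm_r2_mean: dict[tuple[str, str], float]
    lfm_consistent: dict[tuple[str, str], bool]


def analyze_cohort(
    cohort: list[SubjectData],
    *,
    use_true_events: bool = False,
    filter_spec: FilterSpec = FilterSpec(),
    criteria: RockerCriteria = RockerCriteria(),
) -> CohortAnalysis:
    """Full study analysis of a (synthetic) cohort.

    Per subject: calibrate on the static trial, process the barefoot and
    orthosis trials under all three models, keep the representative cycle
    per condition.  Cohort level: rocker prevalence over all cycles,
    linear-fit-method consistency over representative cycles, and the
    3 x 2 factorial analysis of the six parameters.
    """
    cycle_rows = []
    rep_rows = []
    rep_curves: dict[tuple[str, str], list[np.ndarray]] = {}
    for subject in cohort:
        offsets = calibrate_subject(subject.static, filter_spec)
        for condition, trial in subject.trials.items():
            events = subject.truths[condition].events if use_true_events else None
            results = process_trial(
                trial, offsets, events=events,
                filter_spec=filter_spec, criteria=criteria,
            )
            for model, res in results.items():
                for k, (p, heel, pff) in enumerate(
                    zip(res.parameters, res.heel_rocker, res.premature_forefoot)
                ):
                    cycle_rows.append({
                        "subject": res.subject_id,
                        "model": model.value,
                        "condition": condition.value,
                        "cycle": k,
                        "angle_at_fc": p.angle_at_fc,
                        "peak_df": p.peak_df,
                        "t_peak_df": p.t_peak_df,
                        "peak_pf": p.peak_pf,
                        "t_peak_pf": p.t_peak_pf,
                        "rom": p.rom,
                        "heel_rocker": heel,
                        "premature_ff": pff,
                    })
                if res.representative_index is None:
                    continue
                p = res.representative_parameters
                rep_rows.append({
                    "subject": res.subject_id,
                    "model": model.value,
                    "condition": condition.value,
                    "angle_at_fc": p.angle_at_fc,
                    "peak_df": p.peak_df,
                    "t_peak_df": p.t_peak_df,
                    "peak_pf": p.peak_pf,
                    "t_peak_pf": p.t_peak_pf,
                    "rom": p.rom,
                })
                rep_curves.setdefault((model.value, condition.value), []).append(
                    res.cycles[res.representative_index].samples
                )

    parameters = pd.DataFrame(cycle_rows)
    representative = pd.DataFrame(rep_rows)

    tables = {}
    for name in PARAMETER_NAMES:
        tidy = representative[["subject", "model", "condition", name]].rename(
            columns={name: "value"}
        )
        tables[name] = CohortTable(tidy, parameter=name)
    report = run_factorial_pipeline(tables)

    prevalence = (
        parameters.groupby(["model", "condition"])[["heel_rocker", "premature_ff"]]
        .mean()
        .mul(100.0)
        .rename(columns={"heel_rocker": "heel_rocker_pct",
                         "premature_ff": "premature_forefoot_pct"})
        .reset_index()
    )

    lfm_r2_mean: dict[tuple[str, str], float] = {}
    lfm_consistent: dict[tuple[str, str], bool] = {}
    for key, curves in rep_curves.items():
        if len(curves) >= 2:
            res = lfm(curves)
            lfm_r2_mean[key] = res.r2_mean
            lfm_consistent[key] = res.consistent

    return CohortAnalysis(
        parameters=parameters,
        representative=representative,
        tables=tables,
        report=report,
        prevalence=prevalence,
        lfm_r2_mean=lfm_r2_mean,
        lfm_consistent=lfm_consistent,
    )
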