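"""End-to-end study runner: simulate or load a cohort, process every trace,
and emit the accuracy, responsiveness and cohort-summary tables.

The report mirrors the three surfaces a tracker-validation paper prints:

* an accuracy table — one row per group × device × scope (each activity and
  the protocol total) with n, means, mean difference and its one-sample
  t-test, Bland-Altman bias and limits of agreement, ICC(A,1) with its
  reliability band, RMSE and the 10%-error-zone flag;
* a responsiveness table — paired t-tests between cycling loads and between
  walking speed/incline conditions, for the criterion and every device;
* a cohort summary with counts, whole-number percentages and mean (SD)
  per group.

Everything is deterministic under a fixed seed, and every statistic in the
JSON report carries a provenance key naming the operation that produced it.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .agreement import (
    AgreementConfig,
    bland_altman,
    make_paired,
    paired_responsiveness,
    summarize_agreement,
)
from .calorimetry import FilterConfig, HampelConfig, WeirCoefficients, process_trace
from .design import IccDesign, design_table
from .protocol import PatientGroup, build_standard_protocol
from .synthetic import (
    PatientProfile,
    PatientRecord,
    SimulationConfig,
    simulate_study,
)
from . import io as wio

__all__ = ["StudyConfig", "CohortSummary", "summarize_cohort", "run_study", "write_report"]

log = logging.getLogger("wearcal")

# Table-3-style within-patient contrasts: cycling loads and walking
# speed/incline conditions of the standard protocol.
RESPONSIVENESS_PAIRS = [
    ("cycling_low", "cycling_mid"),
    ("cycling_low", "cycling_high"),
    ("cycling_mid", "cycling_high"),
    ("walking_slow", "walking_incline"),
    ("walking_slow", "walking_fast"),
    ("walking_incline", "walking_fast"),
]


@dataclass(frozen=True)
class StudyConfig:
    """Inputs and analysis settings for one study run.

    Either ``simulation`` is set (synthetic study) or all of
    ``cohort_path``/``traces_dir``/``logs_path`` point at existing files
    written in the package's delimited formats.
    """

    simulation: Optional[SimulationConfig] = field(default_factory=SimulationConfig)
    cohort_path: Optional[str] = None
    traces_dir: Optional[str] = None
    logs_path: Optional[str] = None
    weir: WeirCoefficients = WeirCoefficients()
    hampel: HampelConfig = HampelConfig()
    filter: FilterConfig = FilterConfig()
    agreement: AgreementConfig = AgreementConfig()
    icc_design: IccDesign = IccDesign()

    def __post_init__(self) -> None:
        paths = (self.cohort_path, self.traces_dir, self.logs_path)
        if self.simulation is None and not all(paths):
            raise ValueError(
                "either simulation settings or cohort_path/traces_dir/logs_path are required"
            )


@dataclass(frozen=True)
class CohortSummary:
    """Per-group descriptive statistics in publication layout.

    ``categorical`` maps field -> value -> (count, whole percent);
    ``numeric`` maps field -> (mean, sd).
    """

    per_group: dict[str, dict]

    def as_dict(self) -> dict:
        return self.per_group


def _pct(count: int, n: int) -> int:
    # round half up, as tables of counts conventionally do
    return int(np.floor(100.0 * count / n + 0.5))


def summarize_cohort(profiles: list[PatientProfile]) -> CohortSummary:
    """Counts, whole-number percentages, and mean/SD per group."""
    if not profiles:
        raise ValueError("cannot summarise an empty cohort")
    per_group: dict[str, dict] = {}
    for group in PatientGroup:
        members = [p for p in profiles if p.group is group]
        if not members:
            continue
        n = len(members)
        sexes = sorted({p.sex for p in members})
        categorical = {
            "sex": {
                s: {"count": (c := sum(p.sex == s for p in members)), "percent": _pct(c, n)}
                for s in sexes
            }
        }
        numeric = {}
        for name in ("age", "height_cm", "weight_kg", "resting_vo2_lmin", "kinetics_tau_s"):
            vals = np.array([getattr(p, name) for p in members])
            sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
            numeric[name] = {"mean": float(np.mean(vals)), "sd": sd}
        per_group[group.value] = {"n": n, "categorical": categorical, "numeric": numeric}
    return CohortSummary(per_group=per_group)


def _load_records(config: StudyConfig) -> list[PatientRecord]:
    profiles = wio.read_cohort(config.cohort_path)
    logs = wio.read_tracker_logs(config.logs_path)
    logs_by_pid: dict[str, list] = {}
    for lg in logs:
        logs_by_pid.setdefault(lg.patient_id, []).append(lg)
    records = []
    for p in profiles:
        trace_path = Path(config.traces_dir) / f"{p.id}.csv"
        if not trace_path.exists():
            raise FileNotFoundError(f"trace file for patient {p.id} not found: {trace_path}")
        trace = wio.read_trace(trace_path, patient_id=p.id)
        protocol = build_standard_protocol(p.group)
        records.append(PatientRecord(p, protocol, trace, tuple(logs_by_pid.get(p.id, ()))))
    return records


def run_study(config: StudyConfig) -> dict:
    """Run the full pipeline and return the machine-readable report.

    Per patient: the criterion chain turns the gas-exchange trace into
    per-activity and total-protocol kcal; each device's per-activity kcal is
    kcal_end − kcal_start from its log and the total is the span of its
    cumulative counter (rest included). Patients whose trace fails a
    processing stage are excluded and logged, and all paired statistics are
    pairwise-complete per scope.
    """
    if config.simulation is not None:
        records = simulate_study(config.simulation)
    else:
        records = _load_records(config)

    criterion: dict[tuple[str, str], dict[str, float]] = {}  # (group, scope) -> pid -> kcal
    device_ee: dict[tuple[str, str, str], dict[str, float]] = {}  # (group, device, scope)
    exclusions = []
    device_names: list[str] = []
    scopes_by_group: dict[str, list[str]] = {}

    for rec in records:
        grp = rec.profile.group.value
        scopes_by_group.setdefault(
            grp, [s.activity_id for s in rec.protocol.segments] + ["total"]
        )
        try:
            processed = process_trace(
                rec.trace, rec.protocol, weir=config.weir,
                hampel=config.hampel, filt=config.filter,
            )
        except ValueError as exc:
            log.warning("excluding patient %s: %s", rec.profile.id, exc)
            exclusions.append({"patient_id": rec.profile.id, "reason": str(exc)})
            continue
        n_breaths = processed.breath_rate_raw.size
        flag_rate = processed.outlier_indices.size / max(n_breaths, 1)
        if flag_rate > 0.05:
            log.warning("patient %s: Hampel flag rate %.1f%%", rec.profile.id, 100 * flag_rate)
        for seg in processed.segments:
            criterion.setdefault((grp, seg.activity_id), {})[rec.profile.id] = seg.ee_kcal
        criterion.setdefault((grp, "total"), {})[rec.profile.id] = processed.total_kcal
        for lg in rec.logs:
            if lg.device not in device_names:
                device_names.append(lg.device)
            for aid, start, end in lg.rows:
                device_ee.setdefault((grp, lg.device, aid), {})[rec.profile.id] = end - start
            device_ee.setdefault((grp, lg.device, "total"), {})[rec.profile.id] = lg.total_kcal

    accuracy = []
    ba_points = []
    for grp, scopes in sorted(scopes_by_group.items()):
        for device in device_names:
            for scope in scopes:
                crit = criterion.get((grp, scope), {})
                dev = device_ee.get((grp, device, scope), {})
                if len(set(crit) & set(dev)) < 3:
                    continue
                pairs = make_paired(crit, dev, scope=scope,
                                    group=PatientGroup(grp), device_name=device)
                summ = summarize_agreement(pairs, config.agreement)
                accuracy.append(dataclasses.asdict(summ))
                if scope == "total":
                    for mean, diff in bland_altman(pairs, config.agreement).plot_points:
                        ba_points.append({"group": grp, "device": device,
                                          "mean_kcal": mean, "diff_kcal": diff})

    responsiveness = []
    for grp in sorted(scopes_by_group):
        sources = [("criterion", lambda s, g=grp: criterion.get((g, s), {}))]
        for device in device_names:
            sources.append((device, lambda s, g=grp, d=device: device_ee.get((g, d, s), {})))
        for source_name, getter in sources:
            for cond_a, cond_b in RESPONSIVENESS_PAIRS:
                ee_a, ee_b = getter(cond_a), getter(cond_b)
                common = set(ee_a) & set(ee_b)
                if len(common) < 2:
                    continue
                res = paired_responsiveness(
                    {p: ee_a[p] for p in common}, {p: ee_b[p] for p in common},
                    cond_a, cond_b, source=source_name, config=config.agreement,
                )
                row = dataclasses.asdict(res)
                row["group"] = grp
                responsiveness.append(row)

    profiles = [rec.profile for rec in records]
    report = {
        "cohort_summary": summarize_cohort(profiles).as_dict(),
        "accuracy": accuracy,
        "responsiveness": responsiveness,
        "bland_altman_points": ba_points,
        "icc_design": design_table(config.icc_design),
        "exclusions": exclusions,
        "n_patients": len(records),
        "n_excluded": len(exclusions),
        "provenance": {
            "cohort_summary": "study.summarize_cohort",
            "accuracy": "agreement.summarize_agreement "
                        "(mean_difference_test, bland_altman, icc_a1, rmse)",
            "responsiveness": "agreement.paired_responsiveness",
            "bland_altman_points": "agreement.bland_altman",
            "icc_design": "design.icc_sample_size / design.icc_power",
            "criterion_ee": "calorimetry.process_trace "
                            "(weir_rate, hampel_replace, spline_resample_1hz, "
                            "butterworth_lowpass, segment_energy)",
        },
    }
    return report


def write_report(report: dict, out_dir) -> None:
    """Write the JSON report plus the delimited accuracy/responsiveness tables."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    if report["accuracy"]:
        pd.DataFrame(report["accuracy"]).to_csv(out / "accuracy.csv", index=False)
    if report["responsiveness"]:
        pd.DataFrame(report["responsiveness"]).to_csv(out / "responsiveness.csv", index=False)
    if report["bland_altman_points"]:
        pd.DataFrame(report["bland_altman_points"]).to_csv(
            out / "bland_altman_points.csv", index=False
        )
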