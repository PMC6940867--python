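"""Synthetic cohorts: gas-exchange traces and tracker logs with known truth.

Real patient recordings from tracker-validation studies are rarely deposited,
so every downstream stage is exercised on simulated data instead. The
generator's contract is *plausible magnitude plus known ground truth*, not
physiological fidelity:

* Steady-state VO2 targets per activity come from standard metabolic
  (ACSM-style) equations — cycle ergometry at ~10.8 ml O2 per minute per
  watt above a resting + unloaded-cycling term, treadmill walking from the
  speed/grade equation — and from fixed MET values for sedentary, household
  and stair activities.
* Within a recording, VO2 follows the piecewise targets with first-order
  exponential on-kinetics (time constant ``kinetics_tau_s``; slower in the
  HFrEF group), decaying toward resting VO2 during recovery gaps. VCO2 is a
  stepwise respiratory-exchange-ratio multiple of VO2 per intensity band.
* Breaths arrive irregularly, with the mean interval shrinking at higher
  ventilation; breath values carry multiplicative log-normal noise and
  occasional cough-like spikes.
* The ground-truth energy of every activity segment and recovery gap is the
  exact analytic integral of the noise-free Weir rate, using the same Weir
  coefficients the processing pipeline applies, so pipeline error isolates
  processing effects.
* Trackers are modelled only at their EE output: a gain/offset/noise model
  on the true per-activity energy, accumulated into a cumulative kcal
  counter that keeps running through recovery gaps and is quantised to the
  display resolution. The error structure of real devices is proprietary;
  this bias model is a synthetic stand-in.

All randomness flows from one root seed; per-patient and per-device
substreams are derived deterministically from (seed, patient index, device
name), so cohorts reproduce exactly and in parallel-safe fashion.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from math import exp, expm1
from typing import Mapping, Optional, Sequence

import numpy as np

from .calorimetry import WeirCoefficients
from .protocol import (
    Activity,
    ActivityCategory,
    ActivityProtocol,
    PatientGroup,
    build_standard_protocol,
)

__all__ = [
    "PatientProfile",
    "DeviceBiasModel",
    "SimulationConfig",
    "GasExchangeTrace",
    "TrackerLog",
    "PatientRecord",
    "sample_cohort",
    "target_vo2",
    "simulate_gas_exchange",
    "simulate_tracker",
    "simulate_study",
]

#: resting oxygen uptake, ml O2 per kg per minute (1 MET)
MET_ML_KG_MIN = 3.5

# Fixed MET assignments for activities without a work-rate equation
# (compendium-style values for light office/household tasks and stairs).
_ACTIVITY_METS = {
    "sitting": 1.3,
    "standing": 1.4,
    "typing": 1.5,
    "table_cleaning": 2.5,
    "dishwasher": 2.5,
    "vacuuming": 3.3,
    "stairs_up": 4.0,
    "stairs_down": 3.0,
}
_CATEGORY_METS = {
    ActivityCategory.SEDENTARY: 1.3,
    ActivityCategory.HOUSEHOLD: 2.8,
    ActivityCategory.STAIRS: 3.5,
}

# Group sampling targets: (mean, sd) for age [y], height [cm], weight [kg],
# male fraction, and on-kinetics time constant [s] (slower in HFrEF).
_GROUP_SAMPLING = {
    PatientGroup.CAD: dict(
        age=(61.4, 6.9), height=(176.0, 6.8), weight=(84.3, 12.1), male_frac=14 / 19,
        tau=(30.0, 5.0),
    ),
    PatientGroup.HFREF: dict(
        age=(65.1, 6.6), height=(177.0, 5.4), weight=(86.7, 13.7), male_frac=17 / 19,
        tau=(45.0, 8.0),
    ),
}


@dataclass(frozen=True)
class PatientProfile:
    id: str
    group: PatientGroup
    age: float
    sex: str
    height_cm: float
    weight_kg: float
    resting_vo2_lmin: float
    kinetics_tau_s: float

    def __post_init__(self) -> None:
        if min(self.weight_kg, self.height_cm, self.resting_vo2_lmin, self.kinetics_tau_s) <= 0:
            raise ValueError("weight, height, resting VO2 and kinetics tau must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")


def default_resting_vo2(weight_kg: float) -> float:
    """1 MET resting VO2 in L/min for a given body weight."""
    return MET_ML_KG_MIN * weight_kg / 1000.0


@dataclass(frozen=True)
class DeviceBiasModel:
    """Gain/offset/noise stand-in for a tracker's proprietary EE algorithm.

    Device EE per activity = gain × truth + offset_rate × duration +
    Gaussian noise with SD ``noise_sd_kcal + noise_prop × truth``;
    readings are quantised to ``resolution_kcal`` on the display counter.
    """

    gain: float = 1.0
    offset_rate_kcal_min: float = 0.0
    noise_sd_kcal: float = 0.0
    noise_prop: float = 0.0
    resolution_kcal: float = 1.0

    def __post_init__(self) -> None:
        if self.resolution_kcal < 0:
            raise ValueError("resolution must be >= 0 (0 disables quantisation)")
        if self.noise_sd_kcal < 0 or self.noise_prop < 0:
            raise ValueError("noise terms must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the simulated study.

    Defaults mirror the laboratory study being emulated where stated
    (19 patients per group, Table-2-style anthropometrics are built into
    :func:`sample_cohort`) and otherwise use values a physiologist would
    call realistic for breath-by-breath data: ~3 s breaths at rest, ~8%
    breath-level coefficient of variation, rare (0.5%) cough-like spikes
    of 5× local level, and 30–90 s heart-rate-recovery gaps.
    """

    n_per_group: int = 19
    seed: int = 0
    breath_interval_mean_s: float = 3.0
    breath_interval_sd_s: float = 0.6
    outlier_rate: float = 0.005
    outlier_magnitude: float = 5.0
    noise_cv: float = 0.08
    # (MET upper bound, RER) bands, evaluated in order; last band is open
    rer_by_intensity: tuple[tuple[float, float], ...] = ((2.0, 0.82), (4.0, 0.88), (float("inf"), 0.95))
    device_models: Mapping[str, DeviceBiasModel] = field(
        default_factory=lambda: {
            "wristA": DeviceBiasModel(gain=1.2, offset_rate_kcal_min=0.0, noise_sd_kcal=2.0),
            "wristB": DeviceBiasModel(gain=1.0, offset_rate_kcal_min=0.5, noise_sd_kcal=4.0),
        }
    )
    rest_gap_range_s: tuple[float, float] = (30.0, 90.0)
    lead_in_s: float = 30.0
    tail_s: float = 15.0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must be a probability")
        if self.breath_interval_mean_s <= 0:
            raise ValueError("breath intervals must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for _, rer in self.rer_by_intensity:
            if not 0.7 <= rer <= 1.1:
                raise ValueError("RER values must lie in [0.7, 1.1]")
        lo, hi = self.rest_gap_range_s
        if lo < 0 or hi < lo:
            raise ValueError("rest_gap_range_s must be 0 <= lo <= hi")


@dataclass(frozen=True)
class GasExchangeTrace:
    """Irregular breath-by-breath VO2/VCO2 samples on the protocol clock.

    ``truth_ee_per_segment`` / ``truth_ee_rest_kcal`` are only available for
    simulated traces; traces read from disk carry ``None`` there.
    """

    patient_id: str
    times: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    truth_ee_per_segment: Optional[dict[str, float]] = None
    truth_ee_rest_kcal: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        vo2 = np.asarray(self.vo2, dtype=float)
        vco2 = np.asarray(self.vco2, dtype=float)
        if not (t.size == vo2.size == vco2.size):
            raise ValueError("times, vo2 and vco2 must have equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(vo2 < 0) or np.any(vco2 < 0):
            raise ValueError("gas values must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "vo2", vo2)
        object.__setattr__(self, "vco2", vco2)

    @property
    def truth_ee_total_kcal(self) -> Optional[float]:
        """Ground-truth energy over the whole protocol span, rest included."""
        if self.truth_ee_per_segment is None or self.truth_ee_rest_kcal is None:
            return None
        return sum(self.truth_ee_per_segment.values()) + self.truth_ee_rest_kcal


@dataclass(frozen=True)
class TrackerLog:
    """Cumulative-kcal readings one device showed at activity boundaries."""

    patient_id: str
    device: str
    rows: tuple[tuple[str, float, float], ...]  # (activity_id, kcal_start, kcal_end)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for aid, start, end in self.rows:
            if end < start:
                raise ValueError(f"activity {aid!r}: kcal_end < kcal_start")
            if start < prev_end:
                raise ValueError(f"activity {aid!r}: cumulative readings decreased")
            prev_end = end

    def activity_kcal(self, activity_id: str) -> float:
        for aid, start, end in self.rows:
            if aid == activity_id:
                return end - start
        raise KeyError(f"no log row for activity {activity_id!r}")

    @property
    def total_kcal(self) -> float:
        """Device EE over the whole protocol (rest included)."""
        return self.rows[-1][2] - self.rows[0][1]


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient: profile, individual protocol, trace and logs."""

    profile: PatientProfile
    protocol: ActivityProtocol
    trace: GasExchangeTrace
    logs: tuple[TrackerLog, ...]


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, patient_index]))


def _device_rng(seed: int, patient_index: int, device: str) -> np.random.Generator:
    key = zlib.crc32(device.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, patient_index, key]))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def sample_cohort(config: SimulationConfig) -> list[PatientProfile]:
    """Draw ``n_per_group`` patients per group, deterministically per seed.

    Age/height/weight come from group-specific normal distributions matched
    to published cardiac-cohort characteristics, truncated to plausible
    adult ranges; HFrEF on-kinetics time constants are drawn slower than CAD.
    """
    profiles: list[PatientProfile] = []
    idx = 0
    for group in (PatientGroup.CAD, PatientGroup.HFREF):
        par = _GROUP_SAMPLING[group]
        for _ in range(config.n_per_group):
            rng = _patient_rng(config.seed, idx)
            age = _truncated_normal(rng, *par["age"], 18.0, 95.0)
            height = _truncated_normal(rng, *par["height"], 140.0, 210.0)
            weight = _truncated_normal(rng, *par["weight"], 45.0, 160.0)
            sex = "male" if rng.random() < par["male_frac"] else "female"
            tau = _truncated_normal(rng, *par["tau"], 10.0, 120.0)
            profiles.append(
                PatientProfile(
                    id=f"{group.value}-{idx:03d}",
                    group=group,
                    age=age,
                    sex=sex,
                    height_cm=height,
                    weight_kg=weight,
                    resting_vo2_lmin=default_resting_vo2(weight),
                    kinetics_tau_s=tau,
                )
            )
            idx += 1
    return profiles


def target_vo2(activity: Activity, profile: PatientProfile) -> float:
    """Steady-state VO2 target (L/min) for an activity and patient.

    Cycling: VO2 [ml/min] = 10.8·W + 7.0·weight (resting plus unloaded
    cycling, 3.5 ml/kg/min each). Walking: VO2 [ml/kg/min] =
    0.1·v + 1.8·v·grade + 3.5 with v in m/min. Other categories use fixed
    MET assignments scaled by body weight.
    """
    w = profile.weight_kg
    if activity.category is ActivityCategory.CYCLING:
        return (10.8 * activity.load_w + 7.0 * w) / 1000.0
    if activity.category is ActivityCategory.WALKING:
        v_m_min = activity.speed_kmh * 1000.0 / 60.0
        grade = (activity.incline_pct or 0.0) / 100.0
        per_kg = 0.1 * v_m_min + 1.8 * v_m_min * grade + MET_ML_KG_MIN
        return per_kg * w / 1000.0
    met = _ACTIVITY_METS.get(activity.id, _CATEGORY_METS[activity.category])
    return met * MET_ML_KG_MIN * w / 1000.0


def _rer_for(vo2_lmin: float, profile: PatientProfile,
             bands: Sequence[tuple[float, float]]) -> float:
    mets = vo2_lmin / (MET_ML_KG_MIN * profile.weight_kg / 1000.0)
    for upper, rer in bands:
        if mets < upper:
            return rer
    return bands[-1][1]


@dataclass(frozen=True)
class _Piece:
    """One constant-target stretch of the noise-free VO2 trajectory."""

    t_start: float
    t_end: float
    target: float
    v0: float  # VO2 at t_start
    tau: float
    rer: float
    activity_id: Optional[str]  # None for rest/lead/tail

    def vo2_at(self, t: float) -> float:
        dt = t - self.t_start
        if self.tau <= 1e-12:
            return self.target
        return self.target + (self.v0 - self.target) * exp(-dt / self.tau)

    @property
    def v_end(self) -> float:
        return self.vo2_at(self.t_end)

    def integral_vo2(self) -> float:
        """Exact integral of VO2 over the piece, in L (per-minute rate × s / 60)."""
        T = self.t_end - self.t_start
        if self.tau <= 1e-12:
            area_s = self.target * T
        else:
            area_s = self.target * T - (self.v0 - self.target) * self.tau * expm1(-T / self.tau)
        return area_s / 60.0


def _build_trajectory(
    protocol: ActivityProtocol,
    profile: PatientProfile,
    config: SimulationConfig,
    tau: Optional[float] = None,
) -> list[_Piece]:
    """Piecewise-exponential noise-free VO2 trajectory incl. lead-in and tail."""
    tau = profile.kinetics_tau_s if tau is None else tau
    rest = profile.resting_vo2_lmin
    rest_rer = _rer_for(rest, profile, config.rer_by_intensity)
    pieces: list[_Piece] = []
    v = rest
    t = -config.lead_in_s
    if config.lead_in_s > 0:
        pieces.append(_Piece(t, 0.0, rest, v, tau, rest_rer, None))
        v = pieces[-1].v_end
    segs = protocol.segments
    for i, seg in enumerate(segs):
        act = protocol.activity(seg.activity_id)
        tgt = target_vo2(act, profile)
        rer = _rer_for(tgt, profile, config.rer_by_intensity)
        pieces.append(_Piece(seg.start_s, seg.end_s, tgt, v, tau, rer, seg.activity_id))
        v = pieces[-1].v_end
        if i + 1 < len(segs) and segs[i + 1].start_s > seg.end_s:
            pieces.append(_Piece(seg.end_s, segs[i + 1].start_s, rest, v, tau, rest_rer, None))
            v = pieces[-1].v_end
    if config.tail_s > 0:
        end = segs[-1].end_s
        pieces.append(_Piece(end, end + config.tail_s, rest, v, tau, rest_rer, None))
    return pieces


def _piece_at(pieces: list[_Piece], t: float) -> _Piece:
    for p in pieces:
        if p.t_start <= t < p.t_end:
            return p
    return pieces[-1]


def simulate_gas_exchange(
    protocol: ActivityProtocol,
    profile: PatientProfile,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    weir: WeirCoefficients = WeirCoefficients(),
) -> GasExchangeTrace:
    """Simulate one breath-by-breath recording over a protocol.

    The stored ground truth is the exact analytic integral of the
    noise-free Weir rate over each activity segment and over the recovery
    gaps, using the same coefficients the processing pipeline defaults to.
    """
    if protocol.group != profile.group:
        raise ValueError(
            f"protocol group {protocol.group.value} does not match "
            f"profile group {profile.group.value}"
        )
    if rng is None:
        rng = _patient_rng(config.seed, 0)

    pieces = _build_trajectory(protocol, profile, config)

    # ground truth: per-segment and rest-gap Weir integrals
    truth_seg: dict[str, float] = {}
    truth_rest = 0.0
    for p in pieces:
        coeff = weir.c_vo2 + weir.c_vco2 * p.rer
        if weir.apply_scale:
            coeff *= weir.scale
        kcal = coeff * p.integral_vo2()
        if p.activity_id is not None:
            truth_seg[p.activity_id] = truth_seg.get(p.activity_id, 0.0) + kcal
        elif 0.0 <= p.t_start < protocol.end_s:
            truth_rest += kcal  # recovery gaps only, not lead-in/tail

    # breath timestamps: mean interval shrinks with ventilation ~ sqrt(VO2)
    t_first = pieces[0].t_start
    t_last = pieces[-1].t_end
    rest = profile.resting_vo2_lmin
    times = []
    t = t_first + rng.uniform(0, config.breath_interval_mean_s)
    while t < t_last:
        times.append(t)
        v_local = max(_piece_at(pieces, t).vo2_at(t), 0.25 * rest)
        scale = (rest / v_local) ** 0.5
        mean_i = config.breath_interval_mean_s * scale
        sd_i = config.breath_interval_sd_s * scale
        dt = rng.normal(mean_i, sd_i)
        t += max(dt, 0.3 * mean_i)
    times = np.asarray(times)

    clean_vo2 = np.array([_piece_at(pieces, ti).vo2_at(ti) for ti in times])
    rers = np.array([_piece_at(pieces, ti).rer for ti in times])
    clean_vco2 = rers * clean_vo2

    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        mu = -0.5 * sigma**2  # unit-mean log-normal
        vo2 = clean_vo2 * np.exp(rng.normal(mu, sigma, size=times.size))
        vco2 = clean_vco2 * np.exp(rng.normal(mu, sigma, size=times.size))
    else:
        vo2 = clean_vo2.copy()
        vco2 = clean_vco2.copy()

    if config.outlier_rate > 0:
        spikes = rng.random(times.size) < config.outlier_rate
        vo2[spikes] = config.outlier_magnitude * clean_vo2[spikes]
        vco2[spikes] = config.outlier_magnitude * clean_vco2[spikes]

    return GasExchangeTrace(
        patient_id=profile.id,
        times=times,
        vo2=vo2,
        vco2=vco2,
        truth_ee_per_segment=truth_seg,
        truth_ee_rest_kcal=truth_rest,
    )


def simulate_tracker(
    trace: GasExchangeTrace,
    protocol: ActivityProtocol,
    model: DeviceBiasModel,
    rng: "np.random.Generator | int",
    device: str = "device",
) -> TrackerLog:
    """Simulate a tracker's cumulative-kcal readings at activity boundaries.

    The internal counter advances by gain × truth + offset during both
    activities and recovery gaps (noise on activities only), and the
    displayed value is the counter floored to the display resolution, so a
    study total computed from first/last readings includes rest time.
    """
    if trace.truth_ee_per_segment is None:
        raise ValueError("trace carries no ground truth; only simulated traces can drive a tracker")
    missing = [s.activity_id for s in protocol.segments
               if s.activity_id not in trace.truth_ee_per_segment]
    if missing:
        raise ValueError(f"trace does not cover protocol segments: {missing}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    n_act = len(protocol.segments)
    rest_total_s = protocol.end_s - sum(s.duration_s for s in protocol.segments)
    truth_rest = trace.truth_ee_rest_kcal or 0.0

    def quantize(x: float) -> float:
        if model.resolution_kcal <= 0:
            return x
        return np.floor(x / model.resolution_kcal) * model.resolution_kcal

    counter = 0.0
    rows = []
    for i, seg in enumerate(protocol.segments):
        truth = trace.truth_ee_per_segment[seg.activity_id]
        dur_min = seg.duration_s / 60.0
        sd = model.noise_sd_kcal + model.noise_prop * truth
        noise = rng.normal(0.0, sd) if sd > 0 else 0.0
        ee = max(model.gain * truth + model.offset_rate_kcal_min * dur_min + noise, 0.0)
        start = quantize(counter)
        counter += ee
        rows.append((seg.activity_id, start, quantize(counter)))
        if i + 1 < n_act and rest_total_s > 0:
            gap_s = protocol.segments[i + 1].start_s - seg.end_s
            gap_truth = truth_rest * gap_s / rest_total_s
            counter += max(model.gain * gap_truth
                           + model.offset_rate_kcal_min * gap_s / 60.0, 0.0)
    return TrackerLog(patient_id=trace.patient_id, device=device, rows=tuple(rows))


def simulate_study(config: SimulationConfig) -> list[PatientRecord]:
    """Simulate the full study: cohort, per-patient protocols, traces, logs.

    Each patient gets individual heart-rate-recovery gaps drawn uniformly
    from ``rest_gap_range_s``; devices are driven from the patient's trace
    through their named bias models.
    """
    profiles = sample_cohort(config)
    records = []
    for idx, profile in enumerate(profiles):
        # distinct substream from the cohort-sampling one
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, idx, 1]))
        lo, hi = config.rest_gap_range_s
        n_gaps = 13
        gaps = tuple(map(float, rng.uniform(lo, hi, size=n_gaps))) if hi > 0 else (0.0,) * n_gaps
        protocol = build_standard_protocol(profile.group, rest_gaps_s=gaps)
        trace = simulate_gas_exchange(protocol, profile, config, rng=rng)
        logs = tuple(
            simulate_tracker(trace, protocol, model,
                             rng=_device_rng(config.seed, idx, name), device=name)
            for name, model in config.device_models.items()
        )
        records.append(PatientRecord(profile, protocol, trace, logs))
    return records
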