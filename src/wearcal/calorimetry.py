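"""Breath-by-breath gas exchange to per-activity energy expenditure.

The criterion processing chain converts irregular breath-by-breath VO2/VCO2
samples into kcal per protocol activity:

1. Weir conversion: EE rate (kcal/min) = 3.941·VO2 + 1.11·VCO2, gas volumes
   in L/min.
2. Hampel outlier replacement on the breath-wise rate (cough spikes etc.):
   a point deviating more than ``n_sd`` standard deviations from the median
   of its centred window is replaced by that median.
3. Cubic-spline interpolation of the cleaned breath series to a uniform 1 Hz
   grid (no extrapolation outside the observed range).
4. 4th-order Butterworth low-pass at 0.04 Hz, zero-phase by default so no
   group delay smears energy across segment boundaries.
5. Trapezoidal integration of the 1 Hz rate over each activity's segment
   window, and over the whole protocol span (rest gaps included).

Every stage is exposed on its own, and :func:`process_trace` keeps the
intermediate series for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, lfilter, lfilter_zi

from .protocol import ActivityProtocol

__all__ = [
    "WeirCoefficients",
    "HampelConfig",
    "FilterConfig",
    "UniformEnergySeries",
    "SegmentEnergy",
    "ProcessedTrace",
    "weir_rate",
    "hampel_replace",
    "spline_resample_1hz",
    "butterworth_lowpass",
    "segment_energy",
    "process_trace",
]


@dataclass(frozen=True)
class WeirCoefficients:
    """Abbreviated Weir conversion coefficients, kcal per litre of gas.

    ``scale`` is an optional trailing reporting factor; with gas volumes in
    L/min the classical per-minute conversion needs no extra factor, so it
    defaults to off (``apply_scale=False``). It can be enabled to reproduce
    conventions that print a trailing multiplier.
    """

    c_vo2: float = 3.941
    c_vco2: float = 1.11
    scale: float = 1.1440
    apply_scale: bool = False

    def __post_init__(self) -> None:
        if self.c_vo2 <= 0 or self.c_vco2 <= 0 or self.scale <= 0:
            raise ValueError("Weir coefficients must be positive")


@dataclass(frozen=True)
class HampelConfig:
    """Sliding-window outlier detector settings.

    ``half_window`` neighbours per side (default 3, i.e. a 7-point window
    including the centre); a point is flagged when it deviates more than
    ``n_sd`` standard deviations from the window median. The standard
    deviation is estimated robustly from the median absolute deviation
    (1.4826 × MAD, the classical Hampel scale and what signal-processing
    toolboxes call "standard deviations") by default; ``dispersion="sd"``
    switches to the window's sample SD, but note that a sample SD computed
    over a window containing the spike can never flag a lone spike at 3 SD
    (the deviation/SD ratio is bounded by sqrt(window size)).
    """

    half_window: int = 3
    n_sd: float = 3.0
    dispersion: str = "mad"  # or "sd"

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise ValueError("half_window must be >= 1")
        if self.n_sd <= 0:
            raise ValueError("n_sd must be > 0")
        if self.dispersion not in ("mad", "sd"):
            raise ValueError("dispersion must be 'mad' or 'sd'")


@dataclass(frozen=True)
class FilterConfig:
    """Low-pass filter settings: 4th-order Butterworth, 0.04 Hz at fs=1 Hz."""

    order: int = 4
    cutoff_hz: float = 0.04
    fs_hz: float = 1.0
    phase: str = "zero_phase"  # or "causal"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0 < self.cutoff_hz < self.fs_hz / 2:
            raise ValueError("cutoff must lie in (0, fs/2)")
        if self.phase not in ("zero_phase", "causal"):
            raise ValueError("phase must be 'zero_phase' or 'causal'")

    @property
    def min_length(self) -> int:
        # needs room for reflection padding of 3*(order+1) samples
        return 3 * (self.order + 1) + 1


@dataclass(frozen=True)
class UniformEnergySeries:
    """Energy-expenditure rate (kcal/min) sampled at exactly 1 Hz from ``t0``."""

    t0: float
    rate: np.ndarray

    def __post_init__(self) -> None:
        rate = np.asarray(self.rate, dtype=float)
        if rate.ndim != 1:
            raise ValueError("rate must be one-dimensional")
        if not np.all(np.isfinite(rate)):
            raise ValueError("rate contains non-finite values")
        object.__setattr__(self, "rate", rate)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.rate.size, dtype=float)

    @property
    def t_end(self) -> float:
        return self.t0 + max(self.rate.size - 1, 0)


@dataclass(frozen=True)
class SegmentEnergy:
    activity_id: str
    ee_kcal: float
    ee_rate_kcal_min: float


@dataclass(frozen=True)
class ProcessedTrace:
    """Per-activity energies plus every intermediate series of the chain."""

    segments: tuple[SegmentEnergy, ...]
    total_kcal: float
    breath_times: np.ndarray = field(repr=False)
    breath_rate_raw: np.ndarray = field(repr=False)
    breath_rate_clean: np.ndarray = field(repr=False)
    outlier_indices: np.ndarray = field(repr=False)
    series_unfiltered: UniformEnergySeries = field(repr=False)
    series: UniformEnergySeries = field(repr=False)

    def segment(self, activity_id: str) -> SegmentEnergy:
        for seg in self.segments:
            if seg.activity_id == activity_id:
                return seg
        raise KeyError(f"no segment energy for activity {activity_id!r}")


def weir_rate(vo2_lmin, vco2_lmin, coeffs: WeirCoefficients = WeirCoefficients()):
    """Energy expenditure rate (kcal/min) from VO2 and VCO2 in L/min.

    Linear in both gases; vectorised over array inputs. Negative or
    non-finite gas values are rejected.
    """
    vo2 = np.asarray(vo2_lmin, dtype=float)
    vco2 = np.asarray(vco2_lmin, dtype=float)
    if not (np.all(np.isfinite(vo2)) and np.all(np.isfinite(vco2))):
        raise ValueError("gas values must be finite")
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas values must be non-negative")
    rate = coeffs.c_vo2 * vo2 + coeffs.c_vco2 * vco2
    if coeffs.apply_scale:
        rate = rate * coeffs.scale
    return rate if rate.ndim else float(rate)


def hampel_replace(
    values: Sequence[float], config: HampelConfig = HampelConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Replace outliers by the local window median.

    For each point the window is the point plus ``half_window`` neighbours
    per side (shrunk near the edges). A point whose absolute deviation from
    the window median exceeds ``n_sd`` times the window's estimated
    standard deviation (robust 1.4826 × MAD by default, see
    :class:`HampelConfig`) is replaced by the median. Detection runs on the
    original series in a single pass, so earlier replacements do not
    influence later windows.

    Returns the cleaned array and the flagged indices. Sequences shorter
    than a full interior window pass through unflagged.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return x.copy(), np.array([], dtype=int)
    hw = config.half_window
    if x.size < 2 * hw + 1:
        return x.copy(), np.array([], dtype=int)
    out = x.copy()
    flagged = []
    for i in range(x.size):
        lo = max(0, i - hw)
        hi = min(x.size, i + hw + 1)
        window = x[lo:hi]
        med = np.median(window)
        if config.dispersion == "mad":
            sd = 1.4826 * np.median(np.abs(window - med))
        else:
            sd = np.std(window, ddof=1)
        if abs(x[i] - med) > config.n_sd * sd:
            out[i] = med
            flagged.append(i)
    return out, np.asarray(flagged, dtype=int)


def spline_resample_1hz(times: Sequence[float], values: Sequence[float]) -> UniformEnergySeries:
    """Cubic-spline interpolation of an irregular series onto integer seconds.

    The interpolant passes through every input point and is evaluated at
    integer seconds within [ceil(t_first), floor(t_last)]; no extrapolation.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ValueError("times and values must have equal length")
    if t.size < 4:
        raise ValueError("at least 4 points are required for cubic-spline resampling")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing (no duplicates)")
    t0 = float(np.ceil(t[0]))
    t1 = float(np.floor(t[-1]))
    if t1 < t0:
        raise ValueError("observed range contains no integer second")
    grid = np.arange(t0, t1 + 0.5)
    rate = CubicSpline(t, v)(grid)
    return UniformEnergySeries(t0=t0, rate=rate)


def butterworth_lowpass(
    series: UniformEnergySeries, config: FilterConfig = FilterConfig()
) -> UniformEnergySeries:
    """Low-pass the 1 Hz rate series.

    Zero-phase mode runs the filter forward and backward (squared magnitude
    response, no lag); causal mode is a single forward pass initialised at
    the first sample's steady state. DC gain is unity in both modes.
    """
    x = series.rate
    if x.size < config.min_length:
        raise ValueError(
            f"series too short for filtering: {x.size} samples, "
            f"need at least {config.min_length}"
        )
    b, a = butter(config.order, config.cutoff_hz, btype="low", fs=config.fs_hz)
    if config.phase == "zero_phase":
        y = filtfilt(b, a, x, padtype="even", padlen=3 * (config.order + 1))
    else:
        zi = lfilter_zi(b, a) * x[0]
        y, _ = lfilter(b, a, x, zi=zi)
    return UniformEnergySeries(t0=series.t0, rate=y)


def _trapz_between(series: UniformEnergySeries, a: float, b: float) -> float:
    """Exact trapezoidal integral of the piecewise-linear interpolant on [a, b].

    Units: rate is kcal/min, time in seconds, so the result divides by 60.
    """
    if a > b:
        raise ValueError("window start exceeds window end")
    t0, rate = series.t0, series.rate
    if a < t0 - 1e-9 or b > series.t_end + 1e-9:
        raise ValueError(
            f"window [{a}, {b}] extends beyond series support [{t0}, {series.t_end}]"
        )
    grid = series.times
    # knots: window ends plus every interior integer second
    lo = int(np.ceil(a - t0))
    hi = int(np.floor(b - t0))
    knots = np.concatenate(([a], grid[lo : hi + 1], [b]))
    knots = np.unique(np.clip(knots, a, b))
    vals = np.interp(knots, grid, rate)
    return float(np.trapezoid(vals, knots) / 60.0)


def segment_energy(
    series: UniformEnergySeries, protocol: ActivityProtocol
) -> tuple[list[SegmentEnergy], float]:
    """Integrate the rate series over each activity segment and the full span.

    Per-activity kcal is the trapezoidal integral over [start_s, end_s];
    the total integrates from the first activity's start to the last
    activity's end, so rest gaps contribute to the total but to no activity.
    """
    if not protocol.segments:
        return [], 0.0
    out = []
    for seg in protocol.segments:
        try:
            kcal = _trapz_between(series, seg.start_s, seg.end_s)
        except ValueError as exc:
            raise ValueError(f"segment {seg.activity_id!r}: {exc}") from None
        dur_min = seg.duration_s / 60.0
        out.append(SegmentEnergy(seg.activity_id, kcal, kcal / dur_min))
    total = _trapz_between(series, protocol.segments[0].start_s, protocol.end_s)
    return out, total


def process_trace(
    trace,
    protocol: ActivityProtocol,
    weir: WeirCoefficients = WeirCoefficients(),
    hampel: Optional[HampelConfig] = HampelConfig(),
    filt: Optional[FilterConfig] = FilterConfig(),
) -> ProcessedTrace:
    """Run the full criterion chain on a gas-exchange trace.

    ``trace`` is anything exposing ``times``, ``vo2`` and ``vco2`` arrays
    (see :class:`wearcal.synthetic.GasExchangeTrace`). Passing ``None`` for
    ``hampel`` or ``filt`` skips that stage, which is useful for ablation
    experiments on stage ordering.
    """
    try:
        raw = weir_rate(trace.vo2, trace.vco2, weir)
    except ValueError as exc:
        raise ValueError(f"weir stage: {exc}") from None

    if hampel is not None:
        clean, flagged = hampel_replace(raw, hampel)
    else:
        clean, flagged = np.asarray(raw, dtype=float).copy(), np.array([], dtype=int)

    try:
        series_raw = spline_resample_1hz(trace.times, clean)
    except ValueError as exc:
        raise ValueError(f"spline stage: {exc}") from None

    if filt is not None:
        try:
            series = butterworth_lowpass(series_raw, filt)
        except ValueError as exc:
            raise ValueError(f"filter stage: {exc}") from None
    else:
        series = series_raw

    try:
        segs, total = segment_energy(series, protocol)
    except ValueError as exc:
        raise ValueError(f"integration stage: {exc}") from None

    return ProcessedTrace(
        segments=tuple(segs),
        total_kcal=total,
        breath_times=np.asarray(trace.times, dtype=float),
        breath_rate_raw=np.asarray(raw, dtype=float),
        breath_rate_clean=clean,
        outlier_indices=flagged,
        series_unfiltered=series_raw,
        series=series,
    )
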