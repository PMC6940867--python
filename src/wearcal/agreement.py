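"""Device-vs-criterion agreement and responsiveness statistics.

Accuracy of a tracker against the calorimetry criterion is summarised per
activity and over the total protocol by:

* the mean device-minus-criterion difference with a one-sample two-sided
  t-test against zero, plus a descriptive 10%-error-zone flag;
* Bland-Altman bias and 95% limits of agreement (bias ± 1.96 SD of the
  differences), with per-patient plot coordinates exported;
* the two-way absolute-agreement single-measures intraclass correlation
  ICC(A,1), banded as poor (<0.4), fair (0.4–0.59), good (0.6–0.74) or
  excellent (≥0.75);
* the root-mean-square error of the differences.

Responsiveness — a device's ability to detect within-patient changes in
exercise intensity — is a paired t-test on per-activity energies between two
conditions (cycling loads or walking speeds/incline).

Normality is described, not enforced: sample skewness and small-sample
adjusted excess kurtosis are reported per difference set as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .protocol import PatientGroup

__all__ = [
    "AgreementConfig",
    "PairedEE",
    "MeanDifferenceResult",
    "BlandAltmanResult",
    "AgreementSummary",
    "ResponsivenessResult",
    "make_paired",
    "mean_difference_test",
    "bland_altman",
    "icc_a1",
    "icc_category",
    "rmse",
    "paired_responsiveness",
    "skewness_kurtosis",
    "summarize_agreement",
]


@dataclass(frozen=True)
class AgreementConfig:
    """Analysis constants: LoA multiplier, test level, error zone, ICC bands.

    ``icc_bands`` maps a band label to its left-closed lower edge; the
    listed defaults follow the conventional reliability categories
    (<0.4 poor, 0.4–0.59 fair, 0.6–0.74 good, ≥0.75 excellent).
    """

    loa_multiplier: float = 1.96
    alpha: float = 0.05
    error_zone: float = 0.10
    icc_bands: tuple[tuple[str, float], ...] = (
        ("poor", float("-inf")),
        ("fair", 0.4),
        ("good", 0.6),
        ("excellent", 0.75),
    )

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.loa_multiplier <= 0:
            raise ValueError("loa_multiplier must be > 0")
        if self.error_zone < 0:
            raise ValueError("error_zone must be >= 0")


@dataclass(frozen=True)
class PairedEE:
    """Pairwise-complete criterion/device energies for one scope.

    ``scope`` is an activity id or ``"total"``; patients missing either
    measurement are dropped before construction (see :func:`make_paired`).
    """

    patient_ids: tuple[str, ...]
    criterion: np.ndarray
    device: np.ndarray
    scope: str = "total"
    group: Optional[PatientGroup] = None
    device_name: str = "device"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        crit = np.asarray(self.criterion, dtype=float)
        dev = np.asarray(self.device, dtype=float)
        if not (len(self.patient_ids) == crit.size == dev.size):
            raise ValueError("patient_ids, criterion and device must have equal length")
        if crit.size < 2:
            raise ValueError("at least 2 paired observations are required")
        object.__setattr__(self, "criterion", crit)
        object.__setattr__(self, "device", dev)
        object.__setattr__(self, "patient_ids", tuple(self.patient_ids))

    @property
    def n(self) -> int:
        return self.criterion.size

    @property
    def differences(self) -> np.ndarray:
        return self.device - self.criterion

    def swapped(self) -> "PairedEE":
        return PairedEE(
            patient_ids=self.patient_ids,
            criterion=self.device,
            device=self.criterion,
            scope=self.scope,
            group=self.group,
            device_name=self.device_name,
            n_excluded=self.n_excluded,
        )


def make_paired(
    criterion: Mapping[str, float],
    device: Mapping[str, float],
    scope: str = "total",
    group: Optional[PatientGroup] = None,
    device_name: str = "device",
) -> PairedEE:
    """Build a pairwise-complete :class:`PairedEE` from per-patient mappings.

    Patients present in only one mapping (e.g. a failed recording) are
    dropped and counted in ``n_excluded``, mirroring pairwise-complete
    analysis with logged exclusions.
    """
    common = sorted(set(criterion) & set(device))
    excluded = len(set(criterion) | set(device)) - len(common)
    return PairedEE(
        patient_ids=tuple(common),
        criterion=np.array([criterion[p] for p in common]),
        device=np.array([device[p] for p in common]),
        scope=scope,
        group=group,
        device_name=device_name,
        n_excluded=excluded,
    )


@dataclass(frozen=True)
class MeanDifferenceResult:
    mean_diff: float
    sd_diff: float
    t_stat: float
    df: int
    p_value: float
    within_error_zone: bool
    degenerate: bool = False


def mean_difference_test(
    pairs: PairedEE, config: AgreementConfig = AgreementConfig()
) -> MeanDifferenceResult:
    """One-sample two-sided t-test of device-minus-criterion against zero.

    ``within_error_zone`` flags |mean difference| ≤ error_zone × mean
    criterion — a descriptive limit, deliberately decoupled from the test.
    Zero-variance differences yield a degenerate result (t and p are NaN)
    with an exact-equality report through ``mean_diff``.
    """
    d = pairs.differences
    n = d.size
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    within = abs(mean_d) <= config.error_zone * abs(float(np.mean(pairs.criterion)))
    if sd_d == 0.0:
        return MeanDifferenceResult(mean_d, 0.0, float("nan"), n - 1, float("nan"),
                                    within, degenerate=True)
    t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return MeanDifferenceResult(mean_d, sd_d, float(t), n - 1, float(p), within)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    # per-patient (mean of methods, device - criterion) plot coordinates
    plot_points: tuple[tuple[float, float], ...] = field(repr=False)


def bland_altman(
    pairs: PairedEE, config: AgreementConfig = AgreementConfig()
) -> BlandAltmanResult:
    """Bland-Altman bias and limits of agreement (bias ± multiplier × SD)."""
    d = pairs.differences
    bias = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    half = config.loa_multiplier * sd_d
    means = (pairs.criterion + pairs.device) / 2.0
    points = tuple(zip(means.tolist(), d.tolist()))
    return BlandAltmanResult(bias, bias - half, bias + half, points)


def icc_a1(pairs: PairedEE) -> float:
    """Two-way absolute-agreement single-measures ICC, ICC(A,1).

    From the two-way ANOVA decomposition with n subjects and k=2 raters
    (criterion, device):

        ICC = (MS_rows − MS_err) / (MS_rows + (k−1)·MS_err
                                    + (k/n)·(MS_cols − MS_err))

    Absolute agreement penalises systematic offsets between the raters.
    """
    x = np.column_stack([pairs.criterion, pairs.device])
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total == 0.0:
        raise ValueError("ICC undefined: zero total variance")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    if denom == 0.0:
        raise ValueError("ICC undefined: zero denominator")
    return float((ms_rows - ms_err) / denom)


def icc_category(icc: float, config: AgreementConfig = AgreementConfig()) -> str:
    """Band an ICC value; bands are left-closed (0.4→fair, 0.6→good, 0.75→excellent)."""
    if icc > 1.0:
        raise ValueError("ICC cannot exceed 1")
    label = config.icc_bands[0][0]
    for name, lower in config.icc_bands:
        if icc >= lower:
            label = name
    return label


def rmse(pairs: PairedEE) -> float:
    """Root-mean-square of the device-minus-criterion differences."""
    d = pairs.differences
    return float(np.sqrt(np.mean(d**2)))


@dataclass(frozen=True)
class AgreementSummary:
    """Every accuracy statistic for one device × scope × group cell."""

    scope: str
    group: Optional[str]
    device_name: str
    n: int
    n_excluded: int
    mean_criterion: float
    mean_device: float
    mean_diff: float
    sd_diff: float
    t_stat: float
    df: int
    p_value: float
    bias: float
    loa_lower: float
    loa_upper: float
    icc: float
    icc_category: str
    rmse: float
    within_error_zone: bool
    skewness: float
    excess_kurtosis: float
    degenerate: bool


def summarize_agreement(
    pairs: PairedEE, config: AgreementConfig = AgreementConfig()
) -> AgreementSummary:
    """Compute the full accuracy panel for one paired set."""
    md = mean_difference_test(pairs, config)
    ba = bland_altman(pairs, config)
    try:
        icc = icc_a1(pairs)
        cat = icc_category(icc, config)
    except ValueError:
        icc, cat = float("nan"), "undefined"
    if pairs.n >= 3:
        skew, kurt = skewness_kurtosis(pairs.differences)
    else:
        skew, kurt = float("nan"), float("nan")
    return AgreementSummary(
        scope=pairs.scope,
        group=pairs.group.value if pairs.group else None,
        device_name=pairs.device_name,
        n=pairs.n,
        n_excluded=pairs.n_excluded,
        mean_criterion=float(np.mean(pairs.criterion)),
        mean_device=float(np.mean(pairs.device)),
        mean_diff=md.mean_diff,
        sd_diff=md.sd_diff,
        t_stat=md.t_stat,
        df=md.df,
        p_value=md.p_value,
        bias=ba.bias,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
        icc=icc,
        icc_category=cat,
        rmse=rmse(pairs),
        within_error_zone=md.within_error_zone,
        skewness=skew,
        excess_kurtosis=kurt,
        degenerate=md.degenerate,
    )


@dataclass(frozen=True)
class ResponsivenessResult:
    condition_a: str
    condition_b: str
    source: str
    n: int
    mean_diff: float
    t_stat: float
    df: int
    p_value: float
    detected: bool
    degenerate: bool = False


def paired_responsiveness(
    ee_a: Mapping[str, float],
    ee_b: Mapping[str, float],
    condition_a: str,
    condition_b: str,
    source: str = "criterion",
    config: AgreementConfig = AgreementConfig(),
) -> ResponsivenessResult:
    """Paired t-test of per-patient energies between two activity conditions.

    ``ee_a``/``ee_b`` map patient id to kcal under each condition; the same
    patients must appear in both (mismatches are rejected, not silently
    intersected — responsiveness is a within-patient contrast). A constant
    non-zero shift with zero variance is a degenerate-certain detection.
    """
    if set(ee_a) != set(ee_b):
        raise ValueError("conditions must cover the same patients")
    ids = sorted(ee_a)
    if len(ids) < 2:
        raise ValueError("at least 2 patients are required")
    a = np.array([ee_a[p] for p in ids])
    b = np.array([ee_b[p] for p in ids])
    d = b - a
    n = d.size
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    if sd_d == 0.0:
        certain = mean_d != 0.0
        return ResponsivenessResult(condition_a, condition_b, source, n, mean_d,
                                    float("nan"), n - 1,
                                    0.0 if certain else 1.0, certain, degenerate=True)
    t = mean_d / (sd_d / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return ResponsivenessResult(condition_a, condition_b, source, n, mean_d,
                                float(t), n - 1, p, p < config.alpha)


def skewness_kurtosis(values: Sequence[float]) -> tuple[float, float]:
    """Sample skewness and excess kurtosis with small-sample adjustment.

    Used as a normality diagnostic for difference sets; nothing is rejected
    automatically. Kurtosis needs n ≥ 4 and is NaN below that.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("skewness requires at least 3 values")
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=False)) if x.size >= 4 else float("nan")
    return skew, kurt
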