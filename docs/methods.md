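# Methods

## Criterion processing chain

Breath-by-breath indirect calorimetry yields VO₂ and VCO₂ in L/min at
irregular breath times. The criterion EE per activity is computed as:

1. **Weir conversion.** Abbreviated Weir equation,
   `EE (kcal/min) = 3.941·VO₂ + 1.11·VCO₂`. With gas volumes in L/min this
   is already a per-minute rate; an optional trailing reporting factor
   (`WeirCoefficients.scale`, default off) is provided for conventions that
   print one, but is never applied during integration — enabling it would
   inflate one-hour protocol totals out of the physiologically plausible
   few-hundred-kcal range.
2. **Hampel outlier replacement** on the breath-wise rate, before any
   interpolation, so cough spikes cannot be smeared by the spline. Window =
   the point plus 3 neighbours per side (shrunk at the edges); a point is
   replaced by the window median when its deviation from that median
   exceeds 3 estimated standard deviations. The SD is estimated robustly as
   1.4826×MAD (the classical Hampel scale). The alternative of using the
   window's *sample* SD is exposed (`dispersion="sd"`) but cannot work as a
   default: a lone spike inflates the sample SD of its own 7-point window
   so much that its deviation/SD ratio is bounded by √7 ≈ 2.65 and never
   crosses a 3-SD threshold. The MAD convention conversely flags ~5% of
   pure Gaussian noise (the small-window MAD is a noisy scale estimate);
   those false positives are harmless because replacement by the window
   median is energy-neutral to < 0.1%. Detection is single-pass on the
   original series.
3. **Cubic-spline resampling** to integer seconds within the observed
   range, no extrapolation. Not-a-knot boundary conditions; the interpolant
   passes through every breath and reproduces cubic polynomials exactly.
4. **Butterworth low-pass**, order 4, cutoff 0.04 Hz at fs = 1 Hz. Default
   is zero-phase (forward–backward, reflection padding of 3·(order+1)
   samples) so no group delay shifts energy across segment boundaries; a
   causal single-pass mode (initialised at the first sample's steady state)
   is provided since real-time implementations would use one. DC gain is
   exactly 1 in both modes; the causal mode shows the analytic −3 dB
   (0.7071) response at the cutoff.
5. **Segment integration.** Trapezoidal integral of the 1 Hz rate
   (kcal/min) over each activity window divided by 60; windows are
   half-open on the protocol clock so each 1 Hz sample belongs to one
   activity, while integration uses both window endpoints so contiguous
   segments add exactly. The total-protocol energy integrates from the
   first activity's start to the last activity's end, so recovery gaps
   count toward the total but toward no activity — matching how cumulative
   tracker counters are read at the protocol's ends.

Every stage before quantisation is linear or order-preserving, so scaling
both gas channels by k scales every segment energy by k; the tests assert
this to 1e-9.

## Activity protocol

The standard protocol has 14 activities totalling 39 active minutes:
sitting 5, standing 2, typing 3; table cleaning, dishwasher, vacuuming
3 each; stair ascent and descent 1 each; cycling 3 min at each of three
loads; walking 3 min at each of three treadmill settings. Loads/speeds are
group-specific (CAD 0/40/70 W and 4/5.5/4-at-5% km/h; HFrEF 0/25/50 W and
3/4.5/3-at-5% km/h); durations are not. Inter-activity recovery gaps were
heart-rate driven in the laboratory and are therefore modelled as explicit
per-boundary durations, default 0; the simulator draws them uniformly from
30–90 s, a realistic recovery range for low-to-moderate intensities.

## Synthetic cohort generator

The generator's contract is *plausible magnitude with exactly known ground
truth*, not physiological fidelity; acceptance rests on recovering injected
parameters, not on reproducing patient physiology.

- **Anthropometrics** per group from truncated normals matched to published
  cardiac-cohort characteristics (CAD: age 61.4 ± 6.9 y, height 176 ±
  6.8 cm, weight 84.3 ± 12.1 kg, 14/19 male; HFrEF: 65.1 ± 6.6 y, 177 ±
  5.4 cm, 86.7 ± 13.7 kg, 17/19 male). Resting VO₂ is 3.5 ml·kg⁻¹·min⁻¹.
- **Steady-state targets** from standard metabolic equations: cycling
  VO₂ [ml/min] = 10.8·W + 7·weight; walking VO₂ [ml/kg/min] = 0.1·v +
  1.8·v·grade + 3.5 (v in m/min); fixed MET values for sedentary (1.3–1.5),
  household (2.5–3.3) and stair (3.0–4.0) activities.
- **Kinetics**: first-order exponential transitions toward the current
  target with patient-specific time constant τ (CAD 30 ± 5 s, HFrEF 45 ±
  8 s — heart-failure on-kinetics are slower), decaying toward resting VO₂
  during gaps. VCO₂ = RER·VO₂ with RER stepwise by MET band (0.82 below
  2 METs, 0.88 to 4 METs, 0.95 above); dynamic RER drift is irrelevant to
  the statistics under test.
- **Breaths** arrive with mean interval 3 s at rest, shrinking as
  (rest/VO₂)^½ with intensity; values carry unit-mean log-normal noise
  (CV 8%) and, at rate 0.5% per breath, cough-like spikes of 5× local
  level.
- **Ground truth** per segment and per gap is the exact analytic integral
  of the noise-free Weir rate (exponential pieces integrate in closed
  form), using the same Weir coefficients as the pipeline — pipeline error
  therefore isolates processing effects.
- **Trackers** are modelled only at their EE output (vendor algorithms are
  proprietary; this bias model is a labelled stand-in): per-activity device
  EE = gain·truth + offset·duration + Gaussian noise (optional
  proportional term), accumulated into a cumulative counter that also
  advances through recovery gaps and is floored to the display resolution
  (default 1 kcal). Negative increments are clamped at zero so cumulative
  readings never decrease.
- **Randomness**: one root seed; per-patient and per-device substreams are
  derived from (seed, patient index, CRC32(device name)), so cohorts
  reproduce byte-identically and devices can be re-simulated on fixed
  traces (used by the noise-ladder tests).

What a green test does **not** establish: fidelity of real device error
structure (heteroscedasticity, HR-dependence), real breath-noise spectra,
or HR-driven gap lengths. The generator has no heart-rate channel at all.

## Agreement statistics

All tests are two-sided at α = .05. The 10% error zone is a descriptive
flag (|mean difference| ≤ 10% of the criterion mean), deliberately decoupled
from the t-test so both facts are always reported. Bland-Altman abscissa is
the per-patient mean of the two methods. ICC(A,1) comes from the two-way
ANOVA decomposition
`(MS_rows − MS_e) / (MS_rows + (k−1)MS_e + (k/n)(MS_cols − MS_e))`, k = 2;
reliability bands are left-closed ([0.4, 0.6) fair, [0.6, 0.75) good,
≥ 0.75 excellent), which also closes the conventional gap between 0.59 and
0.6. RMSE satisfies `rmse² = bias² + ((n−1)/n)·sd²` identically.
Responsiveness contrasts are per-activity kcal (all contrasted activities
last 3 min, so per-minute rates differ only by a factor 3); zero-variance
difference sets are reported as degenerate (exact equality, or certain
detection for a constant non-zero shift) rather than given a fabricated t
statistic. Patients missing either member of a pair are dropped per scope
and counted. No multiple-testing correction is applied — the analysis
reports one test per printed cell, as validation studies conventionally do;
this is documented rather than silently "fixed".

## ICC study sizing

The exact method treats the one-way ANOVA statistic F = MSB/MSW, whose
distribution under true ICC ρ is λ(ρ)·F(n−1, n(k−1)) with
λ(ρ) = (1+(k−1)ρ)/(1−ρ). Power at ρ₁ for the level-α test of H₀: ρ = ρ₀ is
the upper tail of the central F beyond (λ₀/λ₁)·F_crit, and the sample size
is the smallest n reaching the target power. One-sided α is the default —
the hypothesis is directional. For the reference design (0.35 vs 0.75,
k = 2, α = .05, power .80) the search gives n = 19 (power 0.7995 at 18,
0.8192 at 19); Walter's closed form gives ⌈17.75⌉ = 18, one low, which is
why the discrepancy table always reports both. The closed form depends on
(ρ₀, ρ₁) only through (ln λ₀/λ₁)², hence is symmetric under swapping null
and alternative.

## Numerical conventions and degenerate inputs

- Integration knots are the window ends plus interior integer seconds;
  fractional window boundaries are handled by linear interpolation of the
  1 Hz series.
- Series must cover every segment; violations are rejected naming the
  segment, and `process_trace` annotates every error with its stage.
- Hampel on sequences shorter than one full window passes through
  unflagged; empty input returns empty.
- Spline resampling requires ≥ 4 strictly increasing timestamps; filtering
  requires > 3·(order+1) samples.
- The cohort-summary percentage is ⌊100·count/n + 0.5⌋ (round half up),
  matching how published tables round counts.

## Known limitations

- Per-segment accuracy of the pipeline on clean data is limited by edge
  smearing of the 0.04 Hz filter where adjacent activities differ strongly
  in intensity; with realistic on-kinetics (τ ≥ 30 s) this stays well
  inside the 2% conservation bound the tests enforce, but a τ → 0 world
  with no gaps would not.
- The ICC sizing assumes the one-way framework; the agreement ICC reported
  by the pipeline is two-way absolute-agreement, so achieved power in a
  real study with rater variance will differ from the design value.
- File-based studies reconstruct the protocol timeline from the standard
  zero-gap protocol unless a per-patient protocol file is supplied, because
  tracker logs do not record gap lengths.
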