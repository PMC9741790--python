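# Methods

## The measurement model

One recording is three synchronized channels at a fixed rate (default
100 Hz): COPap and COPml, the anterio-posterior and medio-lateral
center-of-pressure displacement in cm, and vGRF, the resultant vertical
ground reaction force in N. The analysis asks how regular these signals are
across strides, quantified by Sample Entropy, and how that regularity
depends on (a) the preprocessing regime and (b) the entropy template
length m, before using the settled choice (m = 6, r = 0.2·SD) to compare
preferred-speed and maximum-speed walking.

## Sample Entropy

SampEn(m, r, N) = −ln(A/B), with B the number of unordered template pairs
(i, j), i ≠ j, i, j ∈ {0 … N−m−1}, whose m-length subsequences match within
Chebyshev tolerance r (match condition ≤ r), and A the number of those pairs
still matching over m+1 samples. Keeping both counts on the same index range
guarantees A ≤ B and a non-negative value. Conventions fixed here:

- **Tolerance.** r = r_factor × population SD (denominator N) of the full
  analyzed series, r_factor defaulting to 0.2. At N ≈ 2200 the population
  vs. sample SD distinction is negligible, but a single convention keeps
  the scale-covariance property exact. An alternative reading — the mean of
  per-cycle SDs — is available via `compute_r(..., cycle_length=...)` but is
  not the default.
- **Undefined cells.** If B = 0 (no m-matches) or A = 0 (no extensions) the
  entropy is reported as undefined with a reason code, never replaced by a
  ceiling value; grid evaluation degrades cell-wise, and the pipeline drops
  the affected subject from the affected ANOVA to preserve balance.
- **Implementation.** The matcher builds the N×N Boolean Chebyshev
  neighborhood once per (series, r) and extends matches incrementally
  (M_{k+1} = M_k[:-1,:-1] & D[k:,k:]), collecting A, B for all requested m
  in one pass — O(N²) memory, O(N²·m_max) work. An explicit pair-loop brute
  force (`sample_entropy_brute`) is the reference implementation; the test
  suite requires exact count agreement between the two on hundreds of
  random series.

## Preprocessing regimes

- **WHOLE** — the raw channel after edge-cycle trimming, truncated to the
  first n_points samples (default 2200); no amplitude or time-base change.
- **SEGM** — each stride window [b_i, b_{i+1}) (half-open, 0-based)
  piecewise-linearly resampled onto a uniform grid of samples_per_cycle
  points (default 100) including both endpoints, then concatenated. Linear
  interpolation is shape-preserving and exactly testable (a linear ramp
  resamples to a linear ramp).
- **NORM** — SEGM plus per-cycle min–max rescale to [0, 1]; the unit
  interval is read as "the cycle's share of stride length/width". Implemented
  as the cycle's own signal range rather than an externally measured stride
  length, which is the only choice available without kinematic data; cycles
  with zero range raise a degenerate-cycle error. vGRF is never normalized.
- **ZERO** — SEGM plus per-cycle translation so every (COPap, COPml) cycle
  starts at (0, 0). This removes slow positional drift exactly (for
  equal-duration cycles a linear trend translates every cycle onto the same
  segment) while preserving all within-cycle point-to-point distances —
  unlike NORM, which also rescales away amplitude information.

## Stride segmentation

The resultant vGRF of walking has two local minima per stride — one per
foot's single-support midstance. Detection: moving-average smoothing over a
1/20 s window, then two-pass valley picking (prominence ≥ 5% of range to
estimate spacing; second pass with a refractory distance of 0.4 × the median
spacing), then every second valley. Which parity is the reference leg is
decided by the valley heights: the more-loaded leg carries a shallower
single-support valley. With a perfectly symmetric gait the first detected
valley defines the phase — any same-leg landmark yields valid strides, only
the phase anchor shifts. Segmentation reads the vGRF only, so it is
invariant to COP offsets by construction.

## The synthetic generator

Each stride's duration is drawn from a normal distribution truncated at
±3 SD (mean 1.06 s, CV configurable; truncation avoids degenerate strides).
Within a stride, phase runs linearly 0→1 and the channels follow fixed
templates: COPap an asymmetric two-lobe fore-aft curve, COPml one sinusoidal
lateral oscillation per stride, vGRF the sum of two M-shaped per-foot stance
profiles (duty factor 0.65, third-harmonic depth 0.45, contralateral foot
offset by half a stride and under-loaded by `stance_asymmetry`, default 5%),
scaled so the mean equals body weight. The duty/depth pair was chosen so the
two-foot resultant has exactly two minima per stride with no spurious dips
at the double-support handover. The stride-phase origin is placed at the
reference leg's midstance valley, so the generator's ground-truth boundaries
coincide with the landmark a vGRF-based segmenter detects.

On top of the templates: per-stride shape jitter (three random low-order
harmonics per channel per stride, scaled by `within_cycle_shape_jitter`
times the channel's own oscillation scale), additive white Gaussian noise
per channel, and a linear drift on the COP channels (`drift_rate`, cm/s).
Jitter and noise accept a scalar or per-channel mapping — the walking-speed
comparison needs direction-specific jitter, and a single absolute noise SD
is not meaningful across cm and N scales.

What the generator does *not* emulate: colored noise (the synthetic noise is
white by decision, not evidence), inter-subject template differences beyond
the seeded jitter, kinematic coupling between channels, and any
musculoskeletal mechanism. Passing tests therefore demonstrate that the
*machinery* — segmentation, normalization, entropy, statistics — behaves
correctly and is sensitive in the designed directions; they do not validate
biological claims about real gait.

### Walking-condition defaults

Vpref: 30 s at 1.06 s stride time, CV 0.02, jitter
{COPap 0.12, COPml 0.08, vGRF 0.12}, noise {0.2 cm, 0.1 cm, 4 N}. Vmax:
30 s at 0.85 s stride time, CV 0.03, jitter {COPap 0.04, COPml 0.20,
vGRF 0.04}, same noise. The direction of the change encodes the targeted
speed effect — faster walking tightens the fore-aft and vertical pattern
while loosening the lateral one; the magnitudes (jitter reduced to a third,
lateral jitter × 2.5) were fixed once as a clearly detectable but not
extreme manipulation. Condition pairs share a subject seed (Vpref uses it,
Vmax uses it + 1).

## Statistics

Both ANOVAs are computed from explicit sums of squares, not delegated,
because the df structure and the decomposition identity are contracts of
this package; statsmodels and pingouin serve as independent cross-checks in
the tests.

- **Type × m per condition**: balanced fixed-effects two-way ANOVA with
  interaction. 4 Types × 5 m-levels × 23 subjects gives dfs (3, 440),
  (4, 440), (12, 440); the 2-Type vGRF analysis gives (1, 220)/(4, 220).
- **Velocity × Type at m = 6**: balanced split-plot ANOVA with velocity
  within-units and processing method between-units, units being
  subject × method pairs. This treats the method as a between-subjects
  factor even though every method derives from the same subjects — a
  deliberate reproduction of the design that yields the (3, 88)/(1, 88)
  pattern; the caveat is that method-level inference leans on an
  independence assumption the data generation does not satisfy.
- Summary tables report mean ± 0.95 t-based confidence intervals over
  subjects. Tukey post-hocs, outlier tests and sphericity corrections are
  outside this package's scope; p-values come from the F distribution with
  no correction.

Balance is enforced, not approximated: unbalanced or incomplete tables
raise, and subjects with undefined entropy cells are removed from the
affected analysis (logged as a diagnostic).

## Spectral checks and template span

`power_spectrum` is a mean-removed periodogram (rectangular window by
default so the integrated density equals the series variance exactly), with
the "highest relevant frequency" defined as the smallest frequency whose
cumulative power reaches 99% of the total — a conservative, configurable
criterion. `min_neuromotor_interval(f) = 1/f` and
`template_time_span(m, T, n) = m·T/n` round half-up to 3 decimals (banker's
rounding would turn 1/16 = 0.0625 into 0.062 instead of the conventional
0.063).

## Problem sizes

The default experiment (23 subjects × 2 conditions × 5 m-levels, N ≈ 2200)
runs in minutes. The test suite exercises the same code paths at reduced
sizes chosen by design: ANOVA-structure checks run 23 subjects with 8-stride
recordings (the df pattern depends only on the design), and the
speed-discrimination check runs 20 replicates of 4-subject cohorts at
m = 6 with full 30 s recordings, asserting the directional ordering in at
least 90% of replicates.

## Known limitations

- The generator's waveforms are qualitative: realistic enough to carry
  stride structure, drift and jitter, not calibrated to any subject
  population; absolute SampEn values from synthetic data should not be
  compared against published human values.
- Valley-based segmentation assumes a double-bump resultant vGRF; it will
  mis-segment running (flight phases) or pathological single-bump profiles.
- WHOLE truncation takes the first n_points after trimming; no alternative
  anchoring is offered.
- File-mode input expects `time,copap,copml,vgrf` CSV at a constant rate;
  no resampling of irregular time stamps is performed.
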