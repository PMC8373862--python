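# Methods

`digitcoord` quantifies two properties of a cyclic five-digit hand
movement (the motivating task is rotating two balls in the palm, recorded
at 300 Hz and tracked markerlessly at the fingertips): movement *speed*,
and how faithfully the performer can *reproduce* the movement from memory
without the object. This note records the measurement model, the defaults
and why they are what they are, what the synthetic-data generator does and
does not emulate, and the numerical choices that were genuinely open.

## Measurement model

**Preprocessing.** Tracker dropouts (confidence < 0.9 by default) are
linearly interpolated when a gap is at most 30 frames (0.1 s at 300 Hz);
longer gaps or gaps touching a trial boundary make the trial unusable —
we never extrapolate. Each digit's x and y series then pass through a
0.5–5 Hz 2nd-order Butterworth bandpass. The filter is applied
forward–backward (zero phase). This was an open choice: a causal
application would be equally defensible for amplitude measures, but every
quantity downstream is a peak *time*, and a causal 2nd-order bandpass lags
a 2 Hz component by tens of milliseconds — enough to corrupt relative
phase if digits moved at slightly different dominant frequencies. The
doubling of effective order is immaterial because both tasks are filtered
identically. Edges are odd-reflection padded by one low-corner period
(frame_rate / low ≈ 2 s), because 8-s trials are short relative to a
0.5 Hz corner. Both the zero-phase flag and the padding are configurable.

**Extension signal and peaks.** "Maximum extension" needs an operational
definition on 2-D fingertip paths. The default reduces each digit's (x, y)
to its projection on the +y image axis (vertical for a palm-up camera);
`pca` mode (projection on the digit's leading principal direction, sign
fixed by making the largest-magnitude loading positive) and `radial` mode
(distance from the trial centroid) cover unknown camera orientations.
Peaks are local maxima with prominence ≥ 0.25 signal SD and spacing
≥ 0.2 s — half the ~0.4 s plateau cycle, so even the fastest observed
cycles are not suppressed while broadband ripple is. Discrete maxima are
refined by a 3-point parabola fit; at 300 Hz the sub-frame refinement
matters because relative phase divides small time differences by a cycle
duration.

**Cycle time.** One cycle is the interval between consecutive thumb
extension peaks. Aggregation follows the protocol hierarchy: median of
cycles within a trial, median of trial values within a block, mean of the
five block values per day. Trials with fewer than two thumb peaks are
excluded with a logged reason.

**Relative phase and coordination.** For a digit pair (f, h) with f the
lower-numbered digit as reference, each reference cycle [t_f,i, t_f,i+1)
containing exactly one h-peak contributes
φ = (t_h − t_f,i)/(t_f,i+1 − t_f,i) mod 1; cycles with zero or multiple
h-peaks are dropped and counted rather than disambiguated. φ = 0 is
in-phase, φ = 0.5 antiphase. A block's typical ball-rotation pattern is
the vector of circular medians of φ pooled over the block's BRT trials,
one per the 10 unordered digit pairs. The coordination difference — the
recognition-capability measure — takes, per pair, the circular distance
d(a, b) = min(|a−b|, 1−|a−b|) between each reproduction-trial cycle's φ
and the typical median, the median of those distances, and finally the
mean over the 10 pairs; day values are means over the five blocks.

Two conventions here were genuinely open and are exposed as configuration
rather than asserted:

* *Circular vs linear difference.* Phases 0.95 and 0.05 describe nearly
  identical timing; a linear |Δ| of 0.9 would invert their similarity. We
  default to the circular metric (range [0, 0.5]) and provide
  `circular=False` for sensitivity analysis.
* *Circular median.* Implemented by cutting the circle at its largest
  empty arc, unwrapping, and taking the ordinary median (even counts:
  midpoint of the central pair; the first largest gap breaks ties). For
  concentrated samples this equals the linear median and minimizes the sum
  of circular distances; a property test checks the minimization against a
  2001-point grid.

## Statistics

The one-way repeated-measures ANOVA is the classical subject × condition
decomposition; partial η² = SS_cond/(SS_cond+SS_err). Sphericity uses
Mauchly's W on the orthonormal-contrast covariance with the chi-square
approximation *including the second-order term* (the convention of SPSS
and R's ezANOVA); when p < .05 and k ≥ 3, both degrees of freedom are
multiplied by the Greenhouse–Geisser ε (trace form on the double-centered
covariance, clipped to [1/(k−1), 1]) and p is recomputed. The
implementation agrees with pingouin to 1e-8 on random fixtures (test
suite), but pingouin is only an oracle, never the implementation.

Post-hoc contrasts are paired t-tests on adjacent levels with Bonferroni
family size 4 (four adjacent contrasts among five days or five blocks at
family α = .05 ⇒ per-test threshold .0125). Cohen's d for paired contrasts
defaults to mean(Δ)/SD(Δ); the averaged-SD variant is available because
the convention differs across packages. The Wilcoxon signed-rank
comparison of the two measures' day-1 improvements first normalizes each
improvement proportionally, (block1 − block5)/block1, making seconds and
phase units commensurable (z-score normalization is the alternative,
config-switchable); zeros are dropped, ties mid-ranked, z computed without
continuity correction (z > 0 ⇒ the first measure improved more).

## Synthetic-data generator

The generator exists because the underlying video-derived dataset is not
publicly archived; it makes every stage verifiable against exact ground
truth. It emulates the protocol (12 participants, measurement days
{1, 8, 15, 22, 29}, 5 blocks/day, 12 trials/block ordered REP + 10×BRT +
REP, 8 s at 300 Hz) and the two learning curves:

* cycle time T = T_inf + (T0 − T_inf)·exp(−k_perf·u), with u cumulative
  practice in block-equivalents (5/day of home practice between
  measurement days). Defaults T0 = 1.0 s, T_inf = 0.4 s anchor the ~1 s
  naive and ~400 ms plateau scales; k_perf = 0.06 makes speed improve
  measurably within day 1 and plateau by about day 15.
* reproduction phase error δ = delta_inf + (delta0 − delta_inf)·
  exp(−k_rec·(day−1)), constant within a day by construction. Defaults
  delta0 = 0.12, delta_inf = 0.04, k_rec = 0.15: recognition improves
  across weeks but not within day 1. These values are illustrative
  scales, not estimates of any participant data.

Digit d follows A_d·sin(2π(t/T + φ_d)) on the extension axis plus a
quarter-lagged orthogonal component (0.3·A_d), so principal-axis
extraction is non-degenerate; white Gaussian "tracker" noise (SD = 5% of
amplitude) is added per frame. Reproduction trials run 1.3× slower and
perturb each digit's phase offset with an i.i.d. wrapped-normal draw whose
scale is inverted — via a closed-form expression for the expected circular
distance of a wrapped normal — so that the expected pair-phase error
equals δ exactly. Participants share a latent skill factor that couples
naive speed (SD 0.08 s) and initial reproduction error (SD 0.03), giving
the day-1 covariance the correlation analyses look for. Identical seed
and config produce bit-identical datasets.

**A geometric ceiling worth knowing.** Because the 10 pair phases derive
from 5 digit phases, the mean over pairs of circular distances is bounded
by 0.3 (a 3/2 bipartition at opposite poles), and i.i.d. per-digit
perturbations bound the *expected* pair distance by 0.25. Injection
targets up to δ = 0.4 are therefore exercised at the estimator level (per
pair, through `coordination_difference_from_phases`), while
trajectory-level recovery is verified for δ ≤ 0.2, where the wrapped-normal
calibration is feasible.

**What the generator does not emulate:** ball–hand contact dynamics,
biomechanical coupling between digits, slow frequency drift within a
trial, non-Gaussian tracker failure modes (it can inject dropout spans,
but real occlusions correlate across digits), and any muscle-strength
confound. Passing tests therefore show the *pipeline* is correct and
well-calibrated under the stated signal model — not that the kinematic
assumptions hold for any particular camera setup.

## Problem sizes and tolerances

Tests run the cohort at reduced sizes where the full protocol adds no
information: recovery tests use 1–3 participants and 1–2 days; the
dissociation check uses the full 12-participant day-1 cohort over 50
seeds; Type-I calibration uses 1000 table-level null simulations (12 × 5
Gaussian matrices). Numerical tolerances: statistical results match
oracles to 1e-8–1e-10; peak times to within 1 frame (1/300 s); pooled
phase medians to 0.02 at default noise; generator-level δ recovery to
0.03. Degenerate inputs (constant trajectories, < 2 peaks, empty phase
pools, zero-variance contrasts) raise structured errors or logged
exclusions rather than producing numbers.

## Known limitations

No pixel-to-mm calibration (deliberate: all outputs are unit-free); no
continuous (Hilbert-transform) relative phase — the discrete peak-event
definition is the point; the circular-median tie-break and the
even-count midpoint convention are conventions, defensible but not unique;
the Wilcoxon normalization and the Cohen's d variant are documented
choices where the field's usage varies.
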