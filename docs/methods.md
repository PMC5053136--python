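# Methods

This note documents the models, the numerical choices behind them, what the
synthetic-data generator does and does not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The data model

A measurement is a time-ordered series of azimuthally averaged 1D curves
(q, I, σ), one per detector exposure ("frame", 1 s at the default 1 Hz
frame rate), on a fixed q grid.  Internally q is always nm⁻¹ (Å⁻¹ is
converted by the exact factor 10 on I/O).  Intensities are in arbitrary
units on the scale where the forward scattering of an idealized protein is
concentration (mg/ml) × molar mass (kDa); the absolute conversion
1 a.u. = 8.03×10⁻⁴ cm⁻¹ is carried as the constant `AU_TO_INV_CM`.
Curve arithmetic never resamples implicitly: grids must agree to a
relative 1e-9 per point, and `resample_curve` (linear in q) is the single
explicit way to move between grids.  Band edges are inclusive.  Errors
propagate in quadrature through subtraction and averaging.

The gradient program maps frame number → fraction of high-salt buffer B →
salt concentration `c = cA + f·(cB − cA)`.  Step schedules are
right-continuous (a plateau applies from its start frame inclusive), so
frame → salt is a function; outside the programmed window the boundary
composition is held, matching what the pumps do (a strict mode raises
instead).

## Shift-scan correction for linear gradients

The background under the sample run equals the blank run's background
shifted by an unknown, roughly constant number of frames (imperfect
synchronization, co-elution of ions).  The scan subtracts frame-wise at
every trial shift (default −100…+300, step 5 — the granularity at which
the method can honestly distinguish shifts) and scores the flatness of the
normalized low-q/mid-q band-ratio trace across the region of interest:

* ratio per frame r(N) = mean I(0.11–0.5 nm⁻¹) / mean I(1.5–2.5 nm⁻¹),
  computed from per-frame band means (band averaging commutes with
  subtraction, so the scan works from precomputed traces);
* the trace is normalized to mean 1 over the ROI and a straight line is
  fitted — the flatness metric is the RMS residual about that *line*, not
  about the mean: a sloped but straight trace is still a valid
  subtraction, only curvature betrays a systematic error;
* a quadratic fit supplies the curvature: concave-down (negative) means
  under-subtraction, convex means over-subtraction.  A shift is classified
  "acceptable" when |curvature|·(ROI half-width)² < 2 × flatness, i.e. the
  bow is invisible against the residual noise.

**Weighting.**  Both fits and the RMS are inverse-variance weighted with
the propagated per-frame ratio uncertainty
var(r) = (var_low + r²·var_mid)/mid².  This matters: whenever the
mid-band signal of a frame approaches the noise floor the ratio diverges,
and an unweighted RMS is dominated by those spikes — in simulation it
systematically drags the best shift tens of frames toward
under-subtraction (which inflates the denominators).  With weighting the
scan recovers the true offset to the grid step on noise-free data and to
±10 frames in ≥ 90 % of noisy replicates (the acceptance suite measures
this over 20 seeds).  Noise-free input (all σ = 0) falls back to the
unweighted fit.  An all-zero subtracted trace (identical sample and blank
runs) is defined as perfectly flat rather than 0/0-undefined.

The ROI defaults to the contiguous frames around the peak whose total
subtracted scattering exceeds 10 % of the peak height above the median
baseline, fixed once at the trial shift closest to zero; shifts whose
overlap does not cover the whole ROI are dropped so that every shift is
scored on identical frames.  The reported shift uncertainty is the
half-width of the contiguous shift set whose metric lies within one
standard error of the minimum (SE of an RMS over n points ≈ RMS/√(2n)),
floored at the grid step.  An optional refinement pass at step 1 exists
but is off by default.

**Heterogeneous peaks.**  If no shift yields a flat trace the sample
scattering itself changes across the peak (co-eluting species).  The flag
compares the minimum flatness against 5× the metric's null level — for
inverse-variance weights the harmonic-mean ratio uncertainty
√(n/Σσ⁻²) — plus an absolute 1e-9 so noise-free data are judged against
round-off.  At the default noise level the diagnostic has limited power
when the contaminant contributes little mid-band signal (its ratio is then
simply unmeasurable frame by frame); the per-frame Rg/mass traces and the
stable-region CorMap gate are the sharper tools in that regime.

## Exponential transition correction for stepwise gradients

A programmed salt step reaches the measurement position delayed and
smeared into a saturating rise.  With buffer regions before (I) and after
(II) the peak, the mean scattering in the fit band (default 4.5 nm⁻¹ to
the end of the grid, where protein contribution is negligible) is fitted
to the two-parameter model `y(N) = II − (II − I)·exp[−(N − N0)/N′]` for
N ≥ N0 and y = I below.  The levels I and II are *fixed* at the band means
of the averaged buffer regions rather than refitted — this keeps the
q-resolved interpolation exactly consistent with the scalar fit and
reduces the problem to (N0, N′).

Numerics: bounded least squares (`scipy.optimize.least_squares`) with
multi-start over N0 every 5 frames across the inter-region window and two
N′ starts (5 and 20 frames), keeping the lowest cost — the model is
non-convex in N0.  Parameter errors come from the Gauss–Newton covariance
scaled by the residual variance.  χ² is the mean squared residual over the
mean trace variance (plain mean squared residual for noise-free traces).
N′ < 0.5 frames is flagged `hard-step`; a parameter at its bound is
flagged `pinned-at-bound`.  When χ² exceeds 5 the summary recommends
averaged-curve buffer matching instead — an irregular background (e.g. a
transient high-q overshoot) is outside this model.

The per-frame buffer interpolates pointwise,
I_buf(q, N) = w·I(q) + (1−w)·II(q) with w = exp[−(N−N0)/N′] (w = 1 before
the onset), so it is bounded between the two buffers at every q and
reaches the pointwise midpoint at one half-life N′·ln 2.  σ interpolates
with the same weights (the buffers are averages, not independent draws).
Over/under-subtraction bounds subtract buffer II directly and the mean of
I and II; their differences from the model subtraction are summarized as
an approximately constant offset above q = 1 nm⁻¹ and a maximum relative
deviation (against the total signal) below.

The convenience `fit_transition_auto` derives the regions from the
program: region I ends 20 frames before the programmed step; region II is
placed at 5 half-lives past the fitted onset after a first pass and the
model refitted once.  Note a truncation subtlety: at 5 half-lives the
level-II average is still ≈ 3 % of the step short of its asymptote, which
biases N′ at the ~0.5-frame level — fine for data, but exact parameter
recovery on noise-free input needs region II ≥ ~20 N′ past the onset (the
tests place it there).

## Averaged-curve buffer matching

When no frame-wise model applies, the peak frames are averaged and the
best buffer is chosen from a salt-concentration series by minimizing the
absolute difference of mean scattering in 4.25–4.75 nm⁻¹ (ties go to the
lower salt).  The adjacent lower/higher salt steps provide deliberate
under/over subtractions; at a series end the bracket is one-sided and
flagged.

## Curve analysis

**Guinier.**  Weighted linear regression of ln I on q² with weights
(I/σ)² (the first-order variance of ln I); for noise-free input the
Poisson-like fallback w = I is used rather than uniform weights.  Rg =
√(−3·slope); errors from the regression covariance scaled by reduced χ².
The automatic window search is deterministic: window starts scan upward
from the lowest q; for each start the end index is iterated to the fixed
point of qRg ≤ 1.3; windows need ≥ 5 points, a significantly negative
slope (t ≥ 3) and window-to-window Rg stability within 5 %; the longest
admissible window wins, ties to the lowest q_min.  The 1.3 limit is the
standard globular-protein convention; note that for a mathematically ideal
sphere a fit through the full window carries a known systematic of about
+2 % in Rg (the quartic term of ln P), which shrinks below 1 % when the
window is restricted to qRg ≤ ~0.85 — the sphere oracle tests use the
conservative window for exactly this reason.

**Porod.**  I(q) = B + C·q⁻⁴ is fitted over the high-q band (default
3.5 nm⁻¹ to the grid end) with 0 ≤ C and 0 ≤ B ≤ min(binned band means) —
subtraction residuals at high q appear as a small constant that must be
removed before the invariant converges, but the background may never
exceed the signal level (the bound uses binned means because one noisy
point would drag a pointwise minimum to zero).  The invariant
Q = ∫q²(I−B)dq is extended below q_min with the analytic Guinier integral
and above q_max with the fitted tail C/q_max; both extrapolated fractions
are reported.  Vp = 2π²I₀/Q; protein mass = Vp/1.7 nm³ kDa⁻¹.

**Volume of correlation.**  Vc = I₀/∫qI dq with the integral in Å⁻¹ up to
3 nm⁻¹ (0.3 Å⁻¹, the standard upper limit of this analysis); QR = Vc²/Rg
in Å³ and mass = QR/0.1231 Da (reported in kDa).  The estimate is exactly
invariant under intensity rescaling.  The 0.1231 constant is an empirical
calibration on real protein scattering; for a uniform hard sphere, whose
deep form-factor minima shrink ∫qI, it overestimates the mass by ~40 % —
the per-frame *constancy* of the trace across a peak, not its absolute
value, is the diagnostic this estimator serves here.  If the cumulative
integral is still growing at the cap (uncorrected flat background) the
value is flagged unconverged but returned.

**CorMap.**  For two curves on a shared grid the statistic is the longest
run of identical sign among pointwise differences; under the pure-noise
null each sign is a fair coin and the p-value is exact:
P(longest run ≥ C) = 1 − A(n, C−1)/2ⁿ, where A(n, m) = 2 × (compositions
of n into parts ≤ m) counts binary sequences with no run longer than m —
integer arithmetic throughout, so the recurrence is exact at any n (the
tests verify it against exhaustive enumeration for all n ≤ 16).  Exact
zero differences carry no sign information and break runs; two identical
curves short-circuit to C = n, p = 1 with an `identical` flag.  Adjustment
across a comparison set is Bonferroni (min(1, p·k)), a documented and
swappable choice.

**Stable region.**  Frames are scaled to a reference frame (least-squares
factor over the comparison range, default 0.11–2.5 nm⁻¹, removing the
concentration difference), CorMap-tested against it with Bonferroni
adjustment across all frames, and additionally required to keep their
low/mid ratio within 5 σ of the reference's (per-frame propagated σ, so
low-signal frames are gated by CorMap rather than by their meaningless
ratio).  The result is the largest contiguous passing range containing
the reference (default: the low-band maximum).

## The synthetic-data generator

`simulate_run` produces a sample run and a blank (buffer) run with a full
truth record (shift, per-step (N0, N′), per-frame concentrations, species
Rg/volume/mass).  It emulates:

* Gaussian elution peaks (single, double, or contaminated via a second
  species) of homogeneous spheres, with forward scattering = c·M exactly;
* a buffer background b0 + a_salt·salt + capillary term
  amp·(q/0.2 nm⁻¹)⁻⁴ (negligible above 0.2 nm⁻¹), so two salt levels
  differ by a flat offset at higher angles;
* the delayed (15-frame) and exponentially smeared (N′ = 17 frames)
  arrival of programmed salt changes at the capillary; linear gradients
  pass through with the pure delay;
* a clock offset (default 130 frames) between the sample-run and
  blank-run background trajectories;
* Gaussian noise with σ = noise_level·√I (default 0.1, i.e. ≈ 1.6 %
  relative at the buffer level — plausible for 1 s exposures at high
  flux), stored exactly in the σ columns; a Poisson option exists behind
  a flag (Gaussian is the default so that σ is exact and residual signs
  are symmetric, as the CorMap null assumes);
* for the D5-like configuration, a transient flat high-q overshoot after
  each step (decaying with a 30-frame constant), which defeats the
  exponential model and exercises the buffer-matching path.

Defaults are chosen to mirror the experimental conditions: q grid
0.032–4.9 nm⁻¹ (1000 points), 1 Hz, 1 ml/min; a BSA-like species of
66.5 kDa with Rg 2.74 nm (sphere radius 3.5373 nm) at 1.75 mg/ml peak
concentration on a 25 mM → 1 M NaCl gradient; a stepwise variant whose
single 12 % step (142 mM) is programmed so the dispersed onset sits at
frame 1289; and a hexamer-like 320.9 kDa species with Rg 4.65 nm at
3.4 mg/ml for the matching path.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: real protein form factors (a sphere's deep
minima make its mid-q signal weaker than a real globular protein's, which
is the hard regime for every ratio-based diagnostic here), interparticle
structure factor at high concentration, radiation damage, detector
artefacts, instrumental smearing, slow buffer drifts between runs, and
baseline drift in the chromatogram.

## Known limitations

* The Porod volume from noisy runs is biased when the subtracted signal in
  the Porod band lies below the noise floor: residual background then
  leaks into the q⁻⁴ tail term (the README example quantifies ≈ −15 % at
  the default conditions).  The mis-subtraction bounds exist to make this
  visible; treat Vp from weak high-q data as indicative.
* The heterogeneity flag is conservative: with an uninformative mid band
  it reports "consistent with one species" rather than guessing.
* The concave/convex classification presumes the background residual is
  small against the mid-band protein signal; once the residual flips the
  sign of the denominator inside the ROI the trace has a pole and the
  curvature sign is no longer meaningful (the scan still ranks such
  shifts correctly — their flatness is enormous).
* `fit_transition` assumes a single exponential with one (N0, N′) shared
  across q; a q-dependent response or multi-exponential transition is out
  of scope, and χ² > 5 routes the user to buffer matching instead.
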