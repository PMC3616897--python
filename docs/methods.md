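# Methods

This note records the models, numerical choices and limitations behind
`triquant`: what the synthetic spectra emulate, how each quantitation
route works, and what the passing tests do and do not demonstrate about
real instrument data.

## The measurement model

All spectra are zero-order absorbance curves A(λ) on a uniform wavelength
grid, 200–400 nm at 1 nm by default (201 points), 1 cm path implied.
Mixtures follow Beer–Lambert additivity,

    A(λ) = Σᵢ cᵢ · aᵢ(λ) + ε(λ),

with cᵢ the analyte concentrations (µg/mL), aᵢ(λ) absorptivity-like
curves (AU·mL·µg⁻¹) and ε additive Gaussian noise.  Off-grid reads use
linear interpolation; with smooth absorbance curves sampled at 1 nm the
interpolation error is far below instrument noise.  The half-open window
[230, 340) nm defines the 110-point multivariate input; the choice of the
half-open convention (rather than the 111-point closed interval) fixes
the network architecture at 110-10-3 and is configurable.

## The synthetic band library

Each pure component is a sum of Gaussian bands, optionally clipped to
zero above a hard cutoff wavelength.  The frozen defaults are chosen so
that a 10 µg/mL solution peaks between 0.1 and 1.0 AU, which puts the
working calibration slopes at the bench-instrument order of magnitude
(AML: 0.011 AU per µg/mL at 359 nm; HCT: 0.010 at 315 nm; the shared
OLM/HCT absorptivity at 260.5 nm comes out at 0.037).

Structural constraints, all exact by construction:

* OLM and HCT are zero at and above 340 nm (OLM already from 310 nm,
  hence zero at 315 nm where HCT absorbs);
* AML absorbs at 359 nm (band centered there) and everywhere in
  200–400 nm stays above the 10⁻⁴ AU·mL·µg⁻¹ division floor;
* all three overlap strongly in 200–300 nm.

**The isoabsorptive crossing.**  Two OLM band amplitudes are solved from
a 2×2 linear system so that the difference d(λ) = a_OLM(λ) − a_HCT(λ)
satisfies both

    d(260.5) = 0        and        d(260) + d(261) = 0.

The first condition is the crossing itself; the second makes d locally
antisymmetric about 260.5 nm, so the linear interpolant between the 260
and 261 nm grid samples also vanishes exactly at 260.5 nm.  Without it,
the interpolated read at the iso point carries a curvature bias of order
10⁻⁴ relative, which would dominate the noiseless error budget; with it,
the full pipeline is exact to machine precision, and the sign-change
crossing finder lands on 260.5 nm exactly.

**What the simulator does not emulate.**  The true absorptivity curves of
the three drugs are only known graphically; the library reproduces their
constraints, not their shapes.  Hard cutoffs introduce a small (~10⁻⁴)
discontinuity in the OLM/HCT curves where a real spectrum tails off
smoothly.  Stray light, baseline drift, wavelength-registration error and
bandwidth convolution are not modeled; noise is white and homoscedastic
(an optional extra-noise band below 230 nm mimics the unreliable UV edge,
and an optional smooth excipient background is available, both off by
default).  Passing tests therefore demonstrate correctness of the
algorithms under Beer–Lambert assumptions, not robustness to instrument
artefacts.

## Ratio subtraction

Given mixture M = X + Y (X = OLM+HCT, Y = AML) and a unit-concentration
divisor Y′, the ratio M/Y′ equals X/Y′ plus the constant c_Y (the AML
concentration).  The constant is estimated as the **median** of the ratio
over the 350–400 nm plateau — the median rather than the mean because it
is robust to edge effects; the mean is available by flag.  Recovered
spectrum: (M/Y′ − c)·Y′, reported on the largest contiguous region where
the divisor is at or above the division floor of 1e-4 AU (division by
near-zero absorbance is unstable; the default AML divisor clears the
floor everywhere).  The plateau SD is reported as a flatness diagnostic;
when it exceeds 5 % of the constant a warning is logged and recorded in
the result.  Note that at realistic noise this diagnostic fires on nearly
every run: on the plateau the divisor is 0.001–0.01 AU·mL·µg⁻¹, so
division amplifies 0.002 AU noise by two to three orders of magnitude.
The median over ~50 plateau points still estimates the constant to ~1 %;
the diagnostic is informative about *systematic* plateau slope only when
noise is low.

On noiseless data the round trip is exact and independent of the divisor
concentration (the divisor is a free normalization) — both properties are
asserted at 1e-9 relative in the tests.

## Univariate calibration and the resolution pipeline

Calibration lines are ordinary least squares A = S·C + a fitted on pure
standards (8 levels over 5–40 µg/mL for AML and HCT; 2.5–40 for the
isoabsorptive line).  σ of the intercept is the standard OLS intercept
SE, the σ entering LOD = 3.3σ/S and LOQ = 10σ/S.  The isoabsorptive line
is fitted on HCT standards by default; OLM standards are equivalent at
the iso point and selectable.  Predictions outside the fitted range are
returned with an extrapolation warning, and negative concentration
estimates are reported as-is — truncating them at zero would hide a
useful quality signal.

The ternary resolution runs: direct AML at 359 nm → ratio subtraction →
HCT at 315 nm on the recovered spectrum → OLM+HCT total at 260.5 nm →
OLM by subtraction.  Noiseless end-to-end error is below 1e-6 relative
across the whole five-level design grid (measured: ~1e-15).

Error anatomy under noise: AML is the weakest link because its 359 nm
signal is only ~0.08 AU at tablet levels, so an sd = 0.002 AU read is a
2.6 % relative error and the fitted line contributes a correlated bias of
similar size; the OLM+HCT total at 260.5 nm sits on a >1 AU signal and is
correspondingly precise.  A single 9-mixture assay therefore shows a few
percent of AML scatter (SD ≈ 2.3 % of the run mean across seeds), while
the across-seed mean recovery is unbiased — the Monte-Carlo tests (50
seeds) assert 98–103 % means for every analyte on both routes.

## The calibration design

The 25-run, five-level, three-factor layout is generated by a cyclic
difference construction: a frozen base sequence of 25 level indices whose
lag-1 **and** lag-2 ordered pairs each enumerate all 25 level
combinations exactly once (found by deterministic lexicographic search;
uniqueness of pairs is re-verified by a test).  The three factor columns
are the base and its cyclic shifts by one and two rows, so each level
occurs exactly five times per factor and every ordered level pair of any
two factors occurs exactly once — the design is an OA(25, 3, 5, 2).

The published 25-mixture layout this package targets is shipped verbatim
as a fixture.  It satisfies the same balance properties but is *not* a
shift family of any single base sequence (its third column is not a
rotation of the first), so generator output and fixture are compared by
balance, never row order or row sets.

Train/validation split: the default "lab-mixtures" scheme marks as
validation every design row matching one of the nine specificity-study
compositions — on the published layout these are exactly nine rows,
reproducing the 16/9 split.  For custom level sets where the compositions
do not resolve, a deterministic stride (every third row from index 2,
wrapping) fills the validation quota.

## The linear network calibration

Architecture 110-10-3, purelin transfers at both layers (a tansig hidden
transfer is available behind a flag for nonlinear data).  Inputs and
targets are mean-centered with the **training-set** means; validation
rows are never centered with their own statistics.

Training is Levenberg–Marquardt on the full 1143-parameter vector:
damping µ starts at the learning coefficient 0.001, is multiplied by 10
on a rejected step and by 0.1 on an accepted one (defaults 200
iterations, patience 6, seeded fan-in-scaled uniform initialization,
init scale 0.01).  Since the residual count (samples × 3) is far below
the parameter count, the step is solved in residual space via
(JᵀJ+µI)⁻¹Jᵀr = Jᵀ(JJᵀ+µI)⁻¹r, making an iteration cost milliseconds; a
typical fit converges in 10–20 iterations.  After each accepted step the
validation RMSEP is recorded; the returned model is the iterate with the
smallest validation RMSEP (early stopping).  Setting
`AnnHyper(early_stopping=False)` returns the final (converged) iterate
instead, which is what the least-squares oracle tests examine.

Why a linear network at all: with purelin transfers the converged network
is exactly an affine map, equivalent to multivariate OLS on the centered
data.  The value added over plain OLS is the early stopping — with 16
training spectra and 110 wavelengths the least-squares problem is
underdetermined, and at finite noise the unregularized interpolator fits
noise directions; stopping at the validation minimum is the
regularization.  Consequently the OLS-equivalence tests compare converged
models, on all rows for noiseless data (where every spectrum lies in the
three-component span of the training inputs) and on training rows for
noisy data (off the training row space the LS solution is not unique, so
no equivalence can be demanded there).

## Validation statistics

Sample SD uses the n−1 denominator throughout — verified by the fixture
tests: the published summary cells reproduce under n−1 and not under n.
The method comparison uses the pooled-variance two-tailed t (df =
n₁+n₂−2) and the variance-ratio F with the larger variance in the
numerator (df = (n−1, n−1)); critical values at α = 0.05 come from a
two-entry bundled table (t, df 10 → 2.228; F(5,5) → 5.050, the values
printed alongside the published comparison) with scipy quantiles for any
other df.

The packaged fixtures carry the published replicate recoveries, the
published summary cells and the published t/F statistics, each summary or
comparison row with a `consistent` flag.  A handful of printed cells do
not follow from their own printed inputs (two specificity-study summary
columns, one tablet-assay summary column, and the three ANN-column t/F
pairs); these are flagged and excluded from value-level recomputation —
recomputing them would require data the publication does not contain —
but the qualitative below-critical conclusion reproduces for every
column, flagged or not, and is asserted for all of them.

## Problem sizes and determinism

Monte-Carlo suites use 50 seeds (9 mixtures each for the
spectrophotometric route; one 16/9 network fit each for the ANN route)
at sd = 0.002 AU — enough for ~0.1 % standard error on mean recoveries,
and the whole test suite runs in seconds.  Every stochastic component
(noise models, weight initialization) is driven by explicit integer
seeds; identical seeds give bit-identical spectra, weights and reports,
and the CLI embeds the config hash and seed in every output file.

## Known limitations

* The simulator's band shapes are stylized; quantitative agreement with
  published instrument-derived numbers (regression coefficients, LOD/LOQ,
  recovery tables) is not expected and not claimed — those are consumed
  as fixtures, not regenerated.
* Ratio subtraction is implemented for exactly one extended interferent;
  derivative-ratio variants and multi-interferent extensions are out of
  scope.
* The pooled t test assumes equal variances (the published comparison
  uses the df = 10 critical value, implying pooling); Welch's correction
  is deliberately not offered.
* The plateau-flatness diagnostic is noise-dominated at realistic noise
  levels (see above) and should be read accordingly.
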