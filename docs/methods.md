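# Methods

This note records the models implemented in `starchkin`, the conventions
and numerical choices behind them, what the synthetic generators do and do
not emulate, and the package's known limitations.  No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` compute.

## Digestion kinetics

### Multi-phase first-order model

In vitro starch hydrolysis is modeled as first-order approach to an
equilibrium extent, C(t) = C∞(1 − e^(−kt)), with C in percent of total
starch, t in minutes and C∞ ≤ 100%.  Multi-phase digestion concatenates
such segments with per-phase (k_i, C_i∞) and boundaries t_i.  The
generator anchors each phase at the level the previous phase reached:

    C(t) = C(t_{i−1}) + (C_i∞ − C(t_{i−1}))·(1 − e^(−k_i (t − t_{i−1}))),

which makes the noise-free curve continuous and non-decreasing — the
physically required behavior — and makes the LOS slope within each phase
exactly −k_i.

*Convention note.* The per-phase equilibrium read off a LOS segment is
C_inf = exp(intercept)/k, which inverts ln(dC/dt) = −kt + ln(C∞k) with
absolute time.  For phase 1 (anchored at t=0, C=0) this is the generator's
C_1∞ up to discretization bias.  For later phases the relative-time
anchoring above and the absolute-time intercept are different
parameterizations, so the reported phase-2 C_inf is the absolute-time
amplitude, not the generator's C_2∞.  Rate constants are unaffected.  For
whole-curve summaries (AUC ranking across samples) the classical
single-exponential fit is the meaningful source, available via
`auc_source="classical"`.

### LOS transform and discretization

The LOS plot uses y = ln(ΔC/Δt) at the increment midpoint x.  On a uniform
grid of spacing Δ the discrete slope equals −k exactly, and the intercept
is inflated by exactly sinh(kΔ/2)/(kΔ/2) — about +0.06% on C∞ at
k ≈ 0.024 min⁻¹, Δ = 5 min.  This closed form is asserted in the tests.
The standard sampling protocol (0, 5, 10, 20, 30, 40, 50, 60, 90, 120,
180, 360, 540 min) is available as a preset, but its sparse tail leaves
the slow phase with only three LOS points, below the four-point minimum a
segment needs; parameter-recovery work therefore uses the uniform 5-min
grid preset.

Non-positive increments are dropped (the log is undefined), counted, and
surfaced; a warning fires when ≥20% of increments are lost.  Increments
below 10⁻⁹ percent are also treated as flat: they are orders of magnitude
below GOPOD assay resolution, and near saturation they consist of
floating-point cancellation noise that would otherwise scatter the LOS
tail arbitrarily.

### Segmentation

Breakpoints are chosen by exhaustive search over placements with ≥4 LOS
points per segment, scored by BIC = n·ln(SSE/n) + p·ln(n),
p = 2·(#phases) + (#phases − 1), with ties toward fewer phases.
Candidates whose per-phase k values do not strictly decrease, or with any
non-negative slope, are discarded — digestion can only slow down as
accessible substrate is consumed.  SSE/n is floored at 10⁻¹² so that
zero-residual (noise-free) fits remain comparable across model orders;
the floor is far below any measurable residual.  The breakpoint is
reported as the observation time separating the adjacent LOS midpoints at
the fitted boundary, i.e. on the sampling grid.

### Classical fit, AUC, HI, EGI

The classical fit is bounded nonlinear least squares (k ∈ (10⁻⁶, 1]
min⁻¹, C∞ ∈ (0, 100]%), initialized at k = 1/mean(t), C∞ = max(C),
tolerances 10⁻¹⁰.  AUC is the closed form
C∞(t_f−t_0) − (C∞/k)(1 − e^(−k(t_f−t_0))) with t_0/t_f defaulting to the
first/last sample.  HI is reported on the ×100 percent scale (the scale on
which published HI ≈ 70–105 values live) and EGI = 39.71 + 0.549·HI.
Because no white-bread reference dataset is published, the package ships a
clearly synthetic reference (single phase, C∞ = 100%, k = 0.09 min⁻¹ —
a fast, fully digestible food); HI/EGI computed against it rank samples
but are not comparable to published absolute values.

## Digestible fractions

Glucose→starch conversion multiplies released glucose by 162/180 = 0.9
everywhere (Englyst convention); a variant that instead divides by 0.9
appears in print and is available behind `as_printed=True`, but mixing the
two conventions within one analysis is an error.  GF defaults to 0 (free
glucose is rarely reported); with GF = 0, RDS + SDS + RS = 100 by
construction.  Readings within ±1 min of the nominal 20/120-min times are
accepted.

## SAXS lamellar analysis

### Correlation function

L(r) is the cosine transform of the Lorentz-weighted intensity I(q)q²,
normalized to 1 at r = 0.  The finite measured window is completed by the
standard recipes: linear-in-q² extrapolation through the first 5 points to
q = 0, and a Porod tail I = K/q⁴ + b fitted over the top 20% of the q
range, with the flat background b removed everywhere and the K/q⁴ tail
extended to 2 Å⁻¹.  Quadrature is trapezoidal on a q grid fine enough to
give ≥8 samples per period of cos(q·r_max).  Lamellar interference fringes
make the two-parameter (K, b) fit fragile when the fit window spans less
than one fringe; unphysical results (K ≤ 0 or b < 0) fall back to b = 0
with K the window average of I·q⁴.

Validation against the real-space oracle (below) shows the completion is
accurate when the measured window extends a few fringes past the lamellar
peak; the synthetic validation experiments therefore measure to
q = 0.6 Å⁻¹.  On a window truncated at 0.25 Å⁻¹ the small-r part of L(r)
softens (the corner sharpness lives in the unmeasured tail) and deviations
up to ≈0.07 against the oracle appear for a 10.9-nm stack; d itself is
far more robust (<0.5% error in both cases).

### Thickness split and fractal exponent

d is the position of the first interior local maximum of L(r) (parabolic
sub-grid refinement).  The thinner layer thickness is where the linear fit
to the initial decay (fitted where L descends through [0.8, 0.3]) meets
the horizontal baseline through the first minimum; the thicker layer is
d − thinner.  Which layer is crystalline cannot be decided from L(r)
alone, so the assignment is an explicit caller flag (default thinner →
d_c).  2π/q* from the Lorentz-corrected peak is exposed as a secondary
long-period estimate.

The mass-fractal exponent is the log-log OLS slope over either a caller
window or, automatically, the longest contiguous low-q window below the
Lorentz-corrected peak with r² ≥ 0.99 (≥6 points); D_m = −α with a
validity flag for α outside (−3, −1).  The exponent of a power-law
background is recoverable within 0.05 only where that background dominates
the window — composite curves with comparable structure intensity bias the
fit toward the structure.

### Forward model and oracle

The generator builds 1-D two-phase density profiles (crystalline 1,
amorphous 0) of ≥20 lamellar repeats on a 0.05-nm grid, with Gaussian
thickness jitter truncated at ±0.2·mean so layers stay positive.  The
intensity is the ensemble-averaged squared Fourier magnitude divided by q²
(so the emitted curve is consistent with the q² weighting in L(r)), plus
an optional power-law background.  The oracle is the ensemble-averaged
direct autocorrelation of the same mean-subtracted finite profiles,
normalized at r = 0 — exactly the quantity the squared Fourier magnitude
encodes, and computed entirely in real space, independent of the
reciprocal-space pipeline it checks.

## Spectral metrics

The FTIR short-range order ratio uses raw baseline-corrected intensities
at the grid points nearest 1047 and 1022 cm⁻¹ (linear baseline anchored at
1200 and 800 cm⁻¹); no band deconvolution is attempted.

XRD relative crystallinity smooths with Savitzky–Golay (11 points, order
3), estimates the amorphous halo with a rolling-circle minimum envelope —
grey-scale opening by a half-ellipse of lateral semi-axis 5° 2θ and
intensity semi-axis 0.5× the signal maximum — and reports the area above
the envelope as a percentage of the total area above zero.  The ball's
curvature sits between that of a broad halo (σ ≳ 8°) and sub-degree
crystalline reflections, so it follows the former and bridges the latter;
on synthetic patterns with analytically known area splits the recovered Rc
is within ~0.6 points.  Narrower halos (σ ≲ 5°) would need a larger
`ball_height`.  Because the original analyses used proprietary instrument
software with unpublished settings, absolute Rc values from real
diffractograms are not reproduction targets — only synthetic recoveries
and invariances (scale invariance, zero for pure halos) are asserted.

## Surface metrics

Rq is the standard deviation of heights.  GLCM features quantize heights
min–max into 16 levels and accumulate symmetric co-occurrence matrices for
offsets (0,1), (1,0), (1,1), (1,−1); energy = ΣP², contrast = Σ(i−j)²P,
homogeneity = ΣP/(1+|i−j|), entropy = −ΣP·ln P in natural-log units (the
published unit convention is unstated, so "e.u." values are not
comparable).  The GLCM is computed directly from the quantized map because
the package's energy definition (ΣP², not its square root) and offset set
must match exactly; scikit-image's co-occurrence counts serve as an
independent cross-check in the tests.

The box-counting dimension uses differential box counting: box sizes
s ∈ {8, 16, …, side/4}, column height h_box = s·(global range)/side, count
max(1, ceil((h_max−h_min)/h_box)) per column, dimension = slope of ln N
vs ln(1/s).  Boxes of 2 and 4 px are excluded from the ladder: on a
sampled surface the discrete range over so few samples has not converged
to the continuum range, which deflates fine-scale counts and biases the
slope toward 2 (on 1024² fractional-Brownian surfaces with H = 0.5 the
full ladder reads ≈2.25 where 3 − H = 2.5; the truncated ladder reads
2.37–2.44).  Flat maps return 2.0 by convention, flagged.

## Synthetic data: what it does and does not emulate

The generators reproduce the *mathematical structure* of each measurement:
multi-phase exponential kinetics with additive Gaussian read noise clipped
to [0, 100] (emulating GOPOD scatter; no heteroscedasticity, no enzyme
inactivation drift), ideal two-phase lamellar stacks (no transition
layers, no paracrystalline disorder beyond Gaussian thickness jitter, no
instrument smearing), Gaussian peaks on linear baselines (no peak
asymmetry or detector artifacts), and Gaussian random surfaces with exact
Rq rescaling (no tip convolution or scanner bow).  Passing tests therefore
demonstrate correctness of the arithmetic and estimators on clean,
in-model data — not robustness to every instrument artifact of real
measurements.

Defaults encode the studied system: the standard digestion sampling grid;
published kinetic parameter sets for paste and complexes as test fixtures;
stack thicknesses (5.33/5.55 and 1.99/1.98 nm) matching the published
lamellar tables; 2 µm × 2 µm, 256-px height maps with Rq of a few nm.
Noise defaults to zero so ground truth is exact; tests that need noise set
it explicitly.

## Known limitations

- The published HI values cannot be recomputed from kinetic parameters
  because the white-bread reference curve is not published; HI/EGI against
  the synthetic reference are internally consistent but not absolute.
- Phase-2+ C∞ from LOS intercepts is parameterization-dependent (see the
  convention note); cross-study comparison of slow-phase amplitudes should
  use the classical fit.
- Correlation-function accuracy at small r depends on the measured q
  window; instrument windows ending just past the lamellar peak soften
  L(r) below ~1 nm.
- The rolling-circle Rc baseline and the GLCM/entropy conventions are
  documented stand-ins for unpublished instrument-software settings;
  absolute published values for those tables are out of reproduction
  scope.
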