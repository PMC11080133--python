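# Methods

This note documents the models and procedures implemented in
`voltachemo`, the parameters that matter, the design decisions taken
where the design was genuinely open, and the limits of what the synthetic
study can demonstrate.

## Signal model

A differential-pulse voltammogram is a current trace on a uniform
potential grid; the default grid runs 0.00 → +1.30 V in 5 mV steps
(261 points). Each analyte contributes a Gaussian oxidation peak

    i_k(E) = (slope_k · c_k + intercept_k) · exp(−(E − Ep_k)² / (2 σ_k²))

whose apex height is linear in concentration with the analyte's
univariate calibration parameters. The bundled defaults are the three
antiparkinson drugs:

| analyte | Ep (V) | slope (i.u./M) | intercept (i.u.) | linear range (M) | σ (V) |
|---|---|---|---|---|---|
| levodopa (LD) | 0.29 | 0.0681 | −2.76·10⁻⁷ | 4.00·10⁻⁵ – 9.00·10⁻⁴ | 0.020 |
| carbidopa (CD) | 0.28 | 0.0576 | 4.39·10⁻⁶ | 6.48·10⁻⁵ – 4.63·10⁻⁴ | 0.040 |
| entacapone (ENT) | 0.46 | 0.0611 | 2.09·10⁻⁵ | 3.20·10⁻⁶ – 4.00·10⁻⁴ | 0.035 |

Currents are stored in whatever unit the instrument produced ("i.u.";
the slope is that unit per mol/L) — the package never converts current
units.

**Peak widths are a modelling choice**, not a measured quantity: DPV peak
width reflects electrode kinetics, so the reversible LD oxidation is
given a narrow peak and the irreversible CD and ENT oxidations broader
ones. This matters: with Ep separated by only 0.01 V, two *identical*
Gaussians at 0.29/0.28 V would have a shape correlation of 0.988 and no
realistic noise level would permit their resolution — it is the width
(shape) difference that carries the LD/CD information, as it does in real
voltammograms where the two compounds' peak shapes differ. With the
widths above the LD/CD profile correlation drops to ≈ 0.89, which makes
the resolution hard but feasible, reproducing the qualitative overlap of
the instrument data.

## Synthetic-data generator

`simulate()` produces a voltammogram set for a concentration design
with three artifact classes, each switchable and seeded
(`ArtifactSpec`):

* **baseline drift** — an additive smooth background (default:
  exponential decay from the low-potential end), scaled per sample by a
  uniform factor in [0.5, 1.5] of `baseline_scale` and, for the
  exponential kind, with a per-sample decay rate uniform in [2, 4] per
  scan. The rate variation is deliberate: a drift of fixed shape is a
  rank-one perturbation that a single PLS factor absorbs silently,
  whereas real drift varies in shape between runs and genuinely degrades
  an uncorrected calibration.
* **potential jitter** — one rigid shift of the whole trace per sample,
  drawn N(0, `jitter_sd`) in volts and rounded to a whole number of grid
  steps (edge values replicated). This is exactly the insertion/deletion
  model the alignment stage corrects, so alignment quality can be scored
  against ground truth.
* **noise** — additive white Gaussian noise, sd `noise_sd`.

`default_artifacts()` anchors the study conditions to the data set
itself: baseline at 20% of the largest noiseless apex, jitter sd 0.010 V
(two grid steps), noise at 0.05% of the largest apex. The noise level
was chosen once so that the fully preprocessed synthetic calibration
lands in the sub-percent external-error regime a working DPV method
delivers; at 1% noise the LD/CD pair is unresolvable at any preprocessing
stage, i.e. the study itself would be impossible. With all artifacts
disabled the generated matrix is exactly bilinear
(`matrix = A · G`, amplitudes times unit profiles), verified to machine
precision and used as ground truth throughout the tests.

What the generator does **not** emulate: electrochemical mechanism
(Butler–Volmer kinetics, diffusion, adsorption), pH and scan-rate
dependence, peak asymmetry, heteroscedastic or correlated noise,
inter-analyte chemical interaction, and electrode fouling trends across
a run sequence. Passing tests therefore demonstrate the statistical
machinery — baseline removal, shift correction, multivariate calibration
and its diagnostics — under the stated signal model, not instrument
fidelity.

## Baseline correction (airPLS)

The Whittaker smoother solves `(W + λ DᵀD) z = W y` exactly (sparse
solve), with `D` the d-th order difference operator on the index grid
(the grid is uniform by construction; λ is therefore dimensionless and
must be rescaled if the grid density changes). airPLS iterates it,
zeroing the weight of points on or above the fit and weighting points
below by `exp(t·|d_i|/Σ|d⁻|)` at iteration t, endpoints pinned to the
maximum weight; iteration stops when the negative-residual mass falls
below `conv_ratio` (default 0.1%) of the total signal mass, or at
`max_iter` (a cap, default 15). Defaults: λ = 10⁵, 2nd-order
differences.

Numerical notes: the smoother's bias on curved baselines grows with λ
(at λ = 10⁵ a decay-rate-2.5 exponential keeps a few-percent residual at
the steep edge; at λ ≈ 10³ it is below 1%) — residual smooth error of
this size is absorbed by the PLS factors. Corrected = y − baseline holds
exactly by construction. Adding a polynomial of degree < d to the input
moves verbatim into the smoother output (null space of the penalty);
end-to-end the corrected trace is preserved to ~0.1% because the stopping
rule sees the changed signal mass.

## Alignment (icoshift)

Traces are aligned to a target by integer shifts maximising the inner
product of mean-centred segments, searched over ±`max_shift` with ties
broken toward zero then toward the negative shift (the identity is a
fixed point). The signal is split into consecutive intervals of
`interval_width` points; an interval wider than the trace — including
the 800-point default against 261-point traces — means whole-trace rigid
alignment. Edge gaps are filled with the edge value (or NaN markers in
the auditable `missing` mode).

Two pipeline-level choices deviate from the textbook configuration, both
forced by measurement on synthetic ground truth:

* **Target**: the most intense calibration trace (`target_mode="max"`),
  not the average. The average of *unaligned* traces is broadened by the
  very shifts being corrected, and because the LD/CD composite peak's
  shape depends on the mixing ratio, extreme-ratio samples systematically
  mis-align by one grid step against it (2–8 single-step errors per
  25-trace set, against 0 for the scheme below). The average-target mode
  remains the module default.
* **Reference-window estimation** (`reference_window=(0.36, 0.66)` V):
  the physical shift is rigid, so it can be estimated on the one region
  whose shape is composition-independent — the ENT peak, present in
  every sample because of the calibration-line intercept — and applied to
  the whole trace. Whole-trace correlation is biased by the
  composition-dependent LD/CD composite. The window deliberately stops
  at 0.36 V (reaching further left picks up the LD/CD tail and
  reintroduces the bias) and extends to 0.66 V (the flat tail anchors
  the correlation). `max_shift` is capped at 10 points (0.05 V): jitter
  spans a few grid steps, and an unbounded search lets a trace whose
  dominant peak belongs to a different analyte snap onto the wrong
  target peak (33-step gross misalignments observed with the ±50
  default).

A one-grid-step alignment error on a validation sample is the single
most damaging failure mode of the whole pipeline (REP% jumps from < 1%
to > 10%), which is why these two choices are load-bearing.

## Filtering and scaling

Savitzky–Golay coefficients are computed from the pseudo-inverse of the
Vandermonde design on the centred window; edge points are refit on the
truncated asymmetric window so the output keeps the input length.
Derivatives are scaled by `(1/step)^deriv` (per volt). Defaults:
window 15 (70 mV), order 2, first derivative — wide enough to suppress
the noise floor, narrow enough to preserve the 20–40 mV peaks. The first
derivative removes any residual additive offset left by baseline
correction.

Scaling: `center`, `autoscale` ((x−mean)/sd, n−1 denominator), `pareto`
((x−mean)/√sd). The pipeline pareto-scales the filtered spectra inside
the PLS stage — pareto damps the dominance of high-variance potentials
without inflating pure-noise ones the way full autoscaling does.

## Design and split

The calibration design is a multilevel partial factorial: for l levels
(supported: 3, 4, 5, 7 — prime powers) and up to l factors, run
(i, j) ∈ GF(l)² assigns factor k the level `j + k·i` in field
arithmetic. Every level of every factor occurs exactly l times and all
factor columns are exactly orthogonal; levels are coded symmetrically
({−2…+2} for five levels) and mapped affinely onto each analyte's linear
range. The 16/9 calibration/validation split is drawn by seeded
rejection sampling constrained so both subsets span all five levels of
all three factors.

## PLS and component selection

NIPALS PLS2 (inner tolerance 10⁻¹⁰, cap 500 iterations; non-convergence
is warned and the component kept; the loop stops early if either block
is numerically exhausted). NIPALS rather than SIMPLS because the
diagnostics need both score matrices T and U. Regression coefficients
`B = W (PᵀW)⁻¹ Qᵀ` on the scaled spaces; at full rank this equals the
least-squares solution (tested against the pseudo-inverse).

Cross-validation is leave-one-out for ≤ 20 training samples, otherwise
seeded 7-fold venetian blinds; scaling is refit inside every fold. The
selected component count is the smallest A whose pooled RMSECV (root
mean square over analytes) is within `lv_tol` (default 2%) of the curve
minimum — the parsimony reading of "no significant further improvement".
On the default synthetic study this selects 5–10 components depending on
seed: 3 concentration factors plus factors absorbing residual baseline
and shift structure, mirroring the 7 factors a real calibration of this
kind settles on.

## Validation statistics

* `RMSE = √(Σ(y_pred − y_act)²/n)`; `REP% = 100·RMSE/ȳ_act` over the
  same sample set; the identity `REP = 100·RMSE/ȳ` holds for every
  emitted report.
* **CV-ANOVA** per response on the unit-variance scale: SS_total = n−1,
  SS_residual = Σ(cross-validated residual)², SS_regression by
  difference; MS = SS/DF, F = MS_reg/MS_res, p from the upper F tail.
  The DF convention is genuinely unstandardised; the default assigns
  round(5/6·DF_total) to the regression (24 → 20/4, the split the
  reference chemometric software prints for this design size) and is
  configurable. The printed "SD" columns are √MS.
* **Permutation test** (default 40 rounds): refit against shuffled
  responses, regress R² and Q² on |corr(y_perm, y)| including the
  original model at correlation 1, report the zero-correlation
  intercepts. Q² = 1 − PRESS/SS_total under the same CV scheme. A
  clearly negative Q² intercept plus the genuine model exceeding every
  permuted refit supports validity; on valid synthetic calibrations this
  holds in ≥ 95% of seeded repetitions.
* **Leverage**: diagonals of `T(TᵀT)⁻¹Tᵀ` and `U(UᵀU)⁻¹Uᵀ`; each in
  [0, 1], each set sums to the component count.
* **Hotelling T²**: `T²_i = Σ_a t_ia²/s_a²` on centred scores with the
  (n−1)-variance; critical value
  `A(N−1)(N+1)/(N(N−A)) · F_{1−α}(A, N−A)` at α = 0.05.
* **Standardized residuals**: raw residual divided by the RSD, taken as
  the root mean square of the residuals (no re-centring — the residual
  itself already measures displacement); |z| > 2 flags an outlier.
  Normal-probability coordinates use Blom plotting positions.

### Recovery reporting

Per-sample percentage recovery diverges at the bottom of a wide linear
range: ENT's lowest design level is 3.2·10⁻⁶ M while the method's
absolute error is of order 10⁻⁶ M, so a single low-level sample can
swing a mean-of-ratios by tens of percent without saying anything about
the calibration. The pipeline therefore reports three recovery flavours:
per-sample mean ± sd (transparency), pooled recovery
`100·Σŷ/Σy` (overall accuracy), and the three-replicate tablet-assay
recovery at fixed mid-range concentrations (the dosage-form assay
setting, 200:50:200 mg label claim converted to a molar ratio and
diluted to the geometric midpoint of the feasible range). The pooled and
tablet recoveries are the meaningful accuracy statistics.

## Greenness and method comparison

Eco-Scale: score = 100 − Σ penalty points (floored at 0 with a warning);
100 is ideal, > 75 great green, 50–75 acceptable, < 50 inadequate.
Penalty values are user inputs; the bundled worksheets carry the DPV
method's items (score 90) and the reference HPLC comparator's (77).

Method comparison from summary statistics: pooled-variance two-sample t
(the pooled variance is always built from the SDs — printed tables round
sd and variance independently, and the sd carries the underlying data's
digits) and the variance-ratio F (larger/smaller, always ≥ 1), each
judged against a user-supplied tabulated critical value. The bundled
critical values (t 2.132, F 6.39 at p = 0.05) are reproduced as given;
note the tabulated t corresponds to 4 degrees of freedom although the
pooled comparison has 8 — the package applies whatever critical value it
is handed and does not second-guess it.

## Known limitations

* The Gaussian peak model and the artifact magnitudes are stylised; the
  pipeline's quantitative results (REP%, recoveries) characterise the
  method under this model, not any instrument.
* Alignment is integer-resolution; sub-step shifts are out of scope
  (as is dynamic time warping).
* The reference-window alignment default is tuned to the ternary
  defaults (an isolated peak near 0.46 V); other analyte panels need
  their own window, or the classic whole-trace/interval modes.
* CV-ANOVA degrees of freedom follow a convention, not a theorem;
  p-values shift under other DF assignments.
* DModX/distance-to-model diagnostics and coefficient confidence
  intervals are not implemented.
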