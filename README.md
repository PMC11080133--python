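# voltachemo

Chemometric resolution of overlapping differential-pulse voltammograms
(DPV), built for the simultaneous quantification of the ternary
antiparkinson combination levodopa (LD) / carbidopa (CD) / entacapone
(ENT) on a bare glassy-carbon electrode — and, more generally, for any
mixture whose analytes co-oxidise into heavily overlapping peaks.

At pH 2 the anodic peaks of LD and CD sit at 0.29 and 0.28 V and merge
into a single composite; ENT oxidises at 0.46 V with partial overlap.
Univariate peak-height calibration is impossible for LD/CD, so the method
is multivariate end to end:

1. **Synthetic signal generation** — Gaussian oxidation peaks whose apex
   height follows each analyte's univariate calibration line
   (`i_p = slope · c + intercept`), plus run-to-run baseline drift, rigid
   potential jitter and white noise. With artifacts disabled the data are
   exactly bilinear, giving every downstream stage a machine-precision
   ground truth.
2. **airPLS baseline correction** — adaptive iteratively reweighted
   penalized least squares: a Whittaker smoother
   `min_z Σ w_i (y_i − z_i)² + λ ‖D² z‖²` whose weights are iteratively
   concentrated on points below the fit, so it converges to the signal's
   lower envelope (λ = 10⁵, ≤ 15 iterations, 2nd-order differences).
3. **icoshift alignment** — per-trace integer shifts maximising the
   cross-correlation with a target trace, with an insertion/deletion edge
   model; the pipeline estimates each sample's rigid shift on the
   composition-stable ENT peak region.
4. **Savitzky–Golay filtering** — local polynomial least squares
   (window 15, order 2, 1st derivative per volt).
5. **PLS2 calibration (NIPALS)** — on pareto-scaled spectra, with
   leave-one-out RMSECV component selection, fitted to a five-level
   three-factor Brereton mixture design (25 runs, 16 calibration + 9
   validation).
6. **Validation suite** — RMSECV / RMSEP / REP%
   (`RMSE = √(Σ(y_pred − y_act)²/n)`, `REP% = 100·RMSE/ȳ`), CV-ANOVA on
   cross-validated residuals, a 40-round response-permutation test,
   leverage (diag `T(TᵀT)⁻¹Tᵀ`, `U(UᵀU)⁻¹Uᵀ`), Hotelling T², standardized
   residuals, and a three-replicate dosage-form (tablet) assay emulation.
7. **Greenness and method comparison** — analytical Eco-Scale scoring
   (100 − penalty points) and pooled-variance t / variance-ratio F
   comparison against a reference HPLC method.

## Worked example

```python
import voltachemo as vc

result = vc.run_pipeline(vc.PipelineConfig(seed=0), outdir="run")
print(result.n_lv)
print(result.ladder.pivot(index="stage", columns="analyte",
                          values="rep_percent").round(2))
```

prints the selected number of latent variables (6) and the external
prediction error at each preprocessing state:

```
analyte             LD     CD   ENT
stage
raw              21.06  22.60  5.93
airpls           30.54  36.72  5.12
airpls_icoshift   1.08   2.31  1.74
sg                0.31   0.67  0.48
```

Read bottom-up, this is the case for preprocessing: on raw drifting,
jittered voltammograms the external relative error of prediction (REP%)
is in the tens of percent; baseline correction alone can even *raise* it
(the corrected peaks are still misaligned, and removing the baseline
strips variance the factors had been using); once alignment restores
bilinearity the error collapses, and derivative filtering brings it below
1% for all three drugs. The per-analyte report for the same run:

```
LD:  RMSEP 1.66e-06 M,  REP 0.31%,  RMSECV 1.60e-06 M,  R² 1.0000
CD:  RMSEP 1.85e-06 M,  REP 0.67%,  RMSECV 1.79e-06 M,  R² 0.9999
ENT: RMSEP 6.47e-07 M,  REP 0.48%,  RMSECV 6.46e-07 M,  R² 1.0000
```

with pooled validation recoveries of 99.93 / 100.02 / 99.88% and a
three-replicate tablet assay (200:50:200 mg label claim diluted into the
linear ranges) recovering 99.73 ± 0.15, 100.86 ± 0.82 and 99.86 ± 0.13%.
The permutation test for LD gives a Q² intercept of −1.51 with the
genuine model (Q² = 1.00) above every permuted refit (max 0.23) —
the signature of a valid, non-overfitted calibration.

The same workflow is scriptable from the shell:

```bash
voltachemo run --seed 0 --out run     # full study into run/
voltachemo simulate --seed 1          # design.csv + voltammograms.csv
voltachemo baseline volt.csv corr.csv --lambda 1e5
voltachemo calibrate sg.csv design.csv --cv loo
voltachemo compare --a 99.76,0.79,5,0.62 --b 100.13,0.65,5,0.42 \
    --t-critical 2.132
```

Every run directory contains the config, all intermediate matrices, the
serialized model, the validation report and a manifest of seeds and file
hashes; the same config reproduces it byte for byte.

## Greenness

```python
import voltachemo as vc
vc.eco_scale(vc.PROPOSED_DPV_ITEMS).score      # 90.0  ("great green")
vc.eco_scale(vc.REFERENCE_HPLC_ITEMS).score    # 77.0  ("great green")
```

## Documentation

`docs/methods.md` describes the signal model, the preprocessing and
calibration procedure, every tunable parameter with its default and
units, what the synthetic generator does and does not emulate, and the
package's design decisions.
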