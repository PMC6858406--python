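# limbvol

Estimation of lower-limb muscle-group volumes (hip extensors, knee
extensors, knee flexors, ankle plantarflexors) from panoramic-ultrasound and
anthropometric measurements.

The package implements the full model-development workflow for clinical
muscle-volume prediction equations:

* **`limbvol.volumetry`** — criterion muscle and group volumes by
  trapezoidal integration of serial axial cross-sectional areas (CSA), with
  the functional group rosters.
* **`limbvol.reliability`** — between-session typical error of measurement
  (TEM = SD of paired differences / √2, absolute and as % of the
  first-session mean).
* **`limbvol.regression`** — forced-entry OLS with inference and fit
  statistics (SEE, standardised residuals), semi-partial correlation,
  Durbin–Watson with tabulated 5% bounds, Lilliefors normality,
  a quantitative homoscedasticity check, and difference-versus-mean
  (Bland–Altman style) trend analysis.
* **`limbvol.pipeline`** — end-to-end equation development: outlier
  exclusion, semi-partial candidate screening (1 predictor per 15 cases,
  collinearity rule), reproducible 80/20 split, leave-one-out candidate
  retention, final fit, a seven-criterion diagnostic battery, holdout
  cross-validation and model selection.
* **`limbvol.predictor`** — the four published prediction equations with
  their inference statistics frozen in a registry, ±1 SEE uncertainty
  bands, unit/extrapolation guards, and an effect-size sensitivity check
  (detectable ⇔ effect % > SEE %).
* **`limbvol.cohort`** — synthetic cohort generator reproducing the
  published group means/SDs and linear predictor–volume structure (noise SD
  = published SEE), with session replicates and CSA slice profiles whose
  integrals equal the latent volumes. The joint distribution of predictors
  was never published; factors are drawn **independently** by default
  (`measurement_correlation` is an explicit knob).

## Command line

```bash
# synthetic cohort + CSA profiles + data dictionary
limbvol simulate --spec default --seed 1 --n-subjects 18 --out cohort.csv

# criterion volumes from profiles
limbvol volume --profiles cohort_profiles.csv --group hip_extensors

# between-session reliability
limbvol tem --cohort cohort.csv --measurement mt_anterior_thigh_50_cm

# develop + validate a prediction equation (JSON report)
limbvol develop --cohort cohort.csv --profiles cohort_profiles.csv \
    --group hip_extensors --seed 1 --out model.json

# apply a published equation
limbvol estimate --group hip_extensors --mass-kg 80 --thigh-length-m 0.40
limbvol sensitivity --group knee_extensors --effect-pct 5.60
```

## Notes

* Units: CSA in cm², spacing in cm, volumes in cm³, masses in kg, lengths
  in m, muscle thickness in cm. Column names in CSVs encode units
  (`body_mass_kg`, `thigh_length_m`, `mt_anterior_thigh_50_cm`, …).
* The uncertainty band on predictions is ±1 SEE; a proper prediction
  interval would require unpublished development-set design moments.
* Knee-flexor and plantarflexor predictions carry a systematic-error
  caveat (both models showed a significant proportional trend in
  validation).
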