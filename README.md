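# sonotexture

Texture radiomics of obstetric ultrasound for predicting postpartum
blood loss in pregnancies with placenta previa or a low-lying placenta.

Women with a low-lying placenta face an elevated risk of postpartum
hemorrhage, and purely clinical risk factors discriminate only
moderately. This package implements the quantitative-imaging side of
that problem: it extracts first-order and gray-level co-occurrence
(GLCM/Haralick) texture features from 5 × 5 mm regions of interest on
the placenta, the placental underlying myometrium (PUM) and the free
myometrium (FM) at the 20- and 30-week scans, selects informative
features, and models blood loss with Gamma log-link regression.
It is aimed at researchers building or auditing ultrasound radiomics
pipelines for obstetric risk prediction.

## The model

Blood loss y (mL) is strictly positive and right-skewed, so

&nbsp;&nbsp;&nbsp;&nbsp;y | x ~ Gamma, &nbsp; E[y | x] = exp(β₀ + Σⱼ βⱼ xⱼ)

Each exp(βⱼ) is a **mean ratio** (MR): an MR of 1.96 for a binary
predictor means 96% higher expected blood loss when present. The full
chain is:

1. **Extraction** — per ROI: mean, median, SD, skewness, excess
   kurtosis, Shannon entropy (first order), plus 13 Haralick
   descriptors of the symmetric, direction-averaged GLCM at 32 gray
   levels and distance 1 (ASM, contrast, correlation, variance, IDM,
   sum average/variance/entropy, entropy, difference
   variance/entropy, IMC1, IMC2; entropies in bits).
2. **Selection** — min–max normalization; greedy pruning of pairs with
   |r| > 0.9; permutation-importance ranking by a random forest under
   10-fold × 3-repeat cross-validation; top-15 retention.
3. **Modelling** — univariable screening (p < 0.05), AIC-based
   stepwise selection, FDR correction; three models: radiomics-only,
   clinical-only, integrated.
4. **Validation** — RMSE; ROC/AUC at the > 500 mL and > 1000 mL
   hemorrhage thresholds with DeLong inference and paired tests;
   1000-resample bootstrap optimism correction; calibration
   slope/intercept; ICC(2,1) reader reliability with Koo–Li bands.
5. **Design** — noncentral-F power analysis for linear-model F-tests
   parameterized by Cohen's f².

Because the underlying patient data are not distributable, the package
ships a synthetic cohort generator (correlated Gaussian random fields
with planted texture–outcome effects and Gamma-distributed blood loss)
that reproduces the cohort's second-order structure; see
`docs/methods.md`.

## Worked example

```python
import pandas as pd
from sonotexture import extract_features, roc_auc, rmse
from sonotexture.synthetic import CohortSpec, simulate_cohort, cohort_frames
from sonotexture.pipeline import run_study
from sonotexture.types import OUTCOME_COL

spec = CohortSpec(seed=0)                     # 107 subjects, 6 ROIs each
subjects = simulate_cohort(spec)
features = pd.DataFrame({s.subject_id: extract_features(s.patches)
                         for s in subjects}).T
clinical, _ = cohort_frames(subjects)
features[OUTCOME_COL] = clinical[OUTCOME_COL]

results = run_study(features, clinical.drop(columns=[OUTCOME_COL]),
                    seed=0, validate=False,
                    selection_kwargs=dict(folds=5, repeats=2, n_estimators=150))
y = clinical[OUTCOME_COL].to_numpy()
for name in ("radiomics", "clinical", "integrated"):
    fit = results[name].fit
    auc = roc_auc(fit.fitted_mean, y > 500)
    print(f"{name:>10}: AUC(>500) = {100*auc.auc:.2f}%  "
          f"RMSE = {rmse(y, fit.fitted_mean):.1f} mL")
print(results["integrated"].effects.round(3).to_string(index=False))
```

Output:

```
 radiomics: AUC(>500) = 76.30%  RMSE = 493.9 mL
  clinical: AUC(>500) = 70.82%  RMSE = 498.7 mL
integrated: AUC(>500) = 84.52%  RMSE = 375.2 mL

                         term    mr  ci_low  ci_high   p  p_fdr
            PUM_30w_glcm_imc1 3.541   1.978    6.338 0.0    0.0
         placenta_20w_fo_mean 0.304   0.175    0.530 0.0    0.0
placenta_30w_glcm_sum_average 0.285   0.172    0.470 0.0    0.0
            previous_cesarean 2.201   1.624    2.984 0.0    0.0
                   resolution 0.475   0.368    0.613 0.0    0.0
```

This synthetic cohort (median blood loss 475 mL; 51/107 above 500 mL)
carries planted texture and clinical effects; the integrated model
discriminates severe bleeding better than either single-source model,
and its mean ratios read as usual — e.g. a previous cesarean is
associated with a 2.2-fold higher expected blood loss, placenta
previa/low-lying resolution with a 53% reduction.

A command-line interface wraps the same steps:

```bash
sonotexture simulate --out cohort --seed 0
sonotexture extract  --images cohort --rois cohort/rois.csv \
                     --clinical cohort/clinical.csv --out features.csv
sonotexture fit      --features features.csv --covariates cohort/clinical.csv \
                     --out report.json --boot 1000 --seed 0
sonotexture power    --predictors 7 --f2 0.15
```

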