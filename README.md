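# sriaquant

Computer-assisted quantification of interstitial fibrosis in renal
implantation biopsies.

## The problem

When a donor kidney is evaluated at the time of transplantation, an on-call
pathologist grades interstitial fibrosis (IF) on a rapidly prepared frozen
section. Frozen sections have poor stain contrast, a broadened-looking
interstitial matrix and ice-crystal artefacts, so fibrosis is easy to
misjudge — and misjudgement can mean discarding a usable organ. The
formalin-fixed, paraffin-embedded (FFPE) section of the same tissue is the
morphological gold standard but only becomes available later.

`sriaquant` implements a digital image analysis pipeline for this setting:

1. **SRIA quantification.** On a Sirius red-stained section image, the
   collagen signal is separated by two-stain colour deconvolution (or an
   HSV gate), thresholded (Otsu per section pair, or a fixed value), and the
   stained area is expressed as a percentage of the annotated cortex after
   excluding glomeruli, vessels and folds:
   `SRIA = 100 · |stained ∧ cortex ∧ ¬excluded| / |cortex ∧ ¬excluded|`.
   Pairs whose analysed area is below 1 mm² are excluded. The continuous
   percentage is translated to the semi-quantitative IF grade 0–3 by
   configurable cutpoints (default 5/20/50%).
2. **Method agreement.** Frozen vs paraffin measurements are compared by
   Bland–Altman analysis (mean difference, 95% limits of agreement
   `mean ± 1.96·SD`, OLS proportional-bias test of difference on pair
   mean), the two-way consistency average-measures intraclass correlation
   `ICC(C,2) = 1 − 1/F` with an F-quantile confidence interval, and
   quadratic-weighted Cohen's kappa for the ordinal grades. Subgroup
   comparisons of the frozen−paraffin difference use an unpaired t-test
   behind a Shapiro–Wilk normality gate, otherwise Mann–Whitney U.
3. **Outcome modelling.** Delayed graft function (DGF, dialysis within the
   first post-transplant week) is modelled by logistic regression:
   a univariate screen retains covariates at Wald p < 0.1, a multivariate
   fit reports odds ratios with Wald 95% CIs
   (`exp(β ± 1.96·se)`) and variance inflation factors.
4. **Synthetic data.** Because biopsy material cannot be shipped with a
   package, a generator renders paired frozen/paraffin cortex images with
   pixel-exact ground truth (collagen fraction hit to the pixel, additive
   frozen inflation, ice-crystal holes, contrast loss) and simulates
   cohorts in which DGF depends log-linearly on SRIA with a calibrated
   prevalence. Every stage of the pipeline is tested against this ground
   truth.

## Worked example

```python
from sriaquant import (SectionSimConfig, generate_section_pair,
                       quantify_pair, map_to_remuzzi)

cfg = SectionSimConfig(width_px=1024, height_px=1024, microns_per_pixel=2.0,
                       true_fraction_pct=30.0, frozen_delta_pct=7.8, seed=7)
frozen, paraffin, truth_f, truth_p = generate_section_pair(cfg)
pair = quantify_pair(frozen, paraffin)   # deconvolution + pooled pair Otsu

print(f"truth    paraffin {truth_p.realised_fraction_pct:.2f}%  "
      f"frozen {truth_f.realised_fraction_pct:.2f}%")
print(f"measured paraffin {pair.paraffin.fraction_pct:.2f}%  "
      f"frozen {pair.frozen.fraction_pct:.2f}%")
print(f"analysed area {pair.paraffin.analysed_area_mm2:.2f} mm^2")
print("IF grade (paraffin):", map_to_remuzzi(pair.paraffin.fraction_pct).grade)
```

prints

```
truth    paraffin 30.00%  frozen 37.80%
measured paraffin 30.00%  frozen 37.84%
analysed area 2.56 mm^2
IF grade (paraffin): 2
```

The paraffin measurement recovers the 30% ground truth, the frozen member
shows the simulated +7.8 percentage-point cryosection inflation, and 30%
falls into IF grade 2 under the default cutpoints.

The DGF model follows the statsmodels convention — a model object fitted to
a cohort table:

```python
from sriaquant import CohortSimConfig, generate_cohort, DgfLogisticModel

cohort = generate_cohort(CohortSimConfig(n_patients=5000, seed=1))
results = DgfLogisticModel.from_dataframe(
    cohort, covariates=["sria_paraffin_pct", "cit_hours"]).fit()
print(results.summary())        # OR per SRIA percentage point ~ 1.1
```

## Command line

```sh
sriaquant simulate-pair --out-dir demo --true-fraction-pct 30 --seed 7
sriaquant quantify --image demo/sim-000007_paraffin.png
sriaquant pair --frozen demo/sim-000007_frozen.png --paraffin demo/sim-000007_paraffin.png
sriaquant simulate-cohort --out cohort.csv --n-patients 500 --seed 1
sriaquant predict-dgf --cohort cohort.csv --screen-alpha 0.1
sriaquant run --out-dir full-run --seed 1 --n-pairs 10
```

Images are 8-bit RGB PNG/TIFF with a JSON calibration sidecar and a GeoJSON
annotation file (roles: cortex, glomerulus, vessel, fold); tables are CSV.

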