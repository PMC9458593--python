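# Methods

This note records the models implemented in `sriaquant`, their assumptions,
the parameters that matter, and the design choices made where several
reasonable options existed. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## SRIA measurement

**Stain model.** A picrosirius red-stained renal section shows collagen in
the Sirius-red hue family and non-collagenous tissue in picric yellow;
lumina and empty space are white. The package's nominal stain colours are
RGB (185, 40, 55) for Sirius red and (230, 205, 110) for picric yellow.

**Colour separation.** The default channel is two-stain colour
deconvolution in optical-density space (Beer–Lambert): the OD vectors of
the two stains plus their cross-product residual form the stain matrix, and
the deconvolved Sirius-red concentration is divided by a fixed scale of 1.5
so a fully stained pixel sits near the top of [0, 1]. The fixed scale
(rather than per-image normalisation) keeps channels comparable across the
two members of a pair, which pooled thresholding requires. An alternative
`hue_saturation` channel gates HSV hue distance to red (tolerance 0.10 of
the hue circle) weighted by saturation × value; both channels map white to
≈ 0. An all-black image is defined as unstained (channel 0) because maximal
OD in every band carries no stain information.

**Thresholding.** The stain/no-stain threshold is chosen by Otsu's
criterion (256-bin histogram, maximal between-class variance) over the
masked intensities. For a frozen/paraffin pair the default pools both
members' masked pixels into one histogram so the pair shares a threshold —
the per-pair rather than per-section reading of pairwise thresholding;
per-section and fixed-value overrides exist because the choice is genuinely
ambiguous. Pixels with channel ≥ threshold count as stained.

**Region arithmetic.** Exactly one cortex polygon (possibly multi-part) is
the inclusion region; glomerulus/vessel/fold polygons are subtracted.
Polygons are rasterised by pixel-centre inclusion: pixel (row r, col c) is
inside iff the point (x = c, y = r) is strictly interior; coordinates are
0-based, x right, y down. SRIA is the stained percentage of the effective
cortex; the analysed area is `cortex_px · (µm/px)² / 10⁶` mm². Pairs whose
smaller analysed area is below 1 mm² are excluded, boundary inclusive; no
spatial registration of adjacent sections is attempted — the area rule is
applied to each member's own analysed cortex.

**IF grade translation.** The continuous percentage is binned by three
strictly increasing cutpoints into grades 0–3 (`grade 0 iff fraction <
c₁`). The defaults 5/20/50% are this package's convention, not a published
constant: they are configurable, and grade 0 deliberately covers a small
nonzero band because a continuous measurement of real tissue is never
exactly zero. No interstitial-oedema correction is applied.

## Synthetic sections

The generator's purpose is ground truth, not photorealism. Inside an
elliptical cortex (0.45·width × 0.45·height semi-axes), collagen is a
Gaussian random field smoothed with σ = 15 µm — giving interstitial bands
of realistic scale — thresholded at the exact order statistic that makes
the collagen fraction of the effective cortex hit the target (ties are
measure-zero in a continuous field). Circular glomeruli (radius 100 µm) and
vessels (radius 60 µm) are placed without overlap and emitted as exclusion
annotations.

The frozen member models three cryosection artefacts:

* **Additive matrix broadening.** The paraffin collagen skeleton is
  offset by a signed Euclidean distance transform; the offset radius is the
  order statistic that puts the frozen fraction at
  `true_fraction + frozen_delta` exactly (distance ties are broken in
  raster order so the count is pixel-exact). The inflation is therefore
  additive by construction — the same number of percentage points at every
  fibrosis level — matching the absence of proportional bias the agreement
  statistics are designed to detect. `frozen_delta_pct` defaults to +7.8
  pp. Within one simulated pair the delta is deterministic; the cohort
  generator, by contrast, draws per-patient frozen−paraffin offsets from
  N(7.8, 7.9²) pp, since at cohort level the between-biopsy spread of the
  artefact matters. No distributional shape stronger than "mean and SD" is
  asserted anywhere.
* **Ice-crystal holes.** White ellipses (semi-axes 10–40 µm), Poisson count
  with density 1 per mm² of cortex by default, punched out of the tissue.
  Holes remain in the analysed denominator (they are cortex) but carry no
  stain, exactly as a hole in real tissue would behave under thresholding.
* **Contrast loss.** The frozen tissue colours are blended 20% toward the
  mean tissue colour before the ±10 per-channel uniform noise shared by
  both members.

All randomness flows from the single config seed through one
`numpy.random.Generator`; identical config + seed is bit-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real slides: staining variability between laboratories and
scanners, section-thickness effects, tubular/nuclear cytology, partial-
volume colour mixing at collagen boundaries, true serial-section geometry
(the two members share one cortex outline), and annotation error by the
human marking the cortex. Recovery of ground truth here demonstrates that
the measurement chain is correct, not that it is robust to every real-world
confounder.

**Problem sizes.** The default section is 2048×2048 px at 1 µm/px (≈2.7 mm²
cortex, so the 1 mm² rule is exercisable). The test and acceptance runs use
1024×1024 px at 2 µm/px — the identical field of view at quarter cost —
which leaves every pixel-fraction argument unchanged because all rules are
formulated per unit area or per fraction.

## Synthetic cohorts

One row per transplanted patient. Covariate distributions emulate an
elderly deceased-donor implantation-biopsy population: donor age
N(66, 15²) clipped to 18–90 y (median ≈ 69), 64.4% male donors, 82.2%
brain-dead donors, cold ischaemia time log-normal with median 17 h, SRIA
(paraffin) N(33, 6.7²)% clipped to [0, 100]. DGF is drawn from

    logit p = α + ln(OR_sria)·SRIA_paraffin + ln(OR_cit)·CIT

with defaults OR_sria = 1.1 per percentage point and OR_cit = 1.089 per
hour, and α calibrated by Brent root-finding so the mean event probability
over the realised covariates equals the target prevalence (default 0.41).
The calibration makes the empirical prevalence converge to the target at
large n, which the tests verify. Other recorded covariates (recipient
demographics, retransplantation, HLA mismatches, PRA, DSA, reader-noise IF
grades) carry no true effect on DGF; their distributions are invented and
documented in the code.

## Agreement statistics

* **Bland–Altman:** differences are frozen − paraffin; limits of agreement
  are mean ± 1.96·SD with the sample SD (n−1). 1.96 is used exactly, not a
  t-quantile. Proportional bias is the OLS slope of difference on pair
  mean with its two-sided t-test; when the pair means have zero variance
  the slope is undefined and flagged rather than invented.
* **ICC:** two-way consistency, average measures over n subjects × 2
  raters. `ICC(C,2) = (MS_subjects − MS_error)/MS_subjects = 1 − 1/F`,
  F on (n−1, n−1) df; the CI comes from F quantiles,
  `[1 − F*₁₋α/₂/F, 1 − 1/(F·F*₁₋α/₂)]`. Consistency deliberately ignores a
  systematic rater offset, which is precisely why it suits a method pair
  with a known additive artefact. A residual mean square within 1e−12 of
  zero (relative to MS_subjects) is treated as perfect agreement with a
  degenerate CI.
* **Weighted kappa:** quadratic disagreement weights
  `w_ij = ((i−j)/(K−1))²`, `κ = 1 − Σw·O / Σw·E`. When both raters use one
  category the expected disagreement is zero and κ is flagged undefined.
* **Subgroup tests:** Shapiro–Wilk at α = 0.05 per group gates the
  unpaired t-test; groups under 8 observations fail the gate outright
  (the test has essentially no power there) and fall through to
  Mann–Whitney U — exact when the combined n ≤ 12, tie-corrected normal
  approximation otherwise.
* **Relevant difference:** |ΔSRIA| ≥ 10 pp, or any inequality of the two
  IF grades when both are present.

## DGF logistic model

Maximum likelihood by IRLS with step-halving, so the log-likelihood trace
is monotone non-decreasing (a tested invariant); convergence when the
relative log-likelihood change falls below 1e−8, cap 100 iterations. A
coefficient exceeding |β| > 30 marks probable complete separation: the fit
is flagged non-converged with a diagnostic instead of reporting a
meaningless Wald interval. Wald z-tests; odds-ratio CIs are
`exp(β ± 1.96·se)`. Continuous covariates enter untransformed per natural
unit (%, hour, year); booleans as 0/1; donor type as an NHBD indicator with
brain-dead donors as reference. The univariate screen retains candidates at
Wald p < alpha_in (default 0.1) and never aborts on a per-covariate
failure; with alpha_in = 1 the screen-then-fit path coincides with the
direct full fit. VIFs are `1/(1−R²)` from OLS of each covariate on the
others (intercept included, the model intercept itself excluded), exact
collinearity reported as infinity. No multiple-testing correction is
applied across the screens. eGFR and survival endpoints are carried in the
data model but not modelled.

## Pipeline and reproducibility

`run_pipeline` chains simulation → quantification → inclusion → agreement
→ grade translation → score matrix → cohort → DGF models, writes every
number that appears in the human-readable summary to machine-readable
CSV/JSON as well, and emits a manifest (package and library versions, seed,
full config) that, together with the seed, fully determines all outputs —
the end-to-end determinism test asserts byte-level equality of two runs.
Per-biopsy failures are logged with the biopsy id and skipped; fewer than
three included pairs skips the agreement stage rather than fabricating an
ICC.

## Known limitations

* The IF-grade cutpoints are a convention; comparisons of κ across
  grading routes are sensitive to them.
* Otsu assumes a bimodal masked histogram; a section that is almost
  entirely collagen or entirely background degrades gracefully (the
  constant-intensity case errors with advice to use a fixed threshold) but
  intermediate unimodal histograms can threshold poorly — the fixed-value
  override exists for that case.
* The ICC confidence interval is the classical F-quantile interval; no
  small-sample correction is applied.
* Wald intervals are first-order; near-separated logistic fits should be
  read from the diagnostic flag, not the CI.
* The synthetic frozen member derives from the paraffin collagen skeleton,
  so frozen/paraffin are perfectly registered — real adjacent sections are
  not, and the package deliberately does not attempt registration.
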