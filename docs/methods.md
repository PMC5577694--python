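# Methods

## Problem and model

Masking (mammography failure) is the event that an invasive tumor is
visible on ultrasound but the mammogram is read as unsuspicious. The
strongest known predictor is percentage mammographic density (PMD): the
share of breast-region pixels classified as dense tissue by a gray-level
threshold. `mammotex` implements a pipeline that replaces reader-measured
PMD with a value predicted from automatically computed texture features,
and evaluates the substitution inside a clinical logistic risk model

    z    = β₀ + β_age·age + β_bmi·BMI + β_surgery·surgery
           + β_nohrt·[postmeno, no HRT] + β_hrt·[postmeno, HRT]
           + β_digital·[digital technique] + β_pmd·PMD
    risk = exp(z) / (1 + exp(z)),

with reference categories (premenopausal, no surgery, analog) carrying
coefficient 0. `REFERENCE_MASKING_MODEL` holds the coefficients of this
model as estimated in a hospital-based diagnostic cohort of 1334 patients
with 8% masking prevalence (intercept −0.906, age −0.018/yr, BMI
−0.080/kg·m⁻², surgery +0.502, postmenopausal-no-HRT −0.530,
postmenopausal-HRT +0.208, digital +0.416, PMD +0.032/percent). It serves
both as the generative truth of the cohort simulator and as a worked
reference for risk prediction.

## Texture features (363)

All features are computed from pixels inside the breast mask only.
Exact family inventories:

* **moment (76)** — mean, variance, skewness, kurtosis; normalized central
  moments m_k = μ_k/σ^k for k = 2..19; and three bounded transforms of each
  NCM: sign(m)·log(1+|m|), sign(m)·|m|^(1/k), m/(1+|m|). σ = 0 defines all
  standardized moments as 0 so constant regions stay finite.
* **histogram (16)** — relative frequencies in 16 equal-width gray bins
  over [0, 256).
* **markovian (93)** — gray levels quantized to G = 64; symmetric
  co-occurrence matrices at distance 1 and orientations 0/45/90/135°
  (0° = east, 90° = north, pairs counted in both directions, both pixels
  masked). Per orientation: the 13 Haralick statistics; sum-histogram
  mean/variance/energy/entropy; difference-histogram (absolute level
  difference) mean/variance/energy/entropy/inverse-difference; plus five
  orientation-averaged statistics. Natural logarithms; correlation with a
  zero marginal variance is defined as 0.
* **regional (48)** — at thresholds {32, 64, …, 224, 256}: binarize
  gray ≥ t inside the mask, label 4-connected components, and compute
  log(1+count), mean/SD of area, mean compactness 4πA/P² (single pixels,
  whose Crofton perimeter is 0, count as compactness 1), largest-region
  share of the mask, and mean of region mean grays. t = 256 is unreachable
  for 8-bit data, so its six statistics are identically 0 by design.
* **runlength (60)** — G = 16; per direction (same four), the run-length
  matrix of maximal constant-level runs, broken at mask gaps; 15 standard
  statistics (SRE, LRE, GLN, GLNN, RLN, RLNN, RP, GLV, RLV, LGRE, HGRE,
  SRLGE, SRHGE, LRLGE, LRHGE) with 1-based gray-level weights so
  low-gray-level emphasis is defined at level 0.
* **fourier (33)** — the image is cropped to the mask bounding box,
  non-mask pixels are replaced by the masked mean (avoids mask-edge
  ringing), the mean is subtracted and the FFT power spectrum partitioned
  into 16 radial annuli of equal width up to Nyquist (0.5 cycles/pixel) and
  16 angular sectors of 11.25° over [0°, 180°); features are power
  fractions plus the power-weighted mean radius. Corner frequencies beyond
  Nyquist belong to no annulus, so annulus fractions sum to ≤ 1.
* **wavelet (37)** — 4-level separable Daubechies-4 decomposition
  (periodization mode) of the same mean-filled crop; per level the LH/HL/HH
  energies, their fractions of total energy, and Shannon entropies of the
  normalized squared detail coefficients, plus the final approximation
  energy. Detail energies below 10⁻¹² of the total are clamped to 0 so flat
  regions report exact zeros instead of filter-bank roundoff.

The registry is data-driven: names follow
`<family>.<statistic>[.<orientation|level|threshold|bin>]` in a fixed
order, and the per-family counts (76/16/93/48/60/33/37, total 363) are a
hard contract asserted by the tests. The individual statistics within each
family are a reconstruction constrained by those counts; other software
implementing the same families may differ in detail.

## Preselection

Features with |sample skewness| > 10 are dropped (an automated stand-in for
visual box-plot screening; the threshold is a config knob). The remainder
is randomly ordered (seeded) and pruned greedily: a feature is dropped when
its |Spearman ρ| with a higher-ranked retained feature exceeds 0.98.
Absolute correlation is used deliberately — a sign-flipped duplicate is
just as redundant. Constant features have undefined rank correlation and
are treated as uncorrelated. The four central moments and the 16 histogram
bins are re-added unconditionally. Preselection uses no outcome
information and is run once on the full table, never inside CV folds.

## PMD regression and tuning

* **Univariate selection** — per-feature F statistic (= squared t of the
  simple-regression slope), features ordered by increasing p; λ = number
  of top features in an OLS model, grid 1..150 (capped by p and n−2).
* **Lasso** — objective (1/2n)·RSS + λ·Σ|β|, unpenalized intercept
  (scikit-learn's coordinate descent); default grid: 20 geometric steps
  from the smallest fully-sparsifying λ down three decades.
* **Boosting** — L2Boost with simple linear base learners: start from the
  mean, per iteration update the coefficient of the feature whose base
  learner most reduces the residual sum of squares by step × its
  least-squares slope. Step 0.1; iteration grid 10..2000. One path run
  serves the entire grid, which keeps the inner CV cheap.
* **Random forest** — 500 trees, bootstrap resampling; λ = mtry over
  {p/10, p/5, p/3, p/2} rounded; tuned by out-of-bag MSE instead of CV.

Features are standardized to unit variance inside lasso and boosting and
coefficients returned on the original scale. λ is chosen by 10-fold CV of
the mean held-out MSE (folds fixed by seed and shared across the grid),
smallest λ on ties. Predictions are not clipped to [0, 100]: the masking
model consumes them linearly.

## Masking model fitting

Maximum-likelihood logistic regression via statsmodels' Newton iterations
(up to 100, parameter tolerance 1e-8), standard errors from the observed
information matrix. Single-class outcomes raise; perfect separation
surfaces as a fit error with a diagnostic. The fitted model satisfies the
logistic score equation (mean fitted risk = observed prevalence), which
the tests assert to 1e-6.

## Evaluation

* **MSE** — Brier-type mean of (status − risk)².
* **AUC** — Mann–Whitney with ties counted ½, computed from midranks; the
  ROC curve (scikit-learn) integrates to the same number, and a constant
  predictor (the null model) scores exactly 0.500.
* **Continuous NRI** — events count as correctly reclassified when the new
  model raises their risk, nonevents when it lowers it; ties count toward
  neither; NRI = [P(up|event) − P(down|event)] + [P(down|nonevent) −
  P(up|nonevent)] ∈ [−2, 2]. Without ties this equals
  (2·P(up|event) − 1) + (2·P(down|nonevent) − 1).
* **Discovery rates** — per percent cut-off c: the share of the whole
  population with risk > c/100, and the same share among true masked
  tumors.

The double CV uses stratified outer folds (with ~8% prevalence,
unstratified 3-fold splits risk event-free folds). Per-repetition fold
seeds derive from the master seed through `numpy.random.SeedSequence`
counters, so runs are reproducible across platforms. All tuning and
fitting happens strictly on the outer-training two-thirds; summary values
are arithmetic means/SDs over all repetition × fold records.

## Synthetic data

Images: white noise smoothed by an isotropic Gaussian kernel of width
`texture_scale` (a Gaussian random field — cloudy, spatially correlated
texture that keeps co-occurrence and run-length features non-degenerate),
inside an axis-aligned half-ellipse mask covering ~57% of the frame, then
monotonically rescaled per image so the fraction of masked pixels ≥ 128
equals the target PMD within one percentage point. Background pixels are 0.

Cohorts: age, BMI and PMD are normal draws (PMD truncated to [0, 100] by
resampling); surgery and digital technique Bernoulli; menopausal/HRT
status categorical. The default marginals (`REFERENCE_COHORT_PARAMS`) are
the weighted mixture of the masked/non-masked group summaries of the
reference cohort (age ≈ 59.6 ± 12.6 y, BMI ≈ 26.2 ± 4.7 kg/m², PMD ≈ 35.8
± 19.0%, 13.1% prior surgery, 23.6/56.1/20.2% menopausal mix, 38.8%
digital). Covariates are drawn independently — the source cohort reports
no correlation structure, so independence is an assumption of the
generator, not of the data it emulates. Masking is Bernoulli with
probability given by the reference logistic model at the drawn covariates.

What passing tests therefore show: the pipeline's statistical machinery is
correct (counts, oracles, parameter recovery, ordering of model AUCs when
a true density signal exists). What they do not show: performance numbers
on real mammograms — synthetic images encode density almost noiselessly in
the histogram features, so predicted-PMD models approach the observed-PMD
model more closely than texture features would on film-digitized images,
and independent covariates make the clinical-only model weaker than in a
real cohort where age, BMI and density are correlated.

## Problem sizes used in the shipped checks

The acceptance script recovers coefficients from one simulated cohort of
n = 200,000 (at that size the intercept's Monte Carlo SE is ≈ 0.07, the
PMD slope's ≈ 0.0005) and measures the null-model AUC on a 600-patient
cohort with 3 repetitions × 3 folds. The pipeline-ordering test runs the
full image → features → preselection → boosting → double-CV chain at
n = 1334 patients with 64×64 images and 10 repetitions × 3 folds — the
ordering clinical < predicted-PMD ≤ observed-PMD is a property of the
generative model, not of a particular image resolution, and 64×64 keeps
the chain comfortably reproducible on one CPU.

## Known limitations

* The exact member statistics of each feature family are a reconstruction
  under the fixed family counts; numerical values are not interchangeable
  with other texture packages.
* The skewness threshold (10) replaces a human visual screening step; on
  real data the excluded set would differ.
* DICOM ingestion, film-digitizer artifacts and reader variability between
  human PMD readers are out of scope; the fixed density threshold (128)
  stands in for the per-image threshold a reader would choose.
* No confidence intervals for AUC/NRI; the repeated-CV SDs describe fold
  variability, not sampling uncertainty of a future cohort.
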