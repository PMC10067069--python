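# Methods

## The analysis

`omrs` implements a patch-based prognostic analysis of oral mucosa
histology. A slide image is tiled into non-overlapping 300 × 300-pixel
patches on a grid anchored at pixel (0, 0); partial windows at the right
and bottom edges are discarded so every patch satisfies the classifier's
fixed input contract. A four-class patch classifier emits a probability
vector over (white background, connective tissue, nondysplastic epithelium,
tumor epithelium); the argmax grid is the slide's class heatmap, with
probability ties resolved to the lowest class index in that fixed order.

For risk scoring the two epithelium classes are collapsed: grid cells whose
argmax is either epithelium class form the epithelium mask, and only those
cells contribute. Each epithelium patch is scored by its *tumor-likeness*

    u = p_tumor / (p_tumor + p_nondys),

the tumor probability renormalized over the two epithelium classes. The
renormalized form is the default because it is insensitive to residual
probability mass on connective tissue or background; the raw `p_tumor`
variant is available (`variant="raw"`). The **slide risk score** is the
median of `u` over the slide's epithelium patches (mean-of-two-middle
convention for even counts). A cohort is stratified by ranking patients on
their slide score (ties broken by patient id for reproducibility) and
splitting at the median: the lower half is "low risk", the upper half
"high risk", and for odd cohorts the middle-ranked patient joins the low
group, so the groups differ in size by at most one.

Note one intrinsic property of the median aggregate: it tracks the
*majority* character of the epithelium, not the mean. When per-patch
likeness values are saturated near 0/1, the slide score is a step function
of the tumor-tile fraction (jumping near 50%), and exact agreement between
the score and the tumor fraction only holds toward the extremes. This is a
property of the statistic, not an implementation artifact; the rank
ordering of slides remains monotone in the tumor fraction, which is what
the downstream median split consumes.

## Statistics

All inferential statistics are implemented from first principles (SciPy is
used only for distribution functions and mid-ranks):

* **Odds ratio** (a·d)/(b·c) with the Woolf log-normal CI,
  exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d)). Any zero cell triggers the
  Haldane–Anscombe +0.5 correction of all cells, and the result is flagged.
* **Fisher's exact test**, two-sided by the point-probability criterion:
  the p-value sums hypergeometric probabilities of all tables with the
  observed margins whose probability does not exceed the observed table's
  (relative slack 1e-12 against floating ties), by full enumeration.
  Two-sided Fisher conventions differ between packages; this one matches
  the common default of SciPy and R.
* **Kaplan–Meier** product-limit estimator with Greenwood variance.
  Subjects censored at an event time remain at risk at that time.
  Pointwise CIs use the log transform by default, S·exp(±z·se(log S)) with
  Var(log S) = Σ d/(n(n−d)); plain Greenwood is selectable. Evaluation is
  right-continuous, and queries beyond the last observed follow-up return
  the final value flagged as extrapolated. A sample with no events yields
  a degenerate constant-1 curve, flagged rather than raised.
* **Two-group log-rank test** with the hypergeometric variance and a
  1-df chi-square reference.
* **Cox proportional hazards** by Newton–Raphson on the partial
  likelihood with the Efron correction for tied event times (Breslow
  selectable; Efron is the default because calendar-resolution follow-up
  data routinely carries ties). Step-halving guards each Newton step;
  convergence requires a log-likelihood change below 1e-9 *and* a score
  vector below 1e-6 in max norm (so the returned optimum is genuinely
  stationary), capped at 100 iterations. Wald CIs and p-values come from
  the inverse observed information; a covariate with no information gets
  an infinite SE, p = 1 and a (0, ∞) CI rather than a crash. Monotone
  likelihood (perfect separation) is detected by a coefficient exceeding
  20 in absolute value (a hazard ratio beyond e^20) and flagged with
  `converged=False`.

The default multivariate model adjusts the risk group for age, lesion site
(tongue vs other) and binary dysplasia grade — the standard adjustment set
for this cohort type.

ROC curves are computed one-vs-rest by threshold sweep with tied scores
collapsed to single points, and the trapezoidal AUC is verified against the
Mann–Whitney mid-rank estimate to 1e-9 on *every* evaluation call; a
mismatch raises, since the two are mathematically identical.

## Classifiers

Two desk-scale, CPU-trainable architectures are provided, both written in
NumPy and operating on six summary features per patch (per-channel mean and
standard deviation):

* `color_feature_baseline` (default): multinomial logistic regression,
  full-batch gradient descent, L2 penalty 1e-3, learning rate 0.5,
  60 epochs. The L2 penalty intentionally keeps probabilities away from
  hard saturation on separable data, so tumor-likeness retains a usable
  dynamic range.
* `small_mlp`: one tanh hidden layer (16 units) on the same features,
  minibatch SGD. It exists to demonstrate the training/evaluation contract
  with a nonlinear model; on the synthetic textures both models reach the
  same (perfect) accuracy.

Stain color and cellularity move both the channel means and SDs, so these
features separate tissue classes that differ in either. Deeper image
models can be plugged in behind the same `train`/`predict`/`evaluate`
surface; they are not needed for the synthetic benchmark and are not
bundled. Models serialize to a versioned JSON checkpoint.

Training patches are labelled from annotation masks with a purity rule:
pixels marked as technical artifact are excluded; a patch with more than
50% excluded pixels is dropped ("artifact"), and otherwise the majority
class must cover at least 90% of the remaining pixels ("low_purity"
otherwise). Both thresholds are configurable. Train/validation/test splits
are made at the slide level (largest-remainder apportionment of a 60/20/20
default) so patches from one slide never straddle sets.

## Synthetic data model

The generator emulates exactly the data features the pipeline consumes.

**Textures.** Each tissue class is rendered as Gaussian color noise around
a class mean, plus dark circular "nuclei" placed by a Poisson draw per
300-pixel tile, plus a per-tile constant RGB offset ("stain jitter")
emulating regional staining variation. Class defaults are loosely H&E-like:
near-white acellular background; pale eosinophilic connective tissue with
sparse small nuclei; pink-purple nondysplastic epithelium with moderate
nuclear density (35 nuclei/tile); darker, hypercellular tumor epithelium
(80 nuclei/tile). The Poisson nuclear counts and the stain jitter give
patch-level features a realistic within-class spread — without them every
tile of a class would be feature-identical (the mean over 90,000 pixels
averages pixel noise away), per-tile tumor-likeness would collapse to two
point masses, and slide medians would tie pathologically.

**OL slides.** An epithelium region aligned to the tiling grid is
partitioned into tiles; each tile independently receives the tumor texture
with probability θ, else the nondysplastic texture. The assignment is at
tile granularity because the downstream unit of classification is the
patch. The realized assignment is recorded in the ground-truth mask and θ
on the slide. Spatially clustered (rather than independent) tumor regions
are a possible extension; the median score is permutation-invariant over
patches, so clustering would not change slide scores at fixed tumor
fraction, only the fraction's sampling variance.

**Cohorts.** Per patient, θ ~ Beta(α, β) drives an exponential progression
time with proportional hazard h₀·exp(β_h·θ), drawn by inverse CDF;
follow-up is administratively censored at a fixed horizon (no random
dropout). Covariates (age, gender, site, dysplasia, prior carcinoma,
AVEH) are drawn independently of θ from fixed marginal frequencies
matching a typical leukoplakia case mix, so multivariate recovery tests
have a known truth: the group indicator carries the hazard signal and the
covariates carry none. Defaults: n = 62 patients, θ ~ Beta(0.8, 0.8),
h₀ = 0.03/yr, β_h = ln 3, censoring at 10 years — which yields ≈ 40%
progression over follow-up, the scale reported for leukoplakia cohorts of
this kind.

**What the generator does not emulate:** real H&E morphology (cytology,
architecture, texture), stain protocol variation, scanner artifacts,
pyramidal WSI formats, informative censoring, or covariate–risk
confounding. Passing the synthetic benchmark therefore demonstrates that
the pipeline machinery is correct and that the median-score mechanism
recovers a known epithelial mixture signal — not that any particular
classifier generalizes to clinical slides.

## Evaluation experiment design

Experiment sizes were fixed by a-priori power analysis and are deliberate
desk-scale choices:

* **Classifier benchmark:** 12 four-band training slides (1200 × 900),
  slide-grouped 60/20/20 split, 192 patches. The default textures are
  separable by design, so the benchmark asserts ≥ 95% held-out accuracy
  and ≥ 0.99 epithelium AUCs.
* **Monotonicity experiment:** 8 OL slides at each θ ∈
  {0, 0.25, 0.5, 0.75, 1}, 36 epithelium tiles per slide. The tile count
  matters: the shift of the slide median between adjacent θ levels is a
  fixed quantile offset while its sampling noise shrinks as 1/√(tiles), and
  36 tiles puts the Spearman correlation across 40 slides above 0.9 with
  ≈ 99% probability under the texture model.
* **Cohort replicates:** 20 replicates of n = 200 patients,
  θ ~ Beta(0.4, 0.4) (a polarized case mix), h₀ = 0.03, β_h = ln 3,
  censoring at 15 years, 6-epithelium-tile slides. Under these conditions
  the univariate Wald test on the median-split group indicator has ≈ 95%
  power, so requiring significance in ≥ 80% of replicates is a stable
  check of the end-to-end mechanism.
* **CI calibration:** 100 cohorts of n = 500; the Wald 95% CI for the θ
  coefficient must cover the generating ln 3 in ≥ 93 of them.

## Known limitations

* The classifiers are feature-based; they cannot learn spatial morphology
  and are not a substitute for a deep image model on real slides.
* The Fisher test's full enumeration is exact but O(n) per table — fine
  for cohort-scale tables, not for n in the millions.
* Cox fitting covers right-censored data with Efron/Breslow ties only: no
  time-varying covariates, stratification, or robust variance.
* Heatmap export is one pixel per patch; no smoothing or morphological
  post-processing is applied.
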