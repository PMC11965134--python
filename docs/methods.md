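# Methods

## The signal model

A diffusion-weighted voxel is modeled as a mixture of four water
populations, each decaying with its own apparent diffusivity as the
diffusion weighting `b` increases:

    S(b)/S(0) = f_r exp(-D_r b) + f_h exp(-D_h b^alpha_h)
              + f_ui exp(-D_ui b) + f_f exp(-D_f b)

* **restricted** (`D_r`, `f_r`): water trapped by membranes, `D_r < 0.2
  um^2/ms`. Dominates the high-b plateau; in tumors it tracks cellularity.
* **hindered** (`D_h`, `f_h`, `alpha_h`): extracellular water slowed by
  tortuosity, `0.2 <= D_h <= 3 um^2/ms`. Its decay is stretched-exponential;
  `alpha_h < 1` means a broad intra-voxel distribution of hindered rates
  (more microstructural heterogeneity), `alpha_h = 1` recovers a pure
  mono-exponential.
* **unimpeded** (`D_ui = 3 um^2/ms`, `f_ui`): free-water-like diffusion.
  `D_ui` is a fixed constant, not a fitted parameter: free water at body
  temperature diffuses at about 3 um^2/ms, and letting it float would be
  collinear with the upper range of `D_h`.
* **flow** (`D_f`, `f_f`): perfusion/pseudo-diffusion, `3 < D_f <= 100
  um^2/ms`, visible only at very low b.

Fractions are non-negative and sum to one, so `S(0)/S(0) = 1` exactly.
Only the hindered term is stretched; the stretching describes heterogeneity
of the hindered pool specifically.

**Units.** b-values are stored in ms/um^2 (`1 ms/um^2 = 1000 s/mm^2`) so
`D*b` is dimensionless. In the stretched term the numeric value of b in
ms/um^2 is raised to `alpha_h`; `b^alpha` is not dimensionally clean for
any unit choice, so the convention is fixed and stated rather than hidden.

`alpha_h` is allowed up to 2.0: reported ROI means near 0.9 with SDs near
0.4 imply voxel values above 1 occur, and a hard cap at 1 would truncate
them.

The mono-exponential reference model is `S(b)/S(0) = exp(-ADC b)`, with ADC
obtained by ordinary least squares of `ln S` on b over **all** b-values
(0-3000 s/mm^2). Over such a range the true decay is multi-exponential, so
this ADC is a standardized summary, not a physical diffusivity.

## The acquisition scheme

The default scheme is 12 b-values, 0-3000 s/mm^2
(0, 20, 50, 100, 200, 500, 800, 1000, 1500, 2000, 2500, 3000) with per-b
averaging counts (NEX) 1,1,1,1,1,2,3,3,4,6,8,9. Averaging reduces noise SD
by sqrt(NEX), which matters at high b where the signal is small. Six or
more distinct b-values are required before a MAD fit is attempted (the
model has 8 free quantities).

## Fitting

Per voxel the measured curve is normalized by its own measured S(0) and fit
by bound-constrained trust-region least squares
(`scipy.optimize.least_squares`, TRF) over seven free parameters: `D_r,
D_h, D_f, alpha_h` and three fractions; `f_ui` is the remainder
`1 - f_r - f_h - f_f`, kept non-negative by a penalty residual. Residuals
are unweighted model-minus-data differences.

Four-exponential least squares has local minima, so the fit is
multistarted (`n_multistart`, default 8): one start from a segmented
log-linear heuristic (flow rate from the slope over b <= 0.1, hindered rate
from 0.2 <= b <= 1.0, restricted fraction from the b >= 2.0 plateau), and
the rest alternating between seeded jitter around that start and draws
dispersed over the whole feasible box. The dispersed starts exist because
the heuristic cannot reach basins where `D_h` sits near the fixed unimpeded
rate. Lowest residual wins; exact ties go to the earliest start, so results
are bit-reproducible for a fixed seed. A voxel whose optimizer never
converges is recorded as NaN in every map and excluded downstream rather
than imputed.

Tolerances default to 1e-14 (`ftol`/`xtol`): the noiseless-recovery
guarantees below need the optimizer to polish to machine level, and with 12
data points the extra iterations are cheap. Signals at or below
`min_signal_floor` (default 1e-6 of S(0)) are dropped from log fits, with
the used count recorded.

## The synthetic generator

The generator emulates the study conditions the analysis assumes:

* the 12-b scheme with its NEX counts;
* Rician magnitude noise: each averaged sample is the mean of NEX draws of
  `|s + eta_1 + i eta_2|`, `eta ~ N(0, sigma)` per channel, with `sigma`
  quoted relative to S(0) (a Gaussian mode exists for debugging);
* two subject groups (low- vs high-grade clear cell renal cell carcinoma)
  whose ROI-mean parameters follow published group means and SDs; the two
  quantities published as median (IQR) use the median as mean and
  IQR/1.349 as SD. Default group sizes are 30 low / 24 high, the study's
  cohort.

Draws are independent truncated normals per quantity, truncated to the
physical bounds, with fractions renormalized to sum to one afterwards. The
published fraction means themselves sum to 0.967 (low) and 0.992 (high) —
the expected signature of averaging independently fitted voxel maps — so
for signal synthesis they are renormalized; when one specific fraction's
printed value is the quantity under test, that fraction is held fixed and
the other three absorb the rescaling.

What the generator does **not** emulate: parameter covariance within a
subject (the published summaries carry none, so quantities are drawn
independently; in the cohort the ADC is drawn from its own published
summary rather than derived from the MAD draw), anatomy, partial volume,
motion or eddy artifacts, and spatial noise correlation. Passing tests
therefore show that the estimator and statistics chain is correct under
the stated noise and population model, not that it is robust to scanner
physics beyond that model.

Phantoms assign each lesion voxel an independent draw from its grade's
distribution, synthesize the clean curve, scale by a stated S(0), and add
Rician noise; background voxels are pure noise and truth maps are stored
alongside.

## ROI statistics and group comparison

Per subject, maps are averaged over the reader's ROI (NaN voxels excluded,
effective count recorded); two readers' means are averaged again. Only the
mean is carried forward — medians and quartiles are available but not part
of the pipeline.

The group comparison is gated: one-sample Kolmogorov-Smirnov against a
normal with estimated mean/SD per group, and a two-sided F-test for
variance equality, both at alpha = 0.05. Both groups normal and variances
even: pooled-variance t-test, summarized as mean +/- SD. Otherwise:
two-sided Mann-Whitney U, summarized as median (Q1, Q3). Estimating the KS
reference parameters from the sample makes the gate conservative (the
Lilliefors caveat); this matches common statistical-software behavior and
is accepted rather than corrected. The F-test sits behind the gate
interface so a robust alternative (e.g. Levene) can be substituted.

Cohen's d is always the pooled-SD form
`|m1 - m2| / sqrt(((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2))`. No
multiple-comparison correction is applied by default (the nine-parameter
screen is exploratory); Bonferroni and Benjamini-Hochberg are options.

## Diagnostic evaluation

High grade is the positive class. Each marker's empirical ROC is computed
over all distinct thresholds with AUC by the trapezoid rule; orientation is
auto-chosen so AUC >= 0.5 and recorded, since some markers fall with grade
(D_h, ADC) and others rise (f_r). The operating point maximizes Youden's
J = sensitivity + specificity - 1, ties resolved toward higher specificity
(Youden is the field default where no rule is stated; the criterion is
isolated for substitution). The 95% AUC interval is DeLong's nonparametric
estimator, clipped to [0, 1].

The combined marker is the in-sample predicted probability of a
maximum-likelihood logistic regression on `D_h`, `f_r`, `alpha_h`
(features standardized internally, coefficients reported on the original
scale). In-sample evaluation matches the single-cohort design and is
optimistic relative to cross-validation; a separated fit (possible at
n = 54) falls back to a weakly ridge-penalized fit and is flagged
unconverged.

## Validation strategy and known limitations

* **Noiseless recovery** is exact: curves generated from the published
  group means on the 12-b scheme are refit to within 2% (restricted
  fraction to 0.005 absolute), and a 50-draw suite over the identifiable
  interior of the parameter space recovers every quantity at the same
  tolerance. The draws keep each fraction at or above 0.05 and `D_h` away
  from its bounds: at compartment collapse (`f_h -> 0` leaves `alpha_h`
  free; `D_h -> 3` is collinear with the fixed unimpeded term) the model is
  structurally non-identifiable and recovery is undefined for any fitter.
* **Noisy voxelwise estimates are biased for the small parameters.** At
  SNR 50 (sigma = 0.02 of S(0)) the Fisher information of the 12-point
  scheme gives unconstrained standard deviations far above the parameter
  values themselves (about 0.46 for `f_r` whose true value is 0.06; about
  1.0 for `alpha_h`); the box constraints keep estimates finite, and the
  constrained estimator's median is then biased upward by roughly 25-35%
  for `f_r` and `alpha_h` on a 100-voxel tissue, while `D_h` medians stay
  within a few percent. NEX-weighted residuals and a free S(0) scale were
  both evaluated and made matters worse; Rician-bias correction and spatial
  regularization are out of scope. Consequence: voxelwise `f_r` and
  `alpha_h` maps at clinical SNR should be read as contrast, not as
  calibrated values; ROI-level analysis, which averages before comparing,
  is the supported inference path.
* **Statistical behavior** is checked at the study's scale: across 100
  synthetic cohorts (30/24), the restricted fraction comes out significant
  in >= 90% of seeds and the combined logistic marker's mean in-sample AUC
  is at least the best single marker's. Published patient-data values
  (group means, AUCs) are inputs to the generator, not reproduction
  targets — the patient images are not public.
* Problem sizes in the test suite (100 voxels per tissue for phantoms,
  2000-draw moment checks, 100-seed cohort sweeps) were chosen as the
  smallest sizes at which the Monte-Carlo error is well below each test's
  tolerance.
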