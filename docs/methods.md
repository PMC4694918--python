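# Methods

## Model and procedure

The pipeline identifies candidate tumor-suppressive miRNAs by
pharmacologic unmasking and carries them through to a prognostic
signature. Its statistical core is four small, explicit procedures.

**Fold-change screen.** Intensities are treated as normalized linear
single-channel array values; within an arm, replicate samples of a
cell line are averaged before ratios are formed. The selection rule —
fold ≥ `fold_threshold` (default 1.5, inclusive per "1.5 fold or
more") in ≥ `min_lines` (default 2) cell lines — counts only lines
where both arms are detected. A "not detected" call (either arm below
`detection_floor`) is neutral: the bundled worked example selects a
miRNA with only two numeric entries, which forces this reading —
n.d. cannot be disqualifying. `detection_floor` defaults to 0
(everything detected) so data without detection calls lose nothing.
Whether the threshold should be applied to linear or log2 intensities
is not fixed by convention; the implementation applies it to linear
ratios and exposes both the floor and the threshold as parameters. An
optional per-sample 75th-percentile scaling stands in for upstream
array normalization when only raw intensities are available; the
screen itself consumes only ratios.

**Two-group methylation tests.** Beta values (fraction methylated,
[0, 1]) are compared tumor-vs-normal with the pooled-variance
Student's t-test by default (Welch and Mann–Whitney U are options).
Probes link to a feature when within ±`tss_window` (default 2,000 bp,
a conventional promoter-proximal window; "near the TSS" has no
canonical width) of its TSS, with strand-signed distance. Region-level
testing averages a feature's linked probes within each sample first —
the simplest aggregation consistent with per-feature reporting; both
probe and region levels are provided because published figure-level
analyses rarely state which was used. Degenerate inputs follow a fixed
rule: zero spread in both groups gives p = 1 on equal means, p = 0
otherwise (flagged). Raw p-values are reported by default (the
figure-style analysis this mirrors used unadjusted asterisks);
Benjamini–Hochberg is a toggle. Box-plot summaries use min/max
whiskers and linear-interpolation quartiles, stated explicitly because
quartile conventions differ.

**Consensus voting.** The denominator of "at least half of available
algorithms" is per miRNA: aggregation databases expose different
algorithm panels per miRNA, so availability is a mask excluded from
both numerator and denominator. The threshold is the exact rational
`rule_fraction × n_available` compared with ≥ — no rounding (4 of 7
passes at one half). A global-denominator mode exists for sensitivity
analysis. The differential-expression gate uses the linear fold change
of group means with a two-sample t on log2 values and BH adjustment
(the minimal defensible default; the test is pluggable), with an
inclusive fold gate and a strict adjusted-p gate.

**Survival signature.** Univariate Cox fits use Newton–Raphson with
step halving on the Breslow partial log-likelihood, convergence at
|score| < 1e-8, at most 100 iterations; the fitter is single-covariate
by construction because the screen fits one gene at a time (thousands
of fits), and it reproduces `lifelines` coefficients to ~1e-8 on
non-degenerate data (asserted in tests). Perfect separation makes the
partial likelihood monotone; the fitter detects the vanishing
curvature, marks the fit non-converged and warns rather than reporting
the arbitrary stopping point as an estimate. Genes enter the signature
at Wald p < α (default 0.05), split by coefficient sign. The risk
score RS = U − D uses per-sample medians of the C⁺ and C⁻ gene groups;
when several probesets map to one gene their per-sample median should
be taken first, and signature genes missing from a validation platform
are dropped from their group with a logged count. "Equally-spaced
levels" is read as equal-width bins over the observed RS range — the
phrase describes the scale, not the group sizes; a quantile mode would
be trivial for sensitivity analysis but equal-width is the default and
the tested behavior. The last bin is right-closed so the maximum RS
lands in the top level. The association model enters the level as a
single numeric covariate (ordinal trend), matching the reporting of
one hazard ratio per dataset; a categorical (level-vs-reference) mode
is available. Kaplan–Meier curves per level come from `lifelines` and
are checked against the hand product-limit formula in tests.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* each stage
assumes, with planted truth:

- screen: log-normal baselines (log2 intensities normal, mean 7,
  sd 1.5 — typical single-channel array scale), treated-arm fold
  effects drawn uniformly from 2–8× on a random subset of ≥ 2 of 4
  lines, log2-normal noise (sd 0.25 by default). Panel-scale defaults
  (1,205 miRNAs, 74 silenced) mirror the array design the pipeline was
  built around.
- methylation: per-probe baselines uniform in [0.05, 0.2] (unmethylated
  promoters), Gaussian sample noise, an additive tumor shift
  `delta_beta` (default 0.3) on candidate probes, clipped to [0, 1];
  17 tumor vs 5 normal samples by default.
- predictions: 12 algorithms, per-(algorithm, miRNA) availability
  Bernoulli(0.8) with at least one available algorithm guaranteed,
  calls Bernoulli(sensitivity = 0.9 on true pairs, fpr = 0.05
  otherwise).
- survival: standard-normal expression, true RS computed by the same
  median-difference formula from planted C⁺/C⁻ sets, exponential event
  times with hazard `baseline_hazard · exp(beta_rs · RS)`
  (baseline 0.015/month ≈ 46-month median at RS = 0), independent
  Uniform(0, c) censoring with c solved by root-finding so the
  expected censored fraction equals `censor_rate` (default 0.3).

The planted signature defaults to 8 C⁺ / 6 C⁻ genes among 120. This is
a deliberate power choice: a gene contributes roughly 1/k of its
group's median, so the marginal per-gene log hazard ratio scales as
`beta_rs / k`; with k around 19 at beta_rs = 0.7 and n = 1000 the
per-gene Wald z would sit near 1 and no univariate screen could
recover the set — the recovery tests would measure noise, not the
code. Modest group sizes keep individual genes detectable at realistic
cohort sizes while exercising the identical code path.

Not emulated: probe hybridization chemistry and raw-array artifacts,
batch effects, cross-reactive probes, miRBase version drift,
platform-specific probeset multiplicity, and non-proportional hazards.
Passing tests therefore show the procedures are correct and calibrated
under the assumed structure; they do not show robustness to the
technical artifacts of real arrays.

## Numerical and calibration choices

- Cox: Breslow tie handling throughout (ties are common in discretized
  follow-up); score tolerance 1e-8; 95% CI = exp(coef ± 1.96·se).
- The null calibration of the association test is evaluated with a
  *fixed* a-priori signature under beta_rs = 0. Re-screening genes at
  α = 0.05 on a cohort and then testing the resulting score on the
  same cohort is circular (selection and test share the data) and
  inflates the type-I error by construction; cross-cohort validation
  is the correct use, exactly as a signature derived on one dataset is
  validated on independent ones.
- Problem sizes in tests and in `scripts/acceptance.py` (20 simulated
  cohorts of n = 1000 for recovery; 200 cohorts of n = 200 for null
  calibration; 600-miRNA screens) were chosen as the smallest designs
  at which the Monte-Carlo error of each estimate is well below its
  acceptance band.
- Seeds: all generators take explicit integer seeds
  (`numpy.random.default_rng`); identical seed + parameters give
  identical output, and the pipeline summary is byte-reproducible.

## Known limitations

- The Cox fitter is single-covariate only (by design); multivariate
  adjustment, time-dependent covariates and competing risks are out of
  scope.
- The DE gate assumes two groups and roughly log-normal intensities;
  count-based expression data would need a different test behind the
  same interface.
- Equal-width RS binning is sensitive to RS outliers (they stretch the
  range); the numeric-trend association is, however, invariant to any
  affine transformation of RS, which bounds the practical impact.
- The probe annotator is a plain windowed join, adequate for promoter
  windows at array scale; genome-scale interval work should use a
  dedicated interval library.
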