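# Methods

## What the package simulates and why

Illumina BeadChip methylation arrays measure up to ~850,000 CpG sites per
sample, with 8 samples per chip (at fixed row positions) and 12 chips per
plate.  Row, chip and plate are technical *batch factors*: samples sharing
a position are measured under shared conditions, so systematic offsets
between positions (batch effects) are essentially unavoidable.  The common
remedy is the ComBat empirical-Bayes location/scale adjustment, often
applied through integrated pipelines that pass the outcome-of-interest
variable into the correction's model matrix automatically.

This package quantifies a failure mode of that remedy: applied to data that
contain *no* signal at all, the correction can manufacture false positives.
Because real data can always harbour true effects, the cleanest way to
expose the problem is simulation from pure noise — any "significant" probe
found downstream is false by construction.  The package generates such
data, arranges samples on the physical plate/chip/row hierarchy under
different case/control designs, optionally injects small batch offsets,
corrects them, and measures the damage.

## The generative model

Every probe *j* has a mean `mu_j` and standard deviation `sigma_j` on the
beta-value scale (methylated fraction, in [0,1]).  Each simulated value is
an independent draw from Normal(mu_j, sigma_j^2), clamped into
[eps, 1-eps] with eps = 0.001 so that the logit (M-value) transform stays
finite.  There is no probe-probe correlation and no sample effect: the
null is exact.

When no empirical parameter table is supplied (`load_parameter_table`
accepts one, with a configurable column mapping), `emulate_parameter_profile`
draws a synthetic profile with the hallmark features of a whole-blood EPIC
profile:

* means from a three-component Beta mixture — Beta(5,45) (hypomethylated,
  weight 0.45), Beta(45,5) (hypermethylated, 0.45), Beta(8,8)
  (intermediate, 0.10) — giving the canonical bimodal beta landscape;
* SDs from a log-normal with median 0.02 and log-scale sigma 0.6, clipped
  to (1e-4, 0.5].  Blood-derived EPIC probes typically have small,
  right-skewed SDs with a median near 0.02 beta units; the batch-offset
  amplitude (0.01) is therefore comparable to typical probe noise, as it
  is in practice;
* a design-type label (I/II, 16%/84%) carried for schema realism only —
  no type-specific normalization is applied, because the data are
  generated directly on the beta scale and the inflation mechanism under
  study does not involve intra-sample normalization.

Platform sizes are configuration, not constants: 27K/450K profiles are
uniform subsamples of the EPIC profile (defaults 27,000 / 450,000 /
758,289 probes).

## Sample designs

`assign_groups` encodes three canonical case/control arrangements at even
n (labels split exactly n/2 : n/2):

* **balanced** — within every chip, case rows alternate, with the phase
  shifted between chips: each chip is 4/4 and every row position hosts
  each group equally often across chips.  Group is orthogonal to both row
  and chip.
* **unbalanced** — cases fill chips contiguously, with the two chips at
  the group boundary split 4/4 by row.  This is the *maximal estimable*
  confounding: with whole chips per group the outcome is a linear
  combination of the chip indicators, no location/scale model can protect
  it, and reference implementations refuse the design outright (verified
  against the R reference).  The boundary split leaves a fixed, small
  number of within-chip contrasts carrying all the information about the
  group effect — which is exactly what makes outcome-protected correction
  so dangerous here: the group-effect estimate, pinned by a handful of
  boundary samples, is imprinted on every sample while the correction
  strips the between-chip variability that should have tempered the
  downstream test.  Because the informative boundary does not grow with
  n, the induced inflation *increases* with sample size, reproducing the
  qualitative signature of the original study design.  A user-constructed
  perfectly confounded layout is still accepted: the correction then
  drops the protected covariate for that factor with a loud warning and
  flags the fit.
* **random** — a uniform random permutation of the labels.

## The correction

`combat_fit`/`combat_apply` implement parametric empirical-Bayes batch
adjustment from scratch, faithful to the reference implementation to
machine precision (pinned by an elementwise oracle test against
`sva::ComBat` at 1e-6, actual agreement ~1e-14):

1. per-probe OLS over batch indicators plus (optionally) the protected
   outcome indicator; pooled variance uses the 1/n convention;
2. standardization; per-batch location (`gamma_hat`, batch means) and
   scale (`delta_hat`, batch variances, ddof 1) of the standardized data;
3. method-of-moments hyperpriors — normal across probes for locations,
   inverse-gamma for scales;
4. per-batch fixed-point iteration for the posteriors to relative
   tolerance 1e-4 (max 500 iterations; non-convergence warns, never
   aborts).  The stopping rule divides by the *signed* previous location,
   mirroring the reference exactly — probes with negative locations
   contribute negative ratios and never dominate the max.  This quirk is
   retained deliberately: without it, agreement degrades to ~1e-5.

A single-level batch factor is corrected as the identity (there is no
batch structure to remove); the reference errors on this input, so the
identity is this package's own, documented, choice.  Only the parametric
prior pathway exists; `parametric=False` raises.

Multi-factor correction (`sequential_correct`) loops over factors in
order, feeding each pass's output to the next — the EB model itself is
single-factor.  Correction operates on M-values, `log2(beta/(1-beta))`,
by default (matching integrated pipelines' default logit transform), with
`on_mvalues=False` available since direct calls on the beta scale are
also used in the wild.

The scikit-learn estimator `ComBatCorrector` wraps the same fit/apply
pair with `fit(X, y, batch=...)`/`transform` semantics on samples x
features matrices.

## The readout

`fit_dmp` tests each probe with the two-group linear model and
empirical-Bayes variance moderation: hyperparameters (d0, s0^2) come from
the method of moments on log residual variances (with the trigamma-inverse
Newton solve), the moderated t uses the shrunken variance and d0 + df
degrees of freedom (capped at the pooled df).  Agreement with the
independent reference (`limma::eBayes`) is pinned at 1e-8 on a fixture
(actual ~1e-14).  `moderated=False` recovers the ordinary pooled t-test
exactly, as an analytic cross-check.  Testing happens on the beta scale
(effects in beta units), as the integrated pipelines do.

Run-level metrics: arithmetic mean p across probes; the genomic inflation
factor `lambda = median(chi2_1-quantile(1-p)) / 0.4549...` (1 under
calibration); counts of Benjamini-Hochberg q < 0.05 and Bonferroni p <
0.05 probes (both via the standard step-up, cross-checked against a
brute-force implementation).  Q-Q points use (i - 0.5)/m expected
quantiles.

## Batch injection and spike-ins

Injected batch effects model a brightness offset: one Uniform(-a, +a)
draw per factor level (a = 0.01 beta units by default), added to all
probes of the affected samples and redrawn independently every
repetition.  The uniform form is an assumption — only the +/-1% range is
given by the study design — and offsets are constant across probes, a
deliberately basic model (no probe-specific or dye/type-specific
effects).

Spiked true effects use the exact t-quantile calibration: the shift
`delta = t^{-1}(1 - p/2; n1+n2-2) * sd_j * sqrt(1/n1 + 1/n2)` gives a
probe an expected two-sided p equal to the target.  The default spike set
is 2000 sites split equally (100 each) across targets 1e-1..1e-20; equal
allocation is this package's choice, as only the range is prescribed.
Shifts are always positive (case > control); detection metrics are
sign-blind.

## Randomness and reproducibility

A single master seed drives everything through `numpy` `SeedSequence`
substreams keyed by (master seed, repetition), one child per stage
(groups, generation, injection, spiking), so runs are bit-reproducible
and repetitions are independent.  The parameter profile of a scenario is
drawn once per master seed and held fixed across repetitions, as an
empirical parameter table would be.

## Problem sizes

Scenarios default to a reduced-scale profile of 20,000 probes.  Mean p
and lambda are probe-count invariant in expectation; FDR/Bonferroni
counts scale roughly linearly with probe count, so counts from reduced
runs are best read per probe.  Two consequences are worth stating
plainly:

* absolute significant-site counts at 758,289 probes are ~38x the
  reduced-scale counts, and quantities defined by *threshold crossings*
  of small counts (e.g. "the factor level at which the first
  FDR-significant site appears") shift systematically to higher factor
  counts at reduced scale — near the onset, expected full-scale counts
  are below 38, i.e. below 1 reduced-scale count;
* sample-size trends of small tail counts (a random design at large n)
  are Poisson-noise dominated at reduced scale; the calibration metrics
  (mean p, lambda) carry the same trend with far less noise.

Full-scale runs are a matter of setting `n_probes=758_289` and
`n_reps=100` in the scenario configuration; they are multi-hour jobs.

## Known limitations

No probe-probe correlation (probe-wise DMP analysis only — region-level
statistics would need a correlated generator); no missing values; no
spatial within-chip gradients or processing-date factors; batch offsets
probe-constant by design.  Passing tests on these synthetic data show
that the *correction machinery itself* manufactures or destroys signal
under the stated designs; they do not quantify how large the effect is on
any particular real dataset, whose probe SD profile and batch structure
set the actual magnitudes.
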