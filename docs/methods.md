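# Methods

This note documents the models behind `metacog`, the choices made where
the design was genuinely open, and what the synthetic-data generator does
and does not emulate.

## Data model

All estimators consume a table of 2-choice trials: stimulus and response
coded 1/2, confidence an integer on a k-point scale, plus participant
and optional day/condition/difficulty labels. Accuracy is always derived
as `response == stimulus`, never stored. The sufficient statistic for
every measure is the 2 × 2k table of *signed confidence* counts per
stimulus: a response for category 1 with confidence j occupies cell −j, a
response for category 2 cell +j, so the cell order −k … −1, +1 … +k
encodes the decision and the rating jointly.

Readers accept the Confidence Database CSV dialect. Per-dataset recipes
declare the preprocessing the archive's heterogeneity requires: source
category coding (0/1 files are normalized to 1/2), day drops for
multi-session studies with a short first session, order-preserving merges
of rarely-used rating levels (e.g. 11-point → 6-point), and equal-width
binning of continuous 50–100 confidence into six levels. Equal-width
edges are a choice: the archived dataset that needs binning does not
publish its edges, and any monotone binning preserves the rank
information the SDT machinery uses. Participant exclusion uses strict
inequalities: accuracy < 0.60 or > 0.95, or a modal response category or
modal confidence level covering > 0.85 of trials.

## Equal-variance SDT core

Sensitivity and criteria come from the probit transforms of cumulative
rating rates:

    d′ = z(HR) − z(FAR)
    c_i = −(z(HR_i) + z(FAR_i)) / 2,   i = −(k−1) … (k−1)

with HR_i/FAR_i the probability that signed confidence falls above the
i-th cell boundary given stimulus 2/1. Index i = 0 is the decision
criterion c. Stimulus distributions are unit-variance Gaussians placed
symmetrically at ∓d′/2, which makes c = 0 the unbiased point. When any
cumulative rate is exactly 0 or 1, 1/(2·2k) is added to every cell of
both stimulus rows before the transform (the padding convention of the
standard meta-d′ toolbox) and the fit records a flag; ties that leave
empirical criteria non-monotone are separated by a 1e-6 epsilon with a
warning. The model-implied joint distribution (`predict_joint`) places
exact Gaussian segment masses between adjacent criteria; it is the basis
of every "expected" measure, and regenerating rates from it reproduces
the fitted parameters exactly (a fixed point verified to 1e-8 in tests).

## The 17 measures

* **AUC2** — trapezoidal area under the type-2 ROC, points
  (P(conf ≥ j | error), P(conf ≥ j | correct)) for j = 2…k plus (0,0) and
  (1,1), collapsed over responses.
* **Gamma** — (C − D)/(C + D) over concordant/discordant pairs of the
  accuracy × confidence table (ties ignored, the usual convention).
* **Phi** — product–moment correlation between binary accuracy and
  confidence level.
* **ΔConf** — mean confidence on correct minus error trials.

On count tables these are the empirical statistics; on probability tables
the exact expectations of the same statistics, so "expected" variants
need no simulation. Ratio measures divide observed by expected literally
(no re-centering, including AUC2 whose chance level is 0.5); difference
measures subtract. A ratio whose denominator is within 1e-3 of zero is
flagged unstable and reported with a warning — ratio measures are not
meaningful near chance performance.

* **meta-d′** — the sensitivity a noiseless SDT observer would need to
  produce the observed confidence data. The type-1 criterion is anchored
  at the data's relative position (meta-c = meta-d′ · c/d′); meta-d′ and
  2(k−1) response-conditional type-2 criteria maximize the multinomial
  likelihood of confidence given each (stimulus, response) cell.
  Criterion ordering is enforced by a log-increment reparameterization;
  the optimizer is Nelder–Mead from a start at meta-d′ = d′ with type-2
  spacings taken from the observed criteria. M-Ratio = meta-d′/d′,
  M-Diff = meta-d′ − d′.
* **meta-noise (σ_meta)** — lognormal criterion-jitter model: each trial
  draws one multiplier m ~ Lognormal(0, σ_meta) that rescales all
  confidence-criterion distances τ_j, so effective criteria are
  c ± m·τ_j. A single shared multiplicative jitter keeps criteria ordered
  and can never push a confidence criterion across the decision
  criterion; the decision itself is untouched by metacognitive noise.
* **meta-uncertainty** — second-order-uncertainty model: the observer
  scales evidence strength by a noisy estimate of its own sensory noise,
  v = |x − c|/σ̂ with σ̂ ~ Lognormal(−u²/2, u) (unit mean, so u = 0 nests
  the noiseless observer continuously), compared to fixed thresholds.

Both process-model likelihoods marginalize the lognormal variable by
Gauss–Hermite quadrature (61 nodes by default; a node-doubling check is
available and verifies stability to 1e-6) with exact Gaussian segment
masses along the evidence axis, so per-stimulus probabilities conserve
mass by construction and both reduce exactly to fixed-criteria SDT at
zero noise. Fitting is joint MLE over (d′, c, τ, σ) with multi-start
Nelder–Mead (5 restarts by default, fixed seed schedule, ties broken
toward smaller σ).

A consequence of this parameterization worth knowing: with the criterion
distances free, the two process-model likelihoods are reparameterizations
of one another (the log-mean offset is absorbed by the distances), so
their fitted noise values coincide on the same data. They are kept as
separate, independently specified models; published implementations with
more constrained parameterizations can and do diverge.

**Orientation.** For the 15 ability-scaled measures, larger is better;
σ_meta and meta-uncertainty are noise parameters where larger is worse.
Validity and precision analyses orient all measures via a sign table so
that destroying confidence information registers as a decrease
everywhere.

## Assessment battery

* **Corruption** walks trials in stored order, decreasing confidence by
  one point on correct trials (if above 1) and increasing it on errors
  (if below k), stopping at round(proportion · n) corruptions. It is
  deterministic and order-dependent by design, so stored trial order is
  part of the data contract.
* **Precision** = mean over bins of (orig − corrupted)/SD, with SD the
  sample standard deviation (ddof 1) of the uncorrupted per-bin values,
  computed per participant per bin size and then averaged. Positive
  precision certifies validity. Bins where a measure is undefined (e.g.
  no errors) are dropped and counted.
* **Metacognitive-bias recoding** maps a k-point scale to k−1 points two
  ways — all ratings above 1 shifted down (low bias) vs only the top
  rating folded (high bias) — leaving accuracy untouched, so any change
  in a measure between recodings is bias dependence.
* **Dependence designs**: paired t-test between extreme difficulty levels
  with per-level 3-SD outlier removal and pooled-SD Cohen's d (the pooled
  form keeps magnitudes comparable across measures; a difference-score
  denominator would be the paired alternative); repeated-measures ANOVA
  (via pingouin) with partial η²; per-participant Pearson r against |c|,
  Fisher-z averaged. Tests are uncorrected and two-sided.
* **Split-half** cuts each participant's trials into non-overlapping bins
  of twice the nominal size, forms odd/even halves within each bin,
  correlates the half-measures across participants per bin index, and
  Fisher-z averages. The across-participant reading makes it an
  individual-differences reliability.
* **Test–retest** computes the measure per participant per day on
  matching bin indices and reports both ICC(A,1) — the two-way
  absolute-agreement single-measure ICC, which penalizes day-to-day mean
  shifts — and Pearson r, Fisher-z averaged over bin indices and day
  pairs.

## Synthetic data

The generator simulates the lognormal-jitter observer (σ_meta = 0 gives
the ideal SDT observer): configurable d′, criterion, criterion distances,
stimulus prior, trial count, multi-day block structure, and seed. Cohorts
draw per-observer parameters around stated means with stated spreads and
return a ground-truth table so tests never re-derive truth from data.
Fixture presets (ideal_observer, noisy_metacognition, biased_confidence —
whose bias is induced by shifting criterion distances, not relabeling —
and multi_day) regenerate bit-identically from fixed seeds.

What it emulates: equal-variance Gaussian evidence, stationary criteria
(up to the modeled jitter), independent trials, balanced or biased
stimulus priors, day structure. What it does not: reaction times,
learning or fatigue drifts, serial dependence, condition mixtures, or
non-Gaussian evidence. Passing tests therefore certify the estimators and
the assessment machinery under the stated generative assumptions, not the
behavior of any particular human dataset. In particular, synthetic
cohorts are less heterogeneous than human cohorts unless spreads are set
large, so across-subject reliabilities computed on them are typically
lower than values reported for real data at the same bin size.

## Problem sizes and numerics

The test suite and acceptance script size their simulations to be
informative per unit cost: 10⁶-trial frequency checks for
simulator/likelihood agreement (4 SE bands), 10⁵-trial ideal-observer
normalization checks averaged over 5 replicate simulations (the
difference measures have sampling SDs comparable to their tolerance at a
single replicate), 20-observer cohorts at 800–1000 trials for corruption
dose–response with process-model fits at 2 restarts, and recovery grids
of σ ∈ {0.2, 0.5, 1.0} × 5–7 replicates at 10⁴ trials. Convergence
tolerances: 1e-6 on log-likelihood for all fits; probit transforms use
the exact inverse normal CDF throughout.

## Known limitations

Unequal-variance SDT is out of scope (all expected values assume equal
variance). All measures require binned confidence; continuous scales must
be discretized first. Measures other than the process models assume a
single condition — mixing conditions inflates scores. The process-model
measures can only take non-negative values and cannot express confidence
that is *more* informative than the decision. k = 2 scales carry little
information for the process models, and meta-uncertainty is unreliable
below a few hundred trials.
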