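# Methods

This package implements a two-stage analysis: (1) *computational phenotyping*
of long-term forgetting from an adaptive paired-associate learning task, and
(2) prediction of that phenotype from resting-state functional-connectivity
features with an L1-penalized linear model and a validation battery. Because
the behavioral and imaging data this design targets are not publicly
deposited, the package ships a synthetic-study generator that reproduces the
design's conditions end-to-end; all tests and calibration results refer to
that generator.

## The memory model

Each studied item leaves episodic traces. A trace created at time `t_i`
decays as a power law, and the item's activation is the log of the summed
trace strengths:

    A(m, t) = log Σ_i (t − t_i)^(−d_i)

The decay rate of a new trace depends on the activation at its creation,

    d_i = c·exp(A(m, t_i)) + φ,          c = 0.25,

so closely spaced rehearsals produce fast-decaying traces (the spacing
effect). The first trace of an item takes the empty-sum limit `A = −∞`,
hence `d_1 = φ`. The decay intercept φ is the only free parameter; averaged
over an individual's items it is their **speed of forgetting (SoF)**.
Retrieval probability is the logistic of activation, `P = 1/(1+e^(−A))`, and
response latency is `T = t0 + F·e^(−A)` with `t0 = 0.3 s`, `F = 1`.

Units are seconds throughout; the session clock starts at 0. φ is
constrained to [0.10, 0.60], bracketing the adult range reported in the
adaptive-fact-learning literature (~0.25–0.39) with margin.

Numerical notes:

- Activation queries require `t` strictly greater than every trace time; a
  trace laid at the very moment of a probe does not support it.
- The session engine merges encodings closer than 0.25 s into the preceding
  trace. Sub-second repeat encodings are not psychologically meaningful and
  are numerically explosive: a lag ε ≪ 1 s gives trace strength ε^(−d),
  which feeds back into the next decay rate through `c·e^A` and overflows
  within two or three iterations.

## The adaptive session

The scheduler fills a 720-s session over 25 items. At each step it looks
`lookahead = 15 s` ahead; the introduced item with the lowest predicted
activation is tested if that activation falls below
`activation_threshold = −0.8`, otherwise a new item is introduced as a study
trial, and once the pool is exhausted the lowest-activation item is tested
regardless. The clock advances by `rt + 0.6 s` after a correct response and
by `rt + 4 s` (fixed corrective-feedback interval; the live task is
participant-paced, but simulation needs a deterministic clock) after an
error. Traces are laid at trial onset for study trials and correct tests,
and at feedback offset for incorrect tests (re-study during corrective
feedback); the latter is configurable.

**φ re-estimation.** After every test response the item's φ is re-fit by an
exhaustive grid search over [0.10, 0.60] in steps of 0.001: for each
candidate the item's whole decay cascade is rebuilt from its trace times,
each past test trial's latency is predicted at its onset, and the candidate
minimizing the summed squared latency error wins, ties going to the smaller
φ. Observed and predicted latencies are both clamped at the 8-s outlier
bound, which keeps long-lag trials from dominating the objective and makes
the flat region of the objective resolve deterministically toward smaller φ.

By default an incorrect trial contributes its *observed* first-keypress
latency (clamped), not the 8-s ceiling. This choice matters: if every error
is scored as 8 s, the fitted latency converges to
`(1−f)·rt_true + f·8` for error fraction `f`, so any appreciable error rate
biases φ toward the grid ceiling, and binomial variation in per-participant
error counts alone (SD ≈ 0.045 in φ units at f ≈ 0.1) exceeds the
population SD of the phenotype (0.029) — parameter recovery collapses. With
observed-latency scoring the estimator is consistent under the generator's
own response model. The ceiling surrogate remains available as
`error_rt_policy="cap"` for fidelity with production systems in which error
latencies are uninformative.

## The synthetic cohort

`CohortSpec` defaults encode the study conditions: 33 participants, true SoF
drawn from Normal(0.305, 0.029) truncated to [0.20, 0.45] (a smooth density
respecting the observed 0.253–0.385 range), 25 items per 720-s session, and
17-network time series of 210 volumes at TR = 2 s.

The simulated learner tracks its own ground-truth trace history (mirroring
the engine's encoding events). On a test probe with truth activation A it
answers correctly with probability `1/(1+e^(−A/s))` (`s = 1` by default,
i.e., the model's expected-probability curve; smaller `s` gives the sharper,
near-ceiling accuracy of real participants) and responds in
`(t0 + F·e^(−A))·ε` seconds with ε lognormal(0, σ), σ = 0.3 by default.
Study-trial typing latencies are lognormal around a 1.5-s median.

A known limitation follows from sampling correctness at unit scale: items
are tested near threshold activation (−0.8), where the expected-probability
curve yields ≈ 0.3–0.45, so simulated test accuracy (~36%) is far below the
≈ 86% of real adaptive sessions, whose retrieval success is much sharper in
activation than the expected-probability curve. Parameter recovery is
unaffected (latencies carry the φ information), but simulated accuracies
should not be read as behavioral predictions.

**Connectivity.** Each participant's time series is sampled i.i.d. from a
multivariate normal whose precision matrix is built directly from target
partial correlations (unit diagonal, `Ω_ij = −ρ_ij`), so the planted values
are exact by construction. The target is a fixed, sparse base pattern —
modest positive partials within the visual, somatomotor, control and
default-mode systems — plus, on each planted edge,
`γ_e · (SoF − 0.305)/0.029`. The link is planted on the partial-correlation
scale because that is what the predictive analysis consumes; planting on the
covariance scale would distort the targets. Planted edges carry positive
base couplings so the cohort-mean edge sign (needed by the sign-adjusted
weights) is stable. Temporal autocorrelation of fMRI noise is not modeled:
partial correlations are invariant to it to first order. Eigenvalue clipping
(with diagonal renormalization) guards positive definiteness; with the
shipped patterns it never triggers.

The default planted slopes are ±0.10 partial-r per SoF SD on three
DMN-anchored edges. `CohortSpec.low_noise()` — the configuration used for
the pipeline-closure checks — keeps the study's 210 volumes (per-edge
Fisher-z sampling SE ≈ 1/√(210−15−3) ≈ 0.072), raises the slopes to ±0.15
so each planted edge correlates ≈ 0.9 with the true SoF, and halves the
latency noise (σ = 0.15) so the phenotype is estimated nearly noise-free.
The slope sits deliberately in a middle regime: with a much stronger
per-edge signal the three planted edges become redundant (they share the
one-dimensional SoF signal) and the cross-validated model legitimately
keeps only a subset — the collinearity behavior the feature-removal test
probes — whereas at per-edge r ≈ 0.9 the model gains from averaging all
three and reliably selects the full planted support.

## Phenotype aggregation and fit metrics

A participant's SoF is the unweighted mean of final per-item φ over items
presented at least three times (study + test). Model fit replays each
session under the participant-level SoF (all decay rates rebuilt), predicts
each test latency, discards latencies above 8 s as outliers, and bins
observed and predicted latencies into ten 800-ms bins on [0, 8] s.

- **KL divergence** is reported in bits, oriented KL(observed ‖ predicted),
  with 0.5 pseudo-counts added to every bin of both histograms before
  normalizing (empty predicted bins would otherwise give infinite KL).
- **χ²** scales predicted proportions to the observed total, merges adjacent
  bins until every expected count is ≥ 1, and uses dof = bins − 1.
- The predicted histogram is deterministic (no predictive noise): each trial
  contributes its point prediction.
- Accuracy diagnostics code a trial as predicted-correct when P > 0.5
  (A > 0), with the boundary assigned to incorrect.

## Connectomes and features

Pearson connectomes are product-moment correlations across volumes. Partial
correlations condition each pair on the remaining 15 networks and are
computed once from the precision matrix, `ρ_ij = −Ω_ij/√(Ω_ii Ω_jj)` —
algebraically identical to the residual-regression definition, which serves
as the test oracle. A singular covariance falls back to a ridge-regularized
inverse (λ = 1e−6 × mean diagonal) with a warning. Group averages use
Fisher's r-to-z (`tanh(mean(atanh r))`), clipping |r| = 1 at 1−1e−7. The
shipped parcellation is the 17-network resting-state atlas with the
DMN/storage/retrieval grouping (3/8/6 networks); the 45 features are the 3
within-DMN pairs followed by each DMN subnetwork's 14 edges in parcellation
order, and every output serializes this order.

## Prediction and validation

The model solves

    argmin_β  (1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁

by coordinate descent (tolerance 1e−7 for reported fits), with features
standardized to unit variance inside the solver, coefficients reported on
the original scale, and an unpenalized intercept. This objective scaling is
stated explicitly because λ is only interpretable relative to it. λ is
selected by leave-one-out CV on a 100-point log grid from λ_max (the KKT
threshold `max_j |⟨x_j, y−ȳ⟩|/n`) down four decades; each training fold is
standardized on its own; ties resolve toward the sparser model. Path solves
inside the CV loop use a 1e−5 tolerance — the CV curve is insensitive at
that level and the loop runs ~3,300 solves per selection.

The battery mirrors the reference analysis:

- **LOO validation** fixes the selected support, refits the weights by
  unpenalized least squares on each n−1 fold, and correlates held-out
  predictions with observations.
- **Feature removal** re-runs the entire selection on the reduced matrix;
  an all-zero solution ("failed to converge") is the expected outcome when
  the removed set carried all the signal.
- **VIF** is 1/(1−R²) per selected feature; perfect collinearity reports ∞.
- **Permutation null**: the phenotype vector is shuffled (1,000 times by
  default; the shipped analyses and tests use 200), the full
  selection-plus-fit re-run, shuffles classified as intercept-only versus
  converged, and converged shuffles with fitted r at least the observed
  value counted as comparable. The empirical p uses the add-one correction
  (1 + #comparable)/(1 + #shuffles).

## Network-level summaries

Node importance is the L1 norm of selected edge weights incident to each
network (so the grand total is twice the model's L1 norm). The
storage-vs-retrieval contrast is a two-sided one-sample t test of the eight
storage-network importances against zero, zeros included for unselected
networks; the retrieval-group mean is exactly 0 whenever no retrieval edge
is selected. Selection enrichment reports the hypergeometric probability
that a uniform draw of as many edges is as storage-pure as the observed
selection; because the combinatorial convention for within-DMN edges is
genuinely ambiguous, it is a parameter (`exclude` from pool and draw —
the default — `storage`, or `neither`) and the convention is reported next
to the number. Sign-adjusted weights multiply each β by the sign of its
group-mean connectivity so that positive always reads "more connectivity,
faster forgetting"; an exactly-zero group mean yields a zero weight with a
warning.

## What the tests do and do not show

The acceptance battery establishes: exact reproduction of the reference
model's importance statistics from its published weights; the closed-form
forgetting bound (P(600 s; φ=0.3) ≈ 0.128 < 0.25); the 45-edge feature
space; SoF recovery r ≥ 0.9 on the default cohort and r ≥ 0.95 noise-free;
oracle equivalence of the partial-correlation, LASSO and activation paths;
full-pipeline closure on the low-noise cohort (planted support selected,
LOO r ≥ 0.7, permutation p ≤ 0.05, planted signs recovered); and null
calibration (pure-noise phenotypes select nothing in ≥ 90% of seeds; the χ²
fit test rejects at ≈ 5% under the model). Because the generator's volumes
are temporally independent, its response noise is lognormal, and its
connectivity signal is planted exactly on the measured scale, these results
demonstrate internal consistency of the pipeline — not that real cohorts of
this size would yield comparable effect sizes.

Problem sizes were chosen to keep the full battery modest on a single CPU:
permutations at 200, closure on one 33-participant cohort, null calibration
over 50 seeds.
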