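# Methods

This note documents the models implemented in `fakemix`, the choices made
where the design was genuinely open, and what the synthetic-data studies
do and do not show.

## Honest responding: Thurstonian IRT for rank orders

Each item *i* has a latent utility `t_ji = μ_i + λ_i η_{j,trait(i)} + ε_ji`
with independent errors `ε_ji ~ N(0, ψ_i²)` (ψ² is a *variance*
throughout; standardized utilities use ψ² = 1 − λ²). A person ranks the
items of a block by decreasing utility, so the probability of rank order
*r* is the positive-orthant probability of the successive differences: if
utilities and variances are sorted by *r* and `A` is the (B−1)×B
successive-difference contrast matrix,

    P(r) = P(A t > 0),   A t ~ N(A m, A diag(ψ²) A').

The covariance is the quadratic form `A diag(ψ²) Aᵀ` — the only reading
that yields a valid covariance matrix. Orthant probabilities are computed
with scipy's multivariate normal CDF (Genz quasi-Monte-Carlo lattice,
deterministic across calls) via the symmetry identity
`P(d > 0 | d ~ N(m, S)) = P(N(0, S) ≤ m)`, which also batches all persons
of a block-order cell into one call; the accuracy target is 10⁻⁶
absolute (B − 1 ≤ 2 integrals are effectively exact), with a
randomized-QMC fallback (logged, with an error bound) should the CDF
return a non-finite value. Per person-block the R probabilities are then
rescaled to sum to exactly one, absorbing residual integration error;
cells deviating by more than a configurable threshold (default 10⁻⁴)
before rescaling are logged. A Monte-Carlo ordering-frequency oracle in
the test suite checks the analytic probabilities to within three standard
errors.

Ties between utilities have probability zero under the continuous model;
the simulator's ranking uses a stable sort, so exact ties (possible only
at degenerate parameters) break by item order. Errors are independent
within and across blocks; cross-block error correlation is out of scope.

## The Faking Mixture

High-stakes responses are a mixture of faking (rank orders chosen by
desirability) and honest responding:

    P(X_jk = r) = Φ(θ_j + α_k)·softmax(β_k)_r + (1 − Φ(θ_j + α_k))·H_jkr,

with the honest probabilities `H` computed first and held fixed (the
two-step procedure: honest-response data identify the Thurstonian part,
high-stakes data the mixture). β_k1 ≡ 0 identifies each block's softmax;
the block fakability is derived per draw as

    α_k = Φ⁻¹( Σ_r (P_kr − mean(P_k))² ).

The verbal description of this quantity ("sum of squares of the
rank-order probabilities") conflicts with the displayed squared-deviation
form in the source material; the displayed form is implemented (it is
also the one whose degenerate case gives α = Φ⁻¹((R−1)/R), e.g. Φ⁻¹(5/6)
≈ 0.967 for R = 6). The sum-of-squares argument is clamped below at
ε = 10⁻¹⁰ (α floor ≈ −6.36) so the exactly uniform case — measure zero in
the model but routine at sampler initialization — keeps a finite value
and a defined gradient (the gradient through α is set to zero on the
clamped set).

Faking rank-order preferences vary by block only, never by person, and
are deliberately not decomposed into per-item desirabilities. The model
does not correct content-trait estimates for faking.

## Priors and estimation

    β_kr ~ N(0, SD(β)),  θ_j ~ N(M(θ), SD(θ)),
    M(θ) ~ N(1, 2),  Var(θ) ~ Inv-Gamma(1.5, 1),
    Var(β) ~ N(5, 10) truncated to (0, 15).

Second arguments of normal densities are standard deviations; the
truncated normal is mean 5, SD 10 on (0, 15). Either variance can be
fixed instead; the *empirical* preset fixes Var(θ) = 0.25 (a typical
variance for a response-bias trait) and Var(β) = 4 (wide enough for both
low and high block fakabilities), leaving only M(θ) hierarchical.

The discrete faking indicator is marginalized analytically, making the
posterior differentiable, and sampled with an in-package adaptive
Hamiltonian Monte Carlo kernel: leapfrog integration, diagonal mass
matrix estimated from a mid-warmup window, dual-averaging step-size
adaptation to a 0.8 target acceptance rate, jittered leapfrog step counts
(default 16 ± 50%), divergence counting at an energy-error threshold of
1000 (post-warmup only). Gradients of the full log posterior — including
the chain rule through softmax → spread → Φ⁻¹ → probit — are analytic and
verified against finite differences to ~10⁻⁸ relative error in the test
suite; the sampler's log density equals the public mixture log likelihood
plus fully normalized prior densities (also tested, to 10⁻⁸).

Internally the faking trait is sampled non-centered
(θ = M(θ) + SD(θ)·θ̃) and variances on the log scale with Jacobian
corrections; this is a pure reparameterization — reported draws and the
exposed `log_density` are on the natural, centered scale. Initialization:
β at 0, θ̃ at 0, M(θ) at its prior mean, variances at their prior medians,
plus seed-controlled N(0, 0.1²) jitter per chain.

Defaults mirror the recovery-study settings (3 chains × 3500 iterations,
750 warmup); `SamplerConfig.empirical()` gives 6 × 5000 with 2500 warmup.
Convergence is screened with split-R̂ < 1.01 (strict) and an effective
sample size ratio > .001 via arviz; posterior summaries are medians and
95% central intervals, and per block the share of persons whose
posterior-median faking probability exceeds .5 ("predicted to fake").
Derived quantities (α, faking rank-order probabilities) are recomputed
per draw and summarized afterwards, never computed from summarized β.

The multigroup variant fits two groups jointly, sharing β (hence α) on
blocks whose items are identical across questionnaire versions and
estimating separate β elsewhere, with separate θ vectors per group and
shared hyperparameters; per-draw α differences for non-shared blocks give
posterior intervals for fakability comparisons inside the model.

## The synthetic-data generator

The generator reproduces the recovery study's conditions and is the
package's test bed:

* Content traits: multivariate normal, zero mean, unit variances, Big
  Five meta-analytic intercorrelations (N/E/O/A/C ordering).
* Items: 20 triplet blocks over 5 traits by default (traits cycle so each
  trait gets 12 items); μ ~ U(−1, 1), |λ| ~ U(.65, .95),
  ψ² = 1 − λ². One item per triplet is reverse-keyed (uniformly chosen),
  making 2 of 3 within-block comparisons differently keyed — the closest
  realizable value to half; configurable via an explicit keying plan.
* Identifiability: a block's loadings are redrawn when any two magnitudes
  agree within 10⁻³ or any two pairwise magnitude ratios agree within
  10⁻³ (a documented heuristic for "no linear dependencies"; the exact
  operationalization is not specified in the source material). A
  configurable redraw cap raises a design error suggesting another
  keying plan.
* Faking parameters: all R rank-order parameters per block are uniform on
  (−2, 2) for low and (−4, 4) for high fakability — softmax shift
  invariance makes the identification constraint irrelevant at
  generation, so the stored true β is shifted to the identified scale for
  bookkeeping. θ ~ N(M, V) with M ∈ {0, 1, 2}, V ∈ {0.2, 0.5, 1},
  independent of the content traits; all 18 combinations crossed.
* Responses: honest orders by ranking noisy utilities; per person-block a
  Bernoulli faking indicator with probability Φ(θ_j + α_k); faked cells
  replaced by a categorical draw from the block's softmax distribution.

Design constants implied by this generator (reproduced by Monte Carlo in
the acceptance suite): the per-block maximum faking probability has mean
≈ .44 with central 90% band ≈ [.28, .66] for low and mean ≈ .62, band
≈ [.36, .93] for high fakability (reported to one decimal as .4/[.3, .6]
and .6/[.4, .9]); the mean faking probability *of the average respondent*
— Φ(M(θ) + α) averaged over the block distribution — spans ≈ .14 at
(low, M(θ) = 0) to ≈ .91 at (high, M(θ) = 2). Averaging the probit over
the θ distribution instead raises the low corner to ≈ .16–.22 depending
on the variance level; the at-the-mean convention is used for the design
constants.

What the generator does *not* emulate: real item content, response styles
or careless responding, correlation between faking and content traits,
cross-block dependence, or desirability that varies by person. Passing
recovery tests therefore show that the estimator recovers its own
generating process at the stated scale — not that real questionnaires
satisfy the model.

## Recovery study harness

Per replication: draw a design, traits and faking parameters for a
condition, simulate honest + high-stakes responses, compute the honest
table, fit, and score four metrics per parameter family (θ, free β,
hyperparameters, derived α and rank-order probabilities): coverage of 95%
posterior intervals, Pearson correlation of true values with posterior
medians, mean bias, and the SD of bias across parameters within a
replication (condition means of these replication-level values are
reported; a pooled alternative is a config switch away). The true
comparator for the Var(β) hyperparameter is the realized sample variance
of the identified true free β entries — the generating uniform has no
normal variance parameter. Interval endpoints use order-statistic
quantile methods so improper (infinite) draws behave exactly.

Metric variance is decomposed over the three design factors by balanced
full-factorial sums of squares (all main effects, two- and three-way
interactions, residual, as % of total SS) — descriptive only, no F tests;
an independent statsmodels ANOVA oracle checks the decomposition in the
tests. The ANOVA unit is the replication-level metric. Replication
failures are logged and excluded with a reported count; all randomness
derives from one root seed via spawned child sequences, so reports
regenerate bit-identically.

Problem sizes: the full-scale study (18 conditions × 1000 replications at
500 persons, 3 × 3500 iterations) is not a desk-scale computation. The
shipped defaults run a reduced profile (100 persons, 10 blocks, 1 × 800
iterations, 2 replications), clearly labelled as reduced in the report
config. The acceptance checks use paper-scale single replications (500
persons, 20 blocks) with a reduced sampler budget (1 × 1000) — chosen
because the systematic shrinkage-induced negative bias of β and its
ordering across fakability levels are paper-scale phenomena that sampling
noise swamps at much smaller n — plus Monte-Carlo design constants at
10⁵–2·10⁵ simulated blocks.

## Known limitations

* One faking trait, uncorrelated with content traits; no content-domain-
  specific faking tendency.
* Honest probabilities are treated as known in step two; uncertainty from
  the first step does not propagate.
* Estimating Thurstonian item parameters from honest MFC data
  (limited-information SEM) is out of scope; the package consumes item
  parameters or precomputed honest probabilities.
* The HMC kernel is a static-trajectory sampler with diagonal mass; very
  small faking-trait variances can mix slowly (the empirical preset fixes
  Var(θ) for this reason). A handful of post-warmup divergences can occur
  near the fakability floor where the α gradient is steep; they are
  counted and reported per chain.
* R̂ screening at short demo budgets routinely flags a few person
  parameters; the study-scale chain settings are the reference.
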