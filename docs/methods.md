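# Methods

## The scientific problem

Two chimpanzee communities perform the grooming handclasp — a dyadic custom
in which two individuals clasp raised arms while grooming — with
community-specific preferences for which arm region is clasped (wrist,
elbow, forearm, palm, or a pooled "other" category).  The question is how
such style preferences are transmitted: do dominant or older individuals
exert more influence over their partners' styles (dominance/age bias), do
mothers shape their offspring's preferences more than other group members
(vertical transmission), and do individuals converge on the group-typical
style as they mature (majority convergence)?

The central observational difficulty is that a handclasp produces a *pair*
of style records per event, and when both performers show the same variant
it is unknown who chose it.  The model treats "who chose" as a latent state
and marginalizes over it, so preference estimates properly absorb that
uncertainty.

## The model

**Preferences.**  Individual *i* in group *j* carries a preference vector
W_ij over the five variants, reference-coded against wrist (W_ij1 = 0).
Conditional on being the chooser, the probability of performing variant k is
softmax: p_ijk = exp(W_ijk) / Σ_l exp(W_ijl).  Preferences are partially
pooled within groups, W_ijk ~ Normal(μ_jk, σ_W) for k = 2..5, with group
mean preferences μ_jk (μ_j1 = 0).  Because reference-coded means are not
comparable across groups, reports transform μ_j to expected proportions
p̂_jk = softmax(μ_j)_k per MCMC iteration before summarizing.

**Latent chooser.**  Each event is in one of three situations: (a) both
performers choose independently; (b) performer 1 chooses and performer 2
matches exactly; (c) the reverse.  With influence scores I_1, I_2 and a
baseline parameter β_a,

    (π_a, π_b, π_c) = (exp(β_a), I_1, I_2) / (exp(β_a) + I_1 + I_2),

and the influence of an individual at a given observation window is

    I = exp(I_RE + β_age · age_std + β_sex · sex + β_rank · rank_norm),

with an individual-level random effect I_RE ~ Normal(0, σ_I).  Matching in
situations b/c is exact, so a discordant pair proves situation a; the
marginal pair likelihood is

    P(y1, y2) = π_a p_1(y1) p_2(y2) + 1{y1 = y2} [π_b p_1(y1) + π_c p_2(y2)].

The indicators are marginalized analytically rather than sampled; per-event
posterior situation probabilities can be recovered afterwards by
renormalizing the three mixture terms over posterior draws
(`impute_choosers`).

**Maternal variant.**  The preference prior mean interpolates between the
group mean and the mother's preference vector,
W_ijk ~ Normal((1−m) μ_jk + m W_M(ij)k, σ_W), with separate weights m for
the young (age ≤ threshold, default 8 years) and old categories.  Mothers
absent from the data receive an imputed latent vector W_M ~ Normal(μ_jk, σ_W).
Because an individual observed on both sides of the age threshold cannot
carry one static vector with two different maternal priors, maternal-variant
individuals carry one preference vector per age category they were observed
in; each vector's prior uses the m of its own category, and the mother's
referenced vector is her old-category vector (mothers are at least 10 years
older than their offspring, so they essentially always have one).

**Age-split variant.**  Individuals likewise carry separate vectors per age
category, with category-specific dispersions σ_W,young and σ_W,old.
Convergence toward the group style with age appears as
σ_W,young > σ_W,old.  A `combined` variant stacks both extensions; the
maternal and age-split extensions are treated as separate variants by
default because they address different questions.

**Priors.**  μ_jk and every β ~ Normal(0, variance 1000); σ_W, σ_I ~
Uniform(0, 10); m ~ Uniform(0, 1).  The "N(0, 1000)" convention is read as
variance 1000 (SD ≈ 31.6): under a precision reading the prior would be a
near point mass at zero, contradicting its intended vagueness.  The m prior
is the minimal choice on its defined support.

## Covariate preparation

Rank per (individual, window) is the arithmetic mean of the ordinal
assessments of three raters (fewer tolerated with a warning), then linearly
rescaled within each group-window so the best average maps to 1 and the
worst to 0 — the simplest map consistent with the required endpoints.  An
all-equal scale is an error by default (optionally 0.5 with a warning).
Age is computed from birth year and window year and z-scored over the pooled
(individual, window) rows of all groups using the population SD; the choice
of pooling and SD convention only rescales β_age and is fixed here for
reproducibility.  Covariates are time-varying: every event uses the
covariates of its window.

## Sampler

No gradient-based PPL backend is used; the posterior is sampled by an
adaptive Metropolis-within-Gibbs scheme of the family classically applied
to this model (cf. JAGS), with the following blocks per sweep:

* **W slots** — 4-dimensional random-walk proposals per preference vector,
  shaped by a running estimate of each component's posterior SD and a
  per-slot global scale adapted to ~28% acceptance.  Likelihood deltas touch
  only the events adjacent to the slot; discordant events reduce to simple
  log-probability differences.
* **Influence random effects** — scalar random walks (44% target), again
  with event-local likelihood deltas.
* **β coefficients** — scalar random walks over the full event likelihood,
  plus a *translation move* that shifts β_a and every I_RE by the same
  amount: the chooser probabilities are exactly invariant under this shift,
  so the move costs only prior arithmetic and removes the β_a–random-effect
  ridge created by the scale non-identifiability of the chooser equation.
* **μ_jk** — conjugate normal Gibbs draws (exact, also under the maternal
  interpolation, which is linear in μ).
* **Group recentering** — a joint proposal shifting μ_j and all group-j
  preference vectors together.  Prior residuals are invariant (maternal
  means shift identically because mothers share the group), so only the
  likelihood and the μ hyperprior enter.  This samples the group-location
  direction, which componentwise walks traverse extremely slowly for rarely
  performed variants (e.g. a variant with expected proportion 0.001).
* **σ_W, σ_I** — exact Gibbs draws from the truncated inverse-gamma
  conditional implied by the flat Uniform(0, 10) prior.
* **m** — scalar random walks on [0, 1].

Chains advance in lockstep as a vectorized batch from a single master-seeded
generator; runs are bit-reproducible given the seed.  Adaptation
(Robbins–Monro) runs during burn-in only.  Incremental per-event caches are
verified in tests against full recomputation and against an independent,
uncached log-posterior implementation.

Correctness of the posterior itself was cross-checked against JAGS
(`rjags`) on a small dataset (2 groups × 4 individuals, 150 events): all
posterior means and SDs of β, σ and μ parameters agreed to within
Monte-Carlo error.

**Desk-scale defaults** are 4 chains × 2000 retained draws after a burn-in
of 1000 — a scaled-down analogue of the 20-chain, thinned-100k-draw runs
this model family was originally estimated with; split R-hat > 1.01 or
bulk ESS < 400 produce warnings (exit code 3 in the CLI), never silent
passes.  Group means of essentially unobserved variants (true proportion
~0.001) have heavy-tailed, weakly identified posteriors and are the usual
source of residual R-hat warnings; the transmission-bias parameters are
well behaved.

**Summaries** are posterior means with 95% highest-posterior-density
intervals (shortest interval containing ⌈0.95 n⌉ sorted draws; verified
against exhaustive window search).  Group differences and variance/maternal
contrasts are computed per iteration before summarizing; "strong evidence"
for a group difference is operationalized as the 95% HPDI of the
per-iteration difference excluding zero, reported as a boolean column.

## Synthetic data generator

The generator draws populations and events under exactly the model above
and keeps a ground-truth ledger (generating parameters, true preference
vectors, latent situation and chooser per event) that the fitting pipeline
never reads.  Defaults emulate the study conditions: two groups of 36 and
35 individuals, five observation windows spanning 2007–2019, 2049 events
(4098 style productions), ages 5–33 years across the study (first-window
ages uniform on 5–21), 37% males, and true group preference contrasts equal
to the published group preference table (wrist/elbow favored in group 1,
palm dominant in both, overwhelmingly so in group 2).  Transmission-bias
truths default to the published posterior means: β_rank = 2.78,
β_age = 0.440, β_sex = 0.460, σ_I = 0.5, m = (0.259, 0.425), age-split SDs
(2.37, 1.02); β_a, which the study does not report, defaults to 1.0, giving
a realistic majority of independent-choice events once influence scores are
accounted for.

Dominance ranks arise from a latent score increasing with age (so rank and
age correlate, as in the study population) plus persistent individual
noise; three simulated caretakers provide ±1-jittered, re-ranked ordinal
assessments, which flow through the same aggregation/normalization code the
fitting pipeline uses.  Mothers are same-group females at least 10 years
older; dyads are sampled uniformly within groups by default (an optional
Dirichlet partner-affinity mode exists because real handclasp partners are
non-uniform, but no affinity model is fitted).  Performer roles are
randomized per event; the model is role-symmetric.

What the generator does **not** emulate: demographic turnover, non-uniform
partner choice (by default), observation effort varying across windows, and
behavioral time series beyond event lists.  Passing recovery tests
therefore validate the inferential machinery under the model's own
assumptions, not the model's adequacy for any particular real population.

## Validation scenarios and problem sizes

* **Prior recovery** — fitting the combined variant to an empty dataset
  reproduces every prior's moments and support within Monte-Carlo error
  (the μ Gibbs update is exact there; β updates adapt their steps to the
  vague prior scale).
* **Parameter recovery** — 20 replicates of 2 groups × 25 individuals and
  2000 events with β_rank = 2.78 and σ_I = 0.5; 95% HPDIs for β_rank and
  σ_W are checked for ≥ 90% coverage of the truths.  Per-replicate fits use
  4 chains × 800 retained draws (burn-in 700), sized so a replicate fits in
  well under a minute while keeping HPDI endpoints stable.
* **Age-split recovery** — true SDs 2.37 (young) vs 1.02 (old), 1600
  events, and a juvenile-weighted design (first-window ages 2–10 over five
  consecutive yearly windows) so both age categories are well represented;
  the posterior exceedance probability p(σ_young > σ_old) rounds to 1.00.

## Known limitations

* β_a and the random-effect location are only weakly identified (by the
  prior and the RE centering); their marginal posteriors are wide and
  shrink the chooser-probability scale somewhat.  Ratios such as
  exp(β_rank) are well identified.
* Group means of near-unobserved variants mix slowly and may warn on R-hat
  at desk scale; this does not propagate to the bias parameters.
* The maternal variant's per-age-category preference structure is one
  coherent reading of a static-preference model with age-dependent maternal
  weights; alternatives (e.g. a single vector with the m of the individual's
  modal category) would change the interpretation of m only for individuals
  observed across the threshold.
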