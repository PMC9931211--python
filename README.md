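# handclasp

Bayesian models of biased cultural transmission of the grooming handclasp —
a dyadic chimpanzee social custom in which two individuals clasp raised arms
while grooming, using community-specific styles (wrist, elbow, forearm,
palm, or "other").

The package is for researchers in animal culture and social learning who
want to estimate individual and group style preferences from dyadic event
records, and to test transmission-bias hypotheses: whether dominant, older,
or male individuals exert more influence over their partners' styles,
whether mothers shape their offspring's preferences more than other group
members, and whether individuals converge on the group-typical style as
they mature.

## The model

Each event *e* yields a pair of observed variants (y_G1, y_G2).  Individual
*i* in group *j* has a reference-coded preference vector W_ij (W_ij1 = 0)
with choice probabilities p_ijk = exp(W_ijk) / Σ_l exp(W_ijl) and
hierarchical pooling W_ijk ~ N(μ_jk, σ_W).  Who chose the variant is latent:
with influence scores

    I_ij = exp(I_RE,ij + β_age·age_ij + β_sex·sex_ij + β_rank·rank_ij),

the event is in situation *a* (both choose independently), *b* (performer 1
chooses for both) or *c* (performer 2 chooses) with probabilities
(exp(β_a), I_G1, I_G2) / (exp(β_a) + I_G1 + I_G2).  The latent indicators
are marginalized analytically:

    P(y1, y2) = π_a p1(y1) p2(y2) + 1{y1 = y2} [π_b p1(y1) + π_c p2(y2)].

Model variants: `baseline`; `maternal` (preference prior mean interpolates
toward the mother's vector with age-dependent weights m_≤8, m_>8);
`agesplit` (separate preference vectors and dispersions σ_W,≤8 / σ_W,>8 per
age category, so majority convergence appears as σ_W,≤8 > σ_W,>8); and
`combined`.  Inference is MCMC (adaptive Metropolis-within-Gibbs with
conjugate group-mean updates, cross-validated against JAGS), summarized as
posterior means with 95% HPDIs.  See `docs/methods.md` for the full
specification, priors, and sampler details.

Because no observational handclasp dataset is distributed, the package
includes a forward simulator (`handclasp.simulate`) that generates
populations and event tables under the exact generative model, with a
ground-truth ledger for parameter-recovery validation.  Its defaults
emulate the published study conditions (two groups, 71 individuals, five
field seasons 2007–2019, 2049 events).

## Worked example

```python
import handclasp as hc

cfg = hc.SimulationConfig(group_sizes=(12, 12), n_events=600)
ds, truth = hc.simulate_dataset(cfg, seed=8)
print(ds.summary())

sample = hc.run_mcmc(hc.ModelSpec("baseline"), ds, chains=4,
                     iterations=600, burn_in=600, seed=1)
summary = hc.summarize(sample)
print(summary.preferences[["variant", "group1_mean", "group2_mean",
                           "diff_mean", "diff_lo", "diff_hi",
                           "strong_evidence"]].round(3).to_string(index=False))
print(summary.influence[["parameter", "mean", "lo", "hi", "exp_mean"]]
      .round(3).to_string(index=False))
```

prints

```
{'n_individuals': 24, 'n_groups': 2, 'n_windows': 5, 'n_events': 600, 'n_style_productions': 1200}
variant  group1_mean  group2_mean  diff_mean  diff_lo  diff_hi  strong_evidence
  wrist        0.307        0.137      0.170   -0.019    0.367            False
  elbow        0.009        0.002      0.006   -0.004    0.023            False
forearm        0.017        0.012      0.005   -0.024    0.037            False
  other        0.008        0.003      0.005   -0.007    0.020            False
   palm        0.660        0.845     -0.185   -0.419    0.013            False
parameter  mean     lo    hi  exp_mean
   beta_a 1.095 -0.119 2.189     2.989
 beta_age 0.400  0.029 0.827     1.491
 beta_sex 0.247 -0.687 1.342     1.280
beta_rank 3.108  1.559 4.781    22.377
```

The preference table lists, per style variant, the posterior mean expected
proportion for an average member of each group (group means transformed to
the probability scale per MCMC iteration), the per-iteration group
difference with its 95% HPDI, and a strong-evidence flag (difference HPDI
excludes 0 — at this small simulated size the group contrast is visible but
not yet decisive).  The influence table shows the transmission-bias
coefficients: here the generating dominance bias (true β_rank = 2.78) is
recovered as 3.11 with HPDI [1.56, 4.78]; `exp_mean` is the multiplicative
fold change in influence (per covariate unit — e.g. top- vs bottom-ranked,
or one SD of age).

The same pipeline is available from the shell:

```
handclasp simulate --out data --seed 3
handclasp fit --data data --variant agesplit --out fit --seed 1
handclasp summarize --draws fit/draws.csv --out tables
handclasp make-suite --replicates 5 --out suite --seed 2
handclasp recover --suite suite --out recovery
```

Every command writes a `manifest.json` (seed, arguments, versions) that
makes the run exactly reproducible.  Exit codes: 0 success, 2 invalid
input, 3 fit finished with convergence warnings.

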