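# rdskit

Estimation and simulation for **respondent-driven sampling (RDS)** surveys —
chain-referral studies of hidden populations, built around a survey of
illegal-drug use among regular tobacco-and-alcohol users in metropolitan
Taipei (2007–2010, pooled n = 1115, 47 seeds, ≤5 coupons per respondent,
recruitment to about eight waves).

RDS reaches people who cannot be sampled from a frame by letting each
respondent recruit a few peers. The price is a non-random sample: recruits
resemble their recruiters (homophily) and well-connected people are
over-sampled. The package implements the classical reciprocity (RDS-I)
correction and everything around it:

- **Recruitment forests** reconstructed from positional referral codes
  (`F001-1100000000`: seed label + one digit per wave), with full validation
  (orphan codes, coupon limits, wave consistency).
- **The recruitment Markov chain.** With groups defined by a trait (e.g.
  ketamine use), `S[a][b]` is the probability that a group-`a` recruiter
  recruits into group `b`, estimated from recruiter→recruit pairs.
- **Three estimators per trait.** Crude sample proportion; the equilibrium
  proportion π (the stationary distribution of `S`, independent of the
  seeds); and the RDS-adjusted proportion

  ```
  P̂_g = (π_g / D̂_g) / Σ_h (π_h / D̂_h),   D̂_g = n_g / Σ_{i∈g} 1/d_i
  ```

  which corrects π for differential network degree with the harmonic-mean
  degree `D̂_g` (for two groups this is `S_BA·D̂_B / (S_AB·D̂_A + S_BA·D̂_B)`).
- **Dependent (chain) bootstrap** standard errors and percentile 95% CIs,
  Wald contrasts between strata, and printed-precision prevalence ratios.
- **Equilibrium diagnostics**: cumulative per-wave sample proportions with
  the "<2% between adjacent waves, consistently" convergence rule, and the
  number of Markov-recursion steps from the seed composition to π.
- **A chain-referral simulator** (degree-corrected block-model population +
  coupon-limited recruitment) that emulates the study design, so every
  estimator is validated against known truth.

## Worked example

```python
import numpy as np, rdskit

cfg = rdskit.scenario_single_trait(prevalence=0.20, degree_ratio=2.0,
                                   homophily_odds=3.0, rng_seed=1)
pop = rdskit.generate_population(cfg)
records = rdskit.simulate_rds(pop, cfg, np.random.default_rng(2))
forest = rdskit.build_recruitment_forest(records)
part = rdskit.TraitPartition.from_binary_trait(records, "drug:lifetime")

crude = rdskit.crude_proportion(records, part)["user"].proportion
T = rdskit.estimate_transition_matrix(forest, part)
deg = rdskit.harmonic_mean_degrees(records, part)
adj = rdskit.rds_adjusted_proportion(T, deg)["user"].proportion
print(f"true {pop.traits['drug:lifetime'].mean():.3f}  "
      f"crude {crude:.3f}  rds-adjusted {adj:.3f}")
```

prints

```
true 0.205  crude 0.348  rds-adjusted 0.222
```

the story in one line: users know twice as many peers and cluster together,
so the raw sample overstates prevalence by 14 points; weighting by the
recruitment chain's equilibrium and the harmonic-mean degrees brings the
estimate back to the truth (over 200 replicates the adjusted estimator's
mean bias is about −0.01 against +0.11 for the crude one).

The full pipeline — composites (any club/hard drug, use patterns),
onset-stratified tables with ratios and Wald tests, equilibrium traces —
is one call (`rdskit.run_analysis`) or one command:

```
rdskit report --config my_scenario.yaml --seed 1 --out-dir results/report
```

## Analysis scripts

The `analysis/` drivers rebuild the package's result tables under
`results/`: `01` checks every printed prevalence-ratio cell of the published
stratified tables (22/22 reproduce), `02` simulates the study-design survey
(n = 1115 over four yearly rounds), `03` estimates the full prevalence
tables from it, `04` runs the equilibrium diagnostics, and `05` validates
recovery and bootstrap calibration against known truth.

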