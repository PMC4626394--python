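# Methods

This note documents the statistical model, the simulator, the numerical
choices, and the limitations of `rdskit`, in the package's own terms.

## The sampling model

Respondent-driven sampling treats recruitment as a random walk on the hidden
population's social network. With participants partitioned into k groups by
a trait, the walk induces a Markov chain on groups whose transition matrix
`S` is estimated by row-normalising the matrix of recruiter→recruit pair
counts (seeds contribute only as recruiters — they were not recruited, so
they carry no information about transition probabilities). Under the usual
RDS assumptions (recruitment uniform among a recruiter's alters, a single
connected network, sampling fraction small enough to ignore depletion), the
sample composition converges over waves to the chain's stationary
distribution π regardless of the seeds, and the population proportion of
group g is estimated by the reciprocity (RDS-I) estimator

    P̂_g = (π_g / D̂_g) / Σ_h (π_h / D̂_h)

where D̂_g = n_g / Σ_{i∈g} 1/d_i is the harmonic ("multiplicity") mean of
the self-reported degrees in group g. The harmonic mean is the right
average because the walk samples individuals proportionally to degree: the
inverse-degree sum undoes exactly that size bias. An arithmetic-mean variant
would over-correct and is not offered as a default. For k = 2 the estimator
reduces to the closed form `S_BA·D̂_B / (S_AB·D̂_A + S_BA·D̂_B)`, which the
test suite verifies against the general implementation to 1e-12.

Degrees below 1 are treated as invalid: the record stays in the sample (it
still carries trait information for crude proportions and transitions) but
is excluded from the harmonic mean, with the exclusion counted and logged.

### Stationary distribution

π is obtained by solving the linear system `(Sᵀ − I)π = 0, Σπ = 1`
(least-squares on the stacked system), then clipped at zero and
renormalised; the solution is accepted only if the stationarity residual
‖πS − π‖∞ is below 1e-10. Uniqueness is checked structurally first: the
condensation of the positive-transition digraph must have a single sink
class. A reducible chain (e.g. the identity matrix, where every distribution
is stationary) raises a degeneracy error naming the closed classes — it is
reported, never silently patched.

Groups that never appear as recruiters produce all-zero count rows. The
default policy fills such rows uniformly (configurable to a self-loop); the
choice is recorded on the transition matrix and logged. Reciprocity
smoothing — symmetrising the count matrix as `(C + Cᵀ)/2` before
normalising — is implemented but off by default, since whether the original
analyses enabled it is not documented; both toggles are exposed.

## Uncertainty

Standard errors come from a dependent (chain) bootstrap. Each of B
replicates (default B = 1000) regrows a pseudo-sample of the original size:
the first member is drawn uniformly from the observed sample, and each next
member is drawn uniformly from the pool of observed recruits whose recruiter
belonged to the current member's group — a Markov chain on the empirical
recruit pools, which preserves the recruitment dependence that an iid
bootstrap would ignore. If a pool is empty (a group that never recruited)
the chain restarts from a uniformly chosen observed recruit; restarts are
counted and logged, and restart steps are not counted as transitions. The
chosen estimator is recomputed on every replicate (vectorised across
replicates); the SE is the standard deviation over replicates and the 95%
interval the 2.5/97.5 percentiles. Replicates are driven by a single
documented RNG stream, so results are bit-reproducible given a seed.

Stratified contrasts use the Wald statistic z = (p₁ − p₂)/√(se₁² + se₂²)
with a two-sided normal p-value, one test per table row, unadjusted for
multiplicity (mirroring how such tables are conventionally reported).
Prevalence ratios are computed on the *reported* one-decimal percentages
with half-away-from-zero rounding, via decimal arithmetic on the shortest
decimal representation of the inputs, so a midpoint such as 6.1/2.0 = 3.05
rounds to 3.1 exactly as a reader recomputing the table by hand would get.

Stratified estimation (early- vs late-onset tobacco smokers) runs the whole
machinery on each stratum's sub-forest: recruits whose recruiter fell in the
other stratum become pseudo-seeds. This mirrors subgroup analysis in
standard RDS tooling but inherits its weaknesses — cross-stratum edges are
discarded and the degree weights remain whole-network degrees — so
stratum-level estimates are noisier and can be more biased than whole-sample
ones (see Limitations).

## Equilibrium diagnostics

Two views, matching how field reports assess convergence:

- **Empirical**: the trait proportion in the accumulated sample up to each
  wave. Equilibrium is declared at the smallest wave from which *every*
  adjacent-wave change stays below the tolerance ("consistently below", not
  the first crossing). Tolerance defaults to 0.02, the stricter of the two
  conventional cutoffs (0.05 being the common software default).
- **Model-based**: the smallest t with max_g |(vSᵗ)_g − π_g| < tolerance,
  where v is the observed seed composition — the number of waves the
  estimated chain needs to forget its seeds.

Both are checked in the tests against brute-force oracles (independent
per-wave recounts; explicit matrix powering).

## The simulator

The study's field data are confidential, so validation rests on a simulator
that emulates the design rather than any particular dataset.

**Population.** A degree-corrected stochastic-block-model over
{blocking trait} × {onset stratum} blocks. Each member draws an onset
stratum (P(early) = 0.58, matching the observed 647/1115 split), a latent
drug-use propensity per stratum (0.288 early / 0.115 late for the
any-drug scenario), and — conditional on being drug-prone — independent
per-drug indicators scaled so the per-drug lifetime prevalences match the
observed stratified magnitudes. The latent layer is what makes polydrug use
dominate among users, as observed. Past-year use is drawn conditional on
lifetime use (persistence 0.33–0.48 by drug, the observed past-year /
lifetime ratios). Target degrees are log-normal (median 8, σ = 0.6, mean
≈ 10 — the true degree distribution is unreported, so this is an assumption,
not a fact), multiplied for trait-positive members (default 1.5; the
validation benchmarks use 2.0). Ties are sampled Chung-Lu style within and
between blocks with homophily odds (default 3 on the trait, 1.2 on the
stratum); the block-pair tie-mass matrix is rebalanced by iterative
proportional fitting so that expected degrees are preserved exactly — a
plain odds renormalisation would silently wash out the trait–degree
correlation the estimator is supposed to correct.

**Recruitment.** Seeds are drawn per source; hospital seeds oversample
lifetime hard-drug users with enrichment weight 8 (rehabilitation patients).
Recruitment is breadth-first: each recruiter draws a successful-referral
count from a distribution on 0..5 (default mean ≈ 1.5, with 94% of
referrers bringing one to three — matching the reported referral behaviour
and deep enough chains to reach eight waves), then recruits uniformly among
its not-yet-recruited neighbours, without replacement, until the yearly
target or the wave cap (8). A masking parameter lets trait-positive
recruiters down-weight trait-positive neighbours, reproducing the predicted
downward bias of crude prevalence when users conceal like peers. Yearly
rounds are independent forests on the same population, pooled afterwards —
repeated cross-sections, as in the original design (a member resampled in
two rounds appears as two records). The default scenario targets
144/328/350/293 participants from 6/14/15/12 seeds per round (35 community
+ 12 hospital in total).

**What the simulator does not model**: temporal change in the population,
refusals and incentive response, reporting error in traits, and any
particular real network topology (clustering, communities beyond the trait
blocks). Passing the validation suite therefore demonstrates correctness of
the estimation machinery under the model's assumptions, not robustness to
every field violation of them.

## Validation studies and sizes

- **Recovery**: 200 surveys, n = 1000 drawn from populations of 10 000 with
  true prevalence 0.20, users' degrees 2× non-users', homophily odds 3. The
  crude estimator is biased by about +0.11; the RDS-adjusted mean bias is
  ≈ −0.01 (required < 0.02 in magnitude).
- **Calibration**: 500 surveys, n = 300 from populations of 4000
  (prevalence 0.20, homophily 2, trait-independent degrees), B = 200.
  Nominal-95% percentile intervals cover the realised population prevalence
  95.2% of the time (accepted band 92–98%). The estimand per replicate is
  that population's realised prevalence, so finite-population noise in the
  truth is not charged against the interval.
- Population and replicate sizes for the in-repo analysis scripts are
  scaled-down versions of the same studies; the test suite runs the full
  sizes above.

## Known limitations

- Stratified (sub-forest) estimates use whole-network degrees and discard
  cross-stratum recruitment, so subgroup prevalences are less reliable than
  whole-sample ones; in simulations the minority stratum's estimate can be
  visibly biased even when the pooled estimate is accurate. Ratios of
  stratified estimates inherit this.
- The RDS-I estimator assumes with-replacement sampling; at sampling
  fractions well above ~10% of a group, depletion biases appear that no
  option here corrects (successive-sampling estimators are out of scope).
- The coupon-limit invariant (≤5 recruits) is structurally enforced by the
  sibling-digit code space; the explicit coupon-limit error fires on raw
  record lists before code-collision checks, so a six-recruit file is
  diagnosed as a coupon violation rather than a duplicate code.
- Percentile bootstrap intervals at small B are slightly narrow; B ≥ 1000
  is recommended for reported tables (the default).
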