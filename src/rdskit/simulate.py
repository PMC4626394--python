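"""Synthetic populations and chain-referral (RDS) survey simulation.

The study data this package was built around are confidential, so every
estimator and diagnostic is exercised against a simulator that emulates the
field procedure: a hidden population of regular tobacco-and-alcohol users
with drug-use traits clustered in the social network, seeds drawn from
community venues and hospital rehabilitation programs, and coupon-limited
peer recruitment over a bounded number of waves.

Population model
----------------
A degree-corrected stochastic block model over {blocking trait} x {smoking
onset stratum} blocks.  Each member gets

* an onset stratum (early: first tobacco use before 18; late: 18+),
* a latent drug-use propensity drawn per stratum, under which the individual
  drug traits are conditionally independent — this is what makes polydrug
  use common among users, as observed in the field,
* a target degree (log-normal), optionally inflated for trait-positive
  members (drug users tend to know more fellow users of legal substances),
* ties sampled Chung-Lu style with block-pair odds multipliers, renormalised
  to preserve the total number of ties.

Recruitment model
-----------------
Seeds are drawn per source (hospital seeds oversample hard-drug users by an
enrichment factor); each recruiter draws a coupon count (support 0..5, mode
1-3) and recruits uniformly — or with a masking preference — among its
not-yet-recruited eligible neighbours, breadth-first, until the yearly
target size or the wave cap is reached.  Yearly rounds are independent
forests over the same population, pooled afterwards.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .codes import ReferralCode, seed_code
from .errors import ConfigError
from .records import ParticipantRecord

CLUB_DRUGS = ("ketamine", "ecstasy", "marijuana")
HARD_DRUGS = ("methamphetamine", "heroin")


class ExhaustionWarning(UserWarning):
    """The referral process ran out of recruitable members before the target."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class DrugModel:
    """Lifetime prevalence per onset stratum and past-year persistence."""

    lifetime_early: float
    lifetime_late: float
    past_year_given_lifetime: float = 0.4


@dataclass
class TraitModel:
    early_onset_prob: float = 0.58
    any_use_early: float = 0.288
    any_use_late: float = 0.115
    drugs: dict[str, DrugModel] = field(default_factory=dict)
    male_prob: float = 0.573


@dataclass
class DegreeModel:
    """Log-normal target degrees; ``user_multiplier`` scales trait-positives."""

    median: float = 8.0
    sigma: float = 0.6
    user_multiplier: float = 1.5


@dataclass
class HomophilyModel:
    """Within- vs between-group tie odds for the blocking trait and stratum."""

    trait: str = "any_illegal:lifetime"
    odds: float = 3.0
    stratum_odds: float = 1.2


@dataclass
class CouponModel:
    """Distribution of successful referrals per recruiter, support 0..5."""

    probs: tuple[float, ...] = (0.18, 0.35, 0.27, 0.15, 0.04, 0.01)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.size != 6 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError("coupon probabilities must be 6 non-negatives summing to 1")

    @property
    def mean(self) -> float:
        return float(np.dot(np.arange(6), self.probs))


@dataclass
class YearPlan:
    year: int
    target_n: int
    community_seeds: int
    hospital_seeds: int


@dataclass
class SimulationConfig:
    population_size: int = 20000
    trait_model: TraitModel = field(default_factory=TraitModel)
    degree_model: DegreeModel = field(default_factory=DegreeModel)
    homophily: HomophilyModel = field(default_factory=HomophilyModel)
    coupon_model: CouponModel = field(default_factory=CouponModel)
    years: list[YearPlan] = field(default_factory=list)
    max_waves: int = 8
    hospital_enrichment: float = 8.0
    recruit_same_trait_weight: float = 1.0
    degree_noise_sigma: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for p in [
            self.trait_model.early_onset_prob,
            self.trait_model.any_use_early,
            self.trait_model.any_use_late,
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.total_seeds() > self.population_size:
            raise ConfigError("more seeds than population members")
        if self.homophily.odds <= 0 or self.hospital_enrichment <= 0:
            raise ConfigError("odds and enrichment must be positive")

    def total_seeds(self) -> int:
        return sum(y.community_seeds + y.hospital_seeds for y in self.years)

    def total_target(self) -> int:
        return sum(y.target_n for y in self.years)

    # -- declarative round trip --------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coupon_model"]["probs"] = list(d["coupon_model"]["probs"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["trait_model"] = TraitModel(
            **{
                **d.get("trait_model", {}),
                "drugs": {
                    name: DrugModel(**dm)
                    for name, dm in d.get("trait_model", {}).get("drugs", {}).items()
                },
            }
        )
        d["degree_model"] = DegreeModel(**d.get("degree_model", {}))
        d["homophily"] = HomophilyModel(**d.get("homophily", {}))
        cm = d.get("coupon_model", {})
        d["coupon_model"] = CouponModel(tuple(cm.get("probs", CouponModel().probs)))
        d["years"] = [YearPlan(**y) for y in d.get("years", [])]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


@dataclass
class PopulationNetwork:
    """A synthetic hidden population with its undirected tie structure."""

    size: int
    stratum: np.ndarray  # "early"/"late" per member
    traits: dict[str, np.ndarray]  # trait name -> 0/1 per member
    age: np.ndarray
    sex: np.ndarray
    adjacency: list[np.ndarray]  # neighbour indices per member
    block_trait: str

    @property
    def degree(self) -> np.ndarray:
        return np.array([a.size for a in self.adjacency])

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency[i]

    def n_edges(self) -> int:
        return int(self.degree.sum()) // 2


def _derive_composites(traits: dict[str, np.ndarray], drugs: list[str]) -> None:
    """Add any_illegal / any_club / any_hard per window, in place."""
    for window in ("lifetime", "past_year"):
        present = [d for d in drugs if f"{d}:{window}" in traits]
        if not present:
            continue
        stack = np.array([traits[f"{d}:{window}"] for d in present])
        traits[f"any_illegal:{window}"] = stack.any(axis=0).astype(np.int8)
        club = [d for d in present if d in CLUB_DRUGS]
        hard = [d for d in present if d in HARD_DRUGS]
        if club:
            traits[f"any_club:{window}"] = (
                np.array([traits[f"{d}:{window}"] for d in club]).any(axis=0).astype(np.int8)
            )
        if hard:
            traits[f"any_hard:{window}"] = (
                np.array([traits[f"{d}:{window}"] for d in hard]).any(axis=0).astype(np.int8)
            )


def generate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> PopulationNetwork:
    """Draw a population network per the config; reproducible given the seed."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n = config.population_size
    tm = config.trait_model

    early = rng.random(n) < tm.early_onset_prob
    stratum = np.where(early, "early", "late")

    p_any = np.where(early, tm.any_use_early, tm.any_use_late)
    user = rng.random(n) < p_any

    traits: dict[str, np.ndarray] = {}
    for drug, dm in tm.drugs.items():
        p_cond_early = min(dm.lifetime_early / tm.any_use_early, 1.0) if tm.any_use_early else 0.0
        p_cond_late = min(dm.lifetime_late / tm.any_use_late, 1.0) if tm.any_use_late else 0.0
        p_cond = np.where(early, p_cond_early, p_cond_late)
        lifetime = user & (rng.random(n) < p_cond)
        traits[f"{drug}:lifetime"] = lifetime.astype(np.int8)
        traits[f"{drug}:past_year"] = (
            lifetime & (rng.random(n) < dm.past_year_given_lifetime)
        ).astype(np.int8)
    _derive_composites(traits, list(tm.drugs))

    block_trait = config.homophily.trait
    if block_trait not in traits:
        raise ConfigError(
            f"homophily trait {block_trait!r} not among generated traits "
            f"{sorted(traits)}"
        )
    tval = traits[block_trait].astype(bool)

    dm_ = config.degree_model
    target = rng.lognormal(mean=np.log(dm_.median), sigma=dm_.sigma, size=n)
    target = np.where(tval, target * dm_.user_multiplier, target)

    adjacency = _sample_block_edges(
        target, tval, early, config.homophily.odds, config.homophily.stratum_odds, rng, n
    )

    age = rng.integers(18, 51, size=n)
    sex = np.where(rng.random(n) < tm.male_prob, "M", "F")
    return PopulationNetwork(
        size=n,
        stratum=stratum,
        traits=traits,
        age=age,
        sex=sex,
        adjacency=adjacency,
        block_trait=block_trait,
    )


def _sample_block_edges(
    weights: np.ndarray,
    trait: np.ndarray,
    stratum_flag: np.ndarray,
    trait_odds: float,
    stratum_odds: float,
    rng: np.random.Generator,
    n: int,
) -> list[np.ndarray]:
    """Chung-Lu edges with block-pair odds, total tie count preserved."""
    block = trait.astype(int) * 2 + stratum_flag.astype(int)
    n_blocks = 4
    members = [np.nonzero(block == b)[0] for b in range(n_blocks)]
    W = np.array([weights[m].sum() for m in members])
    total_W = weights.sum()
    m_edges = int(round(total_W / 2.0))

    omega = np.ones((n_blocks, n_blocks))
    for a in range(n_blocks):
        for b in range(n_blocks):
            if (a >> 1) == (b >> 1):
                omega[a, b] *= trait_odds
            if (a & 1) == (b & 1):
                omega[a, b] *= stratum_odds
    score = omega * np.outer(W, W)
    if score.sum() <= 0:
        raise ConfigError("infeasible homophily/degree combination: no tie mass")
    # Iterative proportional fitting: rescale the block-pair tie mass so each
    # block's endpoint total matches its degree mass.  This preserves the
    # configured expected degrees (e.g. users' mean degree really is
    # user_multiplier times non-users') while keeping the homophily odds
    # structure of the prior; without it the odds renormalisation would wash
    # out trait-dependent degrees.
    live = W > 0
    M = score.copy()
    for _ in range(200):
        rs = M.sum(axis=1)
        M[live] *= (W[live] / rs[live])[:, None]
        cs = M.sum(axis=0)
        M[:, live] *= (W[live] / cs[live])[None, :]
        if np.max(np.abs(M.sum(axis=1)[live] - W[live]) / W[live]) < 1e-6:
            break
    M = (M + M.T) / 2.0
    pair_counts = rng.multinomial(m_edges, (M / M.sum()).ravel()).reshape(
        n_blocks, n_blocks
    )

    us, vs = [], []
    probs = [weights[m] / weights[m].sum() if m.size else None for m in members]
    for a in range(n_blocks):
        for b in range(n_blocks):
            c = int(pair_counts[a, b])
            if c == 0:
                continue
            if members[a].size == 0 or members[b].size == 0:
                continue
            us.append(rng.choice(members[a], size=c, p=probs[a]))
            vs.append(rng.choice(members[b], size=c, p=probs[b]))
    u = np.concatenate(us) if us else np.array([], dtype=int)
    v = np.concatenate(vs) if vs else np.array([], dtype=int)
    keep = u != v
    u, v = u[keep], v[keep]
    lo, hi = np.minimum(u, v), np.maximum(u, v)
    pairs = np.unique(np.stack([lo, hi], axis=1), axis=0)

    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    bounds = np.searchsorted(src, np.arange(n + 1))
    return [dst[bounds[i]:bounds[i + 1]] for i in range(n)]


# ---------------------------------------------------------------------------
# Recruitment
# ---------------------------------------------------------------------------


def _draw_seeds(
    population: PopulationNetwork,
    n_community: int,
    n_hospital: int,
    enrichment: float,
    rng: np.random.Generator,
) -> list[tuple[int, str]]:
    """Seed members with their source; hospital seeds oversample hard-drug users."""
    degree = population.degree
    eligible = np.nonzero(degree >= 1)[0]
    if eligible.size < n_community + n_hospital:
        raise ConfigError("not enough connected members to seed from")
    hard = population.traits.get(
        "any_hard:lifetime", population.traits[population.block_trait]
    )
    w = np.where(hard[eligible] > 0, enrichment, 1.0)
    hospital = rng.choice(
        eligible, size=n_hospital, replace=False, p=w / w.sum()
    ) if n_hospital else np.array([], dtype=int)
    rest = np.setdiff1d(eligible, hospital)
    community = rng.choice(rest, size=n_community, replace=False)
    out = [(int(i), "community") for i in community]
    out += [(int(i), "hospital") for i in hospital]
    return out


def simulate_rds(
    population: PopulationNetwork,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[ParticipantRecord]:
    """Run the full multi-year chain-referral survey; returns pooled records.

    Each yearly round is an independent forest on the same population
    (repeated cross-sections); referral codes are emitted in the F-code
    dialect with seed labels numbered consecutively across years.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if not config.years:
        raise ConfigError("config.years is empty: nothing to simulate")
    width = max(10, config.max_waves + 1)
    records: list[ParticipantRecord] = []
    seed_counter = 0
    for plan in config.years:
        seed_counter, recs = _simulate_year(
            population, config, plan, seed_counter, width, rng
        )
        records.extend(recs)
    return records


def _simulate_year(
    population: PopulationNetwork,
    config: SimulationConfig,
    plan: YearPlan,
    seed_counter: int,
    width: int,
    rng: np.random.Generator,
) -> tuple[int, list[ParticipantRecord]]:
    coupon_probs = np.asarray(config.coupon_model.probs)
    block = population.traits[population.block_trait]
    mask_w = config.recruit_same_trait_weight

    seeds = _draw_seeds(
        population, plan.community_seeds, plan.hospital_seeds,
        config.hospital_enrichment, rng,
    )
    recruited: dict[int, tuple[ReferralCode, str]] = {}
    queue: deque[int] = deque()
    for member, source in seeds:
        seed_counter += 1
        recruited[member] = (seed_code(f"F{seed_counter:03d}", width), source)
        queue.append(member)

    while queue and len(recruited) < plan.target_n:
        member = queue.popleft()
        code, source = recruited[member]
        if code.wave >= config.max_waves:
            continue
        n_coupons = int(rng.choice(6, p=coupon_probs))
        if n_coupons == 0:
            continue
        nbrs = population.adjacency[member]
        cand = np.array([v for v in nbrs if v not in recruited], dtype=int)
        if cand.size == 0:
            continue
        take = min(n_coupons, cand.size, plan.target_n - len(recruited))
        if take <= 0:
            break
        if mask_w == 1.0 or not block[member]:
            chosen = rng.choice(cand, size=take, replace=False)
        else:
            # Masking: a trait-positive recruiter steers coupons away from
            # fellow users, so their trait-positive neighbours get weight
            # mask_w < 1.  Weighted sampling without replacement via
            # exponential keys.
            w = np.where(block[cand] > 0, mask_w, 1.0)
            keys = rng.exponential(size=cand.size) / w
            chosen = cand[np.argsort(keys)[:take]]
        for sib, v in enumerate(chosen, start=1):
            recruited[int(v)] = (code.child(sib), source)
            queue.append(int(v))

    if len(recruited) < plan.target_n:
        warnings.warn(
            f"year {plan.year}: referral process exhausted at n={len(recruited)} "
            f"before target {plan.target_n}",
            ExhaustionWarning,
            stacklevel=2,
        )

    degree = population.degree
    recs = []
    for member, (code, source) in recruited.items():
        d = int(degree[member])
        if config.degree_noise_sigma > 0:
            d = max(1, int(round(d * np.exp(rng.normal(0.0, config.degree_noise_sigma)))))
        recs.append(
            ParticipantRecord(
                pid=f"{plan.year}-{member:05d}",
                code=code,
                degree=d,
                age_years=int(population.age[member]),
                sex=str(population.sex[member]),
                onset_stratum=str(population.stratum[member]),
                traits={t: int(population.traits[t][member]) for t in population.traits},
                year=plan.year,
                seed_source=source,
            )
        )
    return seed_counter, recs


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def scenario_default(rng_seed: int | None = None) -> SimulationConfig:
    """The study-design scenario: 47 seeds (35 community, 12 hospital), four
    yearly rounds targeting 144/328/350/293 participants (1115 total), at most
    eight recruitment waves, and drug prevalences of the observed magnitude
    conditional on the smoking-onset stratum."""
    drugs = {
        "ketamine": DrugModel(0.163, 0.057, 0.37),
        "ecstasy": DrugModel(0.150, 0.075, 0.34),
        "marijuana": DrugModel(0.136, 0.064, 0.36),
        "methamphetamine": DrugModel(0.102, 0.027, 0.48),
        "heroin": DrugModel(0.043, 0.011, 0.33),
    }
    years = [
        YearPlan(2007, 144, 5, 1),
        YearPlan(2008, 328, 10, 4),
        YearPlan(2009, 350, 11, 4),
        YearPlan(2010, 293, 9, 3),
    ]
    return SimulationConfig(
        population_size=20000,
        trait_model=TraitModel(drugs=drugs),
        years=years,
        max_waves=8,
        rng_seed=rng_seed,
    )


def scenario_single_trait(
    prevalence: float = 0.20,
    degree_ratio: float = 2.0,
    homophily_odds: float = 3.0,
    population_size: int = 10000,
    sample_size: int = 1000,
    n_seeds: int = 10,
    max_waves: int = 12,
    rng_seed: int | None = None,
) -> SimulationConfig:
    """A one-trait benchmark population for estimator validation: known true
    prevalence, trait-correlated degree (``degree_ratio`` x for users), and
    a single survey round."""
    tm = TraitModel(
        early_onset_prob=0.5,
        any_use_early=prevalence,
        any_use_late=prevalence,
        drugs={"drug": DrugModel(prevalence, prevalence, 1.0)},
    )
    return SimulationConfig(
        population_size=population_size,
        trait_model=tm,
        degree_model=DegreeModel(median=8.0, sigma=0.5, user_multiplier=degree_ratio),
        homophily=HomophilyModel(trait="drug:lifetime", odds=homophily_odds,
                                 stratum_odds=1.0),
        coupon_model=CouponModel((0.05, 0.20, 0.30, 0.30, 0.10, 0.05)),
        years=[YearPlan(2007, sample_size, n_seeds, 0)],
        max_waves=max_waves,
        hospital_enrichment=1.0,
        rng_seed=rng_seed,
    )
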