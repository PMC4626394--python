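"""Synthetic population and chain-referral simulation behaviour."""

import collections

import numpy as np
import pytest

from rdskit import (
    SimulationConfig,
    TraitPartition,
    build_recruitment_forest,
    crude_proportion,
    generate_population,
    scenario_default,
    scenario_single_trait,
    simulate_rds,
)
from rdskit.errors import ConfigError
from rdskit.simulate import CouponModel, DegreeModel, ExhaustionWarning, YearPlan


class TestConfig:
    def test_default_scenario_matches_study_design(self):
        cfg = scenario_default()
        assert cfg.total_seeds() == 47
        assert sum(y.community_seeds for y in cfg.years) == 35
        assert sum(y.hospital_seeds for y in cfg.years) == 12
        assert [y.target_n for y in cfg.years] == [144, 328, 350, 293]
        assert cfg.total_target() == 1115
        assert cfg.max_waves == 8

    def test_yaml_round_trip(self, tmp_path):
        cfg = scenario_default(rng_seed=3)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg

    def test_bad_coupon_distribution_rejected(self):
        with pytest.raises(ConfigError):
            CouponModel((0.5, 0.5, 0.5, 0.0, 0.0, 0.0))

    def test_more_seeds_than_members_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(
                population_size=5,
                years=[YearPlan(2007, 5, 10, 0)],
            )


class TestPopulation:
    def test_fixed_seed_is_reproducible(self):
        cfg = scenario_single_trait(population_size=2000, rng_seed=9)
        a = generate_population(cfg)
        b = generate_population(cfg)
        assert a.traits.keys() == b.traits.keys()
        for t in a.traits:
            np.testing.assert_array_equal(a.traits[t], b.traits[t])
        for x, y in zip(a.adjacency, b.adjacency):
            np.testing.assert_array_equal(x, y)

    def test_trait_frequency_matches_config(self):
        cfg = scenario_single_trait(prevalence=0.2, population_size=5000, rng_seed=11)
        pop = generate_population(cfg)
        assert pop.traits["drug:lifetime"].mean() == pytest.approx(0.2, abs=0.02)

    def test_degree_multiplier_realised(self):
        cfg = scenario_single_trait(degree_ratio=2.0, rng_seed=12)
        pop = generate_population(cfg)
        t = pop.traits["drug:lifetime"].astype(bool)
        ratio = pop.degree[t].mean() / pop.degree[~t].mean()
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_null_homophily_mixes_proportionally(self):
        """At odds 1 the within-group tie share matches the degree-mass share."""
        cfg = scenario_single_trait(
            homophily_odds=1.0, degree_ratio=1.0, population_size=6000, rng_seed=13
        )
        pop = generate_population(cfg)
        t = pop.traits["drug:lifetime"].astype(bool)
        deg = pop.degree
        share = deg[t].sum() / deg.sum()
        within = 0
        total = 0
        for i, nbrs in enumerate(pop.adjacency):
            total += nbrs.size
            if t[i]:
                within += t[nbrs].sum()
        observed = within / total  # P(both ends users)
        expected = share**2
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(observed - expected) < 5 * se

    def test_homophily_concentrates_ties(self):
        cfg1 = scenario_single_trait(homophily_odds=1.0, population_size=6000, rng_seed=14)
        cfg5 = scenario_single_trait(homophily_odds=5.0, population_size=6000, rng_seed=14)
        frac = {}
        for key, cfg in (("null", cfg1), ("strong", cfg5)):
            pop = generate_population(cfg)
            t = pop.traits["drug:lifetime"].astype(bool)
            same = sum(int(t[nbr.astype(int)].sum()) for i, nbr in
                       enumerate(pop.adjacency) if t[i])
            frac[key] = same / max(pop.degree[t].sum(), 1)
        assert frac["strong"] > frac["null"] + 0.1


class TestRecruitment:
    def test_no_participant_recruited_twice(self, simulated_survey):
        _, _, records, _ = simulated_survey
        pids = [r.pid for r in records]
        assert len(pids) == len(set(pids))

    def test_wave_equals_graph_distance_from_seed(self, simulated_survey):
        _, _, _, forest = simulated_survey
        for pid in forest.nodes:
            d = 0
            cur = pid
            while (parent := forest.recruiter_of(cur)) is not None:
                cur = parent
                d += 1
            assert forest.wave_of(pid) == d

    def test_zero_coupons_give_isolated_seeds(self):
        cfg = scenario_single_trait(population_size=500, sample_size=100,
                                    n_seeds=5, rng_seed=15)
        cfg.coupon_model = CouponModel((1.0, 0, 0, 0, 0, 0))
        rng = np.random.default_rng(15)
        pop = generate_population(cfg, rng)
        with pytest.warns(ExhaustionWarning):
            records = simulate_rds(pop, cfg, rng)
        forest = build_recruitment_forest(records)
        assert len(forest) == 5
        assert forest.max_wave == 0

    def test_single_coupon_yields_single_chains(self):
        cfg = scenario_single_trait(population_size=2000, sample_size=40,
                                    n_seeds=1, max_waves=60, rng_seed=16)
        cfg.coupon_model = CouponModel((0.0, 1.0, 0, 0, 0, 0))
        rng = np.random.default_rng(16)
        pop = generate_population(cfg, rng)
        records = simulate_rds(pop, cfg, rng)
        forest = build_recruitment_forest(records)
        waves = sorted(r.wave for r in records)
        assert waves == list(range(len(records)))  # one straight chain

    def test_mean_recruits_per_recruiter_between_one_and_three(self):
        """Referrers in the study-design scenario mostly bring 1-3 recruits."""
        means = []
        for rep in range(5):
            cfg = scenario_default(rng_seed=400 + rep)
            rng = np.random.default_rng(400 + rep)
            pop = generate_population(cfg, rng)
            records = simulate_rds(pop, cfg, rng)
            forest = build_recruitment_forest(records)
            kids = collections.Counter(a for a, _ in forest.edges())
            means.append(np.mean(list(kids.values())))
        assert 1.0 <= np.mean(means) <= 3.0

    def test_yearly_counts_and_seed_sources(self):
        cfg = scenario_default(rng_seed=17)
        rng = np.random.default_rng(17)
        pop = generate_population(cfg, rng)
        records = simulate_rds(pop, cfg, rng)
        per_year = collections.Counter(r.year for r in records)
        for plan in cfg.years:
            assert per_year[plan.year] <= plan.target_n
        seeds = [r for r in records if r.is_seed]
        src = collections.Counter(r.seed_source for r in seeds)
        assert len(seeds) == 47
        assert src["community"] == 35 and src["hospital"] == 12

    def test_masking_depresses_crude_prevalence(self):
        """Users steering coupons away from users biases crude prevalence down."""
        crude = {}
        for key, w in (("uniform", 1.0), ("masking", 0.25)):
            vals = []
            for rep in range(8):
                cfg = scenario_single_trait(population_size=4000, sample_size=400,
                                            rng_seed=500 + rep)
                cfg.recruit_same_trait_weight = w
                rng = np.random.default_rng(500 + rep)
                pop = generate_population(cfg, rng)
                records = simulate_rds(pop, cfg, rng)
                part = TraitPartition.from_binary_trait(records, "drug:lifetime")
                vals.append(crude_proportion(records, part)["user"].proportion)
            crude[key] = np.mean(vals)
        assert crude["masking"] < crude["uniform"]


def test_unbiased_crude_under_null_design():
    """With no homophily and trait-independent degree, the crude estimator is
    unbiased (mean error well under 0.01 over replicates)."""
    errs = []
    for rep in range(30):
        cfg = scenario_single_trait(homophily_odds=1.0, degree_ratio=1.0,
                                    population_size=6000, rng_seed=None)
        rng = np.random.default_rng(np.random.SeedSequence(600, spawn_key=(rep,)))
        pop = generate_population(cfg, rng)
        records = simulate_rds(pop, cfg, rng)
        part = TraitPartition.from_binary_trait(records, "drug:lifetime")
        crude = crude_proportion(records, part)["user"].proportion
        errs.append(crude - pop.traits["drug:lifetime"].mean())
    assert abs(np.mean(errs)) < 0.01
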