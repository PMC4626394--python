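"""Shared fixtures: tiny hand-built recruitment forests and a simulated survey."""

from __future__ import annotations

import numpy as np
import pytest

from rdskit import (
    ParticipantRecord,
    build_recruitment_forest,
    generate_population,
    parse_referral_code,
    scenario_single_trait,
    simulate_rds,
)


def make_record(
    pid: str,
    code: str,
    degree: int = 5,
    trait: int = 0,
    stratum: str = "late",
    year: int = 2007,
    age: int = 30,
    **extra_traits,
) -> ParticipantRecord:
    traits = {"drug:lifetime": trait}
    traits.update(extra_traits)
    return ParticipantRecord(
        pid=pid,
        code=parse_referral_code(code),
        degree=degree,
        age_years=age,
        onset_stratum=stratum,
        traits=traits,
        year=year,
    )


@pytest.fixture
def chain3():
    """A single seed with a recruit and a second-wave recruit."""
    return [
        make_record("s", "F001-0000000000", degree=3, trait=1),
        make_record("a", "F001-1000000000", degree=2, trait=0),
        make_record("b", "F001-1100000000", degree=4, trait=0),
    ]


@pytest.fixture
def two_group_forest():
    """Four edges with hand-countable transitions: A->B, A->B, A->A, B->A.

    Groups: trait=1 is A ("user"), trait=0 is B ("non-user").
    """
    recs = [
        make_record("s", "F001-0000000000", trait=1, degree=2),   # A
        make_record("u1", "F001-1000000000", trait=0, degree=4),  # A->B
        make_record("u2", "F001-2000000000", trait=0, degree=2),  # A->B
        make_record("u3", "F001-3000000000", trait=1, degree=1),  # A->A
        make_record("v1", "F001-1100000000", trait=1, degree=3),  # B->A
    ]
    return recs


@pytest.fixture(scope="session")
def simulated_survey():
    """One benchmark single-trait survey (n=1000) plus its population."""
    cfg = scenario_single_trait(rng_seed=101)
    rng = np.random.default_rng(101)
    pop = generate_population(cfg, rng)
    records = simulate_rds(pop, cfg, rng)
    forest = build_recruitment_forest(records)
    return cfg, pop, records, forest
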