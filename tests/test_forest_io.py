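"""Forest construction invariants and participant-file round trips."""

import random

import pytest

from rdskit import build_recruitment_forest, read_participants, write_participants
from rdskit.errors import (
    CouponLimitError,
    DuplicateCodeError,
    MissingParentError,
    SchemaError,
    TraitValueError,
)
from rdskit.records import validate_degrees

from conftest import make_record


class TestForestConstruction:
    def test_single_chain_waves(self, chain3):
        forest = build_recruitment_forest(chain3)
        assert len(forest) == 3
        assert forest.roots == ["s"]
        assert [forest.wave_of(p) for p in ("s", "a", "b")] == [0, 1, 2]
        assert forest.edges() == [("a", "b"), ("s", "a")]

    def test_forest_of_isolated_seeds(self):
        recs = [
            make_record(f"s{i}", f"F{i:03d}-0000000000") for i in range(1, 48)
        ]
        forest = build_recruitment_forest(recs)
        assert len(forest.roots) == 47
        assert forest.max_wave == 0
        assert forest.edges() == []

    def test_coupon_limit_enforced(self):
        recs = [make_record("s", "F001-0000000000")] + [
            make_record(f"c{i}", f"F001-{i}000000000") for i in range(1, 6)
        ]
        build_recruitment_forest(recs)  # five children is legal
        recs6 = recs + [make_record("c6", "F001-1000000000")]  # a sixth recruit
        with pytest.raises(CouponLimitError):
            build_recruitment_forest(recs6)

    def test_orphan_code_lists_missing_parent(self):
        recs = [
            make_record("s", "F001-0000000000"),
            make_record("x", "F001-1100000000"),  # parent F001-1000000000 absent
        ]
        with pytest.raises(MissingParentError) as err:
            build_recruitment_forest(recs)
        assert "F001-1000000000" in err.value.missing_codes

    def test_duplicate_code_rejected(self):
        recs = [
            make_record("a", "F001-0000000000"),
            make_record("b", "F001-0000000000"),
        ]
        with pytest.raises(DuplicateCodeError):
            build_recruitment_forest(recs)

    def test_order_independence(self, simulated_survey):
        """Shuffling the input records yields an identical forest."""
        _, _, records, forest = simulated_survey
        shuffled = records[:]
        random.Random(7).shuffle(shuffled)
        other = build_recruitment_forest(shuffled)
        assert other.edges() == forest.edges()
        assert other.roots == forest.roots

    def test_child_wave_is_parent_wave_plus_one(self, simulated_survey):
        _, _, _, forest = simulated_survey
        for a, b in forest.edges():
            assert forest.wave_of(b) == forest.wave_of(a) + 1

    def test_subset_promotes_orphans_to_roots(self, chain3):
        forest = build_recruitment_forest(chain3)
        sub = forest.subset({"a", "b"})
        assert sub.roots == ["a"]
        assert sub.edges() == [("a", "b")]


class TestParticipantIO:
    def test_round_trip_preserves_records(self, tmp_path, simulated_survey):
        _, _, records, _ = simulated_survey
        path = tmp_path / "participants.csv"
        write_participants(records[:10], path)
        back = read_participants(path)
        assert back == records[:10]

    def test_tab_delimited_accepted(self, tmp_path, chain3):
        path = tmp_path / "participants.tsv"
        write_participants(chain3, path, sep="\t")
        assert read_participants(path) == chain3

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_participants([], path)
        assert read_participants(path) == []

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("pid,code,year\n")
        with pytest.raises(SchemaError):
            read_participants(path)

    def test_non_binary_trait_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "pid,code,year,seed_source,age,sex,onset_stratum,degree,trait:k:lifetime\n"
            "p1,F001-0000000000,2007,community,30,M,late,5,2\n"
        )
        with pytest.raises(TraitValueError):
            read_participants(path)

    def test_unknown_trait_columns_preserved(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text(
            "pid,code,year,seed_source,age,sex,onset_stratum,degree,"
            "trait:betelnut:lifetime\n"
            "p1,F001-0000000000,2007,community,30,M,late,5,1\n"
        )
        (rec,) = read_participants(path)
        assert rec.traits == {"betelnut:lifetime": 1}

    def test_zero_degree_recruiter_flagged_with_warning(self):
        recs = [
            make_record("s", "F001-0000000000", degree=0),
            make_record("a", "F001-1000000000", degree=3),
        ]
        with pytest.warns(UserWarning, match="degree"):
            flagged = validate_degrees(recs)
        assert [r.pid for r in flagged] == ["s"]
        assert recs[0].flags
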