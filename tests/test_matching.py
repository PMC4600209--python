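"""Stratum keys, largest-remainder allocation and matched draws."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rehabrank.data_model import OUTCOME_COL, Item, ValidationError
from rehabrank.matching import (
    AGE_BINS,
    MatchingError,
    StratumKey,
    StratumTable,
    allocate_counts,
    assign_strata,
    draw_matched_sample,
    stratum_key,
)
from rehabrank.synthetic import GeneratorSpec, generate_cohort

from conftest import make_cohort

ADL_CODES = tuple(f"H2{c}" for c in "ABCDEFGHIJ")


def raw_record(**over):
    rec = {c: 0 for c in ADL_CODES}
    rec.update({"GENDER": 0, "B2A": 0, "K5": 0})
    rec.update(over)
    return rec


class TestStratumKey:
    def test_male_45_with_adl_impairment(self):
        key = stratum_key(raw_record(GENDER=1, H2C=2), age=45)
        assert key == StratumKey("<50", 1, 1, 0, 0)

    def test_female_90_all_zero(self):
        assert stratum_key(raw_record(), age=90) == StratumKey(">84", 0, 0, 0, 0)

    def test_negative_age_rejected(self):
        with pytest.raises(ValidationError, match="negative age"):
            stratum_key(raw_record(), age=-1)

    def test_exhaustive_against_independent_predicate(self):
        """Brute force over binary raw items x bin-boundary ages."""
        boundary_ages = [0, 49, 50, 64, 65, 74, 75, 84, 85, 99]

        def oracle(rec, age):
            # independently coded: arithmetic instead of any()/thresholds
            adl = 1 if sum(rec[c] for c in ADL_CODES) > 0 else 0
            cog = 1 if rec["B2A"] > 0 else 0
            falls = 1 if rec["K5"] > 0 else 0
            bin_ = AGE_BINS[sum(age >= e for e in (50, 65, 75, 85))]
            return StratumKey(bin_, rec["GENDER"], adl, cog, falls)

        # vary three representative ADL items to keep the product modest
        for h2a, h2f, h2j, gender, b2a, k5, age in itertools.product(
                (0, 1), (0, 1), (0, 1), (0, 1), (0, 1), (0, 1), boundary_ages):
            rec = raw_record(H2A=h2a, H2F=h2f, H2J=h2j, GENDER=gender, B2A=b2a, K5=k5)
            assert stratum_key(rec, age=age) == oracle(rec, age)


class TestStratumTable:
    def test_packaged_table_is_valid(self, ca_table):
        assert len(ca_table) == 80
        assert abs(ca_table.total - 100.0) < 1e-9

    def test_negative_percentage_rejected(self):
        cells = {StratumKey("<50", 0, 0, 0, 0): 101.0, StratumKey(">84", 1, 1, 1, 1): -1.0}
        with pytest.raises(ValidationError, match="negative"):
            StratumTable(cells)

    def test_total_off_by_more_than_tolerance_rejected(self):
        with pytest.raises(ValidationError, match="total"):
            StratumTable({StratumKey("<50", 0, 0, 0, 0): 99.0})

    def test_csv_round_trip(self, ca_table, tmp_path):
        path = tmp_path / "table.csv"
        ca_table.to_csv(path)
        back = StratumTable.from_csv(path)
        assert back.cells == ca_table.cells


class TestAllocateCounts:
    def test_worked_example_integer_exact(self, ca_table):
        counts = allocate_counts(ca_table, 10_000)
        assert counts[StratumKey("<50", 1, 1, 1, 1)] == 6    # 10,000 x 0.06 %
        assert sum(counts.values()) == 10_000

    def test_zero_percentage_gets_zero(self):
        cells = {StratumKey("<50", 0, 0, 0, 0): 100.0, StratumKey(">84", 1, 1, 1, 1): 0.0}
        counts = allocate_counts(StratumTable(cells), 1234)
        assert counts[StratumKey(">84", 1, 1, 1, 1)] == 0

    def test_nonpositive_n_rejected(self, ca_table):
        with pytest.raises(ValidationError):
            allocate_counts(ca_table, 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.sampled_from([97, 10_000]))
    def test_counts_within_one_of_quota(self, seed, n):
        """Largest-remainder counts sum to n and never stray >= 1 from quota."""
        rng = np.random.default_rng(seed)
        raw = rng.random(80)
        pct = raw / raw.sum() * 100.0
        keys = [StratumKey(b, g, a, c, f)
                for b in AGE_BINS for g in (0, 1) for a in (0, 1)
                for c in (0, 1) for f in (0, 1)]
        table = StratumTable(dict(zip(keys, pct)))
        counts = allocate_counts(table, n)
        assert sum(counts.values()) == n
        for key, p in zip(keys, pct):
            assert abs(counts[key] - n * p / 100.0) < 1.0

    def test_scale_consistency_on_packaged_table(self, ca_table):
        """Doubling n never decreases a stratum count, nor more than doubles it."""
        for n in (500, 1000, 5000):
            a = allocate_counts(ca_table, n)
            b = allocate_counts(ca_table, 2 * n)
            for key in a:
                assert a[key] <= b[key] <= 2 * a[key] + 1


@pytest.fixture(scope="module")
def source():
    return generate_cohort(GeneratorSpec(n=30_000, exact_strata=True, seed=41))


class TestDrawMatchedSample:
    def test_per_stratum_counts_exact(self, source, ca_table):
        sample = draw_matched_sample(source, ca_table, 5_000, seed=7)
        counts = allocate_counts(ca_table, 5_000)
        observed = assign_strata(sample).value_counts()
        for key, c in counts.items():
            assert observed.get(key, 0) == c

    def test_determinism(self, source, ca_table):
        a = draw_matched_sample(source, ca_table, 2_000, seed=3)
        b = draw_matched_sample(source, ca_table, 2_000, seed=3)
        assert list(a.df.index) == list(b.df.index)

    def test_self_matching_returns_permutation(self):
        """Target = source's own empirical distribution at n = source size."""
        from rehabrank.matching import empirical_table
        src = generate_cohort(GeneratorSpec(n=2_000, exact_strata=True, seed=5))
        table = empirical_table(src)
        sample = draw_matched_sample(src, table, src.n, seed=1)
        assert sorted(sample.df.index) == sorted(src.df.index)

    def test_empty_stratum_is_reported(self, ca_table):
        # a tiny multinomial source will miss some of the 80 strata
        src = generate_cohort(GeneratorSpec(n=200, seed=9))
        with pytest.raises(MatchingError, match=r"stratum \("):
            draw_matched_sample(src, ca_table, 5_000, seed=1)

    def test_replacement_tops_up_short_stratum(self):
        from rehabrank.matching import empirical_table
        src = generate_cohort(GeneratorSpec(n=500, exact_strata=True, seed=13))
        table = empirical_table(src)
        sample = draw_matched_sample(src, table, 1_000, seed=2, allow_replacement=True)
        assert sample.n == 1_000
        assert not sample.df.index.duplicated().any()   # repeated clients disambiguated
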