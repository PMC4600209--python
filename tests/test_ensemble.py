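"""Ensemble aggregation arithmetic, ranker comparison and effect directions."""

import numpy as np
import pandas as pd
import pytest

from rehabrank.data_model import ValidationError
from rehabrank.ensemble import (
    RankMatrix,
    RankSummary,
    compare_rankings,
    effect_direction,
    ensemble_ranks,
    summarize,
)
from rehabrank.matching import MatchingError, StratumTable
from rehabrank.synthetic import ExtraItem, GeneratorSpec, default_battery, generate_cohort


def matrix_of(rows: np.ndarray) -> RankMatrix:
    d, K = rows.shape
    return RankMatrix(items=[f"I{j}" for j in range(d)], matrix=rows.astype(float),
                      sample_seeds=list(range(K)))


class TestAggregationArithmetic:
    def test_matches_direct_summation_on_random_rankings(self, rng):
        d, K = 12, 25
        cols = np.column_stack([rng.permutation(d) + 1.0 for _ in range(K)])
        summary = summarize(matrix_of(cols))
        assert np.array_equal(summary.mean_rank, cols.sum(axis=1) / K)
        assert np.allclose(summary.sem, np.std(cols, axis=1, ddof=1) / np.sqrt(K))
        # complete rankings all average to (d+1)/2
        assert abs(summary.mean_rank.mean() - (d + 1) / 2) < 1e-9

    def test_constant_rank_one_has_zero_dispersion(self):
        rows = np.vstack([np.ones(100), np.full(100, 2.0)])
        summary = summarize(matrix_of(rows))
        assert summary.mean_rank[0] == 1.00
        assert summary.sem[0] == 0.00

    def test_alternating_ranks_closed_form(self):
        rows = np.vstack([np.tile([1.0, 2.0], 50), np.tile([2.0, 1.0], 50)])
        summary = summarize(matrix_of(rows))
        assert summary.mean_rank[0] == pytest.approx(1.5)
        assert summary.sem[0] == pytest.approx(0.0502519, abs=1e-4)

    def test_single_sample_dispersion_defined_zero(self):
        summary = summarize(matrix_of(np.array([[3.0], [1.0], [2.0]])))
        assert np.all(summary.sem == 0.0)
        assert list(summary.mean_rank) == [3.0, 1.0, 2.0]


@pytest.fixture(scope="module")
def source():
    spec = GeneratorSpec(
        n=12_000,
        extra_items=default_battery()[:12],
        planted_effects={"B03": 1.8, "B04": -1.5},
        intercept=-1.2,
        seed=77,
        exact_strata=True,
    )
    return generate_cohort(spec)


class TestEnsembleRanks:
    def test_columns_are_complete_rankings(self, source, ca_table):
        matrix, summary = ensemble_ranks(source, ca_table, "path", K=3, n=800,
                                         master_seed=5, n_lambda=40)
        d = matrix.d
        for k in range(matrix.K):
            assert matrix.matrix[:, k].sum() == pytest.approx(d * (d + 1) / 2)
        assert summary.K == 3 and summary.n == 800
        assert np.all((summary.mean_rank >= 1) & (summary.mean_rank <= d))

    def test_planted_items_float_to_top_for_both_rankers(self, source, ca_table):
        for ranker, kw in (("path", {"n_lambda": 40}), ("forest", {"n_trees": 50})):
            _, summary = ensemble_ranks(source, ca_table, ranker, K=3, n=800,
                                        master_seed=1, **kw)
            s = pd.Series(summary.mean_rank, index=summary.items)
            assert s["B03"] <= 3 and s["B04"] <= 4, ranker

    def test_invalid_K_and_unknown_ranker(self, source, ca_table):
        with pytest.raises(ValidationError):
            ensemble_ranks(source, ca_table, "path", K=0, n=100, master_seed=0)
        with pytest.raises(ValidationError, match="unknown ranker"):
            ensemble_ranks(source, ca_table, "boosting", K=1, n=100, master_seed=0)

    def test_shortfall_error_names_sample_index(self, ca_table):
        small = generate_cohort(GeneratorSpec(n=300, extra_items=default_battery()[:3], seed=2))
        with pytest.raises(MatchingError, match="sample 0"):
            ensemble_ranks(small, ca_table, "path", K=2, n=5_000, master_seed=0)


class TestCompareRankings:
    @staticmethod
    def summary_from(ranks: dict[str, float]) -> RankSummary:
        items = list(ranks)
        return RankSummary(items=items, mean_rank=np.array([ranks[i] for i in items]),
                           sem=np.zeros(len(items)), sd=np.zeros(len(items)), K=1, n=0)

    def test_identical_rankings(self):
        s = self.summary_from({f"I{j}": j + 1.0 for j in range(30)})
        report = compare_rankings(s, s, top_threshold=10)
        assert report.spearman == pytest.approx(1.0)
        assert report.both_top == {f"I{j}" for j in range(10)}
        assert not report.only_a and not report.only_b

    def test_reversed_rankings(self):
        a = self.summary_from({f"I{j}": j + 1.0 for j in range(10)})
        b = self.summary_from({f"I{j}": 10.0 - j for j in range(10)})
        assert compare_rankings(a, b).spearman == pytest.approx(-1.0)

    def test_mismatched_item_sets_rejected(self):
        a = self.summary_from({"A": 1.0, "B": 2.0})
        b = self.summary_from({"A": 1.0, "C": 2.0})
        with pytest.raises(ValidationError, match="different item sets"):
            compare_rankings(a, b)

    def test_planted_signal_lands_in_both_top_sets(self, ca_table):
        """5 strong items among 30: both-top-10 captures >= 4 of 5 in >= 90 %
        of replicates (scaled-down surrogate for the full-profile study)."""
        battery = default_battery()[:30]
        planted = {"B03": 1.8, "B04": 1.6, "B05": -1.7, "B08": 1.5, "B09": -1.6}
        wins = 0
        reps = 10
        for rep in range(reps):
            src = generate_cohort(GeneratorSpec(
                n=12_000, extra_items=battery, planted_effects=planted,
                intercept=-1.4, seed=500 + rep, exact_strata=True))
            _, sp = ensemble_ranks(src, ca_table, "path", K=2, n=1_200,
                                   master_seed=rep, n_lambda=40)
            _, sf = ensemble_ranks(src, ca_table, "forest", K=2, n=1_200,
                                   master_seed=rep, n_trees=50)
            report = compare_rankings(sp, sf, top_threshold=10)
            wins += len(report.both_top & set(planted)) >= 4
        assert wins >= 9


class TestEffectDirection:
    def test_planted_signs_recovered_and_null_flagged(self):
        items = (ExtraItem("POS", levels=(0, 1), probs=(0.5, 0.5)),
                 ExtraItem("NEG", levels=(0, 1), probs=(0.5, 0.5)),
                 ExtraItem("NUL", levels=(0, 1), probs=(0.5, 0.5)))
        spec = GeneratorSpec(n=20_000, extra_items=items,
                             planted_effects={"POS": 1.5, "NEG": -1.5},
                             intercept=-1.0, seed=8)
        coh = generate_cohort(spec)
        signs = effect_direction(coh, ["POS", "NEG", "NUL"])
        assert signs["POS"].sign == "+" and not signs["POS"].low_confidence
        assert signs["NEG"].sign == "-" and not signs["NEG"].low_confidence
        assert signs["NUL"].low_confidence

    def test_unknown_item_rejected(self):
        coh = generate_cohort(GeneratorSpec(n=500, seed=1))
        with pytest.raises(ValidationError, match="not present"):
            effect_direction(coh, ["GHOST"])
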