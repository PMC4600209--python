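"""Group-penalized path solver: KKT contracts, oracles and entry-order ranks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rehabrank.data_model import Item, OUTCOME_COL, ValidationError, build_design
from rehabrank.lasso_path import (
    compute_lambda_max,
    entry_order,
    fit_path,
    n_pairwise_interactions,
    rank_items_path,
)

from conftest import design_from_matrix, make_cohort


def logistic_sample(rng, X, beta, intercept=0.0):
    eta = intercept + X @ beta
    return rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))


def kkt_audit(path, design, y):
    """Independent KKT recomputation from the stored coefficients."""
    X, groups = design.X, design.groups
    n = X.shape[0]
    w = np.sqrt(np.bincount(groups).astype(float))
    worst = 0.0
    for i, lam in enumerate(path.lambda_grid):
        beta = path.coefficients[i]
        eta = path.intercepts[i] + X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (p - y) / n
        worst = max(worst, abs(np.mean(p - y)))
        for g in range(design.n_groups):
            cols = np.flatnonzero(groups == g)
            bg = beta[cols]
            nrm = np.linalg.norm(bg)
            if nrm > 0:
                worst = max(worst, np.linalg.norm(grad[cols] + lam * w[g] * bg / nrm))
            else:
                worst = max(worst, max(0.0, np.linalg.norm(grad[cols]) - lam * w[g]))
    return worst


class TestLambdaMax:
    def test_all_zero_just_above_active_just_below(self, rng):
        X = rng.normal(size=(300, 6))
        y = logistic_sample(rng, X, np.array([1.5, -1.0, 0.8, 0, 0, 0]))
        design = design_from_matrix(X, list(range(6)), [f"V{g}" for g in range(6)])
        lam_max = compute_lambda_max(design, y)
        path = fit_path(design, y, n_lambda=2, lambda_min_ratio=0.99)
        solver = path._solver
        b0, beta, _ = solver.fit_at(lam_max * 1.0001)
        assert np.all(beta == 0.0)
        b0, beta, _ = solver.fit_at(lam_max * 0.99)
        assert np.any(beta != 0.0)

    def test_single_class_outcome_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        design = design_from_matrix(X, [0, 1], ["A", "B"])
        with pytest.raises(ValidationError, match="single class"):
            compute_lambda_max(design, np.ones(50))

    def test_orthogonal_column_has_zero_gradient(self, rng):
        y = np.r_[np.zeros(100), np.ones(100)]
        x_orth = rng.normal(size=200)
        resid = y - y.mean()
        x_orth = x_orth - resid * (x_orth @ resid) / (resid @ resid)
        x_sig = resid + 0.1 * rng.normal(size=200)
        design = design_from_matrix(np.c_[x_sig, x_orth], [0, 1], ["S", "O"])
        n = 200
        grad = design.X.T @ (y.mean() - y) / n
        assert abs(grad[1]) < 1e-12


class TestFitPath:
    def test_single_point_grid_is_all_zero(self, rng):
        X = rng.normal(size=(200, 4))
        y = logistic_sample(rng, X, np.array([1.0, 0, 0, 0]))
        design = design_from_matrix(X, [0, 1, 2, 3], list("ABCD"))
        path = fit_path(design, y, n_lambda=1)
        assert np.all(path.coefficients == 0.0)
        assert not path.active.any()

    def test_near_zero_penalty_matches_mle(self, rng):
        """Iteratively-reweighted-least-squares oracle at lambda -> 0."""
        X = rng.normal(size=(500, 4))
        y = logistic_sample(rng, X, np.array([1.2, -0.8, 0.5, 0.0]), intercept=0.3)
        design = design_from_matrix(X, [0, 1, 2, 3], list("ABCD"))
        path = fit_path(design, y, n_lambda=30, lambda_min_ratio=1e-6)
        mle = sm.Logit(y, sm.add_constant(design.X)).fit(disp=0)
        beta_hat = path.coefficients[-1]
        beta_mle = np.asarray(mle.params)[1:]
        rel = np.linalg.norm(beta_hat - beta_mle) / np.linalg.norm(beta_mle)
        assert rel < 1e-3

    def test_kkt_holds_at_every_grid_point(self, rng):
        X = rng.normal(size=(300, 7))
        # one 3-level categorical group (2 cols) + singletons
        groups = [0, 0, 1, 2, 3, 4, 5]
        y = logistic_sample(rng, X, np.array([0.8, -0.5, 1.2, 0, 0.4, 0, 0]))
        design = design_from_matrix(X, groups, [f"V{g}" for g in range(6)])
        path = fit_path(design, y, n_lambda=60)
        assert kkt_audit(path, design, y) < 1e-6

    def test_constant_group_never_enters(self, rng):
        df = pd.DataFrame({
            "DEAD": np.zeros(300, dtype=int),
            "LIVE": rng.integers(0, 2, 300),
            OUTCOME_COL: rng.integers(0, 2, 300),
        })
        coh = make_cohort(df, [Item("DEAD", "categorical", (0, 1)),
                               Item("LIVE", "categorical", (0, 1))])
        design = build_design(coh)
        y = coh.outcome
        path = fit_path(design, y, n_lambda=40)
        dead = design.group_codes.index("DEAD")
        assert not path.active[:, dead].any()
        rv = entry_order(path)
        assert rv.ranks["DEAD"] == max(rv.ranks.values())


class TestEntryOrder:
    def test_staggered_effects_order_and_dense_grid_oracle(self, rng):
        """Entry order matches effect-size order on orthogonalized columns,
        and agrees with a brute-force dense grid (G = 2,000)."""
        n = 1_500
        Q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
        X = Q * np.sqrt(n)
        y = logistic_sample(rng, X, np.array([2.0, 1.0, 0.5]))
        design = design_from_matrix(X, [0, 1, 2], ["STRONG", "MID", "WEAK"])
        rv = rank_items_path(design, y, n_lambda=100)
        assert rv.ranks["STRONG"] < rv.ranks["MID"] < rv.ranks["WEAK"]
        dense = rank_items_path(design, y, n_lambda=2_000)
        assert dense.ranks == rv.ranks

    def test_no_entry_means_total_tie(self, rng):
        X = rng.normal(size=(200, 5))
        y = rng.integers(0, 2, 200)
        design = design_from_matrix(X, list(range(5)), [f"N{j}" for j in range(5)])
        path = fit_path(design, y, n_lambda=1)   # grid = {lambda_max}: nothing enters
        rv = entry_order(path)
        assert all(r == 3.0 for r in rv.ranks.values())   # (d+1)/2 with d=5

    def test_entry_lambda_decreasing_in_rank(self, rng):
        X = rng.normal(size=(400, 6))
        y = logistic_sample(rng, X, np.array([1.5, 1.0, 0.6, 0.3, 0, 0]))
        design = design_from_matrix(X, list(range(6)), [f"V{j}" for j in range(6)])
        path = fit_path(design, y, n_lambda=80)
        rv = entry_order(path)
        entered = {g: lam for g, lam in path.entry_lambda.items()}
        codes = design.group_codes
        pairs = sorted(((rv.ranks[codes[g]], lam) for g, lam in entered.items()))
        lams = [lam for _, lam in pairs]
        assert all(a >= b for a, b in zip(lams, lams[1:]))

    def test_planted_strong_signal_ranks_first(self, rng):
        """Planted beta = 2.0 binary among 29 noise items: rank 1 in >= 95/100."""
        hits = 0
        reps = 100
        for rep in range(reps):
            r = np.random.default_rng(1000 + rep)
            n, d = 2_000, 30
            X = r.integers(0, 2, size=(n, d)).astype(float)
            y = logistic_sample(r, X[:, [0]], np.array([2.0]), intercept=-1.0)
            design = design_from_matrix(X, list(range(d)), [f"I{j}" for j in range(d)])
            rv = rank_items_path(design, y, n_lambda=40)
            hits += rv.ranks["I0"] == 1.0
        assert hits >= 95

    def test_scaling_invariance_through_standardization(self, rng):
        df = pd.DataFrame({
            "Z": rng.normal(size=500),
            "B": rng.integers(0, 2, 500),
        })
        eta = 1.2 * df["Z"].to_numpy() + 0.8 * df["B"].to_numpy() - 0.5
        df[OUTCOME_COL] = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        items = [Item("Z", "continuous"), Item("B", "categorical", (0, 1))]
        coh = make_cohort(df, items)
        base = rank_items_path(build_design(coh), coh.outcome, n_lambda=50)
        df2 = df.copy()
        df2["Z"] = df2["Z"] * 37.5   # positive rescale, then restandardized
        coh2 = make_cohort(df2, items)
        scaled = rank_items_path(build_design(coh2), coh2.outcome, n_lambda=50)
        assert base.ranks == scaled.ranks


def test_pairwise_interaction_count_formula():
    assert n_pairwise_interactions(4) == 6
    assert n_pairwise_interactions(2) == 1
    assert n_pairwise_interactions(1) == 0
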