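"""Random-forest permutation importance as the interaction-aware ranker.

A bagged ensemble of classification trees models interaction effects
automatically, so its permutation-based variable importance measure (VIM)
complements the main-effects-only path ranker: permuting one predictor's
values among each tree's out-of-bag (OOB) records and measuring the drop in
OOB accuracy is a marginal probe of how much the fitted model relies on that
predictor, interactions included.

Trees are scikit-learn ``DecisionTreeClassifier``s fit on explicit bootstrap
resamples so that per-tree OOB index sets are first-class; all of an item's
dummy columns are permuted jointly so importance lands at the original-item
level, comparable with the group-level path ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.tree import DecisionTreeClassifier

from .data_model import Cohort, DesignMatrix, ValidationError, build_design
from .lasso_path import RankVector


@dataclass
class ForestModel:
    """A fitted bagged-tree ensemble with explicit OOB bookkeeping."""

    trees: list
    oob_index: list[np.ndarray]     # per tree, indices never in its bootstrap
    design: DesignMatrix
    y: np.ndarray
    fit_params: dict

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def oob_accuracy(self) -> float:
        """Mean per-tree accuracy on that tree's out-of-bag records."""
        accs = [
            float(np.mean(tree.predict(self.design.X[oob]) == self.y[oob]))
            for tree, oob in zip(self.trees, self.oob_index)
            if len(oob)
        ]
        return float(np.mean(accs))


@dataclass
class VimVector:
    """Per-item permutation importance and the derived ranking."""

    importance: dict[str, float]
    ranks: RankVector


def fit_forest(cohort: Cohort | DesignMatrix, y: np.ndarray | None = None,
               n_trees: int = 500, max_features: str | int = "sqrt",
               min_samples_leaf: int = 5, seed: int = 0) -> ForestModel:
    """Fit ``n_trees`` classification trees on bootstrap resamples.

    Accepts a cohort (dummy-coded internally, unstandardized — trees are
    scale-free) or a prebuilt design plus outcome.  Defaults are the classic
    forest settings: sqrt-many candidate columns per split, Gini impurity,
    minimum leaf 5.
    """
    if isinstance(cohort, Cohort):
        design = build_design(cohort, standardize=False)
        y = cohort.outcome
    else:
        design = cohort
        if y is None:
            raise ValidationError("y is required when passing a DesignMatrix")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome has a single class; cannot fit a forest")
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    n = design.X.shape[0]
    trees, oobs = [], []
    ever_oob = np.zeros(n, dtype=bool)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        inbag = np.zeros(n, dtype=bool)
        inbag[boot] = True
        oob = np.flatnonzero(~inbag)
        ever_oob[oob] = True
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(design.X[boot], y[boot])
        trees.append(tree)
        oobs.append(oob)
    if not ever_oob.all():
        warnings.warn(
            f"{int((~ever_oob).sum())} record(s) are in-bag for every tree; "
            "their signal never reaches an OOB evaluation",
            stacklevel=2,
        )
    return ForestModel(
        trees=trees,
        oob_index=oobs,
        design=design,
        y=y,
        fit_params={"n_trees": n_trees, "max_features": max_features,
                    "min_samples_leaf": min_samples_leaf, "seed": seed},
    )


def permutation_vim(model: ForestModel, repeats: int = 1, seed: int = 0) -> VimVector:
    """Mean OOB-accuracy drop per item under joint permutation of its columns.

    For each tree and each of ``repeats`` independent permutations, an item's
    dummy columns are shuffled together among the tree's OOB records; the
    importance is the accuracy drop averaged over trees and repeats.  An item
    whose columns are constant has exactly zero importance, and the identity
    permutation would by construction yield a zero drop.
    """
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    design, y = model.design, model.y
    codes = design.group_codes
    col_groups = [design.group_columns(g) for g in range(design.n_groups)]
    is_constant = [bool(design.constant_mask[c].all()) for c in col_groups]
    drops = np.zeros(design.n_groups)
    n_eval = 0
    for tree, oob in zip(model.trees, model.oob_index):
        if len(oob) == 0:
            continue
        n_eval += 1
        Xo = design.X[oob].copy()
        yo = y[oob]
        base_acc = float(np.mean(tree.predict(Xo) == yo))
        for g, cols in enumerate(col_groups):
            if is_constant[g]:
                continue  # permutation cannot change a constant column
            saved = Xo[:, cols].copy()
            acc_sum = 0.0
            for _ in range(repeats):
                perm = rng.permutation(len(oob))
                Xo[:, cols] = saved[perm]
                acc_sum += float(np.mean(tree.predict(Xo) == yo))
            Xo[:, cols] = saved
            drops[g] += base_acc - acc_sum / repeats
    if n_eval == 0:
        raise ValidationError("no tree has out-of-bag records")
    drops /= n_eval
    importance = {code: float(drops[g]) for g, code in enumerate(codes)}
    rank_values = rankdata(-drops, method="average")
    ranks = RankVector(
        ranks={code: float(rank_values[g]) for g, code in enumerate(codes)},
        tie_policy_applied="importance descending, ties averaged",
    )
    return VimVector(importance=importance, ranks=ranks)


def rank_items_forest(cohort: Cohort | DesignMatrix, y: np.ndarray | None = None,
                      n_trees: int = 500, max_features: str | int = "sqrt",
                      min_samples_leaf: int = 5, repeats: int = 1,
                      seed: int = 0) -> RankVector:
    """Convenience: fit a forest and rank items by permutation importance."""
    model = fit_forest(cohort, y, n_trees=n_trees, max_features=max_features,
                       min_samples_leaf=min_samples_leaf, seed=seed)
    return permutation_vim(model, repeats=repeats, seed=seed + 1).ranks
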