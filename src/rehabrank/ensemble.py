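"""Ensemble rank aggregation over repeated matched samples.

Ranking variables once on a single sample is unstable, so the procedure
draws K frequency-matched samples S_1..S_K of size n from the source, ranks
the d included items on each with the chosen ranker, and aggregates: for
variable j,

    rbar(j) = (1/K) * sum_k r(j, k),

with a dispersion sigma(j) reported as the standard error of the mean rank,
SD({r(j, k)}) / sqrt(K) (the raw SD is also kept).  The full-scale study
profile is K = 100 samples of n = 10,000; a scaled-down profile (K = 10,
n = 2,000, d ~ 40) drives tests and demos.

Comparing the two rankers' rbar vectors — Spearman correlation plus the set
of items both place in the top ranks — probes interaction effects: items the
forest favours over the main-effects-only path ranker are interaction
suspects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr

from .data_model import Cohort, ValidationError, build_design
from .forest import rank_items_forest
from .lasso_path import RankVector, rank_items_path
from .matching import DEFAULT_MATCHING_ITEMS, MatchingError, MatchingItems, StratumTable, draw_matched_sample


@dataclass
class RankMatrix:
    """r(j, k) for item j (rows) and matched sample k (columns)."""

    items: list[str]
    matrix: np.ndarray          # (d, K)
    sample_seeds: list[int]

    @property
    def d(self) -> int:
        return len(self.items)

    @property
    def K(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=pd.Index(self.items, name="item"),
                            columns=[f"sample_{k}" for k in range(self.K)])


@dataclass
class RankSummary:
    """Per-item mean rank and its dispersion over the K samples."""

    items: list[str]
    mean_rank: np.ndarray
    sem: np.ndarray             # SD / sqrt(K); 0 when K == 1
    sd: np.ndarray              # raw sample SD of the ranks
    K: int
    n: int

    @property
    def d(self) -> int:
        return len(self.items)

    def as_series(self) -> pd.Series:
        return pd.Series(self.mean_rank, index=self.items, name="mean_rank")

    def top(self, threshold: float) -> set[str]:
        """Items with mean rank <= threshold (smaller = more important)."""
        return {it for it, r in zip(self.items, self.mean_rank) if r <= threshold}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "item": self.items,
            "mean_rank": self.mean_rank,
            "sem": self.sem,
            "sd": self.sd,
        }).sort_values("mean_rank").reset_index(drop=True)


def summarize(matrix: RankMatrix, n: int = 0) -> RankSummary:
    """Aggregate a rank matrix into mean ranks and dispersions."""
    K = matrix.K
    mean = matrix.matrix.mean(axis=1)
    if K > 1:
        sd = matrix.matrix.std(axis=1, ddof=1)
    else:
        sd = np.zeros(matrix.d)
    return RankSummary(items=list(matrix.items), mean_rank=mean,
                       sem=sd / np.sqrt(K), sd=sd, K=K, n=n)


def _ranker_fn(ranker, **kwargs):
    if callable(ranker):
        return lambda sample: ranker(sample, **kwargs)
    if ranker == "path":
        def run(sample: Cohort) -> RankVector:
            design = build_design(sample, standardize=True)
            return rank_items_path(design, sample.outcome, **kwargs)
        return run
    if ranker == "forest":
        def run(sample: Cohort) -> RankVector:
            return rank_items_forest(sample, **kwargs)
        return run
    raise ValidationError(f"unknown ranker {ranker!r}; expected 'path' or 'forest'")


def ensemble_ranks(source: Cohort, table: StratumTable, ranker, K: int, n: int,
                   master_seed: int, matching_items: MatchingItems = DEFAULT_MATCHING_ITEMS,
                   **ranker_kwargs) -> tuple[RankMatrix, RankSummary]:
    """Draw K matched samples, rank each, and aggregate.

    Sample k is drawn with seed ``master_seed + k`` — reproducible yet
    independent draws from the fixed source (a client may appear in several
    samples).  Stratum-shortfall errors are re-raised naming the failing
    sample index.
    """
    if K < 1:
        raise ValidationError(f"K must be >= 1, got {K}")
    if n < 1:
        raise ValidationError(f"sample size n must be >= 1, got {n}")
    run = _ranker_fn(ranker, **ranker_kwargs)
    items: list[str] | None = None
    columns = []
    seeds = []
    for k in range(K):
        seed_k = int(master_seed) + k
        seeds.append(seed_k)
        try:
            sample = draw_matched_sample(source, table, n, seed_k, items=matching_items)
        except MatchingError as err:
            raise MatchingError(f"sample {k}: {err}") from err
        rv = run(sample)
        if items is None:
            items = list(rv.ranks)
        columns.append([rv.ranks[it] for it in items])
    matrix = RankMatrix(items=items, matrix=np.array(columns).T, sample_seeds=seeds)
    return matrix, summarize(matrix, n=n)


# ---------------------------------------------------------------------------
# Ranker comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Agreement between two rank summaries over the same item universe."""

    spearman: float
    both_top: set[str]        # mean rank <= threshold under BOTH rankers
    only_a: set[str]          # top under a only
    only_b: set[str]          # top under b only
    top_threshold: float
    paired: pd.DataFrame      # item, mean_rank_a, mean_rank_b


def compare_rankings(a: RankSummary, b: RankSummary,
                     top_threshold: float = 20.0) -> ComparisonReport:
    """Compare two rankers' mean ranks (scatter-plot semantics).

    The ``both_top`` set is the lower-left region of the rbar-vs-rbar
    scatter: items both rankers place at mean rank <= ``top_threshold``;
    ``only_a``/``only_b`` are the off-diagonal regions.
    """
    if set(a.items) != set(b.items):
        raise ValidationError("rank summaries cover different item sets")
    order = list(a.items)
    rb = pd.Series(b.mean_rank, index=b.items).reindex(order).to_numpy()
    ra = np.asarray(a.mean_rank)
    rho = float(spearmanr(ra, rb).statistic)
    top_a, top_b = a.top(top_threshold), b.top(top_threshold)
    paired = pd.DataFrame({"item": order, "mean_rank_a": ra, "mean_rank_b": rb})
    return ComparisonReport(
        spearman=rho,
        both_top=top_a & top_b,
        only_a=top_a - top_b,
        only_b=top_b - top_a,
        top_threshold=top_threshold,
        paired=paired,
    )


# ---------------------------------------------------------------------------
# Effect direction for top items
# ---------------------------------------------------------------------------


@dataclass
class EffectSign:
    sign: str                  # '+' or '-'
    coefficient: float
    std_error: float
    low_confidence: bool       # |coef| < 2 SE
    separation_fallback: bool  # sign came from a lightly penalized refit


def effect_direction(source: Cohort, items: list[str]) -> dict[str, EffectSign]:
    """Direction of association for each top-ranked item.

    Jointly fits an unpenalized logistic model on the named items; a
    categorical item's sign is that of its largest-magnitude level
    coefficient.  Under (quasi-)separation the sign is taken from a lightly
    L2-penalized refit and flagged.
    """
    from .data_model import Item, ItemDictionary  # local to avoid cycle noise

    dic = source.dictionary
    for it in items:
        if it not in dic:
            raise ValidationError(f"item {it!r} not present in cohort")
    sub_dic = ItemDictionary([
        Item(itm.code, itm.kind, itm.levels, include=True)
        for itm in dic if itm.code in set(items)
    ])
    sub = Cohort(source.df, sub_dic, validate=False)
    design = build_design(sub, standardize=False)
    X = sm.add_constant(design.X, has_constant="add")
    y = source.outcome
    separation = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coefs = np.asarray(fit.params)[1:]
        ses = np.asarray(fit.bse)[1:]
        if not np.all(np.isfinite(ses)) or np.any(np.abs(coefs) > 30):
            separation = True
    except Exception:
        separation = True
    if separation:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(penalty="l2", C=100.0, max_iter=2000)
        lr.fit(design.X, y)
        coefs = lr.coef_.ravel()
        ses = np.full_like(coefs, np.nan)
    out: dict[str, EffectSign] = {}
    for g, code in enumerate(design.group_codes):
        cols = design.group_columns(g)
        j = cols[np.argmax(np.abs(coefs[cols]))]
        coef = float(coefs[j])
        se = float(ses[j]) if np.isfinite(ses[j]) else float("nan")
        out[code] = EffectSign(
            sign="+" if coef >= 0 else "-",
            coefficient=coef,
            std_error=se,
            low_confidence=bool(not np.isfinite(se) or abs(coef) < 2 * se),
            separation_fallback=separation,
        )
    return out
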