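"""Group-penalized logistic regression along a solution path, and variable
ranking by order of entry.

The model is the logistic link

    log p_i / (1 - p_i) = b0 + x_i' beta,

estimated by maximizing the penalized log-likelihood

    l(beta) - lambda * sum_g w_g ||beta_g||_2,

where the columns of a multi-level item form one group g, so the item's
dummy variables enter or exit the model together.  With singleton groups the
penalty reduces to the classical L1 lasso.  At lambda >= lambda_max all
penalized coefficients are zero; as lambda decreases, groups attain nonzero
coefficients one after another, and *the order of first entry is the
importance ranking*.  No single lambda is ever selected.

Internally the smooth loss is the mean negative log-likelihood (1/n), so
lambda, gradients and KKT residuals are all on a per-observation scale and
comparable across sample sizes.  The optimizer is blockwise proximal descent
(majorizing each group's loss by its Lipschitz bound) with an active-set
Newton polish to drive KKT residuals below tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DesignMatrix, ValidationError


class ConvergenceError(RuntimeError):
    """A grid point failed to reach the KKT tolerance."""


def n_pairwise_interactions(d: int) -> int:
    """Number of two-way interaction terms among ``d`` main effects
    (``d`` choose 2) — the combinatorial reason the path ranker restricts
    itself to main effects."""
    return math.comb(d, 2)


@dataclass
class RankVector:
    """A complete (possibly tie-averaged) ranking of the ``d`` included
    items; rank 1 = most important."""

    ranks: dict[str, float]
    tie_policy_applied: str = ""

    @property
    def d(self) -> int:
        return len(self.ranks)

    def as_series(self) -> pd.Series:
        return pd.Series(self.ranks, name="rank")


@dataclass
class PathResult:
    """Coefficient trajectories over a decreasing penalty grid."""

    lambda_grid: np.ndarray          # decreasing
    intercepts: np.ndarray
    coefficients: np.ndarray         # (G, p)
    active: np.ndarray               # (G, n_groups) bool
    kkt_residuals: np.ndarray        # (G,)
    entry_lambda: dict[int, float]   # group -> largest grid lambda seen active
    group_codes: list[str]
    _solver: "_Solver" = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        """Long table (lambda, item, coefficient norm) for trajectory plots."""
        rows = []
        groups = self._solver.groups if self._solver is not None else None
        for i, lam in enumerate(self.lambda_grid):
            for g, code in enumerate(self.group_codes):
                cols = np.flatnonzero(groups == g)
                rows.append({"lambda": lam, "item": code,
                             "coef_norm": float(np.linalg.norm(self.coefficients[i, cols]))})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class _Solver:
    """Penalized-logistic solver bound to one (X, y, groups, weights)."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                 weights: np.ndarray, tol: float = 1e-6):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.groups = np.asarray(groups)
        self.weights = np.asarray(weights, dtype=float)
        self.tol = float(tol)
        self.n, self.p = self.X.shape
        self.n_groups = len(weights)
        self.cols = [np.flatnonzero(self.groups == g) for g in range(self.n_groups)]
        self.Xg = [np.ascontiguousarray(self.X[:, c]) for c in self.cols]
        # Lipschitz bound per block: ||X_g||_2^2 / (4n)
        self.Lg = np.array([
            (np.linalg.norm(Xg, 2) ** 2) / (4.0 * self.n) if Xg.size else 0.0
            for Xg in self.Xg
        ])
        self.solvable = self.Lg > 0  # constant / empty groups can never move

    # -- objective pieces ---------------------------------------------------

    def _nll(self, eta: np.ndarray) -> float:
        return float(np.mean(np.logaddexp(0.0, eta) - self.y * eta))

    def _objective(self, eta: np.ndarray, beta: np.ndarray, lam: float) -> float:
        pen = sum(self.weights[g] * np.linalg.norm(beta[self.cols[g]])
                  for g in range(self.n_groups))
        return self._nll(eta) + lam * pen

    def group_grad_norms(self, beta: np.ndarray, b0: float) -> np.ndarray:
        """||grad_g of the mean NLL||_2 per group at (b0, beta)."""
        p = _sigmoid(b0 + self.X @ beta)
        grad = self.X.T @ (p - self.y) / self.n
        return np.array([np.linalg.norm(grad[c]) if len(c) else 0.0 for c in self.cols])

    def kkt_residual(self, b0: float, beta: np.ndarray, lam: float) -> float:
        p = _sigmoid(b0 + self.X @ beta)
        r = p - self.y
        grad = self.X.T @ r / self.n
        res = abs(float(np.mean(r)))
        for g in range(self.n_groups):
            c = self.cols[g]
            if len(c) == 0:
                continue
            bg = beta[c]
            nrm = np.linalg.norm(bg)
            if nrm > 0:
                res = max(res, float(np.linalg.norm(grad[c] + lam * self.weights[g] * bg / nrm)))
            else:
                res = max(res, max(0.0, float(np.linalg.norm(grad[c])) - lam * self.weights[g]))
        return res

    # -- proximal sweeps ----------------------------------------------------

    def _sweep(self, b0: float, beta: np.ndarray, eta: np.ndarray, lam: float,
               rounds: int) -> tuple[float, np.ndarray, np.ndarray]:
        y, n = self.y, self.n
        for _ in range(rounds):
            p = _sigmoid(eta)
            # exact-ish intercept step (1-D Newton)
            r = float(np.mean(p - y))
            w = float(np.mean(p * (1.0 - p)))
            step = r / max(w, 1e-10)
            if step:
                b0 -= step
                eta -= step
                p = _sigmoid(eta)
            for g in range(self.n_groups):
                if not self.solvable[g]:
                    continue
                c = self.cols[g]
                Xg = self.Xg[g]
                grad = Xg.T @ (p - y) / n
                z = beta[c] - grad / self.Lg[g]
                nrm = float(np.linalg.norm(z))
                thr = lam * self.weights[g] / self.Lg[g]
                new = np.zeros_like(z) if nrm <= thr else (1.0 - thr / nrm) * z
                delta = new - beta[c]
                if np.any(delta):
                    eta += Xg @ delta
                    beta[c] = new
                    p = _sigmoid(eta)
        return b0, beta, eta

    # -- active-set Newton polish -------------------------------------------

    def _polish(self, b0: float, beta: np.ndarray, lam: float,
                max_iter: int = 40) -> tuple[float, np.ndarray]:
        active = [g for g in range(self.n_groups)
                  if np.linalg.norm(beta[self.cols[g]]) > 0]
        if not active:
            return b0, beta
        idx = np.concatenate([self.cols[g] for g in active])
        Z = np.column_stack([np.ones(self.n), self.X[:, idx]])
        spans = []
        off = 1
        for g in active:
            k = len(self.cols[g])
            spans.append((g, slice(off, off + k)))
            off += k
        v = np.concatenate([[b0], beta[idx]])

        def full_objective(v_):
            eta = Z @ v_
            pen = 0.0
            for g, sl in spans:
                pen += self.weights[g] * np.linalg.norm(v_[sl])
            return self._nll(eta) + lam * pen

        f0 = full_objective(v)
        for _ in range(max_iter):
            eta = Z @ v
            p = _sigmoid(eta)
            w = np.clip(p * (1.0 - p), 1e-10, None)
            grad = Z.T @ (p - self.y) / self.n
            H = (Z.T * w) @ Z / self.n
            small_norm = False
            for g, sl in spans:
                bg = v[sl]
                nrm = np.linalg.norm(bg)
                if nrm < 1e-10:
                    small_norm = True
                    break
                u = bg / nrm
                grad[sl] += lam * self.weights[g] * u
                k = sl.stop - sl.start
                H[sl, sl] += lam * self.weights[g] / nrm * (np.eye(k) - np.outer(u, u))
            if small_norm:
                break
            gnorm = float(np.linalg.norm(grad, np.inf))
            if gnorm < 0.1 * self.tol:
                break
            H[np.diag_indices_from(H)] += 1e-12
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            t = 1.0
            accepted = False
            for _ls in range(30):
                v_new = v - t * step
                # if the step wants to annihilate a group, hand back to prox
                if any(np.linalg.norm(v_new[sl]) < 1e-12 for _, sl in spans):
                    t *= 0.5
                    continue
                f_new = full_objective(v_new)
                if f_new <= f0 - 1e-14 * t or f_new < f0 + 1e-15:
                    v, f0 = v_new, f_new
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                break
        b0 = float(v[0])
        beta = beta.copy()
        beta[idx] = v[1:]
        return b0, beta

    # -- one grid point ------------------------------------------------------

    def fit_at(self, lam: float, warm: tuple[float, np.ndarray] | None = None,
               max_rounds: int = 300) -> tuple[float, np.ndarray, float]:
        """Solve at one lambda; returns (b0, beta, kkt_residual)."""
        if warm is None:
            ybar = float(np.mean(self.y))
            b0 = math.log(ybar / (1.0 - ybar))
            beta = np.zeros(self.p)
        else:
            b0, beta = warm[0], warm[1].copy()
        eta = b0 + self.X @ beta
        prev_active: tuple | None = None
        for round_ in range(max_rounds):
            b0, beta, eta = self._sweep(b0, beta, eta, lam, rounds=3)
            res = self.kkt_residual(b0, beta, lam)
            if res < self.tol:
                return b0, beta, res
            active = tuple(g for g in range(self.n_groups)
                           if np.linalg.norm(beta[self.cols[g]]) > 0)
            if active == prev_active:
                b0, beta = self._polish(b0, beta, lam)
                eta = b0 + self.X @ beta
                res = self.kkt_residual(b0, beta, lam)
                if res < self.tol:
                    return b0, beta, res
            prev_active = active
        raise ConvergenceError(
            f"no convergence at lambda={lam:.6g}: KKT residual {res:.3g} "
            f"after {max_rounds} rounds"
        )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def _default_weights(design: DesignMatrix) -> np.ndarray:
    """w_g = sqrt(group size), the standard grouped-penalty normalization."""
    sizes = np.array([len(design.group_columns(g)) for g in range(design.n_groups)])
    return np.sqrt(sizes.astype(float))


def compute_lambda_max(design: DesignMatrix, y: np.ndarray,
                       group_weights: np.ndarray | None = None) -> float:
    """Smallest penalty at which the all-zero solution is optimal.

    At the intercept-only optimum the fitted probability is the outcome mean,
    so lambda_max = max_g ||X_g'(ybar - y)|| / (n w_g).  Groups of constant
    columns have zero gradient and never determine lambda_max.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome has a single class; no path exists")
    w = _default_weights(design) if group_weights is None else np.asarray(group_weights, float)
    n = design.X.shape[0]
    ybar = float(np.mean(y))
    grad = design.X.T @ (ybar - y) / n
    norms = np.array([
        np.linalg.norm(grad[design.group_columns(g)]) for g in range(design.n_groups)
    ])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(w > 0, norms / w, 0.0)
    return float(np.max(ratio))


def fit_path(design: DesignMatrix, y: np.ndarray, n_lambda: int = 100,
             lambda_min_ratio: float = 1e-3,
             group_weights: np.ndarray | None = None,
             tol: float = 1e-6) -> PathResult:
    """Fit the penalized path on a log-spaced decreasing grid.

    Every grid point is solved to KKT residual < ``tol`` (per-observation
    gradient scale), warm-started from the previous point; the intercept is
    never penalized.  The first grid point is lambda_max, where the solution
    is exactly zero.
    """
    if n_lambda < 1:
        raise ValidationError("grid needs at least one point")
    w = _default_weights(design) if group_weights is None else np.asarray(group_weights, float)
    lam_max = compute_lambda_max(design, y, w)
    if lam_max <= 0:
        raise ValidationError("lambda_max is zero: no group has any signal-carrying column")
    if n_lambda == 1:
        grid = np.array([lam_max])
    else:
        grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    solver = _Solver(design.X, y, design.groups, w, tol=tol)
    G, p = len(grid), design.X.shape[1]
    coefs = np.zeros((G, p))
    b0s = np.zeros(G)
    kkts = np.zeros(G)
    actives = np.zeros((G, design.n_groups), dtype=bool)
    ybar = float(np.mean(y))
    warm = (math.log(ybar / (1.0 - ybar)), np.zeros(p))
    for i, lam in enumerate(grid):
        if i == 0:
            b0, beta, res = warm[0], warm[1].copy(), 0.0
        else:
            b0, beta, res = solver.fit_at(lam, warm=warm)
        warm = (b0, beta)
        coefs[i] = beta
        b0s[i] = b0
        kkts[i] = res
        actives[i] = [np.linalg.norm(beta[solver.cols[g]]) > 0
                      for g in range(design.n_groups)]
    entry = {}
    for g in range(design.n_groups):
        hits = np.flatnonzero(actives[:, g])
        if len(hits):
            entry[g] = float(grid[hits[0]])
    return PathResult(
        lambda_grid=grid,
        intercepts=b0s,
        coefficients=coefs,
        active=actives,
        kkt_residuals=kkts,
        entry_lambda=entry,
        group_codes=list(design.group_codes),
        _solver=solver,
    )


def entry_order(path: PathResult, floor_frac: float = 1e-4) -> RankVector:
    """Rank items by decreasing first-entry penalty along the path.

    When several groups first appear between adjacent grid points, the
    interval is bisected (geometrically, refitting warm-started) until the
    entries separate or the bracket is narrower than
    ``floor_frac * lambda_max``; what still ties is ordered by the entry
    criterion itself, the pre-entry gradient norm ``||grad_g|| / w_g``, and
    exact remaining ties receive averaged ranks.  Groups that never enter
    share the averaged worst ranks.
    """
    solver = path._solver
    grid = path.lambda_grid
    lam_max = float(grid[0])
    floor = floor_frac * lam_max
    n_groups = len(path.group_codes)

    first_idx: dict[int, int] = {}
    for g in range(n_groups):
        hits = np.flatnonzero(path.active[:, g])
        if len(hits):
            first_idx[g] = int(hits[0])

    # entry lambda (active end of final bracket) and tie score per group
    entry_lam: dict[int, float] = {}
    tie_score: dict[int, float] = {g: 0.0 for g in range(n_groups)}

    by_index: dict[int, list[int]] = {}
    for g, i in first_idx.items():
        by_index.setdefault(i, []).append(g)

    def refine(tied: list[int], hi: float, lo: float,
               warm_hi: tuple[float, np.ndarray]) -> None:
        # all groups in `tied` inactive at hi, active at lo
        if len(tied) == 1 or hi - lo < floor:
            norms = solver.group_grad_norms(warm_hi[1], warm_hi[0])
            for g in tied:
                entry_lam[g] = lo
                tie_score[g] = float(norms[g] / solver.weights[g]) if solver.weights[g] > 0 else 0.0
            return
        mid = math.sqrt(hi * lo)
        b0, beta, _ = solver.fit_at(mid, warm=warm_hi)
        act = [g for g in tied if np.linalg.norm(beta[solver.cols[g]]) > 0]
        inact = [g for g in tied if g not in act]
        if act:
            refine(act, hi, mid, warm_hi)
        if inact:
            refine(inact, mid, lo, (b0, beta))

    for i, tied in sorted(by_index.items()):
        if len(tied) == 1:
            g = tied[0]
            entry_lam[g] = float(grid[i])
            if i > 0:
                warm = (path.intercepts[i - 1], path.coefficients[i - 1])
                norms = solver.group_grad_norms(warm[1], warm[0])
                tie_score[g] = float(norms[g] / solver.weights[g]) if solver.weights[g] > 0 else 0.0
            continue
        if i == 0:
            # several groups active already at lambda_max: should not happen
            # (solution there is exactly zero), but keep the contract total
            for g in tied:
                entry_lam[g] = float(grid[0])
            continue
        warm = (float(path.intercepts[i - 1]), path.coefficients[i - 1].copy())
        refine(sorted(tied), float(grid[i - 1]), float(grid[i]), warm)

    entered = sorted(entry_lam, key=lambda g: (-entry_lam[g], -tie_score[g]))
    ranks = np.empty(len(path.group_codes))
    if entered:
        keys = [(-entry_lam[g], -tie_score[g]) for g in entered]
        # average ranks over exactly-equal keys
        rk = np.empty(len(entered))
        i = 0
        pos = 1
        while i < len(entered):
            j = i
            while j + 1 < len(entered) and keys[j + 1] == keys[i]:
                j += 1
            avg = (pos + pos + (j - i)) / 2.0
            rk[i:j + 1] = avg
            pos += j - i + 1
            i = j + 1
        for g, r in zip(entered, rk):
            ranks[g] = r
    never = [g for g in range(n_groups) if g not in entry_lam]
    if never:
        d = n_groups
        m = len(entry_lam)
        worst = (m + 1 + d) / 2.0
        for g in never:
            ranks[g] = worst
    policy = ("entry-lambda descending; bisection to "
              f"{floor_frac:g}*lambda_max; residual ties by pre-entry gradient "
              "norm then averaged; never-entering groups share averaged worst ranks")
    return RankVector(
        ranks={code: float(ranks[g]) for g, code in enumerate(path.group_codes)},
        tie_policy_applied=policy,
    )


def rank_items_path(design: DesignMatrix, y: np.ndarray, n_lambda: int = 100,
                    lambda_min_ratio: float = 1e-3, tol: float = 1e-6,
                    group_weights: np.ndarray | None = None) -> RankVector:
    """Convenience: fit the path and rank items by entry order."""
    path = fit_path(design, y, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
                    group_weights=group_weights, tol=tol)
    return entry_order(path)
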