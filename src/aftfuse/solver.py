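"""Pathwise coordinate descent for the doubly penalized weighted least squares.

The loss is sum_i w_i (y_i - x_i' theta)^2 with Stute weights w, plus a
folded-concave penalty on each of two coefficient blocks (tuning parameters
lambda1 and lambda2). Because the design has few columns (2p+2), the solver
works on the Gram matrix G = X'WX and moment vector c = X'Wy, so one
coordinate update costs O(d) regardless of n; the inner loop is JIT-compiled.

Columns are labelled by ``pen_block``: 0 = unpenalized (intercepts),
1 = lambda1 block, 2 = lambda2 block. Penalized columns are rescaled to unit
Stute-weighted second moment before solving (no centering: the design carries
no constant column, every column being multiplied by A - e_hat) and
coefficients are mapped back afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .penalties import PenaltySpec
from .stute import StuteWeights

__all__ = ["SolvePath", "solve", "lambda_grid", "select_cv", "select_bic", "stute_weight_vector"]

_TOL = 1e-7
_MAX_SWEEPS = 1000
_LOSS_FLOOR = 1e-12


def stute_weight_vector(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-subject Stute weights in the *original* row order of (time, event)."""
    from .data import SurvivalDataset
    from .stute import compute_stute_weights

    n = len(time)
    ds = SurvivalDataset(
        time=np.asarray(time, float),
        event=np.asarray(event),
        treatment=np.zeros(n, int),
        source=np.ones(n, int),
        covariates=np.empty((n, 0)),
    )
    return compute_stute_weights(ds).unsorted()


@njit(cache=True)
def _prox(z, v, lam, gamma, fam):  # pragma: no cover - exercised via solve()
    """Minimizer of 0.5*v*(b - z/v)^2 + rho(|b|; lam); fam: 0=mcp,1=scad,2=alasso."""
    if lam <= 0.0:
        return z / v
    az = abs(z)
    sz = 1.0 if z >= 0.0 else -1.0
    if fam == 0:  # MCP
        if az <= lam:
            return 0.0
        if az <= v * gamma * lam:
            return sz * (az - lam) / (v - 1.0 / gamma)
        return z / v
    elif fam == 1:  # SCAD
        a = gamma
        if az <= lam * (1.0 + v):
            b = az - lam
            if b < 0.0:
                b = 0.0
            return sz * b / v
        if az <= a * lam * v:
            return sz * (az - a * lam / (a - 1.0)) / (v - 1.0 / (a - 1.0))
        return z / v
    else:  # adaptive lasso (weights folded into lam by caller)
        b = az - lam
        if b < 0.0:
            b = 0.0
        return sz * b / v


@njit(cache=True)
def _cd_sweeps(G, c, pen_block, lam1, lam2, gamma, fam, theta, tol, max_iter):  # pragma: no cover
    """In-place cyclic coordinate descent on the Gram form; returns
    (sweeps used, converged flag)."""
    d = G.shape[0]
    g = G @ theta  # g = G theta, maintained incrementally
    sweeps = 0
    converged = False
    for _ in range(max_iter):
        sweeps += 1
        maxdelta = 0.0
        for j in range(d):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            zt = c[j] - g[j] + gjj * theta[j]
            if pen_block[j] == 0:
                b = zt / gjj
            else:
                lam = lam1 if pen_block[j] == 1 else lam2
                b = _prox(2.0 * zt, 2.0 * gjj, lam, gamma, fam)
            diff = b - theta[j]
            if diff != 0.0:
                theta[j] = b
                for k in range(d):
                    g[k] += G[k, j] * diff
                ad = abs(diff)
                if ad > maxdelta:
                    maxdelta = ad
        if maxdelta < tol:
            converged = True
            break
    return sweeps, converged


class _GramProblem:
    """Standardized Gram-form problem shared across a lambda path."""

    def __init__(self, y: np.ndarray, design: np.ndarray, w: np.ndarray, pen_block: np.ndarray):
        y = np.asarray(y, float)
        X = np.asarray(design, float)
        w = np.asarray(w, float)
        self.pen_block = np.asarray(pen_block, dtype=np.int64)
        if w.sum() <= 0:
            raise ValueError("weights carry zero total mass (all observations censored?)")
        scales = np.ones(X.shape[1])
        m2 = (w[:, None] * X**2).sum(axis=0)
        pen = self.pen_block > 0
        safe = m2 > 1e-300
        scales[pen & safe] = np.sqrt(m2[pen & safe])
        Xs = X / scales
        self.scales = scales
        Wx = Xs * w[:, None]
        self.G = Wx.T @ Xs
        self.c = Wx.T @ y
        self.yy = float(w @ y**2)
        self.n = X.shape[0]

    def loss(self, theta_std: np.ndarray) -> float:
        return float(self.yy - 2 * self.c @ theta_std + theta_std @ self.G @ theta_std)

    def solve_at(self, lam1: float, lam2: float, spec: PenaltySpec, warm: np.ndarray | None = None,
                 tol: float = _TOL, max_iter: int = _MAX_SWEEPS):
        theta = np.zeros(self.G.shape[0]) if warm is None else warm.copy()
        sweeps, converged = _cd_sweeps(
            self.G, self.c, self.pen_block, lam1, lam2, spec.gamma,
            spec.family_code, theta, tol, max_iter,
        )
        return theta, bool(converged)

    def to_original(self, theta_std: np.ndarray) -> np.ndarray:
        return theta_std / self.scales


@dataclass
class SolvePath:
    """Solutions along a (lambda1, lambda2) grid, coefficients on the original scale."""

    lambdas: np.ndarray        # (m, 2)
    coefs: np.ndarray          # (m, d)
    loss: np.ndarray           # (m,) Stute-weighted SSE
    df: np.ndarray             # (m,) number of nonzero coefficients
    converged: np.ndarray      # (m,) bool


def _mask_from_spec(design: np.ndarray, pen_block: np.ndarray, spec: PenaltySpec) -> np.ndarray:
    pb = np.asarray(pen_block, dtype=np.int64).copy()
    if spec.unpenalized_mask is not None:
        pb[np.asarray(spec.unpenalized_mask, bool)] = 0
    return pb


def solve(y, design, weights, spec: PenaltySpec, pen_block, warm_start=None) -> np.ndarray:
    """Solve the penalized problem at the spec's fixed (lambda1, lambda2).

    ``weights`` is either a :class:`StuteWeights` (subject-order weights are
    extracted) or a plain per-row weight vector aligned with ``y``/``design``.
    Returns the coefficient vector with exact zeros where thresholded.
    """
    if spec.lambda1 is None or (np.any(np.asarray(pen_block) == 2) and spec.lambda2 is None):
        raise ValueError("solve() requires fixed lambdas; use select_cv/select_bic to tune")
    w = weights.unsorted() if isinstance(weights, StuteWeights) else np.asarray(weights, float)
    pb = _mask_from_spec(design, pen_block, spec)
    prob = _GramProblem(y, design, w, pb)
    lam2 = spec.lambda2 if spec.lambda2 is not None else 0.0
    # the objective is nonconvex: try several starts, keep the best iterate
    starts: list[np.ndarray | None] = [None]
    try:
        starts.append(np.linalg.solve(prob.G, prob.c))  # unpenalized WLS start
    except np.linalg.LinAlgError:
        pass
    if warm_start is not None:
        starts.append(np.asarray(warm_start, float) * prob.scales)
    best_theta, best_obj = None, np.inf
    for start in starts:
        theta, _ = prob.solve_at(spec.lambda1, lam2, spec, start)
        obj = _penalized_objective(prob, theta, spec.lambda1, lam2, spec)
        if obj < best_obj:
            best_theta, best_obj = theta, obj
    return prob.to_original(best_theta)


def _block_lambda_max(prob: _GramProblem, spec: PenaltySpec, block: int) -> float:
    """Smallest lambda zeroing the block, holding unpenalized columns at their optimum."""
    unpen = np.flatnonzero(prob.pen_block == 0)
    cols = np.flatnonzero(prob.pen_block == block)
    if cols.size == 0:
        return 0.0
    c_adj = prob.c.copy()
    if unpen.size:
        Guu = prob.G[np.ix_(unpen, unpen)]
        try:
            theta_u = np.linalg.solve(Guu, prob.c[unpen])
        except np.linalg.LinAlgError:
            theta_u = np.linalg.lstsq(Guu, prob.c[unpen], rcond=None)[0]
        c_adj = prob.c - prob.G[:, unpen] @ theta_u
    lam_max = float(np.max(np.abs(2.0 * c_adj[cols])))
    return lam_max


def lambda_grid(y, design, weights, pen_block, n1: int = 15, n2: int = 15,
                spec: PenaltySpec | None = None, min_ratio: float = 0.01):
    """Cross-product grid of (lambda1, lambda2) candidates.

    Per block the largest value is the max absolute weighted gradient of the
    unpenalized loss at theta=0 (unpenalized columns profiled out); the grid
    is log-spaced down to ``min_ratio`` times that. A block with no columns
    contributes the single value 0.
    """
    spec = spec or PenaltySpec()
    w = weights.unsorted() if isinstance(weights, StuteWeights) else np.asarray(weights, float)
    pb = _mask_from_spec(design, pen_block, spec)
    prob = _GramProblem(y, design, w, pb)
    grids = []
    for block, size in ((1, n1), (2, n2)):
        if not np.any(pb == block):
            grids.append(np.array([0.0]))
            continue
        lam_max = _block_lambda_max(prob, spec, block)
        if lam_max <= 0:
            raise ValueError("degenerate response: zero gradient for every penalized column")
        grids.append(np.geomspace(lam_max, min_ratio * lam_max, size))
    lam1s, lam2s = grids
    pairs = np.array([(l1, l2) for l1 in lam1s for l2 in lam2s])
    return pairs


def _penalized_objective(prob: _GramProblem, theta_std: np.ndarray, lam1: float, lam2: float,
                         spec: PenaltySpec) -> float:
    from .penalties import penalty_value

    pen = 0.0
    t = np.abs(theta_std)
    b1 = prob.pen_block == 1
    b2 = prob.pen_block == 2
    if lam1 > 0 and b1.any():
        pen += float(np.sum(penalty_value(t[b1], lam1, spec.family, spec.gamma)))
    if lam2 > 0 and b2.any():
        pen += float(np.sum(penalty_value(t[b2], lam2, spec.family, spec.gamma)))
    return prob.loss(theta_std) + pen


def _path(prob: _GramProblem, pairs: np.ndarray, spec: PenaltySpec) -> SolvePath:
    """Sweep over the grid (lambda1 desc outer, lambda2 desc inner).

    The objective is nonconvex, so each point is solved twice — warm-started
    from the neighbouring solution and cold-started from zero — and the
    iterate with the lower penalized objective is kept. This suppresses
    support hysteresis along the path.
    """
    m, d = pairs.shape[0], prob.G.shape[0]
    coefs = np.empty((m, d))
    loss = np.empty(m)
    df = np.empty(m, dtype=int)
    conv = np.empty(m, dtype=bool)
    row_start_warm: np.ndarray | None = None
    warm: np.ndarray | None = None
    prev_l1 = None
    for k in range(m):
        l1, l2 = pairs[k]
        if prev_l1 is not None and l1 != prev_l1:
            warm = row_start_warm  # start new lambda1 row from previous row's first solution
        theta, ok = prob.solve_at(l1, l2, spec, warm)
        if warm is not None:
            theta0, ok0 = prob.solve_at(l1, l2, spec, None)
            if (_penalized_objective(prob, theta0, l1, l2, spec)
                    < _penalized_objective(prob, theta, l1, l2, spec) - 1e-12):
                theta, ok = theta0, ok0
        if prev_l1 is None or l1 != prev_l1:
            row_start_warm = theta.copy()
            prev_l1 = l1
        warm = theta.copy()
        coefs[k] = prob.to_original(theta)
        loss[k] = prob.loss(theta)
        df[k] = int(np.count_nonzero(theta[prob.pen_block > 0]))
        conv[k] = ok
    return SolvePath(lambdas=pairs, coefs=coefs, loss=loss, df=df, converged=conv)


def _kfold_indices(n: int, K: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[f::K] for f in range(K)]


def select_cv(y, design, time, event, pen_block, spec: PenaltySpec | None = None,
              K: int = 5, seed: int = 0, n1: int = 15, n2: int = 15, rule: str = "min",
              val_weights: str = "stute", repeats: int = 1,
              confounding_parsimony: float = 2.0):
    """Tune (lambda1, lambda2) by K-fold cross-validation.

    Stute weights are recomputed on each training and validation subsample
    from their own (time, event) data, because Kaplan-Meier masses are
    sample-dependent. ``rule='min'`` selects the pair minimizing the mean
    validation Stute-weighted squared error; the default ``'1se'`` selects,
    among the pairs within one standard error of that minimum, the one with
    the fewest selected coefficients (ties toward larger lambda1 + lambda2) —
    the usual conservative convention that stabilizes support recovery.
    Deterministic given ``seed``.

    Returns (lambda1, lambda2, full-data SolvePath over the grid, best index).
    """
    spec = spec or PenaltySpec()
    y = np.asarray(y, float)
    design = np.asarray(design, float)
    time = np.asarray(time, float)
    event = np.asarray(event)
    n = y.shape[0]
    if K < 2:
        raise ValueError("K >= 2 folds required")
    w_full = stute_weight_vector(time, event)
    pairs = lambda_grid(y, design, w_full, pen_block, n1, n2, spec)
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(repeats):
        folds.extend(_kfold_indices(n, K, rng))
    fold_err = np.zeros((len(folds), pairs.shape[0]))
    pb = _mask_from_spec(design, pen_block, spec)
    for f, val_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        tr_idx = np.flatnonzero(mask)
        w_tr = stute_weight_vector(time[tr_idx], event[tr_idx])
        if w_tr.sum() <= 0:
            raise ValueError("a CV training fold has zero Stute mass; use fewer folds")
        if val_weights == "stute":
            w_val = stute_weight_vector(time[val_idx], event[val_idx])
        else:  # uniform mass on the fold's events
            w_val = event[val_idx].astype(float) / max(event[val_idx].sum(), 1)
        if w_val.sum() <= 0:
            raise ValueError("a CV validation fold has zero Stute mass; use fewer folds")
        prob = _GramProblem(y[tr_idx], design[tr_idx], w_tr, pb)
        path = _path(prob, pairs, spec)
        resid = y[val_idx][None, :] - path.coefs @ design[val_idx].T  # (m, n_val)
        fold_err[f] = resid**2 @ w_val
    n_eff_folds = len(folds)
    cv_err = fold_err.mean(axis=0)
    best_min = int(np.argmin(cv_err))
    full_prob = _GramProblem(y, design, w_full, pb)
    path = _path(full_prob, pairs, spec)
    if rule == "min":
        best = best_min
    elif rule.startswith(("h", "b")) and rule.endswith("se"):
        # structured one-SE rules: within the paired-SE band around the CV
        # minimum, hold one block's support at the minimizer's and sparsify the
        # other. 'h<k>se' fixes the confounding block and sparsifies the
        # treatment-effect block (largest lambda1); 'b<k>se' fixes the
        # treatment-effect support and sparsifies the confounding block
        # (largest lambda2) — Occam's razor on the confounding explanation.
        frac = float(rule[1:-2]) if rule[1:-2] else 1.0
        diff = fold_err - fold_err[:, best_min][:, None]
        se_band = diff.std(axis=0, ddof=1) / np.sqrt(n_eff_folds)
        band = np.flatnonzero(cv_err - cv_err[best_min] <= frac * se_band)
        b1 = np.flatnonzero(pb == 1)
        b2 = np.flatnonzero(pb == 2)

        def _supp(k: int, cols: np.ndarray) -> tuple:
            return tuple(np.flatnonzero(path.coefs[k][cols] != 0)) if cols.size else ()

        if rule[0] == "h":
            ref = _supp(best_min, b2)
            cand = [k for k in band if _supp(k, b2) == ref]
            best = max(cand, key=lambda k: (pairs[k, 0], -cv_err[k]))
        else:
            ref = _supp(best_min, b1)
            cand = [k for k in band if _supp(k, b1) == ref]
            best = max(cand, key=lambda k: (pairs[k, 1], -cv_err[k]))
    elif rule.endswith("se"):
        frac = 1.0 if rule in ("1se", "level1se") else float(rule.replace("level", "")[:-2])
        if rule.startswith("level"):
            se_band = np.full(pairs.shape[0], fold_err[:, best_min].std(ddof=1) / np.sqrt(n_eff_folds))
        else:
            # paired SE: fold errors are strongly correlated across the grid, so the
            # uncertainty of the *difference* to the minimizer is the relevant scale
            diff = fold_err - fold_err[:, best_min][:, None]
            se_band = diff.std(axis=0, ddof=1) / np.sqrt(n_eff_folds)
        ok = np.flatnonzero(cv_err - cv_err[best_min] <= frac * se_band)
        lam_sum = pairs[:, 0] + pairs[:, 1]
        order = np.lexsort((-lam_sum[ok], path.df[ok]))
        best = int(ok[order[0]])
    else:
        raise ValueError(f"unknown CV rule '{rule}'")
    if confounding_parsimony > 0 and np.any(pb == 2):
        # parsimony check on the confounding block: if a solution with the
        # whole beta block zeroed validates within the paired-SE band of the
        # chosen point, prefer the no-confounding explanation
        b2 = np.flatnonzero(pb == 2)
        free = np.flatnonzero((path.coefs[:, b2] != 0).sum(axis=1) == 0)
        if free.size:
            diff = fold_err - fold_err[:, best][:, None]
            se_diff = diff.std(axis=0, ddof=1) / np.sqrt(n_eff_folds)
            ok = free[cv_err[free] - cv_err[best] <= confounding_parsimony * se_diff[free]]
            if ok.size:
                best = int(ok[np.argmin(cv_err[ok])])
    return float(pairs[best, 0]), float(pairs[best, 1]), path, best


def select_bic(y, design, weights, pen_block, spec: PenaltySpec | None = None,
               n1: int = 15, n2: int = 15):
    """Tune (lambda1, lambda2) by BIC = n*log(loss) + df*log(n).

    df counts nonzero penalized coefficients; ties break toward the larger
    lambda1 + lambda2 (sparser side of the path).
    """
    spec = spec or PenaltySpec()
    w = weights.unsorted() if isinstance(weights, StuteWeights) else np.asarray(weights, float)
    y = np.asarray(y, float)
    n = y.shape[0]
    pairs = lambda_grid(y, design, w, pen_block, n1, n2, spec)
    pb = _mask_from_spec(design, pen_block, spec)
    prob = _GramProblem(y, design, w, pb)
    path = _path(prob, pairs, spec)
    bic = n * np.log(np.maximum(path.loss, _LOSS_FLOOR)) + path.df * np.log(n)
    lam_sum = pairs.sum(axis=1)
    best = int(np.lexsort((-lam_sum, np.round(bic, 10)))[0])
    return float(pairs[best, 0]), float(pairs[best, 1]), path, best
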