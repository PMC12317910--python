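"""The integrative HTE estimator and its RCT-only, naive and oracle variants.

After a Robinson-type residualization, the model

    log T~ = mu(X,S) + (A - e(X,S)) * [tau(X) + (1-S) * uc(X)] + eps

turns into a pseudo-regression: response log T - mu_hat, regressors
(A - e_hat) * [1, X, (1-S), (1-S)X], fitted by Stute-weighted least squares
with separate folded-concave penalties on the tau (alpha) and uc (beta)
covariate blocks. Unmeasured confounding is declared present when any
penalized beta coefficient survives the tuning — the beta intercept, being
unpenalized, is excluded from the detection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalDataset
from .nuisance import LearnerSpec, NuisanceFit, cross_fit
from .penalties import PenaltySpec
from .solver import SolvePath, select_bic, select_cv, solve, stute_weight_vector
from .stute import StuteWeights, compute_stute_weights

__all__ = [
    "ThetaEstimate",
    "DesignBundle",
    "FitOptions",
    "build_design",
    "fit_integrative",
    "fit_rct_only",
    "fit_naive",
    "fit_oracle",
    "refit_fixed",
    "predict_hte",
]


@dataclass
class ThetaEstimate:
    """Fitted (alpha, beta) with supports and tuning metadata.

    ``alpha`` has length p+1, intercept first; ``beta`` likewise, or ``None``
    for variants that exclude the confounding block. Supports are 0-based
    covariate indices (intercepts excluded).
    """

    alpha: np.ndarray
    beta: np.ndarray | None
    support_alpha: np.ndarray
    support_beta: np.ndarray
    confounding_detected: bool
    lambda1: float | None
    lambda2: float | None
    tuning_rule: str
    penalty_family: str
    method: str = "rl"

    @property
    def theta(self) -> np.ndarray:
        """Concatenated coefficient vector (alpha then beta, if present)."""
        return self.alpha if self.beta is None else np.concatenate([self.alpha, self.beta])

    def to_json_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "beta": None if self.beta is None else self.beta.tolist(),
            "support_alpha": self.support_alpha.tolist(),
            "support_beta": self.support_beta.tolist(),
            "confounding_detected": bool(self.confounding_detected),
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "tuning_rule": self.tuning_rule,
            "penalty_family": self.penalty_family,
            "method": self.method,
        }


@dataclass
class DesignBundle:
    """Sorted pseudo-regression pieces consumed by the penalized solver."""

    pseudo_response: np.ndarray   # log T_(i) - mu_hat, sorted by observed time
    design: np.ndarray            # (n, 2p+2) or (n, p+1) without the beta block
    weights: StuteWeights
    pen_block: np.ndarray         # 0 = unpenalized, 1 = alpha block, 2 = beta block
    column_labels: list[str]
    time_sorted: np.ndarray
    event_sorted: np.ndarray
    has_beta: bool


@dataclass(frozen=True)
class FitOptions:
    """Options shared by every estimator variant."""

    penalty: PenaltySpec = field(default_factory=PenaltySpec)
    tuning: str = "cv"            # 'cv' | 'bic' | 'fixed'
    cv_folds: int = 5
    cv_rule: str = "h1se"         # 'min' | 'h<k>se' | '<k>se' | 'level<k>se'
    grid_size: tuple[int, int] = (15, 15)
    seed: int = 0
    learner: LearnerSpec = field(default_factory=LearnerSpec)
    cross_fit_folds: int = 2


def build_design(dataset: SurvivalDataset, nuisance: NuisanceFit,
                 include_beta: bool = True) -> DesignBundle:
    """Assemble the sorted pseudo-response and residualized design matrix.

    Rows are (A - e_hat) * [1, X, (1-S), (1-S)X]; every S=1 row is exactly
    zero in all beta columns. ``include_beta=False`` drops the beta block
    (RCT-only and naive variants).
    """
    e = nuisance.e_hat
    if np.any((e <= 0) | (e >= 1)):
        raise ValueError("e_hat must lie strictly inside (0, 1); clip before building the design")
    sw = compute_stute_weights(dataset)
    o = sw.order
    X = dataset.covariates[o]
    a_resid = (dataset.treatment[o] - e[o])[:, None]
    rwd = (1 - dataset.source[o])[:, None]
    names = dataset.covariate_names
    blocks = [np.ones((dataset.n, 1)), X]
    labels = ["alpha_0"] + [f"alpha_{c}" for c in names]
    pen = [0] + [1] * dataset.p
    if include_beta:
        blocks += [rwd, rwd * X]
        labels += ["beta_0"] + [f"beta_{c}" for c in names]
        pen += [0] + [2] * dataset.p
    design = a_resid * np.hstack(blocks)
    y = np.log(dataset.time[o]) - nuisance.mu_hat[o]
    return DesignBundle(
        pseudo_response=y,
        design=design,
        weights=sw,
        pen_block=np.array(pen),
        column_labels=labels,
        time_sorted=dataset.time[o],
        event_sorted=dataset.event[o],
        has_beta=include_beta,
    )


def _unpack(coefs: np.ndarray, p: int, has_beta: bool, lam1, lam2, options: FitOptions,
            method: str) -> ThetaEstimate:
    alpha = coefs[: p + 1].copy()
    beta = coefs[p + 1 :].copy() if has_beta else None
    support_alpha = np.flatnonzero(alpha[1:] != 0)
    support_beta = np.flatnonzero(beta[1:] != 0) if has_beta else np.array([], dtype=int)
    return ThetaEstimate(
        alpha=alpha,
        beta=beta,
        support_alpha=support_alpha,
        support_beta=support_beta,
        confounding_detected=bool(support_beta.size > 0),
        lambda1=lam1,
        lambda2=lam2,
        tuning_rule=options.tuning,
        penalty_family=options.penalty.family,
        method=method,
    )


def _fit_penalized(dataset: SurvivalDataset, nuisance: NuisanceFit, options: FitOptions,
                   include_beta: bool, method: str) -> ThetaEstimate:
    bundle = build_design(dataset, nuisance, include_beta=include_beta)
    n1, n2 = options.grid_size
    if options.tuning == "cv":
        lam1, lam2, path, best = select_cv(
            bundle.pseudo_response, bundle.design, bundle.time_sorted, bundle.event_sorted,
            bundle.pen_block, options.penalty, K=options.cv_folds, seed=options.seed,
            n1=n1, n2=n2, rule=options.cv_rule,
        )
        coefs = path.coefs[best]
    elif options.tuning == "bic":
        lam1, lam2, path, best = select_bic(
            bundle.pseudo_response, bundle.design, bundle.weights.weights,
            bundle.pen_block, options.penalty, n1=n1, n2=n2,
        )
        coefs = path.coefs[best]
    elif options.tuning == "fixed":
        coefs = solve(bundle.pseudo_response, bundle.design, bundle.weights.weights,
                      options.penalty, bundle.pen_block)
        lam1, lam2 = options.penalty.lambda1, options.penalty.lambda2
    else:
        raise ValueError(f"unknown tuning rule '{options.tuning}'")
    return _unpack(coefs, dataset.p, include_beta, lam1, lam2, options, method)


def _ensure_nuisance(dataset: SurvivalDataset, options: FitOptions,
                     nuisance: NuisanceFit | None, arm_means: bool = False) -> NuisanceFit:
    if nuisance is not None:
        return nuisance
    return cross_fit(dataset, options.learner, K=options.cross_fit_folds,
                     seed=options.seed, arm_means=arm_means)


def fit_integrative(dataset: SurvivalDataset, options: FitOptions | None = None,
                    nuisance: NuisanceFit | None = None) -> ThetaEstimate:
    """The proposed estimator on the combined RCT + RWD sample."""
    options = options or FitOptions()
    if dataset.source.min() == dataset.source.max():
        raise ValueError("integrative fitting needs both S=1 (RCT) and S=0 (RWD) subjects")
    nuisance = _ensure_nuisance(dataset, options, nuisance)
    return _fit_penalized(dataset, nuisance, options, include_beta=True, method="rl")


def fit_rct_only(dataset: SurvivalDataset, options: FitOptions | None = None,
                 nuisance: NuisanceFit | None = None) -> ThetaEstimate:
    """Same pipeline restricted to the S=1 subsample (no confounding block).

    By default the nuisances are cross-fitted on the trial subsample itself,
    so the estimate is computable from trial data alone. A supplied
    ``nuisance`` (aligned with either the full data or the subsample) is used
    instead, e.g. to inject known nuisances.
    """
    options = options or FitOptions()
    idx = np.flatnonzero(dataset.source == 1)
    if idx.size == 0:
        raise ValueError("no RCT subjects (S=1) in the data")
    sub = dataset.subset(idx)
    if nuisance is None:
        nu_sub = cross_fit(sub, options.learner, K=options.cross_fit_folds,
                           seed=options.seed, arm_means=False)
    elif nuisance.e_hat.shape[0] == dataset.n and dataset.n != idx.size:
        nu_sub = nuisance.subset(idx)
    else:
        nu_sub = nuisance
    return _fit_penalized(sub, nu_sub, options, include_beta=False, method="rl.rct")


def fit_naive(dataset: SurvivalDataset, options: FitOptions | None = None,
              nuisance: NuisanceFit | None = None) -> ThetaEstimate:
    """Pooled fit that ignores unmeasured confounding (beta forced to zero)."""
    options = options or FitOptions()
    nuisance = _ensure_nuisance(dataset, options, nuisance)
    return _fit_penalized(dataset, nuisance, options, include_beta=False, method="rl.nai")


def fit_oracle(dataset: SurvivalDataset, support_alpha, support_beta=None,
               options: FitOptions | None = None, nuisance: NuisanceFit | None = None,
               rct_only: bool = False) -> ThetaEstimate:
    """Unpenalized Stute-weighted least squares on the true-support columns.

    ``support_beta=None`` omits the confounding block entirely (the
    naive/RCT-only oracle); an empty support keeps only the intercepts.
    """
    options = options or FitOptions()
    if rct_only:
        idx = np.flatnonzero(dataset.source == 1)
        dataset = dataset.subset(idx)
        nuisance = None if nuisance is None else nuisance.subset(idx)
    nuisance = _ensure_nuisance(dataset, options, nuisance)
    include_beta = support_beta is not None
    bundle = build_design(dataset, nuisance, include_beta=include_beta)
    p = dataset.p
    sa = np.asarray(support_alpha, dtype=int)
    cols = np.concatenate([[0], 1 + sa])
    if include_beta:
        sb = np.asarray(support_beta, dtype=int)
        cols = np.concatenate([cols, [p + 1], p + 2 + sb])
    Xr = bundle.design[:, cols]
    w = bundle.weights.weights
    sq = np.sqrt(w)
    Xw, yw = Xr * sq[:, None], bundle.pseudo_response * sq
    gram = Xw.T @ Xw
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise np.linalg.LinAlgError("restricted oracle design is singular")
    coef_r = np.linalg.solve(gram, Xw.T @ yw)
    coefs = np.zeros(bundle.design.shape[1])
    coefs[cols] = coef_r
    method = "rl.rctor" if rct_only else ("rl.or" if include_beta else "rl.naior")
    est = _unpack(coefs, p, include_beta, None, None, options, method)
    est = ThetaEstimate(**{**est.__dict__, "tuning_rule": "fixed"})
    return est


def refit_fixed(dataset: SurvivalDataset, nuisance: NuisanceFit, estimate: ThetaEstimate,
                options: FitOptions | None = None, include_beta: bool | None = None) -> np.ndarray:
    """Re-solve at the estimate's (lambda1, lambda2) on (a subsample of) the data.

    Stute weights are recomputed from the given rows; nuisance predictions are
    reused. Used by the bootstrap, where tuning stays fixed at the full-data
    selection. Returns the coefficient vector (alpha then beta block).
    """
    options = options or FitOptions()
    if include_beta is None:
        include_beta = estimate.beta is not None
    bundle = build_design(dataset, nuisance, include_beta=include_beta)
    spec = PenaltySpec(
        family=estimate.penalty_family,
        gamma=options.penalty.gamma,
        lambda1=estimate.lambda1 if estimate.lambda1 is not None else 0.0,
        lambda2=estimate.lambda2 if estimate.lambda2 is not None else 0.0,
    )
    coefs = solve(bundle.pseudo_response, bundle.design, bundle.weights.weights, spec,
                  bundle.pen_block, warm_start=None)
    return coefs


def predict_hte(estimate: ThetaEstimate, X: np.ndarray) -> np.ndarray:
    """tau_hat(X) = alpha_0 + X alpha; rows of X must match the fitted p."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != estimate.alpha.shape[0] - 1:
        raise ValueError(f"X has {X.shape[1]} columns; estimate expects {estimate.alpha.shape[0] - 1}")
    return estimate.alpha[0] + X @ estimate.alpha[1:]
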