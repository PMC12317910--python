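"""Alternative pseudo-response estimators for the fused-data HTE problem.

Each comparator reduces to a penalized regression of some nuisance-adjusted
response on the plain design [1, X, (1-S), (1-S)X]:

* ``oa``   — outcome-adjusted (AIPW) response
             A (log T - mu1)/e + mu1 - (1-A)(log T - mu0)/(1-e) - mu0,
             whose conditional mean given (X, S) is X'alpha + (1-S) X'beta;
             all subjects, Stute weights.
* ``gm0``  — response log T - mu0 on the treated (A=1), Stute weights of that
             subset.
* ``gm1``  — response mu1 - log T on the controls (A=0), Stute weights of that
             subset.
* ``meta`` — sample-size-weighted average of the gm0 and gm1 coefficient
             vectors, (n_{A=1} gm0 + n_{A=0} gm1) / n.
* ``gm01`` — fully imputed response mu1 - mu0 on all subjects; the response
             contains no observed outcome, so uniform weights 1/n replace the
             Stute weights.

All share the same penalized weighted-least-squares machinery as the main
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalDataset
from .estimator import FitOptions, ThetaEstimate, _unpack
from .nuisance import NuisanceFit
from .penalties import PenaltySpec
from .solver import select_bic, select_cv, solve, stute_weight_vector

__all__ = ["ComparatorSpec", "oa_response", "fit_comparator"]

_METHODS = ("oa", "gm0", "gm1", "meta", "gm01")


@dataclass(frozen=True)
class ComparatorSpec:
    method: str = "oa"
    options: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown comparator '{self.method}'; choose from {_METHODS}")


def oa_response(dataset: SurvivalDataset, nuisance: NuisanceFit) -> np.ndarray:
    """The adjusted outcome; finite because e_hat is clipped inside (0, 1)."""
    e = nuisance.e_hat
    if nuisance.mu0_hat is None or nuisance.mu1_hat is None:
        raise ValueError("oa_response requires arm means; cross-fit with arm_means=True")
    if np.any((e <= 0) | (e >= 1)):
        raise ValueError("e_hat must be clipped strictly inside (0, 1)")
    logt = np.log(dataset.time)
    A = dataset.treatment
    mu0, mu1 = nuisance.mu0_hat, nuisance.mu1_hat
    return A * (logt - mu1) / e + mu1 - (1 - A) * (logt - mu0) / (1 - e) - mu0


def _plain_design(dataset: SurvivalDataset, idx: np.ndarray):
    X = dataset.covariates[idx]
    rwd = (1 - dataset.source[idx])[:, None]
    design = np.hstack([np.ones((idx.size, 1)), X, rwd, rwd * X])
    pen_block = np.array([0] + [1] * dataset.p + [0] + [2] * dataset.p)
    return design, pen_block


def _fit_pseudo(dataset: SurvivalDataset, idx: np.ndarray, y: np.ndarray,
                options: FitOptions, uniform_weights: bool, method: str) -> ThetaEstimate:
    design, pen_block = _plain_design(dataset, idx)
    time = dataset.time[idx]
    # uniform weights are realized as Stute weights of an event-complete sample
    event = np.ones(idx.size, dtype=int) if uniform_weights else dataset.event[idx]
    n1, n2 = options.grid_size
    if options.tuning == "cv":
        lam1, lam2, path, best = select_cv(y, design, time, event, pen_block, options.penalty,
                                           K=options.cv_folds, seed=options.seed, n1=n1, n2=n2,
                                           rule=options.cv_rule)
        coefs = path.coefs[best]
    elif options.tuning == "bic":
        w = stute_weight_vector(time, event)
        lam1, lam2, path, best = select_bic(y, design, w, pen_block, options.penalty, n1=n1, n2=n2)
        coefs = path.coefs[best]
    elif options.tuning == "fixed":
        w = stute_weight_vector(time, event)
        coefs = solve(y, design, w, options.penalty, pen_block)
        lam1, lam2 = options.penalty.lambda1, options.penalty.lambda2
    else:
        raise ValueError(f"unknown tuning rule '{options.tuning}'")
    return _unpack(coefs, dataset.p, True, lam1, lam2, options, method)


def fit_comparator(dataset: SurvivalDataset, nuisance: NuisanceFit,
                   spec: ComparatorSpec) -> ThetaEstimate:
    """Fit one comparator; see the module docstring for the constructions."""
    options = spec.options
    method = spec.method
    if method == "meta":
        est0 = fit_comparator(dataset, nuisance, ComparatorSpec("gm0", options))
        est1 = fit_comparator(dataset, nuisance, ComparatorSpec("gm1", options))
        n1 = int((dataset.treatment == 1).sum())
        n0 = dataset.n - n1
        w0, w1 = n1 / dataset.n, n0 / dataset.n
        alpha = w0 * est0.alpha + w1 * est1.alpha
        beta = w0 * est0.beta + w1 * est1.beta
        support_alpha = np.flatnonzero(alpha[1:] != 0)
        support_beta = np.flatnonzero(beta[1:] != 0)
        return ThetaEstimate(
            alpha=alpha, beta=beta, support_alpha=support_alpha, support_beta=support_beta,
            confounding_detected=bool(support_beta.size > 0),
            lambda1=None, lambda2=None, tuning_rule=options.tuning,
            penalty_family=options.penalty.family, method="meta",
        )
    if nuisance.mu0_hat is None or nuisance.mu1_hat is None:
        raise ValueError(f"comparator '{method}' requires arm means; cross-fit with arm_means=True")
    if method == "oa":
        idx = np.arange(dataset.n)
        y = oa_response(dataset, nuisance)
        return _fit_pseudo(dataset, idx, y, options, uniform_weights=False, method="oa")
    if method == "gm0":
        idx = np.flatnonzero(dataset.treatment == 1)
        if idx.size == 0:
            raise ValueError("gm0 needs treated subjects (A=1)")
        y = np.log(dataset.time[idx]) - nuisance.mu0_hat[idx]
        return _fit_pseudo(dataset, idx, y, options, uniform_weights=False, method="gm0")
    if method == "gm1":
        idx = np.flatnonzero(dataset.treatment == 0)
        if idx.size == 0:
            raise ValueError("gm1 needs control subjects (A=0)")
        y = nuisance.mu1_hat[idx] - np.log(dataset.time[idx])
        return _fit_pseudo(dataset, idx, y, options, uniform_weights=False, method="gm1")
    # gm01
    idx = np.arange(dataset.n)
    y = nuisance.mu1_hat - nuisance.mu0_hat
    return _fit_pseudo(dataset, idx, y, options, uniform_weights=True, method="gm01")
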