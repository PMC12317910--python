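"""Cross-fitted nuisance estimation: propensity e(X,S) and outcome means.

The estimating loss is Neyman-orthogonal in (e, mu), so nuisances may be
estimated by flexible learners as long as each subject's predictions come from
models trained without that subject's fold (cross-fitting). Censored subjects
influence outcome-mean training only through their Stute weight, which is
zero — mirroring the loss construction.

Default learners: logistic regression for the propensity (well-specified when
treatment shifts Gaussian covariate means), and for the outcome mean the
arm-combination estimator

    mu_hat(X, S) = e_hat(X,S) * mu1_hat(X,S) + (1 - e_hat(X,S)) * mu0_hat(X,S)

with each arm mean fitted by Stute-weighted least squares on the basis
[X, S, (1-S)X, X^2]. Fitting within treatment arm keeps the treatment-effect
signal out of the residual, which matters under censoring: the Kaplan-Meier
measure cannot see outcomes beyond the censoring support, and the smaller the
conditional variance of the response the smaller the resulting distortion of
the weighted projection. A direct pooled regression of log T on (X, S)
('linear', 'polyridge', 'gbt') is available through the learner spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .data import SurvivalDataset
from .solver import stute_weight_vector

__all__ = ["LearnerSpec", "NuisanceFit", "cross_fit", "fit_propensity", "fit_outcome_mean", "fit_arm_means"]

_CLIP = (0.01, 0.99)


@dataclass(frozen=True)
class LearnerSpec:
    """Declarative description of the nuisance learners.

    propensity: 'logistic' or 'known' (constant ``known_propensity``).
    known_propensity_rct: optional randomization probability overriding the
    fitted propensity on S=1 rows (known by design in a trial whose treatment
    is assigned independently of X).
    outcome: 'armlinear' (default; see module docstring), 'linear',
    'polyridge', or 'gbt'.
    include_interactions / include_squares / include_cubes: extend the linear
    basis with (1-S)X, X^2 and X^3 columns (linear-family learners only); the
    polynomial terms let the fit track smooth nonlinear baselines.
    """

    propensity: str = "logistic"
    known_propensity: float | None = None
    known_propensity_rct: float | None = None
    outcome: str = "armlinear"
    include_interactions: bool = True
    include_squares: bool = True
    include_cubes: bool = True
    degree: int = 2
    ridge_alpha: float = 1.0
    gbt_params: tuple = ()
    clip: tuple = _CLIP

    def describe(self) -> dict:
        return {
            "propensity": self.propensity,
            "outcome": self.outcome,
            "include_interactions": self.include_interactions,
            "include_squares": self.include_squares,
            "include_cubes": self.include_cubes,
        }


@dataclass
class NuisanceFit:
    """Per-subject out-of-fold nuisance predictions."""

    e_hat: np.ndarray
    mu_hat: np.ndarray
    mu0_hat: np.ndarray | None
    mu1_hat: np.ndarray | None
    fold_id: np.ndarray
    learner_spec: dict = field(default_factory=dict)

    def subset(self, idx) -> "NuisanceFit":
        return NuisanceFit(
            e_hat=self.e_hat[idx],
            mu_hat=self.mu_hat[idx],
            mu0_hat=None if self.mu0_hat is None else self.mu0_hat[idx],
            mu1_hat=None if self.mu1_hat is None else self.mu1_hat[idx],
            fold_id=self.fold_id[idx],
            learner_spec=dict(self.learner_spec),
        )


def _base_features(dataset: SurvivalDataset, idx: np.ndarray) -> np.ndarray:
    return np.column_stack([dataset.covariates[idx], dataset.source[idx]])


def _linear_features(dataset: SurvivalDataset, idx: np.ndarray, spec: LearnerSpec) -> np.ndarray:
    X = dataset.covariates[idx]
    parts = [X, dataset.source[idx, None].astype(float)]
    if spec.include_interactions:
        parts.append((1 - dataset.source[idx, None]) * X)
    if spec.include_squares:
        parts.append(X**2)
    if spec.include_cubes:
        parts.append(X**3)
    return np.hstack(parts)


def fit_propensity(dataset: SurvivalDataset, train_idx, pred_idx, spec: LearnerSpec) -> np.ndarray:
    """Treatment-probability predictions for ``pred_idx``, trained on ``train_idx``.

    Predictions are clipped to ``spec.clip``; a known trial randomization
    probability, if supplied, replaces the fitted values on S=1 rows.
    """
    train_idx = np.asarray(train_idx)
    pred_idx = np.asarray(pred_idx)
    if spec.propensity == "known":
        if spec.known_propensity is None:
            raise ValueError("propensity='known' requires known_propensity")
        e = np.full(len(pred_idx), float(spec.known_propensity))
    else:
        a_tr = dataset.treatment[train_idx]
        for s in np.unique(dataset.source[train_idx]):
            arm = a_tr[dataset.source[train_idx] == s]
            if arm.min() == arm.max():
                raise ValueError(f"training data has a single treatment arm in source stratum S={s}")
        model = LogisticRegression(C=100.0, max_iter=2000)
        model.fit(_base_features(dataset, train_idx), a_tr)
        e = model.predict_proba(_base_features(dataset, pred_idx))[:, 1]
    if spec.known_propensity_rct is not None:
        e = np.where(dataset.source[pred_idx] == 1, float(spec.known_propensity_rct), e)
    return np.clip(e, *spec.clip)


def _fit_single(dataset: SurvivalDataset, train_idx, pred_idx, spec: LearnerSpec,
                engine: str) -> np.ndarray:
    """One Stute-weighted regression of log T on covariate features."""
    train_idx = np.asarray(train_idx)
    pred_idx = np.asarray(pred_idx)
    if dataset.event[train_idx].sum() == 0:
        raise ValueError("outcome-mean training subset contains no events")
    w = stute_weight_vector(dataset.time[train_idx], dataset.event[train_idx])
    sw = w * len(train_idx)  # per-subject scale keeps ridge alpha interpretable
    y = np.log(dataset.time[train_idx])
    if engine == "linear":
        F_tr = _linear_features(dataset, train_idx, spec)
        F_pr = _linear_features(dataset, pred_idx, spec)
        Z = np.column_stack([np.ones(len(train_idx)), F_tr])
        sq = np.sqrt(sw)
        beta, *_ = np.linalg.lstsq(Z * sq[:, None], y * sq, rcond=None)
        return np.column_stack([np.ones(len(pred_idx)), F_pr]) @ beta
    F_tr = _base_features(dataset, train_idx)
    F_pr = _base_features(dataset, pred_idx)
    if engine == "polyridge":
        poly = PolynomialFeatures(degree=spec.degree, include_bias=False)
        B_tr = poly.fit_transform(F_tr)
        scaler = StandardScaler().fit(B_tr)
        model = Ridge(alpha=spec.ridge_alpha)
        model.fit(scaler.transform(B_tr), y, sample_weight=sw)
        return model.predict(scaler.transform(poly.transform(F_pr)))
    if engine == "gbt":
        from sklearn.ensemble import HistGradientBoostingRegressor

        model = HistGradientBoostingRegressor(max_depth=3, random_state=0, **dict(spec.gbt_params))
        model.fit(F_tr, y, sample_weight=sw)
        return model.predict(F_pr)
    raise ValueError(f"unknown outcome learner '{engine}'")


def fit_arm_means(dataset: SurvivalDataset, train_idx, pred_idx, spec: LearnerSpec):
    """(mu0, mu1) predictions: outcome regressions restricted to each arm."""
    train_idx = np.asarray(train_idx)
    engine = "linear" if spec.outcome == "armlinear" else spec.outcome
    out = []
    for a in (0, 1):
        arm = train_idx[dataset.treatment[train_idx] == a]
        if arm.size == 0 or dataset.event[arm].sum() == 0:
            raise ValueError(f"treatment arm A={a} has no events in the training subset")
        out.append(_fit_single(dataset, arm, pred_idx, spec, engine))
    return out[0], out[1]


def fit_outcome_mean(dataset: SurvivalDataset, train_idx, pred_idx, spec: LearnerSpec,
                     e_pred: np.ndarray | None = None) -> np.ndarray:
    """mu(X,S) = E[log T~ | X, S] predictions for ``pred_idx``.

    For the default 'armlinear' learner the arm means are fitted separately
    and combined with the propensity (law of total expectation); ``e_pred``
    may supply precomputed propensity predictions for ``pred_idx``.
    Raises if the training subset contains no events.
    """
    if spec.outcome == "armlinear":
        mu0, mu1 = fit_arm_means(dataset, train_idx, pred_idx, spec)
        if e_pred is None:
            e_pred = fit_propensity(dataset, train_idx, pred_idx, spec)
        return e_pred * mu1 + (1 - e_pred) * mu0
    return _fit_single(dataset, train_idx, pred_idx, spec, spec.outcome)


def _stratified_folds(dataset: SurvivalDataset, K: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels 0..K-1, round-robin within each (S, A) stratum."""
    fold = np.empty(dataset.n, dtype=int)
    strata = dataset.source * 2 + dataset.treatment
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % K
    return fold


def cross_fit(dataset: SurvivalDataset, spec: LearnerSpec | None = None, K: int = 2,
              seed: int = 0, arm_means: bool = True) -> NuisanceFit:
    """Out-of-fold nuisance predictions for every subject.

    Folds are stratified by (source, treatment); each subject's predictions
    come from models trained on the other folds only. Deterministic given
    ``seed``. ``arm_means=False`` skips (mu0, mu1) storage for learners that
    do not produce them as a by-product.
    """
    spec = spec or LearnerSpec()
    if K < 2:
        raise ValueError("cross-fitting requires K >= 2")
    if dataset.n < 4 * K:
        raise ValueError("n >= 4K required for stratified cross-fitting")
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(dataset, K, rng)
    n = dataset.n
    keep_arms = arm_means or spec.outcome == "armlinear"
    e = np.empty(n)
    mu = np.empty(n)
    mu0 = np.empty(n) if keep_arms else None
    mu1 = np.empty(n) if keep_arms else None
    for f in range(K):
        pred = np.flatnonzero(fold == f)
        train = np.flatnonzero(fold != f)
        try:
            e[pred] = fit_propensity(dataset, train, pred, spec)
        except ValueError as err:
            raise ValueError(f"{err}; try fewer folds") from err
        if spec.outcome == "armlinear":
            mu0[pred], mu1[pred] = fit_arm_means(dataset, train, pred, spec)
            mu[pred] = e[pred] * mu1[pred] + (1 - e[pred]) * mu0[pred]
        else:
            mu[pred] = fit_outcome_mean(dataset, train, pred, spec)
            if keep_arms:
                mu0[pred], mu1[pred] = fit_arm_means(dataset, train, pred, spec)
    return NuisanceFit(e_hat=e, mu_hat=mu, mu0_hat=mu0, mu1_hat=mu1, fold_id=fold,
                       learner_spec=spec.describe())
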