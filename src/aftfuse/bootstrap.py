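"""Nonparametric 0.632 subsampling bootstrap for standard errors and intervals.

Each bootstrap replicate draws round(0.632 n) subjects *without replacement*,
stratified by source so the RCT/RWD mix is preserved, recomputes the Stute
weights on the subsample, and re-solves the penalized problem with the tuning
parameters held fixed at their full-data selection (nuisance predictions are
likewise reused). The SE is the sample standard deviation of the bootstrap
coefficient estimates, rescaled by sqrt(m / (n - m)) with m = round(0.632 n):
an m-out-of-n subsample estimate differs from the full-data estimate with
variance approximately V (1/m - 1/n), so this factor maps the subsampling
spread onto the level-n sampling variance. Intervals are normal,
point +/- z * SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import SurvivalDataset
from .estimator import FitOptions, ThetaEstimate, refit_fixed
from .nuisance import NuisanceFit

__all__ = ["BootstrapSummary", "bootstrap_632", "coverage"]

_FRACTION = 0.632


@dataclass
class BootstrapSummary:
    """Full-data point estimate plus bootstrap uncertainty."""

    point: ThetaEstimate
    se: np.ndarray          # aligned with point.theta
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_boot: int
    subsample_fraction: float
    level: float
    seed: int


def _stratified_subsample(dataset: SurvivalDataset, size: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a without-replacement subsample, proportional within source strata."""
    idx_parts = []
    sources = np.unique(dataset.source)
    remaining = size
    for k, s in enumerate(sources):
        pool = np.flatnonzero(dataset.source == s)
        take = remaining if k == len(sources) - 1 else int(round(size * pool.size / dataset.n))
        take = min(max(take, 1), pool.size)
        remaining -= take
        idx_parts.append(rng.choice(pool, size=take, replace=False))
    return np.sort(np.concatenate(idx_parts))


def _subsample_ok(dataset: SurvivalDataset, idx: np.ndarray, need_both_sources: bool) -> bool:
    a = dataset.treatment[idx]
    if a.min() == a.max():
        return False
    if dataset.event[idx].sum() == 0:
        return False
    if need_both_sources:
        s = dataset.source[idx]
        if s.min() == s.max():
            return False
    return True


def bootstrap_632(dataset: SurvivalDataset, nuisance: NuisanceFit, point: ThetaEstimate,
                  n_boot: int = 500, level: float = 0.95, seed: int = 0,
                  options: FitOptions | None = None, fit=None,
                  subsample_fraction: float = _FRACTION,
                  max_redraws: int = 100) -> BootstrapSummary:
    """Bootstrap the penalized fit; deterministic given ``seed``.

    ``fit`` may override the replicate-level procedure: a callable
    ``fit(subset_dataset, subset_nuisance, point) -> coefficient vector``.
    The default re-solves the penalized problem at the point estimate's
    (lambda1, lambda2) via :func:`aftfuse.estimator.refit_fixed`.
    """
    options = options or FitOptions()
    if fit is None:
        fit = lambda ds, nu, pt: refit_fixed(ds, nu, pt, options)  # noqa: E731
    rng = np.random.default_rng(seed)
    size = int(round(subsample_fraction * dataset.n))
    need_both = dataset.source.min() != dataset.source.max()
    coefs = np.empty((n_boot, point.theta.shape[0]))
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            idx = _stratified_subsample(dataset, size, rng)
            if _subsample_ok(dataset, idx, need_both):
                break
        else:
            raise RuntimeError(f"bootstrap replicate {b}: no valid subsample in {max_redraws} redraws")
        coefs[b] = fit(dataset.subset(idx), nuisance.subset(idx), point)
    se = coefs.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(coefs.shape[1])
    se = se * np.sqrt(size / (dataset.n - size))  # m-out-of-n variance rescaling
    z = stats.norm.ppf(0.5 + level / 2)
    theta = point.theta
    return BootstrapSummary(
        point=point,
        se=se,
        ci_lower=theta - z * se,
        ci_upper=theta + z * se,
        n_boot=n_boot,
        subsample_fraction=subsample_fraction,
        level=level,
        seed=seed,
    )


def coverage(ci_lower: np.ndarray, ci_upper: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-coefficient fraction of replicates whose interval contains the truth.

    ``ci_lower``/``ci_upper`` are (B, d); ``truth`` is (d,).
    """
    lo = np.atleast_2d(np.asarray(ci_lower, float))
    hi = np.atleast_2d(np.asarray(ci_upper, float))
    truth = np.asarray(truth, float)
    hit = (lo <= truth[None, :]) & (truth[None, :] <= hi)
    return hit.mean(axis=0)
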