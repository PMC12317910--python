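"""Replicate-level scoring: RMSE, false discovery rate, identification rate.

Conventions: all three operate on the covariate part of alpha (intercepts are
excluded); a replicate selecting no variables contributes 0 to the FDR (its
discovered-set ratio is 0/0).
"""

from __future__ import annotations

import numpy as np

__all__ = ["rmse", "fdr", "tir"]


def rmse(estimates: np.ndarray, truth: np.ndarray) -> float:
    """sqrt( (B p)^-1 sum_b sum_j (alpha_hat_j^(b) - alpha*_j)^2 ).

    ``estimates`` is (B, p), ``truth`` is (p,).
    """
    estimates = np.atleast_2d(np.asarray(estimates, float))
    truth = np.asarray(truth, float)
    if estimates.shape[0] == 0:
        raise ValueError("need at least one replicate")
    if estimates.shape[1] != truth.shape[0]:
        raise ValueError("estimate and truth dimensions disagree")
    return float(np.sqrt(np.mean((estimates - truth[None, :]) ** 2)))


def fdr(estimates: np.ndarray, truth: np.ndarray) -> float:
    """Mean over replicates of |{j: alpha*_j = 0, alpha_hat_j != 0}| / |{j: alpha_hat_j != 0}|."""
    estimates = np.atleast_2d(np.asarray(estimates, float))
    truth = np.asarray(truth, float)
    null = truth == 0
    selected = estimates != 0
    discovered = selected.sum(axis=1)
    false_disc = (selected & null[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ratio = np.where(discovered > 0, false_disc / np.maximum(discovered, 1), 0.0)
    return float(ratio.mean())


def tir(flags: np.ndarray, truth_confounded: bool) -> float:
    """Fraction of replicates whose confounding call matches the truth."""
    flags = np.asarray(flags, bool)
    return float((flags == bool(truth_confounded)).mean())
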