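"""Folded-concave and adaptive penalties and their scalar proximal updates.

Three families are supported, each with block-specific tuning parameters
(lambda1 for the treatment-effect block, lambda2 for the confounding block):

* MCP (default): rho(t; lam) = lam*t - t^2/(2*gamma) for t <= gamma*lam,
  else gamma*lam^2/2; gamma > 1.
* SCAD: the usual three-piece form; gamma > 2 (default 3.7).
* Adaptive lasso: rho(t; lam) = lam * t (per-coefficient weights are folded
  into lambda by the caller).

All satisfy: nondecreasing on [0, inf), rho(0; lam) = 0, bounded derivative on
(0, inf) — the properties the estimator's sparsity theory requires of the
penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PenaltySpec", "penalty_value", "threshold_update", "FAMILY_CODES"]

FAMILY_CODES = {"mcp": 0, "scad": 1, "alasso": 2}

_DEFAULT_GAMMA = {"mcp": 3.0, "scad": 3.7, "alasso": 2.0}


@dataclass
class PenaltySpec:
    """Penalty family and tuning parameters for the two coefficient blocks.

    ``lambda1`` penalizes the treatment-effect (alpha) covariate block,
    ``lambda2`` the confounding (beta) covariate block; ``None`` means
    "select automatically". ``gamma`` is the concavity parameter (> 1 for
    MCP, > 2 for SCAD; unused by the adaptive lasso).
    """

    family: str = "mcp"
    gamma: float = None  # type: ignore[assignment]
    lambda1: float | None = None
    lambda2: float | None = None
    unpenalized_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILY_CODES:
            raise ValueError(f"unknown penalty family '{self.family}'")
        if self.gamma is None:
            self.gamma = _DEFAULT_GAMMA[self.family]
        if self.family == "mcp" and not self.gamma > 1:
            raise ValueError("MCP requires gamma > 1")
        if self.family == "scad" and not self.gamma > 2:
            raise ValueError("SCAD requires gamma > 2")
        for lam in (self.lambda1, self.lambda2):
            if lam is not None and lam < 0:
                raise ValueError("lambda must be nonnegative")

    @property
    def family_code(self) -> int:
        return FAMILY_CODES[self.family]


def penalty_value(t: float | np.ndarray, lam: float, family: str = "mcp", gamma: float | None = None) -> np.ndarray:
    """rho(t; lam) evaluated elementwise for t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("penalty argument t must be nonnegative")
    if gamma is None:
        gamma = _DEFAULT_GAMMA[family]
    if family == "mcp":
        return np.where(t <= gamma * lam, lam * t - t**2 / (2 * gamma), gamma * lam**2 / 2)
    if family == "scad":
        a = gamma
        r1 = lam * t
        r2 = (2 * a * lam * t - t**2 - lam**2) / (2 * (a - 1))
        r3 = lam**2 * (a + 1) / 2
        return np.where(t <= lam, r1, np.where(t <= a * lam, r2, r3))
    if family == "alasso":
        return lam * t
    raise ValueError(f"unknown penalty family '{family}'")


def threshold_update(z: float, v: float, lam: float, family: str = "mcp", gamma: float | None = None) -> float:
    """Exact minimizer of  0.5*v*(b - z/v)^2 + rho(|b|; lam).

    ``v`` is the (positive) quadratic curvature; this is the scalar update at
    the heart of coordinate descent. For MCP with v=1: 0 for |z| <= lam,
    sign(z)(|z|-lam)/(1-1/gamma) for lam < |z| <= gamma*lam, z beyond.
    """
    if v <= 0:
        raise ValueError("curvature v must be positive")
    if gamma is None:
        gamma = _DEFAULT_GAMMA[family]
    az, sz = abs(z), np.sign(z)
    if family == "mcp":
        if v * gamma <= 1.0:
            # coordinatewise nonconvex: compare the two candidate stationary points
            cands = [0.0, z / v]
            return min(cands, key=lambda b: 0.5 * v * (b - z / v) ** 2 + float(penalty_value(abs(b), lam, "mcp", gamma)))
        if az <= lam:
            return 0.0
        if az <= v * gamma * lam:
            return sz * (az - lam) / (v - 1.0 / gamma)
        return z / v
    if family == "scad":
        a = gamma
        if az <= lam * (1.0 + v):
            b = sz * max(az - lam, 0.0) / v
        elif az <= a * lam * v:
            denom = v - 1.0 / (a - 1.0)
            if denom <= 0:
                cands = [0.0, z / v, sz * max(az - lam, 0.0) / v]
                return min(cands, key=lambda b: 0.5 * v * (b - z / v) ** 2 + float(penalty_value(abs(b), lam, "scad", gamma)))
            b = sz * (az - a * lam / (a - 1.0)) / denom
        else:
            b = z / v
        return float(b)
    if family == "alasso":
        return float(sz * max(az - lam, 0.0) / v)
    raise ValueError(f"unknown penalty family '{family}'")
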