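"""Stute / Kaplan-Meier jump weights for censored least squares.

Sorting the sample by observed time T_(1) <= ... <= T_(n), the weight attached
to the i-th ordered observation is

    w_1 = delta_(1) / n,
    w_i = delta_(i) / (n - i + 1) * prod_{j<i} ((n - j) / (n - j + 1))^delta_(j)

which is exactly the mass the product-limit (Kaplan-Meier) estimator places on
the i-th ordered time. Censored observations receive weight zero; the weights
sum to one minus the Kaplan-Meier survival just after the largest observation,
so the total mass is < 1 when the largest observation is censored. The weights
turn a censored least-squares problem into a weighted complete-data one.

Ties are broken events-first (the standard product-limit convention: a failure
at t precedes a censoring at t), then by original index, so the permutation is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset

__all__ = ["StuteWeights", "sort_by_time", "compute_stute_weights", "km_survival"]


@dataclass
class StuteWeights:
    """Jump weights in sorted-time order, plus the sorting permutation.

    ``order`` maps sorted position -> original row index;
    ``weights[i]`` belongs to the subject at sorted position ``i``.
    """

    order: np.ndarray
    weights: np.ndarray
    total_mass: float

    @property
    def n(self) -> int:
        return int(self.order.shape[0])

    def unsorted(self) -> np.ndarray:
        """Weights re-indexed to original row order."""
        w = np.empty_like(self.weights)
        w[self.order] = self.weights
        return w


def sort_by_time(dataset: SurvivalDataset) -> np.ndarray:
    """Permutation of 0..n-1 giving nondecreasing observed time.

    Ties: events (delta=1) before censored observations, then original index.
    """
    # lexsort: last key is primary
    return np.lexsort((np.arange(dataset.n), -dataset.event, dataset.time))


def _weights_from_sorted_events(delta_sorted: np.ndarray) -> np.ndarray:
    n = delta_sorted.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    # survival factor contributed by ordered obs j: ((n-j)/(n-j+1))^delta_j
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(delta_sorted == 1, (n - i) / (n - i + 1.0), 1.0)
    cumprod = np.cumprod(factors)
    prev = np.concatenate(([1.0], cumprod[:-1]))  # prod over j < i
    return np.where(delta_sorted == 1, prev / (n - i + 1.0), 0.0)


def compute_stute_weights(dataset: SurvivalDataset) -> StuteWeights:
    """Stute weights of the sample, sorted by :func:`sort_by_time`.

    Raises ``ValueError`` on an empty dataset.
    """
    if dataset.n == 0:
        raise ValueError("cannot compute Stute weights on an empty dataset")
    order = sort_by_time(dataset)
    w = _weights_from_sorted_events(dataset.event[order])
    return StuteWeights(order=order, weights=w, total_mass=float(w.sum()))


def km_survival(dataset: SurvivalDataset) -> np.ndarray:
    """Product-limit survival evaluated just after each ordered observation.

    Returns an (n, 2) array with columns (sorted time, S(t+)). Equals
    ``1 - cumsum(stute weights)`` exactly, by the product-limit identity.
    """
    order = sort_by_time(dataset)
    delta = dataset.event[order]
    n = dataset.n
    i = np.arange(1, n + 1, dtype=float)
    factors = np.where(delta == 1, (n - i) / (n - i + 1.0), 1.0)
    surv = np.cumprod(factors)
    return np.column_stack([dataset.time[order], surv])
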