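"""Distances between opinions: Hellinger, total variation, f-divergences.

All distances are computed on unit-mass rescalings, so opinions with any
common overall normalization compare consistently.  The Hellinger distance
uses the [0, 1] convention ``H**2 = 1 - B`` where ``B = sum sqrt(p*q)`` is
the Bhattacharyya overlap; it is 0 iff the opinions coincide and 1 iff their
supports are disjoint.  Total variation is ``(1/2) * sum |p - q|``.

The f-divergence family ``D_f(p||q) = sum_k q_k f(p_k/q_k)`` (f convex)
contains Lyapunov functions of the repeated-persuasion dynamics; the choices
recovering squared Hellinger, total variation, and Kullback-Leibler are
exported as ``F_HELLINGER``, ``F_TV`` and ``F_KL``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple, Union

import numpy as np
from scipy.special import xlogy

from .core import DimensionMismatchError, DiscreteOpinion
from .densities import GaussianParams, GridOpinion

__all__ = [
    "DistanceReport",
    "F_HELLINGER",
    "F_KL",
    "F_TV",
    "bhattacharyya",
    "distance_report",
    "f_divergence",
    "hellinger",
    "hellinger_gaussian",
    "total_variation",
]

Opinion = Union[DiscreteOpinion, GridOpinion]


def _prob_pair(p: Opinion, q: Opinion) -> Tuple[np.ndarray, np.ndarray, Union[float, np.ndarray]]:
    """Unit-mass vectors plus the quadrature measure (1 for discrete)."""
    if isinstance(p, GridOpinion) and isinstance(q, GridOpinion):
        if p.grid != q.grid:
            raise DimensionMismatchError("grid opinions must share the same grid")
        w = np.full(p.grid.n_points, p.grid.spacing)
        w[0] = w[-1] = p.grid.spacing / 2.0
        return p.density, q.density, w
    if isinstance(p, DiscreteOpinion) and isinstance(q, DiscreteOpinion):
        if p.k != q.k:
            raise DimensionMismatchError("opinions have different lengths")
        return p.probabilities, q.probabilities, 1.0
    raise DimensionMismatchError("cannot mix discrete and grid opinions in a distance")


def bhattacharyya(p: Opinion, q: Opinion) -> float:
    """Overlap ``sum sqrt(p*q)`` in [0, 1]."""
    pv, qv, w = _prob_pair(p, q)
    return float(np.clip(np.sum(w * np.sqrt(pv * qv)), 0.0, 1.0))


def hellinger(p: Opinion, q: Opinion) -> float:
    """Hellinger distance ``sqrt(1 - B)`` in [0, 1]."""
    return float(np.sqrt(max(0.0, 1.0 - bhattacharyya(p, q))))


def hellinger_gaussian(a: GaussianParams, b: GaussianParams) -> float:
    """Closed form for two Gaussian opinions.

    ``H^2 = 1 - sqrt(2 s_a s_b / (s_a^2 + s_b^2)) * exp(-(mu_a-mu_b)^2 / (4 (s_a^2+s_b^2)))``.
    """
    s2 = a.sigma**2 + b.sigma**2
    bc = math.sqrt(2.0 * a.sigma * b.sigma / s2) * math.exp(-((a.mu - b.mu) ** 2) / (4.0 * s2))
    return math.sqrt(max(0.0, 1.0 - bc))


def total_variation(p: Opinion, q: Opinion) -> float:
    """Total variation distance ``(1/2) sum |p - q|`` in [0, 1]."""
    pv, qv, w = _prob_pair(p, q)
    return float(np.clip(0.5 * np.sum(w * np.abs(pv - qv)), 0.0, 1.0))


def F_HELLINGER(y: np.ndarray) -> np.ndarray:
    """f-choice recovering twice the squared Hellinger distance."""
    return (np.sqrt(y) - 1.0) ** 2


def F_TV(y: np.ndarray) -> np.ndarray:
    """f-choice recovering total variation."""
    return 0.5 * np.abs(y - 1.0)


def F_KL(y: np.ndarray) -> np.ndarray:
    """f-choice recovering Kullback-Leibler divergence (0 log 0 = 0)."""
    return xlogy(y, y)


def f_divergence(p: Opinion, q: Opinion, f: Callable[[np.ndarray], np.ndarray]) -> float:
    """``D_f(p||q) = sum_k q_k f(p_k/q_k)`` on unit-mass rescalings.

    Requires f convex with a finite f(1); D_f is minimized at ``p = q`` with
    value ``f(1)`` (convexity itself is the caller's contract and is not
    detectable).  Events with ``q_k = 0`` but ``p_k > 0`` make the divergence
    infinite; ``math.inf`` is returned as a flagged sentinel rather than an
    exception.  Events with ``p_k = q_k = 0`` contribute zero.
    """
    pv, qv, w = _prob_pair(p, q)
    if np.any((qv == 0) & (pv > 0)):
        return math.inf
    pos = qv > 0
    ratio = pv[pos] / qv[pos]
    vals = np.asarray(f(ratio), dtype=float)
    ww = w[pos] if isinstance(w, np.ndarray) else w
    return float(np.sum(ww * qv[pos] * vals))


@dataclass(frozen=True)
class DistanceReport:
    """Bundle of the standard distances between two opinions."""

    hellinger: float
    total_variation: float
    bhattacharyya_overlap: float


def distance_report(p: Opinion, q: Opinion) -> DistanceReport:
    b = bhattacharyya(p, q)
    return DistanceReport(
        hellinger=float(np.sqrt(max(0.0, 1.0 - b))),
        total_variation=total_variation(p, q),
        bhattacharyya_overlap=b,
    )
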