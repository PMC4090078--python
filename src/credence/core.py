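"""Discrete probabilistic opinions and the confirmation-biased revision operator.

An opinion over ``K`` mutually exclusive events is a vector of nonnegative
weights with a free overall normalization ``total_mass`` (1 for ordinary
probabilities, 100 for percentages, ...).  Revision of an opinion ``p`` under
a persuading opinion ``q`` proceeds in two steps:

1. *linear pooling* -- the opinions are mixed, ``pi = eps*p + (1-eps)*q``,
   where ``eps`` is the weight the agent places on his own opinion (large
   ``eps`` = low credibility of the persuader);
2. *projection (trimming)* -- the pooled opinion is pulled back toward the
   prior, ``w_k = p_k**eps * pi_k**(1-eps)``, the unique functional form that
   commutes with probabilistic conditioning.

The revised opinion is the renormalization of ``w``.  The composite rule is
conservative at ``eps = 1`` (no change), fully credulous at ``eps = 0``
(adopts ``q`` whenever all ``p_k > 0``), keeps zero probabilities at zero,
ignores persuaders with disjoint support, and is invariant under joint
rescaling of the normalization.

For ``eps > 1`` the pooled vector becomes a *signed* measure and the rule is
continued as ``w_k = p_k**(2-eps) * |pi_k|**(eps-1)`` (the boomerang regime):
the agent moves *away* from the persuader.  See :mod:`credence.dynamics` and
:mod:`credence.experiments` for the phenomena built on these operators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AVERAGE_THEN_PROJECT",
    "PROJECT_THEN_AVERAGE",
    "BOOMERANG",
    "VARIANTS",
    "DegenerateRevisionError",
    "DimensionMismatchError",
    "DiscreteOpinion",
    "OpinionValidationError",
    "RevisionParams",
    "SignedWeights",
    "pool",
    "project",
    "revise",
    "revise_sequence",
]

# Relative tolerance for "sum of weights equals total_mass" on input
# validation; outputs are renormalized exactly.
MASS_RTOL = 1e-9

AVERAGE_THEN_PROJECT = "average_then_project"
PROJECT_THEN_AVERAGE = "project_then_average"
BOOMERANG = "boomerang"
VARIANTS = (AVERAGE_THEN_PROJECT, PROJECT_THEN_AVERAGE, BOOMERANG)


class OpinionValidationError(ValueError):
    """An opinion or parameter object violates its invariants."""


class DimensionMismatchError(ValueError):
    """Two opinions disagree in length or total mass."""


class DegenerateRevisionError(ValueError):
    """Every pooled-projected weight vanished; the rule has no output."""


def _as_weight_array(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise OpinionValidationError("weights must be a 1-D vector")
    if arr.size < 2:
        raise OpinionValidationError("an opinion needs at least K=2 events")
    if not np.all(np.isfinite(arr)):
        raise OpinionValidationError("weights must be finite")
    return arr


@dataclass(frozen=True)
class DiscreteOpinion:
    """Nonnegative weights over K events with free total mass.

    Parameters
    ----------
    weights
        Vector of K >= 2 nonnegative reals summing to ``total_mass``
        (relative tolerance 1e-9).
    total_mass
        The chosen overall normalization, default 1.
    """

    weights: np.ndarray
    total_mass: float = 1.0

    def __post_init__(self) -> None:
        arr = _as_weight_array(self.weights)
        object.__setattr__(self, "weights", arr)
        arr.setflags(write=False)
        if not (self.total_mass > 0 and np.isfinite(self.total_mass)):
            raise OpinionValidationError("total_mass must be a positive real")
        if np.any(arr < 0):
            raise OpinionValidationError("weights must be nonnegative")
        if abs(arr.sum() - self.total_mass) > MASS_RTOL * self.total_mass:
            raise OpinionValidationError(
                f"weights sum to {arr.sum()!r}, expected total_mass={self.total_mass!r}"
            )

    @classmethod
    def from_weights(cls, weights: Iterable[float], total_mass: float = 1.0) -> "DiscreteOpinion":
        """Rescale ``weights`` exactly to ``total_mass`` and build an opinion."""
        arr = _as_weight_array(weights)
        s = arr.sum()
        if s <= 0:
            raise OpinionValidationError("weights must have positive total")
        return cls(arr * (total_mass / s), total_mass)

    @property
    def k(self) -> int:
        return self.weights.size

    @property
    def probabilities(self) -> np.ndarray:
        """Weights rescaled to unit mass."""
        return self.weights / self.total_mass

    def rescaled(self, total_mass: float) -> "DiscreteOpinion":
        return DiscreteOpinion(self.weights * (total_mass / self.total_mass), total_mass)

    def __eq__(self, other: object) -> bool:  # dataclass eq chokes on arrays
        if not isinstance(other, DiscreteOpinion):
            return NotImplemented
        return self.total_mass == other.total_mass and np.array_equal(self.weights, other.weights)


@dataclass(frozen=True)
class RevisionParams:
    """Rule parameters: self-weight ``epsilon`` and the rule variant.

    ``epsilon`` lives in [0, 1] for the normal (confirmation-bias) regime and
    strictly above 1 for the boomerang regime, which requires the
    ``"boomerang"`` variant.
    """

    epsilon: float
    variant: str = AVERAGE_THEN_PROJECT

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise OpinionValidationError(
                f"unknown variant {self.variant!r}; choose one of {VARIANTS}"
            )
        eps = float(self.epsilon)
        if not np.isfinite(eps) or eps < 0:
            raise OpinionValidationError("epsilon must be a finite nonnegative real")
        if self.variant == BOOMERANG and eps <= 1:
            raise OpinionValidationError("the boomerang variant requires epsilon > 1")
        if self.variant != BOOMERANG and eps > 1:
            raise OpinionValidationError(
                f"variant {self.variant!r} requires 0 <= epsilon <= 1 "
                "(use variant='boomerang' for epsilon > 1)"
            )
        object.__setattr__(self, "epsilon", eps)


@dataclass(frozen=True)
class SignedWeights:
    """Pooled measure over K events; entries may be negative when eps > 1."""

    values: np.ndarray
    total_mass: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        arr.setflags(write=False)
        if abs(arr.sum() - self.total_mass) > MASS_RTOL * abs(self.total_mass):
            raise OpinionValidationError("signed weights must sum to total_mass")

    @property
    def k(self) -> int:
        return self.values.size


def _check_compatible(p: DiscreteOpinion, q: DiscreteOpinion) -> None:
    if p.k != q.k:
        raise DimensionMismatchError(f"opinions have different lengths: {p.k} vs {q.k}")
    if abs(p.total_mass - q.total_mass) > MASS_RTOL * max(p.total_mass, q.total_mass):
        raise DimensionMismatchError(
            "opinions use different overall normalizations "
            f"({p.total_mass!r} vs {q.total_mass!r}); rescale one of them explicitly"
        )


def pool(p: DiscreteOpinion, q: DiscreteOpinion, params: RevisionParams) -> SignedWeights:
    """Linear opinion pooling ``eps*p + (1-eps)*q``.

    For ``eps <= 1`` this is a convex combination (a bona fide opinion);
    for ``eps > 1`` it is a signed measure whose negative part encodes the
    persuader's anti-credibility.  The total mass is preserved exactly.
    """
    _check_compatible(p, q)
    eps = params.epsilon
    values = eps * p.weights + (1.0 - eps) * q.weights
    # kill the tiny negative round-off that can appear at eps ~ 1
    if eps <= 1:
        values = np.maximum(values, 0.0)
    values = values * (p.total_mass / values.sum()) if values.sum() != 0 else values
    return SignedWeights(values, p.total_mass)


def projection_weights(
    pi: np.ndarray, p: np.ndarray, epsilon: float
) -> np.ndarray:
    """Raw (unnormalized) projection of a pooled measure onto the prior.

    For ``epsilon <= 1`` returns ``p**eps * pi**(1-eps)``; for ``epsilon > 1``
    the continuation ``p**(2-eps) * |pi|**(eps-1)``, which keeps both
    exponents nonnegative and agrees with the former at ``epsilon = 1``.
    Entries with ``p_k = 0`` are zero by the convention ``0**a = 0`` (a > 0),
    and entries whose pooled value is exactly zero get weight zero.
    Works elementwise for both discrete weights and grid density values.
    """
    pi = np.asarray(pi, dtype=float)
    p = np.asarray(p, dtype=float)
    if pi.shape != p.shape:
        raise DimensionMismatchError("pooled measure and prior have different shapes")
    eps = float(epsilon)
    if eps < 0 or not np.isfinite(eps):
        raise OpinionValidationError("epsilon must be a finite nonnegative real")
    out = np.zeros_like(p)
    if eps == 1.0:
        np.copyto(out, p)
        return out
    pos = p > 0
    if eps == 0.0:
        # full acceptance: proportional to the pooled measure where p > 0
        out[pos] = pi[pos]
        return out
    with np.errstate(divide="ignore", invalid="ignore"):
        if eps < 1.0:
            vals = p[pos] ** eps * np.maximum(pi[pos], 0.0) ** (1.0 - eps)
        else:
            vals = p[pos] ** (2.0 - eps) * np.abs(pi[pos]) ** (eps - 1.0)
    out[pos] = np.nan_to_num(vals, nan=0.0, posinf=0.0)
    return out


def project(pi: SignedWeights, p: DiscreteOpinion, epsilon: float) -> np.ndarray:
    """Project pooled weights onto the prior opinion (unnormalized output)."""
    if pi.k != p.k:
        raise DimensionMismatchError("pooled weights and opinion have different lengths")
    return projection_weights(pi.values, p.weights, epsilon)


def _finalize(raw: np.ndarray, total_mass: float, cause: str) -> DiscreteOpinion:
    s = raw.sum()
    if not (s > 0):
        raise DegenerateRevisionError(
            f"all pooled-projected weights are zero ({cause}); the rule has no output"
        )
    return DiscreteOpinion(raw * (total_mass / s), total_mass)


def revise(p: DiscreteOpinion, q: DiscreteOpinion, params: RevisionParams) -> DiscreteOpinion:
    """Revise opinion ``p`` under persuading opinion ``q``.

    Implements the confirmation-biased rule: pool then project (default),
    project then pool (``project_then_average``), or the signed-measure
    continuation for ``epsilon > 1`` (``boomerang``).  The output is
    renormalized exactly to the common total mass.

    Raises
    ------
    DegenerateRevisionError
        If every projected weight vanishes, e.g. disjoint supports combined
        with ``epsilon = 0`` (the fully credulous agent has nothing left to
        accept).
    """
    _check_compatible(p, q)
    eps = params.epsilon
    if params.variant == PROJECT_THEN_AVERAGE:
        return _revise_project_then_average(p, q, eps)
    if eps == 0.0:
        # Discontinuous limit: the credulous agent adopts q outright when all
        # his probabilities are positive; a zero entry of p facing q-mass
        # there makes the limit ill-defined.
        if np.any((p.weights == 0) & (q.weights > 0)):
            raise DegenerateRevisionError(
                "epsilon=0 with p_k=0 at an event where q_k>0: the credulous "
                "limit conflicts with the zero-preservation axiom"
            )
        return DiscreteOpinion(q.weights.copy(), q.total_mass)
    pooled = pool(p, q, params)
    raw = project(pooled, p, eps)
    return _finalize(raw, p.total_mass, f"epsilon={eps}, variant={params.variant}")


def _revise_project_then_average(
    p: DiscreteOpinion, q: DiscreteOpinion, eps: float
) -> DiscreteOpinion:
    # project q onto p first, renormalize to the common mass, then pool
    if eps == 0.0:
        if np.any((p.weights == 0) & (q.weights > 0)):
            raise DegenerateRevisionError(
                "epsilon=0 with p_k=0 at an event where q_k>0 (reverse-order variant)"
            )
        return DiscreteOpinion(q.weights.copy(), q.total_mass)
    proj = projection_weights(q.weights, p.weights, eps)
    s = proj.sum()
    if s > 0:
        proj = proj * (p.total_mass / s)
        raw = eps * p.weights + (1.0 - eps) * proj
    else:
        # disjoint supports: nothing of q survives projection, keep p
        raw = p.weights.copy()
    return _finalize(raw, p.total_mass, f"epsilon={eps}, variant={PROJECT_THEN_AVERAGE}")


def revise_sequence(
    p: DiscreteOpinion,
    persuaders: Sequence[DiscreteOpinion],
    params: RevisionParams,
) -> DiscreteOpinion:
    """Left-fold of :func:`revise` over an ordered list of persuaders."""
    current = p
    for q in persuaders:
        current = revise(current, q, params)
    return current
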