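"""Continuous opinion families on a 1-D grid, and social-judgment latitudes.

Opinions over a continuous quantity are probability densities discretized on
a uniform grid with trapezoid-rule quadrature.  Two parametric families are
provided: Gaussians (anchor ``mu``, dispersion ``sigma``) and compactly
supported bump densities ``C_b * exp(-b / (1 - x**2))`` on (-1, 1), which are
infinitely differentiable yet strictly zero outside a finite support.

A Gaussian opinion carries the three social-judgment zones: the latitude of
*acceptance* (within 2 sigma of the anchor), *non-commitment* (the 2-3 sigma
shell) and *rejection* (beyond 3 sigma), holding respectively 95.4%, 4.3%
and 0.3% of the probability mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import integrate, stats

from .core import (
    DegenerateRevisionError,
    DimensionMismatchError,
    OpinionValidationError,
    RevisionParams,
    BOOMERANG,
    PROJECT_THEN_AVERAGE,
    projection_weights,
)

__all__ = [
    "Grid",
    "GridOpinion",
    "GaussianParams",
    "BumpParams",
    "Latitudes",
    "gaussian_density",
    "gaussian_latitude_masses",
    "bump_density",
    "revise_density",
    "latitudes",
    "latitude_masses",
]

logger = logging.getLogger(__name__)

DENSITY_NORM_TOL = 1e-6


@dataclass(frozen=True)
class Grid:
    """Uniform 1-D grid, endpoints inclusive."""

    x_lo: float
    x_hi: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.x_lo < self.x_hi:
            raise OpinionValidationError("grid needs x_lo < x_hi")
        if self.n_points < 2:
            raise OpinionValidationError("grid needs at least 2 points")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.x_lo, self.x_hi, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.x_hi - self.x_lo) / (self.n_points - 1)


@dataclass(frozen=True)
class GridOpinion:
    """Nonnegative density values on a grid, trapezoid-normalized to 1."""

    grid: Grid
    density: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "density", arr)
        arr.setflags(write=False)
        if arr.shape != (self.grid.n_points,):
            raise DimensionMismatchError("density length must match grid size")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise OpinionValidationError("density values must be finite and nonnegative")
        integral = np.trapezoid(arr, dx=self.grid.spacing)
        if abs(integral - 1.0) > DENSITY_NORM_TOL:
            raise OpinionValidationError(
                f"density integrates to {integral!r}, expected 1 within {DENSITY_NORM_TOL}"
            )

    @classmethod
    def from_unnormalized(cls, grid: Grid, values: np.ndarray) -> "GridOpinion":
        values = np.asarray(values, dtype=float)
        z = np.trapezoid(values, dx=grid.spacing)
        if not z > 0:
            raise DegenerateRevisionError("cannot normalize an all-zero density")
        return cls(grid, values / z)

    @property
    def x(self) -> np.ndarray:
        return self.grid.points

    def mean(self) -> float:
        return float(np.trapezoid(self.x * self.density, dx=self.grid.spacing))

    def std(self) -> float:
        m = self.mean()
        var = np.trapezoid((self.x - m) ** 2 * self.density, dx=self.grid.spacing)
        return float(np.sqrt(max(var, 0.0)))

    def bin_masses(self) -> np.ndarray:
        """Per-point trapezoid quadrature weights times density (sums to ~1).

        This is the natural discrete opinion induced by the grid opinion.
        """
        w = np.full(self.grid.n_points, self.grid.spacing)
        w[0] = w[-1] = self.grid.spacing / 2.0
        return w * self.density

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridOpinion):
            return NotImplemented
        return self.grid == other.grid and np.array_equal(self.density, other.density)


@dataclass(frozen=True)
class GaussianParams:
    """Gaussian opinion: anchor ``mu`` and dispersion ``sigma > 0``."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise OpinionValidationError("sigma must be positive")


@dataclass(frozen=True)
class BumpParams:
    """Bump opinion ``C_b exp(-b/(1-x^2))`` on (-1, 1); sharpness ``b > 0``.

    Large ``b`` concentrates the density into a Gaussian-like peak at 0;
    small ``b`` approaches the uniform density on the support.  The
    normalization constant has no elementary closed form and is computed by
    adaptive quadrature.
    """

    b: float

    def __post_init__(self) -> None:
        if not (self.b > 0 and np.isfinite(self.b)):
            raise OpinionValidationError("bump sharpness b must be positive")

    @property
    def norm_constant(self) -> float:
        val, _ = integrate.quad(lambda x: np.exp(-self.b / (1.0 - x * x)), -1.0, 1.0)
        return 1.0 / val


@dataclass(frozen=True)
class Latitudes:
    """Social-judgment zones of a Gaussian opinion.

    ``acceptance`` is the interval [mu-2s, mu+2s]; ``non_commitment`` the two
    shells between 2 and 3 sigma; ``rejection`` the two half-lines beyond
    3 sigma.  Together they partition the real line.
    """

    acceptance: Tuple[float, float]
    non_commitment: Tuple[Tuple[float, float], Tuple[float, float]]
    rejection: Tuple[float, float]  # rejection is |x| beyond these two bounds


def latitudes(params: GaussianParams) -> Latitudes:
    """The 2-sigma / 3-sigma latitude partition around the anchor."""
    mu, s = params.mu, params.sigma
    return Latitudes(
        acceptance=(mu - 2 * s, mu + 2 * s),
        non_commitment=((mu - 3 * s, mu - 2 * s), (mu + 2 * s, mu + 3 * s)),
        rejection=(mu - 3 * s, mu + 3 * s),
    )


def gaussian_latitude_masses(params: GaussianParams) -> Tuple[float, float, float]:
    """Exact (analytic) masses of the three zones of a Gaussian opinion.

    Independent of ``mu`` and ``sigma``: (0.9545, 0.0428, 0.0027).
    """
    acc = stats.norm.cdf(2.0) - stats.norm.cdf(-2.0)
    rej = 2.0 * stats.norm.cdf(-3.0)
    return float(acc), float(1.0 - acc - rej), float(rej)


def gaussian_density(params: GaussianParams, grid: Grid) -> GridOpinion:
    """Gaussian opinion discretized and renormalized on the grid.

    Logs a warning when the grid does not span ``mu +/- 5 sigma`` (the
    discretized density then visibly truncates the tails).
    """
    if grid.x_lo > params.mu - 5 * params.sigma or grid.x_hi < params.mu + 5 * params.sigma:
        logger.warning(
            "grid [%g, %g] does not span mu +/- 5 sigma = [%g, %g]; tails are truncated",
            grid.x_lo, grid.x_hi,
            params.mu - 5 * params.sigma, params.mu + 5 * params.sigma,
        )
    values = stats.norm.pdf(grid.points, loc=params.mu, scale=params.sigma)
    return GridOpinion.from_unnormalized(grid, values)


def bump_values(b: float, x: np.ndarray) -> np.ndarray:
    """Unnormalized bump values, exactly zero at and beyond |x| = 1."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    inside = np.abs(x) < 1.0
    out[inside] = np.exp(-b / (1.0 - x[inside] ** 2))
    return out


def bump_density(params: BumpParams, grid: Grid) -> GridOpinion:
    """Bump opinion on (-1, 1) discretized on the grid."""
    if grid.x_lo > -1.0 or grid.x_hi < 1.0:
        raise OpinionValidationError("grid must cover the bump support [-1, 1]")
    return GridOpinion.from_unnormalized(grid, bump_values(params.b, grid.points))


def revise_density(p: GridOpinion, q: GridOpinion, params: RevisionParams) -> GridOpinion:
    """Density form of the revision rule: pointwise weights + renormalization.

    Applies the same two-step rule as the discrete operator to density
    values and renormalizes by trapezoid quadrature.  Agrees with the
    discrete rule on induced bin masses up to O(grid spacing).
    """
    if p.grid != q.grid:
        raise DimensionMismatchError("grid opinions must share the same grid")
    eps = params.epsilon
    if params.variant == PROJECT_THEN_AVERAGE:
        if eps == 0.0:
            return _credulous_density(p, q)
        proj = projection_weights(q.density, p.density, eps)
        z = np.trapezoid(proj, dx=p.grid.spacing)
        raw = eps * p.density + (1.0 - eps) * (proj / z if z > 0 else 0.0)
        return GridOpinion.from_unnormalized(p.grid, raw)
    if eps == 0.0:
        return _credulous_density(p, q)
    pooled = eps * p.density + (1.0 - eps) * q.density
    if params.variant != BOOMERANG:
        pooled = np.maximum(pooled, 0.0)
    raw = projection_weights(pooled, p.density, eps)
    return GridOpinion.from_unnormalized(p.grid, raw)


def _credulous_density(p: GridOpinion, q: GridOpinion) -> GridOpinion:
    if np.any((p.density == 0) & (q.density > 0)):
        raise DegenerateRevisionError(
            "epsilon=0 with p(x)=0 where q(x)>0: credulous limit undefined"
        )
    return GridOpinion(p.grid, q.density.copy())


def latitude_masses(op: GridOpinion, lat: Latitudes) -> Tuple[float, float, float]:
    """Quadrature masses of (acceptance, non-commitment, rejection) zones.

    The grid must cover both rejection boundaries; the three masses sum to
    the total quadrature mass of the opinion (1 up to normalization
    tolerance).
    """
    lo3, hi3 = lat.rejection
    if op.grid.x_lo > lo3 or op.grid.x_hi < hi3:
        raise OpinionValidationError(
            "grid too narrow: it must cover the 3-sigma rejection boundaries"
        )
    x = op.x
    cdf = integrate.cumulative_trapezoid(op.density, x, initial=0.0)
    total = cdf[-1]

    def mass_between(a: float, b: float) -> float:
        return float(np.interp(b, x, cdf) - np.interp(a, x, cdf))

    lo2, hi2 = lat.acceptance
    acc = mass_between(lo2, hi2)
    noncom = mass_between(lo3, lo2) + mass_between(hi2, hi3)
    rej = total - acc - noncom
    return acc, noncom, max(rej, 0.0)
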