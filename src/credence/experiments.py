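"""Drivers for the model's characteristic phenomena.

Each driver wires the revision operator into one experimental setup from the
persuasion literature: the weighted-average (small-discrepancy) limit, the
change-versus-discrepancy relation with its inverted-U shape and abrupt
anchor jump, order-of-presentation (recency/primacy), cognitive dissonance
(bimodal revised opinions), persuasion by a fully certain source, and the
boomerang regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import (
    AVERAGE_THEN_PROJECT,
    BOOMERANG,
    DiscreteOpinion,
    OpinionValidationError,
    RevisionParams,
    revise,
)
from .densities import GaussianParams, Grid, GridOpinion, gaussian_density, revise_density
from .metrics import hellinger, hellinger_gaussian, total_variation

__all__ = [
    "AnchorSet",
    "BoomerangReport",
    "DissonanceOutcome",
    "OrderResult",
    "SweepResult",
    "WAPrediction",
    "boomerang_revision_report",
    "certain_persuader_revision",
    "default_grid",
    "discrepancy_sweep",
    "dissonance_scenario",
    "find_anchors",
    "locate_primacy_crossover",
    "monotone_discrepancy_check",
    "order_experiment",
    "params_for",
    "weighted_average_prediction",
]

SYMMETRY_TOL = 1e-9


def params_for(epsilon: float) -> RevisionParams:
    """Default rule for a given epsilon: boomerang variant iff epsilon > 1."""
    return RevisionParams(epsilon, BOOMERANG if epsilon > 1 else AVERAGE_THEN_PROJECT)


def default_grid(
    gaussians: Sequence[GaussianParams], n_points: int = 2001, pad: float = 6.0
) -> Grid:
    """Grid spanning every anchor +/- ``pad`` dispersions."""
    lo = min(g.mu - pad * g.sigma for g in gaussians)
    hi = max(g.mu + pad * g.sigma for g in gaussians)
    return Grid(lo, hi, n_points)


# ---------------------------------------------------------------------------
# anchors


@dataclass(frozen=True)
class AnchorSet:
    """Local maxima of an opinion density, sorted by height descending."""

    anchors: Tuple[Tuple[float, float], ...]  # (location, height)

    @property
    def dominant(self) -> Tuple[float, float]:
        return self.anchors[0]

    def __len__(self) -> int:
        return len(self.anchors)


def _refine_peak(x: np.ndarray, d: np.ndarray, i: int) -> Tuple[float, float]:
    """Sub-grid peak location/height via local quadratic interpolation."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(d[i])
    y0, y1, y2 = d[i - 1], d[i], d[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # flat or not concave; keep the grid point
        return float(x[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    h = y1 - 0.25 * (y0 - y2) * delta
    return float(x[i] + delta * (x[1] - x[0])), float(h)


def find_anchors(op: GridOpinion, min_height_frac: float = 0.01) -> AnchorSet:
    """Strict interior local maxima with height >= frac * global max.

    Plateau runs (consecutive equal values higher than both neighbours) are
    collapsed to their midpoint.  Peak locations are refined by local
    quadratic interpolation for sub-grid resolution.
    """
    x, d = op.x, op.density
    n = len(d)
    peaks: List[Tuple[float, float]] = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and d[j + 1] == d[j]:
            j += 1
        # run [i, j] of equal values; strict local max if both sides lower
        if d[i - 1] < d[i] and (j + 1 < n and d[j + 1] < d[j]):
            if i == j:
                peaks.append(_refine_peak(x, d, i))
            else:
                mid = (i + j) // 2
                peaks.append((float((x[i] + x[j]) / 2.0), float(d[mid])))
            i = j + 1
        else:
            i = j + 1 if j > i else i + 1
    if not peaks:  # monotone or edge-peaked density: fall back to argmax
        k = int(np.argmax(d))
        peaks = [(float(x[k]), float(d[k]))]
    top = max(h for _, h in peaks)
    kept = [(loc, h) for loc, h in peaks if h >= min_height_frac * top]
    kept.sort(key=lambda t: -t[1])
    return AnchorSet(tuple(kept))


# ---------------------------------------------------------------------------
# weighted-average limit


@dataclass(frozen=True)
class WAPrediction:
    """First-order (small-discrepancy) prediction of the full rule.

    The revised anchor is the weighted average ``w_self*mu_p + w_other*mu_q``
    with weights that depend on the two confidences and on epsilon; the
    dispersion changes by a first-order factor whose sign follows
    ``sigma_q - sigma_p``.  In the boomerang regime ``w_other`` is negative
    (the anchor shifts away) and the dispersion inequality reverses.
    """

    predicted_anchor: float
    weight_self: float
    weight_other: float
    predicted_dispersion_ratio: float


def _wa_weight_other(sp: float, sq: float, eps: float) -> float:
    if eps <= 1.0:
        num = (1.0 - eps) ** 2 * sp**3
        den = eps * sq**3 + eps * (1.0 - eps) * sp * sq**2 + (1.0 - eps) ** 2 * sp**3
        return num / den
    num = -((eps - 1.0) ** 2) * sp**3
    den = eps * sq**3 - (2.0 - eps) * (eps - 1.0) * sp * sq**2 - (eps - 1.0) ** 2 * sp**3
    return num / den


def weighted_average_prediction(
    p: GaussianParams, q: GaussianParams, epsilon: float
) -> WAPrediction:
    """Anchor shift and dispersion change to first order in the discrepancy.

    Valid in the small-discrepancy regime (caller's responsibility); the
    relative error of the predicted shift against the full rule vanishes
    linearly as ``mu_q - mu_p -> 0``.
    """
    w_other = _wa_weight_other(p.sigma, q.sigma, epsilon)
    sgn = 1.0 if epsilon <= 1.0 else -1.0
    ratio = 1.0 + sgn * (1.0 - epsilon) ** 2 * (q.sigma - p.sigma) / p.sigma
    return WAPrediction(
        predicted_anchor=p.mu + w_other * (q.mu - p.mu),
        weight_self=1.0 - w_other,
        weight_other=w_other,
        predicted_dispersion_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# change vs discrepancy


@dataclass(frozen=True)
class SweepResult:
    """Change-discrepancy sweep: table of (m, h, h_tv, anchor_shift)."""

    table: pd.DataFrame
    m_star: float
    m_star_tv: float
    anchor_jump: bool
    jump_m: Optional[float]


def discrepancy_sweep(
    sigma_p: float,
    sigma_q: float,
    epsilon: float,
    m_grid: Sequence[float],
    n_points: int = 2001,
    jump_factor: float = 5.0,
) -> SweepResult:
    """Sweep the anchor discrepancy ``m`` and record the opinion change.

    For each ``m`` the prior is Gaussian(0, sigma_p), the persuader
    Gaussian(m, sigma_q); the change is the Hellinger (and TV) distance
    between the prior and revised opinion, plus the shift of the dominant
    anchor.  ``m_star`` is the discrepancy of maximal Hellinger change.  An
    abrupt anchor jump is flagged when an adjacent-m change in anchor shift
    exceeds ``jump_factor`` times the local secant slope.
    """
    m_grid = np.asarray(list(m_grid), dtype=float)
    if m_grid.size < 10:
        raise OpinionValidationError("m_grid needs at least 10 points")
    if np.any(np.diff(m_grid) <= 0):
        raise OpinionValidationError("m_grid must be strictly increasing")
    params = params_for(epsilon)
    gp = GaussianParams(0.0, sigma_p)
    grid = default_grid(
        [gp, GaussianParams(float(m_grid.max()), sigma_q)], n_points=n_points
    )
    p = gaussian_density(gp, grid)
    rows = []
    for m in m_grid:
        q = gaussian_density(GaussianParams(float(m), sigma_q), grid)
        pt = revise_density(p, q, params)
        shift = find_anchors(pt).dominant[0]
        rows.append((m, hellinger(p, pt), total_variation(p, pt), shift))
    table = pd.DataFrame(rows, columns=["m", "h", "h_tv", "anchor_shift"])
    m_star = float(table.m[table.h.idxmax()])
    m_star_tv = float(table.m[table.h_tv.idxmax()])
    jump_m = _detect_anchor_jump(table, jump_factor, grid.spacing)
    return SweepResult(table, m_star, m_star_tv, jump_m is not None, jump_m)


def _detect_anchor_jump(
    table: pd.DataFrame, factor: float, dx: float
) -> Optional[float]:
    a = table.anchor_shift.to_numpy()
    m = table.m.to_numpy()
    steps = np.abs(np.diff(a))
    for i in range(1, len(steps)):
        local = max(steps[i - 1], 2.0 * dx)
        if steps[i] > factor * local:
            return float(m[i + 1])
    return None


def monotone_discrepancy_check(
    sigma_p: float,
    epsilon: float,
    sigma_q_grid: Sequence[float],
    n_points: int = 2001,
) -> pd.DataFrame:
    """Equal-anchor sweep: discrepancy driven by sigma_q alone.

    Returns a table (sigma_q, discrepancy_h, change_h, change_tv); with
    identical anchors the change is monotone in the discrepancy.
    """
    params = params_for(epsilon)
    gp = GaussianParams(0.0, sigma_p)
    sq_arr = np.asarray(list(sigma_q_grid), dtype=float)
    grid = default_grid([GaussianParams(0.0, max(sigma_p, sq_arr.max()))], n_points=n_points)
    p = gaussian_density(gp, grid)
    rows = []
    for sq in sq_arr:
        gq = GaussianParams(0.0, float(sq))
        q = gaussian_density(gq, grid)
        pt = revise_density(p, q, params)
        rows.append(
            (sq, hellinger_gaussian(gp, gq), hellinger(p, pt), total_variation(p, pt))
        )
    return pd.DataFrame(rows, columns=["sigma_q", "discrepancy_h", "change_h", "change_tv"])


# ---------------------------------------------------------------------------
# order of presentation


@dataclass(frozen=True)
class OrderResult:
    """Outcome of presenting two symmetric persuaders in both orders."""

    final_forward: Union[DiscreteOpinion, GridOpinion]
    final_reverse: Union[DiscreteOpinion, GridOpinion]
    d_to_first: float
    d_to_last: float
    verdict: str  # "recency" | "primacy" | "tie"


def _verdict(d_first: float, d_last: float, tol: float = 1e-12) -> str:
    if d_last < d_first - tol:
        return "recency"
    if d_first < d_last - tol:
        return "primacy"
    return "tie"


def order_experiment(
    p: Union[GaussianParams, DiscreteOpinion],
    q_pair: Union[Tuple[GaussianParams, GaussianParams], Tuple[DiscreteOpinion, DiscreteOpinion]],
    epsilon: float,
    n_points: int = 2001,
) -> OrderResult:
    """Present two persuaders, symmetric about the prior, in both orders.

    For Gaussian inputs the persuaders must mirror each other about the
    prior's anchor with equal dispersions; for discrete inputs the prior
    must be palindromic and the second persuader the reversal of the first.
    Both interactions use the same ``epsilon``.  The verdict compares the
    Hellinger distances from the forward-order final opinion to the first
    and last presented persuaders; outside the boomerang regime the verdict
    is always recency.
    """
    params = params_for(epsilon)
    q, qp = q_pair
    if isinstance(p, GaussianParams):
        if not (
            isinstance(q, GaussianParams)
            and isinstance(qp, GaussianParams)
            and abs((q.mu - p.mu) + (qp.mu - p.mu)) <= SYMMETRY_TOL
            and abs(q.sigma - qp.sigma) <= SYMMETRY_TOL
        ):
            raise OpinionValidationError(
                "persuaders must be symmetric about the prior anchor with equal dispersions"
            )
        grid = default_grid([p, q, qp], n_points=n_points)
        pg = gaussian_density(p, grid)
        qg = gaussian_density(q, grid)
        qpg = gaussian_density(qp, grid)
        fwd = revise_density(revise_density(pg, qg, params), qpg, params)
        rev = revise_density(revise_density(pg, qpg, params), qg, params)
        d_first, d_last = hellinger(fwd, qg), hellinger(fwd, qpg)
    else:
        if not (
            isinstance(q, DiscreteOpinion)
            and isinstance(qp, DiscreteOpinion)
            and np.allclose(p.weights, p.weights[::-1], rtol=0, atol=SYMMETRY_TOL)
            and np.allclose(q.weights[::-1], qp.weights, rtol=0, atol=SYMMETRY_TOL)
        ):
            raise OpinionValidationError(
                "discrete setup needs a palindromic prior and mirrored persuaders"
            )
        fwd = revise(revise(p, q, params), qp, params)
        rev = revise(revise(p, qp, params), q, params)
        d_first, d_last = hellinger(fwd, q), hellinger(fwd, qp)
    return OrderResult(fwd, rev, d_first, d_last, _verdict(d_first, d_last))


def locate_primacy_crossover(
    p: Union[GaussianParams, DiscreteOpinion],
    q_pair,
    lo: float = 1.05,
    hi: float = 3.0,
    tol: float = 1e-3,
    n_points: int = 2001,
) -> float:
    """Bisect for the epsilon where recency flips to primacy (boomerang regime).

    Outside the boomerang regime the rule always yields recency; deep inside
    it the first persuader dominates.  Requires ``gap(lo) > 0 > gap(hi)``
    where ``gap = d_to_first - d_to_last``; the crossover is deterministic
    (no RNG), so the located value is reproducible bit-for-bit.
    """

    def gap(eps: float) -> float:
        res = order_experiment(p, q_pair, eps, n_points=n_points)
        return res.d_to_first - res.d_to_last

    g_lo, g_hi = gap(lo), gap(hi)
    if not (g_lo > 0 > g_hi):
        raise OpinionValidationError(
            f"no recency->primacy crossover bracketed in [{lo}, {hi}]"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# cognitive dissonance


@dataclass(frozen=True)
class DissonanceOutcome:
    anchors: AnchorSet
    classification: str  # single-peak | dissonant | dominated-new | dominated-old


def dissonance_scenario(
    p: GaussianParams,
    q: GaussianParams,
    epsilon: float,
    n_points: int = 2001,
    comparability_band: float = 3.0,
    min_height_frac: float = 0.02,
) -> DissonanceOutcome:
    """Classify the revised opinion's peak structure.

    A narrow, credible persuader centered moderately far from the prior
    anchor splits the revised opinion into two peaks; when their heights are
    within ``comparability_band`` of each other the state is *dissonant*
    (the agent holds two comparably probable, widely separated anchors).
    Raising epsilon suppresses the new peak, lowering it makes the new peak
    dominant, and a narrower prior resists splitting.
    """
    params = params_for(epsilon)
    grid = default_grid([p, q], n_points=n_points)
    pt = revise_density(gaussian_density(p, grid), gaussian_density(q, grid), params)
    anchors = find_anchors(pt, min_height_frac=min_height_frac)
    if len(anchors) == 1:
        loc = anchors.dominant[0]
        cls = "single-peak" if abs(loc - p.mu) <= abs(loc - q.mu) else "dominated-new"
    else:
        (l1, h1), (l2, h2) = anchors.anchors[0], anchors.anchors[1]
        if h1 <= comparability_band * h2:
            cls = "dissonant"
        else:
            cls = "dominated-new" if abs(l1 - q.mu) < abs(l1 - p.mu) else "dominated-old"
    return DissonanceOutcome(anchors, cls)


# ---------------------------------------------------------------------------
# certain persuader


def certain_persuader_revision(
    p: DiscreteOpinion, l: int, epsilon: float
) -> DiscreteOpinion:
    """Revision under a persuader fully certain of event ``l``.

    The persuading opinion is the point mass on ``l``.  Even a small (but
    positive) prior ``p_l`` can become a local or global maximum of the
    revised opinion when epsilon is not close to 1; a strictly zero ``p_l``
    is immune (the zero-preservation axiom keeps the opinion unchanged).
    """
    if not 0.0 < epsilon < 1.0:
        raise OpinionValidationError("certain-persuader analysis needs 0 < epsilon < 1")
    if not 0 <= l < p.k:
        raise OpinionValidationError(f"event index {l} out of range for K={p.k}")
    w = np.zeros(p.k)
    w[l] = p.total_mass
    q = DiscreteOpinion(w, p.total_mass)
    return revise(p, q, RevisionParams(epsilon))


# ---------------------------------------------------------------------------
# boomerang


@dataclass(frozen=True)
class BoomerangReport:
    """Diagnostics of a single boomerang revision of Gaussian opinions."""

    anchor_displacement: float  # dominant anchor minus mu_p
    moves_away: bool  # displacement directed away from the persuader
    peak_height_ratio: float  # revised dominant peak height / prior peak height
    width_ratio: float  # revised dominant FWHM / prior FWHM
    x0: Optional[float]  # near-zero local minimum (signed-measure crossing)
    min_depth_frac: Optional[float]  # its value / dominant peak height
    n_peaks: int
    revised: GridOpinion


def _fwhm(x: np.ndarray, d: np.ndarray, peak_idx: int) -> float:
    half = d[peak_idx] / 2.0
    i = peak_idx
    while i > 0 and d[i] > half:
        i -= 1
    left = np.interp(half, [d[i], d[i + 1]], [x[i], x[i + 1]]) if d[i] <= half else x[0]
    j = peak_idx
    while j < len(d) - 1 and d[j] > half:
        j += 1
    right = (
        np.interp(half, [d[j], d[j - 1]], [x[j], x[j - 1]]) if d[j] <= half else x[-1]
    )
    return float(right - left)


def boomerang_revision_report(
    p: GaussianParams,
    q: GaussianParams,
    epsilon: float,
    n_points: int = 4001,
) -> BoomerangReport:
    """Single revision with ``epsilon > 1`` and its signature diagnostics.

    The dominant anchor displaces away from the persuader's anchor and its
    peak is enhanced and narrowed; the revised density has a deep local
    minimum near the zero crossing of the signed pooled measure.
    """
    if epsilon <= 1.0:
        raise OpinionValidationError("boomerang analysis requires epsilon > 1")
    grid = default_grid([p, q], n_points=n_points)
    pg = gaussian_density(p, grid)
    qg = gaussian_density(q, grid)
    pt = revise_density(pg, qg, RevisionParams(epsilon, BOOMERANG))
    anchors = find_anchors(pt, min_height_frac=0.001)
    a_loc, a_height = anchors.dominant
    displacement = a_loc - p.mu
    towards = np.sign(q.mu - p.mu)
    moves_away = bool(displacement * towards < 0) if towards != 0 else bool(displacement == 0)

    x, d = pt.x, pt.density
    peak_idx = int(np.argmin(np.abs(x - a_loc)))
    width_ratio = _fwhm(x, d, peak_idx) / _fwhm(pg.x, pg.density, int(np.argmax(pg.density)))

    # deepest interior local minimum = the signed-measure crossing point
    interior = (d[1:-1] < d[:-2]) & (d[1:-1] < d[2:])
    x0 = None
    depth = None
    if np.any(interior):
        idxs = np.where(interior)[0] + 1
        kmin = idxs[np.argmin(d[idxs])]
        x0 = float(x[kmin])
        depth = float(d[kmin] / a_height)
    return BoomerangReport(
        anchor_displacement=float(displacement),
        moves_away=moves_away,
        peak_height_ratio=float(a_height / pg.density.max()),
        width_ratio=float(width_ratio),
        x0=x0,
        min_depth_frac=depth,
        n_peaks=len(anchors),
        revised=pt,
    )
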