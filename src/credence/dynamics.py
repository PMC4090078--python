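"""Repeated persuasion dynamics and convergence diagnostics.

When the agent is exposed to the same persuading opinion ``q`` over and over,
the revised opinion sequence ``p_{t+1} = revise(p_t, q)`` has a single fixed
point at ``q`` (for ``0 < eps < 1`` and strictly positive ``q``), and every
f-divergence ``D_f(p_t || q)`` is a Lyapunov function: it decreases strictly
until the fixed point is reached.  Convergence also respects the Le Chatelier
principle: the most overestimated event (largest ``p_k/q_k``) decays
monotonically in time and the most underestimated one rises monotonically
(mildly misestimated events may transiently overshoot under
renormalization).  The *law of diminishing returns*
does not hold, however: the largest single-step opinion change need not be
the first one.

In the boomerang regime (``eps > 1``) the iteration does not approach ``q``;
instead the opinion splits into a bimodal shape whose smaller peak migrates
toward the persuader's anchor while the dominant peak sharpens and drifts
away, eventually becoming stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np

from .core import BOOMERANG, DiscreteOpinion, RevisionParams, revise
from .densities import GridOpinion, revise_density
from .metrics import F_HELLINGER, F_KL, F_TV, f_divergence, hellinger, total_variation

__all__ = [
    "DEFAULT_F_CHOICES",
    "DiagnosticsReport",
    "Trajectory",
    "diagnostics",
    "iterate",
    "iterate_boomerang",
]

Opinion = Union[DiscreteOpinion, GridOpinion]

#: Named convex functions whose f-divergences certify convergence.
DEFAULT_F_CHOICES: Dict[str, Callable] = {
    "hellinger": F_HELLINGER,
    "total_variation": F_TV,
    "kl": F_KL,
}

# Tolerance absorbing floating noise in monotonicity assertions.
MONOTONE_TOL = 1e-12


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed opinions under repeated persuasion by a fixed ``q``."""

    opinions: List[Opinion]
    persuader: Opinion
    params: RevisionParams

    def __len__(self) -> int:
        return len(self.opinions)

    @property
    def initial(self) -> Opinion:
        return self.opinions[0]

    @property
    def final(self) -> Opinion:
        return self.opinions[-1]

    def distances_to_persuader(self) -> np.ndarray:
        return np.array([hellinger(p, self.persuader) for p in self.opinions])

    def step_distances(self) -> np.ndarray:
        """Hellinger distance between consecutive opinions (length T)."""
        return np.array(
            [hellinger(a, b) for a, b in zip(self.opinions, self.opinions[1:])]
        )


def _step(p: Opinion, q: Opinion, params: RevisionParams) -> Opinion:
    if isinstance(p, GridOpinion):
        return revise_density(p, q, params)
    return revise(p, q, params)


def iterate(
    p0: Opinion,
    q: Opinion,
    params: RevisionParams,
    max_steps: int = 10_000,
    tol: float = 1e-8,
) -> Trajectory:
    """Iterate the revision rule with a fixed persuader.

    Stops when ``hellinger(p_t, q) < tol`` or after ``max_steps``.  The
    global-convergence guarantee needs ``0 < eps < 1`` and ``q`` strictly
    positive everywhere; outside that regime the trajectory is still
    recorded faithfully.
    """
    opinions: List[Opinion] = [p0]
    current = p0
    for _ in range(max_steps):
        if hellinger(current, q) < tol:
            break
        current = _step(current, q, params)
        opinions.append(current)
    return Trajectory(opinions, q, params)


def iterate_boomerang(
    p0: GridOpinion,
    q: GridOpinion,
    epsilon: float,
    steps: int = 50,
    tol: float = 0.0,
) -> Trajectory:
    """Repeated persuasion in the boomerang regime (``epsilon > 1``).

    Runs for ``steps`` iterations, stopping early once consecutive opinions
    are stationary (``hellinger(p_t, p_{t-1}) < tol`` with ``tol > 0``).
    The trajectory typically develops a second peak that migrates toward the
    persuader's anchor while the dominant peak narrows and drifts away.
    """
    params = RevisionParams(epsilon, BOOMERANG)
    opinions: List[Opinion] = [p0]
    current = p0
    for _ in range(steps):
        nxt = revise_density(current, q, params)
        opinions.append(nxt)
        if tol > 0 and hellinger(nxt, current) < tol:
            break
        current = nxt
    return Trajectory(opinions, q, params)


@dataclass(frozen=True)
class DiagnosticsReport:
    """Convergence diagnostics of a repeated-persuasion trajectory."""

    lyapunov_series: Dict[str, np.ndarray]
    step_hellinger: np.ndarray
    step_total_variation: np.ndarray
    converged: bool
    iterations_to_tol: Optional[int]
    le_chatelier_violations: int

    def lyapunov_nonincreasing(self, tol: float = MONOTONE_TOL) -> bool:
        return all(
            bool(np.all(np.diff(series) <= tol))
            for series in self.lyapunov_series.values()
            if np.all(np.isfinite(series))
        )


def diagnostics(
    traj: Trajectory,
    f_choices: Optional[Dict[str, Callable]] = None,
    tol: float = 1e-8,
) -> DiagnosticsReport:
    """Lyapunov series, step distances and Le Chatelier violation count.

    For each convex ``f`` the series ``L_t = D_f(p_t || q)`` is reported;
    with ``0 < eps < 1`` and a strictly positive persuader every series is
    non-increasing, strictly until the fixed point.  The Le Chatelier
    property is tracked through the envelope ratios: the probability of the
    most overestimated event (largest ``p_{t,k}/q_k``) must decay
    monotonically in time and the most underestimated one must rise; a
    violation is a step where either envelope moves the wrong way beyond a
    1e-12 tolerance.  (Mildly over/under-estimated events may transiently
    overshoot because of renormalization; the envelopes never do.)
    """
    if len(traj) < 2:
        raise ValueError("diagnostics needs a trajectory of length >= 2")
    f_choices = dict(f_choices or DEFAULT_F_CHOICES)
    q = traj.persuader
    lyap = {
        name: np.array([f_divergence(p, q, f) for p in traj.opinions])
        for name, f in f_choices.items()
    }
    d_to_q = traj.distances_to_persuader()
    converged = bool(d_to_q[-1] < tol)
    iters = int(np.argmax(d_to_q < tol)) if converged else None

    qv = _values(q)
    pos = qv > 0
    ratios = np.array([_values(p)[pos] / qv[pos] for p in traj.opinions])
    rmax = ratios.max(axis=1)
    rmin = ratios.min(axis=1)
    violations = int(np.sum(np.diff(rmax) > MONOTONE_TOL)) + int(
        np.sum(np.diff(rmin) < -MONOTONE_TOL)
    )

    return DiagnosticsReport(
        lyapunov_series=lyap,
        step_hellinger=traj.step_distances(),
        step_total_variation=np.array(
            [total_variation(a, b) for a, b in zip(traj.opinions, traj.opinions[1:])]
        ),
        converged=converged,
        iterations_to_tol=iters,
        le_chatelier_violations=violations,
    )


def _values(op: Opinion) -> np.ndarray:
    if isinstance(op, GridOpinion):
        return op.density
    return op.probabilities
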