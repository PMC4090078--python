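"""Deterministic scenario catalogue.

Every scenario used by the tests, the CLI and the documentation is defined
here as a fully deterministic parameter set (no RNG state).  Names follow
the figure archetypes of the persuasion phenomenology: opinion shift,
anchor reinforcement, bump-density revision, order of presentation,
cognitive dissonance, boomerang revision and boomerang iteration, plus the
worked binary example and the diminishing-returns witness found by a
deterministic grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, Optional, Tuple

import numpy as np

from .core import AVERAGE_THEN_PROJECT, BOOMERANG, DiscreteOpinion, RevisionParams
from .densities import BumpParams, GaussianParams, Grid, bump_density, gaussian_density

__all__ = ["ScenarioSpec", "SCENARIOS", "UnknownScenarioError", "make_scenario"]


class UnknownScenarioError(KeyError):
    """Requested scenario name is not in the catalogue."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Named, versioned, fully deterministic experiment setup."""

    name: str
    description: str
    epsilon: float
    variant: str = AVERAGE_THEN_PROJECT
    opinions: Dict[str, Dict[str, Any]] = field(default_factory=dict)
    grid: Optional[Tuple[float, float, int]] = None
    steps: int = 1

    @property
    def params(self) -> RevisionParams:
        return RevisionParams(self.epsilon, self.variant)

    def build(self) -> Dict[str, Any]:
        """Resolve the spec into live module inputs.

        Returns a dict with the constructed opinions (under their role
        names), ``params``, and ``grid`` when continuous.
        """
        out: Dict[str, Any] = {"params": self.params, "steps": self.steps}
        grid = Grid(*self.grid) if self.grid else None
        out["grid"] = grid
        for role, spec in self.opinions.items():
            family = spec["family"]
            if family == "discrete":
                out[role] = DiscreteOpinion(
                    np.asarray(spec["weights"], dtype=float),
                    spec.get("total_mass", 1.0),
                )
            elif family == "gaussian":
                gp = GaussianParams(spec["mu"], spec["sigma"])
                out[role + "_params"] = gp
                if grid is not None:
                    out[role] = gaussian_density(gp, grid)
            elif family == "bump":
                bp = BumpParams(spec["b"])
                out[role + "_params"] = bp
                if grid is not None:
                    out[role] = bump_density(bp, grid)
            else:
                raise ValueError(f"unknown opinion family {family!r}")
        return out


def _gauss(mu: float, sigma: float) -> Dict[str, Any]:
    return {"family": "gaussian", "mu": mu, "sigma": sigma}


SCENARIOS: Dict[str, ScenarioSpec] = {
    s.name: s
    for s in [
        ScenarioSpec(
            name="eq36_binary",
            description=(
                "Worked binary example: an ignorant prior (1/2, 1/2) meets two "
                "fully convinced, opposite persuaders in sequence at epsilon=1/2."
            ),
            epsilon=0.5,
            opinions={
                "p": {"family": "discrete", "weights": [0.5, 0.5]},
                "q_first": {"family": "discrete", "weights": [1.0, 0.0]},
                "q_second": {"family": "discrete", "weights": [0.0, 1.0]},
            },
        ),
        ScenarioSpec(
            name="fig1_shift",
            description="Gaussian prior pulled toward an overlapping persuader.",
            epsilon=0.5,
            opinions={"p": _gauss(0.0, 1.0), "q": _gauss(1.5, 1.0)},
            grid=(-8.0, 9.5, 100),
        ),
        ScenarioSpec(
            name="fig1_reinforce",
            description="Sharper persuader at the same anchor reinforces the peak.",
            epsilon=0.5,
            opinions={"p": _gauss(0.0, 1.0), "q": _gauss(0.0, 0.5)},
            grid=(-8.0, 8.0, 100),
        ),
        ScenarioSpec(
            name="fig2_bump",
            description="Bump-density revision: broad prior (b=1) vs sharp persuader (b=10).",
            epsilon=0.5,
            opinions={
                "p": {"family": "bump", "b": 1.0},
                "q": {"family": "bump", "b": 10.0},
            },
            grid=(-1.0, 1.0, 401),
        ),
        ScenarioSpec(
            name="fig4_order",
            description="Order of presentation with symmetric Gaussian persuaders.",
            epsilon=0.5,
            opinions={
                "p": _gauss(0.0, 1.0),
                "q_first": _gauss(1.5, 1.0),
                "q_second": _gauss(-1.5, 1.0),
            },
            grid=(-9.5, 9.5, 2001),
        ),
        ScenarioSpec(
            name="fig5_dissonance",
            description=(
                "Cognitive dissonance witness: narrow credible persuader at "
                "moderate separation splits the revised opinion into two "
                "comparable peaks (height ratio ~1.3)."
            ),
            epsilon=0.5,
            opinions={"p": _gauss(0.0, 1.0), "q": _gauss(2.0, 0.3)},
            grid=(-7.0, 8.0, 2001),
        ),
        ScenarioSpec(
            name="fig6_boomerang",
            description="Single boomerang revision (epsilon=1.5): anchor recoils.",
            epsilon=1.5,
            variant=BOOMERANG,
            opinions={"p": _gauss(0.0, 1.0), "q": _gauss(1.5, 1.0)},
            grid=(-10.0, 10.0, 4001),
        ),
        ScenarioSpec(
            name="fig9_boomerang_iterate",
            description=(
                "Repeated boomerang persuasion (epsilon=1.2, 50 steps) reaching "
                "a stationary bimodal opinion."
            ),
            epsilon=1.2,
            variant=BOOMERANG,
            opinions={"p": _gauss(0.0, 1.0), "q": _gauss(1.5, 1.0)},
            grid=(-12.0, 10.0, 2001),
            steps=50,
        ),
        ScenarioSpec(
            name="diminishing_returns",
            description=(
                "Witness (found by deterministic simplex grid search) where the "
                "second persuasion changes the opinion more than the first: "
                "K=3, p0=(0.9, 0.0005, 0.0995), uniform persuader, epsilon=0.5."
            ),
            epsilon=0.5,
            opinions={
                "p": {"family": "discrete", "weights": [0.9, 0.0005, 0.0995]},
                "q": {"family": "discrete", "weights": [1 / 3, 1 / 3, 1 / 3]},
            },
            steps=5,
        ),
    ]
}


def make_scenario(name: str) -> ScenarioSpec:
    """Look up a scenario by name; unknown names list the catalogue."""
    try:
        return SCENARIOS[name]
    except KeyError:
        raise UnknownScenarioError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(SCENARIOS))}"
        ) from None
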