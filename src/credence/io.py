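"""JSON / CSV schemas and atomic file output.

Opinion JSON schema:   ``{"weights": [...], "total_mass": 1.0}``
Density JSON schema:   ``{"family": "gaussian", "mu": ..., "sigma": ...}``,
                       ``{"family": "bump", "b": ...}`` or
                       ``{"family": "grid", "x": [...], "density": [...]}``
Grid opinions export to CSV with columns ``x, density``.

Numeric JSON output uses 17 significant digits so that determinism checks
(identical config => byte-identical output) are meaningful.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Any, Dict, Optional, Union

import numpy as np

from .core import DiscreteOpinion, OpinionValidationError
from .densities import (
    BumpParams,
    GaussianParams,
    Grid,
    GridOpinion,
    bump_density,
    gaussian_density,
)

__all__ = [
    "atomic_write_text",
    "density_spec_to_grid_opinion",
    "dump_json",
    "grid_opinion_to_csv",
    "load_json",
    "load_opinion",
    "opinion_to_dict",
    "save_opinion",
]


def _round17(value: float) -> float:
    return float(f"{value:.17g}")


def atomic_write_text(path: Union[str, Path], text: str) -> None:
    """Write text to ``path`` atomically (tmp file + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def dump_json(obj: Any, path: Optional[Union[str, Path]] = None) -> str:
    text = json.dumps(obj, indent=2, sort_keys=True) + "\n"
    if path is not None:
        atomic_write_text(path, text)
    return text


def load_json(source: Union[str, Path, Dict[str, Any]]) -> Dict[str, Any]:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return json.load(fh)


def opinion_to_dict(op: DiscreteOpinion) -> Dict[str, Any]:
    return {
        "weights": [_round17(w) for w in op.weights],
        "total_mass": _round17(op.total_mass),
    }


def save_opinion(op: DiscreteOpinion, path: Union[str, Path]) -> None:
    dump_json(opinion_to_dict(op), path)


def load_opinion(source: Union[str, Path, Dict[str, Any]]) -> DiscreteOpinion:
    data = load_json(source)
    if "weights" not in data:
        raise OpinionValidationError("opinion JSON needs a 'weights' key")
    return DiscreteOpinion(
        np.asarray(data["weights"], dtype=float), float(data.get("total_mass", 1.0))
    )


def density_spec_to_grid_opinion(
    source: Union[str, Path, Dict[str, Any]], grid: Optional[Grid] = None
) -> GridOpinion:
    """Build a grid opinion from a density JSON spec.

    Parametric families need an explicit ``grid``; the ``"grid"`` family
    carries its own (uniform) abscissae.
    """
    data = load_json(source)
    family = data.get("family")
    if family == "gaussian":
        if grid is None:
            raise OpinionValidationError("gaussian density spec needs a grid")
        return gaussian_density(GaussianParams(data["mu"], data["sigma"]), grid)
    if family == "bump":
        if grid is None:
            raise OpinionValidationError("bump density spec needs a grid")
        return bump_density(BumpParams(data["b"]), grid)
    if family == "grid":
        x = np.asarray(data["x"], dtype=float)
        dens = np.asarray(data["density"], dtype=float)
        dx = np.diff(x)
        if x.size < 2 or not np.allclose(dx, dx[0], rtol=1e-9, atol=0):
            raise OpinionValidationError("grid family needs uniform, increasing x")
        g = Grid(float(x[0]), float(x[-1]), int(x.size))
        return GridOpinion.from_unnormalized(g, dens)
    raise OpinionValidationError(f"unknown density family {family!r}")


def grid_opinion_to_csv(op: GridOpinion, path: Union[str, Path]) -> None:
    lines = ["x,density"]
    lines += [f"{x:.17g},{d:.17g}" for x, d in zip(op.x, op.density)]
    atomic_write_text(path, "\n".join(lines) + "\n")
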