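"""Empirical growth and shape functions as editable control-point curves.

A vegetative Arabidopsis rosette can be described, to a good approximation,
by four one-dimensional functions: the final blade length as a function of
node position along the stem, the relative blade length as a function of
leaf age, the blade half-width contour along the midrib, and the leaf
inclination angle as a function of node position.  Each is represented here
as a :class:`FunctionCurve` — an ordered list of control points on [0, 1]
interpolated with a monotone piecewise cubic (PCHIP), which cannot
overshoot, so grown quantities never go negative between control points.

The bundle of all four curves plus the petiole constants is a
:class:`GrowthFunctionSet`; :func:`default_function_set` loads the curves
shipped with the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator

__all__ = [
    "FunctionCurve",
    "GrowthFunctionSet",
    "eval_curve",
    "leaf_length",
    "leaf_width",
    "default_function_set",
    "load_function_set",
    "save_function_set",
]


class CurveConfigError(ValueError):
    """Raised when a curve's control points violate the curve contract."""


@dataclass(frozen=True)
class FunctionCurve:
    """A function on [0, 1] defined by control points and PCHIP interpolation.

    Parameters
    ----------
    control_points
        Ordered ``(u, v)`` pairs.  Abscissae must be strictly increasing
        with ``u[0] == 0`` and ``u[-1] == 1``.
    """

    control_points: tuple[tuple[float, float], ...]
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __init__(self, control_points: Sequence[Sequence[float]]):
        pts = tuple((float(u), float(v)) for u, v in control_points)
        if len(pts) < 2:
            raise CurveConfigError("a curve needs at least 2 control points")
        us = np.array([p[0] for p in pts])
        if np.any(np.diff(us) <= 0):
            raise CurveConfigError("control abscissae must be strictly increasing")
        if not (math.isclose(us[0], 0.0, abs_tol=1e-12) and math.isclose(us[-1], 1.0, abs_tol=1e-12)):
            raise CurveConfigError("control abscissae must start at 0 and end at 1")
        object.__setattr__(self, "control_points", pts)
        vs = np.array([p[1] for p in pts])
        object.__setattr__(self, "_interp", PchipInterpolator(us, vs, extrapolate=False))

    def __call__(self, u) -> float | np.ndarray:
        u = np.clip(u, 0.0, 1.0)
        out = np.asarray(self._interp(u))
        # control points are reproduced exactly, immune to polynomial round-off
        for cu, cv in self.control_points:
            out = np.where(u == cu, cv, out)
        return float(out) if np.ndim(out) == 0 else out

    # -- serialization ----------------------------------------------------
    def to_list(self) -> list[list[float]]:
        return [[u, v] for u, v in self.control_points]

    @classmethod
    def from_list(cls, pts: Sequence[Sequence[float]]) -> "FunctionCurve":
        return cls(pts)

    def __eq__(self, other) -> bool:
        return isinstance(other, FunctionCurve) and self.control_points == other.control_points

    def __hash__(self) -> int:
        return hash(self.control_points)


def eval_curve(curve: FunctionCurve, u: float) -> float:
    """Evaluate ``curve`` at ``u`` (clamped into [0, 1])."""
    return float(curve(u))


@dataclass(frozen=True)
class GrowthFunctionSet:
    """The four rosette curves plus petiole constants.

    Attributes
    ----------
    f_lmax
        Final blade length (model units) vs. normalized node number.
    f_l
        Relative blade length vs. normalized leaf age; ``f_l(0)=0``,
        ``f_l(1)=1``, non-decreasing.
    f_lw
        Blade width / blade length ratio vs. relative midrib position
        ``x``; zero at both ends (the blade tapers at base and tip).
    f_ang
        Leaf inclination, in degrees of pitch away from the vertical
        stem axis, vs. normalized node number (older leaves lie flatter).
    petiole_length_fraction
        Petiole length as a fraction of blade length.
    petiole_width
        Constant petiole diameter, model units.
    max_node
        Node count used to normalize node numbers: ``n_norm = n / max_node``.
    maturation_plastochrons
        Leaf age (in plastochrons) at which growth saturates; ages are
        normalized by this and clamped to 1.
    """

    f_lmax: FunctionCurve
    f_l: FunctionCurve
    f_lw: FunctionCurve
    f_ang: FunctionCurve
    petiole_length_fraction: float = 0.5
    petiole_width: float = 0.02
    max_node: float = 20.0
    maturation_plastochrons: float = 8.0

    def validate(self) -> None:
        grid = np.linspace(0, 1, 201)
        fl = self.f_l(grid)
        if np.any(np.diff(fl) < -1e-12):
            raise CurveConfigError("f_l must be non-decreasing on [0,1]")
        if abs(float(self.f_lw(0.0))) > 1e-12 or abs(float(self.f_lw(1.0))) > 1e-12:
            raise CurveConfigError("f_lw must vanish at x=0 and x=1")
        ang = self.f_ang(grid)
        if np.any(ang < -1e-9) or np.any(ang > 90 + 1e-9):
            raise CurveConfigError("f_ang must stay within [0, 90] degrees")

    def node_norm(self, n: float) -> float:
        return float(np.clip(n / self.max_node, 0.0, 1.0))


def leaf_length(fs: GrowthFunctionSet, n: float, t: float, x_mult: float = 1.0) -> float:
    """Blade length of the leaf at node ``n`` and normalized age ``t``.

    ``l_n(t) = x_mult * f_lmax(n_norm) * f_l(t)`` with ``n_norm = n / max_node``.
    """
    if x_mult <= 0:
        raise ValueError("x_mult must be positive")
    return x_mult * eval_curve(fs.f_lmax, fs.node_norm(n)) * eval_curve(fs.f_l, t)


def leaf_width(fs: GrowthFunctionSet, n: float, t: float, x: float, x_mult: float = 1.0) -> float:
    """Blade width at relative midrib position ``x``: ``w_n(t,x) = l_n(t) * f_lw(x)``."""
    return leaf_length(fs, n, t, x_mult) * eval_curve(fs.f_lw, x)


# -- serialization --------------------------------------------------------

_CURVE_NAMES = ("f_lmax", "f_l", "f_lw", "f_ang")
_SCALARS = ("petiole_length_fraction", "petiole_width", "max_node", "maturation_plastochrons")


def function_set_to_dict(fs: GrowthFunctionSet) -> dict:
    d = {name: getattr(fs, name).to_list() for name in _CURVE_NAMES}
    d.update({name: float(getattr(fs, name)) for name in _SCALARS})
    return d


def function_set_from_dict(d: dict) -> GrowthFunctionSet:
    kwargs = {name: FunctionCurve(d[name]) for name in _CURVE_NAMES}
    for name in _SCALARS:
        if name in d:
            kwargs[name] = float(d[name])
    fs = GrowthFunctionSet(**kwargs)
    fs.validate()
    return fs


def save_function_set(fs: GrowthFunctionSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(function_set_to_dict(fs), fh, default_flow_style=None, sort_keys=False)


def load_function_set(path) -> GrowthFunctionSet:
    with open(path) as fh:
        return function_set_from_dict(yaml.safe_load(fh))


def default_function_set() -> GrowthFunctionSet:
    """The curves shipped with the package.

    Qualitative shapes: sigmoidal ``f_l``; ``f_lmax`` rising from the first
    nodes to a mid-rosette maximum then declining toward the youngest
    nodes; an ovate ``f_lw`` contour peaking a little past mid-blade; and a
    ``f_ang`` inclination that decreases with node number (young leaves
    stand more upright).
    """
    ref = resources.files("rosettasim").joinpath("data/default_curves.yaml")
    with ref.open() as fh:
        return function_set_from_dict(yaml.safe_load(fh))
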