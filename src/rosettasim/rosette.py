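"""The Arabidopsis rosette grammar and its stochastic parameters.

The rosette is a monopodial structure: a single apex on a short vertical
stem emits, once per plastochron, one internode and one lateral leaf
(petiole + flat blade).  Successive leaves are offset by a stochastic
divergence angle θ_n ~ N(137.5°, 2.5°) — the spiral phyllotactic pattern —
and each leaf's final size is modulated by X_n ~ N(1, 10⁻²).  Development
time is varied between simulations so that the final leaf count is uniform
over a configurable integer range (default 5..20 true leaves).

All randomness is drawn up front into :class:`RosetteParams`;
:func:`build_rosette` is a deterministic function of those draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import yaml

from .curves import GrowthFunctionSet, default_function_set, eval_curve
from .lsystem import ModuleInstance, Production, derive, module
from .turtle import Blade, Scene, TurtleConfig, interpret

__all__ = [
    "StochasticConfig",
    "RosetteParams",
    "sample_rosette_params",
    "build_rosette",
    "blade_azimuth",
    "save_params",
    "load_params",
]

PLASTOCHRON = 1.0  # one time unit per leaf initiation


@dataclass(frozen=True)
class StochasticConfig:
    """Distributional parameters of the stochastic rosette model."""

    x_mu: float = 1.0
    x_sigma: float = 1e-2
    theta_mu: float = 137.5  # degrees
    theta_sigma: float = 2.5  # degrees
    leaf_count_range: tuple[int, int] = (5, 20)

    def __post_init__(self):
        if self.x_sigma < 0 or self.theta_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        lo, hi = self.leaf_count_range
        if lo < 1 or hi < lo:
            raise ValueError("leaf_count_range must be non-empty with lo >= 1")


@dataclass
class RosetteParams:
    """One simulated plant's stochastic draw."""

    target_leaf_count: int
    size_multipliers: list  # X_n, one per leaf, all > 0
    divergence_angles: list  # θ_n in degrees, one per leaf
    inclination_offsets: Optional[list] = None  # per-leaf degrees, default zero
    seed: Optional[int] = None

    def validate(self) -> None:
        k = self.target_leaf_count
        if len(self.size_multipliers) != k or len(self.divergence_angles) != k:
            raise ValueError("per-leaf draws must match target_leaf_count")
        if any(x <= 0 for x in self.size_multipliers):
            raise ValueError("all size multipliers must be positive")
        if self.inclination_offsets is not None and len(self.inclination_offsets) != k:
            raise ValueError("inclination_offsets must match target_leaf_count")

    def to_dict(self) -> dict:
        d = {
            "target_leaf_count": int(self.target_leaf_count),
            "size_multipliers": [float(x) for x in self.size_multipliers],
            "divergence_angles": [float(x) for x in self.divergence_angles],
        }
        if self.inclination_offsets is not None:
            d["inclination_offsets"] = [float(x) for x in self.inclination_offsets]
        if self.seed is not None:
            d["seed"] = int(self.seed)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RosetteParams":
        p = cls(
            target_leaf_count=int(d["target_leaf_count"]),
            size_multipliers=list(d["size_multipliers"]),
            divergence_angles=list(d["divergence_angles"]),
            inclination_offsets=list(d["inclination_offsets"]) if "inclination_offsets" in d else None,
            seed=int(d["seed"]) if "seed" in d else None,
        )
        p.validate()
        return p


def save_params(params: RosetteParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, default_flow_style=None, sort_keys=False)


def load_params(path) -> RosetteParams:
    with open(path) as fh:
        return RosetteParams.from_dict(yaml.safe_load(fh))


def sample_rosette_params(cfg: StochasticConfig, rng: np.random.Generator) -> RosetteParams:
    """Draw one plant: uniform leaf count, i.i.d. size multipliers and angles.

    Size multipliers are truncated at zero (at σ=10⁻² the truncation
    probability is ~10⁻²³; the guard only matters for exotic configs).
    """
    lo, hi = cfg.leaf_count_range
    k = int(rng.integers(lo, hi + 1))
    x = rng.normal(cfg.x_mu, cfg.x_sigma, size=k)
    for _ in range(100):
        bad = x <= 0
        if not bad.any():
            break
        x[bad] = rng.normal(cfg.x_mu, cfg.x_sigma, size=int(bad.sum()))
    else:
        raise RuntimeError("could not draw positive size multipliers")
    theta = rng.normal(cfg.theta_mu, cfg.theta_sigma, size=k)
    return RosetteParams(k, list(map(float, x)), list(map(float, theta)))


def _rosette_productions(params: RosetteParams, fs: GrowthFunctionSet, internode_length: float,
                         dt: float):
    target = params.target_leaf_count
    eps = 1e-9

    def apex_succ(p, clock, rng):
        n, age = int(round(p[0])), p[1]
        m = n + 1  # node number of the leaf being emitted (1-based)
        theta = params.divergence_angles[m - 1]
        ang = eval_curve(fs.f_ang, m / fs.max_node)
        if params.inclination_offsets is not None:
            ang = float(np.clip(ang + params.inclination_offsets[m - 1], 0.0, 90.0))
        return [
            module("/", theta),
            module("I", internode_length, m),
            module("["),
            module("&", ang),
            module("K", m, 0.0),  # leaf placeholder: (node, age)
            module("]"),
            # the matched apex still experiences this step's dt
            module("A", m, age + dt - PLASTOCHRON),
        ]

    apex = Production(
        "A",
        apex_succ,
        condition=lambda p, clock: p[1] >= PLASTOCHRON - eps and int(round(p[0])) < target,
        name="apex-emission",
    )
    return [apex]


def _finalize(string: Sequence[ModuleInstance], params: RosetteParams, fs: GrowthFunctionSet,
              min_blade_length: float) -> list[ModuleInstance]:
    """Expand leaf placeholders K(node, age) into petiole + blade geometry."""
    out: list[ModuleInstance] = []
    for m in string:
        if m.symbol != "K":
            out.append(m)
            continue
        node = int(round(m.params[0]))
        age_norm = min(m.params[1] / fs.maturation_plastochrons, 1.0)
        x_mult = params.size_multipliers[node - 1]
        blade_len = x_mult * eval_curve(fs.f_lmax, node / fs.max_node) * eval_curve(fs.f_l, age_norm)
        if blade_len < min_blade_length:
            continue
        out.append(module("P", fs.petiole_length_fraction * blade_len, node))
        out.append(module("L", blade_len, node))
    return out


def build_rosette(
    params: RosetteParams,
    fs: Optional[GrowthFunctionSet] = None,
    *,
    dt: float = PLASTOCHRON / 10,
    tail_plastochrons: float = 2.0,
    internode_length: float = 0.01,
    min_blade_length: float = 0.0,
    turtle_config: Optional[TurtleConfig] = None,
) -> tuple[Scene, int]:
    """Grow one rosette and return ``(scene, leaf_count_label)``.

    The apex runs for ``target_leaf_count`` plastochrons plus a short tail
    (so the youngest leaves are small but present), then leaf placeholders
    are expanded to petiole + blade modules sized by the growth functions,
    and the string is turtle-interpreted.  The label is the number of blade
    primitives in the scene; with the default ``min_blade_length = 0`` it
    equals ``target_leaf_count`` exactly.
    """
    params.validate()
    fs = fs or default_function_set()
    total_time = params.target_leaf_count * PLASTOCHRON + tail_plastochrons
    # advance the apex age by dt each unmatched step; fire on plastochron boundaries
    n_steps = int(round(total_time / dt))
    # the last emission happens on the step after the final plastochron boundary
    n_steps = max(n_steps, int(round(params.target_leaf_count * PLASTOCHRON / dt)) + 1)
    axiom = [module("A", 0, 0.0)]  # first leaf appears one plastochron in
    string = derive(
        axiom,
        _rosette_productions(params, fs, internode_length, dt),
        dt=dt,
        n_steps=n_steps,
        aging={"A": 1, "K": 1},
    )
    final = _finalize(string, params, fs, min_blade_length)
    scene = interpret(final, fs, turtle_config)
    return scene, len(scene.blades)


def blade_azimuth(blade: Blade) -> float:
    """Azimuth (degrees in [0, 360)) of the blade midrib's horizontal direction."""
    h = blade.frame[:, 0]
    return float(np.degrees(np.arctan2(h[1], h[0])) % 360.0)
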