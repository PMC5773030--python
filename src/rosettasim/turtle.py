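"""3D turtle interpretation of bracketed L-strings into a geometric scene.

The turtle carries a position and a right-handed orthonormal frame
(heading, left, up).  Standard symbols: ``F``/``I``/``P`` draw tapered
cylinder segments, ``L`` emits a flat leaf-blade surface placed at the
current frame, ``+ - & ^ / \\`` rotate about the up, left and heading axes
(degrees), ``[`` ``]`` push and pop the state, ``f`` moves without drawing.
Symbols without a geometric meaning (e.g. the apex ``A``) are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .curves import FunctionCurve, GrowthFunctionSet
from .lsystem import ModuleInstance

__all__ = ["TurtleState", "TurtleConfig", "Cylinder", "Blade", "Scene", "interpret", "InterpretationError"]


class InterpretationError(RuntimeError):
    pass


# Frame columns: heading, left, up.  Initial heading points along +z
# (the stem axis); the camera looks down -z.
_INITIAL_FRAME = np.array([[0.0, 0.0, 1.0],
                           [0.0, 1.0, 0.0],
                           [-1.0, 0.0, 0.0]]).T  # columns H=(0,0,1), L=(0,1,0), U=(-1,0,0)

_ORTHO_TOL = 1e-10


@dataclass
class TurtleState:
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame: np.ndarray = field(default_factory=lambda: _INITIAL_FRAME.copy())

    @property
    def heading(self) -> np.ndarray:
        return self.frame[:, 0]

    @property
    def left(self) -> np.ndarray:
        return self.frame[:, 1]

    @property
    def up(self) -> np.ndarray:
        return self.frame[:, 2]

    def copy(self) -> "TurtleState":
        return TurtleState(self.position.copy(), self.frame.copy())

    def rotate(self, axis_col: int, degrees: float) -> None:
        """Rotate the frame about one of its own axes (0=H, 1=L, 2=U)."""
        axis = self.frame[:, axis_col]
        rad = math.radians(degrees)
        c, s = math.cos(rad), math.sin(rad)
        k = axis / np.linalg.norm(axis)
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) * c + s * kx + (1 - c) * np.outer(k, k)
        self.frame = rot @ self.frame
        err = self.frame.T @ self.frame - np.eye(3)
        if np.abs(err).max() > _ORTHO_TOL:
            u, _, vt = np.linalg.svd(self.frame)
            self.frame = u @ vt

    def forward(self, distance: float) -> None:
        self.position = self.position + distance * self.heading


@dataclass
class Cylinder:
    """A tapered cylinder segment (stem internode or petiole)."""

    p0: np.ndarray
    p1: np.ndarray
    r0: float
    r1: float
    organ: str = "internode"
    node: int = -1


@dataclass
class Blade:
    """A flat leaf blade placed at a frame; the midrib runs along heading.

    Geometry is procedural: points are generated on demand from the blade
    length and the width-contour curve (width at relative midrib position
    ``x`` is ``length * contour(x)``, split evenly about the midrib).
    """

    origin: np.ndarray
    frame: np.ndarray  # columns H, L, U at placement
    length: float
    contour: FunctionCurve
    organ: str = "blade"
    node: int = -1

    def outline(self, n_len: int = 24) -> np.ndarray:
        """Closed outline polygon in world coordinates, shape (2*n_len, 3)."""
        x = np.linspace(0.0, 1.0, n_len + 1)
        half = 0.5 * self.length * np.asarray(self.contour(x))
        mid = self.origin[None, :] + np.outer(x * self.length, self.frame[:, 0])
        side = np.outer(half, self.frame[:, 1])
        upper = mid + side
        lower = (mid - side)[::-1]
        return np.vstack([upper, lower[1:-1]])

    def triangulate(self, n_len: int = 24, n_wid: int = 8) -> tuple[np.ndarray, np.ndarray]:
        """Regular (n_len+1)x(n_wid+1) vertex grid and its triangle faces."""
        x = np.linspace(0.0, 1.0, n_len + 1)
        half = 0.5 * self.length * np.asarray(self.contour(x))
        w = np.linspace(-1.0, 1.0, n_wid + 1)
        mid = self.origin[None, :] + np.outer(x * self.length, self.frame[:, 0])
        verts = (mid[:, None, :] + (half[:, None] * w[None, :])[:, :, None] * self.frame[:, 1][None, None, :])
        verts = verts.reshape(-1, 3)
        faces = []
        ncols = n_wid + 1
        for i in range(n_len):
            for j in range(n_wid):
                a = i * ncols + j
                b = a + 1
                c = a + ncols
                d = c + 1
                faces.append((a, b, c))
                faces.append((b, d, c))
        return verts, np.array(faces, dtype=int)


@dataclass
class Scene:
    """Geometry produced by turtle interpretation."""

    primitives: list = field(default_factory=list)

    @property
    def blades(self) -> list:
        return [p for p in self.primitives if isinstance(p, Blade)]

    def count(self, organ: str) -> int:
        return sum(1 for p in self.primitives if p.organ == organ)

    def projected_points(self, n_len: int = 24, n_circle: int = 12) -> np.ndarray:
        """All primitive boundary points, world coordinates (for extents)."""
        pts = []
        ang = np.linspace(0, 2 * np.pi, n_circle, endpoint=False)
        circ = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        for p in self.primitives:
            if isinstance(p, Blade):
                pts.append(p.outline(n_len))
            else:
                for end, r in ((p.p0, p.r0), (p.p1, p.r1)):
                    ring = np.column_stack([end[0] + r * circ[:, 0], end[1] + r * circ[:, 1],
                                            np.full(len(circ), end[2])])
                    pts.append(ring)
        if not pts:
            return np.zeros((0, 3))
        return np.vstack(pts)


@dataclass
class TurtleConfig:
    internode_radius: float = 0.02
    default_length: float = 1.0
    blade_node_param: int = 1  # index of the node-number parameter on drawing modules


_ROT = {"+": (2, 1.0), "-": (2, -1.0), "&": (1, 1.0), "^": (1, -1.0), "/": (0, 1.0), "\\": (0, -1.0)}


def interpret(
    s: Sequence[ModuleInstance],
    fs: GrowthFunctionSet,
    config: Optional[TurtleConfig] = None,
) -> Scene:
    """Interpret an L-string with bracketed turtle semantics into a Scene."""
    cfg = config or TurtleConfig()
    state = TurtleState()
    stack: list[TurtleState] = []
    scene = Scene()

    def _node(m: ModuleInstance) -> int:
        if len(m.params) > cfg.blade_node_param:
            return int(round(m.params[cfg.blade_node_param]))
        return -1

    for m in s:
        sym = m.symbol
        if sym in _ROT:
            ang = m.params[0] if m.params else 90.0
            state.rotate(_ROT[sym][0], _ROT[sym][1] * ang)
        elif sym == "[":
            stack.append(state.copy())
        elif sym == "]":
            if not stack:
                raise InterpretationError("']' with empty turtle stack")
            state = stack.pop()
        elif sym in ("F", "I", "P"):
            length = m.params[0] if m.params else cfg.default_length
            if sym == "F":
                r0 = m.params[1] if len(m.params) > 1 else cfg.internode_radius
                r1 = m.params[2] if len(m.params) > 2 else r0
                organ, node = "segment", -1
            elif sym == "I":
                r0 = r1 = cfg.internode_radius
                organ, node = "internode", _node(m)
            else:
                r0 = r1 = 0.5 * fs.petiole_width
                organ, node = "petiole", _node(m)
            p0 = state.position.copy()
            state.forward(length)
            scene.primitives.append(Cylinder(p0, state.position.copy(), r0, r1, organ, node))
        elif sym == "f":
            state.forward(m.params[0] if m.params else cfg.default_length)
        elif sym == "L":
            length = m.params[0] if m.params else cfg.default_length
            scene.primitives.append(
                Blade(state.position.copy(), state.frame.copy(), length, fs.f_lw, "blade", _node(m))
            )
        # other symbols (apex, placeholders) have no geometric meaning
    return scene
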