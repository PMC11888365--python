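"""2-D affine transforms: a linear part plus a translation, p' = M p + v."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

__all__ = ["AffineTransform", "affine_named"]

_NAMED_KINDS = ("mirror_h", "mirror_v", "transpose", "translate", "scale", "rotate")


@dataclass(frozen=True)
class AffineTransform:
    """Invertible planar affine map ``p' = M @ p + v``.

    ``M`` is the 2x2 linear part, ``v`` the translation. Composition is
    ``@`` (matrix-style: ``(A @ B)(p) == A(B(p))``).
    """

    M: np.ndarray = field(default_factory=lambda: np.eye(2))
    v: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float).reshape(2, 2)
        v = np.asarray(self.v, dtype=float).reshape(2)
        if abs(np.linalg.det(M)) < 1e-12:
            raise ValueError("affine transform is singular (det(M) ~ 0)")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "v", v)

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (n, 2) coordinate array (or a single (2,) point)."""
        coords = np.asarray(coords, dtype=float)
        single = coords.ndim == 1
        out = np.atleast_2d(coords) @ self.M.T + self.v
        return out[0] if single else out

    def inverse(self) -> "AffineTransform":
        Minv = np.linalg.inv(self.M)
        return AffineTransform(Minv, -Minv @ self.v)

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return AffineTransform(self.M @ other.M, self.M @ other.v + self.v)

    def apply_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        return shapely.transform(geom, self.__call__)

    @property
    def is_axis_aligned(self) -> bool:
        """True when the map sends axis-aligned rectangles to axis-aligned
        rectangles (diagonal or anti-diagonal linear part)."""
        M = self.M
        diag = M[0, 1] == 0 and M[1, 0] == 0
        anti = M[0, 0] == 0 and M[1, 1] == 0
        return diag or anti

    @property
    def is_isometry(self) -> bool:
        return bool(np.allclose(self.M.T @ self.M, np.eye(2), atol=1e-12))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    def __repr__(self) -> str:
        a, b, c, d = self.M.ravel()
        tx, ty = self.v
        return f"AffineTransform(M=[[{a:g}, {b:g}], [{c:g}, {d:g}]], v=[{tx:g}, {ty:g}])"


def affine_named(
    kind: str,
    center: Sequence[float] = (0.0, 0.0),
    *,
    dx: float = 0.0,
    dy: float = 0.0,
    factor: float | None = None,
    angle: float | None = None,
) -> AffineTransform:
    """Build a named transform: mirror, transpose, translate, scale, rotate.

    Mirror/transpose/scale/rotate pivot about ``center`` so the footprint
    stays in place; container-level helpers default ``center`` to the
    container's bounding-box center. ``angle`` is in degrees,
    counter-clockwise. ``mirror_h`` flips left-right (x -> 2cx - x),
    ``mirror_v`` flips up-down, ``transpose`` is (x, y) -> (y, x) about the
    pivot.
    """
    if kind not in _NAMED_KINDS:
        raise ValueError(f"unknown transform kind {kind!r}; expected one of {_NAMED_KINDS}")
    if kind == "translate":
        return AffineTransform(np.eye(2), [dx, dy])

    cx, cy = float(center[0]), float(center[1])
    if kind == "mirror_h":
        M = np.array([[-1.0, 0.0], [0.0, 1.0]])
    elif kind == "mirror_v":
        M = np.array([[1.0, 0.0], [0.0, -1.0]])
    elif kind == "transpose":
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
    elif kind == "scale":
        if factor is None or factor == 0:
            raise ValueError("scale requires a nonzero factor")
        M = np.eye(2) * float(factor)
    else:  # rotate
        if angle is None:
            raise ValueError("rotate requires an angle in degrees")
        t = np.deg2rad(angle)
        M = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        M[np.abs(M) < 1e-15] = 0.0  # make multiples of 90 degrees exact
    c = np.array([cx, cy])
    return AffineTransform(M, c - M @ c)
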