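"""Parametric torso phantom: a superellipse cross-section extruded along +z.

The cross-section is ``|x/a|^n + |y/b|^n = 1``.  ``n = 2`` gives an ellipse;
``n`` around 2.5 gives the flattened-oval shape of a human thorax.  The
phantom carries a high-resolution arc-length table so that belt hardware can
be laid out at equal spacing along the perimeter, which is how a stretched
textile electrode belt sits on a body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .errors import InvalidParameterError
from .surface import SurfaceMesh

__all__ = ["TorsoPhantom", "make_torso_phantom"]

_ARC_TABLE_SIZE = 1 << 19  # samples for the cumulative arc-length table


def _cos_pow(theta: np.ndarray, p: float) -> np.ndarray:
    c = np.cos(theta)
    return np.sign(c) * np.abs(c) ** p


def _sin_pow(theta: np.ndarray, p: float) -> np.ndarray:
    s = np.sin(theta)
    return np.sign(s) * np.abs(s) ** p


@dataclass
class TorsoPhantom:
    """Superellipse cylinder with analytic surface queries."""

    half_width_a: float
    half_depth_b: float
    squareness_n: float
    height: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if self.half_width_a <= 0 or self.half_depth_b <= 0 or self.height <= 0:
            raise InvalidParameterError("phantom dimensions must be positive")
        if self.squareness_n < 2:
            raise InvalidParameterError("squareness exponent must be >= 2")
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        self._theta_table = np.linspace(0.0, 2 * np.pi, _ARC_TABLE_SIZE + 1)
        pts = self.cross_section(self._theta_table)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self._arc_table = np.concatenate([[0.0], np.cumsum(seg)])

    # -- analytic cross-section -------------------------------------------

    def cross_section(self, theta: np.ndarray) -> np.ndarray:
        """Points (N,2) of the cross-section at parameter angle theta (CCW)."""
        p = 2.0 / self.squareness_n
        theta = np.asarray(theta, dtype=float)
        return np.stack(
            [self.half_width_a * _cos_pow(theta, p),
             self.half_depth_b * _sin_pow(theta, p)], axis=-1
        )

    def outward_normal_2d(self, theta: np.ndarray) -> np.ndarray:
        """Unit outward normal of the cross-section (N,2), via the implicit
        gradient; well defined at the axis crossings where the tangent
        parameterization is singular for n > 2."""
        n = self.squareness_n
        p = 2.0 * (n - 1.0) / n
        gx = _cos_pow(np.asarray(theta, dtype=float), p) / self.half_width_a
        gy = _sin_pow(np.asarray(theta, dtype=float), p) / self.half_depth_b
        g = np.stack([gx, gy], axis=-1)
        return g / np.linalg.norm(g, axis=-1, keepdims=True)

    def surface_point(self, theta, z) -> np.ndarray:
        xy = self.cross_section(theta)
        z = np.broadcast_to(np.asarray(z, dtype=float), xy.shape[:-1])
        return np.concatenate([xy, z[..., None]], axis=-1)

    def outward_normal(self, theta) -> np.ndarray:
        n2 = self.outward_normal_2d(theta)
        zeros = np.zeros(n2.shape[:-1] + (1,))
        return np.concatenate([n2, zeros], axis=-1)

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """|x/a|^n + |y/b|^n - 1 for points (N,3); zero on the surface."""
        pts = np.atleast_2d(points)
        n = self.squareness_n
        return (np.abs(pts[:, 0] / self.half_width_a) ** n
                + np.abs(pts[:, 1] / self.half_depth_b) ** n - 1.0)

    # -- arc length --------------------------------------------------------

    @property
    def perimeter(self) -> float:
        """Cross-section perimeter by adaptive quadrature (one quadrant x 4
        only when a = b is false the quadrants still share arc length by the
        symmetry theta -> pi - theta, theta -> -theta)."""
        a, b, n = self.half_width_a, self.half_depth_b, self.squareness_n
        p = 2.0 / n

        def speed(theta: float) -> float:
            c, s = np.cos(theta), np.sin(theta)
            dx = -a * p * np.abs(c) ** (p - 1) * s
            dy = b * p * np.abs(s) ** (p - 1) * c
            return float(np.hypot(dx, dy))

        quarter, _ = quad(speed, 0.0, np.pi / 2, limit=200)
        return 4.0 * quarter

    def arc_length_at(self, theta) -> np.ndarray:
        """Cumulative arc length from theta=0, CCW, via the dense table."""
        theta = np.mod(np.asarray(theta, dtype=float), 2 * np.pi)
        return np.interp(theta, self._theta_table, self._arc_table)

    def theta_at_arc_length(self, s) -> np.ndarray:
        """Inverse of :meth:`arc_length_at` (s in [0, table perimeter))."""
        s = np.mod(np.asarray(s, dtype=float), self._arc_table[-1])
        return np.interp(s, self._arc_table, self._theta_table)

    # -- meshing -----------------------------------------------------------

    def mesh(self, angular_res: int, vertical_res: int) -> SurfaceMesh:
        """Closed-side triangle mesh; ``angular_res * vertical_res`` vertices.

        The angular samples are equally spaced in arc length so triangle
        shapes stay regular even for squarish cross-sections.
        """
        if angular_res < 8 or vertical_res < 8:
            raise InvalidParameterError("mesh resolutions must be >= 8")
        s = np.arange(angular_res) / angular_res * self._arc_table[-1]
        theta = self.theta_at_arc_length(s)
        z = np.linspace(0.0, self.height, vertical_res)
        ring = self.cross_section(theta)  # (A,2)
        verts = np.concatenate(
            [np.tile(ring, (vertical_res, 1)),
             np.repeat(z, angular_res)[:, None]], axis=1
        )
        faces = []
        for j in range(vertical_res - 1):
            base = j * angular_res
            for i in range(angular_res):
                i2 = (i + 1) % angular_res
                v00, v10 = base + i, base + i2
                v01, v11 = v00 + angular_res, v10 + angular_res
                # outward-facing winding (CCW seen from outside)
                faces.append([v00, v10, v11])
                faces.append([v00, v11, v01])
        return SurfaceMesh(verts, np.asarray(faces, dtype=np.int64))


def make_torso_phantom(a: float, b: float, n: float, height: float,
                       angular_res: int = 64, vertical_res: int = 16
                       ) -> tuple[TorsoPhantom, SurfaceMesh]:
    """Build a phantom and its triangle mesh in one call."""
    phantom = TorsoPhantom(a, b, n, height)
    return phantom, phantom.mesh(angular_res, vertical_res)
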