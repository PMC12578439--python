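"""Equidistantly resampled filament centerlines with transported frames.

A traced microtubule backbone is a sparse, hand-clicked polyline.  Geometry
downstream (ring seeding, cylindrical coordinates, the θ angle) needs an
arc-length parameterization and a smooth local frame, so raw traces are
piecewise-linearly interpolated, resampled at a constant arc-length step and
equipped with rotation-minimizing (parallel-transported) frames — Frenet
frames are undefined on the straight stretches that dominate microtubules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegeneratePathError, ValidationError

#: particles farther than this from the centerline are left unassigned
DEFAULT_CAPTURE_RADIUS_NM = 40.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise DegeneratePathError("zero-length tangent")
    return v / n


def _initial_normal(t: np.ndarray) -> np.ndarray:
    # global axis most orthogonal to t, projected into the normal plane;
    # preference order x, y, z so a z-axis path gets normal = +x
    axes = np.eye(3)
    comps = np.abs(axes @ t)
    e = axes[int(np.argmin(comps))]
    return _unit(e - (e @ t) * t)


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b (Rodrigues)."""
    c = float(a @ b)
    v = np.cross(a, b)
    s2 = float(v @ v)
    if s2 < 1e-30:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        p = _initial_normal(a)
        return 2.0 * np.outer(p, p) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s2)


@dataclass
class FilamentPath:
    """An arc-length-uniform centerline with right-handed local frames.

    Attributes
    ----------
    points : (n, 3) nm.
    spacing : nm, constant step between consecutive points.
    tangents, normals, binormals : (n, 3) unit vectors; (t, n, b) is
        right-handed at every point and the normal is parallel-transported.
    polarity : "plus", "minus" or "unknown" — whether the digitized point
        order follows the structural growth direction.
    """

    points: np.ndarray
    spacing: float
    tangents: np.ndarray = field(default=None, repr=False)
    normals: np.ndarray = field(default=None, repr=False)
    binormals: np.ndarray = field(default=None, repr=False)
    polarity: str = "unknown"
    filament_id: int = -1

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValidationError("FilamentPath needs an (n>=2, 3) point array")
        if self.tangents is None:
            self._build_frames()
        self._tree = None

    def _build_frames(self):
        p = self.points
        t = np.empty_like(p)
        t[1:-1] = p[2:] - p[:-2]
        t[0] = p[1] - p[0]
        t[-1] = p[-1] - p[-2]
        norms = np.linalg.norm(t, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise DegeneratePathError("coincident consecutive points")
        t /= norms
        n = np.empty_like(p)
        n[0] = _initial_normal(t[0])
        for i in range(1, len(p)):
            n[i] = _minimal_rotation(t[i - 1], t[i]) @ n[i - 1]
            n[i] = _unit(n[i] - (n[i] @ t[i]) * t[i])  # re-orthogonalize
        self.tangents = t
        self.normals = n
        self.binormals = np.cross(t, n)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        """Total arc length in nm."""
        return float((len(self.points) - 1) * self.spacing)

    @property
    def arc_lengths(self) -> np.ndarray:
        return np.arange(len(self.points)) * self.spacing

    def local_frame(self, index: int):
        """(tangent, normal, binormal) at a path point."""
        return self.tangents[index], self.normals[index], self.binormals[index]

    def reversed(self) -> "FilamentPath":
        """Same centerline digitized in the opposite direction."""
        flip = {"plus": "minus", "minus": "plus", "unknown": "unknown"}
        return FilamentPath(
            self.points[::-1].copy(),
            self.spacing,
            polarity=flip[self.polarity],
            filament_id=self.filament_id,
        )

    def growth_tangents(self) -> np.ndarray:
        """Tangents oriented along the structural growth direction.

        For a minus-polarity path (digitized against growth) the digitized
        tangents are negated; unknown polarity is treated as plus.
        """
        sign = -1.0 if self.polarity == "minus" else 1.0
        return sign * self.tangents

    # -- cylindrical coordinates ------------------------------------------

    def cylindrical_coords(
        self, p, capture_radius: float = DEFAULT_CAPTURE_RADIUS_NM
    ):
        """Map tomogram-frame points onto (s, r, φ) filament coordinates.

        s : arc length (nm) of the foot point, refined by projection onto
            the local tangent (sub-spacing accuracy), clipped to [0, length].
        r : perpendicular distance (nm) to the local tangent line.
        φ : azimuth (degrees in [0, 360)) measured from the transported
            normal towards the binormal.

        Points beyond ``capture_radius`` get NaN in all three fields.
        Accepts a single (3,) point or an (m, 3) array; returns arrays of
        matching leading shape.
        """
        p = np.asarray(p, float)
        single = p.ndim == 1
        pts = p.reshape(-1, 3)
        if self._tree is None:
            self._tree = cKDTree(self.points)
        _, idx = self._tree.query(pts)
        x0 = self.points[idx]
        t = self.tangents[idx]
        n = self.normals[idx]
        b = self.binormals[idx]
        d = pts - x0
        along = np.einsum("ij,ij->i", d, t)
        s = np.clip(idx * self.spacing + along, 0.0, self.length)
        # foot point clamped to the path extent, so r matches the minimal
        # distance to the (finite) centerline also beyond the end caps
        foot = x0 + (s - idx * self.spacing)[:, None] * t
        radial = pts - foot
        r = np.linalg.norm(radial, axis=1)
        phi = np.degrees(
            np.arctan2(np.einsum("ij,ij->i", radial, b),
                       np.einsum("ij,ij->i", radial, n))
        ) % 360.0
        out = np.stack([s, r, phi], axis=1)
        out[r > capture_radius] = np.nan
        if single:
            return out[0]
        return out

    def point_at(self, s: float, phi_deg: float = 0.0, r: float = 0.0) -> np.ndarray:
        """Inverse map: the tomogram-frame point at (s, r, φ).

        Uses the frame of the nearest path node (s is clipped to the path).
        """
        i = int(np.clip(round(s / self.spacing), 0, len(self.points) - 1))
        ds = s - i * self.spacing
        phi = np.radians(phi_deg)
        radial = np.cos(phi) * self.normals[i] + np.sin(phi) * self.binormals[i]
        return self.points[i] + ds * self.tangents[i] + r * radial


def resample_path(
    raw_points,
    spacing: float,
    polarity: str = "unknown",
    filament_id: int = -1,
) -> FilamentPath:
    """Resample a traced polyline at constant arc-length steps.

    The trace is piecewise-linearly interpolated; resampled points sit at
    arc lengths 0, spacing, 2·spacing, … up to the total polyline length
    (the endpoint is included when spacing divides the length).  The first
    input point is preserved exactly.
    """
    raw = np.asarray(raw_points, float)
    if raw.ndim != 2 or raw.shape[1] != 3 or len(raw) < 2:
        raise ValidationError("need >= 2 raw points of dimension 3")
    seg = np.linalg.norm(np.diff(raw, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 0])
    raw = raw[keep]
    if len(raw) < 2:
        raise DegeneratePathError("all trace points coincide")
    seg = np.linalg.norm(np.diff(raw, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(cum[-1])
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    if spacing >= total:
        raise ValidationError(
            f"spacing {spacing} nm >= polyline length {total:.3f} nm"
        )
    n_steps = int(np.floor(total / spacing + 1e-9))
    s = np.arange(n_steps + 1) * spacing
    pts = np.column_stack([np.interp(s, cum, raw[:, k]) for k in range(3)])
    pts[0] = raw[0]
    return FilamentPath(pts, float(spacing), polarity=polarity, filament_id=filament_id)
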