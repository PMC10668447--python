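"""Spherical geometry for headset/controller raycasts and search-array grids.

Conventions
-----------
The calibrated reference frame is right-handed with forward = +z, up = +y,
right = +x.  A direction is summarised by two signed angles in degrees:

``lateral``
    azimuth of the direction, positive toward the player's right,
    ``atan2(x, z)``; range (−180, 180].
``vertical``
    elevation, positive upward, ``asin(y / r)``; range [−90, 90].

These correspond to the horizontal ("latitude") and vertical ("longitude")
raycast angles reported for this class of VR search task; the mapping is a
single documented constant (:data:`RAYCAST_AXIS_LABELS`) so it can be flipped
if a data source uses the opposite labelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: How the package's unambiguous axis names map onto the latitude/longitude
#: labels conventionally used for VR raycast telemetry.
RAYCAST_AXIS_LABELS = {"lateral": "latitude", "vertical": "longitude"}


@dataclass(frozen=True)
class AngularPosition:
    """A direction on the reference sphere, in degrees.

    ``lateral`` is the signed azimuth (positive = player's right),
    ``vertical`` the signed elevation (positive = up).
    """

    lateral: float
    vertical: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lateral <= 180.0):
            raise ValueError(f"lateral angle {self.lateral} outside [-180, 180]")
        if not (-90.0 <= self.vertical <= 90.0):
            raise ValueError(f"vertical angle {self.vertical} outside [-90, 90]")

    def as_tuple(self) -> tuple[float, float]:
        return (self.lateral, self.vertical)


def cartesian_to_angles(direction: Sequence[float]) -> AngularPosition:
    """Convert a Cartesian direction to (lateral, vertical) angles.

    The input need not be unit length but must be non-zero; only the
    direction matters.  Inverse of :func:`angles_to_cartesian` on the unit
    sphere (away from the poles, where the lateral angle degenerates).
    """
    v = np.asarray(direction, dtype=float)
    if v.shape != (3,):
        raise ValueError("direction must be a 3-vector")
    norm = float(np.linalg.norm(v))
    if norm == 0.0 or not np.isfinite(norm):
        raise ValueError("direction must have positive finite norm")
    x, y, z = v / norm
    lateral = np.degrees(np.arctan2(x, z))
    vertical = np.degrees(np.arcsin(np.clip(y, -1.0, 1.0)))
    return AngularPosition(float(lateral), float(vertical))


def angles_to_cartesian(pos: AngularPosition, radius: float = 1.0) -> np.ndarray:
    """Point at ``radius`` metres in the direction given by ``pos``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    lat = np.radians(pos.lateral)
    vert = np.radians(pos.vertical)
    x = radius * np.cos(vert) * np.sin(lat)
    y = radius * np.sin(vert)
    z = radius * np.cos(vert) * np.cos(lat)
    return np.array([x, y, z])


def eccentricity(pos: AngularPosition) -> float:
    """Angular distance (degrees) of a position from straight ahead."""
    cos_e = np.cos(np.radians(pos.vertical)) * np.cos(np.radians(pos.lateral))
    return float(np.degrees(np.arccos(np.clip(cos_e, -1.0, 1.0))))


def angular_distance(a: AngularPosition, b: AngularPosition) -> float:
    """Great-circle angle (degrees) between two directions."""
    va = angles_to_cartesian(a)
    vb = angles_to_cartesian(b)
    return float(np.degrees(np.arccos(np.clip(np.dot(va, vb), -1.0, 1.0))))


def angular_distance_matrix(positions: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Great-circle angles (degrees) from each row of ``positions`` to ``ref``.

    Both arguments are (lateral, vertical) degree pairs; ``positions`` has
    shape (n, 2) and ``ref`` shape (2,).  Vectorised for simulator inner
    loops.
    """
    lat = np.radians(positions[:, 0])
    vert = np.radians(positions[:, 1])
    rl, rv = np.radians(ref[0]), np.radians(ref[1])
    # dot product of unit vectors in the (x, y, z) frame above
    dot = (
        np.cos(vert) * np.sin(lat) * np.cos(rv) * np.sin(rl)
        + np.sin(vert) * np.sin(rv)
        + np.cos(vert) * np.cos(lat) * np.cos(rv) * np.cos(rl)
    )
    return np.degrees(np.arccos(np.clip(dot, -1.0, 1.0)))


def ring_positions(ecc: float, n_elements: int, phase_deg: float = 0.0) -> list[AngularPosition]:
    """``n_elements`` positions evenly spaced on the ring at eccentricity ``ecc``.

    The ring is the circle of directions at great-circle angle ``ecc`` from
    the forward axis; positions are parameterised by a polar angle measured
    counter-clockwise from the player's right (so polar 0° is pure right,
    90° pure up).
    """
    if not (0.0 < ecc < 90.0):
        raise ValueError("ring eccentricity must lie in (0, 90) degrees")
    if n_elements < 1:
        raise ValueError("a ring needs at least one element")
    out = []
    e = np.radians(ecc)
    for k in range(n_elements):
        theta = np.radians(phase_deg + 360.0 * k / n_elements)
        v = np.array([np.sin(e) * np.cos(theta), np.sin(e) * np.sin(theta), np.cos(e)])
        out.append(cartesian_to_angles(v))
    return out


def build_spherical_grid(
    ring_eccentricities: Iterable[float],
    within_ring_spacing: float,
) -> list[AngularPosition]:
    """Search-array grid: concentric rings at the given eccentricities.

    ``within_ring_spacing`` (degrees of polar angle) must divide 360 so the
    rings close; each ring then carries ``360 / spacing`` evenly spaced
    positions.
    """
    if within_ring_spacing <= 0:
        raise ValueError("within-ring spacing must be positive")
    n, rem = divmod(360.0, within_ring_spacing)
    if abs(rem) > 1e-9 and abs(rem - within_ring_spacing) > 1e-9:
        raise ValueError(
            f"within-ring spacing {within_ring_spacing}° does not divide 360°"
        )
    positions: list[AngularPosition] = []
    for ecc in ring_eccentricities:
        positions.extend(ring_positions(ecc, int(round(360.0 / within_ring_spacing))))
    return positions
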