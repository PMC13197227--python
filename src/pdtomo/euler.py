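"""Euler-angle conventions used throughout the package.

A particle orientation is stored as three angles ``(phi, theta, psi)`` in
degrees.  The rotation matrix mapping reference-frame coordinates into the
tomogram frame is

    R(phi, theta, psi) = Rz(psi) @ Rx(theta) @ Rz(phi)

i.e. ``phi`` is applied first as an in-plane spin about the reference z axis,
``theta`` tilts about the (new) x axis and ``psi`` is the final spin.  The
particle z axis therefore depends only on ``(theta, psi)`` while ``phi`` is
the spin about the particle's own symmetry axis — the angle that is
randomized when seeding particles along a tubule.

Canonical ranges: phi, psi in [0, 360); theta in [0, 180].
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "rotation_matrix",
    "euler_from_matrix",
    "zaxis_from_euler",
    "euler_aligning_z",
    "canonical_angles",
]


def rotation_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """3x3 matrix R = Rz(psi) Rx(theta) Rz(phi), angles in degrees."""
    return Rotation.from_euler("ZXZ", [psi, theta, phi], degrees=True).as_matrix()


def euler_from_matrix(mat: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`rotation_matrix`; returns canonical (phi, theta, psi)."""
    psi, theta, phi = Rotation.from_matrix(mat).as_euler("ZXZ", degrees=True)
    return canonical_angles(phi, theta, psi)


def zaxis_from_euler(phi: float, theta: float, psi: float) -> np.ndarray:
    """Unit vector the reference z axis maps to (independent of phi)."""
    return rotation_matrix(phi, theta, psi) @ np.array([0.0, 0.0, 1.0])


def euler_aligning_z(target: np.ndarray, phi: float = 0.0) -> tuple[float, float, float]:
    """Angles rotating the reference z axis onto unit vector ``target``.

    ``phi`` (the in-plane spin) is a free parameter passed through unchanged.
    """
    t = np.asarray(target, dtype=float)
    n = np.linalg.norm(t)
    if n < 1e-12:
        raise ValueError("zero-length axis vector")
    t = t / n
    theta = np.degrees(np.arccos(np.clip(t[2], -1.0, 1.0)))
    # R ez = (sin(theta) sin(psi), -sin(theta) cos(psi), cos(theta))
    if np.sin(np.radians(theta)) < 1e-12:
        psi = 0.0
    else:
        psi = np.degrees(np.arctan2(t[0], -t[1]))
    return canonical_angles(phi, theta, psi)


def canonical_angles(phi: float, theta: float, psi: float) -> tuple[float, float, float]:
    """Reduce angles to phi, psi in [0, 360), theta in [0, 180]."""
    theta = float(theta) % 360.0
    if theta > 180.0:
        # Rx(theta) = Rz(180) Rx(360-theta) Rz(180)
        theta = 360.0 - theta
        phi = phi + 180.0
        psi = psi + 180.0
    return float(phi) % 360.0, float(theta), float(psi) % 360.0
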