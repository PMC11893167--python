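"""Rotation and pose primitives shared by all pipeline stages.

Subtomogram-averaging software stores particle orientations as ZYZ intrinsic
Euler triples (rot, tilt, psi, in degrees) describing the rotation that maps
the reference frame onto the particle.  The body->tomogram rotation used
throughout this package is the transpose of that composed matrix:

    R_body->tomo = (Rz(rot) @ Ry(tilt) @ Rz(psi)).T

Applying ``R_body->tomo`` to a body-frame direction (e.g. the peptide exit
tunnel axis) yields the tomogram-frame direction.  All lengths are Angstrom,
all angles degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


__all__ = [
    "BodyFrameOffsets",
    "euler_to_matrix",
    "matrix_to_euler",
    "body_point_to_tomogram",
    "relative_angle",
]


@dataclass(frozen=True)
class BodyFrameOffsets:
    """Body-frame landmarks of the 80S ribosome used by the analysis.

    ``exit_tunnel`` is the peptide exit position relative to the particle
    center; ``exit_direction`` is the unit axis the exit tunnel points along
    (rendered as the yellow arrow in membrane-context figures).  ``mrna_entry``
    and ``mrna_exit`` mark the 3' mRNA entry and 5' mRNA exit sites used for
    polysome chain detection.  Units: Angstrom in the ribosome body frame.

    The numeric defaults are a generic 80S-scale geometry (the exit tunnel
    ~120 A below the center, mRNA channel sites on the small-subunit side);
    they are configurable because no canonical body-frame coordinates exist
    independent of a particular average map.
    """

    exit_tunnel: np.ndarray
    exit_direction: np.ndarray
    mrna_entry: np.ndarray
    mrna_exit: np.ndarray

    def __post_init__(self) -> None:
        for name in ("exit_tunnel", "exit_direction", "mrna_entry", "mrna_exit"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)
        n = np.linalg.norm(self.exit_direction)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("exit_direction must be nonzero")
            object.__setattr__(self, "exit_direction", self.exit_direction / n)

    @classmethod
    def default(cls) -> "BodyFrameOffsets":
        return cls(
            exit_tunnel=np.array([0.0, 0.0, -120.0]),
            exit_direction=np.array([0.0, 0.0, -1.0]),
            mrna_entry=np.array([80.0, 0.0, -40.0]),
            mrna_exit=np.array([-80.0, 0.0, -40.0]),
        )


def _check_finite(angles) -> np.ndarray:
    a = np.asarray(angles, dtype=float)
    if a.shape[-1] != 3 or not np.all(np.isfinite(a)):
        raise ValueError("Euler angles must be finite (rot, tilt, psi) triples")
    return a


def euler_to_matrix(angles) -> np.ndarray:
    """Convert a ZYZ Euler triple (degrees) to the body->tomogram rotation.

    Parameters
    ----------
    angles : (3,) or (n, 3) array-like
        (rot, tilt, psi) in degrees.

    Returns
    -------
    (3, 3) or (n, 3, 3) ndarray
        ``(Rz(rot) @ Ry(tilt) @ Rz(psi)).T`` — orthonormal, det +1.
    """
    a = _check_finite(angles)
    mats = Rotation.from_euler("ZYZ", a, degrees=True).as_matrix()
    return np.swapaxes(mats, -1, -2)


def matrix_to_euler(matrix: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_to_matrix`; returns (rot, tilt, psi) degrees."""
    m = np.asarray(matrix, dtype=float)
    return Rotation.from_matrix(np.swapaxes(m, -1, -2)).as_euler("ZYZ", degrees=True)


def body_point_to_tomogram(center, angles, offset) -> np.ndarray:
    """Map a body-frame offset to tomogram coordinates.

    ``center`` is the particle center in tomogram frame (A), ``offset`` a
    body-frame displacement (A).  Returns ``center + R @ offset``.
    """
    center = np.asarray(center, dtype=float)
    offset = np.asarray(offset, dtype=float)
    R = euler_to_matrix(angles)
    return center + np.einsum("...ij,...j->...i", R, offset)


def relative_angle(body_axis, angles, normal) -> float:
    """Angle between a rotated body axis and a surface normal, folded to [0, 90].

    Computes ``arccos(|(R @ body_axis) . normal|)`` in degrees.  The absolute
    value makes the result insensitive to the sign convention of either
    vector, so parallel and antiparallel both score 0 deg.
    """
    body_axis = np.asarray(body_axis, dtype=float)
    normal = np.asarray(normal, dtype=float)
    nb = np.linalg.norm(body_axis, axis=-1)
    nn = np.linalg.norm(normal, axis=-1)
    if np.any(nb == 0) or np.any(nn == 0):
        raise ValueError("zero-norm vector passed to relative_angle")
    R = euler_to_matrix(angles)
    rotated = np.einsum("...ij,...j->...i", R, body_axis / nb[..., None] if body_axis.ndim > 1 else body_axis / nb)
    dot = np.abs(np.sum(rotated * (normal / nn[..., None] if normal.ndim > 1 else normal / nn), axis=-1))
    return np.degrees(np.arccos(np.clip(dot, 0.0, 1.0)))
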