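"""Rigid-body frames and the point algebra built on them.

A ``Rigid`` is a proper rotation plus a translation, the currency of the
structure module (per-residue backbone frames) and of superposition-based
metrics.  Rotations are stored as 3x3 matrices; translations in Angstrom.
Frames follow the Gram-Schmidt convention of the AlphaFold2 lineage: the
x-axis points along CA->C, the y-axis lies in the N-CA-C plane on the N side,
and z completes a right-handed triad.  The frame origin is the CA position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation as _R

__all__ = [
    "Rigid",
    "InvalidFrameError",
    "DegenerateGeometryError",
    "frames_from_three_points",
    "kabsch_superpose",
    "dihedral",
    "quaternion_from_bcd",
]

_ORTHO_TOL = 1e-6


class InvalidFrameError(ValueError):
    """Rotation is not orthonormal with determinant +1."""


class DegenerateGeometryError(ValueError):
    """Collinear or coincident points where a frame/dihedral is required."""


def _check_rotation(rot: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    err = np.abs(rot @ np.swapaxes(rot, -1, -2) - np.eye(3))
    if err.max() > tol:
        raise InvalidFrameError(
            f"rotation not orthonormal (max deviation {err.max():.2e})"
        )
    if np.any(np.linalg.det(rot) < 0):
        raise InvalidFrameError("rotation has determinant -1 (reflection)")


@dataclass(frozen=True)
class Rigid:
    """A proper rigid transform y = R x + t, batched over leading axes."""

    rotation: np.ndarray  # (..., 3, 3)
    translation: np.ndarray  # (..., 3)

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=np.float64)
        trans = np.asarray(self.translation, dtype=np.float64)
        if rot.shape[-2:] != (3, 3) or trans.shape[-1] != 3:
            raise InvalidFrameError("rotation must be (...,3,3), translation (...,3)")
        _check_rotation(rot)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)

    @classmethod
    def identity(cls, shape: tuple[int, ...] = ()) -> "Rigid":
        rot = np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
        return cls(rot, np.zeros(shape + (3,)))

    def compose(self, other: "Rigid") -> "Rigid":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        rot = self.rotation @ other.rotation
        trans = (
            np.einsum("...ij,...j->...i", self.rotation, other.translation)
            + self.translation
        )
        return Rigid(rot, trans)

    def invert(self) -> "Rigid":
        rot_inv = np.swapaxes(self.rotation, -1, -2)
        return Rigid(rot_inv, -np.einsum("...ij,...j->...i", rot_inv, self.translation))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (..., 3) through the transform."""
        points = np.asarray(points, dtype=np.float64)
        return (
            np.einsum("...ij,...j->...i", self.rotation, points) + self.translation
        )

    def __getitem__(self, idx) -> "Rigid":
        return Rigid(self.rotation[idx], self.translation[idx])

    @property
    def shape(self) -> tuple[int, ...]:
        return self.rotation.shape[:-2]


def frames_from_three_points(
    n: np.ndarray, ca: np.ndarray, c: np.ndarray, tol: float = 1e-8
) -> Rigid:
    """Backbone frames from N, CA, C coordinates (batched over leading axes).

    Gram-Schmidt with the x-axis along CA->C and CA->N fixing the xy-plane.
    """
    n, ca, c = (np.asarray(a, dtype=np.float64) for a in (n, ca, c))
    v1 = c - ca
    v2 = n - ca
    n1 = np.linalg.norm(v1, axis=-1, keepdims=True)
    if np.any(n1 < tol):
        raise DegenerateGeometryError("CA and C coincide")
    e1 = v1 / n1
    u2 = v2 - np.sum(v2 * e1, axis=-1, keepdims=True) * e1
    n2 = np.linalg.norm(u2, axis=-1, keepdims=True)
    if np.any(n2 < tol):
        raise DegenerateGeometryError("N, CA, C are collinear")
    e2 = u2 / n2
    e3 = np.cross(e1, e2)
    rot = np.stack([e1, e2, e3], axis=-1)  # columns are the local axes
    return Rigid(rot, ca)


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[Rigid, float]:
    """Optimal weighted superposition of ``mobile`` onto ``target``.

    Returns the proper-rotation rigid transform minimising the weighted RMSD
    and that minimum RMSD.  Backed by the closed-form SVD solution
    (``scipy.spatial.transform.Rotation.align_vectors``).
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if mobile.shape != target.shape:
        raise ValueError(f"point-set shapes differ: {mobile.shape} vs {target.shape}")
    if mobile.ndim != 2 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    if weights is None:
        weights = np.ones(len(mobile))
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    wsum = weights.sum()
    mu_m = (weights[:, None] * mobile).sum(0) / wsum
    mu_t = (weights[:, None] * target).sum(0) / wsum
    rot, _ = _R.align_vectors(target - mu_t, mobile - mu_m, weights=weights)
    rmat = rot.as_matrix()
    transform = Rigid(rmat, mu_t - rmat @ mu_m)
    resid = transform.apply(mobile) - target
    rmsd = float(np.sqrt((weights * (resid**2).sum(-1)).sum() / wsum))
    return transform, rmsd


def dihedral(p1, p2, p3, p4, tol: float = 1e-8) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in radians, in (-pi, pi]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    if np.any(b2n < tol) or np.any(np.linalg.norm(n1, axis=-1) < tol) or np.any(
        np.linalg.norm(n2, axis=-1) < tol
    ):
        raise DegenerateGeometryError("degenerate dihedral geometry")
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * (b2 / b2n[..., None]), axis=-1)
    angle = np.arctan2(y, x)
    # map -pi to +pi so the range is (-pi, pi]
    angle = np.where(np.isclose(angle, -np.pi), np.pi, angle)
    return float(angle) if angle.ndim == 0 else angle


def quaternion_from_bcd(b: float, c: float, d: float) -> np.ndarray:
    """Rotation matrix from the non-unit quaternion (1, b, c, d).

    The fixed unit first component makes the zero vector map to the identity
    and keeps every output a valid proper rotation; this parametrises the
    backbone-update deltas of the structure module.
    """
    q = np.stack(
        [np.asarray(b, float), np.asarray(c, float), np.asarray(d, float),
         np.ones(np.shape(b))],
        axis=-1,
    )  # scipy is scalar-last
    q = q / np.linalg.norm(q, axis=-1, keepdims=True)
    return _R.from_quat(q).as_matrix()
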