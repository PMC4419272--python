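"""Domain types and local-deformation tensor mathematics.

Positions live in the frontal (P-D x A-P) plane of the organ, in micrometres:
``+x`` points proximal→distal, ``+y`` anterior→posterior (right-handed frame).
A smooth map ``x = phi(X)`` carries each tissue element from its position
``X`` before a time interval to its position ``x`` after it.  All local
information about the deformation around ``X`` is contained in the deformation
gradient tensor ``F`` (``F_ij = d phi_i / d X_j``), which this module
decomposes into a rotation and a right stretch, ``F = R U``, and summarizes by

* tissue growth rate ``det F`` — the local area expansion factor, and
* deformation anisotropy — magnitude ``lam1/lam2`` (eigenvalues of ``U``,
  ``lam1 >= lam2``) with the ``lam1`` eigenvector as axis; isotropic
  deformation has magnitude exactly 1.

Tensors are expressed in the reference (before-deformation) frame, which makes
anisotropy axes comparable across stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import DegenerateDeformationError, OrientationError

__all__ = [
    "Point2",
    "LandmarkPair",
    "LocalDeformation",
    "polar_decompose",
    "anisotropy",
    "deformation_gradient_of_affine",
]

#: Condition number above which a 2x2 tensor is treated as numerically singular.
_COND_LIMIT = 1e12

#: Relative eigenvalue gap below which a stretch is treated as exactly isotropic.
_ISO_RTOL = 1e-12


@dataclass(frozen=True)
class Point2:
    """A position in the frontal plane, micrometres.

    ``pd`` is the coordinate along the proximal→distal axis (+x), ``ap``
    along the anterior→posterior axis (+y).
    """

    pd: float
    ap: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pd) and np.isfinite(self.ap)):
            raise ValueError(f"non-finite coordinates ({self.pd}, {self.ap})")

    def as_array(self) -> np.ndarray:
        return np.array([self.pd, self.ap], dtype=float)

    @staticmethod
    def from_array(a) -> "Point2":
        a = np.asarray(a, dtype=float)
        return Point2(float(a[0]), float(a[1]))


@dataclass(frozen=True)
class LandmarkPair:
    """One marker's position before (``X``) and after (``x``) deformation."""

    embryo_id: str
    interval_id: str
    X: Point2
    x: Point2

    def __post_init__(self) -> None:
        if not self.embryo_id:
            raise ValueError("embryo_id must be nonempty")


@dataclass(frozen=True)
class LocalDeformation:
    """Full local characterization of a deformation gradient tensor.

    ``aniso_dir`` is the unit axis of maximal stretch in the reference frame,
    sign-normalized to a non-negative x component (non-negative y if x is 0);
    it is ``None`` when the stretch is exactly isotropic, in which case the
    axis is undefined and ``aniso_mag`` is 1.
    """

    F: np.ndarray
    R: np.ndarray
    U: np.ndarray
    growth_rate: float
    aniso_mag: float
    aniso_dir: Optional[np.ndarray] = field(default=None)

    @property
    def is_isotropic(self) -> bool:
        return self.aniso_dir is None

    @property
    def aniso_angle_deg(self) -> float:
        """Axis angle in degrees in [0, 180); NaN for isotropic deformation."""
        if self.aniso_dir is None:
            return float("nan")
        ang = np.degrees(np.arctan2(self.aniso_dir[1], self.aniso_dir[0]))
        return float(ang % 180.0)


def _as_tensor(F) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.shape != (2, 2) or not np.all(np.isfinite(F)):
        raise ValueError("expected a finite 2x2 tensor")
    return F


def polar_decompose(F) -> tuple[np.ndarray, np.ndarray]:
    """Right polar decomposition ``F = R U`` of an orientation-preserving tensor.

    Computed via the SVD ``F = W S V^T`` (``R = W V^T``, ``U = V S V^T``),
    which is robust for near-singular tensors.

    Returns
    -------
    (R, U) : R in SO(2), U symmetric positive definite.

    Raises
    ------
    OrientationError
        if ``det F <= 0``.
    DegenerateDeformationError
        if the condition number of ``F`` exceeds 1e12.
    """
    F = _as_tensor(F)
    det = float(np.linalg.det(F))
    if det <= 0.0:
        raise OrientationError(f"det F = {det:g} <= 0: orientation-reversing map")
    W, s, Vt = np.linalg.svd(F)
    if s[-1] <= 0.0 or s[0] / s[-1] > _COND_LIMIT:
        raise DegenerateDeformationError(
            f"singular values {s}: condition number exceeds {_COND_LIMIT:g}"
        )
    R = W @ Vt
    # det F > 0 guarantees det R = +1 up to round-off.
    U = Vt.T @ np.diag(s) @ Vt
    return R, U


def anisotropy(F) -> tuple[float, Optional[np.ndarray]]:
    """Deformation anisotropy (magnitude, axis) of a deformation gradient.

    The magnitude is the ratio ``lam1/lam2 >= 1`` of the eigenvalues of the
    right stretch tensor ``U``; the axis is the ``lam1`` eigenvector expressed
    in the reference frame.  Isotropic deformation returns ``(1.0, None)``:
    the axis is genuinely undefined, not arbitrary.
    """
    _, U = polar_decompose(F)
    evals, evecs = np.linalg.eigh(U)  # ascending
    lam2, lam1 = float(evals[0]), float(evals[1])
    if lam1 - lam2 <= _ISO_RTOL * lam1:
        return 1.0, None
    v1 = evecs[:, 1].copy()
    if v1[0] < 0.0 or (v1[0] == 0.0 and v1[1] < 0.0):
        v1 = -v1
    return lam1 / lam2, v1


def deformation_gradient_of_affine(A, b=None) -> LocalDeformation:
    """Local deformation of the affine map ``x = A X + b``.

    The translation ``b`` does not enter the deformation gradient (``F = A``
    everywhere); it is accepted for interface symmetry with map fitting.
    """
    A = _as_tensor(A)
    det = float(np.linalg.det(A))
    if det <= 0.0:
        raise OrientationError(f"det A = {det:g} <= 0: orientation-reversing map")
    R, U = polar_decompose(A)
    mag, direction = anisotropy(A)
    return LocalDeformation(
        F=A, R=R, U=U, growth_rate=det, aniso_mag=mag, aniso_dir=direction
    )


def local_deformation(F) -> LocalDeformation:
    """Convenience: full :class:`LocalDeformation` record for a tensor ``F``."""
    return deformation_gradient_of_affine(F)
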