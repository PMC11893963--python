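"""Voxel-grid geometry: the affine map between array indices and patient space.

Conventions (fixed for the whole package):

* Patient coordinates are DICOM LPS millimetres (+x left, +y posterior,
  +z superior).  NIfTI's RAS affines are converted on read.
* Indices are 0-based and ``origin`` is the centre of voxel (0, 0, 0).
* A grid is the pair (4x4 homogeneous affine, shape); the linear part is
  ``orientation @ diag(spacing)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError

__all__ = ["AffineGeometry"]

_ORTHO_TOL = 1e-4


@dataclass(frozen=True)
class AffineGeometry:
    """Affine voxel-index -> patient-mm transform plus the grid extent.

    Parameters
    ----------
    matrix : (4, 4) ndarray
        Homogeneous transform taking a continuous 0-based voxel index
        ``(i, j, k, 1)`` to patient-space millimetres (LPS).
    shape : tuple of int
        Grid extent along each index axis.
    """

    matrix: np.ndarray
    shape: tuple[int, int, int]
    _inverse: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {m.shape}")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise GeometryError(f"invalid grid shape {self.shape}")
        if np.any(self.spacing <= 0):
            raise GeometryError(f"voxel spacing must be positive, got {self.spacing}")
        r = self.orientation
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL):
            raise GeometryError("orientation matrix is not orthonormal (tol 1e-4)")
        try:
            inv = np.linalg.inv(m)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise GeometryError("affine is not invertible") from exc
        object.__setattr__(self, "_inverse", inv)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_components(
        cls,
        spacing,
        origin,
        orientation=None,
        shape=(1, 1, 1),
    ) -> "AffineGeometry":
        """Build from spacing (mm), origin (mm, voxel-centre of index 0) and a
        3x3 direction matrix (defaults to identity, i.e. grid axes aligned
        with the LPS patient axes)."""
        spacing = np.asarray(spacing, dtype=float)
        if np.any(spacing <= 0):
            raise GeometryError(f"voxel spacing must be positive, got {spacing}")
        origin = np.asarray(origin, dtype=float)
        r = np.eye(3) if orientation is None else np.asarray(orientation, dtype=float)
        m = np.eye(4)
        m[:3, :3] = r @ np.diag(spacing)
        m[:3, 3] = origin
        return cls(m, tuple(shape))

    # ------------------------------------------------------------------ #
    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the linear part)."""
        return np.linalg.norm(self.matrix[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        """Patient-space position (mm) of the centre of voxel (0, 0, 0)."""
        return self.matrix[:3, 3].copy()

    @property
    def orientation(self) -> np.ndarray:
        """3x3 direction matrix mapping index axes to patient axes."""
        return self.matrix[:3, :3] / self.spacing[np.newaxis, :]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.matrix[:3, :3])))

    # ------------------------------------------------------------------ #
    def index_to_mm(self, index) -> np.ndarray:
        """Map continuous voxel indices (..., 3) to patient mm."""
        idx = np.asarray(index, dtype=float)
        return idx @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def mm_to_index(self, mm) -> np.ndarray:
        """Map patient mm (..., 3) to continuous voxel indices."""
        pts = np.asarray(mm, dtype=float)
        return pts @ self._inverse[:3, :3].T + self._inverse[:3, 3]

    # ------------------------------------------------------------------ #
    def patient_axis(self, axis: int) -> tuple[int, float]:
        """Return (index_axis, sign) of the grid axis most aligned with
        patient axis ``axis`` (0=L, 1=P, 2=S)."""
        row = self.orientation[axis, :]
        k = int(np.argmax(np.abs(row)))
        return k, float(np.sign(row[k]) or 1.0)

    def approx_equal(self, other: "AffineGeometry", tol_mm: float = 1e-3) -> bool:
        """Same shape and same affine within ``tol_mm`` on every entry."""
        return self.shape == other.shape and bool(
            np.allclose(self.matrix, other.matrix, atol=tol_mm)
        )

    def describe(self) -> str:
        return (
            f"shape={self.shape} spacing={np.round(self.spacing, 4).tolist()} "
            f"origin={np.round(self.origin, 4).tolist()}"
        )
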