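"""Rigid/affine transforms, dense displacement fields and transform chains.

Transforms map world points (mm) forward along the co-registration chain
section frame -> ex-vivo CT -> in-vivo CT -> PET.  Each transform exposes
``apply`` and ``inverse_apply``; chains compose them in declared order.
Displacement-field inverses are computed numerically by fixed-point
iteration, which is accurate for the small, smooth deformations the chain
is meant to carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["Affine", "DisplacementField", "TransformChain"]


@dataclass(frozen=True)
class Affine:
    """A 4x4 homogeneous affine transform on world points in mm."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("Affine requires a 4x4 matrix")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("Affine matrix is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "Affine":
        return cls(np.eye(4))

    @classmethod
    def translation(cls, t) -> "Affine":
        m = np.eye(4)
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m)

    @classmethod
    def rotation(cls, axis, angle_deg: float, center=(0.0, 0.0, 0.0)) -> "Affine":
        """Rotation by ``angle_deg`` about ``axis`` through ``center`` (Rodrigues)."""
        a = np.asarray(axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("rotation axis must be nonzero")
        a = a / n
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        c = np.asarray(center, dtype=float)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c - R @ c
        return cls(m)

    @classmethod
    def rigid(cls, translation, axis=(0, 0, 1), angle_deg: float = 0.0, center=(0, 0, 0)) -> "Affine":
        return cls.translation(translation) @ cls.rotation(axis, angle_deg, center)

    def __matmul__(self, other: "Affine") -> "Affine":
        """Composition: ``(A @ B).apply(x) == A.apply(B.apply(x))``."""
        return Affine(self.matrix @ other.matrix)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "Affine":
        return Affine(np.linalg.inv(self.matrix))

    def inverse_apply(self, pts: np.ndarray) -> np.ndarray:
        return self.inverse().apply(pts)

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.matrix, np.eye(4), atol=1e-12))


class DisplacementField:
    """Dense displacement ``y = x + d(x)`` on a regular grid (trilinear)."""

    def __init__(self, displacements: np.ndarray, spacing, origin) -> None:
        d = np.asarray(displacements, dtype=float)
        if d.ndim != 4 or d.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        self.displacements = d
        self.spacing = np.asarray(spacing, dtype=float)
        self.origin = np.asarray(origin, dtype=float)
        axes = [
            self.origin[a] + np.arange(d.shape[a]) * self.spacing[a] for a in range(3)
        ]
        self._interp = RegularGridInterpolator(
            axes, d, bounds_error=False, fill_value=None
        )

    def _disp(self, pts: np.ndarray) -> np.ndarray:
        return self._interp(np.asarray(pts, dtype=float))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts + self._disp(pts)

    def inverse_apply(
        self, pts: np.ndarray, max_iter: int = 50, tol: float = 1e-6
    ) -> np.ndarray:
        """Fixed-point inversion ``x_{k+1} = y - d(x_k)``; fails loudly on divergence."""
        y = np.asarray(pts, dtype=float)
        x = y.copy()
        for _ in range(max_iter):
            x_new = y - self._disp(x)
            err = np.max(np.linalg.norm(x_new - x, axis=-1)) if x.size else 0.0
            x = x_new
            if err < tol:
                return x
        raise ValueError(
            "displacement field is not numerically invertible within tolerance"
        )


@dataclass
class TransformChain:
    """Ordered transform chain with optional per-section leading transforms.

    ``section_transforms[s]`` (if given) maps the section frame of section
    ``s`` to the frame the global transforms start from; ``global_transforms``
    are then applied in list order.
    """

    global_transforms: list = field(default_factory=list)
    section_transforms: dict[int, object] | None = None

    @classmethod
    def identity(cls) -> "TransformChain":
        return cls([], None)

    def _for_section(self, section: int | None) -> list:
        chain = []
        if self.section_transforms is not None:
            if section is None or section not in self.section_transforms:
                raise KeyError(f"chain has no transform for section {section!r}")
            chain.append(self.section_transforms[section])
        chain.extend(self.global_transforms)
        return chain

    def covers_section(self, section: int) -> bool:
        return self.section_transforms is None or section in self.section_transforms

    def apply(self, pts: np.ndarray, section: int | None = None) -> np.ndarray:
        out = np.asarray(pts, dtype=float)
        for t in self._for_section(section):
            out = t.apply(out)
        return out

    def inverse_apply(self, pts: np.ndarray, section: int | None = None) -> np.ndarray:
        out = np.asarray(pts, dtype=float)
        for t in reversed(self._for_section(section)):
            out = t.inverse_apply(out)
        return out

    def appended(self, transform) -> "TransformChain":
        """A new chain with ``transform`` applied after the existing ones."""
        return TransformChain(
            list(self.global_transforms) + [transform], self.section_transforms
        )
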