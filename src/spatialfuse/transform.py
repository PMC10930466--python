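"""2D affine transforms between modality frames.

Every registered modality carries one :class:`AffineTransform` mapping its
native pixel (or micron) coordinates into the shared reference frame — the
transcriptomics chip micron coordinate system. The linear part must be
invertible so that label rasters can be resampled by inverse mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateTransformError(ValueError):
    """Raised when an affine fit or inversion is singular."""


@dataclass(frozen=True)
class AffineTransform:
    """A 2x3 affine map ``(x, y) -> A @ (x, y) + t``.

    ``matrix`` is the full 2x3 coefficient array ``[A | t]`` acting on column
    vectors; points are passed as ``(n, 2)`` arrays of ``(x, y)``.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2, 3))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise DegenerateTransformError("linear part is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2, 3))

    @classmethod
    def from_params(
        cls,
        scale: float = 1.0,
        rotation_deg: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform":
        """Similarity transform: rotate by ``rotation_deg``, scale, translate."""
        th = np.deg2rad(rotation_deg)
        c, s = np.cos(th), np.sin(th)
        lin = scale * np.array([[c, -s], [s, c]])
        return cls(np.column_stack([lin, np.asarray(translation, dtype=float)]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` (or ``(2,)``) source points into the target frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:, :2].T + self.matrix[:, 2]
        return out[0] if np.ndim(points) == 1 else out

    def inverse(self) -> "AffineTransform":
        lin = self.matrix[:, :2]
        inv = np.linalg.inv(lin)
        t = -inv @ self.matrix[:, 2]
        return AffineTransform(np.column_stack([inv, t]))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        lin = self.matrix[:, :2] @ other.matrix[:, :2]
        t = self.matrix[:, :2] @ other.matrix[:, 2] + self.matrix[:, 2]
        return AffineTransform(np.column_stack([lin, t]))

    def to_json_dict(self) -> dict:
        return {"matrix": self.matrix.tolist()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.asarray(d["matrix"], dtype=float))
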