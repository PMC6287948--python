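"""The 4D dynamic series container.

Axis convention used throughout the package: ``x`` = left→right,
``y`` = ventral→dorsal (increasing toward the back), ``z`` = cranio→caudal
(increasing toward the lung base).  Signal arrays are indexed ``(x, y, z, t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class DynamicSeries:
    """A 4D dynamic contrast-enhanced signal volume.

    Parameters
    ----------
    data
        Signal array of shape ``(nx, ny, nz, nt)``; non-negative.
    dt_s
        Frame interval in seconds (constant frame spacing).
    voxel_size_mm
        Per-axis voxel spacing ``(dx, dy, dz)`` in millimetres.
    lung_mask, trunk_mask
        Optional boolean masks of the lung parenchyma and the pulmonary
        trunk (absent for real data until segmented).
    region_labels
        Optional integer label map of lung regions (0 = outside).
    """

    data: np.ndarray
    dt_s: float
    voxel_size_mm: tuple[float, float, float] = (9.0, 9.0, 15.0)
    lung_mask: np.ndarray | None = None
    trunk_mask: np.ndarray | None = None
    region_labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError(
                f"dynamic series must be 4D (x,y,z,t), got {self.data.ndim}D"
            )
        if self.dt_s <= 0:
            raise ValidationError("frame interval dt_s must be positive")
        if np.any(self.data < 0):
            raise ValidationError("signal must be non-negative")
        for m in (self.lung_mask, self.trunk_mask):
            if m is not None and m.shape != self.data.shape[:3]:
                raise ValidationError("mask shape does not match volume shape")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def frame_times_s(self) -> np.ndarray:
        """Mid-frame acquisition times (strictly increasing, spacing dt_s)."""
        return (np.arange(self.n_frames) + 0.5) * self.dt_s

    @property
    def duration_s(self) -> float:
        """Total time span covered by the acquisition."""
        return self.n_frames * self.dt_s

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


def validate_mask(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    """Coerce a label/mask array to boolean, rejecting values outside {0, 1}."""
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError(f"{name} contains labels outside {{0, 1}}: {vals[:8]}")
    return arr.astype(bool)
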