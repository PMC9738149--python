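"""Core data containers: 4D BOLD series, binary VOI masks, rigid transforms."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

VALID_TISSUES = ("placenta", "brain", "fluid")


@dataclass
class BoldSeries:
    """A 4D BOLD acquisition: intensity array (x, y, z, t) plus geometry.

    Parameters
    ----------
    data
        Real-valued 4D array, axes (x, y, z, t). Arbitrary intensity units.
    voxel_size_mm
        In-plane and through-plane voxel dimensions.
    tr_seconds
        Repetition time between consecutive frames.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr_seconds: float = 2.28

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, t), got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise ValueError(f"need at least 2 frames, got t={self.data.shape[3]}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be 3 positive reals, got {self.voxel_size_mm}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.tr_seconds

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return replace(self, data=data)


@dataclass
class VoiMask:
    """A binary 3D volume of interest on the series' spatial grid."""

    data: np.ndarray
    label: str = "placenta"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        if self.label not in VALID_TISSUES:
            raise ValueError(f"label must be one of {VALID_TISSUES}, got {self.label!r}")
        if not self.data.any():
            raise ValueError(f"mask {self.label!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid motion of one axial slice of one frame.

    ``(dx, dy)`` is a translation in voxels along the first two array axes,
    ``theta`` a counter-clockwise rotation in degrees about the slice centre.
    The forward map rotates first, then translates.
    """

    frame_index: int
    slice_index: int
    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "theta"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def is_identity(self) -> bool:
        return self.dx == 0.0 and self.dy == 0.0 and self.theta == 0.0


def transforms_as_array(
    transforms: Sequence[Sequence[RigidTransform]] | np.ndarray,
    n_frames: int,
    n_slices: int,
) -> np.ndarray:
    """Normalise a transform collection to a float array of shape (t, z, 3)."""
    if isinstance(transforms, np.ndarray):
        arr = np.asarray(transforms, dtype=float)
        if arr.shape != (n_frames, n_slices, 3):
            raise ValueError(
                f"transform array shape {arr.shape} != expected {(n_frames, n_slices, 3)}"
            )
        return arr
    if len(transforms) != n_frames:
        raise ValueError(f"got {len(transforms)} frame transform lists, expected {n_frames}")
    arr = np.zeros((n_frames, n_slices, 3))
    for frame in transforms:
        for tf in frame:
            arr[tf.frame_index, tf.slice_index] = (tf.dx, tf.dy, tf.theta)
    return arr
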