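"""Core image containers: PET volumes, binary masks, and analysis ROIs.

All grids are 3-D arrays indexed ``(x, y, z)`` with physical voxel spacing
in millimetres. SUV (standardized uptake value) is the intensity unit of
every :class:`PETVolume`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

Triple = tuple[float, float, float]


def _as_triple(x) -> Triple:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected a length-3 sequence, got {x!r}")
    return t  # type: ignore[return-value]


@dataclass
class PETVolume:
    """A 3-D grid of SUV values with physical voxel spacing (mm)."""

    values: np.ndarray
    spacing: Triple
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("PETVolume requires a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PETVolume values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be nonnegative")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class SegmentationMask:
    """A binary field on a PET grid; either the truth or a prediction.

    ``meta`` carries provenance (algorithm, parameters, degeneracy flags)
    so that non-exceptional failure modes, e.g. an empty active-contour
    result, stay inspectable without breaking the pipeline.
    """

    values: np.ndarray
    spacing: Triple
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError("SegmentationMask requires a 3-D array")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be binary, found {uniq[:5]}")
            arr = arr.astype(bool)
        self.values = arr
        self.spacing = _as_triple(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        """Total grid voxel count (not the foreground count)."""
        return int(self.values.size)

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class AnalysisROI:
    """A half-open voxel-index bounding box localizing the tumor neighborhood."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.start = tuple(int(v) for v in self.start)  # type: ignore[assignment]
        self.stop = tuple(int(v) for v in self.stop)  # type: ignore[assignment]
        if len(self.start) != 3 or len(self.stop) != 3:
            raise ValueError("ROI start/stop must be voxel-index triples")
        if any(b <= a for a, b in zip(self.start, self.stop)):
            raise ValueError("ROI must be nonempty on every axis")
        if any(a < 0 for a in self.start):
            raise ValueError("ROI start indices must be nonnegative")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))  # type: ignore[return-value]

    def check_within(self, shape: tuple[int, int, int]) -> None:
        if any(b > s for b, s in zip(self.stop, shape)):
            raise ValueError(f"ROI {self.start}..{self.stop} exceeds grid {shape}")

    def embed(self, sub: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
        """Place an ROI-shaped binary field into a full-grid array."""
        out = np.zeros(shape, dtype=bool)
        out[self.slices()] = sub
        return out
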