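"""Clinical task quantities: metabolic tumor volume and total lesion glycolysis.

MTV is the physical volume of the segmented region in mL; TLG is MTV
times the mean SUV inside the region, reported in grams under the usual
SUV ~ g/mL density identification. These are the standard clinical
definitions, with no partial-volume or sub-voxel surface correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from petseval.core import PETVolume, SegmentationMask


@dataclass
class QuantMetrics:
    mtv: float  # mL
    tlg: float  # g
    suv_mean: float  # SUV; NaN for an empty mask
    n_mask_voxels: int


def compute_mtv(mask: SegmentationMask) -> float:
    """Foreground voxel count times voxel volume, in mL."""
    return mask.n_foreground * mask.voxel_volume_mm3 / 1000.0


def compute_tlg(mask: SegmentationMask, volume: PETVolume) -> float:
    """MTV times mean SUV over the foreground, in g; 0 for an empty mask."""
    if not mask.same_grid(volume):
        raise ValueError(
            f"mask grid {mask.shape}/{mask.spacing} does not match "
            f"volume grid {volume.shape}/{volume.spacing}"
        )
    if mask.n_foreground == 0:
        return 0.0
    suv_mean = float(volume.values[mask.values].mean())
    return compute_mtv(mask) * suv_mean


def quantify(mask: SegmentationMask, volume: PETVolume) -> QuantMetrics:
    """Compute MTV, TLG, and supporting statistics for one segmentation."""
    if not mask.same_grid(volume):
        raise ValueError("mask and volume grids do not match")
    n = mask.n_foreground
    mtv = compute_mtv(mask)
    if n == 0:
        return QuantMetrics(mtv=0.0, tlg=0.0, suv_mean=math.nan, n_mask_voxels=0)
    suv_mean = float(volume.values[mask.values].mean())
    return QuantMetrics(mtv=mtv, tlg=mtv * suv_mean, suv_mean=suv_mean, n_mask_voxels=n)
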