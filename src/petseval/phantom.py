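"""Synthetic PET cohort generation with known tumor truth.

Each phantom is a piecewise activity map — a uniform background plus a
tumor of configurable shape, mean uptake, and intratumor texture — imaged
through a Gaussian point-spread function (PSF) with additive Gaussian
noise in SUV space. The ground-truth mask is the pre-blur tumor support,
so the true metabolic tumor volume (MTV) and total lesion glycolysis
(TLG) are known exactly; that exactness is the entire point of simulating
rather than relying on expert delineations as surrogate truth.

The noise model is deliberately image-domain (no sinogram/reconstruction
simulation): the study questions concern segmentation and quantification
downstream of reconstruction, and the PSF width / noise level / voxel
grid triple is what distinguishes one simulated "scanner" from another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from petseval.core import PETVolume, SegmentationMask, Triple

_AXIS_NAMES = ("x", "y", "z")
#: FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PhantomSpec:
    """Parameters for one synthetic patient on one simulated scanner.

    ``equivalent_diameter`` is the diameter (mm) of the sphere with the
    same volume as the tumor; for the ``lumpy`` shape it sizes the core
    sphere to which seeded satellite lumps are added.
    """

    tumor_shape: str = "sphere"  # sphere | ellipsoid | lumpy
    equivalent_diameter: float = 25.0  # mm
    tumor_suv_mean: float = 6.0
    background_suv: float = 1.0
    intratumor_texture_sd: float = 0.0  # SUV
    psf_fwhm: Triple = (7.0, 7.0, 7.0)  # mm
    noise_sd: float = 0.0  # SUV
    voxel_spacing: Triple = (4.0, 4.0, 4.0)  # mm
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_shape not in ("sphere", "ellipsoid", "lumpy"):
            raise ValueError(f"unknown tumor_shape {self.tumor_shape!r}")
        if self.equivalent_diameter <= 0:
            raise ValueError("equivalent_diameter must be > 0")
        if self.background_suv < 0:
            raise ValueError("background_suv must be >= 0")
        if self.tumor_suv_mean <= self.background_suv:
            raise ValueError("tumor_suv_mean must exceed background_suv")
        if np.isscalar(self.psf_fwhm):
            self.psf_fwhm = (float(self.psf_fwhm),) * 3  # type: ignore[assignment]
        else:
            self.psf_fwhm = tuple(float(v) for v in self.psf_fwhm)  # type: ignore[assignment]
        if any(f < 0 for f in self.psf_fwhm):
            raise ValueError("psf_fwhm must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.intratumor_texture_sd < 0:
            raise ValueError("intratumor_texture_sd must be >= 0")
        self.voxel_spacing = tuple(float(v) for v in self.voxel_spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        self.grid_shape = tuple(int(v) for v in self.grid_shape)  # type: ignore[assignment]
        if any(g < 4 for g in self.grid_shape):
            raise ValueError("grid_shape must be at least 4 voxels per axis")


@dataclass
class PhantomRecord:
    """One synthetic patient: image, truth mask, and exact truth values."""

    case_id: str
    volume: PETVolume
    truth_mask: SegmentationMask
    true_mtv: float  # mL
    true_tlg: float  # g
    spec: PhantomSpec
    scanner_id: str = "scanner0"


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, stream]))


def _voxel_centers(spec: PhantomSpec):
    """Physical coordinates (mm) of voxel centers along each axis."""
    return [
        (np.arange(n) + 0.5) * sp
        for n, sp in zip(spec.grid_shape, spec.voxel_spacing)
    ]


def _check_fits(spec: PhantomSpec, center: np.ndarray, extent: np.ndarray) -> None:
    """Require the tumor plus a 2-voxel margin inside the grid."""
    for ax in range(3):
        margin = 2.0 * spec.voxel_spacing[ax]
        lo = center[ax] - extent[ax] - margin
        hi = center[ax] + extent[ax] + margin
        size = spec.grid_shape[ax] * spec.voxel_spacing[ax]
        if lo < 0 or hi > size:
            raise ValueError(
                f"tumor (extent {extent[ax]:.1f} mm) extends beyond the grid "
                f"along the {_AXIS_NAMES[ax]} axis (grid {size:.1f} mm)"
            )


def generate_tumor_mask(spec: PhantomSpec) -> SegmentationMask:
    """Voxelize the tumor support defined by ``spec``.

    The mask is the set of voxels whose centers fall inside the analytic
    shape. Shapes are centered at the grid center with a seeded sub-voxel
    jitter so that cohorts sample different partial-volume phases.
    """
    rng = _rng(spec.seed, 0)
    r_eq = spec.equivalent_diameter / 2.0
    grid_mm = np.array(spec.grid_shape) * np.array(spec.voxel_spacing)
    center = grid_mm / 2.0 + rng.uniform(-0.5, 0.5, 3) * np.array(spec.voxel_spacing)

    ax_x, ax_y, ax_z = _voxel_centers(spec)
    X = ax_x[:, None, None]
    Y = ax_y[None, :, None]
    Z = ax_z[None, None, :]

    if spec.tumor_shape == "sphere":
        extent = np.array([r_eq] * 3)
        _check_fits(spec, center, extent)
        inside = (
            (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
            <= r_eq**2
        )
    elif spec.tumor_shape == "ellipsoid":
        # seeded axis ratios with geometric mean 1 -> volume preserved
        logr = rng.uniform(-0.35, 0.35, 3)
        logr -= logr.mean()
        semi = r_eq * np.exp(logr)
        _check_fits(spec, center, semi)
        inside = (
            ((X - center[0]) / semi[0]) ** 2
            + ((Y - center[1]) / semi[1]) ** 2
            + ((Z - center[2]) / semi[2]) ** 2
            <= 1.0
        )
    else:  # lumpy: core sphere plus seeded surface lumps
        r_core = 0.85 * r_eq
        n_lumps = int(rng.integers(3, 6))
        lump_r = rng.uniform(0.3, 0.5, n_lumps) * r_core
        dirs = rng.normal(size=(n_lumps, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        lump_c = center + dirs * r_core
        extent = np.array([r_core + lump_r.max()] * 3)
        _check_fits(spec, center, extent)
        inside = (
            (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
            <= r_core**2
        )
        for c, r in zip(lump_c, lump_r):
            inside |= (
                (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r**2
            )

    if not inside.any():
        raise ValueError("tumor support voxelized to an empty mask; diameter too small for the grid spacing")
    return SegmentationMask(inside, spec.voxel_spacing, meta={"shape": spec.tumor_shape})


def _activity_map(spec: PhantomSpec, truth: SegmentationMask) -> np.ndarray:
    """Noiseless, unblurred activity: background + tumor + seeded texture.

    Texture is a smoothed Gaussian random field restricted to the tumor,
    rescaled to the requested SD and clipped so activity stays above
    background (a tumor colder than its surround is out of scope here).
    """
    act = np.full(spec.grid_shape, spec.background_suv, dtype=np.float64)
    act[truth.values] = spec.tumor_suv_mean
    if spec.intratumor_texture_sd > 0 and truth.values.any():
        rng = _rng(spec.seed, 1)
        field_ = rng.normal(size=spec.grid_shape)
        field_ = gaussian_filter(field_, sigma=1.5, mode="wrap")
        vals = field_[truth.values]
        sd = vals.std()
        if sd > 0:
            vals = (vals - vals.mean()) / sd * spec.intratumor_texture_sd
        floor = spec.background_suv - spec.tumor_suv_mean  # keep tumor >= background
        act[truth.values] = spec.tumor_suv_mean + np.maximum(vals, floor)
    return act


def render_pet_volume(spec: PhantomSpec, truth: SegmentationMask) -> PETVolume:
    """Image the activity map: Gaussian PSF blur, additive noise, clip at 0.

    Deterministic given ``spec.seed``. Blur uses edge replication so a
    uniform background is preserved and, for tumors away from the grid
    edge, the total activity sum is conserved.
    """
    if truth.shape != spec.grid_shape:
        raise ValueError(
            f"truth grid {truth.shape} does not match spec grid {spec.grid_shape}"
        )
    act = _activity_map(spec, truth)
    sigma_vox = [
        f * FWHM_TO_SIGMA / sp for f, sp in zip(spec.psf_fwhm, spec.voxel_spacing)
    ]
    blurred = gaussian_filter(act, sigma=sigma_vox, mode="nearest") if any(
        s > 0 for s in sigma_vox
    ) else act
    if spec.noise_sd > 0:
        noise = _rng(spec.seed, 2).normal(0.0, spec.noise_sd, spec.grid_shape)
        blurred = blurred + noise
    return PETVolume(np.clip(blurred, 0.0, None), spec.voxel_spacing)


def make_record(spec: PhantomSpec, case_id: str = "case0", scanner_id: str = "scanner0") -> PhantomRecord:
    """Generate mask, image, and exact truth values for one spec.

    True MTV is the voxel count of the truth mask times the voxel volume;
    true TLG is MTV times the mean noiseless pre-blur SUV inside the mask.
    """
    truth = generate_tumor_mask(spec)
    volume = render_pet_volume(spec, truth)
    voxvol_ml = float(np.prod(spec.voxel_spacing)) / 1000.0
    true_mtv = truth.n_foreground * voxvol_ml
    act = _activity_map(spec, truth)
    true_suv_mean = float(act[truth.values].mean())
    true_tlg = true_mtv * true_suv_mean
    return PhantomRecord(
        case_id=case_id,
        volume=volume,
        truth_mask=truth,
        true_mtv=true_mtv,
        true_tlg=true_tlg,
        spec=spec,
        scanner_id=scanner_id,
    )


@dataclass
class ScannerConfig:
    """One simulated scanner: PSF width, noise level, and voxel grid."""

    scanner_id: str
    psf_fwhm: Triple = (7.0, 7.0, 7.0)
    noise_sd: float = 0.3
    voxel_spacing: Triple = (4.0, 4.0, 4.0)
    grid_shape: tuple[int, int, int] = (64, 64, 48)

    def __post_init__(self) -> None:
        if np.isscalar(self.psf_fwhm):
            self.psf_fwhm = (float(self.psf_fwhm),) * 3  # type: ignore[assignment]


@dataclass
class PopulationConfig:
    """Distributions the tumor population is drawn from.

    Diameters follow a truncated lognormal (median ``diameter_median_mm``,
    log-SD ``diameter_log_sd``); tumor uptake a lognormal around
    ``tumor_suv_median``; background uniform on ``background_suv_range``.
    ``texture_fraction`` sets the intratumor texture SD as a fraction of
    the tumor-background contrast.
    """

    diameter_median_mm: float = 25.0
    diameter_log_sd: float = 0.35
    diameter_range_mm: tuple[float, float] = (12.0, 60.0)
    tumor_suv_median: float = 6.0
    tumor_suv_log_sd: float = 0.3
    background_suv_range: tuple[float, float] = (0.8, 1.5)
    texture_fraction: float = 0.1
    shape_probs: dict = field(
        default_factory=lambda: {"sphere": 0.5, "ellipsoid": 0.3, "lumpy": 0.2}
    )

    def __post_init__(self) -> None:
        total = sum(self.shape_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("shape_probs must sum to 1")


def generate_cohort(
    n: int,
    population: PopulationConfig,
    scanners: Sequence[ScannerConfig],
    seed: int,
) -> list[PhantomRecord]:
    """Draw ``n`` phantom patients, assigning scanners round-robin.

    The cohort is a pure function of ``(n, population, scanners, seed)``:
    each case gets an independent child seed spawned from ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    scanners = list(scanners)
    if not scanners:
        raise ValueError("at least one scanner config is required")
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(n)
    records: list[PhantomRecord] = []
    shapes = sorted(population.shape_probs)
    probs = np.array([population.shape_probs[s] for s in shapes])
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        case_seed = int(rng.integers(0, 2**31 - 1))
        scanner = scanners[i % len(scanners)]
        d = float(
            np.clip(
                population.diameter_median_mm
                * np.exp(rng.normal(0.0, population.diameter_log_sd)),
                *population.diameter_range_mm,
            )
        )
        bg = float(rng.uniform(*population.background_suv_range))
        tumor = float(
            population.tumor_suv_median * np.exp(rng.normal(0.0, population.tumor_suv_log_sd))
        )
        tumor = max(tumor, bg * 1.5 + 0.5)  # keep a measurable contrast
        shape = str(rng.choice(shapes, p=probs))
        spec = PhantomSpec(
            tumor_shape=shape,
            equivalent_diameter=d,
            tumor_suv_mean=tumor,
            background_suv=bg,
            intratumor_texture_sd=population.texture_fraction * (tumor - bg),
            psf_fwhm=scanner.psf_fwhm,
            noise_sd=scanner.noise_sd,
            voxel_spacing=scanner.voxel_spacing,
            grid_shape=scanner.grid_shape,
            seed=case_seed,
        )
        records.append(
            make_record(spec, case_id=f"case{i:04d}", scanner_id=scanner.scanner_id)
        )
    return records
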