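"""Conventional PET tumor-segmentation algorithms.

Three families, one representative each:

* thresholding — fixed-fraction SUVmax: keep voxels at or above a fixed
  fraction of the ROI maximum (40% and 50% are the clinical standards);
* boundary detection — Snakes, here a region-based morphological
  Chan-Vese active contour run per axial slice;
* stochastic modeling — a two-class Gaussian mixture over ROI
  intensities with a Potts Markov-random-field smoothness prior,
  fitted by EM with iterated-conditional-modes label updates.

Every algorithm operates inside an analysis ROI (the clinician-localized
tumor neighborhood; in simulation, the truth bounding box dilated by a
margin so the true boundary itself is not leaked) and returns a mask
that is a single 26-connected component within that ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import disk_level_set, morphological_chan_vese

from petseval.core import AnalysisROI, PETVolume, SegmentationMask

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def roi_from_mask(mask: SegmentationMask, margin: int = 8) -> AnalysisROI:
    """Truth bounding box dilated by ``margin`` voxels, clipped to the grid."""
    if mask.n_foreground == 0:
        raise ValueError("cannot build an ROI from an empty mask")
    idx = np.argwhere(mask.values)
    start = np.maximum(idx.min(axis=0) - margin, 0)
    stop = np.minimum(idx.max(axis=0) + 1 + margin, mask.shape)
    return AnalysisROI(tuple(start), tuple(stop))


def _component_containing_max(binary: np.ndarray, intensities: np.ndarray) -> np.ndarray:
    """26-connected component containing the max-intensity voxel.

    Ties on the maximum break by C scan order (first flat index), making
    the reduction deterministic.
    """
    if not binary.any():
        return binary
    labels, _ = ndimage.label(binary, structure=_STRUCT26)
    masked = np.where(binary, intensities, -np.inf)
    peak = np.unravel_index(int(np.argmax(masked)), binary.shape)
    return labels == labels[peak]


def _largest_component(binary: np.ndarray) -> np.ndarray:
    if not binary.any():
        return binary
    labels, n = ndimage.label(binary, structure=_STRUCT26)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def segment_suvmax_threshold(
    volume: PETVolume, roi: AnalysisROI, fraction: float
) -> SegmentationMask:
    """Fixed-fraction SUVmax thresholding inside the ROI.

    Threshold = ``fraction`` x max SUV in the ROI; voxels with
    SUV >= threshold are kept (>= so that fraction 1.0 retains the
    SUVmax voxel itself), then reduced to the 26-connected component
    containing the max-SUV voxel.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    roi.check_within(volume.shape)
    sub = volume.values[roi.slices()]
    suv_max = float(sub.max())
    if suv_max <= 0:
        raise ValueError("no signal in ROI")
    thresholded = sub >= fraction * suv_max
    kept = _component_containing_max(thresholded, sub)
    return SegmentationMask(
        roi.embed(kept, volume.shape),
        volume.spacing,
        meta={
            "algorithm": "suvmax_threshold",
            "fraction": fraction,
            "threshold_suv": fraction * suv_max,
        },
    )


@dataclass
class SnakesParams:
    iterations: int = 100
    smoothing: int = 1
    init_radius: float = 3.0  # voxels
    lambda1: float = 1.0
    lambda2: float = 1.0
    #: skip slices whose in-ROI max is below this fraction of the global
    #: ROI max; keeps the contour off pure-background and blur-halo slices
    min_slice_fraction: float = 0.5


def segment_snakes(
    volume: PETVolume, roi: AnalysisROI, params: SnakesParams | None = None
) -> SegmentationMask:
    """Per-slice morphological Chan-Vese active contour, stacked to 3-D.

    Each axial slice of the ROI is segmented by evolving a disk
    initialized at the in-slice maximum; the bright phase is taken as
    tumor. Slice results are unioned and reduced to the largest
    26-connected component. A degenerate (empty) evolution is flagged in
    the mask's ``meta`` rather than raised: on a contrast-free image no
    boundary exists for a region-based contour to find.
    """
    params = params or SnakesParams()
    roi.check_within(volume.shape)
    sub = volume.values[roi.slices()]
    global_max = float(sub.max())
    out = np.zeros_like(sub, dtype=bool)
    if global_max > 0 and sub.std() > 1e-12:
        for z in range(sub.shape[2]):
            img = sub[:, :, z]
            if float(img.max()) < params.min_slice_fraction * global_max:
                continue
            peak = np.unravel_index(int(np.argmax(img)), img.shape)
            init = disk_level_set(img.shape, center=peak, radius=params.init_radius)
            ls = morphological_chan_vese(
                img,
                num_iter=params.iterations,
                init_level_set=init,
                smoothing=params.smoothing,
                lambda1=params.lambda1,
                lambda2=params.lambda2,
            ).astype(bool)
            if not ls.any() or ls.all():
                continue
            # orient to the bright phase
            if img[ls].mean() < img[~ls].mean():
                ls = ~ls
            # keep the in-slice component grown from the initialization peak
            if ls[peak]:
                lab, _ = ndimage.label(ls, structure=np.ones((3, 3), dtype=bool))
                ls = lab == lab[peak]
            out[:, :, z] = ls
    kept = _largest_component(out)
    meta = {"algorithm": "snakes", "iterations": params.iterations}
    if not kept.any():
        meta["degenerate"] = True
    return SegmentationMask(roi.embed(kept, volume.shape), volume.spacing, meta=meta)


@dataclass
class MRFGMMParams:
    beta: float = 0.7  # Potts interaction strength
    max_iter: int = 50
    tol: float = 1e-5
    icm_sweeps: int = 4
    var_floor: float = 1e-10


def _gmm_log_likelihoods(x: np.ndarray, mu, sd, pi) -> np.ndarray:
    """Per-voxel log pi_k + log N(x | mu_k, sd_k), stacked on axis 0."""
    ll = np.empty((2,) + x.shape)
    for k in range(2):
        ll[k] = (
            np.log(pi[k])
            - 0.5 * np.log(2 * np.pi * sd[k] ** 2)
            - 0.5 * ((x - mu[k]) / sd[k]) ** 2
        )
    return ll


def _neighbor_votes(labels: np.ndarray) -> np.ndarray:
    """Count of 6-neighbors carrying each label, per voxel (axis 0 = class)."""
    votes = np.zeros((2,) + labels.shape)
    for k in range(2):
        ind = (labels == k).astype(np.float64)
        acc = np.zeros_like(ind)
        for ax in range(3):
            for shift in (1, -1):
                acc += np.roll(ind, shift, axis=ax)
        # undo wraparound at the faces
        for ax in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = 0
            sl_hi[ax] = -1
            acc[tuple(sl_lo)] -= np.take(ind, -1, axis=ax)
            acc[tuple(sl_hi)] -= np.take(ind, 0, axis=ax)
        votes[k] = acc
    return votes


def segment_mrf_gmm(
    volume: PETVolume, roi: AnalysisROI, params: MRFGMMParams | None = None
) -> SegmentationMask:
    """Two-class MRF-GMM segmentation of the ROI.

    Model: intensities are a two-component Gaussian mixture; labels carry
    a Potts prior of strength ``beta`` on the 6-neighborhood. Fitting
    alternates EM parameter updates (responsibilities modulated by the
    current label field's neighbor votes) with ICM label updates on a
    checkerboard schedule. Initialization is a median split of the ROI
    intensities, making the whole procedure deterministic. With
    ``beta = 0`` the spatial term vanishes and the fit reduces exactly
    to a plain EM Gaussian mixture.

    The tumor is the higher-mean class, reduced to the 26-connected
    component containing the max-SUV voxel.
    """
    params = params or MRFGMMParams()
    if params.tol <= 0:
        raise ValueError("tol must be positive")
    roi.check_within(volume.shape)
    x = volume.values[roi.slices()].astype(np.float64)
    if np.unique(x).size < 2:
        raise ValueError("ROI intensities are constant; two classes are inseparable")

    def _init(jitter: float):
        # deterministic scalar 2-means split: centers start at the 1st and
        # 99th intensity percentiles so a small tumor in a large ROI still
        # seeds the bright class (a plain median split would place both
        # centers inside the background)
        c = np.percentile(x, [1.0, 99.0])
        if c[0] == c[1]:
            c = np.array([x.min(), x.max()], dtype=np.float64)
        for _ in range(50):
            labels = (np.abs(x - c[1]) < np.abs(x - c[0])).astype(np.int8)
            if labels.min() == labels.max():
                labels = (x > x.mean()).astype(np.int8)
            c_new = np.array([x[labels == 0].mean(), x[labels == 1].mean()])
            if np.allclose(c_new, c):
                c = c_new
                break
            c = c_new
        mu = np.array([x[labels == 0].mean(), x[labels == 1].mean()])
        sd = np.array(
            [max(x[labels == k].std(), 1e-3) for k in (0, 1)], dtype=np.float64
        )
        if jitter:
            rng = np.random.default_rng(0)
            mu = mu + rng.normal(0, jitter * (mu[1] - mu[0] + 1e-6), 2)
        pi = np.array([(labels == 0).mean(), (labels == 1).mean()])
        pi = np.clip(pi, 1e-6, None)
        return labels, mu, sd, pi / pi.sum()

    for attempt, jitter in enumerate((0.0, 0.05)):
        labels, mu, sd, pi = _init(jitter)
        collapsed = False
        for _ in range(params.max_iter):
            votes = _neighbor_votes(labels) if params.beta != 0 else 0.0
            ll = _gmm_log_likelihoods(x, mu, sd, pi) + params.beta * votes
            ll -= ll.max(axis=0, keepdims=True)
            resp = np.exp(ll)
            resp /= resp.sum(axis=0, keepdims=True)
            # M-step; variances are regularized against point-mass
            # singularities (the SUV clip at 0 can create an exact spike)
            nk = resp.sum(axis=(1, 2, 3))
            if np.any(nk < 1.0):
                collapsed = True
                break
            mu_new = (resp * x).sum(axis=(1, 2, 3)) / nk
            var_new = ((resp * (x - mu_new.reshape(2, 1, 1, 1)) ** 2).sum(axis=(1, 2, 3)) / nk)
            if np.any(var_new < params.var_floor):
                collapsed = True
                break
            var_new = var_new + 1e-6 * float(x.var())
            sd_new = np.sqrt(var_new)
            pi_new = nk / nk.sum()
            shift = float(np.abs(mu_new - mu).max())
            mu, sd, pi = mu_new, sd_new, pi_new
            # ICM label updates (checkerboard for determinism + stability)
            if params.beta != 0:
                idx = np.indices(x.shape).sum(axis=0)
                for _s in range(params.icm_sweeps):
                    changed = 0
                    for parity in (0, 1):
                        votes = _neighbor_votes(labels)
                        score = _gmm_log_likelihoods(x, mu, sd, pi) + params.beta * votes
                        new = np.argmax(score, axis=0).astype(np.int8)
                        upd = (idx % 2 == parity) & (new != labels)
                        changed += int(upd.sum())
                        labels[upd] = new[upd]
                    if changed == 0:
                        break
            else:
                labels = np.argmax(resp, axis=0).astype(np.int8)
            if shift < params.tol:
                break
        if not collapsed:
            break
    if collapsed:
        raise ValueError("GMM variance collapse: classes are inseparable in this ROI")

    tumor_class = int(np.argmax(mu))
    tumor = labels == tumor_class
    kept = _component_containing_max(tumor, x) if tumor.any() else tumor
    meta = {
        "algorithm": "mrf_gmm",
        "beta": params.beta,
        "class_means": [float(m) for m in mu],
        "class_sds": [float(s) for s in sd],
    }
    if not kept.any():
        meta["degenerate"] = True
    return SegmentationMask(roi.embed(kept, volume.shape), volume.spacing, meta=meta)
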