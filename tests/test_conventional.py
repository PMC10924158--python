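import numpy as np
import pytest

from petseval.core import AnalysisROI, PETVolume, SegmentationMask
from petseval.conventional import (
    MRFGMMParams,
    SnakesParams,
    roi_from_mask,
    segment_mrf_gmm,
    segment_snakes,
    segment_suvmax_threshold,
)
from petseval.foms import dice_coefficient


def tiny_volume(slice2d, n_slices=1, spacing=(1.0, 1.0, 1.0)):
    arr = np.repeat(np.asarray(slice2d, dtype=float)[:, :, None], n_slices, axis=2)
    return PETVolume(arr, spacing)


class TestSUVmaxThreshold:
    def test_hand_worked_2x2_example(self):
        # max 10 -> threshold 4.0 at 40%; voxels 4 and 10 survive and touch
        vol = tiny_volume([[1, 2], [4, 10]])
        roi = AnalysisROI((0, 0, 0), (2, 2, 1))
        mask = segment_suvmax_threshold(vol, roi, 0.4)
        assert mask.meta["threshold_suv"] == pytest.approx(4.0)
        assert mask.n_foreground == 2
        assert mask.values[1, 0, 0] and mask.values[1, 1, 0]

    def test_uniform_roi_fully_selected(self):
        vol = tiny_volume(np.full((4, 4), 3.0))
        roi = AnalysisROI((0, 0, 0), (4, 4, 1))
        mask = segment_suvmax_threshold(vol, roi, 0.5)
        assert mask.n_foreground == 16

    def test_fraction_one_keeps_only_max(self):
        vol = tiny_volume([[1, 2], [4, 10]])
        roi = AnalysisROI((0, 0, 0), (2, 2, 1))
        mask = segment_suvmax_threshold(vol, roi, 1.0)
        assert mask.n_foreground == 1
        assert mask.values[1, 1, 0]

    def test_invalid_fraction_rejected(self):
        vol = tiny_volume([[1, 2], [4, 10]])
        roi = AnalysisROI((0, 0, 0), (2, 2, 1))
        for f in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                segment_suvmax_threshold(vol, roi, f)

    def test_zero_signal_roi_rejected(self):
        vol = PETVolume(np.zeros((4, 4, 2)), (1, 1, 1))
        roi = AnalysisROI((0, 0, 0), (4, 4, 2))
        with pytest.raises(ValueError, match="no signal"):
            segment_suvmax_threshold(vol, roi, 0.4)

    def test_invariant_to_positive_rescaling(self, noisy_record):
        roi = roi_from_mask(noisy_record.truth_mask, 6)
        m1 = segment_suvmax_threshold(noisy_record.volume, roi, 0.4)
        scaled = PETVolume(noisy_record.volume.values * 3.7, noisy_record.volume.spacing)
        m2 = segment_suvmax_threshold(scaled, roi, 0.4)
        assert np.array_equal(m1.values, m2.values)

    def test_lower_fraction_never_shrinks_mask(self, noisy_record):
        roi = roi_from_mask(noisy_record.truth_mask, 6)
        prev = None
        for f in (0.8, 0.6, 0.5, 0.4, 0.3):
            m = segment_suvmax_threshold(noisy_record.volume, roi, f)
            if prev is not None:
                assert np.all(m.values | ~prev)  # prev subset of m
            prev = m.values

    def test_mask_inside_roi_and_connected(self, noisy_record):
        from scipy import ndimage

        roi = roi_from_mask(noisy_record.truth_mask, 6)
        m = segment_suvmax_threshold(noisy_record.volume, roi, 0.4)
        outside = np.ones(m.shape, dtype=bool)
        outside[roi.slices()] = False
        assert not (m.values & outside).any()
        _, n = ndimage.label(m.values, structure=np.ones((3, 3, 3)))
        assert n == 1


class TestSnakes:
    def test_noiseless_disk_recovered(self, disk_volume):
        vol, truth, roi = disk_volume
        mask = segment_snakes(vol, roi)
        assert dice_coefficient(truth, mask) >= 0.95

    def test_fixed_point_when_initialized_at_truth(self, disk_volume):
        # init disk matches the true radius on a piecewise-constant image:
        # the evolution should stay at the boundary
        vol, truth, roi = disk_volume
        mask = segment_snakes(vol, roi, SnakesParams(init_radius=10.0, iterations=50))
        assert dice_coefficient(truth, mask) >= 0.99

    def test_zero_contrast_flags_degenerate_empty(self):
        vol = PETVolume(np.full((16, 16, 4), 2.0), (1, 1, 1))
        roi = AnalysisROI((0, 0, 0), (16, 16, 4))
        mask = segment_snakes(vol, roi)
        assert mask.n_foreground == 0
        assert mask.meta.get("degenerate") is True


class TestMRFGMM:
    @staticmethod
    def two_class_volume(seed=0, lo=1.0, hi=8.0, sd=0.3, shape=(20, 20, 12)):
        rng = np.random.default_rng(seed)
        truth = np.zeros(shape, dtype=bool)
        truth[6:14, 6:14, 3:9] = True
        vals = np.where(truth, hi, lo) + rng.normal(0, sd, shape)
        return PETVolume(np.clip(vals, 0, None), (1, 1, 1)), truth

    def test_recovers_class_means(self):
        vol, _ = self.two_class_volume()
        roi = AnalysisROI((0, 0, 0), vol.shape)
        mask = segment_mrf_gmm(vol, roi, MRFGMMParams(beta=0.5))
        means = sorted(mask.meta["class_means"])
        assert abs(means[0] - 1.0) / 1.0 < 0.05
        assert abs(means[1] - 8.0) / 8.0 < 0.05

    def test_beta_zero_matches_plain_gmm_oracle(self):
        from sklearn.mixture import GaussianMixture

        vol, _ = self.two_class_volume(seed=3)
        roi = AnalysisROI((0, 0, 0), vol.shape)
        mask = segment_mrf_gmm(vol, roi, MRFGMMParams(beta=0.0))
        x = vol.values.reshape(-1, 1)
        gm = GaussianMixture(2, covariance_type="spherical", random_state=0).fit(x)
        labels = gm.predict(x).reshape(vol.shape)
        tumor_oracle = labels == int(np.argmax(gm.means_.ravel()))
        # compare the full tumor-class field before connectivity reduction:
        # reconstruct it by re-running with the oracle's own reduction
        from scipy import ndimage

        lab, _ = ndimage.label(tumor_oracle, structure=np.ones((3, 3, 3)))
        peak = np.unravel_index(np.argmax(np.where(tumor_oracle, vol.values, -np.inf)), vol.shape)
        oracle_mask = lab == lab[peak]
        agree = (mask.values == oracle_mask).mean()
        assert agree == 1.0

    def test_constant_image_rejected(self):
        vol = PETVolume(np.full((8, 8, 8), 4.0), (1, 1, 1))
        roi = AnalysisROI((0, 0, 0), (8, 8, 8))
        with pytest.raises(ValueError, match="constant|collapse"):
            segment_mrf_gmm(vol, roi)

    def test_invalid_tol_rejected(self):
        vol, _ = self.two_class_volume()
        roi = AnalysisROI((0, 0, 0), vol.shape)
        with pytest.raises(ValueError, match="tol"):
            segment_mrf_gmm(vol, roi, MRFGMMParams(tol=0.0))

    def test_beta_smooths_salt_noise(self):
        # spatial prior should flip isolated misclassified voxels
        vol, truth = self.two_class_volume(seed=9, lo=3.0, hi=10.0, sd=1.2)
        roi = AnalysisROI((0, 0, 0), vol.shape)
        m0 = segment_mrf_gmm(vol, roi, MRFGMMParams(beta=0.0))
        m1 = segment_mrf_gmm(vol, roi, MRFGMMParams(beta=1.0))
        t = SegmentationMask(truth, (1, 1, 1))
        assert dice_coefficient(t, m1) >= dice_coefficient(t, m0)
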