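import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from petseval.unet import (
    UNet2D,
    UNetConfig,
    bce_loss,
    combined_loss,
    dice_loss,
    predict_volume,
    train_on_slices,
    train_unet,
)
from petseval.unet.losses import combined_grad_z
from petseval.unet.model import Adam


class TestLosses:
    def test_perfect_prediction_bce_near_zero(self):
        t = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert bce_loss(t, t) <= 1e-5

    def test_single_voxel_closed_form(self):
        assert bce_loss(np.array([1.0]), np.array([0.5])) == pytest.approx(
            0.6931472, abs=1e-6
        )

    def test_uninformative_half_prediction_is_log2(self):
        rng = np.random.default_rng(0)
        t = (rng.random((5, 5)) > 0.5).astype(float)
        p = np.full((5, 5), 0.5)
        assert bce_loss(t, p) == pytest.approx(np.log(2.0), abs=1e-9)

    def test_dice_zero_at_exact_match(self):
        t = np.array([1.0, 1.0, 0.0])
        assert dice_loss(t, t) == 0.0

    def test_dice_one_at_total_miss(self):
        assert dice_loss(np.ones(4), np.zeros(4)) == pytest.approx(1.0)

    def test_dice_half_overlap(self):
        assert dice_loss(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == pytest.approx(0.5)

    def test_combined_worked_value(self):
        t = np.array([1.0])
        p = np.array([0.5])
        # BCE = 0.693147, Dice = 1 - 2*0.5/(1+0.5) = 1/3 -- combine manually
        lb, ld = bce_loss(t, p), dice_loss(t, p)
        assert combined_loss(t, p, 0.5) == pytest.approx(0.5 * lb + 0.5 * ld, abs=1e-12)
        assert 0.5 * 0.6931472 + 0.5 * 0.5 == pytest.approx(0.5965736, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 2)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2)), np.zeros(4))

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(np.zeros(2), np.zeros(2), 1.2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hnp.arrays(np.float64, (4, 4), elements=st.floats(0, 1)),
        hnp.arrays(np.float64, (4, 4), elements=st.floats(0.01, 0.99)),
    )
    def test_lambda_reductions_exact(self, t, p):
        t = (t > 0.5).astype(float)
        assert combined_loss(t, p, 1.0) == bce_loss(t, p)
        assert combined_loss(t, p, 0.0) == dice_loss(t, p)
        assert 0.0 <= dice_loss(t, p) <= 1.0
        assert bce_loss(t, p) >= 0.0


class TestArchitecture:
    @pytest.mark.parametrize("depth", [2, 3, 4, 5])
    def test_paired_block_and_conv_counts(self, depth):
        net = UNet2D(depth=depth, base_filters=2)
        assert net.n_paired_blocks() == 2 * depth
        assert len(net.conv_layers()) == 5 * depth + 3

    def test_depth_zero_rejected(self):
        with pytest.raises(ValueError):
            UNet2D(depth=0)
        with pytest.raises(ValueError):
            UNetConfig(depth=0)

    def test_indivisible_grid_rejected(self):
        net = UNet2D(depth=3, base_filters=2)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((20, 20)))

    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        net = UNet2D(depth=2, base_filters=2, seed=3)
        x = rng.random((8, 8))
        t = (rng.random((8, 8)) > 0.7).astype(float)
        p = net.forward(x)
        net.backward(combined_grad_z(t, p, 0.6))
        eps = 1e-6
        for li in (0, 4, 9, len(net.conv_layers()) - 1):
            layer = net.conv_layers()[li]
            idx = (layer.W.shape[0] - 1, layer.W.shape[1] - 1)
            orig = layer.W[idx]
            layer.W[idx] = orig + eps
            lp = combined_loss(t, net.forward(x), 0.6)
            layer.W[idx] = orig - eps
            lm = combined_loss(t, net.forward(x), 0.6)
            layer.W[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert layer.dW[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-9)


def _disk_slices(n, rng, size=32):
    imgs, gts = [], []
    for _ in range(n):
        x, y = np.mgrid[:size, :size]
        cx, cy = rng.uniform(10, size - 10, 2)
        r = rng.uniform(4, 8)
        disk = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
        img = 0.15 + 0.85 * disk + rng.normal(0, 0.05, (size, size))
        imgs.append(np.clip(img, 0, None))
        gts.append(disk.astype(float))
    return imgs, gts


class TestTraining:
    def test_training_is_deterministic(self):
        rng = np.random.default_rng(1)
        imgs, gts = _disk_slices(4, rng)
        cfg = UNetConfig(depth=2, base_filters=4, epochs=2, lr=1e-3, folds=2, seed=9)
        m1 = train_on_slices(imgs, gts, cfg)
        m2 = train_on_slices(imgs, gts, cfg)
        for (w1, b1), (w2, b2) in zip(m1.weights(), m2.weights()):
            assert np.array_equal(w1, w2) and np.array_equal(b1, b2)

    def test_loss_decreases_under_adam(self):
        rng = np.random.default_rng(2)
        imgs, gts = _disk_slices(4, rng)
        cfg0 = UNetConfig(depth=2, base_filters=4, epochs=1, dropout_p=0.0, folds=2, seed=5)
        m0 = train_on_slices(imgs, gts, cfg0)
        cfg1 = UNetConfig(depth=2, base_filters=4, epochs=15, dropout_p=0.0, folds=2, seed=5)
        m1 = train_on_slices(imgs, gts, cfg1)
        l0 = np.mean([bce_loss(g, m0.forward(i)) for i, g in zip(imgs, gts)])
        l1 = np.mean([bce_loss(g, m1.forward(i)) for i, g in zip(imgs, gts)])
        assert l1 < l0

    def test_cv_folds_split_by_case_and_report(self):
        from petseval.phantom import PhantomSpec, make_record

        records = [
            make_record(
                PhantomSpec(
                    equivalent_diameter=18.0,
                    tumor_suv_mean=8.0,
                    background_suv=0.5,
                    psf_fwhm=(4.0,) * 3,
                    noise_sd=0.2,
                    voxel_spacing=(3.0, 3.0, 3.0),
                    grid_shape=(32, 32, 16),
                    seed=s,
                ),
                case_id=f"case{s}",
            )
            for s in range(4)
        ]
        cfg = UNetConfig(depth=2, base_filters=4, epochs=3, folds=2, seed=0)
        model, report = train_unet(records, cfg)
        assert len(report.fold_val_dsc) == 2
        all_val = [c for fold in report.fold_cases for c in fold]
        assert sorted(all_val) == sorted(r.case_id for r in records)
        # no case appears in two validation folds
        assert len(set(all_val)) == len(all_val)

    def test_too_few_cases_rejected(self):
        cfg = UNetConfig(depth=2, folds=5)
        with pytest.raises(ValueError, match="fold"):
            train_unet([], cfg)


class TestPredict:
    class _StubModel:
        depth = 2

        def __init__(self, const):
            self.const = const

        def forward(self, x, train=False):
            return np.full(x.shape, self.const)

    def _volume(self):
        from petseval.core import PETVolume

        return PETVolume(np.random.default_rng(0).random((32, 32, 8)) + 0.1, (3, 3, 3))

    def test_output_grids_match_input(self):
        vol = self._volume()
        probs, mask = predict_volume(self._StubModel(0.7), vol)
        assert probs.shape == vol.shape
        assert mask.shape == vol.shape

    def test_constant_low_probability_gives_empty_mask(self):
        _, mask = predict_volume(self._StubModel(0.3), self._volume())
        assert mask.n_foreground == 0

    def test_exact_half_probability_is_foreground(self):
        _, mask = predict_volume(self._StubModel(0.5), self._volume())
        assert mask.n_foreground == mask.n_voxels
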