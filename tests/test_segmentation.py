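import numpy as np
import pytest

from m3mc import segmentation as seg
from m3mc.nn import Adam, Tensor
from m3mc.phantom import PhantomSpec, generate_phantom
from m3mc.segmentation import (
    ARCHITECTURES,
    SegModelConfig,
    SegTrainSpec,
    build_segmentation_model,
    dice_loss,
    one_hot,
    predict_mask,
)
from m3mc.volume_io import Volume3D


@pytest.fixture(scope="module")
def phantom_slice():
    """One 32x32 axial slice through the canal/roots, with labels."""
    v, m, _ = generate_phantom(PhantomSpec(seed=1))
    from m3mc.volume_io import normalize_intensity

    norm = normalize_intensity(v, "minmax").data
    x = norm[16:48, 16:48, 9][None, None]
    y = one_hot(m.labels[16:48, 16:48, 9])[None]
    return x, y


class TestBuildModel:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_output_is_pixelwise_distribution(self, arch, rng):
        model = build_segmentation_model(
            SegModelConfig(architecture=arch, input_size=(32, 32), seed=0)
        )
        out = model(Tensor(rng.normal(size=(2, 1, 32, 32))))
        assert out.shape == (2, 3, 32, 32)
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0, atol=1e-5)

    def test_forward_shape_at_64(self, rng):
        model = build_segmentation_model(SegModelConfig(depth=3, input_size=(64, 64)))
        out = model(Tensor(rng.normal(size=(1, 1, 64, 64))))
        assert out.shape == (1, 3, 64, 64)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SegModelConfig(depth=3, input_size=(60, 64))

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_parameter_count_grows_with_width(self, arch):
        def count(base):
            cfg = SegModelConfig(architecture=arch, base_filters=base, input_size=(32, 32))
            return sum(p.data.size for p in build_segmentation_model(cfg).parameters())

        assert count(8) > count(4)

    def test_pretrained_encoder_not_available(self):
        cfg = SegModelConfig(architecture="dense_unet", pretrained_encoder=True)
        with pytest.raises(NotImplementedError):
            build_segmentation_model(cfg)


class TestDiceLoss:
    def test_perfect_prediction_is_near_zero(self):
        t = np.zeros((1, 3, 2, 2))
        t[0, 0, :, :] = 1
        t[0, 0, 0, 0], t[0, 1, 0, 0] = 0, 1
        assert float(dice_loss(Tensor(t), t).data) < 1e-5

    def test_uniform_prediction_closed_form(self):
        """Uniform 1/3 probabilities vs a 2x2 one-hot target: per-class soft
        Dice is (2 N_c/3)/(N/3 + N_c)."""
        t = np.zeros((1, 3, 2, 2))
        t[0, 0, :, :] = 1  # class 0 owns all 4 pixels
        t[0, 0, 0, 0], t[0, 2, 0, 0] = 0, 1  # except one pixel of class 2
        pred = np.full((1, 3, 2, 2), 1 / 3)
        n = 4
        expected = 1 - np.mean(
            [(2 * nc / 3) / (n / 3 + nc) for nc in (3, 0, 1)]
        )
        assert float(dice_loss(Tensor(pred), t, eps=0).data) == pytest.approx(expected)

    def test_disjoint_hard_predictions_loss_one(self):
        # every class appears, but never at the same pixel in pred and target
        t = np.zeros((1, 3, 2, 2))
        t[0, 0, 0, :] = 1
        t[0, 1, 1, :] = 1
        p = np.zeros((1, 3, 2, 2))
        p[0, 1, 0, :] = 1
        p[0, 2, 1, :] = 1
        assert float(dice_loss(Tensor(p), t).data) == pytest.approx(1.0, abs=1e-6)

    def test_empty_in_both_class_counts_as_perfect(self):
        # a class absent from pred AND target contributes Dice 1, so the
        # perfect-prediction identity holds on masks that lack a structure
        t = np.zeros((1, 3, 2, 2))
        t[0, 0] = 1
        assert float(dice_loss(Tensor(t), t).data) == pytest.approx(0.0, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(Tensor(np.zeros((1, 3, 2, 2))), np.zeros((1, 3, 4, 4)))

    def test_invariant_to_joint_spatial_permutation(self, rng):
        p = rng.dirichlet(np.ones(3), size=(1, 4, 4)).transpose(0, 3, 1, 2)
        t = one_hot(rng.integers(0, 3, size=(4, 4)))[None]
        perm = rng.permutation(16)
        p2 = p.reshape(1, 3, -1)[:, :, perm].reshape(1, 3, 4, 4)
        t2 = t.reshape(1, 3, -1)[:, :, perm].reshape(1, 3, 4, 4)
        assert float(dice_loss(Tensor(p), t).data) == pytest.approx(
            float(dice_loss(Tensor(p2), t2).data)
        )


class TestTraining:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_overfit_one_slice_all_families(self, arch, phantom_slice):
        """Every family memorizes a single slice (guards wiring bugs)."""
        x, y = phantom_slice
        model = build_segmentation_model(
            SegModelConfig(architecture=arch, input_size=(32, 32), seed=0)
        )
        opt = Adam(model.parameters(), lr=5e-3)
        loss = None
        for _ in range(300):
            pred = model(Tensor(x))
            loss = dice_loss(pred, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            if float(loss.data) < 0.04:
                break
        assert float(loss.data) < 0.05

    def test_training_reduces_loss(self):
        v, m, _ = generate_phantom(PhantomSpec(seed=2))
        # train on a thin sub-volume to keep the run short
        sub_v = Volume3D(v.data[16:48, 16:48, 8:12], v.spacing)
        from m3mc.volume_io import MultiClassMask

        sub_m = MultiClassMask(m.labels[16:48, 16:48, 8:12], m.spacing)
        model = build_segmentation_model(SegModelConfig(input_size=(32, 32), seed=0))
        spec = SegTrainSpec(learning_rate=3e-3, max_epochs=6, batch_size=4, seed=0)
        model, history = seg.train_segmentation(model, [(sub_v, sub_m)], spec)
        assert len(history) == 6
        assert history.train_loss.iloc[-1] < history.train_loss.iloc[0]

    def test_empty_dataset_rejected(self):
        model = build_segmentation_model(SegModelConfig(input_size=(32, 32)))
        with pytest.raises(ValueError):
            seg.train_segmentation(model, [], SegTrainSpec(max_epochs=1))


class TestPredictMask:
    def test_shape_and_background_contract(self):
        v, _, _ = generate_phantom(PhantomSpec(seed=3))
        model = build_segmentation_model(SegModelConfig(input_size=(64, 64), seed=0))
        # force the head to predict background everywhere
        model.head.weight.data[:] = 0
        model.head.bias.data[:] = [10.0, 0.0, 0.0]
        out = predict_mask(model, v)
        assert out.shape == v.shape
        assert (out.labels == 0).all()

    def test_grid_mismatch_rejected(self):
        v, _, _ = generate_phantom(PhantomSpec(seed=3))
        model = build_segmentation_model(SegModelConfig(input_size=(32, 32)))
        with pytest.raises(ValueError):
            predict_mask(model, v)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_segmentation_model(SegModelConfig(input_size=(32, 32), seed=0))
        x = rng.normal(size=(1, 1, 32, 32))
        model.set_training(False)
        before = model(Tensor(x)).data
        seg.save_model(model, tmp_path / "snet.npz")
        restored = seg.load_model(tmp_path / "snet.npz")
        restored.set_training(False)
        np.testing.assert_allclose(restored(Tensor(x)).data, before)
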