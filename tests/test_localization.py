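import numpy as np
import pytest

from m3mc.localization import (
    MultichannelInput,
    assemble_channels,
    closest_pair,
    crop_classification_volume,
)
from m3mc.sdm import BinaryMask, compute_sdm
from m3mc.volume_io import MultiClassMask, Volume3D


def mask_with(points1, points2, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
    labels = np.zeros(shape, dtype=int)
    for p in points1:
        labels[tuple(p)] = 1
    for p in points2:
        labels[tuple(p)] = 2
    return MultiClassMask(labels, spacing)


class TestClosestPair:
    def test_3_4_5_triangle(self):
        m = mask_with([(0, 0, 0)], [(3, 4, 0)])
        a, b, d = closest_pair(m)
        assert (a, b) == ((0, 0, 0), (3, 4, 0))
        assert d == pytest.approx(5.0)

    def test_face_adjacent_contact(self):
        m = mask_with([(2, 2, 2)], [(3, 2, 2)], spacing=(0.2, 0.2, 0.2))
        _, _, d = closest_pair(m)
        assert d == pytest.approx(0.2)

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            closest_pair(mask_with([(0, 0, 0)], []))

    def test_matches_exhaustive_all_pairs(self, rng):
        """KD-tree search equals the brute-force all-pairs minimum."""
        for _ in range(100):
            labels = np.zeros((7, 7, 7), dtype=int)
            labels[(rng.random((7, 7, 7)) < 0.1)] = 1
            labels[(labels == 0) & (rng.random((7, 7, 7)) < 0.1)] = 2
            m = MultiClassMask(labels, (1.0, 1.0, 1.0))
            if not ((labels == 1).any() and (labels == 2).any()):
                continue
            _, _, d = closest_pair(m)
            p1 = np.argwhere(labels == 1).astype(float)
            p2 = np.argwhere(labels == 2).astype(float)
            expected = np.sqrt(((p1[:, None] - p2[None]) ** 2).sum(-1)).min()
            assert d == pytest.approx(expected)

    def test_tie_break_lexicographic_zyx(self):
        # two symmetric minimizing pairs; the (z, y, x)-smallest M3 point wins
        m = mask_with([(2, 2, 0), (2, 2, 4)], [(2, 3, 0), (2, 3, 4)])
        a, b, _ = closest_pair(m)
        assert a == (2, 2, 0)
        assert b == (2, 3, 0)


class TestCrop:
    def test_identity_when_shape_matches(self, rng):
        f = rng.normal(size=(6, 6, 6))
        (out,) = crop_classification_volume([f], (3, 3, 3), (6, 6, 6))
        np.testing.assert_array_equal(out, f)

    def test_known_window(self):
        f = np.arange(6 * 6 * 6, dtype=float).reshape(6, 6, 6)
        (out,) = crop_classification_volume([f], (3, 3, 3), (4, 4, 2))
        np.testing.assert_array_equal(out, f[1:5, 1:5, 2:4])
        assert out.size == 32

    def test_mask_channel_never_gains_from_padding(self):
        mask = np.ones((4, 4, 4))
        (out,) = crop_classification_volume([mask], (0, 0, 0), (8, 8, 8))
        assert out.sum() == mask.sum()

    def test_translation_commutes_with_crop(self, rng):
        f = np.zeros((16, 16, 16))
        f[6:10, 6:10, 6:10] = rng.normal(size=(4, 4, 4))
        (a,) = crop_classification_volume([f], (8, 8, 8), (6, 6, 6))
        shifted = np.roll(f, (2, 1, 3), axis=(0, 1, 2))
        (b,) = crop_classification_volume([shifted], (10, 9, 11), (6, 6, 6))
        np.testing.assert_array_equal(a, b)


class TestAssemble:
    def test_single_channel(self, default_phantom):
        v, m, _ = default_phantom
        x = assemble_channels(v, m, None, ["image"], crop_shape=(32, 32, 16))
        assert x.channels.shape == (1, 32, 32, 16)
        assert x.channel_names == ("image",)

    def test_image_sdm_order(self, default_phantom):
        v, m, _ = default_phantom
        s = compute_sdm(BinaryMask(m.binary(), m.spacing))
        x = assemble_channels(v, m, s, ["sdm", "image"], crop_shape=(32, 32, 16))
        assert x.channel_names == ("image", "sdm")

    def test_crop_contains_closest_pair(self, default_phantom):
        v, m, _ = default_phantom
        a, b, _ = closest_pair(m)
        x = assemble_channels(v, m, None, ["mask"], crop_shape=(32, 32, 16))
        starts = [c - s // 2 for c, s in zip(x.center, x.crop_shape)]
        for point in (a, b):
            assert all(
                0 <= p - s0 < sh for p, s0, sh in zip(point, starts, x.crop_shape)
            )

    def test_mask_and_sdm_channels_keep_invariants(self, default_phantom):
        v, m, _ = default_phantom
        s = compute_sdm(BinaryMask(m.binary(), m.spacing))
        x = assemble_channels(v, m, s, ["mask", "sdm"], crop_shape=(32, 32, 16))
        mask_c, sdm_c = x.channels
        assert set(np.unique(mask_c)) <= {0.0, 1.0}
        assert (sdm_c[mask_c == 1] <= 0).all()
        assert (sdm_c[mask_c == 0] > 0).all()

    def test_sdm_padding_uses_in_crop_maximum(self):
        labels = np.zeros((8, 8, 8), dtype=int)
        labels[3:5, 3:5, 3:5] = 1
        labels[6, 3, 3] = 2
        m = MultiClassMask(labels)
        v = Volume3D(np.random.default_rng(0).normal(size=(8, 8, 8)))
        s = compute_sdm(BinaryMask(m.binary(), m.spacing))
        x = assemble_channels(v, m, s, ["sdm"], center=(4, 4, 4), crop_shape=(16, 16, 16))
        sdm_c = x.channels[0]
        # padded corner voxels must carry the in-crop max, not 0
        assert sdm_c[0, 0, 0] == sdm_c.max()

    def test_empty_config_rejected(self, default_phantom):
        v, m, _ = default_phantom
        with pytest.raises(ValueError):
            assemble_channels(v, m, None, [])

    def test_channel_order_enforced_by_type(self):
        with pytest.raises(ValueError):
            MultichannelInput(
                np.zeros((2, 4, 4, 4)),
                channel_names=("sdm", "image"),
                center=(0, 0, 0),
                crop_shape=(4, 4, 4),
            )
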