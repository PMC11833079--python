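import numpy as np
import pytest
from scipy import ndimage

from paleocanal.io import BONE, CANAL, GrayVolume, LabelVolume
from paleocanal.segmentation import (
    auto_thresholds,
    denoise,
    despeckle,
    dice,
    hysteresis_threshold,
    remove_subresolution,
)

SP = (2.0, 2.0, 2.0)


def gv(data):
    return GrayVolume(np.asarray(data, np.float32), SP)


def lv(labels):
    return LabelVolume(np.asarray(labels, np.uint8), SP)


# --- denoise ---------------------------------------------------------------


def test_denoise_is_noop_on_clean_data():
    data = np.ones((24, 24, 24), np.float32)
    data[:12] = 2.0
    out = denoise(gv(data)).data
    assert np.max(np.abs(out - data)) / 2.0 < 1e-6


def test_denoise_suppresses_flat_noise():
    rng = np.random.default_rng(0)
    sigma = 0.1
    data = 1.0 + rng.normal(0, sigma, (64, 64, 64)).astype(np.float32)
    out = denoise(gv(data)).data
    assert out.std() < 0.3 * sigma


def test_denoise_keeps_step_edge_within_one_voxel():
    rng = np.random.default_rng(1)
    data = np.where(
        np.arange(48)[:, None, None] < 24, 1.0, 2.0
    ).astype(np.float32) * np.ones((48, 24, 24), np.float32)
    data = data + rng.normal(0, 0.1, data.shape).astype(np.float32)
    out = denoise(gv(data)).data
    profile = out.mean(axis=(1, 2))
    crossing = np.argmax(profile > 1.5)
    assert abs(crossing - 24) <= 1


# --- thresholds ------------------------------------------------------------


def test_auto_thresholds_separate_two_modes():
    rng = np.random.default_rng(2)
    data = np.where(rng.random((32, 32, 32)) < 0.3, 100.0, 200.0)
    low, high = auto_thresholds(gv(data))
    assert 100.0 < high < 200.0
    assert low < high


def test_auto_thresholds_reject_constant_and_unimodal():
    with pytest.raises(ValueError, match="manual"):
        auto_thresholds(gv(np.full((8, 8, 8), 5.0)))
    rng = np.random.default_rng(3)
    with pytest.raises(ValueError, match="manual"):
        auto_thresholds(gv(1.0 + 0.01 * rng.normal(size=(16, 16, 16))))


def test_degenerate_hysteresis_equals_simple_threshold():
    rng = np.random.default_rng(4)
    data = rng.random((16, 16, 16))
    out = hysteresis_threshold(gv(data), 0.5, 0.5)
    np.testing.assert_array_equal(out.labels == CANAL, data < 0.5)


def test_all_below_low_is_all_canal():
    out = hysteresis_threshold(gv(np.zeros((8, 8, 8))), 1.0, 2.0)
    assert (out.labels == CANAL).all()


def test_low_above_high_rejected():
    with pytest.raises(ValueError):
        hysteresis_threshold(gv(np.zeros((4, 4, 4))), 2.0, 1.0)


def test_hysteresis_keeps_only_seeded_blob():
    """Two dark blobs split by a bright wall; only the one with a sub-low seed survives."""
    data = np.full((5, 5, 5), 1.0)
    data[0:2, :, :] = 0.4  # blob A, weak only
    data[3:5, :, :] = 0.4  # blob B, weak ...
    data[4, 2, 2] = 0.1  # ... with a strong seed
    out = hysteresis_threshold(gv(data), low=0.2, high=0.5)
    canal = out.labels == CANAL
    assert canal[3:5].all() and not canal[0:2].any()


# --- cleanup ---------------------------------------------------------------


def test_despeckle_removes_single_voxel_and_identity_at_one():
    labels = np.full((8, 8, 8), BONE, np.uint8)
    labels[4, 4, 4] = CANAL
    out = despeckle(lv(labels), min_voxels=2)
    assert (out.labels == BONE).all()
    out1 = despeckle(lv(labels), min_voxels=1)
    np.testing.assert_array_equal(out1.labels, labels)


def test_despeckle_matches_component_size_oracle():
    rng = np.random.default_rng(5)
    labels = np.where(rng.random((24, 24, 24)) < 0.04, CANAL, BONE).astype(np.uint8)
    min_vox = 3
    out = despeckle(lv(labels), min_voxels=min_vox)
    lab, n = ndimage.label(labels == CANAL, structure=np.ones((3, 3, 3), bool))
    expected = np.zeros_like(labels)
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() >= min_vox:
            expected[comp] = CANAL
    np.testing.assert_array_equal(out.labels == CANAL, expected == CANAL)


def test_despeckle_idempotent():
    rng = np.random.default_rng(6)
    labels = np.where(rng.random((20, 20, 20)) < 0.05, CANAL, BONE).astype(np.uint8)
    once = despeckle(lv(labels), min_voxels=4)
    twice = despeckle(once, min_voxels=4)
    np.testing.assert_array_equal(once.labels, twice.labels)


def _axial_cylinder(labels, cx, cy, r_vox):
    x, y = np.meshgrid(np.arange(labels.shape[0]), np.arange(labels.shape[1]), indexing="ij")
    labels[(x - cx) ** 2 + (y - cy) ** 2 <= r_vox**2] = CANAL


def test_remove_subresolution_drops_thin_keeps_wide():
    labels = np.full((40, 40, 20), BONE, np.uint8)
    labels[5, 5:7, :] = CANAL  # ~2-4 um wide line
    _axial_cylinder(labels, 28, 28, 3.0)  # 12-um cylinder
    out = remove_subresolution(lv(labels), resolution=6.0)
    assert not (out.labels[5, 5:7, :] == CANAL).any()
    assert (out.labels[28, 28, :] == CANAL).all()


def test_remove_subresolution_matches_distance_transform_oracle():
    rng = np.random.default_rng(7)
    labels = np.full((32, 32, 16), BONE, np.uint8)
    for cx, cy, r in ((6, 6, 1.0), (16, 20, 2.2), (26, 8, 3.5)):
        _axial_cylinder(labels, cx, cy, r)
    res = 6.0
    out = remove_subresolution(lv(labels), resolution=res)
    lab, n = ndimage.label(labels == CANAL, structure=np.ones((3, 3, 3), bool))
    edt = ndimage.distance_transform_edt(labels == CANAL, sampling=SP)
    for i in range(1, n + 1):
        comp = lab == i
        kept = (out.labels[comp] == CANAL).all()
        expected = 2.0 * edt[comp].max() >= res
        assert kept == expected
    # idempotence
    np.testing.assert_array_equal(out.labels, remove_subresolution(out, res).labels)


def test_stages_conserve_label_codes(small_run):
    assert set(np.unique(small_run["label"].labels)) <= {BONE, CANAL}


def test_dice_of_identical_is_one():
    labels = np.where(np.random.default_rng(8).random((10, 10, 10)) < 0.2, CANAL, BONE)
    assert dice(lv(labels.astype(np.uint8)), lv(labels.astype(np.uint8))) == 1.0
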