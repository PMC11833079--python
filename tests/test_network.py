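import numpy as np
import pytest
from scipy import ndimage

from paleocanal.io import BONE, CANAL, LabelVolume
from paleocanal.network import (
    build_graph,
    canal_diameters,
    classify_nodes,
    longitudinal_frequency,
    network_stats,
    orientation_stats,
    porosity,
    radial_profile,
    skeletonize,
)
from conftest import make_cylinder_label

SP = (2.0, 2.0, 2.0)


def lv(labels):
    return LabelVolume(np.asarray(labels, np.uint8), SP)


# --- skeletonization -------------------------------------------------------


def test_cylinder_skeleton_is_axial_centerline():
    lab = make_cylinder_label(radius_um=8.0)
    sk = skeletonize(lab)
    pts = np.argwhere(sk)
    interior = pts[(pts[:, 2] > 10) & (pts[:, 2] < 70)]
    center = (lab.shape[0] - 1) / 2.0
    dist = np.hypot(interior[:, 0] - center, interior[:, 1] - center)
    assert len(interior) > 0 and dist.max() <= np.sqrt(2.0) + 1e-9


def test_empty_canal_phase_gives_empty_skeleton():
    lab = lv(np.full((8, 8, 8), BONE))
    assert not skeletonize(lab).any()


def test_skeleton_preserves_component_count():
    labels = np.full((40, 40, 40), BONE, np.uint8)
    x, y = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
    for cx, cy in ((10, 10), (28, 30)):
        labels[(x - cx) ** 2 + (y - cy) ** 2 <= 2.5**2] = CANAL
    lab = lv(labels)
    sk = skeletonize(lab)
    s26 = np.ones((3, 3, 3), bool)
    _, n_canal = ndimage.label(lab.labels == CANAL, structure=s26)
    _, n_skel = ndimage.label(sk, structure=s26)
    assert n_canal == n_skel == 2


# --- graph building --------------------------------------------------------


def _graph_from(labels):
    lab = lv(labels)
    return build_graph(skeletonize(lab), lab)


def test_straight_path_is_one_edge_two_terminals():
    labels = np.full((30, 9, 9), BONE, np.uint8)
    labels[3:27, 4, 4] = CANAL
    g = _graph_from(labels)
    kinds = sorted(n.kind for n in g.nodes if n.degree > 0)
    assert kinds == ["terminal", "terminal"]
    assert len(g.edges) == 1
    bfrac, tfrac = classify_nodes(g)
    assert (bfrac, tfrac) == (0.0, 1.0)


def test_y_phantom_has_one_branching_three_terminal():
    labels = np.full((40, 40, 9), BONE, np.uint8)
    labels[4:21, 20, 4] = CANAL  # stem
    for i in range(16):  # two arms
        labels[20 + i, 20 + i, 4] = CANAL
        labels[20 + i, 20 - i, 4] = CANAL
    g = _graph_from(labels)
    bfrac, tfrac = classify_nodes(g)
    assert bfrac == pytest.approx(0.25)
    assert tfrac == pytest.approx(0.75)


def test_graph_recovers_truth_node_kinds(small_run):
    """Measured branching fraction tracks the generator's ground truth."""
    truth_b, _ = small_run["truth_network"].node_fractions()
    meas_b, _ = classify_nodes(small_run["graph"])
    assert abs(meas_b - truth_b) < 0.15


def test_no_degree_two_nodes_in_graph(small_run):
    for n in small_run["graph"].nodes:
        assert n.degree != 2 or n.kind == "branching"


# --- statistics ------------------------------------------------------------


def test_cylinder_diameter_estimate():
    lab = make_cylinder_label(radius_um=10.0)
    g = build_graph(skeletonize(lab), lab)
    mean, sd = canal_diameters(g, exclude_above=100.0)
    assert mean == pytest.approx(20.0, abs=1.0)


@pytest.mark.parametrize("r_vox", [2.0, 3.0, 5.0])
def test_diameter_estimator_bias_below_one_voxel(r_vox):
    lab = make_cylinder_label(shape=(41, 41, 60), radius_um=2.0 * r_vox)
    g = build_graph(skeletonize(lab), lab)
    mean, _ = canal_diameters(g, exclude_above=1e9)
    assert abs(mean - 4.0 * r_vox) < 2.0  # one 2-um voxel


def test_mean_of_two_equal_length_edges():
    from paleocanal.network import CanalGraph, GraphEdge

    g = CanalGraph()
    for d in (8.0, 12.0):
        g.edges.append(
            GraphEdge(u=None, v=None, polyline_um=np.zeros((2, 3)), radii_um=np.full(2, d / 2),
                      length_um=10.0, mean_diameter_um=d)
        )
    mean, sd = canal_diameters(g, exclude_above=30.0)
    assert mean == pytest.approx(10.0)
    assert sd == pytest.approx(2.0)


def test_exclusion_cutoff_errors_when_everything_is_a_pore():
    from paleocanal.network import CanalGraph, GraphEdge

    g = CanalGraph()
    g.edges.append(
        GraphEdge(u=None, v=None, polyline_um=np.zeros((2, 3)), radii_um=np.full(2, 40.0),
                  length_um=10.0, mean_diameter_um=80.0)
    )
    with pytest.raises(ValueError, match="excluded"):
        canal_diameters(g, exclude_above=30.0)


def test_frequency_counts_cylinders_per_area():
    # 5 parallel cylinders in a 0.1 mm^2 section -> 50 mm^-2
    nx = ny = 158  # (158*2 um)^2 ~ 0.0999 mm^2
    labels = np.full((nx, ny, 20), BONE, np.uint8)
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    for cx, cy in ((20, 20), (60, 120), (100, 40), (130, 130), (40, 80)):
        labels[(x - cx) ** 2 + (y - cy) ** 2 <= 2.0**2] = CANAL
    freq = longitudinal_frequency(lv(labels))
    area_mm2 = (nx * 2e-3) * (ny * 2e-3)
    assert freq == pytest.approx(5 / area_mm2, rel=1e-6)


def test_frequency_zero_without_canals():
    assert longitudinal_frequency(lv(np.full((8, 8, 12), BONE))) == 0.0


def test_frequency_needs_enough_slices():
    with pytest.raises(ValueError, match="slices"):
        longitudinal_frequency(lv(np.full((8, 8, 4), BONE)))


def test_porosity_exact_count():
    labels = np.full((10, 10, 10), BONE, np.uint8)
    labels.ravel()[:160] = CANAL
    assert porosity(lv(labels)) == pytest.approx(0.16)
    assert porosity(lv(np.full((4, 4, 4), BONE))) == 0.0
    with pytest.raises(ValueError):
        porosity(lv(np.zeros((4, 4, 4), dtype=np.uint8)))


def test_orientation_classes_for_axis_aligned_edges():
    # axial canal away from the centroid
    labels = np.full((40, 40, 40), BONE, np.uint8)
    labels[10, 10, 5:35] = CANAL
    g = _graph_from(labels)
    assert orientation_stats(g)["longitudinal"] == pytest.approx(1.0)
    # radial canal: along +x through the centroid line
    labels = np.full((40, 40, 40), BONE, np.uint8)
    labels[6:34, 20, 20] = CANAL
    g = _graph_from(labels)
    assert orientation_stats(g)["radial"] == pytest.approx(1.0)
    # laminar canal: along y at an x-offset (tangential to the centroid)
    labels = np.full((40, 40, 40), BONE, np.uint8)
    labels[32, 6:34, 20] = CANAL
    g = _graph_from(labels)
    assert orientation_stats(g)["laminar"] == pytest.approx(1.0)


def test_radial_profile_flat_for_uniform_random():
    rng = np.random.default_rng(9)
    p = 0.1
    labels = np.where(rng.random((80, 80, 40)) < p, CANAL, BONE).astype(np.uint8)
    prof = radial_profile(lv(labels), n_bins=5)
    # binomial CI: smallest bin holds > 10k voxels -> 4 sigma < 0.012
    assert np.all(np.abs(prof - p) < 0.015)


def test_radial_profile_inner_only():
    labels = np.full((60, 60, 20), BONE, np.uint8)
    x, y = np.meshgrid(np.arange(60), np.arange(60), indexing="ij")
    rho = np.hypot(x - 29.5, y - 29.5)
    labels[rho < 10] = CANAL
    prof = radial_profile(lv(labels), n_bins=6)
    assert prof[0] > 0.5
    assert np.all(prof[3:] == 0.0)


def test_network_stats_bundle(small_run):
    s = small_run["stats"]
    assert s.branching_frac + s.terminal_frac == pytest.approx(1.0)
    assert sum(s.orientation_fracs.values()) == pytest.approx(1.0)
    assert 0.0 <= s.porosity <= 1.0
    assert s.orientation_fracs["longitudinal"] > 0.5
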