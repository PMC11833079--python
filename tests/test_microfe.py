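import numpy as np
import pytest

from paleocanal.io import BACKGROUND, BONE, CANAL, LabelVolume
from paleocanal.microfe import (
    LoadCase,
    Material,
    MaterialSpec,
    assign_materials,
    element_stresses,
    homogenize,
    mean_density,
    solve_case,
    voigt_modulus,
)

SP = (2.0, 2.0, 2.0)


def lv(labels, spacing=SP):
    return LabelVolume(np.asarray(labels, np.uint8), spacing)


def two_phase_spec(E2=2.0, nu2=0.3, rho2=1.0):
    return MaterialSpec(canal_liquid=Material(E=E2, nu=nu2, rho=rho2))


# --- materials and meshing -------------------------------------------------


def test_material_invariants():
    with pytest.raises(ValueError):
        Material(E=0.0, nu=0.3, rho=1.0)
    with pytest.raises(ValueError):
        Material(E=1.0, nu=0.5, rho=1.0)
    with pytest.raises(ValueError):
        Material(E=1.0, nu=0.3, rho=-1.0)


def test_solid_scenario_is_pore_free_control():
    labels = np.full((4, 4, 4), BONE, np.uint8)
    labels[0, 0, :] = CANAL
    mesh, mats = assign_materials(lv(labels), MaterialSpec(), "solid")
    assert mats[0] == mats[1] == MaterialSpec().bone


def test_interior_background_is_rejected():
    labels = np.full((6, 6, 6), BONE, np.uint8)
    labels[3, 3, 3] = BACKGROUND
    with pytest.raises(ValueError, match="interior background"):
        assign_materials(lv(labels), MaterialSpec(), "solid")


def test_boundary_background_padding_is_excluded_not_fatal():
    labels = np.full((6, 6, 6), BONE, np.uint8)
    labels[0, :, :] = BACKGROUND
    mesh, _ = assign_materials(lv(labels), MaterialSpec(), "solid")
    assert len(mesh.conn) == 5 * 6 * 6


def test_downsample_majority_vote_matches_hand_count():
    rng = np.random.default_rng(0)
    labels = rng.choice([BONE, CANAL], size=(4, 4, 4), p=[0.5, 0.5]).astype(np.uint8)
    mesh, _ = assign_materials(lv(labels), two_phase_spec(), "liquid", downsample=2)
    assert mesh.shape == (2, 2, 2)
    for e, (i, j, k) in enumerate(mesh.elem_index):
        block = labels[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 2 * k : 2 * k + 2]
        n_canal = (block == CANAL).sum()
        expected = 1 if n_canal > 4 else 0 if n_canal < 4 else mesh.mat_id[e]
        assert mesh.mat_id[e] == expected


def test_element_floor_at_imaging_resolution():
    labels = np.full((4, 4, 4), BONE, np.uint8)
    with pytest.raises(ValueError, match="resolution"):
        assign_materials(lv(labels), MaterialSpec(), "solid", min_element_um=4.0)
    assign_materials(lv(labels), MaterialSpec(), "solid", downsample=2, min_element_um=4.0)


# --- solver ----------------------------------------------------------------


def test_zero_strain_gives_zero_displacement():
    labels = np.full((4, 4, 4), BONE, np.uint8)
    mesh, mats = assign_materials(lv(labels), MaterialSpec(), "solid")
    u = solve_case(mesh, mats, LoadCase(kind="uniaxial", axis="z", applied_strain=0.0),
                   coarse_init=False)
    assert np.abs(u).max() == 0.0


def test_homogeneous_uniaxial_field_is_uniform_strain():
    labels = np.full((6, 6, 6), BONE, np.uint8)
    mesh, mats = assign_materials(lv(labels), MaterialSpec(), "solid")
    case = LoadCase(kind="uniaxial", axis="z", applied_strain=0.02)
    u = solve_case(mesh, mats, case, tol=1e-10, coarse_init=False)
    sf = element_stresses(u, mesh, mats)
    # uniform uniaxial stress state: sigma_zz = E*eps, all else ~0
    assert np.allclose(sf.sigma[:, 2], 20.0 * 0.02, rtol=1e-6)
    assert np.abs(sf.sigma[:, [0, 1, 3, 4, 5]]).max() < 1e-6


def test_stress_invariants():
    labels = np.full((4, 4, 4), BONE, np.uint8)
    mesh, mats = assign_materials(lv(labels), MaterialSpec(), "solid")
    u = solve_case(mesh, mats, LoadCase(kind="uniaxial", axis="x", applied_strain=0.01),
                   tol=1e-10, coarse_init=False)
    sf = element_stresses(u, mesh, mats)
    assert np.all(sf.von_mises >= 0)
    assert np.all(np.diff(sf.principal, axis=1) <= 1e-12)  # descending
    # uniaxial (sigma, 0, 0): von Mises = sigma
    np.testing.assert_allclose(sf.von_mises, sf.principal[:, 0], rtol=1e-6)


def test_von_mises_closed_forms():
    """Hydrostatic -> 0; uniaxial -> sigma; principal (3,1,-1) -> sqrt(12)."""
    def vm(p1, p2, p3):
        return np.sqrt(((p1 - p2) ** 2 + (p2 - p3) ** 2 + (p3 - p1) ** 2) / 2)

    assert vm(5.0, 5.0, 5.0) == 0.0
    assert vm(7.0, 0.0, 0.0) == pytest.approx(7.0)
    assert vm(3.0, 1.0, -1.0) == pytest.approx(np.sqrt(12.0))


# --- homogenization --------------------------------------------------------


def test_monotone_in_canal_stiffness():
    """Raising E_canal never softens any effective constant (16^3 instance)."""
    rng = np.random.default_rng(1)
    labels = np.where(rng.random((16, 16, 16)) < 0.2, CANAL, BONE).astype(np.uint8)
    lab = lv(labels)
    prev = None
    for E2 in (0.02, 2.0, 20.0):
        ec = homogenize(lab, two_phase_spec(E2=E2), "liquid", tol=1e-9, coarse_init=False)
        cur = [ec.E_r, ec.E_t, ec.E_z, ec.G_rt, ec.G_tz, ec.G_rz]
        if prev is not None:
            assert all(c >= p - 1e-6 for c, p in zip(cur, prev))
        prev = cur


def test_reciprocity_of_poisson_ratios():
    rng = np.random.default_rng(2)
    labels = np.where(rng.random((16, 16, 16)) < 0.15, CANAL, BONE).astype(np.uint8)
    ec = homogenize(lv(labels), two_phase_spec(E2=2.0), "liquid", tol=1e-9, coarse_init=False)
    for nu_ij, E_i, nu_ji, E_j in (
        (ec.nu_rt, ec.E_r, ec.nu_tr, ec.E_t),
        (ec.nu_rz, ec.E_r, ec.nu_zr, ec.E_z),
        (ec.nu_tz, ec.E_t, ec.nu_zt, ec.E_z),
    ):
        assert nu_ij / E_i == pytest.approx(nu_ji / E_j, rel=0.01)


def test_mean_density_closed_forms():
    labels = np.full((10, 10, 10), BONE, np.uint8)
    assert mean_density(lv(labels), MaterialSpec(), "solid") == pytest.approx(2.0)
    labels.ravel()[:160] = CANAL  # 16 % porosity
    spec = MaterialSpec()
    rho_solid = mean_density(lv(labels), spec, "solid")
    red_gas = (rho_solid - mean_density(lv(labels), spec, "gas")) / rho_solid
    red_liq = (rho_solid - mean_density(lv(labels), spec, "liquid")) / rho_solid
    assert red_gas == pytest.approx(0.16, abs=0.001)
    assert red_liq == pytest.approx(0.05, abs=0.001)


def test_mesh_refinement_consistency(default_runs):
    """E_z changes by <2 % between 32^3-ish and 64^3-ish discretisations."""
    from paleocanal.microfe import _Operator, _face_area_um2, _face_reaction
    from paleocanal.pipeline import _crop

    label = _crop(default_runs[1]["label"], [128, 128, 128])
    spec = MaterialSpec()
    Ez = {}
    for f in (4, 2):
        mesh, mats = assign_materials(label, spec, "gas", downsample=f)
        case = LoadCase(kind="uniaxial", axis="z", applied_strain=0.02)
        u = solve_case(mesh, mats, case, tol=1e-6)
        op = _Operator(mesh, mats)
        Ez[f] = _face_reaction(op, u, mesh, 2, 2) / (_face_area_um2(mesh, 2) * 0.02)
    assert abs(Ez[4] - Ez[2]) / Ez[2] < 0.02
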