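import numpy as np
import pytest

from porinflux.io_core import AtomRecord, StructureModel, assign_formal_charges
from porinflux.pore_profile import (constriction_zone_charge, potential_profile,
                                    principal_axis, radius_profile)
from porinflux.synthetic_data import channel_axis, make_channel_fixture
from porinflux.units import COULOMB_V_A


def test_cylinder_profile_matches_geometry():
    """Wall radius 5 A of carbon atoms (vdW 1.70) -> pore radius 3.30 A."""
    st = make_channel_fixture(10, 5.0, 30.0)
    profile = radius_profile(st, axis=channel_axis(st), z_step=1.0)
    interior = (profile.z_grid > profile.z_grid.min() + 3) & \
               (profile.z_grid < profile.z_grid.max() - 3)
    np.testing.assert_allclose(profile.radius[interior], 5.0 - 1.70, atol=1e-6)
    assert profile.narrowest_radius == pytest.approx(3.30, abs=1e-6)


def _ring(radius, z, start_id, n=16, element="X"):
    return [AtomRecord(start_id + j, element, element, "GLY",
                       int(z) + 100, "A",
                       np.array([radius * np.cos(2 * np.pi * j / n),
                                 radius * np.sin(2 * np.pi * j / n), z]))
            for j in range(n)]


def test_cone_narrowest_at_narrow_end():
    atoms = []
    radii = np.linspace(8.0, 3.0, 21)
    for k, r in enumerate(radii):
        atoms += _ring(r, 1.0 * k, 16 * k)
    st = StructureModel(atoms=atoms)
    axis = (np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    profile = radius_profile(st, axis=axis, z_step=0.5)
    assert abs(profile.narrowest_z - 20.0) <= 0.5 + 1e-9
    assert profile.narrowest_radius == pytest.approx(3.0 - 1.5, abs=1e-9)
    # brute-force fine-grid oracle at a few z values
    pos = st.positions
    vdw = np.array([a.vdw_radius for a in st.atoms])
    for z in (4.0, 10.0, 16.0):
        mask = np.abs(pos[:, 2] - z) <= 3.0
        expected = max(np.min(np.hypot(pos[mask, 0], pos[mask, 1]) - vdw[mask]),
                       0.0)
        k = np.argmin(np.abs(profile.z_grid - z))
        assert profile.radius[k] == pytest.approx(expected, abs=1e-9)


def test_profile_undefined_where_no_atoms():
    atoms = _ring(5.0, 0.0, 0) + _ring(5.0, 20.0, 16)
    st = StructureModel(atoms=atoms)
    profile = radius_profile(st, axis=(np.zeros(3), np.array([0, 0, 1.0])),
                             z_step=1.0, slab_half=3.0)
    mid = np.abs(profile.z_grid - 10.0) < 2.0
    assert np.all(np.isnan(profile.radius[mid]))
    assert not np.isnan(profile.narrowest_radius)


def test_slab_contained_cloud_equals_brute_force(rng):
    pts = rng.uniform(-2, 2, (30, 3))
    pts[:, 2] *= 0.5  # z extent within one slab
    pts[:, :2] += np.sign(pts[:, :2]) * 3  # keep off-axis
    atoms = [AtomRecord(i, "X", "X", "GLY", 1, "A", p)
             for i, p in enumerate(pts)]
    st = StructureModel(atoms=atoms)
    profile = radius_profile(st, axis=(np.zeros(3), np.array([0, 0, 1.0])),
                             z_step=0.25, slab_half=3.0)
    k = np.argmin(np.abs(profile.z_grid))
    expected = max(float(np.min(np.hypot(pts[:, 0], pts[:, 1]) - 1.5)), 0.0)
    assert profile.radius[k] == pytest.approx(expected, abs=1e-9)


def test_principal_axis_of_cylinder_points_along_z():
    st = make_channel_fixture(10, 5.0, 30.0)
    origin, direction = principal_axis(st)
    assert abs(direction[2]) > 0.999


def test_cz_charge_single_asp_at_narrowest():
    st = make_channel_fixture(10, 5.0, 24.0, charged_residues=[("ASP", 0.0)])
    st = assign_formal_charges(st)
    profile = radius_profile(st, axis=channel_axis(st), z_step=1.0)
    report = constriction_zone_charge(st, profile, cz_radius=5.0)
    assert report.net_charge_cz == -1
    assert any(key[2] == "ASP" for key in report.cz_residues)


def test_cz_charge_hand_geometry():
    """2 ARG within 5 A of the narrowest point, 1 GLU ~9.5 A away -> +2."""
    st = make_channel_fixture(10, 5.0, 24.0,
                              charged_residues=[("ARG", 0.0), ("ARG", 2.0),
                                                ("GLU", 9.0)])
    st = assign_formal_charges(st)
    profile = radius_profile(st, axis=channel_axis(st), z_step=1.0)
    report = constriction_zone_charge(st, profile, cz_radius=5.0)
    assert report.net_charge_cz == +2
    assert report.net_charge_pore == +1  # all three line the pore surface


def test_cz_charge_invariant_under_rigid_motion():
    st = make_channel_fixture(8, 5.0, 20.0, charged_residues=[("ASP", 1.0)])
    st = assign_formal_charges(st)
    profile = radius_profile(st, axis=channel_axis(st), z_step=1.0)
    base = constriction_zone_charge(st, profile)
    shift = np.array([7.0, -3.0, 11.0])
    moved = StructureModel(atoms=[
        AtomRecord(a.atom_id, a.name, a.element, a.residue_name, a.residue_id,
                   a.chain_id, a.position + shift, a.vdw_radius, a.formal_charge)
        for a in st.atoms])
    origin, direction = channel_axis(st)
    profile2 = radius_profile(moved, axis=(origin + shift, direction), z_step=1.0)
    report2 = constriction_zone_charge(moved, profile2)
    assert report2.net_charge_cz == base.net_charge_cz


def test_potential_profile_no_charges_is_zero():
    st = make_channel_fixture(5, 5.0, 15.0)  # no formal charges assigned
    axis = channel_axis(st)
    phi = potential_profile(st, axis, np.linspace(-5, 5, 11), debye_length=8.0)
    np.testing.assert_allclose(phi, 0.0)


def test_potential_profile_single_charge_closed_form():
    atoms = [AtomRecord(0, "NZ", "N", "LYS", 1, "A",
                        np.array([0.0, 0.0, 4.0]), formal_charge=1)]
    st = StructureModel(atoms=atoms)
    axis = (np.zeros(3), np.array([0.0, 0.0, 1.0]))
    z_grid = np.array([-6.0, -2.0, 0.0, 2.0, 8.0])
    lam, eps = 8.0, 80.0
    phi = potential_profile(st, axis, z_grid, debye_length=lam, eps_r=eps)
    raw = np.array([COULOMB_V_A * np.exp(-abs(z - 4.0) / lam)
                    / (eps * abs(z - 4.0)) for z in z_grid])
    np.testing.assert_allclose(phi, raw - raw[0], rtol=1e-12)


def test_potential_profile_symmetry_and_superposition(rng):
    atoms = [AtomRecord(0, "CG", "C", "ASP", 1, "A",
                        np.array([3.0, 0.0, -5.0]), formal_charge=-1),
             AtomRecord(1, "CG", "C", "ASP", 2, "A",
                        np.array([3.0, 0.0, 5.0]), formal_charge=-1)]
    st = StructureModel(atoms=atoms)
    axis = (np.zeros(3), np.array([0.0, 0.0, 1.0]))
    z = np.linspace(-8, 8, 17)
    phi = potential_profile(st, axis, z, debye_length=10.0)
    shifted = phi - phi[len(z) // 2]
    np.testing.assert_allclose(shifted, shifted[::-1], atol=1e-12)
    # superposition: sum of single-charge profiles equals the pair profile
    one = StructureModel(atoms=[atoms[0]])
    two = StructureModel(atoms=[atoms[1]])
    p1 = potential_profile(one, axis, z, debye_length=10.0)
    p2 = potential_profile(two, axis, z, debye_length=10.0)
    np.testing.assert_allclose(phi, p1 + p2, atol=1e-12)


def test_potential_profile_excludes_coincident_charge():
    atoms = [AtomRecord(0, "NZ", "N", "LYS", 1, "A",
                        np.array([0.0, 0.0, 0.0]), formal_charge=1)]
    st = StructureModel(atoms=atoms)
    axis = (np.zeros(3), np.array([0.0, 0.0, 1.0]))
    with pytest.warns(UserWarning, match="excluded"):
        phi = potential_profile(st, axis, np.array([0.0, 5.0]), debye_length=8.0)
    assert np.isfinite(phi).all()
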