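import numpy as np
import pytest

from porinflux.conformation import (detect_transition, dihedral_series,
                                    pca_projection, rmsf, segment_rmsd,
                                    wrap_angle)
from porinflux.io_core import AtomRecord, StructureModel, Trajectory


def build_structure(spec):
    """spec: list of (name, resname, resid, chain)."""
    return StructureModel(atoms=[
        AtomRecord(atom_id=i, name=n, element=n[0], residue_name=rn,
                   residue_id=ri, chain_id=ch, position=np.zeros(3))
        for i, (n, rn, ri, ch) in enumerate(spec)
    ])


def make_traj(structure, coords, dt=0.1):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return Trajectory(structure=structure, times=np.arange(n) * dt,
                      coords=coords, boxes=np.tile([500.0, 500.0, 500.0], (n, 1)))


ANCHORS = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])


def _anchored_structure(n_extra):
    spec = [("CA", "GLY", i + 1, "A") for i in range(4)]
    spec += [("CA", "ALA", 10 + i, "A") for i in range(n_extra)]
    return build_structure(spec)


def test_rmsf_static_and_alternating():
    st = _anchored_structure(1)
    coords = np.tile(np.vstack([ANCHORS, [[20, 0, 0]]]), (8, 1, 1))
    traj = make_traj(st, coords)
    vals = rmsf(traj, [4], [0, 1, 2, 3])
    assert vals[("A", 10)] == pytest.approx(0.0, abs=1e-12)
    # one atom alternating +/- d about its mean along x
    d = 1.5
    coords2 = coords.copy()
    coords2[:, 4, 0] = 20.0 + d * np.array([1, -1] * 4)
    vals = rmsf(make_traj(st, coords2), [4], [0, 1, 2, 3])
    assert vals[("A", 10)] == pytest.approx(d, rel=1e-9)


def test_rmsf_invariant_under_rigid_translation(rng):
    st = _anchored_structure(2)
    base = np.vstack([ANCHORS, [[20, 0, 0], [0, 20, 0]]])
    coords = np.tile(base, (6, 1, 1))
    coords += rng.normal(0, 5, size=(6, 1, 3))  # same shift for all atoms
    vals = rmsf(make_traj(st, coords), [4, 5], list(range(6)))
    assert all(v == pytest.approx(0.0, abs=1e-9) for v in vals.values())


def test_segment_rmsd_reference_and_translation():
    st = _anchored_structure(2)
    base = np.vstack([ANCHORS, [[20, 0, 0], [21, 0, 0]]])
    coords = np.tile(base, (5, 1, 1))
    coords[2:, 4:, 0] += 2.0  # segment rigidly displaced by 2 A
    series = segment_rmsd(make_traj(st, coords), [4, 5], [0, 1, 2, 3])
    np.testing.assert_allclose(series.values, [0, 0, 2, 2, 2], atol=1e-9)


def test_segment_rmsd_matches_direct_formula(rng):
    st = _anchored_structure(3)
    base = np.vstack([ANCHORS, rng.uniform(15, 25, (3, 3))])
    coords = np.tile(base, (4, 1, 1))
    coords[1:, 4:, :] += rng.normal(0, 1, size=(3, 3, 3))
    series = segment_rmsd(make_traj(st, coords), [4, 5, 6], [0, 1, 2, 3])
    for f in range(4):
        expected = np.sqrt(np.mean(np.sum(
            (coords[f, 4:] - coords[0, 4:]) ** 2, axis=1)))
        assert series.values[f] == pytest.approx(expected, rel=1e-9)


# --- dihedrals -------------------------------------------------------------

def reference_dihedral(p0, p1, p2, p3):
    """Independent dihedral: signed angle between the two bond planes."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return wrap_angle(ang)


def nerf_place(a, b, c, r, theta_deg, phi_deg):
    """Place atom d at distance r from c, angle theta at c, dihedral phi."""
    theta = np.radians(theta_deg)
    phi = np.radians(phi_deg)
    bc = (c - b) / np.linalg.norm(c - b)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-r * np.cos(theta), r * np.cos(phi) * np.sin(theta),
                   r * np.sin(phi) * np.sin(theta)])
    return c + np.column_stack([bc, m, n]) @ d2


def build_backbone(n_res, phi, psi, omega=180.0):
    """Idealised backbone (N, CA, C per residue) at fixed phi/psi."""
    coords = [np.array([0.0, 0, 0]), np.array([1.458, 0, 0])]
    coords.append(nerf_place(np.array([0.0, 1, 0]), coords[0], coords[1],
                             1.525, 111.2, 0.0))
    for _ in range(1, n_res):
        n_i = nerf_place(*coords[-3:], 1.329, 116.2, psi)
        ca_i = nerf_place(*coords[-2:], n_i, 1.458, 121.7, omega)
        c_i = nerf_place(coords[-1], n_i, ca_i, 1.525, 111.2, phi)
        coords += [n_i, ca_i, c_i]
    spec = []
    for r in range(n_res):
        spec += [(nm, "ALA", r + 1, "A") for nm in ("N", "CA", "C")]
    return build_structure(spec), np.array(coords)


def test_dihedral_alpha_helix_geometry():
    st, coords = build_backbone(4, phi=-57.0, psi=-47.0)
    traj = make_traj(st, coords[None, :, :].repeat(2, axis=0))
    series = dihedral_series(traj, "A", 2)
    assert series.phi[0] == pytest.approx(-57.0, abs=2.0)
    assert series.psi[0] == pytest.approx(-47.0, abs=2.0)


def test_dihedral_planar_trans_and_mirror():
    st, coords = build_backbone(3, phi=180.0, psi=180.0)
    traj = make_traj(st, coords[None].repeat(2, axis=0))
    series = dihedral_series(traj, "A", 2)
    assert abs(series.phi[0]) == pytest.approx(180.0, abs=1e-6)
    mirrored = coords.copy()
    mirrored[:, 0] *= -1
    st2, c2 = build_backbone(4, phi=-57.0, psi=-47.0)
    m = c2.copy()
    m[:, 0] *= -1
    s_orig = dihedral_series(make_traj(st2, c2[None].repeat(2, 0)), "A", 2)
    s_mirr = dihedral_series(make_traj(st2, m[None].repeat(2, 0)), "A", 2)
    assert s_mirr.phi[0] == pytest.approx(-s_orig.phi[0], abs=1e-6)
    assert s_mirr.psi[0] == pytest.approx(-s_orig.psi[0], abs=1e-6)


def test_dihedral_terminal_residue_missing_angle():
    st, coords = build_backbone(3, phi=-60.0, psi=-40.0)
    series = dihedral_series(make_traj(st, coords[None].repeat(2, 0)), "A", 1)
    assert series.phi is None and series.psi is not None


def test_dihedral_matches_reference_on_random_points(rng):
    """Direct-formula agreement to 1e-6 degrees on random 4-point sets."""
    from porinflux.conformation import _dihedral
    for _ in range(300):
        p = rng.uniform(-5, 5, (4, 3))
        got = _dihedral(*p)
        want = reference_dihedral(*p)
        assert abs(float(got) - want) < 1e-6 or \
            abs(abs(float(got)) - 180.0) < 1e-6  # +/-180 are the same angle


def test_detect_transition_step_and_constant():
    times = np.arange(100) * 1.0
    assert detect_transition(np.zeros(100), times, 2.0, 10) == []
    vals = np.where(np.arange(100) >= 40, 120.0, 0.0)
    events = detect_transition(vals, times, 60.0, 10, circular=True)
    assert events == [40.0]


def test_detect_transition_wraparound_no_event():
    times = np.arange(50) * 1.0
    vals = np.where(np.arange(50) >= 20, 179.0, -179.0)
    assert detect_transition(vals, times, 60.0, 5, circular=True) == []


def test_detect_transition_time_reversal_symmetry():
    n = 80
    times = np.arange(n) * 1.0
    vals = np.where(np.arange(n) >= 30, 100.0, 0.0)
    fwd = detect_transition(vals, times, 50.0, 5)
    rev = detect_transition(vals[::-1], times, 50.0, 5)
    assert fwd == [30.0] and rev == [float(n - 30)]


def test_detect_transition_validation():
    with pytest.raises(ValueError):
        detect_transition([], [], 1.0, 1)
    with pytest.raises(ValueError):
        detect_transition([1.0, 2.0], [0.0, 1.0], 1.0, 5)


def test_pca_single_mode_and_static(rng):
    st = _anchored_structure(2)
    base = np.vstack([ANCHORS, [[20, 0, 0], [0, 20, 0]]])
    n = 200
    coords = np.tile(base, (n, 1, 1))
    coords[:, 4, 0] += 3.0 * np.sin(np.linspace(0, 8 * np.pi, n))
    evals, evec1, proj = pca_projection(make_traj(st, coords), [4, 5],
                                        [0, 1, 2, 3])
    assert abs(evec1[0]) > 0.99          # x of first selected atom
    assert evals[1] == pytest.approx(0.0, abs=1e-9)
    static = np.tile(base, (5, 1, 1))
    evals0, _, _ = pca_projection(make_traj(st, static), [4, 5], [0, 1, 2, 3])
    assert np.all(evals0 < 1e-12)


def test_pca_two_modes_recover_variances(rng):
    st = _anchored_structure(2)
    base = np.vstack([ANCHORS, [[20, 0, 0], [0, 20, 0]]])
    n = 1000
    coords = np.tile(base, (n, 1, 1))
    coords[:, 4, 0] += rng.normal(0, 2.0, n)   # variance 4
    coords[:, 5, 1] += rng.normal(0, 1.0, n)   # variance 1
    evals, _, _ = pca_projection(make_traj(st, coords), [4, 5], [0, 1, 2, 3])
    assert evals[0] == pytest.approx(4.0, rel=0.1)
    assert evals[1] == pytest.approx(1.0, rel=0.1)
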