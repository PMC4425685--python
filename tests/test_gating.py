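import numpy as np
import pytest

from porinflux.gating import (BindingSite, TimelineEvent, closure_fit,
                              event_timeline, site_occupancy)
from porinflux.synthetic_data import (BindingSiteSpec, SpeciesSpec, SynthConfig,
                                      make_decay_series, simulate_ions)

from conftest import ion_structure, traj_from_z


def _site_traj(ion_z, site_z=50.0):
    """One ion moving in z past a static site atom at (50, 50, site_z)."""
    import porinflux.io_core as io_core
    n_frames = len(ion_z)
    st_atoms = ion_structure(1).atoms + [
        io_core.AtomRecord(atom_id=1, name="STE", element="X",
                           residue_name="STE", residue_id=99, chain_id="S",
                           position=np.array([50.0, 50.0, site_z]))]
    st = io_core.StructureModel(atoms=st_atoms, box=np.array([100.0] * 3))
    coords = np.zeros((n_frames, 2, 3))
    coords[:, :, :2] = 50.0
    coords[:, 0, 2] = ion_z
    coords[:, 1, :] = [50.0, 50.0, site_z]
    return io_core.Trajectory(structure=st, times=np.arange(n_frames) * 0.1,
                              coords=coords,
                              boxes=np.tile([100.0] * 3, (n_frames, 1)))


def test_occupancy_never_within_cutoff():
    traj = _site_traj(np.full(50, 80.0))
    occ = site_occupancy(traj, BindingSite("niche I", [1]), {0: "K"})
    assert occ.intervals == [] and occ.first_binding_time is None


def test_occupancy_scripted_interval_hand_checked():
    z = np.full(200, 80.0)
    z[100:110] = 50.0  # within cutoff for frames 100-109
    traj = _site_traj(z)
    occ = site_occupancy(traj, BindingSite("niche I", [1]), {0: "K"})
    assert len(occ.intervals) == 1
    ion, t_on, t_off = occ.intervals[0]
    assert ion == 0
    assert t_on == pytest.approx(10.0)
    assert t_off == pytest.approx(10.9)
    assert occ.first_binding_time == pytest.approx(10.0)


def test_occupancy_gap_tolerance_merges_one_frame_gaps():
    z = np.full(60, 80.0)
    z[10:20] = 50.0
    z[20] = 80.0    # single-frame gap
    z[21:30] = 50.0
    traj = _site_traj(z)
    occ = site_occupancy(traj, BindingSite("s", [1]), {0: "K"})
    assert len(occ.intervals) == 1


def test_occupancy_default_cutoff_and_species_filter():
    assert BindingSite("s", [1]).cutoff == 3.5
    z = np.full(20, 50.0)
    traj = _site_traj(z)
    occ = site_occupancy(traj, BindingSite("s", [1], species="CL"), {0: "K"})
    assert occ.intervals == []
    with pytest.raises(ValueError):
        site_occupancy(traj, BindingSite("s", []), {0: "K"})


def merge_intervals(intervals, dt, gap_frames=1):
    """Merge (site, ion, t_on, t_off) records separated by <= gap_frames."""
    merged = []
    for rec in sorted(intervals):
        if merged and merged[-1][0] == rec[0] and merged[-1][1] == rec[1] \
                and rec[2] - merged[-1][3] <= (gap_frames + 1) * dt + 1e-9:
            merged[-1] = (*merged[-1][:3], rec[3])
        else:
            merged.append(tuple(rec))
    return merged


def test_occupancy_reproduces_simulator_binding_intervals():
    """Geometric occupancy on BD output equals the logged binding intervals
    when the cutoff matches the capture radius (1-frame gap tolerance: a
    release followed by immediate recapture merges)."""
    cfg = SynthConfig(box=(40, 40, 80),
                      species=[SpeciesSpec("K", 12, 1, 196.0)],
                      binding_sites=[BindingSiteSpec((10, 10, 20), 2.5, 0.02),
                                     BindingSiteSpec((30, 30, 60), 2.5, 0.05)],
                      voltage=0.0, n_steps=6000, dt=1e-3, save_every=1, seed=21)
    traj, gt = simulate_ions(cfg)
    smap = {i: "K" for i in range(12)}
    got = []
    for s_idx, site_atom in enumerate((12, 13)):
        occ = site_occupancy(traj, BindingSite(f"s{s_idx}", [site_atom],
                                               cutoff=2.5), smap)
        got += [(s_idx, int(ion), round(t_on, 9), round(t_off, 9))
                for ion, t_on, t_off in occ.intervals]
    want = [(s, i, round(t_on, 9), round(t_off, 9))
            for s, i, t_on, t_off in gt.realized_binding_intervals]
    assert sorted(got) == merge_intervals(want, cfg.dt)
    assert len(want) >= 3


def test_timeline_precedence_and_sorting(rng):
    flip = TimelineEvent(84.0, "B", "segment_flip", "112-GA-113")
    bound = TimelineEvent(114.0, "B", "site_bound", "niche I")
    tl = event_timeline([bound], [flip])
    assert tl.precedes("segment_flip", "site_bound", monomer="B") is True
    assert tl.precedes("site_bound", "segment_flip", monomer="B") is False
    assert tl.precedes("hbond_lost", "site_bound") is None
    assert event_timeline([]).events == []

    events = [TimelineEvent(float(t), m, k, f"e{j}")
              for j, (t, m, k) in enumerate(zip(
                  rng.integers(0, 50, 100),
                  rng.choice(["A", "B", "C"], 100),
                  rng.choice(["segment_flip", "site_bound", "hbond_lost"], 100)))]
    shuffled = list(events)
    rng.shuffle(shuffled)
    tl1 = event_timeline(events)
    tl2 = event_timeline(shuffled)
    assert tl1.events == tl2.events
    assert all(tl1.events[i].time <= tl1.events[i + 1].time
               for i in range(len(tl1.events) - 1))


def test_closure_fit_exact_model():
    cs = make_decay_series(100.0, 0.01, 50.0, 20, 0.0, seed=0)
    fit = closure_fit(cs)
    assert fit.ok
    assert fit.a == pytest.approx(100.0, rel=1e-6)
    assert fit.b == pytest.approx(0.01, rel=1e-6)
    assert fit.t_to_fraction(0.05) == pytest.approx(np.log(20) / fit.b)


def test_closure_fit_noisy_matches_grid_search_oracle():
    cs = make_decay_series(100.0, 0.01, 50.0, 40, 5.0, seed=42)
    fit = closure_fit(cs)
    assert fit.ok
    assert abs(fit.a - 100.0) < 10.0
    assert abs(fit.b - 0.01) < 0.003
    # 2-D grid-search SSE oracle
    a_grid = np.linspace(70, 130, 241)
    b_grid = np.linspace(0.004, 0.02, 321)
    t, y = cs.window_mid_times, cs.currents
    sse = ((y[None, None, :]
            - a_grid[:, None, None] * np.exp(-b_grid[None, :, None] * t)) ** 2
           ).sum(axis=2)
    ia, ib = np.unravel_index(np.argmin(sse), sse.shape)
    assert fit.a == pytest.approx(a_grid[ia], abs=2 * (a_grid[1] - a_grid[0]))
    assert fit.b == pytest.approx(b_grid[ib], abs=2 * (b_grid[1] - b_grid[0]))
    assert fit.sse <= sse[ia, ib] + 1e-9


def test_closure_fit_rejects_rising_data():
    from porinflux.electrophys import CurrentSeries
    cs = CurrentSeries("total", 0, 50.0, (np.arange(5) + 0.5) * 50.0,
                       np.array([10.0, 20.0, 30.0, 40.0, 50.0]))
    with pytest.warns(UserWarning):
        fit = closure_fit(cs)
    assert not fit.ok and fit.a is None
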