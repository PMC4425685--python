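import numpy as np
import pytest

from porinflux.io_core import AtomRecord, StructureModel, Trajectory


def ion_structure(n: int, box=(100.0, 100.0, 100.0), label="K") -> StructureModel:
    """n single-atom ions in a box; positions are placeholders (frame data
    lives in the Trajectory)."""
    atoms = [
        AtomRecord(atom_id=i, name=label, element=label, residue_name=label,
                   residue_id=i + 1, chain_id="I",
                   position=np.zeros(3))
        for i in range(n)
    ]
    return StructureModel(atoms=atoms, box=np.asarray(box, dtype=float))


def traj_from_z(z: np.ndarray, box=(100.0, 100.0, 100.0), dt=0.1,
                label="K") -> Trajectory:
    """Trajectory whose ions move only in z; z has shape (n_frames, n_ions)."""
    z = np.asarray(z, dtype=float)
    n_frames, n_ions = z.shape
    coords = np.zeros((n_frames, n_ions, 3))
    coords[:, :, 0] = 50.0
    coords[:, :, 1] = 50.0
    coords[:, :, 2] = z
    st = ion_structure(n_ions, box, label)
    return Trajectory(structure=st, times=np.arange(n_frames) * dt,
                      coords=coords, boxes=np.tile(box, (n_frames, 1)))


def brute_force_crossings(z, times, box_z, z_low, z_high, buf):
    """Independent per-ion compartment automaton, plain-python reference.

    Same contract as the analysis: committed below/inside/above states,
    hysteresis buffer on exits, |dz| > box_z/2 toggles below<->above with
    no event.  Returns [(ion, direction, t_enter, t_exit), ...].
    """
    BELOW, INSIDE, ABOVE = 0, 1, 2
    n_frames, n_ions = z.shape
    events = []
    for i in range(n_ions):
        zi = z[0, i]
        state = BELOW if zi < z_low else ABOVE if zi > z_high else INSIDE
        origin = None
        t_enter = None
        for f in range(1, n_frames):
            zf = z[f, i]
            if abs(zf - z[f - 1, i]) > box_z / 2:
                if state == BELOW:
                    state = ABOVE
                elif state == ABOVE:
                    state = BELOW
                else:
                    state = (BELOW if zf < z_low
                             else ABOVE if zf > z_high else INSIDE)
                    origin = None
                    t_enter = None
                continue
            if state == BELOW and zf > z_low:
                state, origin, t_enter = INSIDE, BELOW, times[f]
            elif state == ABOVE and zf < z_high:
                state, origin, t_enter = INSIDE, ABOVE, times[f]
            if state == INSIDE:
                if zf > z_high + buf:
                    if origin == BELOW:
                        te = times[f - 1] if t_enter >= times[f] else t_enter
                        events.append((i, +1, te, times[f]))
                    state, origin, t_enter = ABOVE, None, None
                elif zf < z_low - buf:
                    if origin == ABOVE:
                        te = times[f - 1] if t_enter >= times[f] else t_enter
                        events.append((i, -1, te, times[f]))
                    state, origin, t_enter = BELOW, None, None
    return events


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


THREE_ATOM_PDB = """\
CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.200   3.300   3.000  1.00  0.00           C
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path
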