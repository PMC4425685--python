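"""Geometric hydrogen-bond detection and monomer-count persistence maps.

A bond is present when the donor-acceptor distance is within a cutoff
(default 3.5 A, inclusive) and, when a hydrogen is available, the D-H...A
angle deviates from linear by at most a tolerance (default 30 deg).  For a
homotrimeric channel, the persistence map reports for each bond and time
window in how many of the three monomers the bond is present (0-3), which
is how differences in the loop-anchoring network between voltage
conditions become visible at a glance.  Salt bridges can be screened with
the same distance criterion by omitting hydrogens (the angle test is then
waived with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import StructureModel, Trajectory


@dataclass
class HBondSpec:
    max_da_distance: float = 3.5       # A, inclusive
    max_dha_angle_deviation: float = 30.0   # degrees from linear, inclusive

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not (0 < self.max_dha_angle_deviation <= 90):
            raise ValueError("angle deviation must lie in (0, 90]")


@dataclass
class HBondMap:
    """bonds x windows monomer counts plus per-bond/monomer persistence."""

    bond_labels: list[str]
    window_mid_times: np.ndarray
    counts: np.ndarray                      # (n_bonds, n_windows), ints 0..3
    persistence: pd.DataFrame               # columns bond, chain, fraction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.bond_labels,
                            columns=np.round(self.window_mid_times, 6))


def _find_hydrogen(structure: StructureModel, donor_id: int) -> int | None:
    """Hydrogen covalently attached to the donor: nearest H in the same
    residue within 1.3 A."""
    donor = structure.atom_by_id(donor_id)
    best, best_d = None, 1.3
    for a in structure.atoms:
        if (a.element == "H" and a.chain_id == donor.chain_id
                and a.residue_id == donor.residue_id):
            d = float(np.linalg.norm(a.position - donor.position))
            if d < best_d:
                best, best_d = a.atom_id, d
    return best


def detect_hbonds(structure: StructureModel,
                  donors: Sequence[int], acceptors: Sequence[int],
                  spec: HBondSpec | None = None,
                  coords: np.ndarray | None = None,
                  ) -> list[tuple[int, int, float, float | None]]:
    """Hydrogen bonds in one frame between donor and acceptor selections.

    Returns (donor_id, acceptor_id, distance, dha_deviation) tuples; the
    deviation is None when the donor has no attached hydrogen (the angle
    criterion is then skipped with a warning).  Both cutoffs are inclusive.
    ``coords`` overrides the structure's own coordinates (same atom order).
    """
    spec = spec or HBondSpec()
    pos = coords if coords is not None else structure.positions
    bonds = []
    for d_id in donors:
        di = structure.index_of(d_id)
        h_id = _find_hydrogen(structure, d_id)
        if h_id is None:
            warnings.warn(f"donor {d_id}: no attached hydrogen; "
                          "angle criterion skipped")
        for a_id in acceptors:
            if a_id == d_id:
                continue
            ai = structure.index_of(a_id)
            dist = float(np.linalg.norm(pos[ai] - pos[di]))
            if dist > spec.max_da_distance:
                continue
            deviation = None
            if h_id is not None:
                hi = structure.index_of(h_id)
                v1 = pos[di] - pos[hi]
                v2 = pos[ai] - pos[hi]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                deviation = float(180.0 - angle)
                if deviation > spec.max_dha_angle_deviation:
                    continue
            bonds.append((d_id, a_id, dist, deviation))
    return bonds


def hbond_monomer_map(traj: Trajectory,
                      bond_defs: Mapping[str, Mapping[str, tuple[int, int]]],
                      window: float,
                      spec: HBondSpec | None = None,
                      presence_fraction: float = 0.5) -> HBondMap:
    """Per-window monomer counts (0-3) and per-monomer persistence.

    ``bond_defs`` maps a bond label to a per-chain mapping of
    (donor_id, acceptor_id); the equivalent bond must be defined in each
    monomer.  Within a window a bond counts as present in a monomer if it
    is present in at least ``presence_fraction`` of the window's frames;
    the map value is the number of monomers.  Persistence is the fraction
    of all frames the bond is present, per monomer.
    """
    spec = spec or HBondSpec()
    if traj.n_frames > 1:
        frame_dt = float(traj.times[1] - traj.times[0])
        if window < frame_dt:
            raise ValueError("window shorter than the frame spacing")
    st = traj.structure
    labels = sorted(bond_defs)
    chains = sorted({c for per in bond_defs.values() for c in per})

    hydrogens = {
        (label, chain): _find_hydrogen(st, pair[0])
        for label, per in bond_defs.items() for chain, pair in per.items()
    }
    present = np.zeros((len(labels), len(chains), traj.n_frames), dtype=bool)
    for bi, label in enumerate(labels):
        for ci, chain in enumerate(chains):
            if chain not in bond_defs[label]:
                raise ValueError(f"bond {label!r} undefined in chain {chain!r}")
            d_id, a_id = bond_defs[label][chain]
            di, ai = st.index_of(d_id), st.index_of(a_id)
            h_id = hydrogens[(label, chain)]
            dvec = traj.coords[:, ai] - traj.coords[:, di]
            dist = np.linalg.norm(dvec, axis=1)
            ok = dist <= spec.max_da_distance
            if h_id is not None:
                hi = st.index_of(h_id)
                v1 = traj.coords[:, di] - traj.coords[:, hi]
                v2 = traj.coords[:, ai] - traj.coords[:, hi]
                cosang = np.sum(v1 * v2, axis=1) / (
                    np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                ok &= (180.0 - angle) <= spec.max_dha_angle_deviation
            present[bi, ci] = ok

    t0 = traj.times[0]
    win_idx = np.floor((traj.times - t0) / window + 1e-9).astype(int)
    n_windows = win_idx.max() + 1
    counts = np.zeros((len(labels), n_windows), dtype=int)
    mids = np.empty(n_windows)
    for w in range(n_windows):
        frames = win_idx == w
        mids[w] = t0 + (w + 0.5) * window
        frac = present[:, :, frames].mean(axis=2)
        counts[:, w] = (frac >= presence_fraction).sum(axis=1)
    persistence = pd.DataFrame([
        {"bond": label, "chain": chain,
         "fraction": float(present[bi, ci].mean())}
        for bi, label in enumerate(labels) for ci, chain in enumerate(chains)
    ])
    return HBondMap(bond_labels=labels, window_mid_times=mids,
                    counts=counts, persistence=persistence)
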