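"""Membrane-crossing detection, residency times and ion density maps.

An ion counts as having permeated only if it moves from one side of the
membrane slab to the other: per ion, a three-compartment automaton
(below / inside / above) tracks committed states, with a hysteresis buffer
on each face so boundary jitter cannot double-count.  A periodic jump in z
(frame-to-frame |dz| > box_z/2) toggles below <-> above without producing
an event.  Each completed event is assigned to the monomer whose pore axis
is laterally nearest at the ion's midplane passage.

Automaton contract (shared with the synthetic-data ground-truth logger,
which implements it independently at step resolution):

* committed entry: from below when z > z_low, from above when z < z_high;
* committed exit: only past the far face plus the buffer
  (z > z_high + buffer, resp. z < z_low - buffer); an exit on the entry
  side is a retreat and produces no event;
* an entry and exit may cascade within one frame;
* after a periodic wrap the compartment provenance is cleared, so the next
  traversal must be observed in full to count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import Trajectory


@dataclass
class MembraneSlab:
    z_low: float
    z_high: float
    buffer: float = 2.0
    monomer_axes: Sequence[tuple[float, float]] = ()

    def __post_init__(self):
        if not self.z_low < self.z_high:
            raise ValueError("slab requires z_low < z_high")
        if self.z_high - self.z_low <= 0:
            raise ValueError("zero-thickness slab")
        if self.buffer < 0:
            raise ValueError("buffer must be >= 0")


@dataclass
class PermeationEvent:
    ion_id: int
    species: str
    direction: int        # +1 toward +z, -1 toward -z
    t_enter: float        # ns
    t_exit: float         # ns
    monomer: int | None = None

    def __post_init__(self):
        if not self.t_enter < self.t_exit:
            raise ValueError("event requires t_enter < t_exit")


@dataclass
class FluxSeries:
    """Cumulative net-crossing step function for one species x monomer."""

    species: str
    monomer: int | None
    times: np.ndarray       # event times, ns
    steps: np.ndarray       # +1 / -1 per event
    t_start: float
    t_end: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.steps = np.asarray(self.steps, dtype=int)
        if not np.all(np.isin(self.steps, (-1, 1))) and len(self.steps):
            raise ValueError("flux steps must be +/-1")

    @property
    def cumulative_net(self) -> np.ndarray:
        return np.cumsum(self.steps)

    def value_at(self, t: np.ndarray) -> np.ndarray:
        """Cumulative net crossings at times t (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        return np.concatenate(([0], self.cumulative_net))[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ns": self.times, "step": self.steps,
            "cumulative_net": self.cumulative_net,
            "species": self.species, "monomer": self.monomer,
        })


_BELOW, _INSIDE, _ABOVE = 0, 1, 2


def detect_crossings(
    traj: Trajectory,
    slab: MembraneSlab,
    species_map: Mapping[int, str],
) -> tuple[list[PermeationEvent], dict[tuple[str, int | None], FluxSeries]]:
    """Detect completed membrane traversals for the ions in ``species_map``.

    Returns the event list and one :class:`FluxSeries` per
    (species, monomer) pair, consistent with the event list.  ``species_map``
    maps atom_id to species label; all mapped atoms must exist.
    """
    if np.any(~np.isfinite(traj.boxes)):
        raise ValueError("trajectory frames lack box dimensions")
    ion_ids = sorted(species_map)
    try:
        cols = np.array([traj.structure.index_of(i) for i in ion_ids])
    except KeyError as exc:
        raise KeyError(f"ion_id {exc} not present in structure") from exc
    n = len(ion_ids)
    z = traj.coords[:, cols, 2]
    xy = traj.coords[:, cols, :2]
    times = traj.times
    z_low, z_high, buf = slab.z_low, slab.z_high, slab.buffer
    z_mid = 0.5 * (z_low + z_high)
    axes = np.asarray(slab.monomer_axes, dtype=float) \
        if len(slab.monomer_axes) else None

    state = np.where(z[0] < z_low, _BELOW,
                     np.where(z[0] > z_high, _ABOVE, _INSIDE))
    origin = np.full(n, -1, dtype=int)
    t_enter = np.full(n, np.nan)
    mid_xy = np.full((n, 2), np.nan)
    events: list[PermeationEvent] = []

    def _assign_monomer(i, frame):
        if axes is None:
            return None
        p = mid_xy[i] if np.isfinite(mid_xy[i, 0]) else xy[frame, i]
        box = traj.boxes[frame, :2]
        d = axes - p
        d -= box * np.round(d / box)
        return int(np.argmin(np.einsum("ij,ij->i", d, d)))

    for f in range(1, traj.n_frames):
        zf = z[f]
        box_z = traj.boxes[f, 2]
        jumped = np.abs(zf - z[f - 1]) > box_z / 2.0
        for i in np.nonzero(jumped)[0]:
            if state[i] == _BELOW:
                state[i] = _ABOVE
            elif state[i] == _ABOVE:
                state[i] = _BELOW
            else:
                state[i] = (_BELOW if zf[i] < z_low
                            else _ABOVE if zf[i] > z_high else _INSIDE)
                origin[i] = -1
                t_enter[i] = np.nan
                mid_xy[i] = np.nan
        act = np.nonzero(~jumped)[0]
        za = zf[act]
        st = state[act]
        enter_b = act[(st == _BELOW) & (za > z_low)]
        enter_a = act[(st == _ABOVE) & (za < z_high)]
        for idx, org in ((enter_b, _BELOW), (enter_a, _ABOVE)):
            state[idx] = _INSIDE
            origin[idx] = org
            t_enter[idx] = times[f]
            mid_xy[idx] = np.nan
        inside = act[state[act] == _INSIDE]
        if len(inside):
            # record lateral position at first midplane passage
            passed = np.nonzero(
                ((origin[inside] == _BELOW) & (z[f, inside] >= z_mid))
                | ((origin[inside] == _ABOVE) & (z[f, inside] <= z_mid))
            )[0]
            for i in inside[passed]:
                if not np.isfinite(mid_xy[i, 0]):
                    mid_xy[i] = xy[f, i]
        exit_up = inside[zf[inside] > z_high + buf]
        exit_dn = inside[zf[inside] < z_low - buf]
        for idx, new_state, direction in ((exit_up, _ABOVE, +1),
                                          (exit_dn, _BELOW, -1)):
            for i in idx:
                if (direction == +1 and origin[i] == _BELOW) or \
                        (direction == -1 and origin[i] == _ABOVE):
                    # a traversal completed within one frame interval entered
                    # after the previous frame
                    te = float(t_enter[i])
                    if te >= times[f]:
                        te = float(times[f - 1])
                    events.append(PermeationEvent(
                        ion_id=ion_ids[i],
                        species=species_map[ion_ids[i]],
                        direction=direction,
                        t_enter=te,
                        t_exit=float(times[f]),
                        monomer=_assign_monomer(i, f),
                    ))
                state[i] = new_state
                origin[i] = -1
                t_enter[i] = np.nan
                mid_xy[i] = np.nan

    flux = build_flux_series(events, species_map, float(times[0]),
                             float(times[-1]),
                             n_monomers=(len(slab.monomer_axes) or None))
    return events, flux


def build_flux_series(events: Sequence[PermeationEvent],
                      species_map: Mapping[int, str],
                      t_start: float, t_end: float,
                      n_monomers: int | None = None,
                      ) -> dict[tuple[str, int | None], FluxSeries]:
    """Group events into per-(species, monomer) cumulative flux series."""
    species = sorted(set(species_map.values()))
    monomers: list[int | None] = list(range(n_monomers)) if n_monomers else [None]
    grouped: dict[tuple, list] = {(s, m): [] for s in species for m in monomers}
    for ev in sorted(events, key=lambda e: e.t_exit):
        key = (ev.species, ev.monomer)
        grouped.setdefault(key, []).append(ev)
    return {
        key: FluxSeries(
            species=key[0], monomer=key[1],
            times=np.array([e.t_exit for e in evs]),
            steps=np.array([e.direction for e in evs], dtype=int),
            t_start=t_start, t_end=t_end,
        )
        for key, evs in grouped.items()
    }


def merge_flux(series: Sequence[FluxSeries], species: str = "total",
               monomer: int | None = None) -> FluxSeries:
    """Merge several flux series into one (events interleaved by time)."""
    if not series:
        raise ValueError("nothing to merge")
    times = np.concatenate([s.times for s in series])
    steps = np.concatenate([s.steps for s in series])
    order = np.argsort(times, kind="stable")
    return FluxSeries(species=species, monomer=monomer, times=times[order],
                      steps=steps[order],
                      t_start=min(s.t_start for s in series),
                      t_end=max(s.t_end for s in series))


def residency_times(events: Sequence[PermeationEvent]) -> pd.DataFrame:
    """Per-species residency durations (t_exit - t_enter) with summaries.

    Returns a tidy frame with one row per species: n, mean and median
    duration in ns, plus the raw durations as a list column.
    """
    rows = []
    by_species: dict[str, list[float]] = {}
    for ev in events:
        by_species.setdefault(ev.species, []).append(ev.t_exit - ev.t_enter)
    for sp in sorted(by_species):
        d = np.array(by_species[sp])
        rows.append({"species": sp, "n_events": len(d),
                     "mean_ns": float(d.mean()), "median_ns": float(np.median(d)),
                     "durations_ns": d.tolist()})
    return pd.DataFrame(rows, columns=["species", "n_events", "mean_ns",
                                       "median_ns", "durations_ns"])


def ion_density_grid(traj: Trajectory, selection: Sequence[int],
                     voxel: float) -> tuple[np.ndarray, list[np.ndarray]]:
    """Time-averaged number density on a voxel grid covering the box (A^-3).

    Returns (grid, bin_edges).  density[i,j,k] = mean over frames of the
    ion count in the voxel divided by the voxel volume.  Positions are
    wrapped into the primary box of each frame before binning.
    """
    if voxel <= 0:
        raise ValueError("voxel must be > 0")
    box = traj.boxes[0]
    if np.any(voxel > box):
        raise ValueError("voxel larger than the box")
    nbins = np.maximum(1, np.ceil(box / voxel)).astype(int)
    edges = [np.arange(nb + 1) * voxel for nb in nbins]
    grid = np.zeros(tuple(nbins))
    cols = [traj.structure.index_of(i) for i in selection]
    if cols:
        for f in range(traj.n_frames):
            p = traj.coords[f, cols] % traj.boxes[f]
            h, _ = np.histogramdd(p, bins=edges)
            grid += h
    grid /= traj.n_frames * voxel ** 3
    return grid, edges
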