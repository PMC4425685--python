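"""Niche occupancy, gating-event timelines and closure kinetics.

Voltage gating in porins proceeds as an ordered cascade: a main-chain flip
opens an acidic niche between loop L3 and the barrel wall, a cation lodges
in it, further rearrangements expose a second niche, and finally an
aromatic side chain swings into the lumen and throttles the current.  This
module provides the three analysis pieces for that picture: geometric
binding-site occupancy series, a merged time-ordered event timeline with
precedence queries, and an exponential closure fit I(t) = a exp(-b t) to
windowed currents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .electrophys import CurrentSeries
from .io_core import Trajectory

DEFAULT_OCCUPANCY_CUTOFF = 3.5  # A


@dataclass
class BindingSite:
    label: str
    site_atoms: Sequence[int]          # atom_ids
    cutoff: float = DEFAULT_OCCUPANCY_CUTOFF
    species: str | None = None         # restrict to one ion species if set

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class OccupancySeries:
    site: str
    times: np.ndarray
    occupant: np.ndarray               # ion_id per frame, -1 if empty
    intervals: list[tuple[int, float, float]]   # (ion, t_on, t_off)

    @property
    def first_binding_time(self) -> float | None:
        return self.intervals[0][1] if self.intervals else None


@dataclass(frozen=True)
class TimelineEvent:
    time: float
    monomer: int | str | None
    kind: str    # segment_flip | dihedral_flip | site_bound | site_released
    #            | hbond_lost | hbond_formed
    label: str = ""


@dataclass
class DecayFit:
    a: float | None                    # pA
    b: float | None                    # 1/ns
    sse: float | None
    ok: bool

    def t_to_fraction(self, fraction: float) -> float:
        """Time for the current to decay to the given fraction: ln(1/f)/b."""
        if not self.ok:
            raise ValueError("fit failed; no parameters")
        if not (0 < fraction < 1):
            raise ValueError("fraction must lie in (0, 1)")
        if self.b == 0:
            return float("inf")
        return float(np.log(1.0 / fraction) / self.b)


def site_occupancy(traj: Trajectory, site: BindingSite,
                   species_map: Mapping[int, str],
                   gap_tolerance: int = 1) -> OccupancySeries:
    """Occupancy of a binding site over a trajectory.

    A frame is occupied if any ion of the filtered species lies within
    ``site.cutoff`` (inclusive) of any site atom, by minimum-image
    distance; the recorded occupant is the nearest such ion.  Occupied
    stretches of the same ion are merged across gaps of up to
    ``gap_tolerance`` frames into intervals (ion, t_on, t_off).
    """
    site_cols = [traj.structure.index_of(i) for i in site.site_atoms]
    if not site_cols:
        raise ValueError("empty site selection")
    ion_ids = sorted(i for i in species_map
                     if site.species is None or species_map[i] == site.species)
    ion_cols = np.array([traj.structure.index_of(i) for i in ion_ids],
                        dtype=int)
    if not len(ion_cols):
        return OccupancySeries(site=site.label, times=traj.times.copy(),
                               occupant=np.full(traj.n_frames, -1, dtype=int),
                               intervals=[])
    occupant = np.full(traj.n_frames, -1, dtype=int)
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        d = traj.coords[f, ion_cols, None, :] - traj.coords[f, None, site_cols, :]
        d -= box * np.round(d / box)
        dist2 = np.min(np.sum(d * d, axis=-1), axis=1)
        near = dist2 <= site.cutoff ** 2
        if near.any():
            occupant[f] = ion_ids[int(np.argmin(np.where(near, dist2, np.inf)))]

    intervals: list[tuple[int, float, float]] = []
    cur_ion, t_on, last_on = -1, 0.0, -1
    for f in range(traj.n_frames):
        ion = occupant[f]
        if ion >= 0:
            if cur_ion == ion and f - last_on <= gap_tolerance + 1:
                last_on = f
            else:
                if cur_ion >= 0:
                    intervals.append((cur_ion, t_on, float(traj.times[last_on])))
                cur_ion, t_on, last_on = ion, float(traj.times[f]), f
        elif cur_ion >= 0 and f - last_on > gap_tolerance:
            intervals.append((cur_ion, t_on, float(traj.times[last_on])))
            cur_ion = -1
    if cur_ion >= 0:
        intervals.append((cur_ion, t_on, float(traj.times[last_on])))
    return OccupancySeries(site=site.label, times=traj.times.copy(),
                           occupant=occupant, intervals=intervals)


_KIND_ORDER = ("segment_flip", "dihedral_flip", "site_bound", "site_released",
               "hbond_lost", "hbond_formed")


@dataclass
class Timeline:
    events: list[TimelineEvent]

    def precedes(self, kind_a: str, kind_b: str,
                 monomer=None) -> bool | None:
        """Whether the first event of kind_a precedes the first of kind_b.

        Restricted to one monomer if given; None if either kind is absent.
        """
        def first(kind):
            for ev in self.events:
                if ev.kind == kind and (monomer is None or ev.monomer == monomer):
                    return ev.time
            return None

        ta, tb = first(kind_a), first(kind_b)
        if ta is None or tb is None:
            return None
        return ta < tb


def event_timeline(*sources: Sequence[TimelineEvent]) -> Timeline:
    """Merge event lists into a stable time-ordered timeline.

    Sorted by (time, kind, label); the kind order follows the gating
    cascade (conformational flips before binding before H-bond changes) so
    simultaneous events render in mechanistic order.
    """
    merged = [ev for src in sources for ev in src]
    merged.sort(key=lambda e: (
        e.time,
        _KIND_ORDER.index(e.kind) if e.kind in _KIND_ORDER else len(_KIND_ORDER),
        e.label))
    return Timeline(events=merged)


def closure_fit(current: CurrentSeries) -> DecayFit:
    """Fit I(t) = a exp(-b t) to windowed currents by nonlinear least squares.

    Initialisation comes from a log-linear fit of the positive samples.
    Non-positive or non-decreasing data flag the fit as failed and no
    parameters are returned.
    """
    t = current.window_mid_times
    y = current.currents
    if len(t) < 3:
        raise ValueError("closure fit needs >= 3 windows")
    pos = y > 0
    if pos.sum() < 3 or np.polyfit(t, y, 1)[0] > 0:
        warnings.warn("closure_fit: data non-positive or non-decreasing; "
                      "fit not attempted")
        return DecayFit(a=None, b=None, sse=None, ok=False)
    coef = np.polyfit(t[pos], np.log(y[pos]), 1)
    a0, b0 = float(np.exp(coef[1])), float(max(-coef[0], 0.0))
    try:
        popt, _ = curve_fit(lambda tt, a, b: a * np.exp(-b * tt), t, y,
                            p0=(a0, b0), maxfev=10_000)
    except RuntimeError:
        warnings.warn("closure_fit: optimiser failed to converge")
        return DecayFit(a=None, b=None, sse=None, ok=False)
    a, b = float(popt[0]), float(popt[1])
    if a <= 0 or b < 0:
        return DecayFit(a=None, b=None, sse=None, ok=False)
    sse = float(np.sum((y - a * np.exp(-b * t)) ** 2))
    return DecayFit(a=a, b=b, sse=sse, ok=True)
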