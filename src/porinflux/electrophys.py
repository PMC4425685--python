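"""Currents, conductance, diffusion coefficients and selectivity.

The current carried by a species is obtained from the slope of its
cumulative net-crossing step function within non-overlapping time windows
(default 50 ns, aligned to t = 0), converted to pA via the elementary
charge.  Channel conductance is the least-squares slope of the I-V curve
(default voltage set [-1, 0, +1] V).  Simulated diffusion coefficients come
from the Einstein relation (MSD slope / 6) at zero field, and currents may
be rescaled by the ratio of experimental to simulated diffusion
coefficients before the I-V fit ("corrected" conductance).  Selectivity is
the ratio of cation to anion current per monomer, averaged over monomers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_core import Trajectory
from .permeation import FluxSeries
from .units import PA_PER_E_PER_NS, d_A2ns_to_cm2s

#: accepted bulk diffusion coefficients at infinite dilution, 1e-5 cm^2/s.
#: The corresponding internal values are 100x these, in A^2/ns.
D_EXPERIMENTAL_1E5_CM2_S = {"K": 1.96, "CL": 2.02}

DEFAULT_VOLTAGES = (-1.0, 0.0, 1.0)
DEFAULT_WINDOW_NS = 50.0

# samples per window used to regress the cumulative-crossing step function
_SAMPLES_PER_WINDOW = 201


@dataclass
class CurrentSeries:
    species: str
    monomer: int | None
    window_length: float           # ns
    window_mid_times: np.ndarray   # ns
    currents: np.ndarray           # pA

    def __post_init__(self):
        self.window_mid_times = np.asarray(self.window_mid_times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.window_length <= 0:
            raise ValueError("window_length must be > 0")
        if self.window_mid_times.shape != self.currents.shape:
            raise ValueError("times and currents must have equal length")

    @property
    def mean_current(self) -> float:
        return float(self.currents.mean())


@dataclass
class IVResult:
    voltages: tuple[float, ...]
    total_currents: dict[float, float]          # pA per voltage
    conductance_raw: float                      # nS
    conductance_corrected: float | None         # nS
    intercept_pA: float
    per_species_currents: dict[float, dict[str, float]]
    selectivity_per_voltage: dict[float, tuple[float, float]]  # mean, sd


def window_currents(flux: FluxSeries, charge: int,
                    window: float = DEFAULT_WINDOW_NS) -> CurrentSeries:
    """Windowed currents from a cumulative net-crossing series.

    Within each non-overlapping window (aligned to t = 0) the crossing rate
    is the least-squares slope of the cumulative net count versus time,
    evaluated on a dense uniform sampling of the step function; the current
    is slope x charge x 160.2176634 pA/(e/ns).
    """
    span = flux.t_end - flux.t_start
    if window > span:
        raise ValueError(f"window {window} ns longer than trajectory span {span} ns")
    n_windows = int(np.floor((flux.t_end - 0.0) / window + 1e-9))
    first = int(np.floor(flux.t_start / window + 1e-9))
    mids, currents = [], []
    for w in range(first, n_windows):
        t0, t1 = w * window, (w + 1) * window
        ts = np.linspace(t0, t1, _SAMPLES_PER_WINDOW)
        ns_counts = flux.value_at(ts).astype(float)
        slope = np.polyfit(ts, ns_counts, 1)[0]
        mids.append(0.5 * (t0 + t1))
        currents.append(slope * charge * PA_PER_E_PER_NS)
    return CurrentSeries(species=flux.species, monomer=flux.monomer,
                         window_length=window,
                         window_mid_times=np.array(mids),
                         currents=np.array(currents))


def iv_conductance(currents_by_voltage: Mapping[float, float]
                   ) -> tuple[float, float]:
    """Least-squares I-V slope in nS (and intercept in pA).

    ``currents_by_voltage`` maps voltage (V) to total current (pA); at
    least two distinct voltages are required.
    """
    volts = np.array(sorted(currents_by_voltage))
    if len(np.unique(volts)) < 2:
        raise ValueError("need at least 2 distinct voltages for an I-V slope")
    amps_nA = np.array([currents_by_voltage[v] for v in volts]) / 1000.0
    slope, intercept = np.polyfit(volts, amps_nA, 1)
    return float(slope), float(intercept * 1000.0)


def msd_diffusion(traj: Trajectory, selection: Sequence[int],
                  fit_window: tuple[float, float] = (0.1, 0.5),
                  weighted: bool = True) -> tuple[float, float]:
    """Diffusion coefficient from the Einstein relation at zero field.

    Coordinates are unwrapped internally (minimum-image frame-to-frame
    displacements), the mean squared displacement is averaged over ions and
    time origins, and D = slope/6 of MSD versus lag time over the fraction
    range ``fit_window`` of the maximum lag.  With ``weighted`` (default)
    each lag point enters the fit with weight proportional to its inverse
    standard error — the MSD estimate at lag L rests on ~(n-L)/L
    independent segments, so long lags are far noisier than short ones.
    Returns (D in A^2/ns, D in 1e-5 cm^2/s).
    """
    if traj.n_frames < 100:
        raise ValueError("msd_diffusion needs >= 100 frames")
    cols = [traj.structure.index_of(i) for i in selection]
    if not cols:
        raise ValueError("empty selection")
    r = traj.coords[:, cols, :]
    d = np.diff(r, axis=0)
    d -= traj.boxes[1:, None, :] * np.round(d / traj.boxes[1:, None, :])
    unwrapped = np.concatenate([r[:1], r[:1] + np.cumsum(d, axis=0)], axis=0)
    n = traj.n_frames
    max_lag = n - 1
    lags = np.unique(np.linspace(1, max_lag, min(max_lag, 200)).astype(int))
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        disp = unwrapped[lag:] - unwrapped[:-lag]
        msd[k] = np.mean(np.sum(disp ** 2, axis=-1))
    tau = traj.times[lags] - traj.times[0]
    lo, hi = fit_window
    tmax = tau[-1]
    mask = (tau >= lo * tmax) & (tau <= hi * tmax)
    if mask.sum() < 2:
        raise ValueError("fit window selects fewer than 2 lag points")
    if weighted:
        w = np.sqrt((n - lags[mask]) / lags[mask] ** 2)
        slope = np.polyfit(tau[mask], msd[mask], 1, w=w)[0]
    else:
        slope = np.polyfit(tau[mask], msd[mask], 1)[0]
    d_A2ns = float(slope / 6.0)
    return d_A2ns, d_A2ns_to_cm2s(d_A2ns)


def corrected_conductance(
    per_species_currents_by_voltage: Mapping[float, Mapping[str, float]],
    d_sim: Mapping[str, float],
    d_exp: Mapping[str, float],
) -> tuple[float, float]:
    """Diffusion-corrected I-V slope in nS (and intercept in pA).

    Each species' current is multiplied by D_exp/D_sim for that species
    (units of the two mappings must match each other) before the least-
    squares I-V fit of the summed totals.
    """
    species = {sp for cur in per_species_currents_by_voltage.values() for sp in cur}
    for sp in species:
        if sp not in d_sim or sp not in d_exp:
            raise KeyError(f"missing diffusion coefficient for species {sp!r}")
        if d_sim[sp] <= 0:
            raise ValueError(f"non-positive simulated D for species {sp!r}")
    totals = {
        v: sum(cur[sp] * d_exp[sp] / d_sim[sp] for sp in cur)
        for v, cur in per_species_currents_by_voltage.items()
    }
    return iv_conductance(totals)


def selectivity_ratio(
    per_monomer_currents: Mapping[int, tuple[float, float]],
) -> tuple[float, float]:
    """Cation/anion current-ratio selectivity, averaged over monomers.

    ``per_monomer_currents`` maps monomer index to (I_cation, I_anion) in
    pA at one voltage.  Returns (mean, population sd) of |I_cat|/|I_an|
    over monomers; monomers with zero anion current are flagged as
    infinitely selective and excluded from the mean with a warning.
    """
    import warnings

    ratios = []
    for mono, (i_cat, i_an) in sorted(per_monomer_currents.items()):
        if i_an == 0.0:
            warnings.warn(f"monomer {mono}: zero anion current; "
                          "infinite selectivity excluded from mean")
            continue
        ratios.append(abs(i_cat) / abs(i_an))
    if not ratios:
        return float("inf"), 0.0
    r = np.array(ratios)
    return float(r.mean()), float(r.std())  # population sd
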