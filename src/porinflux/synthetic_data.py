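"""Ground-truth-known synthetic inputs.

The centrepiece is a Brownian-dynamics (BD) electrolyte simulator: point
ions of one or more species drift in a uniform axial electric field
E = V/L_z and diffuse by overdamped Langevin dynamics, with periodic
boundaries in all axes, an optional impermeable membrane slab pierced by
cylindrical pores, and optional sticky binding sites with first-order
escape.  Every membrane traversal and binding interval the simulator
actually executes is logged step-by-step into a :class:`GroundTruth`
record, so that the downstream analyses (crossing detection, currents,
selectivity, occupancy) can be validated against exact known answers.

Also provided: a pseudo-atom cylindrical channel fixture (a stand-in for a
porin barrel), scripted hydrogen-bond on/off trajectories, and noisy
exponential-decay current series for closure-kinetics fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_core import AtomRecord, StructureModel, Trajectory, PH7_CHARGES, vdw_for
from .units import kT_eV


@dataclass
class SpeciesSpec:
    label: str
    count: int
    charge: int          # e
    diffusion: float     # A^2/ns


@dataclass
class BindingSiteSpec:
    center: tuple[float, float, float]  # A
    capture_radius: float               # A
    p_off: float                        # escape probability per step
    capacity: int = 1


@dataclass
class SynthConfig:
    """Brownian-dynamics run configuration.

    Defaults correspond to a desk-scale 1 M KCl electrolyte at 310 K:
    a 50 x 50 x 100 A box holds 150 K+ and 150 Cl- (0.6 mM A^-3 ~ 1 M per
    species), with diffusion coefficients 196 / 202 A^2/ns (the accepted
    bulk values 1.96 / 2.02 x 1e-5 cm^2/s).
    """

    box: tuple[float, float, float] = (50.0, 50.0, 100.0)
    membrane_z: tuple[float, float] | None = None
    pores: Sequence[tuple[float, float, float]] = ()   # (cx, cy, radius)
    species: Sequence[SpeciesSpec] = field(default_factory=lambda: [
        SpeciesSpec("K", 150, +1, 196.0),
        SpeciesSpec("CL", 150, -1, 202.0),
    ])
    voltage: float = 0.0          # V, field along +z is voltage/box_z
    temperature: float = 310.0    # K
    dt: float = 1e-3              # ns
    n_steps: int = 100_000
    binding_sites: Sequence[BindingSiteSpec] = ()
    seed: int = 0
    save_every: int = 10          # frame stride; 1 => exact step-level frames
    slab_buffer: float = 2.0      # hysteresis buffer for crossing logging, A

    def __post_init__(self):
        self.species = [s if isinstance(s, SpeciesSpec) else SpeciesSpec(*s)
                        for s in self.species]
        self.binding_sites = [b if isinstance(b, BindingSiteSpec)
                              else BindingSiteSpec(*b) for b in self.binding_sites]
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if any(s.count <= 0 for s in self.species):
            raise ValueError("species counts must be > 0")
        if any(r <= 0 for _, _, r in self.pores):
            raise ValueError("pore radius must be > 0")
        for _, _, r in self.pores:
            if r >= min(self.box[0], self.box[1]) / 2:
                raise ValueError("pore radius must be smaller than half the box width")
        for b in self.binding_sites:
            if not (0.0 <= b.p_off <= 1.0):
                raise ValueError("p_off must lie in [0, 1]")
        for i, bi in enumerate(self.binding_sites):
            for bj in self.binding_sites[i + 1:]:
                d = np.linalg.norm(np.subtract(bi.center, bj.center))
                if d < bi.capture_radius + bj.capture_radius:
                    raise ValueError("binding sites overlap")
        if self.membrane_z is not None:
            z1, z2 = self.membrane_z
            if not (0 < z1 < z2 < self.box[2]):
                raise ValueError("membrane_z must satisfy 0 < z1 < z2 < box_z")


@dataclass
class GroundTruth:
    """Exact record of what the simulator executed, plus analytic anchors."""

    expected_drift_velocity: dict[str, float]   # A/ns, signed
    expected_plane_flux: dict[str, float]       # net crossings/ns (free mode)
    realized_crossings: list[tuple[int, int, float]]       # (ion, dir, time)
    realized_binding_intervals: list[tuple[int, int, float, float]]
    species_of: dict[int, str]
    ion_charge: dict[int, int]


def drift_velocity(charge: int, diffusion: float, voltage: float,
                   box_z: float, temperature: float) -> float:
    """Stokes-Einstein drift v = q e E D / kT in A/ns (E = V/L_z)."""
    if voltage == 0.0:
        return 0.0
    e_field = voltage / box_z            # V/A
    return charge * e_field * diffusion / kT_eV(temperature)


def _inside_pore_mask(xy: np.ndarray, pores, box) -> np.ndarray:
    """Laterally inside any pore cylinder, minimum image in x/y."""
    ok = np.zeros(len(xy), dtype=bool)
    for cx, cy, r in pores:
        dx = xy[:, 0] - cx
        dy = xy[:, 1] - cy
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        ok |= dx * dx + dy * dy <= r * r
    return ok


class _SlabAutomaton:
    """Per-step three-compartment crossing logger with hysteresis.

    Runs on the simulator's own step-resolved, wrap-aware path record and is
    therefore independent of the frame-level analysis in
    :mod:`porinflux.permeation`, while obeying the same contract: an event
    is committed only for a below->inside->above (direction +1) or
    above->inside->below (-1) traversal, an exit commits only past the slab
    face plus the hysteresis buffer, and a periodic z-wrap toggles
    below<->above without an event.
    """

    BELOW, INSIDE, ABOVE = 0, 1, 2

    def __init__(self, n_ions: int, z0: np.ndarray, z_low: float, z_high: float,
                 buffer: float):
        self.z_low, self.z_high, self.buf = z_low, z_high, buffer
        self.state = np.where(z0 < z_low, self.BELOW,
                              np.where(z0 > z_high, self.ABOVE, self.INSIDE))
        self.origin = np.full(n_ions, -1, dtype=int)  # -1: unknown provenance
        self.events: list[tuple[int, int, float]] = []

    def step(self, z: np.ndarray, wrapped: np.ndarray, time: float):
        for i in np.nonzero(wrapped)[0]:
            if self.state[i] == self.BELOW:
                self.state[i] = self.ABOVE
            elif self.state[i] == self.ABOVE:
                self.state[i] = self.BELOW
            else:
                zi = z[i]
                self.state[i] = (self.BELOW if zi < self.z_low
                                 else self.ABOVE if zi > self.z_high else self.INSIDE)
                self.origin[i] = -1
        active = np.nonzero(~wrapped)[0]
        zi = z[active]
        st = self.state[active]
        # entries
        enter_b = (st == self.BELOW) & (zi > self.z_low)
        enter_a = (st == self.ABOVE) & (zi < self.z_high)
        idx_b = active[enter_b]
        idx_a = active[enter_a]
        self.state[idx_b] = self.INSIDE
        self.origin[idx_b] = self.BELOW
        self.state[idx_a] = self.INSIDE
        self.origin[idx_a] = self.ABOVE
        # exits (re-read states so a same-step enter+exit cascades)
        st = self.state[active]
        inside = st == self.INSIDE
        exit_up = inside & (zi > self.z_high + self.buf)
        exit_dn = inside & (zi < self.z_low - self.buf)
        for i in active[exit_up]:
            if self.origin[i] == self.BELOW:
                self.events.append((int(i), +1, time))
            self.state[i] = self.ABOVE
            self.origin[i] = -1
        for i in active[exit_dn]:
            if self.origin[i] == self.ABOVE:
                self.events.append((int(i), -1, time))
            self.state[i] = self.BELOW
            self.origin[i] = -1


def simulate_ions(config: SynthConfig) -> tuple[Trajectory, GroundTruth]:
    """Run the BD simulation and return (trajectory, ground truth).

    Update rule per ion and step (Euler-Maruyama, overdamped):
    dr = (q e E D / kT) z_hat dt + sqrt(2 D dt) xi, with xi standard normal
    per axis and E = voltage/box_z applied uniformly over the whole box.
    Positions wrap periodically in all axes.  The membrane slab reflects
    ions specularly except laterally inside a pore cylinder; an ion leaving
    a pore sideways is reflected off the cylinder wall.  A bound ion is
    frozen at its site centre and escapes with probability p_off per step,
    re-appearing just outside the capture radius.

    The run is fully reproducible from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    box = np.asarray(cfg.box, dtype=float)
    n_ions = sum(s.count for s in cfg.species)

    labels, charges, diffs = [], [], []
    for s in cfg.species:
        labels += [s.label] * s.count
        charges += [s.charge] * s.count
        diffs += [s.diffusion] * s.count
    charges = np.array(charges, dtype=float)
    diffs = np.array(diffs, dtype=float)

    kT = kT_eV(cfg.temperature)
    e_field = cfg.voltage / box[2]
    drift = charges * e_field * diffs / kT * cfg.dt          # A per step, z
    sigma = np.sqrt(2.0 * diffs * cfg.dt)                    # A per step/axis

    # initial placement: uniform, outside the slab unless inside a pore
    pos = rng.uniform(0.0, 1.0, size=(n_ions, 3)) * box
    if cfg.membrane_z is not None:
        z1, z2 = cfg.membrane_z
        for _ in range(10_000):
            in_slab = (pos[:, 2] > z1) & (pos[:, 2] < z2)
            bad = in_slab & ~_inside_pore_mask(pos[:, :2], cfg.pores, box)
            if not bad.any():
                break
            pos[bad] = rng.uniform(0.0, 1.0, size=(int(bad.sum()), 3)) * box
        else:  # pragma: no cover
            raise RuntimeError("could not place ions outside the membrane")

    frozen = np.zeros(n_ions, dtype=bool)
    site_occupant = [-1] * len(cfg.binding_sites)
    site_centers = np.array([b.center for b in cfg.binding_sites], dtype=float) \
        if cfg.binding_sites else np.zeros((0, 3))
    bind_start = {}
    intervals: list[tuple[int, int, float, float]] = []

    n_saved = cfg.n_steps // cfg.save_every + 1
    frames = np.empty((n_saved, n_ions + len(cfg.binding_sites), 3))
    times = np.empty(n_saved)

    def _store(k, step):
        frames[k, :n_ions] = pos
        if len(cfg.binding_sites):
            frames[k, n_ions:] = site_centers
        times[k] = step * cfg.dt

    _store(0, 0)
    saved = 1

    if cfg.membrane_z is not None:
        automaton = _SlabAutomaton(n_ions, pos[:, 2].copy(), cfg.membrane_z[0],
                                   cfg.membrane_z[1], cfg.slab_buffer)
        plane_z = None
    else:
        automaton = None
        plane_z = box[2] / 2.0
        plane_events: list[tuple[int, int, float]] = []
        z_unwrapped = pos[:, 2].copy()

    for step in range(1, cfg.n_steps + 1):
        t = step * cfg.dt
        noise = rng.standard_normal((n_ions, 3)) * sigma[:, None]
        disp = noise
        disp[:, 2] += drift
        disp[frozen] = 0.0
        new = pos + disp

        if cfg.membrane_z is not None:
            z1, z2 = cfg.membrane_z
            in_slab_new = (new[:, 2] > z1) & (new[:, 2] < z2)
            lateral_ok = _inside_pore_mask(new[:, :2], cfg.pores, box)
            blocked = in_slab_new & ~lateral_ok & ~frozen
            if blocked.any():
                idx = np.nonzero(blocked)[0]
                was_outside = (pos[idx, 2] <= z1) | (pos[idx, 2] >= z2)
                # face reflection for ions that hit the slab from outside
                face_lo = was_outside & (pos[idx, 2] <= z1)
                face_hi = was_outside & (pos[idx, 2] >= z2)
                new[idx[face_lo], 2] = 2 * z1 - new[idx[face_lo], 2]
                new[idx[face_hi], 2] = 2 * z2 - new[idx[face_hi], 2]
                # lateral reflection off the pore wall for ions inside a pore
                for i in idx[~was_outside]:
                    cx, cy, r = min(
                        cfg.pores,
                        key=lambda p: (pos[i, 0] - p[0]) ** 2 + (pos[i, 1] - p[1]) ** 2,
                    )
                    dx, dy = new[i, 0] - cx, new[i, 1] - cy
                    rr = np.hypot(dx, dy)
                    if rr > r:
                        scale = max(2 * r - rr, 1e-6) / rr
                        new[i, 0] = cx + dx * scale
                        new[i, 1] = cy + dy * scale

        # periodic wrap; remember which ions wrapped in z
        pre_wrap_z = new[:, 2].copy()
        new %= box
        z_wrapped = new[:, 2] != pre_wrap_z

        if plane_z is not None:
            dz = pre_wrap_z - pos[:, 2]
            old_u = z_unwrapped.copy()
            z_unwrapped += dz
            k_new = np.floor((z_unwrapped - plane_z) / box[2])
            k_old = np.floor((old_u - plane_z) / box[2])
            dn = (k_new - k_old).astype(int)
            for i in np.nonzero(dn != 0)[0]:
                d = int(np.sign(dn[i]))
                for _ in range(abs(dn[i])):
                    plane_events.append((int(i), d, t))

        pos = new

        # binding sites: release first, then capture (never both in a step)
        for s_idx, site in enumerate(cfg.binding_sites):
            occ = site_occupant[s_idx]
            if occ >= 0:
                if site.p_off > 0 and rng.random() < site.p_off:
                    direction = rng.standard_normal(3)
                    direction /= np.linalg.norm(direction)
                    pos[occ] = (site_centers[s_idx]
                                + direction * (site.capture_radius + 0.5)) % box
                    frozen[occ] = False
                    intervals.append((s_idx, occ, bind_start.pop(occ),
                                      (step - 1) * cfg.dt))
                    site_occupant[s_idx] = -1
            else:
                d = pos - site_centers[s_idx]
                d -= box * np.round(d / box)
                dist2 = np.einsum("ij,ij->i", d, d)
                cand = np.nonzero((dist2 <= site.capture_radius ** 2) & ~frozen)[0]
                if len(cand):
                    chosen = int(cand[np.argmin(dist2[cand])])
                    pos[chosen] = site_centers[s_idx]
                    frozen[chosen] = True
                    site_occupant[s_idx] = chosen
                    bind_start[chosen] = t

        if automaton is not None:
            automaton.step(pos[:, 2], z_wrapped, t)

        if step % cfg.save_every == 0:
            _store(saved, step)
            saved += 1

    # close dangling binding intervals at the final frame
    for s_idx, occ in enumerate(site_occupant):
        if occ >= 0:
            intervals.append((s_idx, occ, bind_start.pop(occ), cfg.n_steps * cfg.dt))

    atoms = []
    for i in range(n_ions):
        atoms.append(AtomRecord(
            atom_id=i, name=labels[i], element=labels[i], residue_name=labels[i],
            residue_id=i + 1, chain_id="I", position=frames[0, i],
            formal_charge=int(charges[i]),
        ))
    for s_idx in range(len(cfg.binding_sites)):
        atoms.append(AtomRecord(
            atom_id=n_ions + s_idx, name="STE", element="X", residue_name="STE",
            residue_id=s_idx + 1, chain_id="S", position=site_centers[s_idx],
        ))
    structure = StructureModel(atoms=atoms, box=box.copy())
    traj = Trajectory(structure=structure, times=times, coords=frames,
                      boxes=np.tile(box, (n_saved, 1)))

    area = box[0] * box[1]
    volume = float(np.prod(box))
    vel = {s.label: drift_velocity(s.charge, s.diffusion, cfg.voltage,
                                   box[2], cfg.temperature) for s in cfg.species}
    flux = {s.label: s.count / volume * area * vel[s.label] for s in cfg.species}
    gt = GroundTruth(
        expected_drift_velocity=vel,
        expected_plane_flux=flux,
        realized_crossings=(automaton.events if automaton is not None
                            else plane_events),
        realized_binding_intervals=intervals,
        species_of={i: labels[i] for i in range(n_ions)},
        ion_charge={i: int(charges[i]) for i in range(n_ions)},
    )
    return traj, gt


# ---------------------------------------------------------------------------
# toy channel fixture
# ---------------------------------------------------------------------------

WALL_INSET = 2.0  # charged side-chain carrier atoms sit this far inside the wall


def make_channel_fixture(n_rings: int, ring_radius: float, length: float,
                         charged_residues: Sequence[tuple[str, float]] = (),
                         hbond_pairs: Sequence[tuple[float, float]] = (),
                         n_chains: int = 1,
                         atoms_per_ring: int = 12) -> StructureModel:
    """Build a pseudo-atom cylindrical channel (a toy porin barrel).

    Each chain is a stack of ``n_rings`` carbon rings of radius
    ``ring_radius`` spanning ``length`` along z, centred in its own lateral
    slot of the box.  ``charged_residues`` places single-atom residues
    (e.g. ``("ASP", 0.0)``) at the stated z (measured from the cylinder
    midplane), inset ``WALL_INSET`` A from the wall so they face the lumen.
    ``hbond_pairs`` places donor(N,H)/acceptor(O) residues on the wall at
    the stated z values; the donor-acceptor distance equals the z
    separation.  Layout is identical in every chain, so per-monomer
    equivalent bonds and residues exist by construction.
    """
    if ring_radius <= 0:
        raise ValueError("ring_radius must be > 0")
    for resname, z in charged_residues:
        if abs(z) > length / 2:
            raise ValueError(f"charged residue {resname} z={z} outside cylinder")
    for zd, za in hbond_pairs:
        if abs(zd) > length / 2 or abs(za) > length / 2:
            raise ValueError("hbond pair z outside cylinder")

    gap = 10.0
    slot = 2 * ring_radius + gap
    box = np.array([slot * n_chains + gap, 2 * ring_radius + 2 * gap,
                    length + 2 * gap])
    zmid = box[2] / 2
    atoms: list[AtomRecord] = []
    atom_id = 0
    chain_names = [chr(ord("A") + c) for c in range(n_chains)]
    for c, chain in enumerate(chain_names):
        cx = gap + ring_radius + c * slot
        cy = box[1] / 2
        for k in range(n_rings):
            z = zmid + (-length / 2 + k * length / max(n_rings - 1, 1))
            for j in range(atoms_per_ring):
                theta = 2 * np.pi * j / atoms_per_ring
                atoms.append(AtomRecord(
                    atom_id=atom_id, name=f"C{j+1}", element="C",
                    residue_name="GLY", residue_id=k + 1, chain_id=chain,
                    position=np.array([cx + ring_radius * np.cos(theta),
                                       cy + ring_radius * np.sin(theta), z]),
                    vdw_radius=vdw_for("C"),
                ))
                atom_id += 1
        for i, (resname, z) in enumerate(charged_residues):
            carrier = PH7_CHARGES.get(resname, (0, "CA"))[1]
            theta = 2 * np.pi * (i + 0.25) / max(len(charged_residues), 1)
            r = ring_radius - WALL_INSET
            atoms.append(AtomRecord(
                atom_id=atom_id, name=carrier, element=carrier[0],
                residue_name=resname, residue_id=100 + i, chain_id=chain,
                position=np.array([cx + r * np.cos(theta),
                                   cy + r * np.sin(theta), zmid + z]),
                vdw_radius=vdw_for(carrier[0]),
            ))
            atom_id += 1
        for i, (zd, za) in enumerate(hbond_pairs):
            theta = 2 * np.pi * (i + 0.5) / max(len(hbond_pairs), 1)
            wx = cx + ring_radius * np.cos(theta)
            wy = cy + ring_radius * np.sin(theta)
            h_off = 1.0 * np.sign(za - zd) if za != zd else 1.0
            atoms.append(AtomRecord(
                atom_id=atom_id, name="N", element="N", residue_name="HBD",
                residue_id=200 + 2 * i, chain_id=chain,
                position=np.array([wx, wy, zmid + zd])))
            atoms.append(AtomRecord(
                atom_id=atom_id + 1, name="H", element="H", residue_name="HBD",
                residue_id=200 + 2 * i, chain_id=chain,
                position=np.array([wx, wy, zmid + zd + h_off])))
            atoms.append(AtomRecord(
                atom_id=atom_id + 2, name="O", element="O", residue_name="HBA",
                residue_id=201 + 2 * i, chain_id=chain,
                position=np.array([wx, wy, zmid + za])))
            atom_id += 3
    return StructureModel(atoms=atoms, box=box)


def channel_axis(structure: StructureModel, chain: str = "A") -> tuple[np.ndarray, np.ndarray]:
    """Axis (origin, unit direction) of a fixture chain's cylinder (along z)."""
    wall = [a for a in structure.atoms
            if a.chain_id == chain and a.residue_name == "GLY"]
    if not wall:
        raise ValueError(f"no wall atoms in chain {chain!r}")
    xy = np.array([a.position for a in wall])
    origin = np.array([xy[:, 0].mean(), xy[:, 1].mean(), xy[:, 2].mean()])
    return origin, np.array([0.0, 0.0, 1.0])


def make_hbond_schedule_trajectory(structure: StructureModel,
                                   schedule: dict,
                                   n_frames: int,
                                   dt: float = 0.1) -> Trajectory:
    """Animate a fixture so that scripted H-bonds are on/off per frame.

    ``schedule`` maps bond label (``"hb0"``, ``"hb1"``, ...) to a per-chain
    mapping of boolean arrays of length ``n_frames``; during "off" frames
    the acceptor oxygen of that pair is displaced 5 A laterally outward,
    far beyond any geometric H-bond cutoff.  Chains absent from a bond's
    mapping keep the bond "on".
    """
    base = structure.positions
    box = structure.box if structure.box is not None else \
        base.max(axis=0) - base.min(axis=0) + 20.0
    acceptor_idx: dict[tuple[str, str], int] = {}
    centers: dict[str, np.ndarray] = {}
    for idx, a in enumerate(structure.atoms):
        if a.residue_name == "HBA" and a.name == "O":
            pair = (a.residue_id - 201) // 2
            acceptor_idx[(f"hb{pair}", a.chain_id)] = idx
        if a.residue_name == "GLY":
            centers.setdefault(a.chain_id, []).append(a.position)
    centers = {c: np.mean(np.array(v), axis=0) for c, v in centers.items()}
    for label, per_chain in schedule.items():
        for chain in per_chain:
            if (label, chain) not in acceptor_idx:
                raise ValueError(f"unknown bond label {label!r} in chain {chain!r}")
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    for label, per_chain in schedule.items():
        for chain, on in per_chain.items():
            on = np.asarray(on, dtype=bool)
            if len(on) != n_frames:
                raise ValueError(f"schedule for {label}/{chain} has wrong length")
            idx = acceptor_idx[(label, chain)]
            direction = base[idx] - centers[chain]
            direction[2] = 0.0
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
            off_pos = base[idx] + 5.0 * direction
            coords[~on, idx, :] = off_pos
    times = np.arange(n_frames) * dt
    return Trajectory(structure=structure, times=times, coords=coords,
                      boxes=np.tile(np.asarray(box, dtype=float), (n_frames, 1)))


def make_decay_series(a: float, b: float, window: float, n_windows: int,
                      noise_sd: float, seed: int):
    """Noisy samples of I(t) = a exp(-b t) at window midpoints (pA)."""
    from .electrophys import CurrentSeries

    if a <= 0:
        raise ValueError("a must be > 0")
    if b < 0:
        raise ValueError("b must be >= 0")
    if n_windows < 3:
        raise ValueError("need at least 3 windows to fit a decay")
    rng = np.random.default_rng(seed)
    t = (np.arange(n_windows) + 0.5) * window
    currents = a * np.exp(-b * t)
    if noise_sd > 0:
        currents = currents + rng.normal(0.0, noise_sd, size=n_windows)
    return CurrentSeries(species="total", monomer=0, window_length=window,
                         window_mid_times=t, currents=currents)
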