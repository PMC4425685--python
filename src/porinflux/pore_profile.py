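"""Pore radius profile, constriction zone and screened-potential profile.

The pore radius at height z along the channel axis is the smallest gap
between the axis and the van der Waals surface of any atom within a thin
slab around z; the global minimum defines the narrowest point.  The
constriction zone (CZ) is the set of residues with any atom within a
fixed radius (default 5 A) of that narrowest axis point, and its net
formal charge is a first-order descriptor of ion selectivity.  A
simplified screened-Coulomb (Debye-Hueckel) potential profile along the
axis stands in for a full Poisson-Boltzmann calculation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_core import StructureModel
from .units import COULOMB_V_A


@dataclass
class PoreProfile:
    axis_origin: np.ndarray      # point on the axis, A
    axis_direction: np.ndarray   # unit vector
    z_grid: np.ndarray           # axial coordinate relative to origin, A
    radius: np.ndarray           # A; NaN where no atoms are in the slab
    narrowest_z: float
    narrowest_radius: float

    def axis_point(self, z: float) -> np.ndarray:
        return self.axis_origin + z * self.axis_direction


@dataclass
class CZReport:
    cz_residues: set
    net_charge_cz: int
    net_charge_pore: int
    per_residue: dict


def principal_axis(structure: StructureModel, selection=None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis (origin, unit direction) of the selected atoms.

    Default axis for a barrel: the dominant eigenvector of the coordinate
    covariance, oriented toward +z.  Porin barrels are straight, so a fixed
    axis (no per-slice optimisation) is adequate.
    """
    if selection is None:
        pos = structure.positions
    else:
        pos = np.array([structure.atom_by_id(i).position for i in selection])
    center = pos.mean(axis=0)
    cov = np.cov((pos - center).T)
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, np.argmax(evals)]
    if direction[2] < 0:
        direction = -direction
    return center, direction / np.linalg.norm(direction)


def radius_profile(structure: StructureModel,
                   axis: tuple[np.ndarray, np.ndarray] | None = None,
                   z_step: float = 1.0,
                   slab_half: float = 3.0) -> PoreProfile:
    """Pore radius along the axis.

    At each grid point z the radius is the minimum over atoms within
    +/- ``slab_half`` of z of (lateral distance from the axis minus the
    atom's van der Waals radius), floored at 0.  Grid points whose slab
    holds no atoms get NaN (reported as undefined, not an error).
    """
    if z_step <= 0:
        raise ValueError("z_step must be > 0")
    origin, direction = axis if axis is not None else principal_axis(structure)
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    pos = structure.positions
    vdw = np.array([a.vdw_radius for a in structure.atoms])
    rel = pos - origin
    z_axial = rel @ direction
    lateral = np.linalg.norm(rel - np.outer(z_axial, direction), axis=1)
    z_lo, z_hi = z_axial.min(), z_axial.max()
    z_grid = np.arange(z_lo, z_hi + z_step / 2, z_step)
    radius = np.full(len(z_grid), np.nan)
    contact = np.full(len(z_grid), -1, dtype=int)
    for k, z in enumerate(z_grid):
        mask = np.abs(z_axial - z) <= slab_half
        if mask.any():
            idx = np.nonzero(mask)[0]
            gaps = lateral[idx] - vdw[idx]
            j = int(np.argmin(gaps))
            radius[k] = max(float(gaps[j]), 0.0)
            contact[k] = idx[j]
    if np.all(np.isnan(radius)):
        raise ValueError("axis does not intersect the molecule")
    k_min = int(np.nanargmin(radius))
    # the slab minimum forms a plateau of width ~slab_half around the
    # contact atom; report that atom's axial position as the narrow point
    narrowest_z = float(z_axial[contact[k_min]])
    return PoreProfile(axis_origin=origin, axis_direction=direction,
                       z_grid=z_grid, radius=radius,
                       narrowest_z=narrowest_z,
                       narrowest_radius=float(radius[k_min]))


def constriction_zone_charge(structure: StructureModel, profile: PoreProfile,
                             cz_radius: float = 5.0,
                             lining_cutoff: float = 3.0,
                             z_range: tuple[float, float] | None = None
                             ) -> CZReport:
    """Net formal charge at the constriction zone and along the pore lining.

    CZ residues are those with any atom within ``cz_radius`` of the
    narrowest axis point (a sphere about it); pore-lining residues are
    those with any atom within ``lining_cutoff`` of the local pore surface
    (|lateral - radius(z)| <= cutoff) over ``z_range`` along the axis
    (default: wherever the profile is defined).  Charges must have been
    assigned beforehand.
    """
    if np.isnan(profile.narrowest_radius):
        raise ValueError("profile undefined at its minimum")
    cz_point = profile.axis_point(profile.narrowest_z)
    origin, direction = profile.axis_origin, profile.axis_direction
    if z_range is None:
        defined = ~np.isnan(profile.radius)
        z_range = (float(profile.z_grid[defined].min()),
                   float(profile.z_grid[defined].max()))

    cz_residues, per_residue = set(), {}
    pore_charge = 0
    seen_pore = set()
    for a in structure.atoms:
        key = (a.chain_id, a.residue_id, a.residue_name)
        if np.linalg.norm(a.position - cz_point) <= cz_radius:
            cz_residues.add(key)
        rel = a.position - origin
        z = float(rel @ direction)
        if z_range[0] <= z <= z_range[1]:
            k = int(np.clip(np.round((z - profile.z_grid[0]) /
                                     (profile.z_grid[1] - profile.z_grid[0])),
                            0, len(profile.z_grid) - 1))
            local_r = profile.radius[k]
            if not np.isnan(local_r):
                lateral = float(np.linalg.norm(rel - z * direction))
                if abs(lateral - local_r) <= lining_cutoff and key not in seen_pore:
                    seen_pore.add(key)

    charge_by_res: dict[tuple, int] = {}
    for a in structure.atoms:
        key = (a.chain_id, a.residue_id, a.residue_name)
        charge_by_res[key] = charge_by_res.get(key, 0) + a.formal_charge
    net_cz = 0
    for key in cz_residues:
        q = charge_by_res.get(key, 0)
        if q:
            per_residue[key] = q
        net_cz += q
    pore_charge = sum(charge_by_res.get(key, 0) for key in seen_pore)
    return CZReport(cz_residues=cz_residues, net_charge_cz=int(net_cz),
                    net_charge_pore=int(pore_charge), per_residue=per_residue)


def potential_profile(structure: StructureModel,
                      axis: tuple[np.ndarray, np.ndarray],
                      z_grid: np.ndarray,
                      debye_length: float,
                      eps_r: float = 80.0,
                      reference_index: int = 0) -> np.ndarray:
    """Screened-Coulomb potential along the axis, in volts.

    phi(z) = sum_i q_i exp(-r_i/lambda_D) / (4 pi eps0 eps_r r_i) over the
    formally charged atoms, shifted so the grid point ``reference_index``
    (the intracellular entrance by convention) reads 0.  Charges closer
    than 0.1 A to a grid point are excluded there with a warning.
    """
    if debye_length <= 0:
        raise ValueError("debye_length must be > 0")
    origin, direction = axis
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    z_grid = np.asarray(z_grid, dtype=float)
    charged = [(a.formal_charge, a.position) for a in structure.atoms
               if a.formal_charge != 0]
    phi = np.zeros(len(z_grid))
    for k, z in enumerate(z_grid):
        point = origin + z * direction
        for q, pos in charged:
            r = float(np.linalg.norm(pos - point))
            if r < 0.1:
                warnings.warn(f"charge at {r:.3f} A from grid point {k}; excluded")
                continue
            phi[k] += COULOMB_V_A * q * np.exp(-r / debye_length) / (eps_r * r)
    return phi - phi[reference_index]
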