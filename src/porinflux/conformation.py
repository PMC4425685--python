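"""Structural fluctuation and motion analyses.

RMSF per residue, segment RMSD against the frame-0 reference, backbone
phi/psi dihedral series, step-transition detection on scalar or angular
series, and PCA of the superposed coordinates.  All measures superpose
each frame onto frame 0 (the crystal conformation) by Kabsch least squares
on a caller-chosen selection — for porins, typically the beta-barrel
C-alpha atoms, which stay rigid under applied voltage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import StructureModel, Trajectory


@dataclass
class ScalarSeries:
    label: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


@dataclass
class AngleSeries:
    residue: tuple[str, int]       # (chain, resid)
    times: np.ndarray
    phi: np.ndarray | None         # degrees in (-180, 180], None if terminal
    psi: np.ndarray | None


def wrap_angle(deg):
    """Wrap angles (degrees) to the canonical interval (-180, 180]."""
    a = np.asarray(deg, dtype=float)
    wrapped = -(((-a) + 180.0) % 360.0 - 180.0)
    return wrapped


def circular_diff(a, b):
    """Smallest signed angular difference a - b in degrees, in (-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto reference.

    Returns (R, t) such that mobile @ R.T + t best fits reference.
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    return rot, trans


def _superposed_coords(traj: Trajectory, superpose_ids) -> np.ndarray:
    """All-atom coordinates with every frame fitted onto frame 0."""
    fit_cols = [traj.structure.index_of(i) for i in superpose_ids]
    if not fit_cols:
        raise ValueError("empty superposition selection")
    ref = traj.coords[0, fit_cols]
    out = np.empty_like(traj.coords)
    out[0] = traj.coords[0]
    for f in range(1, traj.n_frames):
        rot, trans = kabsch_superpose(traj.coords[f, fit_cols], ref)
        out[f] = traj.coords[f] @ rot.T + trans
    return out


def rmsf(traj: Trajectory, selection, superpose_selection) -> dict[tuple, float]:
    """Per-residue RMSF (A) of the selected (typically main-chain) atoms.

    Each frame is superposed onto frame 0 using ``superpose_selection``;
    per atom, RMSF is the RMS deviation from the time-mean position; the
    per-residue value is the mean over that residue's selected atoms.
    Returns {(chain, resid): rmsf}.
    """
    if traj.n_frames < 2:
        raise ValueError("rmsf needs >= 2 frames")
    sel = list(selection)
    if not sel:
        raise ValueError("empty selection")
    coords = _superposed_coords(traj, superpose_selection)
    cols = [traj.structure.index_of(i) for i in sel]
    x = coords[:, cols, :]
    mean_pos = x.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((x - mean_pos) ** 2, axis=-1), axis=0))
    out: dict[tuple, list] = {}
    for aid, val in zip(sel, per_atom):
        a = traj.structure.atom_by_id(aid)
        out.setdefault((a.chain_id, a.residue_id), []).append(val)
    return {k: float(np.mean(v)) for k, v in out.items()}


def segment_rmsd(traj: Trajectory, segment_selection, superpose_selection,
                 label: str = "segment") -> ScalarSeries:
    """RMSD (A) of a segment versus its frame-0 coordinates over time.

    Frames are first superposed on ``superpose_selection`` (e.g. barrel
    C-alphas), then the RMSD of the segment atoms against the frame-0
    reference is reported per frame.
    """
    seg = list(segment_selection)
    if not seg:
        raise ValueError("empty segment selection")
    coords = _superposed_coords(traj, superpose_selection)
    cols = [traj.structure.index_of(i) for i in seg]
    ref = coords[0, cols]
    diff = coords[:, cols, :] - ref
    vals = np.sqrt(np.mean(np.sum(diff ** 2, axis=-1), axis=1))
    return ScalarSeries(label=label, times=traj.times.copy(), values=vals)


def _dihedral(p0, p1, p2, p3):
    """Signed dihedral angle (degrees) of four points, IUPAC convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def dihedral_series(traj: Trajectory, chain: str, resid: int) -> AngleSeries:
    """Backbone phi/psi time series of one residue, wrapped to (-180, 180].

    phi = C(i-1)-N-CA-C, psi = N-CA-C-N(i+1).  For a chain-terminal residue
    the undefined angle is reported as None.
    """
    st = traj.structure

    def _backbone(rid, name):
        for a in st.atoms:
            if a.chain_id == chain and a.residue_id == rid and a.name == name:
                return st.index_of(a.atom_id)
        return None

    n_i = _backbone(resid, "N")
    ca_i = _backbone(resid, "CA")
    c_i = _backbone(resid, "C")
    if None in (n_i, ca_i, c_i):
        raise ValueError(f"residue {chain}/{resid} lacks backbone atoms")
    c_prev = _backbone(resid - 1, "C")
    n_next = _backbone(resid + 1, "N")

    phi = psi = None
    if c_prev is not None:
        phi = _dihedral(traj.coords[:, c_prev], traj.coords[:, n_i],
                        traj.coords[:, ca_i], traj.coords[:, c_i])
    if n_next is not None:
        psi = _dihedral(traj.coords[:, n_i], traj.coords[:, ca_i],
                        traj.coords[:, c_i], traj.coords[:, n_next])
    return AngleSeries(residue=(chain, resid), times=traj.times.copy(),
                       phi=phi, psi=psi)


def detect_transition(values, times, threshold: float, persistence: int,
                      circular: bool = False) -> list[float]:
    """Times of persistent step transitions in a scalar or angular series.

    An event is called at the first frame where the deviation from the
    running pre-event baseline (the mean of all frames since the previous
    event) exceeds ``threshold`` and stays above it for at least
    ``persistence`` consecutive frames.  Angular series use the circular
    difference.  After an event the baseline restarts from the event frame.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("empty series")
    if persistence > n:
        raise ValueError("persistence exceeds series length")

    def _dev(x, base):
        return np.abs(circular_diff(x, base)) if circular else np.abs(x - base)

    events: list[float] = []
    seg_start = 0
    f = 1
    while f < n:
        baseline_vals = values[seg_start:f]
        if circular:
            rad = np.radians(baseline_vals)
            base = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
        else:
            base = baseline_vals.mean()
        if _dev(values[f], base) > threshold:
            run_end = min(f + persistence, n)
            if run_end - f >= persistence and np.all(
                    _dev(values[f:run_end], base) > threshold):
                events.append(float(times[f]))
                seg_start = f
                f = f + 1
                continue
        f += 1
    return events


def pca_projection(traj: Trajectory, selection, superpose_selection
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the superposed selected coordinates.

    Returns (eigenvalues descending, first eigenvector of shape (3n,),
    per-frame scalar projection onto eigenvector 1).
    """
    if traj.n_frames < 3:
        raise ValueError("pca_projection needs >= 3 frames")
    sel = list(selection)
    if not sel:
        raise ValueError("empty selection")
    coords = _superposed_coords(traj, superpose_selection)
    cols = [traj.structure.index_of(i) for i in sel]
    x = coords[:, cols, :].reshape(traj.n_frames, -1)
    x = x - x.mean(axis=0)
    cov = x.T @ x / (traj.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    first = evecs[:, order[0]]
    return evals, first, x @ first
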