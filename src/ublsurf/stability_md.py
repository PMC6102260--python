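"""Thermal-melt Tm extraction and ensemble/trajectory flexibility metrics.

Melt curves (temperature vs fluorescence signal, e.g. the F350/F330 ratio
of a nanoDSF run sampled in 0.036 degC steps) are smoothed with a moving
second-order polynomial (Savitzky-Golay, default window 25 points) and the
melting temperature is read off as the global maximum of the first
derivative, with parabolic sub-grid interpolation.  A derivative maximum at
the grid boundary (the signature of a flat or truncated transition) is
flagged unreliable instead of reported.

Trajectory metrics operate on frame stacks (F, N, 3): residue-wise RMSF
about the iteratively fitted mean structure, neighbour-counting RMSD
clustering (GROMOS-style), and centroid distance time series between two
atom groups.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .structio import Structure, select_atoms
from .superpose import apply_transform, kabsch


@dataclasses.dataclass
class MeltCurve:
    """One melt curve on a strictly increasing, uniform temperature grid."""

    temperature: np.ndarray  # degC
    signal: np.ndarray  # arbitrary units
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal lengths differ")
        steps = np.diff(self.temperature)
        if len(steps) == 0 or np.any(steps <= 0):
            raise ValueError("temperature grid must be strictly increasing")

    @property
    def step(self) -> float:
        return float(np.mean(np.diff(self.temperature)))


@dataclasses.dataclass
class TmResult:
    tm: float | None  # degC; None when unreliable
    derivative_peak_height: float
    smoothing: dict
    boundary_flag: bool
    replicates: list[float] = dataclasses.field(default_factory=list)
    mean: float | None = None
    sd: float | None = None


@dataclasses.dataclass
class RmsfProfile:
    per_residue: dict[int, float]  # residue number -> Angstrom
    alignment_range: tuple[int, int] | None
    n_frames: int


@dataclasses.dataclass
class ClusterResult:
    """Disjoint frame clusters ordered by decreasing size."""

    clusters: list[tuple[int, list[int]]]  # (center frame, member frames incl. center)
    cutoff: float


def read_melt_csv(path: str | Path) -> list[MeltCurve]:
    """Read melt curves from CSV: temperature, signal[, replicate]."""
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    cols = list(df.columns)
    if len(cols) >= 3:
        curves = []
        for rep, grp in df.groupby(cols[2], sort=False):
            curves.append(
                MeltCurve(grp[cols[0]].to_numpy(), grp[cols[1]].to_numpy(),
                          replicate_id=str(rep))
            )
        return curves
    return [MeltCurve(df[cols[0]].to_numpy(), df[cols[1]].to_numpy())]


def _single_tm(curve: MeltCurve, smooth_window: int, polyorder: int) -> TmResult:
    t, y = curve.temperature, curve.signal
    n = len(t)
    if n < 3 * smooth_window:
        raise ValueError(
            f"curve too short ({n} points) for window {smooth_window}"
        )
    steps = np.diff(t)
    if not np.allclose(steps, steps.mean(), rtol=1e-3, atol=1e-9):
        raise ValueError("non-uniform temperature grid")
    delta = float(steps.mean())
    window = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
    smoothed = savgol_filter(y, window, polyorder)
    deriv = savgol_filter(smoothed, window, polyorder, deriv=1, delta=delta)
    idx = int(np.argmax(deriv))
    edge = window // 2
    boundary = idx < edge or idx >= n - edge
    smoothing = {"window": window, "polyorder": polyorder}
    if boundary:
        return TmResult(tm=None, derivative_peak_height=float(deriv[idx]),
                        smoothing=smoothing, boundary_flag=True)
    # sub-grid peak position: quadratic fit of the derivative around its
    # maximum (half-width ~1.5x the smoothing window), which averages out
    # point-to-point noise far better than a 3-point parabola
    half = int(1.5 * window)
    lo, hi = max(0, idx - half), min(n, idx + half + 1)
    coeff = np.polyfit(t[lo:hi] - t[idx], deriv[lo:hi], 2)
    if coeff[0] < 0:
        offset = float(np.clip(-coeff[1] / (2 * coeff[0]),
                               -half * delta, half * delta))
    else:  # degenerate curvature: keep the grid maximum
        offset = 0.0
    tm = float(t[idx] + offset)
    return TmResult(tm=tm, derivative_peak_height=float(deriv[idx]),
                    smoothing=smoothing, boundary_flag=False)


def melt_tm(
    curve: MeltCurve | Sequence[MeltCurve],
    smooth_window: int = 25,
    polyorder: int = 2,
) -> TmResult:
    """Tm of one melt curve, or per-replicate Tm plus mean +/- sd for several."""
    if isinstance(curve, MeltCurve):
        return _single_tm(curve, smooth_window, polyorder)
    results = [_single_tm(c, smooth_window, polyorder) for c in curve]
    tms = [r.tm for r in results if r.tm is not None]
    if not tms:
        first = results[0]
        first.replicates = []
        return first
    mean = float(np.mean(tms))
    sd = float(np.std(tms, ddof=1)) if len(tms) > 1 else 0.0
    return TmResult(
        tm=mean,
        derivative_peak_height=float(np.mean(
            [r.derivative_peak_height for r in results if r.tm is not None])),
        smoothing=results[0].smoothing,
        boundary_flag=any(r.boundary_flag for r in results),
        replicates=tms,
        mean=mean,
        sd=sd,
    )


def frames_from_structure(
    structure: Structure,
    residue_range: tuple[int, int] | None = None,
    atom_set: Sequence[str] = ("CA",),
    chain_id: str | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Stack a multi-model structure into (F, N, 3) plus residue labels."""
    chain_id = chain_id or structure.chain_ids(0)[0]
    if residue_range is None:
        residues = structure.chain(chain_id)
        residue_range = (residues[0].seq_number, residues[-1].seq_number)
    labels = [
        r.seq_number
        for r in structure.chain(chain_id)
        if residue_range[0] <= r.seq_number <= residue_range[1]
        and any(a.name in atom_set for a in r.atoms)
    ]
    frames = []
    for i in range(structure.n_models):
        frames.append(
            select_atoms(structure, chain_id, residue_range, atom_set,
                         model_index=i, strict=True)
        )
    arr = np.array(frames)
    if len(atom_set) == 1 and arr.shape[1] != len(labels):
        raise ValueError("frame/atom mismatch across models")
    return arr, labels


def read_xyz_table(path: str | Path) -> np.ndarray:
    """Read frames from a plain table with columns frame, x, y, z -> (F, N, 3)."""
    df = pd.read_csv(path, comment="#", sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    cols = list(df.columns)
    frames = []
    n_atoms = None
    for _, grp in df.groupby(cols[0], sort=True):
        xyz = grp[cols[1:4]].to_numpy(dtype=float)
        if n_atoms is None:
            n_atoms = len(xyz)
        elif len(xyz) != n_atoms:
            raise ValueError("frames differ in atom count")
        frames.append(xyz)
    return np.array(frames)


def _fit_frames(
    frames: np.ndarray,
    fit_indices: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Superpose all frames onto their iteratively refined mean structure."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (F >= 2, N, 3) frame stack")
    idx = np.arange(frames.shape[1]) if fit_indices is None else np.asarray(fit_indices)
    mean = frames[0].copy()
    for _ in range(max_iter):
        fitted = []
        for f in frames:
            sup = kabsch(f[idx], mean[idx])
            fitted.append(apply_transform(f, sup))
        fitted = np.array(fitted)
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        frames = fitted
        if shift < tol:
            break
    return frames


def rmsf(
    frames: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom RMSF (Angstrom) about the mean after iterative fitting.

    ``fit_indices`` restricts the superposition to a rigid sub-selection
    (e.g. the structured core) while fluctuations are still reported for
    every atom.
    """
    fitted = _fit_frames(frames, fit_indices)
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


def rmsf_profile(
    structure: Structure,
    fit_range: tuple[int, int] | None = None,
    atom_set: Sequence[str] = ("CA",),
    chain_id: str | None = None,
) -> RmsfProfile:
    """Residue-wise CA RMSF of a multi-model structure or trajectory."""
    frames, labels = frames_from_structure(structure, None, atom_set, chain_id)
    fit_idx = None
    if fit_range is not None:
        fit_idx = np.array(
            [i for i, num in enumerate(labels) if fit_range[0] <= num <= fit_range[1]]
        )
        if len(fit_idx) < 3:
            raise ValueError(f"fit range {fit_range} selects fewer than 3 atoms")
    values = rmsf(frames, fit_idx)
    return RmsfProfile(
        per_residue={num: float(v) for num, v in zip(labels, values)},
        alignment_range=fit_range,
        n_frames=frames.shape[0],
    )


def pairwise_rmsd_matrix(frames: np.ndarray) -> np.ndarray:
    """Fitted RMSD between every frame pair."""
    frames = np.asarray(frames, dtype=float)
    f = frames.shape[0]
    mat = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            mat[i, j] = mat[j, i] = kabsch(frames[j], frames[i]).rmsd
    return mat


def rmsd_cluster(frames: np.ndarray, cutoff: float) -> ClusterResult:
    """Neighbour-counting (GROMOS) clustering on fitted pairwise RMSDs.

    Repeatedly take the frame with the most unassigned neighbours within
    *cutoff* (ties: lowest frame index) as a cluster center, assign it and
    its neighbours, remove them, and continue.  Every frame lands in exactly
    one cluster; clusters come out ordered by decreasing size (ties: lower
    center index first, preserved by the greedy order).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("need a (F >= 1, N, 3) frame stack")
    f = frames.shape[0]
    if f == 1:
        return ClusterResult(clusters=[(0, [0])], cutoff=cutoff)
    mat = pairwise_rmsd_matrix(frames)
    remaining = list(range(f))
    clusters: list[tuple[int, list[int]]] = []
    while remaining:
        best_center, best_members = None, None
        for i in remaining:
            members = [j for j in remaining if mat[i, j] <= cutoff]
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = i, members
        clusters.append((best_center, sorted(best_members)))
        remaining = [j for j in remaining if j not in set(best_members)]
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return ClusterResult(clusters=clusters, cutoff=cutoff)


def group_distance(
    frames: np.ndarray,
    group_a: Sequence[int],
    group_b: Sequence[int],
    weights_a: Sequence[float] | None = None,
    weights_b: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-frame distance between the centroids of two atom-index groups.

    Centroids are unweighted by default; pass per-atom weights (e.g. masses)
    for mass-weighted centers.
    """
    frames = np.asarray(frames, dtype=float)
    ga, gb = np.asarray(group_a, dtype=int), np.asarray(group_b, dtype=int)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("empty atom group")
    ca = np.average(frames[:, ga, :], axis=1, weights=weights_a)
    cb = np.average(frames[:, gb, :], axis=1, weights=weights_b)
    return np.linalg.norm(ca - cb, axis=1)
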