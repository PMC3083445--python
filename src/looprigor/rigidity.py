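"""Binding-loop rigidity: least-squares superposition and Cα RMSD profiles.

The rigidity of a canonical inhibitor loop is read out as the per-frame
RMSD of its Cα atoms after optimal rigid-body superposition, either
against the starting structure (conformational drift) or against the
trajectory-average structure (fluctuation about the adopted conformation),
plus a per-residue RMSD profile that localises flexibility along the loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Topology, Trajectory, TrajectorySet, calpha_indices

__all__ = [
    "Superposition",
    "RigidityProfile",
    "kabsch_superpose",
    "rmsd_to_start",
    "rmsd_to_average",
    "rigidity_profile",
    "average_structure",
    "per_residue_rmsd",
]


@dataclass(frozen=True)
class Superposition:
    """A proper rotation + translation fitting mobile onto reference."""

    rotation: np.ndarray  # (3, 3), determinant +1
    translation: np.ndarray  # (3,), Å
    rmsd: float  # Å, after the fit

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RigidityProfile:
    """Per-frame (and optionally per-residue) RMSD series.

    ``per_run[r]`` is run r's per-frame RMSD in Å; ``pooled_mean`` averages
    the runs at each frame index (replicates share a common length).
    """

    per_run: tuple[np.ndarray, ...]
    pooled_mean: np.ndarray
    reference_kind: str  # "start" or "average"
    per_residue: Mapping[int, float] | None = None


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Reflections are excluded; the returned rotation is always proper.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must have shape (n, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_center, mobile - mob_center)
    matrix = rot.as_matrix()
    translation = ref_center - matrix @ mob_center
    # Recompute the residual directly: the rssd reported by align_vectors
    # loses precision to cancellation for near-exact fits.
    residual = mobile @ matrix.T + translation - reference
    rmsd = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return Superposition(rotation=matrix, translation=translation, rmsd=rmsd)


def _selection_indices(top: Topology, chain_id: str, selection: str) -> tuple[np.ndarray, np.ndarray]:
    """Topology indices + residue numbers for a named selection of one chain."""
    if selection == "CA":
        return calpha_indices(top, chain_id)
    if selection == "all":
        idx = np.flatnonzero(top.chains == chain_id)
        if idx.size == 0:
            raise ValueError(f"chain {chain_id!r} not present in topology")
        return idx, top.resids[idx]
    raise ValueError(f"unknown selection {selection!r} (expected 'CA' or 'all')")


def _as_runs(traj: TrajectorySet | Trajectory) -> tuple[Trajectory, ...]:
    if isinstance(traj, TrajectorySet):
        return traj.runs
    return (traj,)


def rmsd_to_start(
    traj: TrajectorySet | Trajectory, chain_id: str, selection: str = "CA"
) -> RigidityProfile:
    """Per-frame RMSD of each run against its own first frame."""
    runs = _as_runs(traj)
    idx, _ = _selection_indices(runs[0].topology, chain_id, selection)
    if idx.size == 0:
        raise ValueError("empty selection")
    per_run = []
    for run in runs:
        ref = run.coords[0, idx]
        series = np.array(
            [kabsch_superpose(run.coords[f, idx], ref).rmsd for f in range(run.n_frames)]
        )
        per_run.append(series)
    pooled = np.mean(np.stack(per_run), axis=0)
    return RigidityProfile(per_run=tuple(per_run), pooled_mean=pooled, reference_kind="start")


def average_structure(
    traj: TrajectorySet | Trajectory,
    chain_id: str,
    selection: str = "CA",
    iterate: bool = False,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> np.ndarray:
    """Mean structure of the selection over all frames of all runs.

    Every frame is superposed onto the first frame of the first run before
    averaging.  With ``iterate=True`` the superposition target is refreshed
    to the current average until it moves less than ``tol`` Å (RMS).
    """
    runs = _as_runs(traj)
    total_frames = sum(run.n_frames for run in runs)
    if total_frames < 2:
        raise ValueError("average structure needs at least 2 frames")
    idx, _ = _selection_indices(runs[0].topology, chain_id, selection)
    reference = runs[0].coords[0, idx]
    for _ in range(max_iter if iterate else 1):
        fitted = [
            kabsch_superpose(run.coords[f, idx], reference).apply(run.coords[f, idx])
            for run in runs
            for f in range(run.n_frames)
        ]
        mean = np.mean(np.stack(fitted), axis=0)
        shift = float(np.sqrt(np.mean((mean - reference) ** 2)))
        reference = mean
        if not iterate or shift < tol:
            break
    return reference


def rmsd_to_average(
    traj: TrajectorySet | Trajectory, chain_id: str, selection: str = "CA"
) -> RigidityProfile:
    """Per-frame RMSD of every run against the pooled average structure."""
    runs = _as_runs(traj)
    idx, resnums = _selection_indices(runs[0].topology, chain_id, selection)
    avg = average_structure(traj, chain_id, selection)
    per_run = tuple(
        np.array([kabsch_superpose(run.coords[f, idx], avg).rmsd for f in range(run.n_frames)])
        for run in runs
    )
    pooled = np.mean(np.stack(per_run), axis=0)
    return RigidityProfile(per_run=per_run, pooled_mean=pooled, reference_kind="average")


def rigidity_profile(
    traj: TrajectorySet | Trajectory, chain_id: str, reference: str = "start"
) -> RigidityProfile:
    """Dispatch on reference kind (``start`` or ``average``)."""
    if reference == "start":
        return rmsd_to_start(traj, chain_id)
    if reference == "average":
        return rmsd_to_average(traj, chain_id)
    raise ValueError(f"unknown reference {reference!r} (expected 'start' or 'average')")


def per_residue_rmsd(
    traj: TrajectorySet | Trajectory,
    reference: np.ndarray,
    chain_id: str,
) -> dict[int, float]:
    """Per-residue Cα RMSD about ``reference`` after a global per-frame fit.

    Each frame's Cα set is superposed onto the reference as a whole; the
    deviation of each residue's Cα is then pooled over all frames of all
    runs (global-fit frame, per-residue readout).
    """
    runs = _as_runs(traj)
    idx, resnums = calpha_indices(runs[0].topology, chain_id)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (idx.size, 3):
        raise ValueError(
            f"reference shape {reference.shape} does not match the {idx.size}-residue selection"
        )
    sq_sum = np.zeros(idx.size)
    n_frames = 0
    for run in runs:
        for f in range(run.n_frames):
            fitted = kabsch_superpose(run.coords[f, idx], reference).apply(run.coords[f, idx])
            sq_sum += np.sum((fitted - reference) ** 2, axis=1)
            n_frames += 1
    values = np.sqrt(sq_sum / n_frames)
    return {int(r): float(v) for r, v in zip(resnums, values)}
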