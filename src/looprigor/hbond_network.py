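"""Geometric hydrogen-bond detection and trajectory network statistics.

A hydrogen bond is recorded between a donor heavy atom D (N or O carrying
at least one hydrogen H) and an acceptor A (N or O) when the D···A distance
is at most ``max_da_distance`` (default 3.3 Å) and, for at least one
attached hydrogen, the D-H···A angle deviates from linearity by at most
``max_angle_deviation`` (default 40°, i.e. the angle at H is >= 140°).
Bond identity across frames is the directed heavy-atom pair; which hydrogen
satisfied the test is irrelevant to occupancy.  Intra-residue pairs are
excluded; adjacent-residue backbone pairs are not.

Bonds are classified by the chain roles of their endpoints: *internal*
(both on an inhibitor chain), *intermolecular* (one inhibitor, one
protease) or *other* (everything else, excluded from summaries).
Replicate statistics follow the mean-over-runs / SEM-over-run-means
convention for independent trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np

from .structure_io import (
    INHIBITOR,
    PROTEASE,
    OTHER,
    Frame,
    RoleAssignment,
    Trajectory,
    TrajectorySet,
    assign_roles,
)

__all__ = [
    "INTERNAL",
    "INTERMOLECULAR",
    "HBondCriteria",
    "HBondKey",
    "HBondRecord",
    "NetworkSummary",
    "detect_hbonds_frame",
    "run_presence",
    "classify_bond",
    "occupancy",
    "persistent_network",
    "per_residue_frequency",
    "summarize",
    "percent_change",
    "display_round",
]

INTERNAL = "internal"
INTERMOLECULAR = "intermolecular"

BOND_CLASSES = (INTERNAL, INTERMOLECULAR, OTHER)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance criteria for a hydrogen bond."""

    max_da_distance: float = 3.3  # Å, donor-acceptor heavy-atom distance
    max_angle_deviation: float = 40.0  # degrees away from a linear D-H···A
    require_hydrogens: bool = True

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not 0 < self.max_angle_deviation < 90:
            raise ValueError("max_angle_deviation must be in (0, 90) degrees")


@dataclass(frozen=True, order=True)
class HBondKey:
    """Directed donor→acceptor identity: ``(chain, residue, atom)`` each."""

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor cannot be the same atom")

    def residues(self) -> tuple[tuple[str, int], ...]:
        d = (self.donor[0], self.donor[1])
        a = (self.acceptor[0], self.acceptor[1])
        return (d,) if d == a else (d, a)


@dataclass(frozen=True)
class HBondRecord:
    """A detected bond with per-run occupancies."""

    key: HBondKey
    bond_class: str
    replicate_occupancies: tuple[float, ...]

    @property
    def occupancy(self) -> float:
        """Mean occupancy across runs."""
        return float(np.mean(self.replicate_occupancies))


@dataclass(frozen=True)
class NetworkSummary:
    """Replicate-averaged hydrogen-bond network statistics.

    ``per_frame_counts[cls][run]`` is the per-frame bond count series;
    ``mean_count[cls]`` is the mean over runs of the per-run mean counts and
    ``sem_count[cls]`` the standard error across run means (``None`` for a
    single run).  ``per_residue_frequency`` sums mean occupancies over all
    bonds touching each inhibitor residue.
    """

    records: tuple[HBondRecord, ...]
    persistent_bonds: tuple[HBondRecord, ...]
    per_frame_counts: Mapping[str, tuple[np.ndarray, ...]]
    mean_count: Mapping[str, float]
    sem_count: Mapping[str, float | None]
    per_residue_frequency: Mapping[tuple[str, int], float]
    n_runs: int
    frames_analyzed: int
    criteria: HBondCriteria
    persistence_threshold: float = 0.5


# ---------------------------------------------------------------------------
# Candidate pairs and vectorised detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _PairTable:
    donor_idx: np.ndarray  # (P,) topology index of donor heavy atom
    acceptor_idx: np.ndarray  # (P,)
    keys: tuple[HBondKey, ...]
    exp_donor: np.ndarray  # (M,) expanded rows, one per (pair, hydrogen)
    exp_hydrogen: np.ndarray  # (M,)
    exp_acceptor: np.ndarray  # (M,)
    starts: np.ndarray  # (P,) reduceat boundaries into the expanded rows

    @property
    def n_pairs(self) -> int:
        return len(self.keys)


def _build_pairs(topology, roles: RoleAssignment, criteria: HBondCriteria) -> _PairTable:
    donors = np.flatnonzero(roles.donor_heavy)
    acceptors = np.flatnonzero(roles.acceptor)
    if criteria.require_hydrogens:
        bare = [
            f"{topology.chains[d]}:{topology.resids[d]}:{topology.names[d]}"
            for d in donors
            if not roles.donor_hydrogens.get(int(d), ())
        ]
        if bare:
            raise ValueError(
                "require_hydrogens is set but these donors have no hydrogens: "
                + ", ".join(bare)
            )

    d_list: list[int] = []
    a_list: list[int] = []
    keys: list[HBondKey] = []
    exp_d: list[int] = []
    exp_h: list[int] = []
    exp_a: list[int] = []
    starts: list[int] = []
    for d in donors:
        d_res = (str(topology.chains[d]), int(topology.resids[d]))
        hydrogens = roles.donor_hydrogens.get(int(d), ())
        for a in acceptors:
            if a == d:
                continue
            if (str(topology.chains[a]), int(topology.resids[a])) == d_res:
                continue  # intra-residue pairs are excluded
            starts.append(len(exp_d))
            d_list.append(int(d))
            a_list.append(int(a))
            keys.append(
                HBondKey(
                    donor=(d_res[0], d_res[1], str(topology.names[d])),
                    acceptor=(
                        str(topology.chains[a]),
                        int(topology.resids[a]),
                        str(topology.names[a]),
                    ),
                )
            )
            if criteria.require_hydrogens:
                for h in hydrogens:
                    exp_d.append(int(d))
                    exp_h.append(int(h))
                    exp_a.append(int(a))

    return _PairTable(
        donor_idx=np.asarray(d_list, dtype=int),
        acceptor_idx=np.asarray(a_list, dtype=int),
        keys=tuple(keys),
        exp_donor=np.asarray(exp_d, dtype=int),
        exp_hydrogen=np.asarray(exp_h, dtype=int),
        exp_acceptor=np.asarray(exp_a, dtype=int),
        starts=np.asarray(starts, dtype=int),
    )


def _presence_chunk(coords: np.ndarray, pairs: _PairTable, criteria: HBondCriteria) -> np.ndarray:
    """Boolean presence matrix (n_frames, n_pairs) for a coordinate chunk."""
    if pairs.n_pairs == 0:
        return np.zeros((coords.shape[0], 0), dtype=bool)
    d_xyz = coords[:, pairs.donor_idx]
    a_xyz = coords[:, pairs.acceptor_idx]
    dist = np.linalg.norm(d_xyz - a_xyz, axis=-1)
    ok = dist <= criteria.max_da_distance
    if criteria.require_hydrogens:
        v1 = coords[:, pairs.exp_donor] - coords[:, pairs.exp_hydrogen]
        v2 = coords[:, pairs.exp_acceptor] - coords[:, pairs.exp_hydrogen]
        cos = np.sum(v1 * v2, axis=-1) / (
            np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
        )
        angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        angle_ok = angle >= 180.0 - criteria.max_angle_deviation
        ok &= np.logical_or.reduceat(angle_ok, pairs.starts, axis=1)
    return ok


def run_presence(
    run: Trajectory,
    roles: RoleAssignment,
    criteria: HBondCriteria = HBondCriteria(),
    chunk: int = 500,
) -> tuple[_PairTable, np.ndarray]:
    """Presence matrix (n_frames, n_pairs) for every candidate pair of a run."""
    pairs = _build_pairs(run.topology, roles, criteria)
    blocks = [
        _presence_chunk(run.coords[f : f + chunk], pairs, criteria)
        for f in range(0, run.n_frames, chunk)
    ]
    presence = np.concatenate(blocks, axis=0) if blocks else np.zeros((0, pairs.n_pairs), bool)
    return pairs, presence


def detect_hbonds_frame(
    frame: Frame,
    roles: RoleAssignment,
    criteria: HBondCriteria = HBondCriteria(),
) -> set[HBondKey]:
    """Hydrogen bonds present in a single frame."""
    pairs = _build_pairs(frame.topology, roles, criteria)
    present = _presence_chunk(frame.coords[None], pairs, criteria)[0]
    return {pairs.keys[i] for i in np.flatnonzero(present)}


# ---------------------------------------------------------------------------
# Classification and statistics
# ---------------------------------------------------------------------------

def classify_bond(key: HBondKey, chain_roles: Mapping[str, str]) -> str:
    """``internal`` / ``intermolecular`` / ``other`` by the endpoint chain roles."""
    try:
        role_d = chain_roles[key.donor[0]]
        role_a = chain_roles[key.acceptor[0]]
    except KeyError as exc:
        raise ValueError(f"chain {exc.args[0]!r} has no assigned role") from None
    if role_d == INHIBITOR and role_a == INHIBITOR:
        return INTERNAL
    if {role_d, role_a} == {INHIBITOR, PROTEASE}:
        return INTERMOLECULAR
    return OTHER


def occupancy(
    run: Trajectory,
    key: HBondKey,
    roles: RoleAssignment | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> float:
    """Fraction of the run's frames in which ``key`` is present."""
    if run.n_frames == 0:
        raise ValueError("run has no frames")
    if roles is None:
        roles = assign_roles(run)
    pairs, presence = run_presence(run, roles, criteria)
    try:
        j = pairs.keys.index(key)
    except ValueError:
        return 0.0
    return float(presence[:, j].mean())


def persistent_network(
    records: Iterable[HBondRecord], threshold: float = 0.5
) -> tuple[HBondRecord, ...]:
    """Bonds with mean occupancy strictly above ``threshold``."""
    return tuple(r for r in records if r.occupancy > threshold)


def per_residue_frequency(
    records: Iterable[HBondRecord],
    chain_roles: Mapping[str, str],
) -> dict[tuple[str, int], float]:
    """Summed occupancy of all bonds touching each inhibitor residue.

    A bond between two inhibitor residues contributes its occupancy to both.
    Values are unrounded; use :func:`display_round` for the one-decimal form.
    """
    inhibitor_chains = {c for c, role in chain_roles.items() if role == INHIBITOR}
    freq: dict[tuple[str, int], float] = {}
    for record in records:
        for chain, resid in record.key.residues():
            if chain in inhibitor_chains:
                freq[(chain, resid)] = freq.get((chain, resid), 0.0) + record.occupancy
    return freq


def display_round(value: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching tabulated display conventions."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def summarize(
    traj: TrajectorySet,
    criteria: HBondCriteria = HBondCriteria(),
    table=None,
    burn_in: int = 0,
    persistence_threshold: float = 0.5,
) -> NetworkSummary:
    """Full network summary of a replicate trajectory set.

    ``burn_in`` drops that many initial frames of every run before any
    statistic is computed (none by default: production frames are assumed
    already equilibrated).
    """
    if not any(role == INHIBITOR for role in traj.chain_roles.values()):
        raise ValueError("at least one chain must be labelled 'inhibitor'")
    if traj.frames_per_run - burn_in <= 0:
        raise ValueError("burn-in leaves no frames to analyse")

    roles = assign_roles(traj, table)
    pairs = _build_pairs(traj.topology, roles, criteria)
    classes = np.array([classify_bond(k, traj.chain_roles) for k in pairs.keys], dtype=object)

    per_frame_counts: dict[str, list[np.ndarray]] = {c: [] for c in BOND_CLASSES}
    per_frame_counts["total"] = []
    occ_runs = np.zeros((traj.n_runs, pairs.n_pairs))
    for r, run in enumerate(traj.runs):
        _, presence = run_presence(run, roles, criteria)
        presence = presence[burn_in:]
        occ_runs[r] = presence.mean(axis=0) if presence.size else 0.0
        for cls in BOND_CLASSES:
            per_frame_counts[cls].append(presence[:, classes == cls].sum(axis=1))
        per_frame_counts["total"].append(presence.sum(axis=1))

    ever = np.flatnonzero(occ_runs.max(axis=0) > 0)
    records = tuple(
        HBondRecord(
            key=pairs.keys[j],
            bond_class=str(classes[j]),
            replicate_occupancies=tuple(float(x) for x in occ_runs[:, j]),
        )
        for j in ever
    )

    mean_count: dict[str, float] = {}
    sem_count: dict[str, float | None] = {}
    for cls, runs_counts in per_frame_counts.items():
        run_means = np.array([c.mean() for c in runs_counts])
        mean_count[cls] = float(run_means.mean())
        sem_count[cls] = (
            float(run_means.std(ddof=1) / np.sqrt(traj.n_runs)) if traj.n_runs > 1 else None
        )

    return NetworkSummary(
        records=records,
        persistent_bonds=persistent_network(records, persistence_threshold),
        per_frame_counts={c: tuple(v) for c, v in per_frame_counts.items()},
        mean_count=mean_count,
        sem_count=sem_count,
        per_residue_frequency=per_residue_frequency(records, traj.chain_roles),
        n_runs=traj.n_runs,
        frames_analyzed=traj.frames_per_run - burn_in,
        criteria=criteria,
        persistence_threshold=persistence_threshold,
    )


def percent_change(variant_mean: float, reference_mean: float) -> float:
    """Percent change of a variant's mean count versus the reference variant.

    Returned unrounded; tables display it to one decimal.
    """
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (variant_mean - reference_mean) / reference_mean
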