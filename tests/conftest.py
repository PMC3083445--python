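"""Shared fixtures: hand-built frames and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from looprigor.hbond_network import HBondCriteria, HBondKey
from looprigor.structure_io import Frame, Topology, Trajectory, TrajectorySet


def build_frame(atoms: list[tuple], frame_index: int = 0) -> Frame:
    """Frame from (name, element, chain, resid, resname, xyz) tuples."""
    topology = Topology(
        serials=list(range(1, len(atoms) + 1)),
        names=[a[0] for a in atoms],
        elements=[a[1] for a in atoms],
        resids=[a[3] for a in atoms],
        resnames=[a[4] for a in atoms],
        chains=[a[2] for a in atoms],
    )
    coords = np.array([a[5] for a in atoms], dtype=float)
    return Frame(topology, coords, frame_index=frame_index)


def single_run(frames_coords: np.ndarray, topology: Topology,
               chain_roles=None) -> TrajectorySet:
    return TrajectorySet(
        runs=(Trajectory(topology, np.asarray(frames_coords, dtype=float)),),
        chain_roles=chain_roles or {},
    )


def amide_pair_frame(acceptor_xyz, donor_xyz=(0.0, 0.0, 0.0), h_xyz=(1.0, 0.0, 0.0)):
    """Minimal two-residue frame: one backbone N-H donor, one carbonyl O."""
    return build_frame(
        [
            ("N", "N", "I", 1, "ALA", donor_xyz),
            ("H", "H", "I", 1, "ALA", h_xyz),
            ("CA", "C", "I", 1, "ALA", (0.0, 2.0, 0.0)),
            ("N", "N", "I", 2, "ALA", (20.0, 0.0, 0.0)),
            ("H", "H", "I", 2, "ALA", (21.0, 0.0, 0.0)),
            ("O", "O", "I", 2, "ALA", acceptor_xyz),
        ]
    )


def brute_force_hbonds(frame: Frame, roles, criteria: HBondCriteria) -> set[HBondKey]:
    """Exhaustive O(donors x acceptors x hydrogens) reference detector."""
    top = frame.topology
    found = set()
    for d in np.flatnonzero(roles.donor_heavy):
        d_res = (str(top.chains[d]), int(top.resids[d]))
        for a in np.flatnonzero(roles.acceptor):
            if a == d:
                continue
            if (str(top.chains[a]), int(top.resids[a])) == d_res:
                continue
            if np.linalg.norm(frame.coords[d] - frame.coords[a]) > criteria.max_da_distance:
                continue
            if criteria.require_hydrogens:
                ok = False
                for h in roles.donor_hydrogens.get(int(d), ()):
                    v1 = frame.coords[d] - frame.coords[h]
                    v2 = frame.coords[a] - frame.coords[h]
                    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
                    if angle >= 180.0 - criteria.max_angle_deviation:
                        ok = True
                        break
                if not ok:
                    continue
            found.add(
                HBondKey(
                    donor=(d_res[0], d_res[1], str(top.names[d])),
                    acceptor=(str(top.chains[a]), int(top.resids[a]), str(top.names[a])),
                )
            )
    return found


def random_two_chain_frame(gen: np.random.Generator, n_residues: int = 8) -> Frame:
    """Random compact frame with N-H/O backbone chemistry on two chains.

    Coordinates are drawn in a box tight enough that some donor/acceptor
    pairs fall inside the geometric cutoffs by chance.
    """
    atoms = []
    for i in range(n_residues):
        chain = "I" if i < n_residues // 2 else "E"
        resid = i % (n_residues // 2) + 1
        origin = gen.uniform(0.0, 6.0, size=3)
        h_dir = gen.normal(size=3)
        h_dir /= np.linalg.norm(h_dir)
        atoms.append(("N", "N", chain, resid, "ALA", tuple(origin)))
        atoms.append(("H", "H", chain, resid, "ALA", tuple(origin + h_dir)))
        atoms.append(("O", "O", chain, resid, "ALA", tuple(gen.uniform(0.0, 6.0, size=3))))
    return build_frame(atoms)


@pytest.fixture
def rng0() -> np.random.Generator:
    return np.random.default_rng(20260919)
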