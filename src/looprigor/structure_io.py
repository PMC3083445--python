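"""Multi-model PDB input/output and hydrogen-bond chemistry annotation.

A trajectory is stored as one shared :class:`Topology` (per-atom metadata)
plus a dense ``(n_frames, n_atoms, 3)`` coordinate array per run, so the
geometric analyses downstream can vectorise over frames.  Coordinates are
in Ångström and residue numbers are 1-based, as in the PDB format.  The
reader is deliberately strict: every model must carry the identical atom
list, insertion codes are rejected, and parse failures name the offending
line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "INHIBITOR",
    "PROTEASE",
    "OTHER",
    "PDBFormatError",
    "TopologyError",
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "TrajectorySet",
    "DonorAcceptorTable",
    "RoleAssignment",
    "default_donor_acceptor_table",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "assign_roles",
    "select_calpha",
    "calpha_indices",
]

INHIBITOR = "inhibitor"
PROTEASE = "protease"
OTHER = "other"


class PDBFormatError(ValueError):
    """Raised for malformed or unwritable PDB records."""


class TopologyError(ValueError):
    """Raised when atom sets are inconsistent across models or runs."""


@dataclass(frozen=True)
class Atom:
    """A single atom with PDB-style identity and a position in Å."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(
                f"atom {self.name!r}: position must be a finite 3-vector, got {self.position!r}"
            )
        object.__setattr__(self, "position", pos)


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    for char in stripped:
        if char.isalpha():
            return char.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


class Topology:
    """Immutable per-atom metadata shared by every frame of a trajectory.

    ``(chain_id, residue_number, name)`` must be unique across atoms.
    """

    __slots__ = ("serials", "names", "elements", "resids", "resnames", "chains", "_index")

    def __init__(
        self,
        serials: Sequence[int],
        names: Sequence[str],
        elements: Sequence[str],
        resids: Sequence[int],
        resnames: Sequence[str],
        chains: Sequence[str],
    ) -> None:
        self.serials = np.asarray(serials, dtype=int)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.resids = np.asarray(resids, dtype=int)
        self.resnames = np.asarray(resnames, dtype=object)
        self.chains = np.asarray(chains, dtype=object)
        n = len(self.serials)
        for arr, label in (
            (self.names, "names"),
            (self.elements, "elements"),
            (self.resids, "resids"),
            (self.resnames, "resnames"),
            (self.chains, "chains"),
        ):
            if len(arr) != n:
                raise ValueError(f"topology field {label} has length {len(arr)}, expected {n}")
        index: dict[tuple[str, int, str], int] = {}
        for i in range(n):
            key = (str(self.chains[i]), int(self.resids[i]), str(self.names[i]))
            if key in index:
                raise TopologyError(f"duplicate atom {key} in topology")
            index[key] = i
        self._index = index

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def atom_key(self) -> tuple:
        """Hashable identity of the atom list (used to compare runs)."""
        return tuple(
            (str(c), int(r), str(n), str(rn))
            for c, r, n, rn in zip(self.chains, self.resids, self.names, self.resnames)
        )

    def index_of(self, chain_id: str, residue_number: int, name: str) -> int:
        return self._index[(chain_id, residue_number, name)]

    def atoms(self, coords: np.ndarray) -> tuple[Atom, ...]:
        return tuple(
            Atom(
                serial=int(self.serials[i]),
                name=str(self.names[i]),
                element=str(self.elements[i]),
                residue_number=int(self.resids[i]),
                residue_name=str(self.resnames[i]),
                chain_id=str(self.chains[i]),
                position=coords[i],
            )
            for i in range(self.n_atoms)
        )

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, str]]:
        """Ordered unique ``(chain, resid, resname)``, optionally one chain."""
        seen: dict[tuple[str, int], str] = {}
        for c, r, rn in zip(self.chains, self.resids, self.resnames):
            if chain_id is not None and c != chain_id:
                continue
            seen.setdefault((str(c), int(r)), str(rn))
        return sorted(((c, r, rn) for (c, r), rn in seen.items()), key=lambda t: (t[0], t[1]))


@dataclass(frozen=True)
class Frame:
    """One coordinate set of a trajectory (a lightweight view)."""

    topology: Topology
    coords: np.ndarray  # (n_atoms, 3), Å
    frame_index: int = 0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frame coords shape {coords.shape} does not match topology "
                f"({self.topology.n_atoms} atoms)"
            )
        object.__setattr__(self, "coords", coords)

    @property
    def atoms(self) -> tuple[Atom, ...]:
        return self.topology.atoms(self.coords)


@dataclass(frozen=True)
class Trajectory:
    """One run: a topology and frame coordinates stacked into an array."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(f"trajectory coords shape {coords.shape} invalid for topology")
        object.__setattr__(self, "coords", coords)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def frame(self, i: int) -> Frame:
        return Frame(self.topology, self.coords[i], frame_index=i)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass(frozen=True)
class TrajectorySet:
    """A set of replicate runs over one topology, with chain roles.

    ``chain_roles`` maps chain id to ``inhibitor`` / ``protease`` / ``other``;
    chains absent from the mapping are treated as ``other``.
    """

    runs: tuple[Trajectory, ...]
    chain_roles: Mapping[str, str]

    def __post_init__(self) -> None:
        runs = tuple(self.runs)
        if not runs:
            raise ValueError("TrajectorySet requires at least one run")
        key0 = runs[0].topology.atom_key()
        for j, run in enumerate(runs[1:], start=2):
            if run.topology.atom_key() != key0:
                raise TopologyError(f"run {j} has a different topology from run 1")
            if run.n_frames != runs[0].n_frames:
                raise TopologyError(
                    f"run {j} has {run.n_frames} frames, run 1 has {runs[0].n_frames}"
                )
        for role in dict(self.chain_roles).values():
            if role not in (INHIBITOR, PROTEASE, OTHER):
                raise ValueError(f"unknown chain role {role!r}")
        object.__setattr__(self, "runs", runs)
        object.__setattr__(self, "chain_roles", dict(self.chain_roles))

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def frames_per_run(self) -> int:
        return self.runs[0].n_frames

    @property
    def topology(self) -> Topology:
        return self.runs[0].topology

    def role(self, chain_id: str) -> str:
        return self.chain_roles.get(chain_id, OTHER)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(raw: str, lineno: int) -> tuple:
    line = raw.rstrip("\n").ljust(80)
    altloc = line[16]
    icode = line[26]
    if icode != " ":
        raise PDBFormatError(f"insertion codes are not supported (line {lineno})")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21]
        resid = int(line[22:26])
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except ValueError as exc:
        raise PDBFormatError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from None
    if not name:
        raise PDBFormatError(f"empty atom name at line {lineno}")
    element = line[76:78].strip()
    if not element:
        element = _guess_element(name)
    return serial, name, element, resname, chain, resid, xyz, altloc


def read_multimodel_pdb(
    path: str | Path, chain_roles: Mapping[str, str] | None = None
) -> TrajectorySet:
    """Read a multi-model PDB file into a single-run :class:`TrajectorySet`.

    ``MODEL``/``ENDMDL`` records delimit frames; a file without ``MODEL``
    records yields one frame.  All models must list the same atoms in the
    same order.  Only the first alternate location of each atom is kept.
    """
    path = Path(path)
    frames_meta: list[list[tuple]] = []
    frames_xyz: list[list[np.ndarray]] = []
    current_meta: list[tuple] | None = None
    current_xyz: list[np.ndarray] | None = None
    saw_model = False

    def close_frame() -> None:
        nonlocal current_meta, current_xyz
        if current_meta is not None:
            if not current_meta:
                raise PDBFormatError(f"{path}: MODEL block with no atoms")
            frames_meta.append(current_meta)
            frames_xyz.append(current_xyz)  # type: ignore[arg-type]
        current_meta, current_xyz = None, None

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            record = raw[:6]
            if record == "MODEL ":
                if current_meta:
                    raise PDBFormatError(
                        f"MODEL record at line {lineno} inside an open model block"
                    )
                saw_model = True
                current_meta, current_xyz = [], []
            elif record == "ENDMDL":
                close_frame()
            elif record in ("ATOM  ", "HETATM"):
                parsed = _parse_atom_line(raw, lineno)
                serial, name, element, resname, chain, resid, xyz, altloc = parsed
                if altloc not in (" ", "A"):
                    continue  # keep first altloc only
                if current_meta is None:
                    if saw_model:
                        raise PDBFormatError(
                            f"ATOM record outside MODEL block at line {lineno}"
                        )
                    current_meta, current_xyz = [], []
                current_meta.append((serial, name, element, resname, chain, resid))
                current_xyz.append(xyz)  # type: ignore[union-attr]
    close_frame()

    if not frames_meta:
        raise PDBFormatError(f"{path}: no atoms found")

    meta0 = frames_meta[0]
    key0 = [(m[4], m[5], m[1]) for m in meta0]
    for k, meta in enumerate(frames_meta[1:], start=2):
        if [(m[4], m[5], m[1]) for m in meta] != key0:
            raise TopologyError(f"{path}: model {k} has a different atom set from model 1")

    topology = Topology(
        serials=[m[0] for m in meta0],
        names=[m[1] for m in meta0],
        elements=[m[2] for m in meta0],
        resids=[m[5] for m in meta0],
        resnames=[m[3] for m in meta0],
        chains=[m[4] for m in meta0],
    )
    coords = np.stack([np.stack(xyz) for xyz in frames_xyz])
    run = Trajectory(topology, coords)
    return TrajectorySet(runs=(run,), chain_roles=dict(chain_roles or {}))


def _format_atom_name(name: str) -> str:
    # Names of up to 3 characters start in column 14; 4-character names
    # (common for hydrogens such as HH11) occupy columns 13-16.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_multimodel_pdb(traj: TrajectorySet | Trajectory, path: str | Path) -> None:
    """Write a single run as a multi-model PDB file (one MODEL per frame)."""
    if isinstance(traj, TrajectorySet):
        if traj.n_runs > 1:
            raise ValueError(
                "TrajectorySet has multiple runs; write each run to its own file"
            )
        run = traj.runs[0]
    else:
        run = traj
    if run.n_frames == 0 or run.n_atoms == 0:
        raise ValueError("cannot write an empty trajectory")
    if np.any(run.coords >= 1e4) or np.any(run.coords <= -1e3):
        raise PDBFormatError("coordinate magnitude exceeds the fixed PDB field width")

    top = run.topology
    with open(path, "w") as handle:
        for f in range(run.n_frames):
            handle.write(f"MODEL     {f + 1:4d}\n")
            for i in range(top.n_atoms):
                x, y, z = run.coords[f, i]
                handle.write(
                    "ATOM  {serial:5d} {name:4s} {resname:<3s} {chain:1s}{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n".format(
                        serial=int(top.serials[i]) % 100000,
                        name=_format_atom_name(str(top.names[i])),
                        resname=str(top.resnames[i]),
                        chain=str(top.chains[i]),
                        resid=int(top.resids[i]),
                        x=x,
                        y=y,
                        z=z,
                        occ=1.0,
                        b=0.0,
                        elem=str(top.elements[i])[:2],
                    )
                )
            handle.write("ENDMDL\n")
        handle.write("END\n")


# ---------------------------------------------------------------------------
# Donor / acceptor chemistry
# ---------------------------------------------------------------------------

BACKBONE_N_HYDROGENS = ("H", "HN", "H1", "H2", "H3", "HT1", "HT2", "HT3")
BACKBONE_ACCEPTORS = ("O", "OXT", "OT1", "OT2")


@dataclass(frozen=True)
class DonorAcceptorTable:
    """Side-chain donor/acceptor chemistry per residue type.

    ``donors`` maps ``(residue_name, heavy_atom)`` to the names of its
    attached hydrogens; ``acceptors`` is a set of ``(residue_name, atom)``.
    Backbone amide N (donor, except proline) and carbonyl O (acceptor) are
    implicit for every residue type listed in ``residues``.
    """

    donors: Mapping[tuple[str, str], tuple[str, ...]]
    acceptors: frozenset
    residues: frozenset

    def __post_init__(self) -> None:
        for (resname, heavy), hydrogens in dict(self.donors).items():
            if _guess_element(heavy) not in ("N", "O"):
                raise ValueError(f"donor heavy atom {resname}:{heavy} must be N or O")
            if not hydrogens:
                raise ValueError(f"donor {resname}:{heavy} lists no hydrogens")
        for resname, atom in self.acceptors:
            if _guess_element(atom) not in ("N", "O"):
                raise ValueError(f"acceptor atom {resname}:{atom} must be N or O")


def default_donor_acceptor_table() -> DonorAcceptorTable:
    """Standard amino-acid N/O hydrogen-bond chemistry (explicit-hydrogen MD)."""
    donors: dict[tuple[str, str], tuple[str, ...]] = {}
    acceptors: set[tuple[str, str]] = set()

    def donor(res: str, heavy: str, *hs: str) -> None:
        donors[(res, heavy)] = hs

    def acceptor(res: str, *atoms: str) -> None:
        for a in atoms:
            acceptors.add((res, a))

    donor("SER", "OG", "HG", "HG1")
    acceptor("SER", "OG")
    donor("THR", "OG1", "HG1")
    acceptor("THR", "OG1")
    donor("TYR", "OH", "HH")
    acceptor("TYR", "OH")
    donor("ASN", "ND2", "HD21", "HD22")
    acceptor("ASN", "OD1")
    donor("GLN", "NE2", "HE21", "HE22")
    acceptor("GLN", "OE1")
    donor("LYS", "NZ", "HZ1", "HZ2", "HZ3")
    donor("ARG", "NE", "HE")
    donor("ARG", "NH1", "HH11", "HH12")
    donor("ARG", "NH2", "HH21", "HH22")
    donor("TRP", "NE1", "HE1")
    acceptor("ASP", "OD1", "OD2")
    acceptor("GLU", "OE1", "OE2")
    for his in ("HIS", "HSD", "HSE", "HSP", "HID", "HIE", "HIP"):
        donor(his, "ND1", "HD1")
        donor(his, "NE2", "HE2")
        acceptor(his, "ND1", "NE2")

    residues = {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
    }
    return DonorAcceptorTable(
        donors=donors, acceptors=frozenset(acceptors), residues=frozenset(residues)
    )


@dataclass(frozen=True)
class RoleAssignment:
    """Per-atom hydrogen-bond roles for one topology.

    ``donor_hydrogens`` maps the topology index of each donor heavy atom to
    the indices of its attached hydrogens (possibly empty for trajectories
    stripped of hydrogens).
    """

    donor_heavy: np.ndarray  # bool, per atom
    acceptor: np.ndarray  # bool, per atom
    is_hydrogen: np.ndarray  # bool, donor-attached hydrogens
    donor_hydrogens: Mapping[int, tuple[int, ...]]


def _topology_of(obj) -> Topology:
    if isinstance(obj, Topology):
        return obj
    if isinstance(obj, (Frame, Trajectory)):
        return obj.topology
    if isinstance(obj, TrajectorySet):
        return obj.topology
    raise TypeError(f"cannot extract a topology from {type(obj).__name__}")


def assign_roles(traj, table: DonorAcceptorTable | None = None) -> RoleAssignment:
    """Flag each atom as donor heavy / acceptor / donor hydrogen.

    Residue types absent from the table fall back to backbone-only chemistry
    (N-H donor, C=O acceptor) with a warning.  Deterministic and idempotent:
    the output depends only on the topology and the table.
    """
    top = _topology_of(traj)
    if table is None:
        table = default_donor_acceptor_table()

    donor_heavy = np.zeros(top.n_atoms, dtype=bool)
    acceptor = np.zeros(top.n_atoms, dtype=bool)
    is_hydrogen = np.zeros(top.n_atoms, dtype=bool)
    donor_hydrogens: dict[int, tuple[int, ...]] = {}
    warned: set[str] = set()

    by_residue: dict[tuple[str, int], dict[str, int]] = {}
    resname_of: dict[tuple[str, int], str] = {}
    for i in range(top.n_atoms):
        key = (str(top.chains[i]), int(top.resids[i]))
        by_residue.setdefault(key, {})[str(top.names[i])] = i
        resname_of[key] = str(top.resnames[i])

    for key, atoms in by_residue.items():
        resname = resname_of[key]
        known = resname in table.residues
        if not known and resname not in warned:
            warnings.warn(
                f"residue type {resname!r} not in donor/acceptor table; "
                "using backbone-only fallback",
                stacklevel=2,
            )
            warned.add(resname)
        # Backbone amide nitrogen: donor unless proline.
        if "N" in atoms and resname != "PRO":
            n_idx = atoms["N"]
            hs = tuple(atoms[h] for h in BACKBONE_N_HYDROGENS if h in atoms)
            donor_heavy[n_idx] = True
            donor_hydrogens[n_idx] = hs
            for h in hs:
                is_hydrogen[h] = True
        # Backbone carbonyl / terminal oxygens: acceptors.
        for name in BACKBONE_ACCEPTORS:
            if name in atoms:
                acceptor[atoms[name]] = True
        if not known:
            continue
        for (res, heavy), h_names in dict(table.donors).items():
            if res == resname and heavy in atoms:
                idx = atoms[heavy]
                hs = tuple(atoms[h] for h in h_names if h in atoms)
                donor_heavy[idx] = True
                donor_hydrogens[idx] = hs
                for h in hs:
                    is_hydrogen[h] = True
        for res, name in table.acceptors:
            if res == resname and name in atoms:
                acceptor[atoms[name]] = True

    return RoleAssignment(
        donor_heavy=donor_heavy,
        acceptor=acceptor,
        is_hydrogen=is_hydrogen,
        donor_hydrogens=donor_hydrogens,
    )


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def calpha_indices(top: Topology, chain_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Topology indices of CA atoms of one chain, in residue-number order.

    Returns ``(indices, residue_numbers)``.  Residues lacking a CA atom are
    skipped with a warning; a chain with no CA atoms is an error.
    """
    chain_mask = top.chains == chain_id
    if not np.any(chain_mask):
        raise ValueError(f"chain {chain_id!r} not present in topology")
    indices: list[int] = []
    resnums: list[int] = []
    for chain, resid, _resname in top.residues(chain_id):
        try:
            idx = top.index_of(chain, resid, "CA")
        except KeyError:
            warnings.warn(
                f"residue {chain}:{resid} has no CA atom; skipped", stacklevel=2
            )
            continue
        indices.append(idx)
        resnums.append(resid)
    if not indices:
        raise ValueError(f"chain {chain_id!r} has no CA atoms")
    return np.asarray(indices, dtype=int), np.asarray(resnums, dtype=int)


def select_calpha(frame: Frame, chain_id: str) -> np.ndarray:
    """CA coordinates of one chain in residue-number order, shape (n, 3)."""
    idx, _ = calpha_indices(frame.topology, chain_id)
    return frame.coords[idx]
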