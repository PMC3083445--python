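"""Synthetic inputs for every pipeline stage.

Two families of generators stand in for resources the analyses normally
consume — GPU-scale molecular dynamics and plate-reader kinetics:

* toy two-chain trajectories (a 14-residue cyclic-inhibitor stand-in plus
  a protease stand-in) in which named donor→acceptor hydrogen bonds are
  switched on per frame with programmed Bernoulli occupancies, by placing
  the acceptor either in ideal bond geometry (2.9 Å, collinear) or
  displaced beyond 5 Å; geometry realism is deliberately minimal because
  the unit under test is the analysis, not the physics;
* kinetic datasets drawn from the competitive, Morrison, slow-binding and
  exponential-decay models at stated parameter values with optional
  Gaussian noise.

Every generator is deterministic given its seed and emits a machine-
readable ground-truth record alongside the data.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import kinetics
from .hbond_network import INTERNAL, INTERMOLECULAR, HBondKey, classify_bond
from .structure_io import INHIBITOR, PROTEASE, Topology, Trajectory, TrajectorySet

__all__ = [
    "ProgrammedBond",
    "internal_bond",
    "intermolecular_bond",
    "TrajectorySpec",
    "TrajectoryGroundTruth",
    "KineticsSpec",
    "KineticsDataset",
    "rng",
    "substream",
    "make_trajectory",
    "make_variant_panel",
    "make_kinetics",
]

# Backbone stand-in geometry: residues strung along x at a spacing that
# keeps every non-programmed donor/acceptor pair far outside the 3.3 Å
# cutoff; chains separated in y.
_RESIDUE_SPACING = 12.0  # Å
_CHAIN_SEPARATION = 40.0  # Å
_BOND_ON_DISTANCE = 2.9  # Å, donor N to placed acceptor O (collinear with H)
_BOND_OFF_DISTANCE = 6.0  # Å, displaced position when the bond is absent
_ATOM_OFFSETS = {
    "N": np.array([0.0, 0.0, 0.0]),
    "H": np.array([0.0, 0.0, 1.0]),
    "CA": np.array([1.5, 0.0, 0.0]),
    "C": np.array([3.0, 0.0, 0.0]),
    "O": np.array([3.0, 0.0, -1.2]),
}


def rng(seed: int) -> np.random.Generator:
    """Deterministic generator: identical seed, identical stream."""
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Independent, reproducible sub-stream keyed by (seed, *keys).

    String keys are hashed with CRC-32 so streams are stable across
    platforms and Python processes.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for key in keys:
        if isinstance(key, str):
            entropy.append(zlib.crc32(key.encode("utf-8")))
        else:
            entropy.append(int(key) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class ProgrammedBond:
    """A donor-residue → acceptor-residue bond with a target occupancy.

    The donor contributes its backbone N-H, the acceptor its carbonyl O.
    """

    donor_chain: str
    donor_residue: int
    acceptor_chain: str
    acceptor_residue: int
    occupancy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")
        if (self.donor_chain, self.donor_residue) == (self.acceptor_chain, self.acceptor_residue):
            raise ValueError("a programmed bond cannot stay within one residue")

    def key(self) -> HBondKey:
        return HBondKey(
            donor=(self.donor_chain, self.donor_residue, "N"),
            acceptor=(self.acceptor_chain, self.acceptor_residue, "O"),
        )


def internal_bond(donor_residue: int, acceptor_residue: int, occupancy: float,
                  chain: str = "I") -> ProgrammedBond:
    return ProgrammedBond(chain, donor_residue, chain, acceptor_residue, occupancy)


def intermolecular_bond(donor_residue: int, acceptor_residue: int, occupancy: float,
                        inhibitor_chain: str = "I", protease_chain: str = "E") -> ProgrammedBond:
    return ProgrammedBond(inhibitor_chain, donor_residue, protease_chain, acceptor_residue,
                          occupancy)


@dataclass(frozen=True)
class TrajectorySpec:
    """Study conditions for one synthetic trajectory set.

    Defaults mirror the analysed ensembles: three replicate runs of 5000
    saved frames over a 14-residue cyclic inhibitor bound to a protease.
    """

    n_residues_inhibitor: int = 14
    n_residues_protease: int = 20
    programmed_bonds: tuple[ProgrammedBond, ...] = ()
    n_frames: int = 5000
    n_runs: int = 3
    jitter_sigma: float = 0.05  # Å, isotropic Gaussian noise on every atom
    seed: int = 0
    inhibitor_chain: str = "I"
    protease_chain: str = "E"

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_runs < 1:
            raise ValueError("n_frames and n_runs must be at least 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")
        object.__setattr__(self, "programmed_bonds", tuple(self.programmed_bonds))
        limits = {
            self.inhibitor_chain: self.n_residues_inhibitor,
            self.protease_chain: self.n_residues_protease,
        }
        seen_acceptors: set[tuple[str, int]] = set()
        for bond in self.programmed_bonds:
            for chain, resid in (
                (bond.donor_chain, bond.donor_residue),
                (bond.acceptor_chain, bond.acceptor_residue),
            ):
                if chain not in limits:
                    raise ValueError(f"programmed bond references unknown chain {chain!r}")
                if not 1 <= resid <= limits[chain]:
                    raise ValueError(
                        f"programmed bond references missing residue {chain}:{resid}"
                    )
            acc = (bond.acceptor_chain, bond.acceptor_residue)
            if acc in seen_acceptors:
                raise ValueError(
                    f"residue {acc[0]}:{acc[1]} is the acceptor of two programmed bonds; "
                    "each carbonyl O can realise only one"
                )
            seen_acceptors.add(acc)

    @property
    def chain_roles(self) -> dict[str, str]:
        return {self.inhibitor_chain: INHIBITOR, self.protease_chain: PROTEASE}


@dataclass(frozen=True)
class TrajectoryGroundTruth:
    """What the generator actually placed, for closure tests."""

    bonds: tuple[ProgrammedBond, ...]
    keys: tuple[HBondKey, ...]
    classes: tuple[str, ...]
    presence: tuple[np.ndarray, ...]  # per run, (n_frames, n_bonds) bool

    def realized_occupancy(self, run: int) -> np.ndarray:
        return self.presence[run].mean(axis=0)

    def expected_mean_count(self, bond_class: str) -> float:
        return float(
            sum(b.occupancy for b, c in zip(self.bonds, self.classes) if c == bond_class)
        )

    def per_frame_counts(self, run: int, bond_class: str) -> np.ndarray:
        mask = np.array([c == bond_class for c in self.classes])
        return self.presence[run][:, mask].sum(axis=1)

    def to_json(self) -> str:
        payload = {
            "bonds": [
                {
                    "donor": f"{b.donor_chain}:{b.donor_residue}:N",
                    "acceptor": f"{b.acceptor_chain}:{b.acceptor_residue}:O",
                    "class": c,
                    "programmed_occupancy": b.occupancy,
                    "realized_occupancy": [
                        float(self.presence[r][:, j].mean()) for r in range(len(self.presence))
                    ],
                }
                for j, (b, c) in enumerate(zip(self.bonds, self.classes))
            ],
            "expected_mean_internal": self.expected_mean_count(INTERNAL),
            "expected_mean_intermolecular": self.expected_mean_count(INTERMOLECULAR),
        }
        return json.dumps(payload, indent=2)


def _build_topology(spec: TrajectorySpec) -> tuple[Topology, np.ndarray]:
    """Template topology and base coordinates for the two-chain system."""
    serials, names, elements, resids, resnames, chains = [], [], [], [], [], []
    base = []
    serial = 0
    chain_specs = [
        (spec.inhibitor_chain, spec.n_residues_inhibitor, 0.0),
        (spec.protease_chain, spec.n_residues_protease, _CHAIN_SEPARATION),
    ]
    for chain_id, n_res, y in chain_specs:
        for res in range(1, n_res + 1):
            # Gentle deterministic wiggle keeps the chain (and its Cα trace)
            # non-collinear so rigid-body superposition is well conditioned,
            # without bringing non-programmed donor/acceptor pairs anywhere
            # near the geometric cutoffs.
            origin = np.array(
                [
                    res * _RESIDUE_SPACING,
                    y + 2.0 * np.sin(0.7 * res),
                    1.5 * np.cos(1.3 * res),
                ]
            )
            for name, offset in _ATOM_OFFSETS.items():
                serial += 1
                serials.append(serial)
                names.append(name)
                elements.append(name[0])
                resids.append(res)
                resnames.append("ALA")
                chains.append(chain_id)
                base.append(origin + offset)
    topology = Topology(serials, names, elements, resids, resnames, chains)
    return topology, np.array(base)


def make_trajectory(spec: TrajectorySpec) -> tuple[TrajectorySet, TrajectoryGroundTruth]:
    """Generate a replicate trajectory set with programmed bond occupancies.

    For each programmed bond and frame, with probability ``occupancy`` the
    acceptor O is placed 2.9 Å from the donor N collinear with its H
    (satisfying the default criteria), otherwise 6.0 Å away (violating
    them).  Frames are independent; each run draws from its own seeded
    sub-stream; Gaussian jitter is then added to every coordinate.
    """
    topology, base = _build_topology(spec)
    donor_n = [
        topology.index_of(b.donor_chain, b.donor_residue, "N") for b in spec.programmed_bonds
    ]
    acceptor_o = [
        topology.index_of(b.acceptor_chain, b.acceptor_residue, "O")
        for b in spec.programmed_bonds
    ]
    probs = np.array([b.occupancy for b in spec.programmed_bonds])
    z_hat = np.array([0.0, 0.0, 1.0])

    runs = []
    presence_per_run = []
    for r in range(spec.n_runs):
        gen = substream(spec.seed, "trajectory-run", r)
        coords = np.broadcast_to(base, (spec.n_frames, *base.shape)).copy()
        if spec.programmed_bonds:
            present = gen.random((spec.n_frames, len(probs))) < probs
            for j, (n_idx, o_idx) in enumerate(zip(donor_n, acceptor_o)):
                on_pos = base[n_idx] + _BOND_ON_DISTANCE * z_hat
                off_pos = base[n_idx] + _BOND_OFF_DISTANCE * z_hat
                coords[:, o_idx] = np.where(present[:, j, None], on_pos, off_pos)
        else:
            present = np.zeros((spec.n_frames, 0), dtype=bool)
        if spec.jitter_sigma > 0:
            coords = coords + gen.normal(0.0, spec.jitter_sigma, size=coords.shape)
        runs.append(Trajectory(topology, coords))
        presence_per_run.append(present)

    traj_set = TrajectorySet(runs=tuple(runs), chain_roles=spec.chain_roles)
    classes = tuple(
        classify_bond(b.key(), spec.chain_roles) for b in spec.programmed_bonds
    )
    truth = TrajectoryGroundTruth(
        bonds=spec.programmed_bonds,
        keys=tuple(b.key() for b in spec.programmed_bonds),
        classes=classes,
        presence=tuple(presence_per_run),
    )
    return traj_set, truth


def make_variant_panel(
    base: TrajectorySpec,
    variants: Mapping[str, Sequence[ProgrammedBond]] | Iterable[tuple[str, Sequence[ProgrammedBond]]],
) -> dict[str, tuple[TrajectorySet, TrajectoryGroundTruth]]:
    """One trajectory set per variant over a shared topology.

    Seeds derive deterministically from the base seed and the variant name,
    so panels are reproducible and variant order is irrelevant.
    """
    items = list(variants.items()) if isinstance(variants, Mapping) else list(variants)
    if not items:
        raise ValueError("variant map is empty")
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate variant names: {dupes}")
    panel = {}
    for name, bonds in items:
        seed = int(
            np.random.SeedSequence(
                [int(base.seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))]
            ).generate_state(1)[0]
            % (2**31)
        )
        spec = replace(base, programmed_bonds=tuple(bonds), seed=seed)
        panel[name] = make_trajectory(spec)
    return panel


# ---------------------------------------------------------------------------
# Kinetic datasets
# ---------------------------------------------------------------------------

_REQUIRED = {
    "competitive": (("vmax", "km_uM", "ki_nM"), ("substrate_uM", "inhibitor_nM")),
    "morrison": (("ki_nM", "enzyme_nM", "substrate_uM", "km_uM"), ("inhibitor_nM",)),
    "slow_binding": (
        ("kon_m1s1", "koff_s1", "inhibitor_nM", "substrate_uM", "km_uM", "v0"),
        ("time_s",),
    ),
    "decay": (("a0", "t_half"), ("time",)),
}


@dataclass(frozen=True)
class KineticsSpec:
    """A kinetic model, its true parameters, a design grid and a noise level.

    ``noise_sigma`` is the Gaussian noise standard deviation as a fraction
    of the model's uninhibited reference signal.
    """

    model: str
    params: Mapping[str, float]
    design: Mapping[str, Sequence[float]]
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _REQUIRED:
            raise ValueError(f"unknown model {self.model!r}; expected one of {sorted(_REQUIRED)}")
        needed_params, needed_design = _REQUIRED[self.model]
        missing = [p for p in needed_params if p not in self.params]
        if missing:
            raise ValueError(f"model {self.model!r} is missing parameters: {missing}")
        missing = [d for d in needed_design if d not in self.design or len(self.design[d]) == 0]
        if missing:
            raise ValueError(f"model {self.model!r} is missing design grids: {missing}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(self, "design", {k: list(v) for k, v in self.design.items()})


@dataclass(frozen=True)
class KineticsDataset:
    """Generated tables plus the generating truth."""

    tables: Mapping[str, pd.DataFrame]
    truth: Mapping[str, float]

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in self.tables.items():
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        truth_path = outdir / "ground_truth.json"
        truth_path.write_text(json.dumps(dict(self.truth), indent=2))
        written.append(truth_path)
        return written


def make_kinetics(spec: KineticsSpec) -> KineticsDataset:
    """Evaluate the named model on the design grid, with seeded noise."""
    gen = substream(spec.seed, "kinetics", spec.model)
    p = dict(spec.params)

    def noisy(values: np.ndarray, scale: float) -> np.ndarray:
        if spec.noise_sigma == 0:
            return values
        return values + gen.normal(0.0, spec.noise_sigma * scale, size=values.shape)

    if spec.model == "competitive":
        S, I = np.meshgrid(spec.design["substrate_uM"], spec.design["inhibitor_nM"])
        S, I = S.ravel(), I.ravel()
        v = kinetics.competitive_velocity(S, I, p["vmax"], p["km_uM"], p["ki_nM"])
        table = pd.DataFrame(
            {"substrate_uM": S, "inhibitor_nM": I, "velocity": noisy(v, p["vmax"])}
        )
        return KineticsDataset(tables={"rates": table}, truth=p)

    if spec.model == "morrison":
        I = np.asarray(spec.design["inhibitor_nM"], dtype=float)
        ki_app = p["ki_nM"] * (1.0 + p["substrate_uM"] / p["km_uM"])
        frac = kinetics.morrison_fraction(p["enzyme_nM"], I, ki_app)
        table = pd.DataFrame({"inhibitor_nM": I, "fractional_velocity": noisy(frac, 1.0)})
        return KineticsDataset(
            tables={"fractions": table}, truth={**p, "ki_app_nM": ki_app}
        )

    if spec.model == "slow_binding":
        t = np.asarray(spec.design["time_s"], dtype=float)
        correction = 1.0 + p["substrate_uM"] / p["km_uM"]
        k_obs = p["koff_s1"] + p["kon_m1s1"] * kinetics.nM_to_M(p["inhibitor_nM"]) / correction
        vs = p["v0"] * p["koff_s1"] / k_obs
        uninhibited = p["v0"] * t
        coadd = kinetics.slow_binding_progress(t, p["v0"], vs, k_obs)
        preformed = kinetics.slow_binding_progress(t, 0.0, vs, k_obs)
        scale = p["v0"] * float(t.max())
        tables = {
            "uninhibited": pd.DataFrame({"time_s": t, "signal": noisy(uninhibited, scale)}),
            "coadd": pd.DataFrame({"time_s": t, "signal": noisy(coadd, scale)}),
            "preformed": pd.DataFrame({"time_s": t, "signal": noisy(preformed, scale)}),
        }
        truth = {**p, "k_obs_s1": float(k_obs), "vs": float(vs),
                 "ki_nM": p["koff_s1"] / p["kon_m1s1"] * 1e9}
        return KineticsDataset(tables=tables, truth=truth)

    # decay
    t = np.asarray(spec.design["time"], dtype=float)
    lam = np.log(2.0) / p["t_half"]
    values = p["a0"] * np.exp(-lam * t)
    table = pd.DataFrame({"time": t, "activity": noisy(values, p["a0"])})
    return KineticsDataset(
        tables={"decay": table}, truth={**p, "decay_rate": float(lam)}
    )
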