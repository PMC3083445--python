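# looprigor

Rigidity and potency analysis for canonical-loop serine protease
inhibitors.

Standard-mechanism (Laskowski) inhibitors such as the 14-residue cyclic
peptide SFTI-1 bind their target protease through a rigid canonical loop
held in shape by an internal hydrogen-bond network and a disulfide bond.
When the contact β-sheet of such a scaffold is re-engineered for a new
target (for example the SFTI-FCQR series directed at kallikrein-related
peptidase 4, a prostate-cancer protease), substitutions can silently
erode that internal network — and with it the loop rigidity that tight,
standard-mechanism binding depends on.  `looprigor` implements the
analysis side of an in-silico screen built on exactly this idea: count
internal hydrogen bonds across MD trajectory frames for each variant,
read out loop rigidity as Cα RMSD, rank the variants, and test whether
the ranking predicts measured inhibition constants.

The package is aimed at structural bioinformaticians and enzymologists
who have trajectory coordinates and/or assay tables and want the whole
chain from geometry to kinetics in one tested toolbox.

## What it computes

**Hydrogen-bond networks** (`looprigor.hbond_network`).  A bond is
counted between donor heavy atom D (N/O with attached H) and acceptor A
(N/O) in a frame when the D···A distance is ≤ 3.3 Å and the D–H···A angle
is within 40° of linear (both configurable).  Per-bond *occupancy* is the
fraction of frames containing the bond; bonds are *internal* (both atoms
on the inhibitor) or *intermolecular* (inhibitor–protease).  Replicate
runs are summarised as mean ± SEM over run means, with a >50%-occupancy
persistence filter and per-residue bond frequencies.

**Loop rigidity** (`looprigor.rigidity`).  Optimal rigid-body
superposition (Kabsch, reflections excluded), per-frame Cα RMSD against
the starting or trajectory-average structure, and per-residue RMSD
profiles.

**Inhibition kinetics** (`looprigor.kinetics`):

- competitive model `v = Vmax·S/(KM(1+I/Ki)+S)`;
- Morrison tight-binding fractional velocity
  `v_i/v_0 = 1 − [(E+I+Ki′) − √((E+I+Ki′)² − 4EI)]/(2E)` with
  `Ki′ = Ki(1+S/KM)`, fitted with KM fixed;
- four-parameter logistic IC50;
- slow-binding progress curves `P(t) = v_s t + (v_0−v_s)(1−e^{−k_obs t})/k_obs`
  and k_off extraction from the uninhibited / co-addition / preformed-complex
  curve triple (`k_off = k_obs·v_s/v_0`), plus `k_on = k_off/Ki`;
- exponential decay half-lives `t½ = ln2/λ`.

**Screening** (`looprigor.screening`).  Ranks variants by mean internal
bond count, computes % change versus a reference variant, joins measured
Ki/IC50 values, and reports Spearman and Pearson (on Ki and log₁₀ Ki)
rigidity–potency correlations.  `looprigor.reference_data` bundles the
published 19-variant SFTI-FCQR residue-14 screen and its assay constants.

**Synthetic data** (`looprigor.synthetic_data`).  Deterministic, seeded
generators for two-chain toy trajectories with programmable per-bond
occupancies and for kinetic datasets drawn from any of the models above —
so every stage is testable without an MD engine or a plate reader.

## Worked example

```python
import numpy as np
from looprigor import hbond_network as hb, kinetics as kin
from looprigor import screening as scr, synthetic_data as sd

base = sd.TrajectorySpec(n_frames=1000, n_runs=3, seed=0)
panel = sd.make_variant_panel(base, {
    "rigid-variant":     [sd.internal_bond(d, d + 7, p) for d, p in zip(range(1, 6), (1.0, 1.0, 0.9, 0.9, 0.9))],
    "reference-variant": [sd.internal_bond(d, d + 7, p) for d, p in zip(range(1, 6), (1.0, 0.9, 0.8, 0.6, 0.4))],
    "floppy-variant":    [sd.internal_bond(d, d + 7, p) for d, p in zip(range(1, 6), (0.8, 0.6, 0.5, 0.4, 0.3))],
})
summaries = {name: hb.summarize(traj) for name, (traj, _) in panel.items()}
report = scr.build_report(summaries, "reference-variant",
                          potencies={"rigid-variant": 0.04,
                                     "reference-variant": 3.9,
                                     "floppy-variant": 21.0})
for v in report.variants:
    print(f"{v.variant_name:20s} {v.internal_mean:5.2f}  {v.internal_pct_change:+6.1f}%  Ki={v.ki_nM} nM")
print("Spearman rho (internal vs Ki):", report.correlations["internal"].spearman_rho)

I = np.geomspace(0.0015, 1.5, 8)
spec = sd.KineticsSpec("morrison",
                       {"ki_nM": 0.0386, "enzyme_nM": 0.15,
                        "substrate_uM": 500.0, "km_uM": 679.9},
                       {"inhibitor_nM": list(I)})
t = sd.make_kinetics(spec).tables["fractions"]
fit = kin.fit_morrison(t["inhibitor_nM"], t["fractional_velocity"],
                       enzyme_nM=0.15, substrate_uM=500.0, km_uM=679.9)
print(f"fitted Ki = {fit.params['ki_nM']:.4f} nM (Ki_app = {fit.params['ki_app_nM']:.4f} nM)")
print(f"kon = {kin.second_order_kon(0.031, fit.params['ki_nM']):.3g} M^-1 s^-1")
```

prints

```
rigid-variant         4.70   +27.2%  Ki=0.04 nM
reference-variant     3.70    +0.0%  Ki=3.9 nM
floppy-variant        2.60   -29.7%  Ki=21.0 nM
Spearman rho (internal vs Ki): -1.0
fitted Ki = 0.0386 nM (Ki_app = 0.0670 nM)
kon = 8.03e+08 M^-1 s^-1
```

The three variants were programmed with internal bond-count means of
4.7, 3.7 and 2.6; detection recovers those means, the % changes follow,
and a strictly inverse rigidity–potency ranking gives Spearman ρ = −1.
The Morrison fit recovers the generating tight-binding Ki exactly on
noiseless data; Ki_app exceeds Ki by the substrate-competition factor
1 + S/KM ≈ 1.74, and the implied association rate constant is in the
diffusion-controlled regime.

The same workflow is available from a shell:

```sh
looprigor simulate-traj --spec spec.yaml --out sim/
looprigor hbonds --traj sim/run1.pdb --traj sim/run2.pdb --traj sim/run3.pdb --out net/
looprigor rank --summaries variants/ --reference "SFTI-FCQR Asp14" --potencies ki.csv --out screen.tsv
looprigor fit-ki --mode morrison --data fractions.csv --enzyme-nm 0.15 --km-um 679.9 --substrate-um 500
```

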