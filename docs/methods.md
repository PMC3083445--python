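# Methods

This note documents the models implemented in `looprigor`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Hydrogen-bond detection

A hydrogen bond is a geometric event between a donor heavy atom D (N or
O carrying at least one hydrogen) and an acceptor A (N or O):

- D···A distance ≤ `max_da_distance` (default **3.3 Å**), and
- for at least one attached hydrogen, the D–H···A angle at H deviates
  from linearity by at most `max_angle_deviation` (default **40°**,
  i.e. the angle is ≥ 140°).

These defaults are the cutoffs commonly used in VMD-style trajectory
analysis of protease–inhibitor complexes; both are configurable.  Bond
identity across frames is the *directed heavy-atom pair* — which
hydrogen satisfied the test in a given frame is irrelevant, so a
rotating ammonium or guanidino group still counts as one persistent
bond.  Intra-residue pairs are excluded; adjacent-residue backbone pairs
are not, because canonical-loop networks genuinely contain i→i±1 bonds.
A cyclic backbone needs no special casing: detection is purely geometric
and the topology never assumes chain termini.

Donor/acceptor chemistry comes from a configurable per-residue table
(`DonorAcceptorTable`); the default covers the 20 standard amino acids
(backbone amide N–H donor except proline, carbonyl/terminal O acceptors,
and the usual side-chain cases: Ser/Thr/Tyr hydroxyls as both donor and
acceptor, Asn/Gln amides, Lys ammonium, the three Arg guanidino
nitrogens, Trp indole N–H, Asp/Glu carboxylates, His imidazole
nitrogens).  Sulfur is deliberately excluded.  Unknown residue types
fall back to backbone-only chemistry with a warning.  A hydrogen-free
mode (`require_hydrogens=False`) accepts on distance alone, for
coordinate sets stripped of hydrogens; reports flag it.

**Replicate statistics.**  Occupancy is the fraction of a run's frames
containing a bond.  Class counts (internal = both atoms on the
inhibitor; intermolecular = inhibitor–protease; everything else =
"other" and excluded from summaries) are averaged per run, then the
mean and SEM are taken *across run means* with n = number of runs.
Within-run frame autocorrelation is deliberately ignored — replicate
trajectories, not frames, are the unit of independence.  With a single
run the SEM is reported as absent rather than zero.  No burn-in is
applied by default (production frames are assumed equilibrated); a
`burn_in` option drops initial frames.  The persistence filter keeps
bonds with occupancy *strictly above* 0.5, matching the convention of
showing only majority-occupancy bonds.  Per-residue frequencies sum the
occupancies of every bond touching a residue (a bond inside the
inhibitor contributes to both its residues); display rounding is one
decimal, half away from zero, while stored values stay unrounded.

## Rigidity (Cα RMSD)

Superposition is the least-squares rigid-body fit computed via
`scipy.spatial.transform.Rotation.align_vectors` (Kabsch-equivalent;
reflections excluded).  The residual is re-evaluated directly from the
fitted coordinates because the solver's reported residual loses
precision to cancellation for near-exact fits.

Two reference conventions are provided, because they answer different
questions: RMSD to the *starting structure* measures conformational
drift away from the design template, RMSD to the *average structure*
measures fluctuation about whatever conformation the loop adopted.  The
average structure is single-pass by default — superpose every frame onto
the first frame of the first run, then take the per-atom mean — which is
deterministic and sufficient at these sizes; an `iterate` flag refreshes
the target until it moves < 1e-4 Å RMS.  Per-residue RMSD uses a
*global* fit per frame with a per-residue readout, so a floppy tail
shows up at the tail rather than contaminating the fit.  Multi-run input
yields per-run profiles plus a pooled mean; fitting and readout
selections default to the inhibitor Cα set and are configurable.

## Kinetics

Units are explicit in every signature (`substrate_uM`, `inhibitor_nM`,
`km_uM`, …) and converted to molar only inside mixed expressions; this
suffix convention replaces a heavier unit-registry object and removes
the silent-mismatch failure mode that dominates this kind of analysis.

- **Competitive inhibition**: `v = Vmax·S/(KM(1+I/Ki)+S)`; the fit
  estimates Vmax, KM (optionally fixed) and Ki by Levenberg–Marquardt
  least squares (lmfit), with data-derived starting values and standard
  errors from the Jacobian.  Data with no inhibited measurements is
  rejected as unidentifiable.
- **Morrison tight binding**: when inhibitor depletion by enzyme is
  non-negligible the fractional velocity follows the closed-form
  quadratic in (E, I, Ki_app).  The fit is parameterised on Ki_app and
  transformed to Ki = Ki_app/(1+S/KM) with KM held fixed at the supplied
  value; KM uncertainty is *not* propagated (an explicit choice matching
  standard practice for this assay).  A stoichiometric-titration regime
  (fitted Ki_app ≪ E) triggers a conditioning warning.
- **IC50**: four-parameter logistic on log-concentration with asymptotes
  fixable at 1/0 (the default) and a free Hill slope.  IC50 is treated
  as descriptive — under tight-binding conditions it gravitates to
  E/2 + Ki_app rather than Ki, which is why Ki is the mechanistic
  quantity reported alongside it.
- **Slow binding**: progress curves
  `P(t) = v_s t + (v_0−v_s)(1−e^{−k_obs t})/k_obs`.  From the
  three-curve design (uninhibited; co-addition of substrate and
  inhibitor; preformed enzyme–inhibitor complex) the primary estimator
  is `k_off = k_obs·v_s/v_0` from the co-addition fit.  A secondary
  "intercept" estimator is also reported: extrapolate both inhibited
  steady-state lines back to y = 0 and take 1/Δt of the two time-axis
  intercepts.  When the preformed complex starts fully bound the two
  estimators coincide, so their agreement is a useful internal
  consistency check; both are reported because the graphical reading of
  the steady-state difference admits either interpretation.
  `k_on = k_off/Ki` converts to the second-order association constant.
- **Half-life**: `A(t) = A0·e^{−λt}` fitted by nonlinear least squares
  (log-linear regression provides the start), `t½ = ln2/λ` with the SE
  by first-order propagation.  A non-decaying series warns and reports
  an infinite half-life rather than failing.

All fitters are deterministic given the data: starting values derive
from the data, convergence tolerances are 1e-12 on the relative
parameter change, parameters are bounded at zero where physical, and
non-convergence is reported in the result, never silently.

## Screening

Variants are ranked by mean internal bond count (descending, stable
name-order tie-break).  Percent change versus the reference variant is
`100·(variant − reference)/reference`, displayed to one decimal.
Correlation with potency is computed three ways — Spearman ρ, Pearson on
log₁₀ Ki, Pearson on raw Ki — because potencies span orders of magnitude
and the scale-free rank statement is the one the data supports;
correlations use only variants with a measured Ki and require at least
three of them.  Variants without potency data remain first-class rows.
Internal, intermolecular and total counts are all reported; no
significance claim is attached to any of them.  Fold changes are
reported to three significant figures.

The bundled `reference_data` module carries the published 19-variant
SFTI-FCQR residue-14 screen (internal/intermolecular means ± SEM), the
seven measured Morrison Ki and IC50 values against KLK4, the KLK14
IC50 pair, the competitive-model Ki of the Asp14 variant, the FVQR-pNA
KM (679.9 µM), the Asn14 slow-binding constants and the Lys14
degradation half-life.  Joining the bundled bond counts and Ki values
reproduces the perfectly inverse internal-count ranking (ρ = −1 over
n = 7), while the intermolecular ranking is not perfectly inverse — the
contrast that singles out the internal network as the predictive
feature.

## Synthetic data: what it emulates and what it does not

The trajectory generator builds a two-chain stand-in (14-residue
"inhibitor", 20-residue "protease", five backbone atoms per residue)
whose residues are spaced ~12 Å apart with a gentle deterministic
wiggle, so that no unprogrammed donor–acceptor pair can approach the
cutoffs and the Cα trace is non-collinear (well-conditioned
superposition).  Each programmed bond is realised per frame by a
Bernoulli draw at its target occupancy: the acceptor carbonyl O is
placed 2.9 Å from the donor N, collinear with its hydrogen (satisfying
the criteria) or displaced to 6 Å (violating them).  Gaussian jitter
(default σ = 0.05 Å, small enough never to flip a placed bond across the
3.3 Å / 40° thresholds) is then added to every coordinate.  Defaults
mirror the study conditions of the screen being emulated: 3 replicate
runs × 5000 frames; tests use fewer frames where binomial power
suffices.

This is deliberately *not* physics: frames are independent (no
autocorrelation), bonds are independent (no cooperativity), geometry is
schematic, and there are no solvent, side-chain rotamers or forces.
Consequently, passing closure tests demonstrates that the *analysis*
(detection, classification, occupancy statistics, replicate averaging,
ranking) is correct — not that any MD ensemble is reproduced.  The same
applies to the kinetics generators, which evaluate the fitted models
themselves at chosen designs ("inverse crime" by construction): noiseless
closures verify the fitters' correctness and the noisy, seeded variants
verify calibration (truth within ~3 SE), nothing more.

Randomness is handled through `numpy` `SeedSequence` streams keyed by
(seed, purpose, run) with CRC-32 hashing of string keys, so runs,
variants and models draw from independent, platform-stable streams, and
a panel's variant seeds are independent of insertion order.

## Problem sizes

The default test-suite and acceptance runs use desk-scale inputs chosen
for statistical sufficiency: kinetic designs of 8–30 points (matching
the published assay layouts), trajectory closures at 200–2000 frames for
unit tests, and one 3 × 5000-frame occupancy-recovery check at the full
emulated scale.  Binomial 3σ bounds at n = 15 000 frames resolve
occupancy errors of ~1%, which is the precision the replicate SEMs in
the emulated screen actually carry.

## Known limitations

- The PDB layer is deliberately strict (fixed columns, consistent models,
  no insertion codes, first altloc only) and handles multi-model PDB
  only — no DCD/XTC/mmCIF.  Large trajectories should stay in memory via
  the synthetic generators rather than round-tripping through PDB text.
- Hydrogen-bond scoring is binary-geometric; no energies, no
  water-mediated bridges, no salt-bridge special-casing.
- The Morrison fit treats KM as exact; enabling KM-uncertainty
  propagation is left to the caller via repeated fits.
- IC50 fits assume a monotone transition within the sampled range.
- The slow-binding module fits single-step binding (one exponential
  relaxation); two-step induced-fit mechanisms are out of scope.
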