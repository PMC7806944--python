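# Methods

## The model

abfekit computes standard binding free energies through a restrained
dissociation cycle. Harmonic restraints are attached to the protein and
the ligand, the ligand is alchemically transferred from the binding site
to bulk solvent, and the restraints are released again; the sum of the
step free energies is −ΔG°_bind. The restraints serve two purposes: they
keep the decoupling ligand localized (connecting the calculation to the
1 M standard state), and they rigidify conformational degrees of freedom
so each alchemical window converges quickly. In exact arithmetic the
conformational restraints cancel between attach and release; their use is
a variance-reduction device, not an approximation.

Two alchemical routes are assembled. In double decoupling (DD) the
electrostatic and Lennard-Jones interactions of the ligand are turned off
separately in the bound state (components `e`, `v`) and in a pure-solvent
box (`f`, `w`); the transfer term is the bound-minus-unbound difference.
In simultaneous decoupling–recoupling (SDR) a second copy of the ligand
far from the protein (z offset `dd_dist`) is recoupled while the bound
copy decouples, so the net charge of the box never changes; the `e` and
`v` components then already are differences and `f`/`w` do not exist.
The attach–pull–release (APR) physical path is deliberately a stub.

Components are stored as the ΔG of their named process and summed
literally; ΔG°_bind is reported negative-favourable, and
Kd = C° exp(ΔG°_bind/RT).

## Restraint frame geometry

The complex is first aligned to a reference protein structure:
Needleman–Wunsch global sequence alignment on the Cα sequences (match +1,
mismatch −1, gap −2; traceback ties broken diagonal → up → left so paired
lists are reproducible) followed by Kabsch superposition of the matched
Cα pairs, with the ligand co-transformed. The stand-in for a structural
aligner is a declared design choice: for the same-family proteins this
workflow assumes, sequence-guided Cα superposition is adequate and
dependency-free.

L1 is the ligand heavy atom inside the strike-zone square (side
2·`l1_range`, centred at (x_P1+`l1_x`, y_P1+`l1_y`)) with the smallest
|z − z_P1| in [`l1_z`, `l1_zm`]; bounds are inclusive and ties break by
lowest serial. N1 sits 5.0 Å from L1 toward P1 along z; the system is
rotated about z (smaller-magnitude solution, ties positive) so P1, L1, N1
share one x value; N2 takes P1's x,y at N1's z; N3 sits |N1−N2| above N2.
This guarantees |N1−L1| = 5.00 Å and right angles N2−N1−L1 and N1−N2−P1,
keeping the T1/T4 dihedral restraints away from gimbal lock. L2 then
minimises |∠(N1,L1,L2) − 90°| subject to `min_adis` ≤ |L1−L2| ≤
`max_adis`, and L3 analogously via ∠(L1,L2,L3). Only heavy atoms are
anchor candidates, consistent with the heavy-atom torsion policy.

A pose is *unstable* when no L1 candidate remains in the zone (the ligand
left the site during equilibration); unstable poses are flagged, skipped,
and excluded from the pose combination rather than penalised.

## Restraints

All terms are harmonic, `U = k (x − x0)²` with no ½ factor — the form the
window-scaling and release formulas assume — with k in kcal/mol/Å² for
distances and kcal/mol/rad² for angles and dihedrals (angular reference
values are stored in degrees and converted inside the energy; dihedral
differences wrap to (−180°, 180°]). Reference values are measured from
the starting coordinates, so the restraint energy of the start structure
is exactly zero. Window i scales every spring as `attach_rest(i)/100 · k`,
with the schedule running 0 → 100.

Ligand TR terms: D1 = N1–L1, A1 = N2–N1–L1, A2 = N1–L1–L2,
T1 = N3–N2–N1–L1, T2 = N2–N1–L1–L2, T3 = N1–L1–L2–L3. Protein TR terms
mirror them through P1–P3 (D2, A3, A4, T4–T6). Protein conformational
restraints are the three anchor–anchor distances plus, optionally,
backbone φ = C_{i−1}–N–Cα–C and ψ = N–Cα–C–N_{i+1} for a residue range;
ω is never restrained (the peptide bond is already rigid). Ligand
conformational restraints are the three L-anchor distances plus one
heavy-atom torsion per *central bond* — a heavy-heavy bond whose two ends
both have further heavy neighbours — with ring torsions included. Where the
choice of torsion through a bond is arbitrary, the lexicographically
smallest heavy quadruple is taken, for reproducibility. Decoding a ligand
topology's dihedral list follows the AMBER convention (atom index
= |entry|/3 + 1; a negative third entry only marks a skipped 1–4 term and
is kept, a negative fourth entry marks an improper and is dropped;
redundant terms on one bond are deduplicated by the central-bond rule).

## Estimators

**MBAR.** Per-window free energies solve the standard self-consistent
equations on the reduced potentials u_k(x) = βU_k(x), with log-sum-exp
stabilisation, convergence when no reduced free energy moves by more than
1e-8 kT, and a 10 000-iteration cap (non-convergence raises with the
residual). The gauge is G of the first window = 0. The asymptotic
standard error of a free-energy difference is available from the
estimator's weight-matrix covariance (thin-SVD form); it was validated
against the empirical scatter of independent replicates on the Gaussian
fixtures.

**TI-GQ.** ΔG = Σ w_i ⟨∂U/∂λ⟩_i with Gauss–Legendre nodes/weights mapped
to [0,1] (12 nodes by default; exact for polynomial integrands up to
degree 23). User-supplied `lambdas`/`weights` override the defaults.

**TR release.** The six-dimensional standard-state integral factorises
into six 1-D integrals: radial (with the r² Jacobian, truncated where the
integrand falls below 1e-16 of its peak), two polar (sin θ Jacobian over
[0, π]), and three periodic dihedrals (wrapped quadratic over a full
turn, hence independent of the reference value). Each is evaluated by
adaptive quadrature at 1e-8 relative tolerance. The stiff-spring Gaussian
closed form `kT ln[(C°/8π²) r0² sinθ0 sinΘ0 π³(kT)³ (k_d k_a⁵)^{−1/2}]`
agrees to <0.01 kcal/mol for k ≥ 100. Tighter springs make the release
more negative (larger in magnitude): the restrained volume shrinks
relative to the standard-state volume 1661 Å³.

**Uncertainties.** Each window's trajectory is split into `blocks`
contiguous blocks (remainder samples go to the last blocks), the
estimator is re-run per block, and σ = sqrt((1/N_b) Σ (x_n − x̄)²) with x̄
the full-trajectory estimate — a deliberately conservative spread
(roughly √N_b times a standard error), reported as-is and combined across
components in quadrature. Where a calibrated standard error is needed
(estimator-recovery coverage tests) the MBAR asymptotic SE is used
instead, because a block-derived SE carries enough χ² estimation noise at
N_b = 10 to break nominal 3σ coverage on its own.

Constants: R = 1.98720425864083e-3 kcal/(mol K); default temperature
298.15 K; C° = 1 M = 1/1661 Å⁻³.

## Synthetic data

The samplers replace MD with distributions whose free energies are known
exactly, so estimator error is attributable solely to the estimator:

* harmonic windows — direct Gaussian draws from
  exp[−β(k_sys(x−x_sys)² + k_win(x−x0)²)]; variance kT/(2(k_sys+k_win))
  under the no-½ convention; attach ΔG known in closed form from the
  partition-function ratio;
* the toy alchemical model U(x;λ) = (1−λ)U_A + λU_B with harmonic end
  states — Gaussian at every λ, ∂U/∂λ available per sample, end-state
  partition functions integrable to machine precision;
* multivariate restraint windows — each restraint coordinate fluctuates
  independently about its reference with an intrinsic spring
  `synth_k_sys` (20 kcal/mol/rad² or Å² by default, a stiffness at which
  adjacent attach windows overlap well), so the exact component ΔG is a
  sum of 1-D closed forms;
* a Metropolis sampler of the six TR coordinates including the
  r² sinθ sinΘ Jacobian, used to cross-check the analytic release against
  an MBAR route over spring-scaled windows;
* the synthetic complex — a rigid 30-residue helical Cα/N/C scaffold with
  designated P1/P2/P3 and a 12-heavy-atom ring-plus-tail ligand placed in
  the strike zone (z offset 7 Å from P1, inside the [5.5, 14] Å window),
  with the complex handed over under a seeded random rigid transform that
  the alignment stage must undo. Strike-zone defaults (l1_x = l1_y = 0,
  l1_range = 2.5, l1_z = 5.5, l1_zm = 14, min_adis = 3, max_adis = 7 Å)
  were chosen once to satisfy the construction's own constraints
  (l1_z > 5 Å so N1 fits between P1 and L1).

What the synthetic sources do *not* emulate: correlated samples (MD time
series), anharmonicity and multimodality of real restraint coordinates,
soft-core λ dependence, and finite-box electrostatics. Passing tests
therefore demonstrate the correctness of the statistics and geometry, not
the accuracy of any force field; headline ΔG values of real systems
require microsecond-scale GPU sampling and are out of scope here, with
per-window samples from such simulations consumable through the TSV
interface.

## Numerical and design choices

* Window schedules default to the attach percentages
  0, 0.5, 1.0, 2.4, 5.5, 11.8, 24, 44.5, 100 — a geometric-ish ladder
  giving adjacent-window overlap for stiff restraints.
* The PDB reader/writer targets wwPDB v3.3 columns; altlocs other than
  blank/'A' are dropped with a logged warning; dummy particles are
  written as HETATM records with the reserved residue name `DUM`.
* Ligand-graph automorphisms for symmetry-aware RMSD are found by
  exhaustive element-labelled graph matching, size-capped; callers can
  always supply permutations directly. RMSD is computed without refitting
  (structures are assumed pre-aligned).
* The z-padding solver inverts the linear water-count model with a
  0.5-damped Newton iteration (bisection fallback), to ±0.5 waters;
  water packing densities (TIP3P 0.0329 Å⁻³ by default) are configurable
  inputs, not constants.
* Degenerate inputs fail loudly: collinear points in angles/dihedrals or
  superposition, empty structures, non-monotone schedules, non-positive
  release springs (divergent integrals), SDR with `f`/`w` components.
* Problem sizes in the test suite (2 000–50 000 samples per window,
  10–23 windows, 100-replicate coverage runs) are chosen so the full
  statistical battery runs in about a minute on one CPU while leaving
  every stochastic tolerance at its nominal 3σ meaning.

## Known limitations

No autocorrelation-based subsampling (samples are assumed independent, as
the synthetic sources guarantee); no bootstrapped covariance between
components; no flat-bottom or time-varying restraints; no soft-core
functional forms (those live in the MD engine; this package consumes its
per-window outputs); mmCIF, protonation and force-field parameterisation
are out of scope.
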