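# Methods

## The model

`topochrom` simulates a single interphase chromatin fibre as a confined
random multiblock copolymer driven out of equilibrium by
Topoisomerase-II (Topo-II) activity.

**Polymer.** The fibre is a chain of N beads of two species: A
(euchromatin) and B (heterochromatin), appearing in blocks of b beads
(default b = 4) whose order along the chain is a uniformly random
permutation. Composition is the *volume* fraction phi_A of A beads; for
the equal-bead monodisperse model this equals the number fraction, for
the bidisperse model (d_A = 46 nm, d_B = 61 nm) the bead counts are
chosen (in block multiples) so the volume composition is closest to the
target (the preset value 0.3544 gives N_A = 9916, N_B = 7748 at
N = 17664).

**Units.** Lengths are measured in l = d_ct/12 = 117.6 nm (d_ct the
chromatin-territory cavity diameter, set by packing 50.807 Mbp at the
density of a diploid genome in a 7 um nucleus), energies in
e = kB T = 4.28 pN nm at T = 310 K, and times in tau = eta l^3 / e =
0.57 ms with nucleoplasmic viscosity eta = 1.5 cP. Each bead holds
2.4203 kbp; close-packing of 22 nm nucleosomes (200 bp each) gives the
monodisperse bead diameter 50.5086 nm.

**Interactions** (energies in e, lengths in l):

- FENE bonds, h = -(k r0^2 / 2) ln(1 - r^2/r0^2), k = 22, r0 the sum of
  the two bead diameters.
- A truncated Gaussian pair potential h_vex = +/- eps_vex
  exp(-alpha_vex r^2) for r <= 1, repulsive (+) by default. The width
  alpha_vex is fixed by requiring the minimum of bond + repulsion to sit
  at the mean bead diameter; the constraint
  k rm^2/(1 - rm^2/r0^2) = 2 eps alpha rm^2 exp(-alpha rm^2) has two
  roots and the larger (steeper Gaussian) is used — for the monodisperse
  parameters (eps = 8) it evaluates to 7.959, matching the tabulated
  7.9585. The bidisperse per-pair constants are stored as tabulated;
  re-deriving them from the constraint reproduces them only to ~1–2%,
  so the tables are treated as ground truth and the solver is validated
  on the monodisperse row.
- Heterochromatin affinity between B beads,
  h_HC = -eps_HC r^2 exp[-alpha_HC (c - r)^2] for r <= 1 with
  c = d_B - 1/(alpha_HC d_B) and alpha_HC = 100, which places the
  minimum exactly at r = d_B so the bead-sizing criterion is untouched.
- Wall confinement modelled as the interaction of a star polymer
  (functionality s = 2, corona radius Rs = 0.65 d/2, screening
  kappa = 2/d) with a flat wall, p = 4. The constant gamma in the
  potential is fixed to
  gamma = sqrt(pi) erfc(kRs) exp(k^2 Rs^2) / [kRs (1 + 2 k^2 Rs^2)],
  the unique choice that makes the two branches join with a continuous
  first derivative at Rs (verified analytically and in tests). In slab
  geometry both walls contribute and the two in-plane axes are periodic.

Gaussian and affinity potentials are truncated (not shifted) at the
cutoff 1 l; the residual jump is the truncated tail
(eps exp(-alpha) < 3e-3 e) and is asserted in tests.

**Dynamics.** Overdamped Langevin (Brownian) dynamics with per-bead
Stokes friction gamma_i = 3 pi eta d_i, integrated by Euler–Maruyama at
dt = 1e-4 tau. A run is an annealing span (discarded; checked against
the criterion that the rms bead displacement exceed the cavity radius)
followed by a production span from which snapshots are stored.

**Topo-II kinetics.** A proximal AA pair (separation <= 1 l, not
adjacent along the chain by default) is caught by an implicit enzyme at
Poisson rate lambda_ra; the caught pair's steric repulsion flips to
attraction (locked N-gate), advances to a no-interaction state (strand
passage window) at lambda_an = 16.7/tau, and is released back to
repulsion at lambda_nr = 500/tau. Mean dwells are 1/lambda_an = 0.0599
tau and 1/lambda_nr = 0.0020 tau; the enzymatic activity is
Lambda = lambda_ra (1/lambda_an + 1/lambda_nr), so lambda_ra = 10 and
0.5 per tau give Lambda = 0.6188 and 0.0309. Transitions use the exact
per-step probability 1 - exp(-rate dt). A bound pair separated beyond
1 l pauses its clock indefinitely and resumes on re-approach.

Kinetics are **pair-based**: every eligible AA pair undergoes the cycle
independently, so at Lambda = 0.6188 roughly 38% of in-range AA contacts
are in a non-repulsive state at any instant. An alternative
interpretation — at most one bound pair per bead ("exclusive" binding,
as if a single enzyme clamps both segments and saturates them — is
available behind the `exclusive_binding` flag. It is not the default
because it caps the perturbation at one of the ~50 in-range A
neighbours per bead (~2% of contacts) and, in our diagnostics, produces
no microphase separation at any activity, which is inconsistent with
the model's documented behaviour; pair-based kinetics reproduce it.

**Variants.** RANR is the full three-state cycle; RAR removes the
no-interaction state (attraction exits directly at lambda_an); RNR
removes the attraction state (capture enters no-interaction, released
at lambda_nr). PHANTOM permanently disables AA steric repulsion (the
equilibrium self-avoiding/phantom mixture); NONTRANSIENT replaces the
kinetics by a static AA Gaussian whose amplitude is the cycle-time
weighted average [(1/lambda_ra)(+eps) + (1/lambda_an)(-eps)] / (cycle
time) — one reading of a "non-transient effective attraction comparable
to" a given activity; PASSIVE has no activity.

## Numerical choices

- **Initial conformation**: a constructive "equilibrated ideal chain" —
  bond lengths drawn from the exact FENE Boltzmann density
  r^2 exp(-h_spring), isotropic directions, steps resampled if they
  come within 0.1 l of the wall. This is exact for an ideal chain and
  cheaper and better defined than pre-running a phantom simulation.
- **Soft start**: the first 0.5 tau of annealing run at dt/10 so the
  steric overlaps of the fresh ideal-chain configuration relax without
  kicking a bead through the thin repulsive wall layer.
- **Near-overstretch sub-stepping**: under strong activity a bond is
  occasionally pulled deep into the FENE divergence where one Euler
  step of noise could jump past r0. A proposed step carrying any bond
  beyond 0.98 r0 is discarded and re-integrated as ten dt/10 sub-steps
  with recomputed forces. The trigger lives in the far tail of the
  bond-length distribution, so the amortised cost and the statistical
  effect are negligible; a bond reaching r0 regardless is a fatal
  error, as is any bead reaching the wall (no silent reflection).
- **Neighbour search**: linked-cell build of a Verlet pair list with
  skin 0.3 l, rebuilt when any bead has moved half the skin. Gaussian
  factors use a 16385-point exp(-u) lookup table (linear interpolation,
  absolute error < 1e-6); the force cross-check against the analytic
  reference is tested at this accuracy.
- **Determinism**: all randomness derives from the protocol seed via
  named seed streams (soft-start, annealing, production); reruns are
  bitwise identical, and a checkpoint (positions + bound-pair registry +
  segment seed) restarts bitwise reproducibly.

## Analysis

- The cavity is partitioned into cubic cells of edge 1 l. Each cell's
  accessible-volume weight v is the fraction of a fixed scrambled Sobol
  point set falling inside the geometry (deterministic; total volume
  reproduced to 0.5%).
- Per cell, delta_phi = (nA VA - nB VB)/(nA VA + nB VB); empty cells are
  undefined and excluded with weight renormalisation. The distribution
  P(delta_phi) is v-weighted, normalised per snapshot, then averaged;
  the Binder cumulant 1 - <x^4>/3<x^2>^2 and the moment coefficient of
  skewness are computed from the raw weighted samples (bin-count
  independent; 41 bins on [-1, 1] for display only).
- Local nematic order: bonds between consecutive same-species beads are
  unit-normalised, assigned to the cell of the bond midpoint, and
  Q = <(3 u u^T - I)/2> per cell is diagonalised; S is the eigenvalue of
  largest magnitude (+1 aligned, -1/2 planar-isotropic). The scalar
  mean excludes cells whose centre lies within 1 l of the wall, where
  confinement itself aligns bonds.
- Heterochromatin foci: single-linkage clustering of B beads at cutoff
  d_B; clusters of at least 2b members are foci. Per focus the gyration
  tensor in the centre-of-mass frame gives Rg, the relative shape
  anisotropy kappa^2 = (3/2) sum(lam^4)/ (sum lam^2)^2 - 1/2 (0 sphere,
  1 line), and the mean member radial coordinate.
- Surface localisation: number fraction of B in the outermost shell of
  width 1 l divided by the global B fraction.
- Cross-model density correlation: per-cell A density (counts divided
  by accessible cell volume), Pearson-correlated between snapshots
  paired by production-time index and averaged; the normalisation is
  symmetric in the two models' standard deviations.

## Mean-field model

The lattice theory of a self-avoiding (B) / phantom (A') mixture with
doublet formation is implemented exactly as the free energy
f = mixing entropy + doublet entropy + f_int with
f_int = eps [c Phi^2 - 2 c Phi + c + 1/2], c(alpha) = -alpha^2 + alpha
- 1/2. The pair-counting convention (like pairs weighted 1/2) is the
unique one under which the stated pair energies reproduce the closed
form, and the identity is asserted to 1e-12. alpha*(Phi, eps) solves
2 ln(alpha/(1-2alpha)) + eps (1-Phi)(1-2alpha) = 0 by bracketed root
finding (grid fallback); f* curvature uses Richardson-refined central
differences, and the convex-to-concave transition is located by
bisection over eps. No binodal/common-tangent construction is
attempted.

## Reduced-scale phenomenology

Full-scale runs (N = 20992, 2 x 2010 tau) are available as presets but
are cluster-scale jobs. The packaged acceptance checks run a reduced
preset chosen to keep the full test suite on a single CPU within
minutes: monodisperse beads, b = 4, phi_A = 0.5, cavity diameter
12 l (N/20992)^(1/3) (the full-scale bead density), dt = 1e-4 tau,
3-5 tau of annealing plus 5-7 tau of production. Most variants use
N = 768 (cavity 3.98 l); the full three-state active run uses N = 1536
(cavity 5.02 l, 27 interior grid cells instead of 8) because the
nematic statistics of the B phase need more interior volume. At this
scale the checks are sign/shape checks — bimodality of P(delta_phi),
the sign of the mean nematic order of AA and BB bonds, and the variant
fingerprint (RANR/RAR negative S_AA, RNR near zero, PHANTOM not
significantly negative) — not value matches; the published production
values (e.g. S_AA = -0.0726, S_BB = 0.3060) require the full-scale
system, and the weakest signature (the positive radial order of BB
bonds under activity) sits at the edge of resolution at the reduced
scale.

## What the synthetic fixtures do and do not show

The fixture generators (uniform mixtures, sharp two-phase spheres,
tangent-bond shells, planar bond sets, line/ball clusters, Gaussian
fields) have closed-form signatures and validate the analysis
machinery, not the polymer physics: passing them shows the estimators
are correct, while the phenomenology of real chromatin (finite-width
interfaces, chain connectivity correlations, excluded-volume
structure) is exercised only by the reduced simulations above.

## Known limitations

- No hydrodynamic interactions, bending stiffness, or explicit diffusing
  enzymes; rates are uniform across the cavity.
- Euler–Maruyama at dt = 1e-4 tau carries O(dt) sampling bias
  (quantified in the dimer test as invisible at KS n = 1000).
- The reduced test scale has few interior grid cells, so nematic
  means carry sampling errors of order 0.01–0.02; variant
  discrimination at this scale is statistical, not exact.
- The cross-correlation and RDF-composition operations are exercised on
  synthetic inputs only; no experimental image data ships with the
  package.
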