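# Methods

`exopath` models, at pseudo-atomic scale, how a monosaccharide product
leaves a deep pocket-shaped glycosidase active site, and the measurements
that surround that question: binding free energies from equilibrium
constants, competitive-inhibition and SPR fits, sugar ring-puckering
analysis, and free-energy reconstruction by well-tempered metadynamics.
This note records the models, their assumptions, the defaults, and what the
synthetic test systems do and do not establish.

## Structural model and energy function

Structures are ordered heavy-atom lists with per-atom van der Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80 Å; pseudo-beads 1.70 Å). PDB input keeps
the highest-occupancy alternate conformer (ties: first in file) and drops
hydrogens, because all downstream scoring is heavy-atom. Ligand placement
is a rigid-body pose (unit quaternion + translation) about the ligand
centroid.

The interaction energy is a 12-6 Lennard-Jones sum over receptor-ligand
pairs within a 12 Å cutoff, with the pair minimum placed at the radii sum,
plus a directionless donor-acceptor well: −(polar strength) × g(r) with
g = 1 below 3.0 Å, switching smoothly to 0 at 3.5 Å. Two deliberate
choices:

* **ε = 0.02 kcal/mol per pair.** A deep pocket surrounds the ligand with
  hundreds of wall beads; at a conventional ε ≈ 0.1 their summed r⁻⁶ tails
  add to ~−14 kcal/mol, an artificial ~10 kT desolvation barrier that traps
  any ligand inside regardless of geometry. Keeping the dispersive term
  weak leaves sterics intact (the r⁻¹² wall towers over kT at any ε here)
  and lets the designed polar sites set the egress thermodynamics.
* **A pair "clashes"** when its distance is below 0.7 × (sum of radii); the
  factor is exposed in the parameters.

Pose minimisation is steepest descent with backtracking on the six
rigid-body degrees of freedom (plus gate torsions on request), with central
finite-difference gradients — adequate for the tiny DOF counts involved.

## Synthetic pocket

The toy receptor encodes the features that make product egress from a
pocket-shaped exo-hydrolase non-trivial:

* a ~13 Å-deep cylindrical channel (radius 5 Å, bead lattice 1.7 Å) with a
  polar binding well
  at the floor — the −1 subsite analogue;
* three 3-bead gate side chains at 60% of the channel height whose tips
  close the lumen to a 1.4 Å aperture — the toll-like barrier analogue of
  an Arg/Asp/Glu triad; each gate has one torsion that swings its chain
  outward and upward, clearing the lumen;
* a lateral alcove behind a hole in the wall above the gate plane, carrying
  an attractive polar site (default depth 3.6 kcal/mol = 3 kT) placed just
  inside the mouth, within hydrogen-bond range of channel-side poses — the
  transient lateral cavity analogue;
* a wall built as a *thick two-layer shell split into two halves* joined
  only at the floor, the two seams kept narrow enough (≈3.5 Å bead gap)
  that squeezing through one sterically costs tens of kcal/mol while the
  elastic network still treats the halves as separate domains. Each half is
  elastically rigid, so the softest elastic
  normal mode of the assembly is a clamshell opening of the two halves —
  a two-domain, cork-like collective motion.

Construction is certified at build time by an exhaustive pose-grid scan
(0.5 Å translations, a spread of orientations): the ligand sits clash-free
in the well; no clash-free grid path connects the well to the exit on rigid
coordinates; and a clash-free corridor exists once the gate torsions
retract the side chains. The "blocked" verdict uses the liberal notion that
a position is free if *any* sampled orientation is free, which
over-approximates reachability and therefore makes blockage a strong
certificate; the "open" verdict uses the stricter fixed-orientation flood
fill.

The ligand is a six-bead pyranose-ring analogue (O5, C1–C5, ring radius
1.34 Å, Cremer-Pople amplitude Q = 0.55 Å in a named conformer) with an
exocyclic C6 bead and a C4-OH marker bead used by the migration termination
criterion. The gate aperture (1.4 Å) is far narrower than the ligand's
circumscribed radius (~2.3 Å).

**What the toy does not emulate:** atomistic side-chain chemistry, solvent,
electrostatics, the real enzyme's dimensions or residue identities.
Passing tests show that the *algorithms* behave as claimed on a system with
the stated topology (deep well, closable barrier, lateral site, collective
opening), not that they reproduce any particular protein.

## Elastic network modes

Standard anisotropic network model: nodes connected by springs of constant
γ within a cutoff; off-diagonal 3×3 super-elements −γ r̂ r̂ᵀ; diagonal
blocks close the row sums. Eigenpairs come from a dense symmetric solver;
modes with |λ| below 10⁻⁸ × λmax are the six rigid-body motions and are
excluded from the reported count. Nodes are one per residue (all beads of a
gate side chain ride their residue node rigidly — the block/cluster
variant; with single-bead residues it reduces exactly to the per-atom
model). Mode displacement scales the shape so the *largest node
displacement* equals the requested amplitude in Å; 2.2 Å along the lowest
non-rigid mode is the canonical "displaced backbone" used by the two-stage
analysis, with both signs tried since an eigenvector's sign is arbitrary.
For the toy pocket the ANM cutoff is 3.0 Å — the toy is an order of
magnitude smaller than a protein, and the cutoff is chosen on the same
footing relative to the bead spacing (1.7 Å) as a 15 Å cutoff is to Cα
spacing.

## Genetic exit-path search

A path candidate is a fixed-length chain of 16 waypoint poses, the first
pinned to the bound pose, consecutive translations bounded by 1.5 Å.
NSGA-II (binary tournament on rank and crowding distance, one-point
crossover over waypoint index, Gaussian mutation of pose components at 0.3
per gene) evolves two objectives: minimise the summed clash count and
maximise reach. Two implementation choices matter:

* **Selection uses the clash-free prefix reach** (the largest separation
  attained before the first clashing waypoint) as the second objective;
  this rewards candidates that actually thread constrictions rather than
  ones that overshoot while clashing. The returned front is recomputed
  under the reporting objectives (total clash, reach).
* **A memetic repair operator** re-orients (and nudges by ±0.35 Å) the
  first clashing waypoint against a small orientation library, applied to
  half the offspring. Narrow apertures require specific ring orientations
  that blind Gaussian mutation rarely samples.

Population 64 and 240 generations are the defaults, and the displaced-stage
search is restarted once per mode sign with a derived seed if it fails; at
that budget the search reliably finds the opened corridor on the displaced
receptor across seeds while never finding one on rigid coordinates (none exists — the
certification guarantees it, and the search cannot contradict a steric
fact). Initial probes are straight chains in a wide cone about the exit
direction, so off-axis corridors are explored; seeding cannot affect the
rigid verdict for the same reason.

## Metropolis Monte-Carlo migration

Each step: random ligand translation (uniform in a 1 Å ball) and rotation
(uniform axis, ≤20°); a backbone displacement along one of the six lowest
modes, amplitude uniform in ±0.5 Å; a gate-torsion trial where each gate
keeps the best of five random angles in [0°, 100°] by its gate-ligand
energy (gates feel the ligand pressing and yield — the side-chain
adjustment step); optional minimisation; Metropolis acceptance at kT = 1.2
kcal/mol (acceptance ≈ 0.5 on the default toy). A trajectory ends when both
the ring-centroid and marker-bead separations exceed 15 Å, or at 30 000
steps.

The energy-vs-separation profile bins accepted states in 0.5 Å separation
bins. Dwell (transient-site) detection flags bins whose *10th-percentile*
energy is a local minimum of ≥0.75 kcal/mol topographic prominence with a
visit count above the neighbourhood median. The low quantile, not the bin
mean, carries the signal: the attractive site is off-axis, and a separation
bin mixes its visits with same-separation in-channel states that dilute a
mean beyond recognition. A single off-path site also smears over several
separation bins (a shell at fixed radius spans a range of separations),
which is why prominence-based peak detection replaces naive
neighbour-comparison.

With the default cavity well (3 kT) the profile shows a flagged dwell
between the barrier and the exit and trajectory counts pile up there; with
the well removed, no bin in that window is flagged. With mobile gates
essentially all of 20 seeds exit; with gates frozen and mode displacement
off, none do — the migration engine reproduces the blocked/open dichotomy
independently of the genetic search.

## Ring puckering and conformer classification

Cremer-Pople coordinates follow the standard construction (centroid
translation, mean plane from the two Fourier sums, out-of-plane
projections, m = 2 component and alternating sum). For the ring ordered
O5, C1…C5 the plane normal is oriented so that θ = 0 is the ⁴C₁ chair.
The 38 canonical IUPAC conformers are *generated*, not tabulated: each
ideal out-of-plane pattern (alternating chair, opposite-pair boat,
1,3-pair skew-boat, single-atom envelope, adjacent-pair half-chair) is run
through the same Cremer-Pople code to place its (θ, φ) vertex, so the
classifier, the ligand generator and the analysis code cannot disagree by
convention. Classification is nearest-vertex by great-circle distance;
amplitudes below the planar tolerance report "planar". The (qx, qy)
collective variables are the Cartesian equatorial components
(Q sinθ cosφ, Q sinθ sinφ); qz keeps the chair poles distinguished.

## Well-tempered metadynamics

The engine is a classical overdamped-Langevin walker on an analytic 2-D
potential — deliberately so: the contract is the bias algorithm, validated
against quadrature, not any electronic-structure energetics. Gaussians of
initial height 1 kcal/mol and width 0.1 (CV units) are deposited every 200
steps with the well-tempered decay exp(−V_bias/((γ−1)kT)), γ = 10,
kT = 0.596 kcal/mol (300 K). The bias and its gradient are accumulated
analytically on a 101² grid and interpolated at the walker; boundaries are
reflective; the default budget is 8×10⁵ steps (dt = 2×10⁻³).

The free-energy estimate is F = −γ/(γ−1) × V_bias, time-averaged over the
final 20% of depositions and min-shifted. Basin ΔF is the
Boltzmann-integrated difference between the two half-planes (far smoother
than tracking grid minima); the convergence diagnostic is the systematic
trend of that series across the tail (difference of half-means), which is
below 0.2 kcal/mol at the default budget on the reference double well.
Accuracy at the stated hill parameters: basin ΔF within ~0.1 kcal/mol of
the quadrature oracle on the asymmetric double well, barriers within
~0.5 kcal/mol of a ridge-scan oracle, and pointwise agreement at
hill-width resolution inside sampled wells (raw grids carry deposition
ripples of a few tenths of kcal/mol — an intrinsic property of 1 kcal
hills of width 0.1, visible in any metadynamics reconstruction at these
settings). Barriers between basins are read from the grid by bottleneck
(minimax) Dijkstra: the reported barrier is the maximum energy along the
path that minimises that maximum.

## Binding kinetics and affinities

Competitive inhibition follows v = Vmax·S/(KM(1 + I/Ki) + S). The
simulated assay mirrors the published design: six substrate concentrations
spanning 0.8–6.6 mM, six inhibitor concentrations spanning 0.4–3 × Ki, in
duplicate, with multiplicative Gaussian noise (rate errors scale with
signal). Fitting is unweighted nonlinear least squares in log-parameter
space; the Dixon diagnostic fits 1/v against I per substrate level and
reports the mean pairwise intersection abscissa, which equals −Ki exactly
for the competitive model. SPR steady-state affinities use the 1:1
isotherm Req = Rmax·C/(KD + C) on a geometric 0.1–10 × KD dilution series
with one duplicated concentration.

Free energies convert by ΔG = RT ln K (K the dissociation constant in M,
R = 8.314 J mol⁻¹ K⁻¹) — i.e. −RT ln Ka with the association constant —
negative for sub-molar K. SPR-derived rows convert at 298.15 K (25 °C
measurements) and inhibition-derived rows at 303.15 K (30 °C assays); this
pairing reproduces the published HvExoI panel to the printed 0.1 kJ/mol.
Fold-ratios are reported to two significant figures.

## Problem sizes

Default budgets — GA population 64 × 160 generations, 20 migration seeds ×
30 000 steps, 8×10⁵ metadynamics steps, 100 simulated assays per recovery
study — are chosen so the full analysis runs on a single CPU core in
minutes while leaving the stochastic checks comfortable margins.

## Known limitations

* The energy model has no electrostatics, solvation or directional
  hydrogen bonds; "binding energy" profiles are meaningful in shape
  (minima locations, barriers in units of kT), not in absolute value.
* Absolute elastic-mode frequencies depend on the arbitrary γ and are not
  comparable to spectroscopic values; only mode ordering and shape are
  contractual.
* Electronic-structure conformational free energies (the chair/skew-boat
  stabilisation energies of the bound sugar), docking scores and
  crystallographic refinement statistics are out of scope and not
  desk-reproducible with this package; the corresponding behaviours are
  covered qualitatively by the property suites on analytic potentials and
  synthetic pockets.
* The pose-grid certification is exhaustive at 0.5 Å / a finite
  orientation set; it bounds what rigid search can find at that
  resolution, not continuum feasibility.
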