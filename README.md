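# exopath

Ligand egress pathways, sugar ring puckering and binding thermodynamics for
pocket-shaped exo-hydrolases, at desk scale.

Exo-acting glycoside hydrolases with deep pocket-shaped active sites face a
topological puzzle: the product of one catalytic round sits at the bottom of
a ~13 Å pocket while the next substrate binds above it, so how does the
product get out? For the barley β-d-glucan glucohydrolase family this was
resolved computationally — the glucose product cannot pass the side-chain
constriction of the catalytic region on rigid coordinates, but a collective
backbone motion opens a transient lateral route. `exopath` re-implements
that style of analysis as a self-contained Python library, testable end to
end on synthetic systems:

* **structures & energetics** — heavy-atom PDB I/O, vdW clash counting, a
  Lennard-Jones + polar-well interaction model, rigid-body pose
  minimisation;
* **elastic modes** — anisotropic network model (springs of constant γ
  within a cutoff; Hessian super-elements −γ r̂ r̂ᵀ), rigid-mode
  separation, and mode-directed displacement with a max-node amplitude
  convention;
* **exit-path search** — NSGA-II over waypoint chains minimising clash
  counts while maximising the separation reached, producing
  clash-vs-separation profiles;
* **migration** — Metropolis Monte-Carlo ligand migration (random pose
  perturbations, backbone mode moves, side-chain gate trials), terminated
  when the ligand is >15 Å from its bound position, with
  binding-energy-vs-separation profiles and transient-site (dwell)
  detection;
* **ring puckering** — Cremer-Pople (Q, θ, φ) coordinates, classification
  onto the 38 canonical IUPAC pyranose conformers, and a well-tempered
  metadynamics engine (Gaussian hills, height decay exp(−V_b/((γ−1)kT)),
  estimator F = −γ/(γ−1)·V_b) validated against quadrature on analytic
  surfaces;
* **kinetics** — competitive inhibition v = Vmax·S/(KM(1+I/Ki)+S) with
  Dixon diagnostics, SPR steady-state 1:1 fits Req = Rmax·C/(KD+C), and
  ΔG = −RT ln Ka conversions;
* **synthetic systems** — a certified toy pocket (binding well, three-gate
  toll barrier, lateral cavity, clamshell elastic domains), ring ligands in
  named conformers, and simulated assay datasets, so every stage runs
  without downloads.

## Worked example

```python
from exopath import (PipelineConfig, run_egress_analysis, table1_report)

# binding free energies of the published HvExoI ligand panel
print(table1_report().round({"delta_G_kJ_mol": 1}).to_string(index=False))

# the two-stage egress analysis on the certified synthetic pocket
report = run_egress_analysis(PipelineConfig(seed=7, n_migration_seeds=5,
                                            run_frozen_control=False))
print(report.rigid_exit_found, report.mode_displaced_exit_found,
      report.mc_exit_fraction)
```

The affinity table prints, among others, `Glc ... -21.7` and
`G2SG-OMe ... -15.1` (kJ/mol; dissociation constants converted at the
measurement temperatures, 25 °C for SPR rows and 30 °C for inhibition
rows), with the fold-ratio column showing the ~320-fold affinity gap
between the two thio-analogues. The egress report prints
`False True 1.0`: no clash-free exit exists on rigid coordinates, a 2.2 Å
displacement along the lowest elastic mode opens one, and all five
Monte-Carlo migration seeds leave the pocket once the gate side chains are
allowed to move.

Short narrative scripts in `examples/` exercise each capability one at a
time (affinity table, ring conformers, elastic modes, path search,
migration profile, metadynamics double well, kinetics fits).

A thin CLI wraps the same calls:

```bash
exopath kinetics table1          # the affinity panel with ΔG
exopath --seed 7 --out out run   # full pipeline, JSON report in out/
```

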