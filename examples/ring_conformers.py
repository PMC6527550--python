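"""Cremer-Pople coordinates of ideal pyranose-ring conformers.

Builds ring-bead ligands in named canonical conformations, computes their
puckering coordinates and classifies them back; the chair sits at the
theta = 0 pole, the skew-boat and boat on the equator.
"""

from exopath import classify_conformer, cremer_pople, make_ring_ligand

for label in ("4C1", "1C4", "1S3", "B3O", "planar"):
    lig = make_ring_ligand(label)
    pc = cremer_pople(lig.ring_coords)
    print(f"{label:>7s}: Q = {pc.Q:.3f} Å, theta = {pc.theta:6.1f}°, "
          f"phi = {pc.phi:6.1f}°  ->  classified {classify_conformer(pc)}")
print("\nQ is the total puckering amplitude; theta/phi locate the conformer "
      "on the puckering sphere (0° = 4C1 chair, 90° = equatorial "
      "boats/skew-boats, 180° = 1C4).")
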