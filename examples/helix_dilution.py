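"""Hydrogen-bond dilution of an ideal alpha helix.

A 12-residue poly-alanine helix carries 8 backbone i -> i+4 hydrogen bonds.
Removing them from weakest to strongest fragments the rigid core: each
profile line shows the energy of the bond just broken and the per-residue
labels (l = largest rigid region, s = separately rigid, f = flexible).
"""

from flexsig import (analyze_rigidity, find_hbonds, make_helix_peptide)

helix = make_helix_peptide(12, with_hbonds=True)
print(f"backbone hydrogen bonds: {len(find_hbonds(helix))}")

analysis = analyze_rigidity(helix)
print(f"selected energy cutoff: {analysis.energy_cutoff:.2f} kcal/mol\n")
print(" energy   donor acceptor  labels        rigid%")
for step in analysis.profile.steps:
    donor = step.removed_donor if step.removed_donor is not None else "-"
    acc = step.removed_acceptor if step.removed_acceptor is not None else "-"
    print(f"{step.energy:7.2f}  {donor!s:>5} {acc!s:>8}  "
          f"{step.label_string}  {100 * step.fraction_rigid:5.1f}")

# The topmost line is the fully bonded helix (mostly one rigid cluster);
# by the last line every hydrogen bond is broken and the backbone is a
# flexible chain (all residues f).
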