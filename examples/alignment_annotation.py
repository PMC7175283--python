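"""Residue-correspondence tables from a pairwise structural alignment.

Builds two small peptides, aligns them (here via a hand-written aligned
FASTA standing in for Dali output), marks key residues by distance to a
ligand atom, and renders the annotated alignment plus the aligned
B-column value table.
"""

import numpy as np

from flexsig import (AnnotationSpec, key_residues, parse_dali_alignment,
                     render_bat, render_brat)
from flexsig.structure import write_pdb_with_values
from flexsig.synthetic import make_helix_peptide

query = make_helix_peptide(8)
query.source_id = "helix8"
subject = make_helix_peptide(6)
subject.source_id = "helix6"

# helix6 matches the first six residues of helix8 (poly-alanine)
aln = parse_dali_alignment(">helix8\nAAAAAAAA\n>helix6\nAAAAAA--\n")

spec = AnnotationSpec(mode="ligand_distance", distance_cutoff=6.0,
                      ligand_atoms=query.residues[2].atom("CA").xyz[None, :])
key = {"helix8": key_residues(query, spec)}
print("key residues within 6 A of the probe atom:", sorted(key["helix8"]))

print("\nannotated alignment (CSV, * marks key residues):")
print(render_brat(aln, query, subject, key=key))

# carry a per-residue value in the B column and align it
for res, value in zip(query.residues, np.linspace(0, 70, 8)):
    for atom in res.atoms:
        object.__setattr__(atom, "bvalue", float(value))
df = render_bat(query, [(subject, aln)])
print("aligned value table (three rows per structure):")
print(df.to_string(index=False))
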