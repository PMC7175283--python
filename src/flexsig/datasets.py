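"""Reference dataset metadata: the 27 ligand-bound class A GPCR structures.

A transcription of the curated activity table (18 inhibitor-bound inactive
and 9 activator-bound active receptors, one chain each, all solved at
2.9 A resolution or better).  Reproducing the full structural analysis
requires downloading and protonating these entries; the table itself drives
the class-balance arithmetic and serves as the label source for users who
supply the coordinate files.
"""

from __future__ import annotations

import pandas as pd

#: (pdb_id, activity, chain, resolution_A, description)
GPCR_ACTIVITY_TABLE: tuple[tuple[str, int, str, float, str], ...] = (
    ("2VT4", 0, "A", 2.7, "Beta1 adrenergic receptor"),
    ("3ODU", 0, "A", 2.5, "CXCR4 chemokine receptor"),
    ("3V2Y", 0, "A", 2.8, "Sphingosine 1-phosphate receptor"),
    ("3VW7", 0, "A", 2.2, "Protease-activated receptor 1"),
    ("3EML", 0, "A", 2.6, "A2A adenosine receptor"),
    ("2RH1", 0, "A", 2.4, "Beta2 adrenergic receptor"),
    ("1GZM", 0, "A", 2.6, "Bovine rhodopsin"),
    ("4DKL", 0, "A", 2.8, "Mu-opioid receptor"),
    ("3PBL", 0, "A", 2.9, "Dopamine D3 receptor"),
    ("4DJH", 0, "A", 2.9, "Kappa opioid receptor"),
    ("4MBS", 0, "A", 2.7, "CCR5 chemokine receptor"),
    ("4S0V", 0, "A", 2.5, "OX2 orexin receptor"),
    ("4U15", 0, "A", 2.8, "M3 muscarinic receptor"),
    ("4XNW", 0, "A", 2.7, "Purinergic receptor P2Y1"),
    ("4YAY", 0, "A", 2.9, "Angiotensin receptor"),
    ("4Z35", 0, "A", 2.9, "Lysophosphatidic acid receptor 1"),
    ("5CXV", 0, "A", 2.7, "M1 muscarinic acetylcholine receptor"),
    ("5T1A", 0, "A", 2.8, "CC chemokine receptor 2"),
    ("3QAK", 1, "A", 2.7, "A2A adenosine receptor"),
    ("4IAR", 1, "A", 2.7, "5-HT1b receptor"),
    ("4PXZ", 1, "A", 2.5, "Purinergic receptor P2Y12"),
    ("2YDV", 1, "A", 2.6, "A2A receptor"),
    ("3PQR", 1, "A", 2.8, "Metarhodopsin II"),
    ("5C1M", 1, "A", 2.1, "Mu-opioid receptor"),
    ("4XES", 1, "A", 2.6, "Neurotensin receptor"),
    ("5GLH", 1, "A", 2.8, "Endothelin receptor type B"),
    ("5TVN", 1, "A", 2.9, "5-HT2b receptor"),
)

RESOLUTION_CUTOFF = 2.9  # A


def gpcr_activity_table() -> pd.DataFrame:
    """The activity-label table as a DataFrame indexed by PDB id."""
    df = pd.DataFrame(GPCR_ACTIVITY_TABLE,
                      columns=["pdb_id", "activity", "chain", "resolution",
                               "description"])
    return df.set_index("pdb_id")


def filter_by_resolution(df: pd.DataFrame,
                         max_resolution: float = RESOLUTION_CUTOFF) -> pd.DataFrame:
    """Keep structures solved at or better than the resolution cutoff."""
    return df[df["resolution"] <= max_resolution]
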