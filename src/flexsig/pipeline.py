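"""End-to-end per-structure analysis: structure -> interactions -> dilution
-> energy selection -> residue labels -> segment states."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import SegmentScheme, SegmentStateVector, segment_states
from .interactions import HBondParams, find_all_interactions
from .rigidity import (AnalysisConfig, ConstraintNetwork, DilutionProfile,
                       RigidDecomposition, build_constraint_network,
                       compute_flexibility_index, hydrogen_bond_dilution,
                       label_residues, run_pebble_game, select_energy_cutoff)
from .structure import ProteinStructure

logger = logging.getLogger(__name__)


@dataclass
class RigidityAnalysis:
    """Everything the dilution analysis produces for one structure."""

    structure: ProteinStructure
    profile: DilutionProfile
    energy_cutoff: float
    network: ConstraintNetwork
    decomposition: RigidDecomposition
    residue_labels: list[str]              # per residue, in structure order
    flexibility_index: np.ndarray          # per residue, 0-100

    def labels_by_resnum(self) -> dict[int, str]:
        return {res.resnum: lab
                for res, lab in zip(self.structure.residues,
                                    self.residue_labels)}


def analyze_rigidity(s: ProteinStructure,
                     config: AnalysisConfig | None = None,
                     params: HBondParams | None = None) -> RigidityAnalysis:
    """Dilute the hydrogen-bond network, select the analysis energy, and
    decompose the structure at that energy."""
    config = config or AnalysisConfig()
    params = params or HBondParams()
    interactions = find_all_interactions(s, params)
    profile = hydrogen_bond_dilution(s, interactions, config)
    cutoff = select_energy_cutoff(profile, config)
    net = build_constraint_network(interactions, cutoff)
    decomp = run_pebble_game(net)
    labels = label_residues(decomp, s, config)
    flex = compute_flexibility_index(decomp, net, s)
    logger.info("%s: energy cutoff %.2f kcal/mol, %d dilution steps, "
                "%.0f%% residues rigid", s.source_id, cutoff,
                len(profile.steps),
                100 * sum(l != "flexible" for l in labels) / max(len(labels), 1))
    return RigidityAnalysis(structure=s, profile=profile, energy_cutoff=cutoff,
                            network=net, decomposition=decomp,
                            residue_labels=labels, flexibility_index=flex)


def flexibility_states(s: ProteinStructure, scheme: SegmentScheme,
                       activity: int,
                       config: AnalysisConfig | None = None,
                       params: HBondParams | None = None) -> SegmentStateVector:
    """Segment-level f/s/l state vector for one labelled structure."""
    analysis = analyze_rigidity(s, config, params)
    return segment_states(analysis.labels_by_resnum(), scheme,
                          s.source_id, activity)
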