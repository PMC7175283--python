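"""Synthetic inputs with known ground truth.

Three generator families drive testing and calibration of the pipeline:
body-bar networks whose generic rigidity is known analytically (chains,
rings, cliques) or checkable against a rigidity-matrix rank oracle (random
graphs); ideal-geometry poly-alanine peptides — an alpha helix whose
``i -> i+4`` backbone hydrogen bonds are guaranteed by construction, or an
extended strand with none; and binary flexibility-feature matrices with
class-discriminative features planted at chosen prevalences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import (FEATURE_NAMES, N_FEATURES, SEGMENT_NAMES, STATES,
                       FeatureMatrix)
from .interactions import Kind
from .rigidity import ConstraintNetwork
from .structure import Atom, ProteinStructure, ResidueRef, place_amide_hydrogen

# ---------------------------------------------------------------------------
# Body-bar networks
# ---------------------------------------------------------------------------


def make_bodybar_network(kind: str, n: int, bars: int = 5,
                         seed: int = 0) -> ConstraintNetwork:
    """Deterministic body-bar test networks.

    ``chain``/``ring``/``clique`` use ``bars`` bars on every edge and have
    closed-form floppy-mode counts; ``random`` draws an Erdos-Renyi edge set
    with bar counts sampled from the policy {2, 5, 6}.
    """
    if n < 2:
        raise ValueError("need at least 2 bodies")
    rng = np.random.default_rng(seed)
    edges: dict[tuple[int, int], int] = {}
    if kind == "chain":
        for i in range(1, n):
            edges[(i, i + 1)] = bars
    elif kind == "ring":
        for i in range(1, n):
            edges[(i, i + 1)] = bars
        edges[(1, n)] = bars
    elif kind == "clique":
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                edges[(i, j)] = bars
    elif kind == "random":
        p_edge = 0.45
        choices = np.array([2, 5, 6])
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if rng.random() < p_edge:
                    edges[(i, j)] = int(rng.choice(choices))
        if not edges:  # never return an edgeless network
            edges[(1, 2)] = int(rng.choice(choices))
    else:
        raise ValueError(f"unknown network kind {kind!r}")
    return ConstraintNetwork(bodies=tuple(range(1, n + 1)), edges=edges,
                             kinds={e: Kind.COVALENT_ROTATABLE for e in edges})


# ---------------------------------------------------------------------------
# Ideal-geometry peptides
# ---------------------------------------------------------------------------

# bond lengths (A) and angles (degrees) for an ideal backbone
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_C_CA_CB = 120.8, 110.1

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -140.0, 135.0
OMEGA = 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement: position d bonded to c with the given
    internal coordinates (angle b-c-d, torsion a-b-c-d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_helix_peptide(n_res: int, with_hbonds: bool = True,
                       seed: int | None = None,
                       jitter: float = 0.0) -> ProteinStructure:
    """Poly-alanine peptide at canonical torsions with amide hydrogens.

    ``with_hbonds`` selects alpha-helical torsions (phi = -57, psi = -47),
    whose geometry guarantees ``n_res - 4`` backbone ``i -> i+4`` hydrogen
    bonds; otherwise an extended strand with none.  ``jitter`` adds
    zero-mean Gaussian noise (A) to the heavy-atom coordinates before the
    hydrogens are placed, producing distinct but still hydrogen-bonded
    fixtures from different seeds.
    """
    if n_res < 5:
        raise ValueError("need at least 5 residues")
    phi, psi = (HELIX_PHI, HELIX_PSI) if with_hbonds else (STRAND_PHI, STRAND_PSI)
    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([_B_N_CA, 0.0, 0.0])]
    a = math.radians(_A_N_CA_C)
    c_pos = [ca_pos[0] + _B_CA_C * np.array([-math.cos(a), math.sin(a), 0.0])]
    for i in range(1, n_res):
        n_i = _place(n_pos[-1], ca_pos[-1], c_pos[-1], _B_C_N, _A_CA_C_N, psi)
        ca_i = _place(ca_pos[-1], c_pos[-1], n_i, _B_N_CA, _A_C_N_CA, OMEGA)
        c_i = _place(c_pos[-1], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        n_pos.append(n_i)
        ca_pos.append(ca_i)
        c_pos.append(c_i)
    o_pos = [_place(n_pos[i], ca_pos[i], c_pos[i], _B_C_O, _A_CA_C_O, psi - 180.0)
             for i in range(n_res)]
    cb_pos = [_place(n_pos[i], c_pos[i], ca_pos[i], _B_CA_CB, _A_C_CA_CB, 122.55)
              for i in range(n_res)]

    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        for arr in (n_pos, ca_pos, c_pos, o_pos, cb_pos):
            for i in range(n_res):
                arr[i] = arr[i] + rng.normal(0.0, jitter, 3)

    residues: list[ResidueRef] = []
    serial = 0
    for i in range(n_res):
        atoms: list[Atom] = []

        def add(name: str, element: str, pos: np.ndarray) -> None:
            nonlocal serial
            serial += 1
            atoms.append(Atom(serial=serial, name=name, element=element,
                              coords=tuple(float(x) for x in pos)))

        add("N", "N", n_pos[i])
        if i > 0:  # amide hydrogen; the N-terminal nitrogen is left bare
            add("H", "H", place_amide_hydrogen(n_pos[i], c_pos[i - 1], ca_pos[i]))
        add("CA", "C", ca_pos[i])
        add("C", "C", c_pos[i])
        add("O", "O", o_pos[i])
        add("CB", "C", cb_pos[i])
        residues.append(ResidueRef(chain="A", resnum=i + 1, resname="ALA",
                                   atoms=atoms))
    tag = "helix" if with_hbonds else "strand"
    return ProteinStructure(residues=residues, source_id=f"{tag}{n_res}")


# ---------------------------------------------------------------------------
# Planted feature matrices
# ---------------------------------------------------------------------------

#: Default planted signature: the four ligand-proximal segments whose
#: flexibility states discriminate activation, at class-conditional
#: prevalences emulating the strongest observed profiles (inactive receptors
#: share a rigid scaffold through ECL1 and the extracellular thirds of
#: helices 3 and 5; active receptors decouple them).  All four separations
#: are >= 0.5.
DEFAULT_PLANTED: tuple[tuple[str, float, float], ...] = (
    ("ECL1l", 0.20, 0.85),
    ("H2.2s", 0.65, 0.00),
    ("H3.1f", 0.70, 0.05),
    ("H5.1l", 0.20, 0.85),
)

#: Background state distribution for non-planted segments: most segments sit
#: in the largest rigid region near the analysis energy, with occasional
#: separately-rigid or flexible assignments.
DEFAULT_BACKGROUND: dict[str, float] = {"f": 0.2, "s": 0.2, "l": 0.6}


@dataclass
class FeatureGenSpec:
    """Parameters of the planted-feature matrix generator."""

    n_active: int = 9
    n_inactive: int = 18
    planted: tuple[tuple[str, float, float], ...] = DEFAULT_PLANTED
    background: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("both classes need at least one structure")
        for name, fa, fi in self.planted:
            if name not in FEATURE_NAMES:
                raise ValueError(f"unknown planted feature {name!r}")
            if not (0 <= fa <= 1 and 0 <= fi <= 1):
                raise ValueError(f"planted frequencies for {name} outside [0,1]")
        if not math.isclose(sum(self.background.values()), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")


def _segment_distributions(spec: FeatureGenSpec
                           ) -> dict[str, dict[int, np.ndarray]]:
    """Per-segment categorical state distributions for each class."""
    planted_by_seg: dict[str, list[tuple[str, float, float]]] = {}
    for name, fa, fi in spec.planted:
        seg, st = name[:-1], name[-1]
        planted_by_seg.setdefault(seg, []).append((st, fa, fi))
    out: dict[str, dict[int, np.ndarray]] = {}
    for seg in SEGMENT_NAMES:
        per_class: dict[int, np.ndarray] = {}
        for cls, slot in ((1, 1), (0, 2)):
            fixed = {st: (fa if cls == 1 else fi)
                     for st, fa, fi in planted_by_seg.get(seg, [])}
            mass = sum(fixed.values())
            if mass > 1 + 1e-9:
                raise ValueError(
                    f"planted frequencies for segment {seg} (class {cls}) sum"
                    f" to {mass:.3f} > 1")
            free = [st for st in STATES if st not in fixed]
            bg_total = sum(spec.background[st] for st in free)
            probs = np.array([
                fixed.get(st, (1.0 - mass) * spec.background[st] / bg_total)
                for st in STATES])
            per_class[cls] = probs / probs.sum()
        out[seg] = per_class
    return out


def make_feature_dataset(spec: FeatureGenSpec | None = None) -> FeatureMatrix:
    """Sample a labelled one-hot feature matrix from the generator spec.

    Every structure draws one f/s/l state per segment from its
    class-conditional distribution, so each row carries exactly 29 set bits.
    """
    spec = spec or FeatureGenSpec()
    rng = np.random.default_rng(spec.seed)
    dists = _segment_distributions(spec)
    ids: list[str] = []
    labels: list[int] = []
    rows: list[np.ndarray] = []
    groups = [(0, spec.n_inactive, "inactive"), (1, spec.n_active, "active")]
    for cls, count, prefix in groups:
        for j in range(count):
            row = np.zeros(N_FEATURES, dtype=np.int8)
            for si, seg in enumerate(SEGMENT_NAMES):
                state = rng.choice(3, p=dists[seg][cls])
                row[si * 3 + state] = 1
            ids.append(f"{prefix}_{j + 1:02d}")
            labels.append(cls)
            rows.append(row)
    return FeatureMatrix(structure_ids=ids, data=np.vstack(rows),
                         labels=np.array(labels, dtype=np.int8))
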