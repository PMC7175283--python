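"""Detection of the interactions that form the molecular constraint network.

Four interaction kinds are produced: covalent bonds (labelled rotatable or
locked), hydrogen bonds carrying a Mayo-style energy, salt bridges with a
fixed strong energy, and hydrophobic tethers.  Together they are the input
to the body-bar rigidity analysis.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, ProteinStructure, ResidueRef

logger = logging.getLogger(__name__)


class Kind(str, Enum):
    COVALENT_ROTATABLE = "covalent_rotatable"
    COVALENT_LOCKED = "covalent_locked"
    HBOND = "hbond"
    SALT_BRIDGE = "salt_bridge"
    HYDROPHOBIC = "hydrophobic"


@dataclass(frozen=True, order=True)
class Interaction:
    """A typed edge between two atoms, identified by serial numbers."""

    atom_i: int
    atom_j: int
    kind: Kind
    energy: float = 0.0  # kcal/mol; < 0 for hbond/salt_bridge
    donor: int | None = None
    acceptor: int | None = None

    def __post_init__(self) -> None:
        if self.atom_i >= self.atom_j:
            raise ValueError("interaction endpoints must satisfy atom_i < atom_j")
        if self.kind in (Kind.HBOND, Kind.SALT_BRIDGE) and self.energy >= 0:
            raise ValueError(f"{self.kind.value} energy must be negative")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.atom_i, self.atom_j)


def _edge(i: int, j: int, kind: Kind, energy: float = 0.0,
          donor: int | None = None, acceptor: int | None = None) -> Interaction:
    a, b = (i, j) if i < j else (j, i)
    return Interaction(a, b, kind, energy, donor, acceptor)


@dataclass
class HBondParams:
    """Geometric and energetic hydrogen-bond parameters.

    The energy well is the Mayo-form potential used throughout the rigidity
    lineage: ``E = V0 * (5 (d0/d)^12 - 6 (d0/d)^10) * F`` with ``d`` the
    donor--acceptor distance and ``F = cos^2(theta_DHA)`` an angular
    attenuation in (0, 1].
    """

    V0: float = 8.0            # kcal/mol well depth
    d0: float = 2.8            # A equilibrium donor-acceptor distance
    d_DA_max: float = 3.6      # A donor-acceptor cutoff
    d_HA_max: float = 2.6      # A hydrogen-acceptor cutoff
    theta_min: float = 110.0   # degrees, minimum D-H...A angle
    salt_bridge_energy: float = -10.0  # kcal/mol, fixed

    def __post_init__(self) -> None:
        if self.V0 <= 0:
            raise ValueError("V0 must be positive")
        if not self.d0 < self.d_DA_max:
            raise ValueError("d0 must be below d_DA_max")
        if not 0 < self.theta_min < 180:
            raise ValueError("theta_min must lie in (0, 180)")

    def energy(self, d_DA: float, theta_DHA_deg: float) -> float:
        r = self.d0 / d_DA
        radial = self.V0 * (5.0 * r**12 - 6.0 * r**10)
        return radial * math.cos(math.radians(theta_DHA_deg)) ** 2


# ---------------------------------------------------------------------------
# Covalent bonding templates (heavy atoms).  Bonds absent from the template
# residue are simply skipped (e.g. truncated side chains).
# ---------------------------------------------------------------------------

_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

_SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

#: Intra-residue bonds frozen by partial double-bond character or ring
#: planarity (sp2-sp2): carbonyl, carboxylate, amide, guanidinium, aromatic
#: and imidazole rings.
_LOCKED_SIDECHAIN: dict[str, set[frozenset[str]]] = {
    "ARG": {frozenset(p) for p in [("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")]},
    "ASN": {frozenset(p) for p in [("CG", "OD1"), ("CG", "ND2")]},
    "ASP": {frozenset(p) for p in [("CG", "OD1"), ("CG", "OD2")]},
    "GLN": {frozenset(p) for p in [("CD", "OE1"), ("CD", "NE2")]},
    "GLU": {frozenset(p) for p in [("CD", "OE1"), ("CD", "OE2")]},
    "HIS": {frozenset(p) for p in [("CG", "ND1"), ("CG", "CD2"),
                                   ("ND1", "CE1"), ("CD2", "NE2"),
                                   ("CE1", "NE2")]},
    "PHE": {frozenset(p) for p in [("CG", "CD1"), ("CG", "CD2"),
                                   ("CD1", "CE1"), ("CD2", "CE2"),
                                   ("CE1", "CZ"), ("CE2", "CZ")]},
    "TRP": {frozenset(p) for p in [("CG", "CD1"), ("CG", "CD2"),
                                   ("CD1", "NE1"), ("NE1", "CE2"),
                                   ("CD2", "CE2"), ("CD2", "CE3"),
                                   ("CE2", "CZ2"), ("CE3", "CZ3"),
                                   ("CZ2", "CH2"), ("CZ3", "CH2")]},
    "TYR": {frozenset(p) for p in [("CG", "CD1"), ("CG", "CD2"),
                                   ("CD1", "CE1"), ("CD2", "CE2"),
                                   ("CE1", "CZ"), ("CE2", "CZ")]},
}

PEPTIDE_BOND_MAX = 1.7   # A, C(i)-N(i+1)
DISULFIDE_MAX = 2.5      # A, SG-SG
GENERIC_BOND_MAX = 1.9   # A, fallback for unknown residues
HYDROGEN_ATTACH_MAX = 1.5  # A, H to its parent heavy atom


def _intra_residue_bonds(res: ResidueRef) -> list[Interaction]:
    out: list[Interaction] = []
    if res.resname in _SIDECHAIN_BONDS:
        locked = _LOCKED_SIDECHAIN.get(res.resname, set())
        for a_name, b_name in _BACKBONE_BONDS + _SIDECHAIN_BONDS[res.resname]:
            a, b = res.atom(a_name), res.atom(b_name)
            if a is None or b is None:
                continue
            pair = frozenset((a_name, b_name))
            if pair in (frozenset(("C", "O")), frozenset(("C", "OXT"))):
                is_locked = True  # carbonyl / carboxylate terminus
            else:
                is_locked = pair in locked
            kind = Kind.COVALENT_LOCKED if is_locked else Kind.COVALENT_ROTATABLE
            out.append(_edge(a.serial, b.serial, kind))
    else:
        logger.warning("unknown residue %s %s%d: using generic distance bonding",
                       res.resname, res.chain, res.resnum)
        heavy = res.heavy_atoms
        for a, b in itertools.combinations(heavy, 2):
            if np.linalg.norm(a.xyz - b.xyz) < GENERIC_BOND_MAX:
                out.append(_edge(a.serial, b.serial, Kind.COVALENT_ROTATABLE))
    # Hydrogens: attach each to the nearest heavy atom; an X-H bond carries
    # no independent rotation (a point-like H has no orientation), so it is
    # locked.
    heavy = res.heavy_atoms
    for h in res.atoms:
        if not h.is_hydrogen:
            continue
        if not heavy:
            continue
        parent = min(heavy, key=lambda a: np.linalg.norm(a.xyz - h.xyz))
        if np.linalg.norm(parent.xyz - h.xyz) <= HYDROGEN_ATTACH_MAX:
            out.append(_edge(parent.serial, h.serial, Kind.COVALENT_LOCKED))
        else:
            logger.warning("hydrogen serial %d too far from any heavy atom",
                           h.serial)
    return out


def find_covalent_bonds(s: ProteinStructure) -> list[Interaction]:
    """Covalent bonds from residue templates plus peptide and disulfide links.

    Peptide bonds (partial double-bond character) are locked; disulfides are
    rotatable single bonds.
    """
    bonds: list[Interaction] = []
    for res in s.residues:
        bonds.extend(_intra_residue_bonds(res))
    # peptide bonds between consecutive residues of the same chain
    for prev, res in zip(s.residues, s.residues[1:]):
        if prev.chain != res.chain:
            continue
        c, n = prev.atom("C"), res.atom("N")
        if c is not None and n is not None and \
                np.linalg.norm(c.xyz - n.xyz) < PEPTIDE_BOND_MAX:
            bonds.append(_edge(c.serial, n.serial, Kind.COVALENT_LOCKED))
    # disulfides
    sgs = [res.atom("SG") for res in s.residues if res.resname == "CYS"]
    sgs = [a for a in sgs if a is not None]
    for a, b in itertools.combinations(sgs, 2):
        if np.linalg.norm(a.xyz - b.xyz) < DISULFIDE_MAX:
            bonds.append(_edge(a.serial, b.serial, Kind.COVALENT_ROTATABLE))
    return sorted(set(bonds), key=lambda e: e.pair)


def _covalent_adjacency(bonds: list[Interaction]) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for b in bonds:
        adj.setdefault(b.atom_i, set()).add(b.atom_j)
        adj.setdefault(b.atom_j, set()).add(b.atom_i)
    return adj


_SALT_DONOR_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_SALT_ACCEPTOR_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


def _salt_bridge_pairs(s: ProteinStructure, p: HBondParams) -> set[tuple[int, int]]:
    donors = [a for res in s.residues
              for a in res.atoms if a.name in _SALT_DONOR_ATOMS.get(res.resname, ())]
    acceptors = [a for res in s.residues
                 for a in res.atoms if a.name in _SALT_ACCEPTOR_ATOMS.get(res.resname, ())]
    pairs: set[tuple[int, int]] = set()
    for d in donors:
        for a in acceptors:
            if np.linalg.norm(d.xyz - a.xyz) <= p.d_DA_max:
                pairs.add((d.serial, a.serial))
    return pairs


def find_salt_bridges(s: ProteinStructure,
                      p: HBondParams | None = None) -> list[Interaction]:
    """Charged side-chain N (Arg/Lys/His) to carboxylate O (Asp/Glu) pairs
    within the donor-acceptor cutoff, at a fixed strong energy so that they
    persist through hydrogen-bond dilution."""
    p = p or HBondParams()
    out = [_edge(d, a, Kind.SALT_BRIDGE, p.salt_bridge_energy, donor=d, acceptor=a)
           for d, a in _salt_bridge_pairs(s, p)]
    return sorted(set(out), key=lambda e: e.pair)


def find_hbonds(s: ProteinStructure, p: HBondParams | None = None,
                covalent: list[Interaction] | None = None) -> list[Interaction]:
    """Hydrogen bonds from D-H...A geometry with a Mayo-form energy.

    Donors are N/O atoms carrying at least one hydrogen; acceptors are O
    atoms and hydrogen-free N atoms.  Candidates must satisfy
    ``d(D,A) <= d_DA_max``, ``d(H,A) <= d_HA_max`` and
    ``angle(D,H,A) >= theta_min``; only negative energies are kept.  Pairs
    already covalently bonded, 1-3 neighbours, or qualifying as salt bridges
    are excluded.
    """
    p = p or HBondParams()
    covalent = covalent if covalent is not None else find_covalent_bonds(s)
    adj = _covalent_adjacency(covalent)
    atom_by_serial = {a.serial: a for a in s.atoms}
    res_of = {a.serial: res for res in s.residues for a in res.atoms}

    # donor -> attached hydrogens
    hydrogens: dict[int, list[Atom]] = {}
    for serial, neighbours in adj.items():
        a = atom_by_serial.get(serial)
        if a is None or a.is_hydrogen:
            continue
        hs = [atom_by_serial[n] for n in neighbours
              if n in atom_by_serial and atom_by_serial[n].is_hydrogen]
        if hs:
            hydrogens[serial] = sorted(hs, key=lambda h: h.serial)

    donors = [a for a in s.atoms if a.element in ("N", "O") and a.serial in hydrogens]
    acceptors = [a for a in s.atoms
                 if (a.element == "O")
                 or (a.element == "N" and a.serial not in hydrogens)]
    if not donors or not acceptors:
        return []
    salt_pairs = _salt_bridge_pairs(s, p)

    acc_tree = cKDTree(np.array([a.xyz for a in acceptors]))
    bonds: dict[tuple[int, int], Interaction] = {}
    for d in donors:
        for ai in acc_tree.query_ball_point(d.xyz, p.d_DA_max):
            a = acceptors[ai]
            if a.serial == d.serial:
                continue
            if a.serial in adj.get(d.serial, ()):  # covalently bonded
                continue
            if adj.get(d.serial, set()) & adj.get(a.serial, set()):  # 1-3
                continue
            key = (d.serial, a.serial) if d.serial < a.serial else (a.serial, d.serial)
            if (d.serial, a.serial) in salt_pairs:
                continue
            d_DA = float(np.linalg.norm(d.xyz - a.xyz))
            best: Interaction | None = None
            for h in hydrogens[d.serial]:
                d_HA = float(np.linalg.norm(h.xyz - a.xyz))
                if d_HA > p.d_HA_max:
                    continue
                v1 = d.xyz - h.xyz
                v2 = a.xyz - h.xyz
                cosang = float(np.dot(v1, v2) /
                               (np.linalg.norm(v1) * np.linalg.norm(v2)))
                theta = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if theta < p.theta_min:
                    continue
                e = p.energy(d_DA, theta)
                if e < 0 and (best is None or e < best.energy):
                    best = _edge(d.serial, a.serial, Kind.HBOND, e,
                                 donor=d.serial, acceptor=a.serial)
            if best is not None and (key not in bonds or best.energy < bonds[key].energy):
                bonds[key] = best
    # deterministic order: ascending energy, then donor, then acceptor
    return sorted(bonds.values(), key=lambda b: (b.energy, b.donor, b.acceptor))


_VDW_RADII = {"C": 1.7, "S": 1.8}
HYDROPHOBIC_SLACK = 0.25  # A beyond the van der Waals radii sum


def find_hydrophobic_tethers(s: ProteinStructure) -> list[Interaction]:
    """Carbon/sulfur contact tethers between residues >= 2 apart in sequence.

    At most one tether per residue pair (the closest atom pair), with a
    distance criterion of the van der Waals radii sum plus a small slack.
    """
    entries = []  # (seq_index, atom)
    for res in s.residues:
        for a in res.atoms:
            if a.element in _VDW_RADII:
                entries.append((res.seq_index, a))
    if not entries:
        return []
    coords = np.array([a.xyz for _, a in entries])
    tree = cKDTree(coords)
    max_cut = _VDW_RADII["S"] * 2 + HYDROPHOBIC_SLACK
    best: dict[tuple[int, int], tuple[float, Interaction]] = {}
    for i, j in tree.query_pairs(max_cut):
        ri, ai = entries[i]
        rj, aj = entries[j]
        if abs(ri - rj) < 2:
            continue
        cutoff = _VDW_RADII[ai.element] + _VDW_RADII[aj.element] + HYDROPHOBIC_SLACK
        dist = float(np.linalg.norm(ai.xyz - aj.xyz))
        if dist > cutoff:
            continue
        key = (ri, rj) if ri < rj else (rj, ri)
        edge = _edge(ai.serial, aj.serial, Kind.HYDROPHOBIC)
        if key not in best or dist < best[key][0]:
            best[key] = (dist, edge)
    return sorted((e for _, e in best.values()), key=lambda e: e.pair)


def find_all_interactions(s: ProteinStructure,
                          p: HBondParams | None = None) -> list[Interaction]:
    """Full constraint inventory: covalent + hbond + salt bridge + tethers."""
    p = p or HBondParams()
    covalent = find_covalent_bonds(s)
    cov_pairs = {b.pair for b in covalent}
    others = (find_hbonds(s, p, covalent) + find_salt_bridges(s, p)
              + find_hydrophobic_tethers(s))
    return covalent + [b for b in others if b.pair not in cov_pairs]
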