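"""PDB structure container, reading, sanitization, and value-carrying output.

The pipeline operates on single protein chains stripped of waters, ligands,
hydrogens, and anisotropic records, mirroring the preparation used before
rigidity analysis.  Reading goes through :mod:`gemmi`; the in-memory
representation is a flat, ordered list of atoms grouped into residues, which
is all the constraint-network machinery downstream needs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Three-letter codes accepted as standard amino acids during sanitization.
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class EmptyStructureError(ValueError):
    """Raised when a PDB file yields no atoms."""


@dataclass(frozen=True)
class Atom:
    """One atom: serial number, name, element, position, occupancy, B column."""

    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    bvalue: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}) has no element")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.serial} has non-finite coordinates")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class ResidueRef:
    """A residue identified by author numbering, holding its atoms."""

    chain: str
    resnum: int
    resname: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    #: 0-based sequential index from the N-terminus, assigned by the parent
    #: structure; author numbering is kept alongside for alignment output.
    seq_index: int = -1

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ProteinStructure:
    """Ordered residues (file order) of one or more chains."""

    residues: list[ResidueRef] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        seen_serials: set[int] = set()
        seen_keys: set[tuple[str, int, str]] = set()
        for i, res in enumerate(self.residues):
            if res.key in seen_keys:
                raise ValueError(f"duplicate residue {res.key}")
            seen_keys.add(res.key)
            res.seq_index = i
            for atom in res.atoms:
                if atom.serial in seen_serials:
                    raise ValueError(f"duplicate atom serial {atom.serial}")
                seen_serials.add(atom.serial)

    @property
    def atoms(self) -> list[Atom]:
        return [a for res in self.residues for a in res.atoms]

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for res in self.residues:
            if res.chain not in out:
                out.append(res.chain)
        return out

    def residue_of(self, serial: int) -> ResidueRef:
        return self._serial_map()[serial]

    def _serial_map(self) -> dict[int, ResidueRef]:
        return {a.serial: res for res in self.residues for a in res.atoms}

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


def _pick_altlocs(raw: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Resolve alternate locations per atom name.

    Keeps blank-altloc atoms as-is; among lettered conformers of the same
    atom name, keeps the highest occupancy, ties broken by the earliest
    altloc letter.
    """
    by_name: dict[str, list[gemmi.Atom]] = {}
    order: list[str] = []
    for a in raw:
        by_name.setdefault(a.name, []).append(a)
        if a.name not in order:
            order.append(a.name)
    kept: list[gemmi.Atom] = []
    for name in order:
        group = sorted(by_name[name], key=lambda a: (-a.occ, a.altloc or "~"))
        kept.append(group[0])
    return kept


def read_pdb(path: str | Path, source_id: str | None = None) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Only the first MODEL is used; ANISOU records never create atoms (gemmi
    parses them as metadata); alternate locations are resolved to the
    highest-occupancy conformer.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no atoms found")
    model = st[0]
    residues: list[ResidueRef] = []
    serial = 0
    for chain in model:
        for res in chain:
            picked = _pick_altlocs(list(res))
            atoms: list[Atom] = []
            for a in picked:
                serial += 1
                element = a.element.name if a.element.name else _element_from_name(a.name)
                atoms.append(Atom(
                    serial=a.serial if a.serial > 0 else serial,
                    name=a.name,
                    element=element.upper(),
                    coords=(a.pos.x, a.pos.y, a.pos.z),
                    occupancy=a.occ,
                    bvalue=a.b_iso,
                    altloc=a.altloc if a.altloc not in ("", "\0", " ") else "",
                ))
            if atoms:
                residues.append(ResidueRef(
                    chain=chain.name,
                    resnum=res.seqid.num,
                    resname=res.name.strip(),
                    icode=res.seqid.icode.strip(),
                    atoms=atoms,
                ))
    if not residues:
        raise EmptyStructureError(f"{path}: no atoms found")
    sid = source_id if source_id is not None else path.stem
    return ProteinStructure(residues=residues, source_id=sid)


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name by convention."""
    stripped = name.strip()
    if not stripped:
        return "X"
    if stripped[0].isdigit():  # e.g. 1HB2
        return "H"
    if len(name) >= 2 and name[0] != " " and name[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return name[:2].capitalize()
    return stripped[0].upper()


def sanitize_structure(s: ProteinStructure, chain: str) -> ProteinStructure:
    """Keep only standard amino-acid heavy atoms of one chain.

    Removes waters, hydrogens, non-protein HETATM residues and every other
    chain, logging each category of removal.  Idempotent.
    """
    available = s.chains
    if chain not in available:
        raise ValueError(
            f"chain {chain!r} not present in {s.source_id or 'structure'}; "
            f"available chains: {', '.join(available)}"
        )
    kept: list[ResidueRef] = []
    n_water = n_het = n_hydro = 0
    for res in s.residues:
        if res.chain != chain:
            continue
        if res.resname in WATER_NAMES:
            n_water += 1
            continue
        if res.resname not in STANDARD_RESIDUES:
            n_het += 1
            continue
        heavy = res.heavy_atoms
        n_hydro += len(res.atoms) - len(heavy)
        if heavy:
            kept.append(ResidueRef(res.chain, res.resnum, res.resname, res.icode,
                                   atoms=list(heavy)))
    if n_water or n_het or n_hydro:
        logger.info(
            "%s chain %s: removed %d waters, %d hetero residues, %d hydrogens",
            s.source_id, chain, n_water, n_het, n_hydro,
        )
    return ProteinStructure(residues=kept, source_id=s.source_id)


_PDB_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resnum:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # Columns 13-16: element right-aligned into 13-14 for 1-letter elements.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(s: ProteinStructure, path: str | Path) -> None:
    """Write standard ATOM records (coordinates to 3 decimals, B to 2)."""
    write_pdb_with_values(s, [a.bvalue for a in s.atoms], path)


def write_pdb_with_values(s: ProteinStructure, values: Sequence[float],
                          path: str | Path) -> None:
    """Write the structure with per-atom ``values`` in the B-value column.

    The B column (PDB columns 61-66) is commonly repurposed to carry
    quantities such as a per-residue flexibility index for visualization.
    """
    atoms = s.atoms
    if len(values) != len(atoms):
        raise ValueError(f"{len(values)} values for {len(atoms)} atoms")
    value_of = {a.serial: float(v) for a, v in zip(atoms, values)}
    lines: list[str] = []
    prev_chain: str | None = None
    for res in s.residues:
        if prev_chain is not None and res.chain != prev_chain:
            lines.append("TER\n")
        prev_chain = res.chain
        for a in res.atoms:
            lines.append(_PDB_ATOM_FMT.format(
                serial=a.serial,
                name=_format_atom_name(a.name, a.element),
                altloc=a.altloc or " ",
                resname=res.resname,
                chain=res.chain or "A",
                resnum=res.resnum,
                icode=res.icode or " ",
                x=a.coords[0], y=a.coords[1], z=a.coords[2],
                occ=a.occupancy, b=value_of[a.serial],
                element=a.element,
            ))
    lines.append("TER\nEND\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# Naive geometric protonation
# ---------------------------------------------------------------------------

N_H_LENGTH = 1.01
O_H_LENGTH = 0.96


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("zero-length vector")
    return v / n


def place_amide_hydrogen(n_pos: np.ndarray, prev_c_pos: np.ndarray,
                         ca_pos: np.ndarray) -> np.ndarray:
    """Ideal sp2 amide hydrogen: in the peptide plane, bisector-opposite the
    two heavy neighbours of N."""
    d = -( _unit(prev_c_pos - n_pos) + _unit(ca_pos - n_pos))
    return n_pos + N_H_LENGTH * _unit(d)


def protonate_naive(s: ProteinStructure) -> ProteinStructure:
    """Add backbone amide hydrogens at ideal sp2 geometry.

    This is a deliberately minimal protonator so that self-contained fixtures
    can exercise hydrogen-bond detection; it places only the backbone H-N
    hydrogen (the donor relevant to secondary-structure hydrogen bonds) and
    is not equivalent to an energy-optimized protonation protocol, which the
    pipeline otherwise expects as pre-protonated input.
    """
    max_serial = max((a.serial for a in s.atoms), default=0)
    new_residues: list[ResidueRef] = []
    serial = max_serial
    prev_res: ResidueRef | None = None
    n_placed = 0
    for res in s.residues:
        atoms = list(res.atoms)
        n = res.atom("N")
        ca = res.atom("CA")
        if (prev_res is not None and prev_res.chain == res.chain
                and res.resname != "PRO" and n is not None and ca is not None):
            prev_c = prev_res.atom("C")
            if prev_c is not None and res.atom("H") is None:
                serial += 1
                h_pos = place_amide_hydrogen(n.xyz, prev_c.xyz, ca.xyz)
                atoms.append(Atom(serial=serial, name="H", element="H",
                                  coords=tuple(h_pos)))
                n_placed += 1
        new_residues.append(ResidueRef(res.chain, res.resnum, res.resname,
                                       res.icode, atoms=atoms))
        prev_res = res
    logger.info("naive protonation: placed %d backbone amide hydrogens "
                "(not equivalent to an optimized protonation)", n_placed)
    return ProteinStructure(residues=new_residues, source_id=s.source_id)
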