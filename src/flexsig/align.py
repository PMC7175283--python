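"""Structure-based alignment annotation: residue correspondence tables.

Starting from a pairwise structural alignment (Dali text output or a
two-record aligned FASTA), these tools map residue correspondences between
a query and a subject, mark key residues (given as ranges or by distance to
ligand atoms), and emit annotated alignment tables as CSV or HTML — either
residue-level annotations (the BRAT view) or per-residue numeric values
carried in the B-value column, laid out on a common reference grid (the BAT
view).
"""

from __future__ import annotations

import html as _html
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure import ProteinStructure, ResidueRef

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

_GAP_CHARS = {"-", "."}


@dataclass
class DaliAlignment:
    """Pairwise alignment: columns of (query position, subject position).

    Positions are 0-based indices into the ungapped sequences; ``None``
    marks a gap.  Lowercase letters in Dali output flag structurally
    unaligned residues; such residues are kept but never paired, so every
    pairing is a bijection on the aligned columns.
    """

    query_id: str
    subject_id: str
    query_seq: str           # ungapped, uppercase
    subject_seq: str
    columns: list[tuple[int | None, int | None]] = field(default_factory=list)
    z_score: float | None = None

    def __post_init__(self) -> None:
        for seq, slot in ((self.query_seq, 0), (self.subject_seq, 1)):
            positions = [c[slot] for c in self.columns if c[slot] is not None]
            if positions != sorted(set(positions)):
                raise ValueError("alignment columns must preserve residue order")
            if positions and (positions[0] != 0 or positions[-1] != len(seq) - 1):
                raise ValueError("alignment columns must cover the sequences")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def gapped(self) -> tuple[str, str]:
        q = "".join("-" if c[0] is None else self.query_seq[c[0]]
                    for c in self.columns)
        s = "".join("-" if c[1] is None else self.subject_seq[c[1]]
                    for c in self.columns)
        return q, s

    def paired_positions(self) -> list[tuple[int, int]]:
        return [(q, s) for q, s in self.columns if q is not None and s is not None]


def _columns_from_gapped(q_gapped: str, s_gapped: str
                         ) -> tuple[str, str, list[tuple[int | None, int | None]]]:
    if len(q_gapped) != len(s_gapped):
        raise ValueError("aligned sequences differ in length")
    cols: list[tuple[int | None, int | None]] = []
    qi = si = 0
    q_seq: list[str] = []
    s_seq: list[str] = []
    for qc, sc in zip(q_gapped, s_gapped):
        q_is_res = qc not in _GAP_CHARS
        s_is_res = sc not in _GAP_CHARS
        aligned = q_is_res and s_is_res and qc.isupper() and sc.isupper()
        if aligned:
            cols.append((qi, si))
        else:
            # unaligned (lowercase) or gapped positions never pair
            if q_is_res:
                cols.append((qi, None))
            if s_is_res:
                cols.append((None, si))
        if q_is_res:
            q_seq.append(qc.upper())
            qi += 1
        if s_is_res:
            s_seq.append(sc.upper())
            si += 1
    return "".join(q_seq), "".join(s_seq), cols


_DALI_HEADER = re.compile(r"Z-score\s*=\s*([0-9.]+)")
_DALI_IDS = re.compile(r"Query\s*=\s*(\S+).*?Sbjct\s*=\s*(\S+)")


def parse_dali_alignment(text: str, query_id: str = "query",
                         subject_id: str = "subject") -> DaliAlignment:
    """Parse a Dali pairwise alignment block or a two-record aligned FASTA.

    Dali blocks are repeated groups of ``Query``/``Sbjct`` sequence lines
    (lowercase marks structurally unaligned stretches); the alternate
    dialect is a plain aligned FASTA with two records.
    """
    if text.lstrip().startswith(">"):
        return _parse_aligned_fasta(text)
    q_parts: list[str] = []
    s_parts: list[str] = []
    z: float | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if m := _DALI_HEADER.search(line):
            z = float(m.group(1))
        if m := _DALI_IDS.search(line):
            query_id, subject_id = m.group(1), m.group(2)
        stripped = line.strip()
        for prefix, parts in (("Query", q_parts), ("Sbjct", s_parts)):
            if stripped.startswith(prefix):
                fields = stripped.split()
                if len(fields) < 2:
                    raise ValueError(f"line {lineno}: {prefix} line without a"
                                     " sequence block")
                seq = fields[1]
                if not re.fullmatch(r"[A-Za-z.\-]+", seq):
                    raise ValueError(f"line {lineno}: unparseable sequence"
                                     f" block {seq!r}")
                parts.append(seq)
    if not q_parts or not s_parts:
        raise ValueError("no Query/Sbjct alignment blocks found")
    q_gapped, s_gapped = "".join(q_parts), "".join(s_parts)
    q_seq, s_seq, cols = _columns_from_gapped(q_gapped, s_gapped)
    return DaliAlignment(query_id=query_id, subject_id=subject_id,
                         query_seq=q_seq, subject_seq=s_seq,
                         columns=cols, z_score=z)


def _parse_aligned_fasta(text: str) -> DaliAlignment:
    records: list[tuple[str, str]] = []
    name, chunks = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name, chunks = line[1:].split()[0], []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        records.append((name, "".join(chunks)))
    if len(records) != 2:
        raise ValueError(f"aligned FASTA must contain exactly 2 records,"
                         f" found {len(records)}")
    (qid, q_gapped), (sid, s_gapped) = records
    q_seq, s_seq, cols = _columns_from_gapped(q_gapped, s_gapped)
    return DaliAlignment(query_id=qid, subject_id=sid, query_seq=q_seq,
                         subject_seq=s_seq, columns=cols)


def write_aligned_fasta(aln: DaliAlignment) -> str:
    """Serialise as a two-record aligned FASTA (round-trips through
    :func:`parse_dali_alignment`)."""
    q, s = aln.gapped()
    return f">{aln.query_id}\n{q}\n>{aln.subject_id}\n{s}\n"


# ---------------------------------------------------------------------------
# Key-residue definitions
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSpec:
    """Key residues by explicit ranges or by distance to ligand atoms."""

    mode: str  # "ranges" | "ligand_distance"
    ranges: tuple[tuple[int, int], ...] = ()
    distance_cutoff: float = 4.5
    ligand_atoms: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("ranges", "ligand_distance"):
            raise ValueError(f"unknown annotation mode {self.mode!r}")
        if self.mode == "ligand_distance" and self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")


def key_residues_by_ranges(s: ProteinStructure,
                           spec: AnnotationSpec) -> set[int]:
    """Residue numbers falling inside any of the annotation ranges."""
    out = set()
    for res in s.residues:
        if any(a <= res.resnum <= b for a, b in spec.ranges):
            out.add(res.resnum)
    return out


def key_residues_by_distance(s: ProteinStructure,
                             spec: AnnotationSpec) -> set[int]:
    """Residues with any heavy atom within the cutoff of any ligand atom."""
    if spec.ligand_atoms is None or len(spec.ligand_atoms) == 0:
        raise ValueError("ligand_distance mode requires ligand atoms")
    ligand = np.asarray(spec.ligand_atoms, dtype=float).reshape(-1, 3)
    out = set()
    for res in s.residues:
        coords = np.array([a.coords for a in res.heavy_atoms])
        d = np.linalg.norm(coords[:, None, :] - ligand[None, :, :], axis=2)
        if (d <= spec.distance_cutoff).any():
            out.add(res.resnum)
    return out


def key_residues(s: ProteinStructure, spec: AnnotationSpec) -> set[int]:
    if spec.mode == "ranges":
        return key_residues_by_ranges(s, spec)
    return key_residues_by_distance(s, spec)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _map_to_residues(seq: str, s: ProteinStructure) -> list[ResidueRef]:
    """Sequence positions -> structure residues, in order.

    The alignment sequence must match the structure residue-for-residue;
    one-letter-code mismatches are reported but tolerated (e.g. nonstandard
    residues rendered as X by the aligner).
    """
    if len(seq) != len(s.residues):
        raise ValueError(
            f"{s.source_id}: alignment sequence has {len(seq)} residues but"
            f" the structure has {len(s.residues)}")
    mismatches = sum(
        1 for ch, res in zip(seq, s.residues)
        if THREE_TO_ONE.get(res.resname, "X") != ch.upper())
    if mismatches:
        logger.warning("%s: %d one-letter-code mismatches against the"
                       " alignment", s.source_id, mismatches)
    return list(s.residues)


def render_brat(aln: DaliAlignment, query: ProteinStructure,
                subject: ProteinStructure,
                key: Mapping[str, set[int]] | None = None,
                fmt: str = "csv",
                annotations: Mapping[str, tuple[int, int]] | None = None,
                ) -> str:
    """Annotated pairwise alignment: one row per structure, one column per
    alignment column; key residues are flagged (CSV: ``*`` suffix; HTML:
    boldface).

    ``key`` maps structure ids to sets of author residue numbers;
    ``annotations`` optionally labels query-residue ranges (e.g. segment
    names) above the columns in the HTML view.
    """
    key = key or {}
    q_res = _map_to_residues(aln.query_seq, query)
    s_res = _map_to_residues(aln.subject_seq, subject)
    for sid, wanted in key.items():
        known = {r.resnum for r in (q_res if sid == aln.query_id else s_res)}
        for resnum in sorted(wanted - known):
            logger.warning("key residue %s:%d not present in the alignment;"
                           " skipped", sid, resnum)

    def cell(residues: list[ResidueRef], pos: int | None, sid: str) -> tuple[str, bool]:
        if pos is None:
            return "-", False
        res = residues[pos]
        letter = THREE_TO_ONE.get(res.resname, "X")
        flagged = res.resnum in key.get(sid, ())
        return f"{letter}{res.resnum}", flagged

    rows = []
    for sid, residues, slot in ((aln.query_id, q_res, 0),
                                (aln.subject_id, s_res, 1)):
        cells = [cell(residues, col[slot], sid) for col in aln.columns]
        rows.append((sid, cells))

    if fmt == "csv":
        buf = io.StringIO()
        header = ["structure"] + [f"col{i + 1}" for i in range(aln.n_columns)]
        buf.write(",".join(header) + "\n")
        for sid, cells in rows:
            buf.write(",".join([sid] + [text + ("*" if flag else "")
                                        for text, flag in cells]) + "\n")
        return buf.getvalue()
    if fmt == "html":
        lines = ["<table>"]
        if annotations:
            ann_cells = []
            for col in aln.columns:
                label = ""
                if col[0] is not None:
                    resnum = q_res[col[0]].resnum
                    for name, (a, b) in annotations.items():
                        if a <= resnum <= b:
                            label = name
                            break
                ann_cells.append(f"<td>{_html.escape(label)}</td>")
            lines.append("<tr><td></td>" + "".join(ann_cells) + "</tr>")
        for sid, cells in rows:
            tds = []
            for text, flag in cells:
                content = _html.escape(text)
                tds.append(f"<td><b>{content}</b></td>" if flag
                           else f"<td>{content}</td>")
            lines.append(f"<tr><td>{_html.escape(sid)}</td>" + "".join(tds)
                         + "</tr>")
        lines.append("</table>")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def residue_values(s: ProteinStructure) -> list[float]:
    """Per-residue value from the B column: mean over the residue's atoms."""
    return [float(np.mean([a.bvalue for a in res.atoms])) for res in s.residues]


def render_bat(reference: ProteinStructure,
               others: Sequence[tuple[ProteinStructure, DaliAlignment]],
               path: str | Path | None = None) -> pd.DataFrame:
    """Numeric-value alignment table on the reference residue grid.

    Every structure contributes three rows — chain+residue number, residue
    name, and the per-residue value carried in the B column (mean over the
    residue's atoms, 2 decimals) — with ``-`` at unaligned positions.  Each
    subject must be aligned to the reference (reference as alignment query).
    """
    ref_res = list(reference.residues)
    n_cols = len(ref_res)
    ref_vals = residue_values(reference)

    def rows_for(sid: str, residues: list[ResidueRef | None],
                 values: list[float | None]) -> list[list[str]]:
        num_row = [sid, "residue_number"]
        name_row = [sid, "residue_name"]
        val_row = [sid, "value"]
        for res, val in zip(residues, values):
            if res is None:
                num_row.append("-")
                name_row.append("-")
                val_row.append("-")
            else:
                num_row.append(f"{res.chain}{res.resnum}")
                name_row.append(res.resname)
                val_row.append(f"{val:.2f}")
        return [num_row, name_row, val_row]

    all_rows = rows_for(reference.source_id, ref_res, ref_vals)
    for subject, aln in others:
        if aln.query_id != reference.source_id:
            raise ValueError(
                f"alignment for {subject.source_id} does not use"
                f" {reference.source_id} as its reference query")
        s_res = _map_to_residues(aln.subject_seq, subject)
        s_vals = residue_values(subject)
        by_ref: dict[int, int] = {q: s for q, s in aln.paired_positions()}
        residues = [s_res[by_ref[i]] if i in by_ref else None
                    for i in range(n_cols)]
        values = [s_vals[by_ref[i]] if i in by_ref else None
                  for i in range(n_cols)]
        all_rows.extend(rows_for(subject.source_id, residues, values))

    columns = ["structure", "row"] + [f"c{i + 1}" for i in range(n_cols)]
    df = pd.DataFrame(all_rows, columns=columns)
    if path is not None:
        df.to_csv(path, index=False)
    return df
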