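"""Sequence and structure I/O plus the core aligned-family data model.

Reads aligned FASTA (family alignments), plain FASTA (single sequences)
and PDB coordinate files, normalizing everything to a small set of
dataclasses used by the rest of the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from famtrend.errors import (
    AlignmentShapeError,
    MissingChainError,
    MissingIdError,
    ParseError,
)

log = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Gap character used internally; '.' on input is normalized to this.
GAP = "-"

#: Unknown residue: legal in alignments, never matches in similarity metrics.
UNKNOWN = "X"

#: Full alignment alphabet.
ALPHABET = STANDARD_RESIDUES | {UNKNOWN, GAP}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped protein sequence with its identifier."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if GAP in self.seq:
            raise ParseError(f"SequenceRecord {self.id!r} contains gap characters")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignedFamily:
    """A protein-family multiple sequence alignment.

    Rows are equal-length strings over the 20 amino-acid letters, 'X'
    (unknown) and '-' (gap). Terminal gap runs are treated as display
    filler, distinct from internal gaps (see :func:`terminal_filler_mask`).
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentShapeError(
                f"{len(self.ids)} ids but {len(self.rows)} rows"
            )
        if not self.rows:
            raise AlignmentShapeError("alignment has no rows")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            bad = next(i for i, r in enumerate(self.rows) if len(r) != len(self.rows[0]))
            raise AlignmentShapeError(
                f"record {self.ids[bad]!r} has length {len(self.rows[bad])}, "
                f"expected {len(self.rows[0])}"
            )
        seen: set[str] = set()
        for i, rid in enumerate(self.ids):
            if not rid:
                raise ParseError(f"record {i} has an empty id")
            if rid in seen:
                raise ParseError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
        for rid, row in zip(self.ids, self.rows):
            for col, ch in enumerate(row):
                if ch not in ALPHABET:
                    raise ParseError(
                        f"illegal character {ch!r} in record {rid!r} at column {col + 1}"
                    )

    @property
    def n(self) -> int:
        """Number of sequences (rows)."""
        return len(self.rows)

    @property
    def length(self) -> int:
        """Alignment width (columns)."""
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        """Return the aligned row for ``seq_id``."""
        return self.rows[self.index(seq_id)]

    def index(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise MissingIdError(
                f"sequence id {seq_id!r} not in family ({self.n} rows)"
            ) from None

    def degapped(self, seq_id: str) -> str:
        """The ungapped sequence of one row."""
        return self.row(seq_id).replace(GAP, "")

    def column(self, col: int) -> str:
        """Characters of 1-based column ``col``, top to bottom."""
        if not 1 <= col <= self.length:
            raise FamilyColumnError(col, self.length)
        return "".join(r[col - 1] for r in self.rows)


class FamilyColumnError(IndexError, ValueError):
    def __init__(self, col: int, length: int):
        super().__init__(f"column {col} out of range [1, {length}]")


@dataclass(frozen=True)
class StructureResidue:
    """One residue from a coordinate file: key, one-letter code, heavy atoms."""

    key: str  # residue number as given in the file, insertion code appended
    code: str  # one-letter code; 'X' if the three-letter code is unknown
    coords: np.ndarray = field(compare=False)  # (n_atoms, 3) float array, Å

    def __post_init__(self) -> None:
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) == 0:
            raise ParseError(f"residue {self.key}: needs >=1 atom with xyz coordinates")


@dataclass
class StructureChain:
    """An ordered list of residues of one chain, ATOM records only."""

    chain_id: str
    residues: list[StructureResidue]

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, key: str) -> StructureResidue:
        for r in self.residues:
            if r.key == key:
                return r
        raise MissingIdError(f"residue key {key!r} not in chain {self.chain_id}")


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_alignment(path: str | Path) -> AlignedFamily:
    """Read an aligned FASTA file into an :class:`AlignedFamily`.

    Lowercase letters are uppercased and '.' is normalized to '-'.
    Raises :class:`AlignmentShapeError` when record lengths differ and
    :class:`ParseError` on illegal characters or an empty file.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    rows = [_normalize(str(r.seq)) for r in records]
    return AlignedFamily(ids=ids, rows=rows)


def write_alignment(family: AlignedFamily, path: str | Path) -> None:
    """Write the family back out as aligned FASTA (one line per sequence)."""
    with open(path, "w") as fh:
        for rid, row in zip(family.ids, family.rows):
            fh.write(f">{rid}\n{row}\n")


def read_sequence(path: str | Path) -> SequenceRecord:
    """Read the first record of a FASTA file, degapped and uppercased.

    Logs a warning if the file holds more than one record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    if len(records) > 1:
        log.warning("%s contains %d records; using the first (%s)",
                    path, len(records), records[0].id)
    seq = _normalize(str(records[0].seq)).replace(GAP, "")
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise ParseError(
                f"illegal character {ch!r} in record {records[0].id!r} at position {i + 1}"
            )
    return SequenceRecord(id=records[0].id, seq=seq)


def write_sequence(record: SequenceRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.id}\n{record.seq}\n")


def read_structure(path: str | Path, chain: str) -> StructureChain:
    """Extract one chain from a PDB coordinate file.

    Only ATOM records are used (HETATM is ignored), hydrogens are
    dropped, three-letter codes are mapped to one-letter ('X' for
    non-standard residues), and insertion codes are kept as part of the
    residue key (e.g. ``"100A"``).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    available = [c.id for c in model.get_chains()]
    if chain not in available:
        raise MissingChainError(
            f"chain {chain!r} not found in {path}; available chains: "
            + ", ".join(repr(c) for c in available)
        )
    residues: list[StructureResidue] = []
    for res in model[chain].get_residues():
        hetflag, resseq, icode = res.id
        if hetflag.strip():  # HETATM or water
            continue
        coords = np.array(
            [a.coord for a in res.get_atoms() if (a.element or "").strip() != "H"],
            dtype=float,
        )
        if len(coords) == 0:
            continue
        key = f"{resseq}{icode.strip()}"
        code = _THREE_TO_ONE.get(res.get_resname().strip().upper(), UNKNOWN)
        residues.append(StructureResidue(key=key, code=code, coords=coords))
    return StructureChain(chain_id=chain, residues=residues)


def terminal_filler_mask(
    family: AlignedFamily,
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Per-row terminal gap runs, as 0-based half-open column ranges.

    Returns for each row a ``((0, lead_end), (trail_start, L))`` pair
    covering the maximal leading and trailing runs of '-'. Internal gaps
    are not filler. For an all-gap row the whole width is assigned to the
    leading range and the trailing range is empty.
    """
    out = []
    L = family.length
    for row in family.rows:
        lead = 0
        while lead < L and row[lead] == GAP:
            lead += 1
        if lead == L:  # all gaps: leading run consumes everything
            out.append(((0, L), (L, L)))
            continue
        trail = L
        while trail > 0 and row[trail - 1] == GAP:
            trail -= 1
        out.append(((0, lead), (trail, L)))
    return out
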