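"""Seeded synthetic-family generator with planted ground truth.

Stands in for an external contest dataset: rows are drawn from a planted
consensus with i.i.d. per-column substitutions, a parent/mutant pair is
derived from the consensus with planted candidate positions, and
symmetric position pairs can be planted at chosen offsets from the
termini. The same seed always produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from famtrend.errors import FamtrendError
from famtrend.sequence_io import (
    AlignedFamily,
    SequenceRecord,
    write_alignment,
    write_sequence,
)

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

PARENT_ID = "parent"
MUTANT_ID = "mutant"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic family.

    ``candidates`` are (position, parent residue, mutant residue)
    triples; the planted consensus carries the mutant residue at each.
    ``symmetric_offsets`` plant one candidate pair per offset k, at
    positions k and length+1-k. Positions are 1-based over an ungapped
    alignment of width ``length``.
    """

    n_rows: int = 200
    length: int = 250
    substitution_rate: float = 0.05
    consensus: str | None = None
    candidates: tuple[tuple[int, str, str], ...] = ()
    symmetric_offsets: tuple[int, ...] = ()
    seed: int = 0
    include_pair_in_family: bool = True

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.length < 1:
            raise FamtrendError("n_rows and length must be >= 1")
        if not 0.0 <= self.substitution_rate < 0.5:
            raise FamtrendError(
                f"substitution rate must be in [0, 0.5), got {self.substitution_rate}"
            )
        if self.consensus is not None and len(self.consensus) != self.length:
            raise FamtrendError("explicit consensus length must equal spec length")
        for pos, p_res, m_res in self.candidates:
            if not 1 <= pos <= self.length:
                raise FamtrendError(f"planted position {pos} outside [1, {self.length}]")
            if p_res == m_res:
                raise FamtrendError(f"planted candidate at {pos} does not mutate")
        for k in self.symmetric_offsets:
            if not 1 <= k <= self.length // 2:
                raise FamtrendError(
                    f"symmetric offset {k} invalid for length {self.length}"
                )


@dataclass
class FixtureResult:
    family: AlignedFamily
    parent: SequenceRecord
    mutant: SequenceRecord
    truth: dict  # consensus, candidates, symmetric_pairs


def _planted_candidates(spec: FixtureSpec, rng: np.random.Generator, cons: list[str]):
    """Expand explicit + symmetric plants into (pos, parent_res) pairs."""
    plants: dict[int, tuple[str, str]] = {}

    def plant(pos: int, p_res: str | None, m_res: str | None):
        if pos in plants:
            raise FamtrendError(f"overlapping planted candidates at position {pos}")
        if m_res is not None:
            cons[pos - 1] = m_res
        mutant_res = cons[pos - 1]
        if p_res is None:
            others = [str(r) for r in _RESIDUES if r != mutant_res]
            p_res = others[rng.integers(len(others))]
        if p_res == mutant_res:
            raise FamtrendError(
                f"planted parent residue equals consensus at position {pos}"
            )
        plants[pos] = (p_res, mutant_res)

    for pos, p_res, m_res in spec.candidates:
        plant(pos, p_res, m_res)
    for k in spec.symmetric_offsets:
        for pos in (k, spec.length + 1 - k):
            plant(pos, None, None)
    return plants


def generate_family(spec: FixtureSpec) -> FixtureResult:
    """Generate the family, the parent/mutant pair and the truth table."""
    rng = np.random.default_rng(spec.seed)
    if spec.consensus is not None:
        cons = list(spec.consensus.upper())
    else:
        cons = [str(c) for c in _RESIDUES[rng.integers(20, size=spec.length)]]
    plants = _planted_candidates(spec, rng, cons)
    cons_arr = np.array(cons)

    # i.i.d. substitutions: uniform over the 19 other residues
    rows_arr = np.tile(cons_arr, (spec.n_rows, 1))
    mask = rng.random((spec.n_rows, spec.length)) < spec.substitution_rate
    if mask.any():
        shift = rng.integers(1, 20, size=int(mask.sum()))
        base = np.searchsorted(_RESIDUES, rows_arr[mask])
        rows_arr[mask] = _RESIDUES[(base + shift) % 20]

    ids = [f"seq{i:04d}" for i in range(spec.n_rows)]
    rows = ["".join(r) for r in rows_arr]

    mutant_seq = "".join(cons)
    parent_chars = list(cons)
    for pos, (p_res, _m) in plants.items():
        parent_chars[pos - 1] = p_res
    parent_seq = "".join(parent_chars)

    if spec.include_pair_in_family:
        ids += [PARENT_ID, MUTANT_ID]
        rows += [parent_seq, mutant_seq]

    half = (spec.length + 1) / 2
    sym_pairs = sorted(
        (k, spec.length + 1 - k, k) for k in spec.symmetric_offsets if k != half
    )
    truth = {
        "consensus": mutant_seq,
        "candidates": sorted(
            (pos, p_res, m_res) for pos, (p_res, m_res) in plants.items()
        ),
        "symmetric_pairs": sym_pairs,
    }
    return FixtureResult(
        family=AlignedFamily(ids=ids, rows=rows),
        parent=SequenceRecord(id=PARENT_ID, seq=parent_seq),
        mutant=SequenceRecord(id=MUTANT_ID, seq=mutant_seq),
        truth=truth,
    )


def write_fixture(result: FixtureResult, outdir: str | Path) -> None:
    """Write family.fasta, parent.fasta, mutant.fasta and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_alignment(result.family, outdir / "family.fasta")
    write_sequence(result.parent, outdir / "parent.fasta")
    write_sequence(result.mutant, outdir / "mutant.fasta")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("kind\tposition\tparent_res\tmutant_res\tpartner\toffset\n")
        for pos, p_res, m_res in result.truth["candidates"]:
            fh.write(f"candidate\t{pos}\t{p_res}\t{m_res}\t\t\n")
        for i, j, k in result.truth["symmetric_pairs"]:
            fh.write(f"symmetric_pair\t{i}\t\t\t{j}\t{k}\n")
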