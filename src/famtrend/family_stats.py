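"""Per-column residue distributions, family consensus and conservation."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from famtrend.errors import FamtrendError
from famtrend.sequence_io import GAP, AlignedFamily


@dataclass
class ColumnDistribution:
    """Residue counts and frequencies of one alignment column.

    ``frequencies`` are computed over non-gap entries unless the
    distribution was built gap-inclusively; ``modal_residue`` is None for
    an all-gap column.
    """

    column: int  # 1-based
    counts: dict[str, int]  # residue letter -> count (no gap key)
    gap_count: int
    frequencies: dict[str, float]
    modal_residue: str | None
    modal_frequency: float


@dataclass
class ConsensusSequence:
    """Aligned consensus string plus the per-column modal frequency."""

    seq: str  # length L; '-' at all-gap columns
    modal_frequencies: list[float]  # 0.0 at all-gap columns

    def degapped(self) -> str:
        return self.seq.replace(GAP, "")


def column_distribution(
    family: AlignedFamily, column: int, include_gaps: bool = False
) -> ColumnDistribution:
    """Distribution of residues in one 1-based column.

    With ``include_gaps`` the frequency denominator is the row count n
    rather than the number of non-gap entries.
    """
    chars = family.column(column)  # validates range
    counts = Counter(c for c in chars if c != GAP)
    gap_count = len(chars) - sum(counts.values())
    denom = family.n if include_gaps else sum(counts.values())
    if denom:
        freqs = {res: cnt / denom for res, cnt in counts.items()}
    else:
        freqs = {}
    if counts:
        # max count, ties broken alphabetically by one-letter code
        modal = min(counts, key=lambda r: (-counts[r], r))
        modal_freq = freqs.get(modal, 0.0)
    else:
        modal, modal_freq = None, 0.0
    return ColumnDistribution(
        column=column,
        counts=dict(counts),
        gap_count=gap_count,
        frequencies=freqs,
        modal_residue=modal,
        modal_frequency=modal_freq,
    )


def consensus(family: AlignedFamily) -> ConsensusSequence:
    """Per-column most frequent non-gap residue (alphabetical tie-break)."""
    chars: list[str] = []
    freqs: list[float] = []
    for col in range(1, family.length + 1):
        dist = column_distribution(family, col)
        if dist.modal_residue is None:
            chars.append(GAP)
            freqs.append(0.0)
        else:
            chars.append(dist.modal_residue)
            freqs.append(dist.modal_frequency)
    return ConsensusSequence(seq="".join(chars), modal_frequencies=freqs)


def reference_match_profile(
    family: AlignedFamily, reference_id: str
) -> list[float | None]:
    """Fraction of rows sharing the reference's residue, per column.

    The reference itself is included in the numerator and denominator, so
    defined values lie in (0, 1]. Columns where the reference has a gap
    yield None.
    """
    ref_row = family.row(reference_id)
    profile: list[float | None] = []
    for col in range(family.length):
        ref_char = ref_row[col]
        if ref_char == GAP:
            profile.append(None)
            continue
        hits = sum(1 for r in family.rows if r[col] == ref_char)
        profile.append(hits / family.n)
    return profile


def conserved_columns(
    family: AlignedFamily, threshold: float = 0.9
) -> list[tuple[int, str, float]]:
    """Columns whose modal non-gap frequency reaches ``threshold``.

    Mostly-gap columns (more than half the rows gapped) are excluded to
    avoid consensus artifacts at filler-heavy termini. Returns 1-based
    (column, modal residue, modal frequency) tuples.
    """
    if not 0.0 < threshold <= 1.0:
        raise FamtrendError(f"threshold must be in (0, 1], got {threshold}")
    out = []
    for col in range(1, family.length + 1):
        dist = column_distribution(family, col)
        non_gap = family.n - dist.gap_count
        if 2 * non_gap < family.n:
            continue
        if dist.modal_residue is not None and dist.modal_frequency >= threshold:
            out.append((col, dist.modal_residue, dist.modal_frequency))
    return out


def write_distribution(
    family: AlignedFamily, path: str | Path, columns=None, header_comment: str = ""
) -> None:
    """TSV export: column, residue, count, frequency (plus gap rows)."""
    cols = columns if columns is not None else range(1, family.length + 1)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("column\tresidue\tcount\tfrequency\n")
        for col in cols:
            dist = column_distribution(family, col)
            for res in sorted(dist.counts):
                fh.write(
                    f"{col}\t{res}\t{dist.counts[res]}\t{dist.frequencies[res]:.6g}\n"
                )
            if dist.gap_count:
                fh.write(f"{col}\t-\t{dist.gap_count}\t\n")


def write_consensus(cons: ConsensusSequence, path: str | Path, seq_id: str = "consensus") -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq_id}\n{cons.seq}\n")
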