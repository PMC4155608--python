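"""Parent-vs-mutant diffing and candidate functional-mutation detection.

``diff_runs`` finds maximal runs of differing alignment columns between
two aligned rows. ``consensus_candidates`` flags the substituted columns
where the mutant agrees with the family consensus, and
``symmetric_pairs`` finds candidate positions equidistant from the two
sequence termini.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from famtrend.errors import FamtrendError
from famtrend.family_stats import column_distribution, consensus
from famtrend.sequence_io import GAP, AlignedFamily


@dataclass
class MutationRun:
    """A maximal contiguous block of differing columns (1-based inclusive)."""

    start: int
    end: int
    ref_seq: str  # reference characters over [start, end]
    alt_seq: str  # alternate characters over [start, end]
    n_substituted: int  # residue <-> residue
    n_inserted: int  # ref gap, alt residue ("created")
    n_deleted: int  # ref residue, alt gap ("deleted")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DiffResult:
    runs: list[MutationRun]
    run_count: int
    total_columns: int  # differing columns summed over runs


@dataclass
class CandidateMutation:
    """A substituted column annotated with consensus/conservation/symmetry."""

    column: int  # 1-based alignment column
    parent_position: int  # 1-based position in the parent's degapped sequence
    parent_residue: str
    mutant_residue: str
    consensus_residue: str
    consensus_frequency: float
    mutant_matches_consensus: bool
    parent_matches_consensus: bool
    highly_conserved: bool
    symmetric_partner: int | None = None  # partner parent_position, if paired


def diff_runs(ref_row: str, alt_row: str) -> DiffResult:
    """Maximal runs of columns at which two aligned rows differ.

    A column differs when its characters are unequal: residue-residue
    (substituted), gap-residue (inserted in the alternate), or
    residue-gap (deleted). Gap-gap columns never differ.
    """
    if len(ref_row) != len(alt_row):
        raise FamtrendError(
            f"row length mismatch: {len(ref_row)} vs {len(alt_row)}"
        )
    runs: list[MutationRun] = []
    start = None
    for col, (r, a) in enumerate(zip(ref_row + GAP, alt_row + GAP)):
        # sentinel equal pair at the end closes any open run
        differs = r != a if col < len(ref_row) else False
        if differs and start is None:
            start = col
        elif not differs and start is not None:
            ref_seg = ref_row[start:col]
            alt_seg = alt_row[start:col]
            n_ins = sum(1 for x in ref_seg if x == GAP)
            n_del = sum(1 for x in alt_seg if x == GAP)
            runs.append(
                MutationRun(
                    start=start + 1,
                    end=col,
                    ref_seq=ref_seg,
                    alt_seq=alt_seg,
                    n_substituted=len(ref_seg) - n_ins - n_del,
                    n_inserted=n_ins,
                    n_deleted=n_del,
                )
            )
            start = None
    total = sum(r.length for r in runs)
    return DiffResult(runs=runs, run_count=len(runs), total_columns=total)


def _degapped_positions(row: str) -> dict[int, int]:
    """Map 1-based alignment column -> 1-based degapped position."""
    pos = 0
    out = {}
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            pos += 1
            out[col] = pos
    return out


def consensus_candidates(
    family: AlignedFamily,
    parent_id: str,
    mutant_id: str,
    threshold: float = 0.9,
) -> list[CandidateMutation]:
    """Candidate mutations: columns where parent and mutant residues differ.

    Indel columns are skipped — a candidate needs a residue on both
    sides. Consensus residue and modal frequency come from the whole
    family; ``highly_conserved`` means modal frequency >= ``threshold``.
    The list is sorted by descending consensus frequency, then column.
    """
    parent_row = family.row(parent_id)
    mutant_row = family.row(mutant_id)
    cons = consensus(family)
    parent_pos = _degapped_positions(parent_row)
    candidates: list[CandidateMutation] = []
    for col in range(1, family.length + 1):
        p, m = parent_row[col - 1], mutant_row[col - 1]
        if p == m or p == GAP or m == GAP:
            continue
        c_res = cons.seq[col - 1]
        c_freq = cons.modal_frequencies[col - 1]
        candidates.append(
            CandidateMutation(
                column=col,
                parent_position=parent_pos[col],
                parent_residue=p,
                mutant_residue=m,
                consensus_residue=c_res,
                consensus_frequency=c_freq,
                mutant_matches_consensus=(m == c_res),
                parent_matches_consensus=(p == c_res),
                highly_conserved=(c_freq >= threshold),
            )
        )
    candidates.sort(key=lambda c: (-c.consensus_frequency, c.column))
    return candidates


def symmetric_pairs(
    candidates: list[CandidateMutation], parent_length: int
) -> list[tuple[int, int, int]]:
    """Pairs of candidate positions equidistant from the two termini.

    Positions are the parent's degapped residue numbers. A pair (i, j),
    i < j, is symmetric when i + j = L + 1 where L is the parent's
    degapped length; the reported offset is i (distance from the start,
    equal to j's distance from the far end). The exact-center position
    cannot pair with itself. Pair members are annotated in place via
    ``symmetric_partner``.
    """
    by_pos = {c.parent_position: c for c in candidates}
    pairs: list[tuple[int, int, int]] = []
    for i in sorted(by_pos):
        j = parent_length + 1 - i
        if j > i and j in by_pos:
            pairs.append((i, j, i))
            by_pos[i].symmetric_partner = j
            by_pos[j].symmetric_partner = i
    return pairs


REPORT_COLUMNS = (
    "column",
    "parent_pos",
    "parent_res",
    "mutant_res",
    "consensus_res",
    "consensus_freq",
    "highly_conserved",
    "matches_consensus",
    "symmetric_partner",
)


def candidate_report(
    candidates: list[CandidateMutation],
    pairs: list[tuple[int, int, int]] | None = None,
) -> list[dict]:
    """TSV-ready rows, ranked by descending consensus frequency.

    Symmetric-pair members carry their partner's position; they are
    annotated, never dropped — whether a symmetric pair is benign is a
    judgment left to the analyst.
    """
    partner: dict[int, int] = {}
    for i, j, _offset in pairs or []:
        partner[i] = j
        partner[j] = i
    rows = []
    for c in sorted(candidates, key=lambda c: (-c.consensus_frequency, c.column)):
        rows.append({
            "column": c.column,
            "parent_pos": c.parent_position,
            "parent_res": c.parent_residue,
            "mutant_res": c.mutant_residue,
            "consensus_res": c.consensus_residue,
            "consensus_freq": round(c.consensus_frequency, 6),
            "highly_conserved": c.highly_conserved,
            "matches_consensus": c.mutant_matches_consensus,
            "symmetric_partner": partner.get(
                c.parent_position, c.symmetric_partner
            ),
        })
    return rows


def write_candidate_report(
    rows: list[dict], path: str | Path, header_comment: str = ""
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    "" if row[c] is None else str(row[c]) for c in REPORT_COLUMNS
                )
                + "\n"
            )
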