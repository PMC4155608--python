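"""Map alignment columns onto structure residues; measure site proximity.

The mapper runs a semiglobal pairwise alignment (terminal gaps free) of
a family row's degapped sequence against the residues observed in a
coordinate chain, so structures with truncated termini or missing
interior residues still map cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from scipy.spatial.distance import cdist

from famtrend.errors import FamtrendError, LowIdentityError, MissingIdError
from famtrend.sequence_io import GAP, StructureChain


@dataclass
class ColumnResidueMap:
    """One-to-one, order-preserving pairing of columns and residue keys."""

    pairs: list[tuple[int, str]]  # (1-based alignment column, residue key)
    mismatches: list[tuple[int, str]]  # mapped pairs whose residues differ
    unmatched_columns: list[int]
    unmatched_residues: list[str]
    identity: float  # fraction of aligned pairs with identical residues

    def key_for_column(self, column: int) -> str:
        for col, key in self.pairs:
            if col == column:
                return key
        raise MissingIdError(f"alignment column {column} has no mapped residue")


@dataclass
class ProximityResult:
    """Minimum heavy-atom distances from candidate residues to a site."""

    distances: dict[str, float]  # residue key -> Å
    within_cutoff: dict[str, bool]
    cutoff: float


def _aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    # semiglobal: terminal gaps on either sequence are free
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # biopython < 1.88 names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def map_columns_to_structure(
    family_row: str,
    chain: StructureChain,
    min_identity: float = 0.30,
) -> ColumnResidueMap:
    """Pair alignment columns with the chain's residues.

    Aligns the degapped row against the chain sequence (match +1,
    mismatch -1, gap -2, free terminal gaps). Mismatched aligned pairs
    are still mapped but listed in ``mismatches``. Refuses (raises
    :class:`LowIdentityError`) when identity over aligned pairs falls
    below ``min_identity`` — usually a sign of the wrong chain.
    """
    columns = [i + 1 for i, ch in enumerate(family_row) if ch != GAP]
    seq = family_row.replace(GAP, "")
    if not seq:
        raise FamtrendError("row has no residues to map")
    if not chain.residues:
        raise FamtrendError(f"chain {chain.chain_id} has no residues")
    alignment = _aligner().align(seq, chain.sequence)[0]
    pairs: list[tuple[int, str]] = []
    mismatches: list[tuple[int, str]] = []
    matched_cols: set[int] = set()
    matched_res: set[int] = set()
    n_ident = 0
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        for qi, ti in zip(range(qs, qe), range(ts, te)):
            col = columns[qi]
            key = chain.residues[ti].key
            pairs.append((col, key))
            matched_cols.add(qi)
            matched_res.add(ti)
            if seq[qi] == chain.residues[ti].code:
                n_ident += 1
            else:
                mismatches.append((col, key))
    identity = n_ident / len(pairs) if pairs else 0.0
    if not pairs and min_identity > 0:
        raise LowIdentityError("no residues could be aligned to the chain")
    if identity < min_identity:
        raise LowIdentityError(
            f"sequence/structure identity {identity:.1%} below threshold "
            f"{min_identity:.1%}; is {chain.chain_id!r} the right chain?"
        )
    return ColumnResidueMap(
        pairs=pairs,
        mismatches=mismatches,
        unmatched_columns=[columns[i] for i in range(len(seq)) if i not in matched_cols],
        unmatched_residues=[
            chain.residues[i].key
            for i in range(len(chain.residues))
            if i not in matched_res
        ],
        identity=identity,
    )


def site_proximity(
    candidates: list[str],
    site: list[str],
    chain: StructureChain,
    cutoff: float,
) -> ProximityResult:
    """Minimum heavy-atom distance (Å) from each candidate to the site set.

    Candidates that are themselves site members get distance 0. Raises
    on unknown residue keys or a non-positive cutoff.
    """
    if cutoff <= 0:
        raise FamtrendError(f"cutoff must be > 0 Å, got {cutoff}")
    if not site:
        raise FamtrendError("site residue set is empty")
    site_set = set(site)
    site_coords = np.vstack([chain.residue(k).coords for k in site])
    distances: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for key in candidates:
        res = chain.residue(key)  # raises MissingIdError on unknown key
        if key in site_set:
            d = 0.0
        else:
            d = float(cdist(res.coords, site_coords).min())
        distances[key] = d
        flags[key] = d <= cutoff
    return ProximityResult(distances=distances, within_cutoff=flags, cutoff=cutoff)


def selection_string(residue_keys: list[str], chain_id: str) -> str:
    """Viewer-agnostic selection text: ``chain A and resi 10+23+107A``."""
    if not residue_keys:
        raise FamtrendError("selection requires at least one residue key")

    def sort_key(k: str):
        num = "".join(ch for ch in k if ch.isdigit() or ch == "-")
        icode = k[len(num):]
        return (int(num), icode)

    keys = sorted(set(residue_keys), key=sort_key)
    return f"chain {chain_id} and resi " + "+".join(keys)


def write_proximity_report(
    result: ProximityResult, path: str | Path, header_comment: str = ""
) -> None:
    """TSV export: residue key, min distance (Å), within-cutoff flag."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("residue\tmin_distance_A\twithin_cutoff\n")
        for key, d in result.distances.items():
            fh.write(f"{key}\t{d:.3f}\t{result.within_cutoff[key]}\n")
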