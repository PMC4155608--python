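"""Sorting weights for the trend image: seven sequence-similarity metrics.

All string metrics treat 'X' (unknown residue) as matching nothing, not
even another 'X'. Edit distances operate on degapped sequences; the
positional/compositional counters and the fragment-frequency weight
operate on aligned rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from famtrend.errors import FamtrendError
from famtrend.residue_schemes import ResidueScheme, get_scheme
from famtrend.sequence_io import GAP, UNKNOWN, AlignedFamily

#: Metrics where a smaller weight means more similar.
DISTANCE_METRICS = frozenset({"edit", "weighted_edit", "selected_edit"})

#: Metrics where a larger weight means more similar.
SIMILARITY_METRICS = frozenset({
    "fragment_frequency",
    "common_positional",
    "common_positional_pct",
    "common_compositional",
    "common_compositional_pct",
    "ngram_common",
})

METRIC_NAMES = tuple(sorted(DISTANCE_METRICS | SIMILARITY_METRICS))


def _chars_match(a: str, b: str) -> bool:
    # 'X' never matches, not even itself
    return a == b and a != UNKNOWN


def _levenshtein(a: str, b: str, sub_cost) -> float:
    """Row-wise DP; ``sub_cost(x, y)`` gives the substitution cost."""
    if not a:
        return float(len(b))
    if not b:
        return float(len(a))
    prev = np.arange(len(b) + 1, dtype=float)
    cur = np.empty(len(b) + 1, dtype=float)
    for i, ca in enumerate(a, start=1):
        cur[0] = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1.0,  # delete ca
                cur[j - 1] + 1.0,  # insert cb
                prev[j - 1] + sub_cost(ca, cb),
            )
        prev, cur = cur, prev
    return float(prev[len(b)])


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit costs on degapped sequences."""
    a = a.replace(GAP, "")
    b = b.replace(GAP, "")
    return int(_levenshtein(a, b, lambda x, y: 0.0 if _chars_match(x, y) else 1.0))


def weighted_edit_distance(a: str, b: str, scheme: ResidueScheme | str) -> float:
    """Levenshtein with class-aware substitution costs.

    Substituting two different residues of the same scheme class costs
    0.5; different classes (or 'X' on either side) cost 1; identical
    non-'X' residues cost 0. Insertions/deletions cost 1.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if not scheme.is_partition:
        raise FamtrendError(
            f"scheme {scheme.name!r} is not a partition and cannot weight edits"
        )

    def cost(x: str, y: str) -> float:
        if _chars_match(x, y):
            return 0.0
        if x == UNKNOWN or y == UNKNOWN:
            return 1.0
        cx, cy = scheme.class_of(x), scheme.class_of(y)
        if cx is not None and cx is cy:
            return 0.5
        return 1.0

    a = a.replace(GAP, "")
    b = b.replace(GAP, "")
    return _levenshtein(a, b, cost)


def common_residues(
    a_row: str, b_row: str, positional: bool = True
) -> tuple[int, float]:
    """Count of common residues between two aligned rows, plus a percentage.

    Positional mode counts columns where both rows carry the identical
    non-'X' residue. Compositional mode ignores position: it is the size
    of the multiset intersection of the two degapped residue compositions
    ('X' excluded). The percentage divides by the length of the shorter
    degapped sequence (0 when that length is 0).
    """
    if len(a_row) != len(b_row):
        raise FamtrendError(
            f"row length mismatch: {len(a_row)} vs {len(b_row)}"
        )
    if positional:
        count = sum(
            1 for x, y in zip(a_row, b_row) if x != GAP and _chars_match(x, y)
        )
    else:
        from collections import Counter

        ca = Counter(c for c in a_row if c not in (GAP, UNKNOWN))
        cb = Counter(c for c in b_row if c not in (GAP, UNKNOWN))
        count = sum((ca & cb).values())
    denom = min(
        len(a_row) - a_row.count(GAP),
        len(b_row) - b_row.count(GAP),
    )
    pct = 100.0 * count / denom if denom else 0.0
    return count, pct


def ngram_common(a: str, b: str, n: int = 3) -> int:
    """Number of distinct length-``n`` substrings the two sequences share.

    Substrings containing 'X' are excluded (unknown residues match
    nothing). Sequences shorter than ``n`` contribute an empty set.
    """
    if n < 1:
        raise FamtrendError(f"n-gram length must be >= 1, got {n}")

    def grams(s: str) -> set[str]:
        s = s.replace(GAP, "")
        return {
            s[i : i + n]
            for i in range(len(s) - n + 1)
            if UNKNOWN not in s[i : i + n]
        }

    return len(grams(a) & grams(b))


def selected_edit_distance(a_row: str, b_row: str, columns) -> int:
    """Edit distance restricted to a set of 1-based alignment columns.

    Both rows are projected onto the selected columns (in column order),
    gaps are dropped from each projection independently, and the plain
    edit distance of the projections is returned.
    """
    cols = sorted(set(columns))
    if not cols:
        raise FamtrendError("selected_edit_distance requires a nonempty column set")
    L = len(a_row)
    if len(b_row) != L:
        raise FamtrendError(f"row length mismatch: {L} vs {len(b_row)}")
    if cols[0] < 1 or cols[-1] > L:
        raise FamtrendError(f"selected columns outside [1, {L}]")
    pa = "".join(a_row[c - 1] for c in cols).replace(GAP, "")
    pb = "".join(b_row[c - 1] for c in cols).replace(GAP, "")
    return edit_distance(pa, pb)


def fragment_frequency_weight(
    family: AlignedFamily, row_index: int, window: tuple[int, int] | None = None
) -> float:
    """Fraction of family rows identical to this row over a column window.

    ``window`` is a 1-based inclusive (start, end) pair; the default is
    the full alignment width. Comparison is character-exact, gaps
    included, so the value is always in (0, 1].
    """
    start, end = window if window is not None else (1, family.length)
    if not (1 <= start <= end <= family.length):
        raise FamtrendError(
            f"window ({start}, {end}) invalid for alignment of width {family.length}"
        )
    frag = family.rows[row_index][start - 1 : end]
    hits = sum(1 for r in family.rows if r[start - 1 : end] == frag)
    return hits / family.n


@dataclass(frozen=True)
class MetricSpec:
    """A sorting metric plus its parameters.

    ``n`` applies to ngram_common, ``scheme`` to weighted_edit,
    ``window`` (1-based inclusive) to fragment_frequency and ``columns``
    (1-based set) to selected_edit.
    """

    name: str
    n: int = 3
    scheme: str = "polarity"
    window: tuple[int, int] | None = None
    columns: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.name not in METRIC_NAMES:
            raise FamtrendError(
                f"unknown metric {self.name!r}; valid metrics: {', '.join(METRIC_NAMES)}"
            )
        if self.n < 1:
            raise FamtrendError(f"n must be >= 1, got {self.n}")

    @property
    def larger_is_more_similar(self) -> bool:
        return self.name in SIMILARITY_METRICS


@dataclass
class SortResult:
    """Per-row weights relative to a reference and the induced row order."""

    reference_id: str
    spec: MetricSpec
    weights: list[float]
    order: list[int]  # permutation of row indices, most similar first

    def ranked_ids(self, family: AlignedFamily) -> list[str]:
        return [family.ids[i] for i in self.order]


def sort_family(family: AlignedFamily, reference_id: str, spec: MetricSpec) -> SortResult:
    """Weight every row against the reference and order rows by weight.

    Distance metrics sort ascending (reference first with weight 0),
    similarity metrics descending. Ties keep the original row order.
    """
    ref_idx = family.index(reference_id)
    ref_row = family.rows[ref_idx]
    weights: list[float] = []
    for i, row in enumerate(family.rows):
        name = spec.name
        if name == "edit":
            w: float = edit_distance(ref_row, row)
        elif name == "weighted_edit":
            w = weighted_edit_distance(ref_row, row, spec.scheme)
        elif name == "selected_edit":
            cols = spec.columns if spec.columns else frozenset(range(1, family.length + 1))
            w = selected_edit_distance(ref_row, row, cols)
        elif name == "common_positional":
            w = common_residues(ref_row, row, positional=True)[0]
        elif name == "common_positional_pct":
            w = common_residues(ref_row, row, positional=True)[1]
        elif name == "common_compositional":
            w = common_residues(ref_row, row, positional=False)[0]
        elif name == "common_compositional_pct":
            w = common_residues(ref_row, row, positional=False)[1]
        elif name == "ngram_common":
            w = ngram_common(ref_row.replace(GAP, ""), row.replace(GAP, ""), spec.n)
        elif name == "fragment_frequency":
            w = fragment_frequency_weight(family, i, spec.window)
        else:  # pragma: no cover - guarded by MetricSpec
            raise FamtrendError(f"unknown metric {name!r}")
        weights.append(float(w))
    sign = -1.0 if spec.larger_is_more_similar else 1.0
    order = sorted(range(family.n), key=lambda i: (sign * weights[i], i))
    return SortResult(reference_id=reference_id, spec=spec, weights=weights, order=order)


def write_sort_result(
    result: SortResult, family: AlignedFamily, path: str | Path, header_comment: str = ""
) -> None:
    """Export a SortResult as TSV with columns rank, id, weight."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("rank\tid\tweight\n")
        for rank, idx in enumerate(result.order, start=1):
            fh.write(f"{rank}\t{family.ids[idx]}\t{result.weights[idx]:g}\n")
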