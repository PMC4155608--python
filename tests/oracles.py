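"""Independent brute-force oracles used to check the package's metrics.

Everything here is deliberately naive (plain recursion, full
enumeration) and shares no code with the implementation under test.
"""

from __future__ import annotations

from collections import Counter
from functools import lru_cache


def brute_levenshtein(a: str, b: str, sub_cost=None) -> float:
    """Recursive edit distance; unit indels, pluggable substitution cost."""
    if sub_cost is None:
        sub_cost = lambda x, y: 0.0 if x == y else 1.0

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> float:
        if i == len(a):
            return float(len(b) - j)
        if j == len(b):
            return float(len(a) - i)
        return min(
            go(i + 1, j) + 1.0,
            go(i, j + 1) + 1.0,
            go(i + 1, j + 1) + sub_cost(a[i], b[j]),
        )

    return go(0, 0)


def brute_positional_common(a_row: str, b_row: str) -> int:
    return sum(
        1
        for x, y in zip(a_row, b_row)
        if x == y and x not in "-X"
    )


def brute_compositional_common(a_row: str, b_row: str) -> int:
    ca = Counter(c for c in a_row if c not in "-X")
    cb = Counter(c for c in b_row if c not in "-X")
    return sum(min(ca[k], cb[k]) for k in set(ca) | set(cb))


def brute_ngrams(s: str, n: int) -> set[str]:
    s = s.replace("-", "")
    return {
        s[i : i + n] for i in range(len(s) - n + 1) if "X" not in s[i : i + n]
    }


def brute_column_counts(rows: list[str], col0: int) -> tuple[Counter, int]:
    """(residue counts, gap count) of a 0-based column."""
    chars = [r[col0] for r in rows]
    counts = Counter(c for c in chars if c != "-")
    return counts, chars.count("-")


def brute_diff_columns(a: str, b: str) -> list[int]:
    """0-based columns where the two aligned rows differ."""
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def brute_min_distance(coords_a, coords_b) -> float:
    """All-pairs minimum Euclidean distance, pure Python."""
    best = float("inf")
    for ax, ay, az in coords_a:
        for bx, by, bz in coords_b:
            d = ((ax - bx) ** 2 + (ay - by) ** 2 + (az - bz) ** 2) ** 0.5
            best = min(best, d)
    return best
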