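"""Render the trend image: one pixel block per residue, one row per sequence.

Cell colors follow the active scheme; internal gaps are white, terminal
filler gray, out-of-scheme residues black. Up to two column-window
"paddles" may be overlaid by darkening the covered pixels. Rendering is
bit-exact deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from famtrend.errors import FamtrendError
from famtrend.family_stats import column_distribution
from famtrend.residue_schemes import (
    FREQ_BIN_COLORS,
    ResidueScheme,
    cell_color,
    frequency_bin,
    get_scheme,
    write_legend,
)
from famtrend.sequence_io import GAP, AlignedFamily, terminal_filler_mask
from famtrend.similarity import SortResult

#: Multiplier applied to pixels under a paddle window.
PADDLE_DARKEN = 0.7


@dataclass
class TrendRaster:
    """The rendered trend image plus the metadata to interpret it."""

    pixels: np.ndarray  # (n*row_scale, L*col_scale, 3) uint8
    row_order: list[int]  # family row index per image row block, top to bottom
    scheme_name: str
    paddles: tuple[tuple[int, int], ...] = ()

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def _resolve_order(family: AlignedFamily, order) -> list[int]:
    if order is None:
        return list(range(family.n))
    if isinstance(order, SortResult):
        return list(order.order)
    return list(order)


def _validate_paddles(paddles, length: int) -> tuple[tuple[int, int], ...]:
    paddles = tuple(paddles or ())
    if len(paddles) > 2:
        raise FamtrendError(
            f"at most 2 paddle windows supported, got {len(paddles)}"
        )
    for start, end in paddles:
        if not (1 <= start <= end <= length):
            raise FamtrendError(
                f"paddle window ({start}, {end}) outside [1, {length}]"
            )
    return paddles


def _finish(
    grid: np.ndarray,
    family: AlignedFamily,
    row_order: list[int],
    scheme_name: str,
    paddles,
    row_scale: int,
    col_scale: int,
) -> TrendRaster:
    if row_scale < 1 or col_scale < 1:
        raise FamtrendError("row_scale and col_scale must be >= 1")
    for start, end in paddles:
        block = grid[:, start - 1 : end, :].astype(np.float64) * PADDLE_DARKEN
        grid[:, start - 1 : end, :] = block.astype(np.uint8)
    pixels = np.repeat(np.repeat(grid, row_scale, axis=0), col_scale, axis=1)
    return TrendRaster(
        pixels=pixels,
        row_order=row_order,
        scheme_name=scheme_name,
        paddles=tuple(paddles),
    )


def render(
    family: AlignedFamily,
    order: SortResult | list[int] | None = None,
    scheme: ResidueScheme | str = "chemical",
    row_scale: int = 1,
    col_scale: int = 1,
    paddles=(),
) -> TrendRaster:
    """Render the family as a trend raster under a partition scheme."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if not scheme.is_partition:
        raise FamtrendError(
            "use fragment_frequency_render for the fragment_frequency scheme"
        )
    paddles = _validate_paddles(paddles, family.length)
    row_order = _resolve_order(family, order)
    filler = terminal_filler_mask(family)
    grid = np.zeros((family.n, family.length, 3), dtype=np.uint8)
    for out_r, fam_r in enumerate(row_order):
        row = family.rows[fam_r]
        (l0, l1), (t0, t1) = filler[fam_r]
        for col, ch in enumerate(row):
            if l0 <= col < l1 or t0 <= col < t1:
                grid[out_r, col] = scheme.filler_color
            else:
                grid[out_r, col] = cell_color(scheme, ch)
    return _finish(grid, family, row_order, scheme.name, paddles, row_scale, col_scale)


def fragment_frequency_render(
    family: AlignedFamily,
    order: SortResult | list[int] | None = None,
    window: tuple[int, int] | None = None,
    row_scale: int = 1,
    col_scale: int = 1,
) -> TrendRaster:
    """Render with cells colored by their column's residue frequency.

    Each non-gap cell gets the 5-bin sequential color of the frequency of
    its own residue within its column (non-gap denominator). Gap and
    filler rules are unchanged. ``window`` is an optional paddle overlay.
    """
    scheme = get_scheme("fragment_frequency")
    paddles = _validate_paddles([window] if window else (), family.length)
    row_order = _resolve_order(family, order)
    filler = terminal_filler_mask(family)
    freq_by_col = [
        column_distribution(family, col).frequencies
        for col in range(1, family.length + 1)
    ]
    grid = np.zeros((family.n, family.length, 3), dtype=np.uint8)
    for out_r, fam_r in enumerate(row_order):
        row = family.rows[fam_r]
        (l0, l1), (t0, t1) = filler[fam_r]
        for col, ch in enumerate(row):
            if l0 <= col < l1 or t0 <= col < t1:
                grid[out_r, col] = scheme.filler_color
            elif ch == GAP:
                grid[out_r, col] = scheme.gap_color
            else:
                freq = freq_by_col[col].get(ch, 0.0)
                grid[out_r, col] = FREQ_BIN_COLORS[frequency_bin(freq)]
    return _finish(
        grid, family, row_order, scheme.name, paddles, row_scale, col_scale
    )


def write_raster(raster: TrendRaster, path: str | Path) -> None:
    """Write the raster as PNG, with a sidecar ``<stem>.legend.tsv``."""
    path = Path(path)
    Image.fromarray(raster.pixels, mode="RGB").save(path, format="PNG")
    write_legend(get_scheme(raster.scheme_name), path.with_suffix(".legend.tsv"))


def read_raster_pixels(path: str | Path) -> np.ndarray:
    """Decode a PNG back into an (H, W, 3) uint8 array."""
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
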