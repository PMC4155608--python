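"""Named amino-acid classification schemes and their display colors.

Four partition schemes (chemical, polarity, charge, solvent_contact)
assign each standard residue to exactly one class; the fifth scheme,
``fragment_frequency``, is not a partition — it colors cells by the
binned per-column frequency of the residue and is handled by the raster
module through :data:`FREQ_BIN_EDGES` / :data:`FREQ_BIN_COLORS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from famtrend.errors import FamtrendError
from famtrend.sequence_io import GAP, STANDARD_RESIDUES, UNKNOWN

RGB = tuple[int, int, int]

GAP_COLOR: RGB = (255, 255, 255)
FILLER_COLOR: RGB = (190, 190, 190)
UNASSIGNED_COLOR: RGB = (0, 0, 0)

# Okabe-Ito colorblind-safe qualitative palette.
_QUAL = [
    (230, 159, 0),    # orange
    (86, 180, 233),   # sky blue
    (0, 158, 115),    # bluish green
    (240, 228, 66),   # yellow
    (0, 114, 178),    # blue
    (213, 94, 0),     # vermillion
    (204, 121, 167),  # reddish purple
]

#: Upper edges of the first four frequency bins (fifth bin is (0.8, 1]).
FREQ_BIN_EDGES: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)

#: Sequential 5-color palette, low to high frequency.
FREQ_BIN_COLORS: tuple[RGB, ...] = (
    (239, 243, 255),
    (189, 215, 231),
    (107, 174, 214),
    (49, 130, 189),
    (8, 81, 156),
)


@dataclass(frozen=True)
class ResidueClass:
    name: str
    members: frozenset[str]
    color: RGB


@dataclass(frozen=True)
class ResidueScheme:
    """A named partition of the 20 residues into colored classes."""

    name: str
    classes: tuple[ResidueClass, ...]
    gap_color: RGB = GAP_COLOR
    filler_color: RGB = FILLER_COLOR
    unassigned_color: RGB = UNASSIGNED_COLOR
    is_partition: bool = True
    _lookup: dict[str, ResidueClass] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        lookup: dict[str, ResidueClass] = {}
        for cls in self.classes:
            for res in cls.members:
                if res in lookup:
                    raise FamtrendError(
                        f"scheme {self.name}: residue {res} in two classes"
                    )
                if res not in STANDARD_RESIDUES:
                    raise FamtrendError(
                        f"scheme {self.name}: {res!r} is not a standard residue"
                    )
                lookup[res] = cls
        object.__setattr__(self, "_lookup", lookup)

    def class_of(self, residue: str) -> ResidueClass | None:
        return self._lookup.get(residue)


def _scheme(name: str, groups: list[tuple[str, str]], *, partition: bool = True) -> ResidueScheme:
    classes = tuple(
        ResidueClass(cname, frozenset(members), _QUAL[i % len(_QUAL)])
        for i, (cname, members) in enumerate(groups)
    )
    return ResidueScheme(name=name, classes=classes, is_partition=partition)


_SCHEMES: dict[str, ResidueScheme] = {
    "chemical": _scheme("chemical", [
        ("aliphatic", "GAVLIP"),
        ("aromatic", "FYW"),
        ("sulfur", "CM"),
        ("hydroxyl", "ST"),
        ("basic", "KRH"),
        ("acidic_amide", "DENQ"),
    ]),
    "polarity": _scheme("polarity", [
        ("nonpolar", "GAVLIPFMW"),
        ("polar_uncharged", "STCYNQ"),
        ("polar_charged", "DEKRH"),
    ]),
    "charge": _scheme("charge", [
        ("positive", "KRH"),
        ("negative", "DE"),
        ("neutral", "GAVLIPFMWSTCYNQ"),
    ]),
    # hydrophobic = positive Kyte-Doolittle hydropathy
    "solvent_contact": _scheme("solvent_contact", [
        ("buried", "AVLIMFC"),
        ("exposed", "GPSTWYNQDEKRH"),
    ]),
    "fragment_frequency": _scheme("fragment_frequency", [], partition=False),
}

SCHEME_NAMES = tuple(_SCHEMES)


def get_scheme(name: str) -> ResidueScheme:
    """Return a scheme by name; raises listing valid names if unknown."""
    try:
        return _SCHEMES[name]
    except KeyError:
        raise FamtrendError(
            f"unknown scheme {name!r}; valid schemes: {', '.join(SCHEME_NAMES)}"
        ) from None


def classify(scheme: ResidueScheme | str, residue: str) -> str:
    """Class name of ``residue`` under ``scheme``, or ``"gap"``/``"unassigned"``.

    '-' maps to "gap"; 'X' and any residue outside the scheme's classes
    map to "unassigned".
    """
    if len(residue) != 1:
        raise FamtrendError(f"classify expects a single character, got {residue!r}")
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if residue == GAP:
        return "gap"
    if residue == UNKNOWN:
        return "unassigned"
    cls = scheme.class_of(residue)
    return cls.name if cls is not None else "unassigned"


def cell_color(scheme: ResidueScheme, residue: str) -> RGB:
    """Display color of one alignment cell (ignores filler, see raster)."""
    if residue == GAP:
        return scheme.gap_color
    cls = scheme.class_of(residue)
    return cls.color if cls is not None else scheme.unassigned_color


def frequency_bin(freq: float) -> int:
    """0-based bin index of a frequency in [0, 1] over the 5 sequential bins."""
    if not 0.0 <= freq <= 1.0:
        raise FamtrendError(f"frequency {freq} outside [0, 1]")
    for i, edge in enumerate(FREQ_BIN_EDGES):
        if freq < edge:
            return i
    return len(FREQ_BIN_EDGES)


def legend_rows(scheme: ResidueScheme) -> list[tuple[str, str, str, int, int, int]]:
    """Legend as (scheme, class, members, R, G, B) rows, special cells last."""
    rows = [
        (scheme.name, c.name, "".join(sorted(c.members)), *c.color)
        for c in scheme.classes
    ]
    if not scheme.is_partition:
        rows = [
            (scheme.name, f"freq_bin_{i + 1}", "", *color)
            for i, color in enumerate(FREQ_BIN_COLORS)
        ]
    rows.append((scheme.name, "unassigned", "", *scheme.unassigned_color))
    rows.append((scheme.name, "gap", "", *scheme.gap_color))
    rows.append((scheme.name, "filler", "", *scheme.filler_color))
    return rows


def write_legend(scheme: ResidueScheme, path: str | Path) -> None:
    """Write the scheme legend as TSV: scheme, class, members, R, G, B."""
    with open(path, "w") as fh:
        fh.write("scheme\tclass\tmembers\tR\tG\tB\n")
        for row in legend_rows(scheme):
            fh.write("\t".join(str(x) for x in row) + "\n")
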