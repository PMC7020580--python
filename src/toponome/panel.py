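"""Marker panel definitions.

A panel is the ordered list of markers imaged in one cyclic-immunofluorescence
run.  Marker indices start at 0 (the convention of the imaging-cycler software
this package emulates), and every per-pixel combinatorial code is read positionally
against the panel: character ``i`` of a code refers to marker ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered, immutable list of marker names.

    Parameters
    ----------
    names
        Marker names in acquisition order.  Index ``i`` in every binary stack,
        CMP code and signature vector refers to ``names[i]``.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("a panel needs at least 2 markers")
        if len(set(self.names)) != len(self.names):
            raise ValueError("marker names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def validate_marker(self, marker: int) -> int:
        if not 0 <= marker < len(self):
            raise ValueError(f"marker index {marker} outside panel 0..{len(self) - 1}")
        return marker

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """All unordered marker pairs (i, j), i < j, in canonical order."""
        return list(combinations(range(len(self)), 2))


#: The 13-marker alveolar-macrophage panel (indices 0-12): cellular
#: autofluorescence plus 12 immune / cytoskeletal markers.
DEFAULT_PANEL = MarkerPanel(
    (
        "autofluorescence",  # 0  granular AF of the macrophage
        "sialoadhesin",      # 1  CD169
        "CD44",              # 2
        "actin",             # 3
        "tubulin",           # 4
        "CD68",              # 5
        "CD163",             # 6
        "CD45",              # 7
        "CD18",              # 8
        "F4/80",             # 9
        "CD15",              # 10
        "iNOS",              # 11
        "phalloidin",        # 12 filamentous actin
    )
)
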