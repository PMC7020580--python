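"""Per-pixel combinatorial molecular phenotypes (CMPs).

A CMP is a binary code over the marker panel: character ``i`` is '1' when
marker ``i`` reached threshold in that pixel and '0' otherwise, so an n-marker
panel admits 2**n codes.  The all-zero code is reserved as *background* — such
pixels carry no phenotype and are excluded from every table.  This module
merges a :class:`~toponome.image_prep.BinaryStack` into a per-pixel code map,
builds ranked frequency tables (rank 0 = most abundant), filters them by
marker, renders pseudocolored composites, and round-trips code maps through a
plain-text file format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .image_prep import BinaryStack
from .panel import MarkerPanel

#: reserved all-zero code: no marker present, not a phenotype
BACKGROUND = 0


def code_to_bits(code: int, n_markers: int) -> str:
    """Integer code -> positional bit string (character i = marker i)."""
    if not 0 <= code < (1 << n_markers):
        raise ValueError(f"code {code} out of range for {n_markers} markers")
    return "".join("1" if code >> i & 1 else "0" for i in range(n_markers))


def bits_to_code(bits: str) -> int:
    """Positional bit string -> integer code (inverse of :func:`code_to_bits`)."""
    if not bits or set(bits) - {"0", "1"}:
        raise ValueError(f"not a binary code string: {bits!r}")
    return sum(1 << i for i, b in enumerate(bits) if b == "1")


def code_markers(code: int, n_markers: int) -> list[int]:
    """Indices of the markers present in a code."""
    return [i for i in range(n_markers) if code >> i & 1]


def variant_codes(base: int, free_markers: list[int], n_markers: int) -> list[int]:
    """All codes that agree with ``base`` outside ``free_markers``.

    Codes identical on the fixed markers but varying over k free markers form a
    family of 2**k near-identical phenotypes.
    """
    for m in free_markers:
        if not 0 <= m < n_markers:
            raise ValueError(f"marker {m} outside panel")
    if len(set(free_markers)) != len(free_markers):
        raise ValueError("free markers must be distinct")
    fixed = base
    for m in free_markers:
        fixed &= ~(1 << m)
    out = []
    for assignment in range(1 << len(free_markers)):
        code = fixed
        for k, m in enumerate(free_markers):
            if assignment >> k & 1:
                code |= 1 << m
        out.append(code)
    return out


def rank_color(rank: int) -> tuple[int, int, int]:
    """Deterministic palette: a unique, never-black RGB color per rank.

    ``(rank + 1) * 0x9E3779B1 mod 2**24`` — multiplication by an odd constant
    is a bijection on 24-bit values, so distinct ranks can never collide and
    rank 0 can never map to black (reserved for background).
    """
    if rank < 0:
        raise ValueError("rank must be >= 0")
    v = ((rank + 1) * 0x9E3779B1) % (1 << 24)
    return (v >> 16 & 0xFF, v >> 8 & 0xFF, v & 0xFF)


def _color_hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def _hex_color(s: str) -> tuple[int, int, int]:
    s = s.lstrip("#")
    return (int(s[0:2], 16), int(s[2:4], 16), int(s[4:6], 16))


@dataclass
class CMPMap:
    """2D grid of integer CMP codes per pixel (0 = background)."""

    codes: np.ndarray
    panel: MarkerPanel
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2D grid")
        if self.codes.min() < 0 or self.codes.max() >= (1 << len(self.panel)):
            raise ValueError("code values outside panel range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def n_background(self) -> int:
        return int(np.count_nonzero(self.codes == BACKGROUND))


def merge_to_cmp_map(stack: BinaryStack, sample_id: str = "") -> CMPMap:
    """Stack the n binary masks into one integer code per pixel (bit i = marker i)."""
    weights = (1 << np.arange(len(stack.panel), dtype=np.int64))[:, None, None]
    codes = (stack.masks.astype(np.int64) * weights).sum(axis=0)
    return CMPMap(codes=codes, panel=stack.panel, sample_id=sample_id)


def _sort_codes_by_frequency(codes: np.ndarray, counts: np.ndarray, n_markers: int):
    """Order descending by count; ties broken by bit-string ascending."""
    bitstrings = [code_to_bits(int(c), n_markers) for c in codes]
    order = sorted(range(len(codes)), key=lambda k: (-int(counts[k]), bitstrings[k]))
    return order, bitstrings


def frequency_table(cmap: CMPMap) -> pd.DataFrame:
    """Ranked table of every distinct non-background code in the map.

    Columns: ``rank`` (0 = most abundant), ``code`` (bit string), ``frequency``
    (pixel count), ``color_hex``.  Ties in frequency are broken by code string
    ascending so ranks are stable.  ``df.attrs`` carries ``total_distinct``,
    ``n_background`` and ``sample_id``.
    """
    vals, counts = np.unique(cmap.codes, return_counts=True)
    keep = vals != BACKGROUND
    vals, counts = vals[keep], counts[keep]
    order, bitstrings = _sort_codes_by_frequency(vals, counts, len(cmap.panel))
    df = pd.DataFrame(
        {
            "rank": np.arange(len(order)),
            "code": [bitstrings[k] for k in order],
            "frequency": [int(counts[k]) for k in order],
            "color_hex": [_color_hex(rank_color(r)) for r in range(len(order))],
        }
    )
    df.attrs["total_distinct"] = len(df)
    df.attrs["n_background"] = cmap.n_background
    df.attrs["sample_id"] = cmap.sample_id
    return df


def _rerank(df: pd.DataFrame) -> pd.DataFrame:
    out = df.reset_index(drop=True).copy()
    out["rank"] = np.arange(len(out))
    return out


def filter_by_marker(table: pd.DataFrame, marker: int) -> pd.DataFrame:
    """Rows whose code contains ``marker``, order preserved, re-ranked from 0.

    Original colors travel with the codes (a code keeps its whole-image color).
    """
    if not table.empty and not 0 <= marker < len(table["code"].iloc[0]):
        raise ValueError(f"marker {marker} outside panel")
    keep = table["code"].str[marker] == "1" if len(table) else []
    out = _rerank(table[keep] if len(table) else table)
    out.attrs.update(table.attrs)
    out.attrs["filtered_marker"] = marker
    return out


def top_n(table: pd.DataFrame, n: int) -> pd.DataFrame:
    """First min(n, len) rows of a ranked table."""
    if n < 0:
        raise ValueError("n must be >= 0")
    out = table.head(n).reset_index(drop=True)
    out.attrs.update(table.attrs)
    return out


def pseudocolor(cmap: CMPMap, table: pd.DataFrame) -> np.ndarray:
    """(H, W, 3) uint8 composite: each code painted its table color, background black.

    Raises ``KeyError`` naming any map code missing from the table.
    """
    lut = np.zeros((1 << len(cmap.panel), 3), dtype=np.uint8)
    known = np.zeros(1 << len(cmap.panel), dtype=bool)
    known[BACKGROUND] = True
    for code_str, hexcol in zip(table["code"], table["color_hex"]):
        lut[bits_to_code(code_str)] = _hex_color(hexcol)
        known[bits_to_code(code_str)] = True
    present = np.unique(cmap.codes)
    missing = present[~known[present]]
    if missing.size:
        raise KeyError(
            f"codes present in map but absent from table: "
            f"{[code_to_bits(int(c), len(cmap.panel)) for c in missing[:5]]}"
        )
    return lut[cmap.codes]


def decode_pseudocolor(rgb: np.ndarray, table: pd.DataFrame, panel: MarkerPanel) -> CMPMap:
    """Invert :func:`pseudocolor` using the table's color assignment."""
    by_color = {_hex_color(h): bits_to_code(c) for c, h in zip(table["code"], table["color_hex"])}
    h, w, _ = rgb.shape
    codes = np.zeros((h, w), dtype=np.int64)
    flat = rgb.reshape(-1, 3)
    packed = flat[:, 0].astype(np.int64) << 16 | flat[:, 1].astype(np.int64) << 8 | flat[:, 2]
    lut: dict[int, int] = {0: BACKGROUND}
    for (r, g, b), code in by_color.items():
        lut[r << 16 | g << 8 | b] = code
    codes = np.array([lut[int(p)] for p in packed], dtype=np.int64).reshape(h, w)
    return CMPMap(codes=codes, panel=panel)


def write_pseudocolor_png(rgb: np.ndarray, path: str | Path) -> None:
    Image.fromarray(rgb, mode="RGB").save(Path(path))


def write_cmp_map(cmap: CMPMap, path: str | Path) -> None:
    """Write a code map as UTF-8 text: header lines then one line per
    non-background pixel, row-major: ``<row>\\t<col>\\t<code>``."""
    path = Path(path)
    rows, cols = np.nonzero(cmap.codes != BACKGROUND)
    n = len(cmap.panel)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#width {cmap.shape[1]}\n")
        fh.write(f"#height {cmap.shape[0]}\n")
        fh.write(f"#markers {','.join(cmap.panel.names)}\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r}\t{c}\t{code_to_bits(int(cmap.codes[r, c]), n)}\n")


class CMPMapParseError(ValueError):
    """Malformed CMP map file; message carries the offending line number."""


def read_cmp_map(path: str | Path, sample_id: str = "") -> CMPMap:
    """Read a map written by :func:`write_cmp_map` (lossless round trip)."""
    path = Path(path)
    header: dict[str, str] = {}
    entries: list[tuple[int, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, value = line[1:].split(" ", 1)
                except ValueError:
                    raise CMPMapParseError(f"line {lineno}: malformed header {line!r}")
                header[key] = value
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise CMPMapParseError(f"line {lineno}: expected 'row<TAB>col<TAB>code'")
            entries.append((lineno, line))
    for key in ("width", "height", "markers"):
        if key not in header:
            raise CMPMapParseError(f"missing #{key} header")
    width, height = int(header["width"]), int(header["height"])
    panel = MarkerPanel(tuple(header["markers"].split(",")))
    codes = np.zeros((height, width), dtype=np.int64)
    for lineno, line in entries:
        r_s, c_s, bits = line.split("\t")
        if len(bits) != len(panel):
            raise CMPMapParseError(
                f"line {lineno}: code length {len(bits)} != panel size {len(panel)}"
            )
        try:
            r, c = int(r_s), int(c_s)
            code = bits_to_code(bits)
        except ValueError as err:
            raise CMPMapParseError(f"line {lineno}: {err}")
        if not (0 <= r < height and 0 <= c < width):
            raise CMPMapParseError(f"line {lineno}: pixel ({r}, {c}) outside image")
        codes[r, c] = code
    return CMPMap(codes=codes, panel=panel, sample_id=sample_id)
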