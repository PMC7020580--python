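"""Per-cell CMP profiles, top-k tables, signatures and segmented-bar summaries.

Whole-image code maps are mined cell by cell: a region of interest (a pixel
list, or a polygon rasterized to one) is cut from the map, its non-background
codes are counted and ranked, and the cell is summarized by its k most abundant
codes (k = 20 by default, with the k = 10 view a first-class citizen).  Two
summaries matter downstream:

* the *binary table* (k rows x markers, presence 0/1) and *pixel table* (same
  rows, the code's pixel count replicated across its member markers);
* the *signature* — for each marker, how many of the top-k codes contain it,
  and how many pixels those codes occupy — the per-cell line-graph fingerprint
  used for population gating.

Segmented-bar summaries display each top code as a stack of one segment per
member marker (each segment as tall as the code's pixel count, so a 3-marker
code of 296 pixels shows an apparent 888-pixel bar while truly occupying 296
pixels — the overlay line keeps the true count visible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .cmp_core import CMPMap, _sort_codes_by_frequency

DEFAULT_TOP_K = 20


@dataclass
class CellRegion:
    """A selected cell: its id and pixel set (0-based row/col, origin top-left)."""

    cell_id: str
    pixels: np.ndarray  # (N, 2) int rows/cols
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2 or len(self.pixels) == 0:
            raise ValueError("pixels must be a non-empty (N, 2) array")

    @classmethod
    def from_polygon(
        cls, cell_id: str, vertices: list[tuple[float, float]],
        shape: tuple[int, int], sample_id: str = "",
    ) -> "CellRegion":
        """Rasterize a closed polygon (row, col vertices) to a pixel set.

        Even-odd fill including boundary pixels.
        """
        img = Image.new("1", (shape[1], shape[0]), 0)
        draw = ImageDraw.Draw(img)
        xy = [(c, r) for r, c in vertices]
        draw.polygon(xy, fill=1, outline=1)
        arr = np.asarray(img, dtype=bool)
        rows, cols = np.nonzero(arr)
        return cls(cell_id=cell_id, pixels=np.column_stack([rows, cols]), sample_id=sample_id)

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


@dataclass
class CellProfile:
    """Ranked code counts within one cell."""

    region: CellRegion
    cmp_freq: list[tuple[str, int]]  # (code bit string, pixel count), descending
    n_pixels: int
    n_background: int

    @property
    def n_distinct(self) -> int:
        return len(self.cmp_freq)


@dataclass
class CellSignature:
    """Marker-wise summary of a cell's top-k codes (the line-graph vectors)."""

    cell_id: str
    cmp_count_per_marker: np.ndarray
    pixel_count_per_marker: np.ndarray
    top_k: int = DEFAULT_TOP_K
    sample_id: str = ""


def extract_cell(cmap: CMPMap, region: CellRegion) -> CellProfile:
    """Count every non-background code inside the region (the "lasso" pull).

    Order and tie rules match the whole-image frequency table: descending
    count, ties by code string ascending.
    """
    h, w = cmap.shape
    r, c = region.pixels[:, 0], region.pixels[:, 1]
    bad = (r < 0) | (r >= h) | (c < 0) | (c >= w)
    if bad.any():
        raise ValueError(
            f"region {region.cell_id}: pixels outside {h}x{w} image: "
            f"{region.pixels[bad][:5].tolist()}"
        )
    codes = cmap.codes[r, c]
    nonbg = codes[codes != 0]
    vals, counts = np.unique(nonbg, return_counts=True)
    order, bitstrings = _sort_codes_by_frequency(vals, counts, len(cmap.panel))
    return CellProfile(
        region=region,
        cmp_freq=[(bitstrings[k], int(counts[k])) for k in order],
        n_pixels=int(len(codes)),
        n_background=int(len(codes) - len(nonbg)),
    )


def _top_rows(profile: CellProfile, k: int) -> list[tuple[str, int]]:
    if k < 1:
        raise ValueError("k must be >= 1")
    return profile.cmp_freq[:k]


def top_k_tables(
    profile: CellProfile,
    k: int = DEFAULT_TOP_K,
    image_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary and pixel tables for the cell's k most abundant codes.

    Both tables have one row per code with integer marker columns ``"0"`` ..
    ``"n-1"``, an ``order`` column (1 = most abundant in the cell), and a
    ``image_rank`` column carrying the code's rank in the whole-image frequency
    table when one is supplied (0-based; the image's most abundant code is rank
    0).  The binary table records presence; the pixel table replicates the
    code's pixel count across its member markers, with the count itself in a
    ``pixels`` column.  A final ``total`` row holds the column sums (for the
    pixel table's ``pixels`` column: the cell's top-k pixel total).

    Cells with fewer than k distinct codes yield correspondingly shorter tables.
    """
    rows = _top_rows(profile, k)
    n_markers = len(rows[0][0]) if rows else 0
    rank_of: dict[str, int] = {}
    if image_table is not None:
        rank_of = dict(zip(image_table["code"], image_table["rank"]))
    marker_cols = [str(m) for m in range(n_markers)]
    binary: dict[str, list] = {c: [] for c in marker_cols}
    pixel: dict[str, list] = {c: [] for c in marker_cols}
    meta: dict[str, list] = {"order": [], "image_rank": [], "code": []}
    pixels_col: list[int] = []
    for i, (code, count) in enumerate(rows):
        for m in range(n_markers):
            bit = int(code[m])
            binary[marker_cols[m]].append(bit)
            pixel[marker_cols[m]].append(bit * count)
        meta["order"].append(i + 1)
        meta["image_rank"].append(rank_of.get(code, pd.NA))
        meta["code"].append(code)
        pixels_col.append(count)
    binary_df = pd.DataFrame({**meta, **binary})
    pixel_df = pd.DataFrame({**meta, **pixel, "pixels": pixels_col})
    # bottom-line sums, as printed under the per-cell tables
    total_b = {c: binary_df[c].sum() for c in marker_cols}
    total_p = {c: pixel_df[c].sum() for c in marker_cols}
    binary_df.loc["total"] = {"order": pd.NA, "image_rank": pd.NA, "code": "total", **total_b}
    pixel_df.loc["total"] = {
        "order": pd.NA, "image_rank": pd.NA, "code": "total",
        **total_p, "pixels": sum(pixels_col),
    }
    return binary_df, pixel_df


def signature(profile: CellProfile, k: int = DEFAULT_TOP_K) -> CellSignature:
    """Marker-content vectors over the cell's top-k codes.

    ``cmp_count_per_marker[i]`` — how many of the top-k codes contain marker i
    (0 when the marker appears in none of them); ``pixel_count_per_marker[i]``
    — total pixels of those codes.
    """
    rows = _top_rows(profile, k)
    n_markers = len(rows[0][0]) if rows else 0
    cmp_count = np.zeros(n_markers, dtype=int)
    pixel_count = np.zeros(n_markers, dtype=int)
    for code, count in rows:
        for m, bit in enumerate(code):
            if bit == "1":
                cmp_count[m] += 1
                pixel_count[m] += count
    return CellSignature(
        cell_id=profile.region.cell_id,
        cmp_count_per_marker=cmp_count,
        pixel_count_per_marker=pixel_count,
        top_k=k,
        sample_id=profile.region.sample_id,
    )


@dataclass
class SegmentedBars:
    """Bar spec for the top-k codes: one stacked bar per code.

    ``bars`` columns: ``order``, ``code``, ``pixels`` (true pixel count, the
    overlay-line value), ``n_members``, ``apparent_total`` (= members x pixels,
    the stacked bar's visual height).  ``total_pixels`` is the true cumulative
    pixel count of the k codes; ``top10_ratio`` the top-10 / top-k pixel ratio.
    """

    bars: pd.DataFrame
    total_pixels: int
    top10_ratio: float
    k: int


def segmented_bars(profile: CellProfile, k: int = DEFAULT_TOP_K) -> SegmentedBars:
    rows = _top_rows(profile, k)
    records = []
    for i, (code, count) in enumerate(rows):
        members = [m for m, bit in enumerate(code) if bit == "1"]
        records.append(
            {
                "order": i + 1,
                "code": code,
                "pixels": count,
                "n_members": len(members),
                "members": members,
                "apparent_total": len(members) * count,
            }
        )
    bars = pd.DataFrame(records)
    total = int(sum(r["pixels"] for r in records))
    top10 = int(sum(r["pixels"] for r in records[:10]))
    return SegmentedBars(
        bars=bars,
        total_pixels=total,
        top10_ratio=(top10 / total) if total else float("nan"),
        k=k,
    )


def signatures_frame(
    signatures: list[CellSignature], groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Stack signatures into a cells x markers frame of CMP counts.

    Index = cell id; columns ``m0`` .. ``m<n-1>`` plus ``sample`` and, when a
    subject->group mapping is given, ``group`` (cells are matched to subjects
    via their ``sample_id``).
    """
    if not signatures:
        raise ValueError("no signatures given")
    n = len(signatures[0].cmp_count_per_marker)
    data = {
        f"m{m}": [s.cmp_count_per_marker[m] for s in signatures] for m in range(n)
    }
    df = pd.DataFrame(data, index=[s.cell_id for s in signatures])
    df["sample"] = [s.sample_id for s in signatures]
    if groups is not None:
        df["group"] = [groups[s.sample_id] for s in signatures]
    return df


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def plot_signature(sig: CellSignature, ax=None, pixels: bool = False, **kwargs):
    """Line-graph signature: marker index vs CMP count (or pixel count)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    y = sig.pixel_count_per_marker if pixels else sig.cmp_count_per_marker
    ax.plot(np.arange(len(y)), y, marker="o", label=sig.cell_id, **kwargs)
    ax.set_xlabel("marker")
    ax.set_ylabel("pixels in top-k CMPs" if pixels else f"CMPs (of top {sig.top_k})")
    ax.set_xticks(np.arange(len(y)))
    return ax


def plot_segmented_bars(spec: SegmentedBars, ax=None, cmap_name: str = "tab20"):
    """Stacked bars of marker segments per code with the true-pixel overlay line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    colors = plt.get_cmap(cmap_name)
    for _, row in spec.bars.iterrows():
        bottom = 0
        for m in row["members"]:
            ax.bar(row["order"], row["pixels"], bottom=bottom, color=colors(m % 20),
                   edgecolor="white", linewidth=0.3)
            bottom += row["pixels"]
    ax.plot(spec.bars["order"], spec.bars["pixels"], color="red", linewidth=2)
    ax.set_xlabel(f"top {spec.k} CMPs (by abundance)")
    ax.set_ylabel("pixels")
    return ax
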