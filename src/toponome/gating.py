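"""Population-level hi/lo gating of cell signatures.

Analogous to flow-cytometry gating: for each marker, find the maximum per-cell
CMP count over the population (out of each cell's top-k codes), set the
marker's *limit* at half that maximum (rounding down for odd maxima), and call
a cell **hi** for the marker when its count is at or above the limit, **lo**
when strictly below.  Sequential conjunctive hi/lo criteria then carve out cell
subpopulations, whose group composition reveals treatment-enriched phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def compute_limit(max_count: int) -> int:
    """Half-of-max gating threshold: floor(max / 2).

    Reproduces the printed rule — a max of 13 gates at >= 6, 15 at >= 7,
    14 at >= 7.
    """
    if max_count < 0:
        raise ValueError("max_count must be >= 0")
    return max_count // 2


@dataclass(frozen=True)
class GateCriterion:
    """One hi/lo rule: cmp_count >= limit ('hi') or < limit ('lo')."""

    marker: int
    direction: str  # "hi" | "lo"

    def __post_init__(self) -> None:
        if self.direction not in ("hi", "lo"):
            raise ValueError("direction must be 'hi' or 'lo'")

    @classmethod
    def parse(cls, text: str) -> "GateCriterion":
        """Parse ``"m7:hi"`` / ``"3:lo"`` style criterion strings."""
        marker_s, _, direction = text.strip().partition(":")
        return cls(marker=int(marker_s.lstrip("m")), direction=direction)


def parse_criteria(text: str) -> list[GateCriterion]:
    """Parse a comma-separated criteria string, e.g. ``"m7:hi,m3:hi"``."""
    return [GateCriterion.parse(t) for t in text.split(",") if t.strip()]


def marker_limits(signatures: pd.DataFrame) -> pd.DataFrame:
    """Per-marker max, limit and hi-cell counts over the population.

    ``signatures`` is the cells x markers frame from
    :func:`~toponome.single_cell.signatures_frame` (columns ``m0`` .. plus
    ``group``).  Returns one row per marker: ``max_count``, ``limit``,
    ``n_at_or_above`` and one ``n_<group>`` column per group.
    """
    marker_cols = [c for c in signatures.columns if c.startswith("m") and c[1:].isdigit()]
    if not marker_cols or len(signatures) == 0:
        raise ValueError("signatures frame must contain cells and marker columns")
    groups = sorted(signatures["group"].unique()) if "group" in signatures else []
    records = []
    for col in sorted(marker_cols, key=lambda c: int(c[1:])):
        max_count = int(signatures[col].max())
        limit = compute_limit(max_count)
        hi = signatures[col] >= limit
        rec = {
            "marker": int(col[1:]),
            "max_count": max_count,
            "limit": limit,
            "n_at_or_above": int(hi.sum()),
        }
        for g in groups:
            rec[f"n_{g}"] = int((hi & (signatures["group"] == g)).sum())
        records.append(rec)
    return pd.DataFrame(records).set_index("marker")


@dataclass
class SelectionResult:
    """Outcome of a sequential hi/lo screen."""

    criteria: list[GateCriterion]
    cell_ids: list[str]
    per_group: dict[str, int]
    consensus: dict[int, str]  # non-criterion markers hi/lo in >= fraction of cells
    consensus_fraction: float

    @property
    def n_selected(self) -> int:
        return len(self.cell_ids)


def select_cells(
    signatures: pd.DataFrame,
    limits: pd.DataFrame,
    criteria: list[GateCriterion],
    consensus_fraction: float = 0.8,
) -> SelectionResult:
    """Apply hi/lo criteria conjunctively and summarize the selected cells.

    The criteria are an intersection, so their order never changes the final
    set.  Whole-population limits are reused at every step (limits are computed
    once, not re-derived within sub-populations).  Markers *not* used as
    criteria that are hi (or lo) in at least ``consensus_fraction`` of the
    selected cells are reported as the selection's consensus annotation —
    the "present in most, or all, members" features.
    """
    keep = np.ones(len(signatures), dtype=bool)
    for crit in criteria:
        if crit.marker not in limits.index:
            raise ValueError(f"unknown marker {crit.marker}")
        col = signatures[f"m{crit.marker}"]
        limit = limits.loc[crit.marker, "limit"]
        keep &= (col >= limit).to_numpy() if crit.direction == "hi" else (col < limit).to_numpy()
    selected = signatures[keep]
    per_group = (
        selected["group"].value_counts().to_dict() if "group" in signatures else {}
    )
    consensus: dict[int, str] = {}
    used = {c.marker for c in criteria}
    if len(selected):
        for marker in limits.index:
            if marker in used:
                continue
            hi_frac = float(
                (selected[f"m{marker}"] >= limits.loc[marker, "limit"]).mean()
            )
            if hi_frac >= consensus_fraction:
                consensus[int(marker)] = "hi"
            elif 1.0 - hi_frac >= consensus_fraction:
                consensus[int(marker)] = "lo"
    return SelectionResult(
        criteria=list(criteria),
        cell_ids=list(selected.index),
        per_group={k: int(v) for k, v in per_group.items()},
        consensus=consensus,
        consensus_fraction=consensus_fraction,
    )


def enrichment_summary(
    result: SelectionResult, baseline: float = 0.5, group: str | None = None
) -> dict:
    """Group fractions of a selection plus a two-sided binomial p-value.

    ``baseline`` is the population share of the focal group (0.5 for the
    balanced 57 + 57 design).  The p-value is a convenience beyond the raw
    counts.  Raises on an empty selection, where fractions are undefined.
    """
    n = result.n_selected
    if n == 0:
        raise ValueError("enrichment is undefined for an empty selection")
    fractions = {g: c / n for g, c in result.per_group.items()}
    if group is None:
        group = max(result.per_group, key=result.per_group.get)
    k = result.per_group.get(group, 0)
    p = float(stats.binomtest(k, n, baseline, alternative="two-sided").pvalue)
    return {
        "n_selected": n,
        "per_group": dict(result.per_group),
        "fractions": fractions,
        "focal_group": group,
        "focal_fraction": k / n,
        "binomial_p": p,
        "baseline": baseline,
    }


def scan_criteria(
    signatures: pd.DataFrame,
    limits: pd.DataFrame,
    max_depth: int = 2,
    min_cells: int = 5,
) -> pd.DataFrame:
    """Optional extension: exhaustive scan over small criterion combinations.

    The reference workflow picks screens manually; this utility enumerates all
    1..max_depth-criterion conjunctions and reports their composition, as a
    starting point for manual review.
    """
    from itertools import combinations, product

    markers = list(limits.index)
    records = []
    for depth in range(1, max_depth + 1):
        for combo in combinations(markers, depth):
            for dirs in product(("hi", "lo"), repeat=depth):
                crits = [GateCriterion(m, d) for m, d in zip(combo, dirs)]
                res = select_cells(signatures, limits, crits)
                if res.n_selected < min_cells:
                    continue
                top = max(res.per_group, key=res.per_group.get, default=None)
                records.append(
                    {
                        "criteria": ",".join(f"m{c.marker}:{c.direction}" for c in crits),
                        "n_selected": res.n_selected,
                        "top_group": top,
                        "top_fraction": res.per_group.get(top, 0) / res.n_selected,
                    }
                )
    return pd.DataFrame(records).sort_values("top_fraction", ascending=False, ignore_index=True)
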