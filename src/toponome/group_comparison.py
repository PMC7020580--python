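"""Whole-image between-group statistics.

Two groups of three subjects each are compared at the whole-image level:

* **Conservation counts** — for each marker, take every subject's 50 most
  abundant codes *containing that marker* and count codes present in all three
  subjects of a group ("triplets") or in exactly two ("2-of-3", split into the
  patterns x-2-3, 1-x-3, 1-2-x; triplets are never double-counted).  High
  counts mean the group's subjects share their abundant phenotypes — low
  between-subject heterogeneity.
* **Aligned rank test** — the 13 per-marker conservation totals of the two
  groups form a randomized complete block design (marker = block).  Values are
  aligned by removing each block's mean, ranked jointly, and the group rank sum
  is referred to its exact sign-flip permutation distribution (2^13 flips).
* **Pairwise similarity** — for every unordered marker pair the Jaccard index
  of the two binary masks (margin excluded) gives a 78-vector per subject;
  groups are compared pair-by-pair and on the mean profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cmp_core import filter_by_marker, top_n
from .image_prep import BinaryStack

TOP_N_PER_MARKER = 50
PATTERNS = ("x-2-3", "1-x-3", "1-2-x")


@dataclass
class ConservationCount:
    """Triplet / 2-of-3 counts for one marker within one 3-subject group."""

    marker: int
    group: str
    n_triplet: int
    n_2of3_by_pattern: dict[str, int]
    triplet_codes: frozenset[str]

    @property
    def n_2of3(self) -> int:
        return sum(self.n_2of3_by_pattern.values())

    @property
    def n_either(self) -> int:
        return self.n_triplet + self.n_2of3


def marker_top50_sets(
    tables: list[pd.DataFrame], marker: int, n: int = TOP_N_PER_MARKER
) -> list[set[str]]:
    """Per sample: the n most abundant codes containing ``marker``, as code sets."""
    if not tables:
        raise ValueError("at least one sample table required")
    return [set(top_n(filter_by_marker(t, marker), n)["code"]) for t in tables]


def conservation_counts(
    tables: list[pd.DataFrame],
    marker: int,
    group: str = "",
    n: int = TOP_N_PER_MARKER,
    strict: bool = True,
) -> ConservationCount:
    """Triplets and 2-of-3 patterns for one marker across a group's samples.

    ``strict`` enforces the three-subjects-per-group study design; with
    ``strict=False`` any number of samples is accepted and "2-of-3" generalizes
    to codes present in exactly len-1 samples (pattern named by the missing
    sample index).
    """
    if strict and len(tables) != 3:
        raise ValueError("the study design has exactly 3 samples per group")
    sets = marker_top50_sets(tables, marker, n=n)
    triple = frozenset(set.intersection(*sets)) if sets else frozenset()
    patterns: dict[str, int] = {}
    k = len(sets)
    for missing in range(k):
        others = [sets[i] for i in range(k) if i != missing]
        present = set.intersection(*others) - triple if others else set()
        if k == 3:
            name = PATTERNS[missing]
        else:
            name = f"missing-{missing + 1}"
        patterns[name] = len(present)
    return ConservationCount(
        marker=marker,
        group=group,
        n_triplet=len(triple),
        n_2of3_by_pattern=patterns,
        triplet_codes=triple,
    )


def common_triplets(
    a: ConservationCount, b: ConservationCount
) -> tuple[frozenset[str], int]:
    """Triplet codes both groups share, and the signed count difference (a - b)."""
    if a.marker != b.marker:
        raise ValueError("conservation counts refer to different markers")
    return a.triplet_codes & b.triplet_codes, a.n_triplet - b.n_triplet


def conservation_table(
    group_a_tables: list[pd.DataFrame],
    group_b_tables: list[pd.DataFrame],
    group_names: tuple[str, str] = ("KO", "SPA1"),
    n_markers: int = 13,
    n: int = TOP_N_PER_MARKER,
) -> pd.DataFrame:
    """Marker x {triplet, 2-of-3 patterns, totals} table for both groups.

    One row per (group, statistic); columns are the markers plus a ``total``
    column.  The final rows give the common-triplet counts per marker and the
    signed per-marker triplet difference (group A - group B).
    """
    rows = {}
    counts = {}
    for name, tables in zip(group_names, (group_a_tables, group_b_tables)):
        counts[name] = [
            conservation_counts(tables, m, group=name, n=n) for m in range(n_markers)
        ]
        rows[(name, "triplet")] = [c.n_triplet for c in counts[name]]
        for pat in PATTERNS:
            rows[(name, pat)] = [c.n_2of3_by_pattern[pat] for c in counts[name]]
        rows[(name, "2-of-3 total")] = [c.n_2of3 for c in counts[name]]
        rows[(name, "triplet + 2-of-3")] = [c.n_either for c in counts[name]]
    a, b = group_names
    rows[("common", "triplets")] = [
        len(common_triplets(ca, cb)[0]) for ca, cb in zip(counts[a], counts[b])
    ]
    rows[("difference", f"{a} - {b} triplets")] = [
        common_triplets(ca, cb)[1] for ca, cb in zip(counts[a], counts[b])
    ]
    df = pd.DataFrame(rows, index=[f"m{m}" for m in range(n_markers)]).T
    df["total"] = df.sum(axis=1)
    return df


def aligned_rank_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    seed: int = 0,
    n_mc: int = 20000,
) -> tuple[float, float]:
    """Aligned-rank permutation test for paired (blocked) two-group data.

    Observations are paired by block (here: marker).  Each block's mean is
    subtracted (alignment), all aligned values are ranked jointly (ties get
    average ranks), and the statistic is group A's rank sum.  The two-sided
    p-value is computed over sign flips within blocks — exhaustively for up to
    13 blocks (8192 flips), else by seeded Monte Carlo with ``n_mc`` draws.

    Returns ``(rank_sum_A, p_value)``.  All-tied data gives p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("group totals must be equal-length 1D vectors")
    k = len(a)
    block_mean = (a + b) / 2.0
    aligned = np.concatenate([a - block_mean, b - block_mean])
    ranks = stats.rankdata(aligned)
    ra, rb = ranks[:k], ranks[k:]
    t_obs = float(ra.sum())
    center = (ra + rb).sum() / 2.0  # E[T] under exchangeability within blocks

    # flipping block i swaps which group holds which aligned value
    if k <= 13:
        flips = ((np.arange(1 << k)[:, None] >> np.arange(k)) & 1).astype(bool)
        stats_all = np.where(flips, rb, ra).sum(axis=1)
        p = float(np.mean(np.abs(stats_all - center) >= np.abs(t_obs - center) - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        flips = rng.integers(0, 2, size=(n_mc, k)).astype(bool)
        stats_mc = np.where(flips, rb, ra).sum(axis=1)
        # add-one correction keeps Monte-Carlo p-values valid
        p = float(
            (1 + np.sum(np.abs(stats_mc - center) >= np.abs(t_obs - center) - 1e-12))
            / (1 + n_mc)
        )
    return t_obs, min(p, 1.0)


def pairwise_similarity(stack: BinaryStack) -> pd.Series:
    """Jaccard index for every unordered marker pair over non-margin pixels.

    ``J(i, j) = |Mi & Mj| / |Mi | Mj|``; 0 when both masks are empty.  Returns
    a Series indexed by ``(i, j)`` tuples in canonical order.
    """
    keep = stack.interior()
    masks = stack.masks[:, keep]
    out = {}
    for i, j in combinations(range(len(stack.panel)), 2):
        inter = int(np.count_nonzero(masks[i] & masks[j]))
        union = int(np.count_nonzero(masks[i] | masks[j]))
        out[(i, j)] = inter / union if union else 0.0
    return pd.Series(out, name="jaccard")


def compare_similarity_profiles(
    group_a: list[pd.Series],
    group_b: list[pd.Series],
    alpha: float = 0.05,
    method: str = "ttest",
    seed: int = 0,
    n_mc: int = 20000,
) -> dict:
    """Compare two groups' 78-pair similarity profiles.

    Per pair, the samples' coefficients are compared with a Welch t-test
    (default) or an exact two-sample permutation test over all group splits
    (with 3-vs-3 samples that test has only 20 splits, so its smallest
    two-sided p is 0.1 — it cannot reach conventional significance and exists
    for completeness).  The mean-profile test pairs the two groups' per-pair
    means over the 78 pairs and sign-flip permutes the differences (seeded
    Monte Carlo).  No multiplicity correction is applied across pairs.

    Returns a dict with ``per_pair`` (DataFrame: pair, mean_a, mean_b, p,
    significant), ``n_significant``, and ``mean_test_p``.
    """
    if method not in ("ttest", "permutation"):
        raise ValueError("method must be 'ttest' or 'permutation'")
    pairs = list(group_a[0].index)
    mat_a = np.array([[s[p] for p in pairs] for s in group_a])  # samples x pairs
    mat_b = np.array([[s[p] for p in pairs] for s in group_b])
    pvals = np.empty(len(pairs))
    for j in range(len(pairs)):
        xa, xb = mat_a[:, j], mat_b[:, j]
        if method == "ttest":
            if np.ptp(np.concatenate([xa, xb])) == 0:
                pvals[j] = 1.0
            else:
                pvals[j] = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        else:
            pvals[j] = _exact_two_sample_permutation_p(xa, xb)
    per_pair = pd.DataFrame(
        {
            "pair": pairs,
            "mean_a": mat_a.mean(axis=0),
            "mean_b": mat_b.mean(axis=0),
            "p": pvals,
            "significant": pvals < alpha,
        }
    )
    # mean-profile test: paired over the 78 pairs
    diff = mat_a.mean(axis=0) - mat_b.mean(axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_mc, len(diff)))
    t_obs = abs(diff.mean())
    t_mc = np.abs((signs * diff).mean(axis=1))
    mean_p = float((1 + np.sum(t_mc >= t_obs - 1e-15)) / (1 + n_mc))
    return {
        "per_pair": per_pair,
        "n_significant": int(per_pair["significant"].sum()),
        "mean_test_p": mean_p,
        "method": method,
        "alpha": alpha,
        "multiple_testing_correction": "none",
    }


def _exact_two_sample_permutation_p(xa: np.ndarray, xb: np.ndarray) -> float:
    """Two-sided exact permutation p for the difference in means (all splits)."""
    pooled = np.concatenate([xa, xb])
    na = len(xa)
    obs = abs(xa.mean() - xb.mean())
    count = total = 0
    for idx in combinations(range(len(pooled)), na):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        d = abs(pooled[sel].mean() - pooled[~sel].mean())
        count += d >= obs - 1e-15
        total += 1
    return count / total
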