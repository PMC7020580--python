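"""Cell extraction, top-k tables, signatures and segmented bars."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

import toponome as tp
from toponome import single_cell as sc
from .conftest import random_cmp_map


def make_profile(cmp_freq, n_pixels=None, cell_id="c0"):
    """Assemble a CellProfile directly from (code, count) pairs."""
    total = sum(c for _, c in cmp_freq)
    region = sc.CellRegion(cell_id, np.array([[0, 0]]))
    return sc.CellProfile(
        region=region,
        cmp_freq=sorted(cmp_freq, key=lambda t: (-t[1], t[0])),
        n_pixels=n_pixels or total,
        n_background=(n_pixels or total) - total,
    )


class TestExtractCell:
    def test_single_code_region(self, small_panel):
        codes = np.zeros((8, 8), dtype=int)
        codes[2:4, 2:7] = 5
        cmap = tp.CMPMap(codes=codes, panel=small_panel)
        region = sc.CellRegion("c", np.argwhere(codes == 5))
        prof = tp.extract_cell(cmap, region)
        assert prof.cmp_freq == [("1010", 10)]
        assert prof.n_pixels == 10 and prof.n_background == 0

    def test_all_background_region(self, small_panel):
        cmap = tp.CMPMap(codes=np.zeros((8, 8), dtype=int), panel=small_panel)
        prof = tp.extract_cell(cmap, sc.CellRegion("c", [[1, 1], [1, 2]]))
        assert prof.n_distinct == 0 and prof.n_background == 2

    def test_matches_dictionary_count_oracle(self, rng):
        for _ in range(20):
            cmap = random_cmp_map(rng)
            pix = np.unique(rng.integers(0, 64, size=(150, 2)), axis=0)
            prof = tp.extract_cell(cmap, sc.CellRegion("c", pix))
            oracle = Counter(
                tp.code_to_bits(int(cmap.codes[r, c]), 13)
                for r, c in pix
                if cmap.codes[r, c] != 0
            )
            assert dict(prof.cmp_freq) == dict(oracle)
            counts = [c for _, c in prof.cmp_freq]
            assert counts == sorted(counts, reverse=True)

    def test_out_of_bounds_pixels_reported(self, small_panel):
        cmap = tp.CMPMap(codes=np.zeros((8, 8), dtype=int), panel=small_panel)
        with pytest.raises(ValueError, match=r"\[9, 1\]"):
            tp.extract_cell(cmap, sc.CellRegion("c", [[1, 1], [9, 1]]))

    def test_polygon_equals_pixel_list_for_rectangle(self, rng):
        cmap = random_cmp_map(rng, shape=(32, 32))
        poly = sc.CellRegion.from_polygon(
            "p", [(5, 5), (5, 15), (12, 15), (12, 5)], (32, 32)
        )
        rows, cols = np.mgrid[5:13, 5:16]
        explicit = sc.CellRegion("e", np.column_stack([rows.ravel(), cols.ravel()]))
        p1 = tp.extract_cell(cmap, poly)
        p2 = tp.extract_cell(cmap, explicit)
        assert p1.cmp_freq == p2.cmp_freq


class TestTopKTables:
    def test_pixel_row_replicates_count_across_members(self):
        code = "0010000110000"  # markers 2, 7, 8
        prof = make_profile([(code, 296), ("1000000000000", 100)])
        _, pixel_df = tp.top_k_tables(prof, k=20)
        row = pixel_df.iloc[0]
        assert row["pixels"] == 296
        assert row["2"] == row["7"] == row["8"] == 296
        assert sum(row[str(m)] for m in range(13)) == 3 * 296

    def test_single_cmp_column_sums(self):
        prof = make_profile([("1010000000001", 40)])
        binary_df, pixel_df = tp.top_k_tables(prof, k=20)
        total_b = binary_df.loc["total"]
        total_p = pixel_df.loc["total"]
        for m, bit in enumerate("1010000000001"):
            assert total_b[str(m)] == int(bit)
            assert total_p[str(m)] == int(bit) * 40
        assert pixel_df.loc["total", "pixels"] == 40

    def test_column_sums_match_brute_force(self, rng):
        codes = rng.integers(1, 1 << 13, size=30)
        freq = [(tp.code_to_bits(int(c), 13), int(n)) for c, n in
                zip(codes, rng.integers(1, 400, size=30))]
        prof = make_profile(freq)
        binary_df, pixel_df = tp.top_k_tables(prof, k=20)
        rows = prof.cmp_freq[:20]
        for m in range(13):
            assert binary_df.loc["total", str(m)] == sum(
                int(code[m]) for code, _ in rows
            )
            assert pixel_df.loc["total", str(m)] == sum(
                int(code[m]) * n for code, n in rows
            )
        assert pixel_df.loc["total", "pixels"] == sum(n for _, n in rows)

    def test_truncates_when_fewer_than_k(self):
        prof = make_profile([("1000000000000", 5), ("0100000000000", 3)])
        binary_df, _ = tp.top_k_tables(prof, k=20)
        assert len(binary_df) == 3  # 2 codes + total row

    def test_image_rank_column(self):
        prof = make_profile([("1000000000000", 5)])
        table = pd.DataFrame({"code": ["1000000000000"], "rank": [7]})
        binary_df, _ = tp.top_k_tables(prof, k=5, image_table=table)
        assert binary_df.iloc[0]["image_rank"] == 7


class TestSignature:
    def test_marker_in_all_topk(self):
        freq = [(tp.code_to_bits((1 << 5) | (1 << i), 13), 10 - i) for i in range(4)]
        prof = make_profile(freq)
        sig = tp.signature(prof, k=4)
        assert sig.cmp_count_per_marker[5] == 4

    def test_absent_marker_scores_zero(self):
        prof = make_profile([("0100000000000", 9)])
        sig = tp.signature(prof)
        assert sig.cmp_count_per_marker[0] == 0
        assert sig.pixel_count_per_marker[0] == 0

    def test_vectors_match_brute_force(self, rng):
        codes = rng.choice(1 << 13, size=40, replace=False)
        codes = codes[codes > 0]
        freq = [(tp.code_to_bits(int(c), 13), int(n)) for c, n in
                zip(codes, rng.integers(1, 100, size=len(codes)))]
        prof = make_profile(freq)
        sig = tp.signature(prof, k=20)
        rows = prof.cmp_freq[:20]
        for m in range(13):
            assert sig.cmp_count_per_marker[m] == sum(
                1 for code, _ in rows if code[m] == "1"
            )
            assert sig.pixel_count_per_marker[m] == sum(
                n for code, n in rows if code[m] == "1"
            )
        assert sig.cmp_count_per_marker.max() <= 20

    def test_count_and_pixel_signatures_agree_in_shape(self, demo_binary_stack, demo_scene):
        # cells with strongly separated marker usage show the same peaks in
        # both the CMP-count and the pixel-count vector
        scene, _, _ = demo_scene
        cmap = tp.merge_to_cmp_map(demo_binary_stack)
        from scipy.stats import spearmanr

        for cell in scene.cells[:3]:
            region = sc.CellRegion(
                cell.cell_id, np.column_stack([cell.rows, cell.cols])
            )
            sig = tp.signature(tp.extract_cell(cmap, region))
            rho = spearmanr(
                sig.cmp_count_per_marker, sig.pixel_count_per_marker
            ).statistic
            assert rho > 0


class TestSegmentedBars:
    def test_three_member_cmp_apparent_total(self):
        prof = make_profile([("0010000110000", 296)])
        spec = tp.segmented_bars(prof, k=20)
        row = spec.bars.iloc[0]
        assert row["n_members"] == 3
        assert row["apparent_total"] == 888
        assert row["pixels"] == 296

    def test_single_member(self):
        prof = make_profile([("0001000000000", 123)])
        spec = tp.segmented_bars(prof, k=10)
        assert spec.bars.iloc[0]["apparent_total"] == 123

    def test_apparent_totals_match_members_times_count(self, rng):
        codes = rng.choice(np.arange(1, 1 << 13), size=25, replace=False)
        freq = [(tp.code_to_bits(int(c), 13), int(n)) for c, n in
                zip(codes, rng.integers(1, 500, size=25))]
        prof = make_profile(freq)
        spec = tp.segmented_bars(prof, k=20)
        for _, row in spec.bars.iterrows():
            assert row["apparent_total"] == row["code"].count("1") * row["pixels"]

    def test_topk_pixel_monotonicity(self, rng):
        codes = rng.choice(np.arange(1, 1 << 13), size=30, replace=False)
        freq = [(tp.code_to_bits(int(c), 13), int(n)) for c, n in
                zip(codes, rng.integers(1, 500, size=30))]
        prof = make_profile(freq, n_pixels=sum(n for _, n in freq) + 50)
        top10 = tp.segmented_bars(prof, k=10).total_pixels
        top20 = tp.segmented_bars(prof, k=20).total_pixels
        assert top10 <= top20 <= prof.n_pixels
        assert tp.segmented_bars(prof, k=20).top10_ratio == top10 / top20
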