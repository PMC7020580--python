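"""Conservation set algebra, the aligned rank test and pairwise similarity."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import toponome as tp
from toponome import group_comparison as gc
from toponome.image_prep import BinaryStack


def table_from_codes(codes_with_freq):
    """Minimal ranked table from (code, frequency) pairs."""
    rows = sorted(codes_with_freq, key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(
        {
            "rank": range(len(rows)),
            "code": [c for c, _ in rows],
            "frequency": [f for _, f in rows],
            "color_hex": ["#FFFFFF"] * len(rows),
        }
    )


def codes(*ints):
    return {tp.code_to_bits(i, 13) for i in ints}


class TestConservation:
    def test_identical_sets_all_triplets(self):
        t = table_from_codes([(tp.code_to_bits(3, 13), 10), (tp.code_to_bits(1, 13), 5)])
        c = gc.conservation_counts([t, t, t], marker=0)
        assert c.n_triplet == 2
        assert c.n_2of3 == 0

    def test_two_of_three_set_algebra_example(self):
        # S1={a,b}, S2={b,c}, S3={c,d} (all containing marker 0)
        a, b, c, d = 1, 3, 5, 9
        t1 = table_from_codes([(tp.code_to_bits(a, 13), 4), (tp.code_to_bits(b, 13), 3)])
        t2 = table_from_codes([(tp.code_to_bits(b, 13), 4), (tp.code_to_bits(c, 13), 3)])
        t3 = table_from_codes([(tp.code_to_bits(c, 13), 4), (tp.code_to_bits(d, 13), 3)])
        cc = gc.conservation_counts([t1, t2, t3], marker=0)
        assert cc.n_triplet == 0
        assert cc.n_2of3_by_pattern == {"x-2-3": 1, "1-x-3": 0, "1-2-x": 1}

    def test_disjoint_sets_all_zero(self):
        t1 = table_from_codes([(tp.code_to_bits(1, 13), 4)])
        t2 = table_from_codes([(tp.code_to_bits(3, 13), 4)])
        t3 = table_from_codes([(tp.code_to_bits(5, 13), 4)])
        cc = gc.conservation_counts([t1, t2, t3], marker=0)
        assert cc.n_triplet == 0 and cc.n_2of3 == 0

    def test_strict_mode_requires_three_samples(self):
        t = table_from_codes([(tp.code_to_bits(1, 13), 1)])
        with pytest.raises(ValueError, match="3 samples"):
            gc.conservation_counts([t, t], marker=0)
        assert gc.conservation_counts([t, t], marker=0, strict=False).n_triplet == 1

    def test_counts_match_set_oracle_on_random_tables(self, rng):
        for _ in range(10):
            tables = []
            for _ in range(3):
                cs = rng.choice(np.arange(1, 1 << 13), size=80, replace=False)
                tables.append(
                    table_from_codes(
                        [(tp.code_to_bits(int(c), 13), int(f)) for c, f in
                         zip(cs, rng.integers(1, 1000, size=80))]
                    )
                )
            for marker in (0, 7):
                sets = gc.marker_top50_sets(tables, marker)
                oracle_sets = [
                    set(t[t["code"].str[marker] == "1"].head(50)["code"]) for t in tables
                ]
                assert sets == oracle_sets
                cc = gc.conservation_counts(tables, marker)
                s1, s2, s3 = sets
                triple = s1 & s2 & s3
                assert cc.n_triplet == len(triple)
                assert cc.n_2of3_by_pattern["x-2-3"] == len((s2 & s3) - triple)
                assert cc.n_2of3_by_pattern["1-x-3"] == len((s1 & s3) - triple)
                assert cc.n_2of3_by_pattern["1-2-x"] == len((s1 & s2) - triple)
                # set identity: triplet + each 2-of-3 = pairwise intersection
                assert cc.n_triplet + cc.n_2of3_by_pattern["1-2-x"] == len(s1 & s2)

    def test_common_triplets(self):
        t_a = table_from_codes([(tp.code_to_bits(c, 13), 2) for c in (1, 3, 5)])
        t_b = table_from_codes([(tp.code_to_bits(c, 13), 2) for c in (3, 9)])
        ca = gc.conservation_counts([t_a] * 3, marker=0)
        cb = gc.conservation_counts([t_b] * 3, marker=0)
        shared, diff = gc.common_triplets(ca, cb)
        assert shared == codes(3)
        assert diff == 1
        same_shared, same_diff = gc.common_triplets(ca, ca)
        assert same_shared == ca.triplet_codes and same_diff == 0


class TestAlignedRankTest:
    def test_identical_groups_p_one(self):
        x = np.arange(13, dtype=float)
        _, p = tp.aligned_rank_test(x, x)
        assert p == 1.0

    def test_constant_shift_gives_extreme_orbit(self):
        x = np.arange(13, dtype=float) * 3
        _, p = tp.aligned_rank_test(x + 10, x)
        assert p == pytest.approx(2 / 2**13)

    def test_matches_brute_force_enumeration(self, rng):
        # small k: compare against an independent full enumeration
        from scipy.stats import rankdata

        k = 6
        a = rng.normal(size=k)
        b = rng.normal(size=k)
        _, p = tp.aligned_rank_test(a, b)
        mean = (a + b) / 2
        aligned = np.concatenate([a - mean, b - mean])
        ranks = rankdata(aligned)
        ra, rb = ranks[:k], ranks[k:]
        center = (ra + rb).sum() / 2
        obs = abs(ra.sum() - center)
        count = 0
        for bits in range(1 << k):
            flip = np.array([(bits >> i) & 1 for i in range(k)], dtype=bool)
            t = np.where(flip, rb, ra).sum()
            count += abs(t - center) >= obs - 1e-12
        assert p == pytest.approx(count / (1 << k))

    def test_symmetry_under_group_swap(self, rng):
        a = rng.normal(size=13)
        b = rng.normal(size=13)
        assert tp.aligned_rank_test(a, b)[1] == pytest.approx(
            tp.aligned_rank_test(b, a)[1]
        )


def random_stack(rng, density=0.3):
    masks = rng.random((13, 48, 48)) < density
    return BinaryStack(masks, tp.DEFAULT_PANEL, margin=4)


class TestPairwiseSimilarity:
    def test_identical_nonempty_masks(self, rng):
        masks = np.zeros((13, 48, 48), dtype=bool)
        masks[:, 10:20, 10:20] = True
        sims = tp.pairwise_similarity(BinaryStack(masks, tp.DEFAULT_PANEL, margin=4))
        assert len(sims) == 78
        assert np.allclose(sims.values, 1.0)

    def test_disjoint_masks_zero(self):
        masks = np.zeros((13, 48, 48), dtype=bool)
        masks[0, 10:12, 10:12] = True
        masks[1, 20:22, 20:22] = True
        sims = tp.pairwise_similarity(BinaryStack(masks, tp.DEFAULT_PANEL, margin=4))
        assert sims[(0, 1)] == 0.0

    def test_known_ratio(self):
        masks = np.zeros((13, 64, 64), dtype=bool)
        # inside the margin-4 interior: |A&B| = 50, |A|B| = 150
        masks[0].flat[np.arange(100)] = False
        masks[0][10, 0:50] = True
        masks[0][11, 0:50] = True  # A: 100 px
        masks[1][11, 0:50] = True
        masks[1][12, 0:50] = True  # B: 100 px, overlap 50, union 150
        sims = tp.pairwise_similarity(BinaryStack(masks, tp.DEFAULT_PANEL, margin=4))
        assert sims[(0, 1)] == pytest.approx(1 / 3)

    def test_matches_pixel_count_oracle(self, rng):
        stack = random_stack(rng)
        sims = tp.pairwise_similarity(stack)
        keep = stack.interior()
        for (i, j) in [(0, 1), (4, 12), (7, 8)]:
            mi, mj = stack.masks[i][keep], stack.masks[j][keep]
            expect = (mi & mj).sum() / (mi | mj).sum()
            assert sims[(i, j)] == pytest.approx(expect)
        assert ((sims.values >= 0) & (sims.values <= 1)).all()

    def test_margin_pixels_are_excluded(self, rng):
        stack = random_stack(rng)
        inner = BinaryStack(
            np.array([tp.binarize(m, 1) for m in stack.masks]),
            tp.DEFAULT_PANEL,
            margin=4,
        )
        corrupted = stack.masks.copy()
        corrupted[:, :4, :] = True  # garbage inside the margin band only
        sims_a = tp.pairwise_similarity(inner)
        sims_b = tp.pairwise_similarity(
            BinaryStack(corrupted, tp.DEFAULT_PANEL, margin=4)
        )
        pd.testing.assert_series_equal(sims_a, sims_b)


class TestCompareSimilarityProfiles:
    def _profiles(self, rng, shift_pairs=(), delta=0.0, n=3):
        out = []
        for _ in range(n):
            vals = {p: rng.uniform(0.2, 0.4) for p in combinations(range(13), 2)}
            for p in shift_pairs:
                vals[p] += delta
            out.append(pd.Series(vals))
        return out

    def test_identical_groups_nothing_significant(self, rng):
        group = self._profiles(rng)
        res = gc.compare_similarity_profiles(group, group, seed=0)
        assert res["n_significant"] == 0
        assert res["mean_test_p"] > 0.05

    def test_permutation_floor_is_point_one(self, rng):
        # 3-vs-3 exact permutation has 20 splits: minimal two-sided p = 2/20
        a = self._profiles(rng, delta=0.0)
        b = self._profiles(rng, shift_pairs=list(combinations(range(13), 2)), delta=0.5)
        res = gc.compare_similarity_profiles(a, b, method="permutation", seed=0)
        assert res["per_pair"]["p"].min() == pytest.approx(0.1)
        assert res["n_significant"] == 0

    def test_planted_shift_found_by_ttest(self, rng):
        shifted = list(combinations(range(13), 2))[:40]
        a = self._profiles(rng)
        b = self._profiles(rng, shift_pairs=shifted, delta=0.5)
        res = gc.compare_similarity_profiles(a, b, method="ttest", seed=0)
        sig_pairs = set(res["per_pair"].loc[res["per_pair"]["significant"], "pair"])
        assert len(sig_pairs & set(shifted)) >= 35
        assert res["n_significant"] <= 50  # unshifted pairs mostly quiet
        assert res["mean_test_p"] < 0.01
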