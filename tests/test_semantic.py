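"""Letter encoding, k-mer overlap distances, embedding and silhouette."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memprobe.errors import ConfigurationError, EmptySetError, ShortStringError
from memprobe.order import OrderProfile
from memprobe.semantic import (
    DistanceMatrix,
    EncodingConfig,
    KmerConfig,
    cluster_quality,
    deduplicate,
    distance_matrix,
    embed_2d,
    encode_profile,
    kmer_set,
    overlap_coefficient,
    string_similarity,
)


def _profile(values, chain="sn1", start=2):
    idx = list(range(start, start + len(values)))
    return OrderProfile(chain, idx, list(values), [-v for v in values],
                        n_lipids_used=10, selection="all", frame_scope="single frame")


class TestEncoding:
    def test_all_values_at_low_bound_give_first_letter(self):
        s = encode_profile(_profile([0.0, 0.0, 0.0]))
        assert s == "AAA"

    def test_default_binning_floor_arithmetic(self):
        # width 0.02 over [0, 0.52]: 0.21 -> bin 10 -> "K"
        assert encode_profile(_profile([0.21])) == "K"
        assert encode_profile(_profile([0.0])) == "A"
        assert encode_profile(_profile([0.52])) == "Z"  # top edge -> last letter

    def test_concatenation_order_and_length(self):
        sn1 = _profile([0.1] * 16, chain="sn1")
        sn2 = _profile([0.3] * 18, chain="sn2")
        s = encode_profile([sn1, sn2])
        assert len(s) == 34
        assert s == "F" * 16 + "P" * 18

    def test_out_of_range_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert encode_profile(_profile([0.60])) == "Z"

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 0.49), min_size=1, max_size=30))
    def test_monotone_under_bin_width_shift(self, values):
        cfg = EncodingConfig()
        before = encode_profile(_profile(values), cfg)
        after = encode_profile(_profile([v + cfg.bin_width for v in values]), cfg)
        assert all(b2 > b1 for b1, b2 in zip(before, after))


class TestKmerSet:
    def test_single_length_enumeration(self):
        assert kmer_set("ABCD", KmerConfig(2, 2)) == {"AB", "BC", "CD"}

    def test_set_semantics_deduplicate(self):
        assert kmer_set("AAAA", KmerConfig(2, 3)) == {"AA", "AAA"}

    def test_short_string_raises(self):
        with pytest.raises(ShortStringError):
            kmer_set("A", KmerConfig(2, 8))

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        cfg = KmerConfig(2, 8)
        for _ in range(25):
            s = "".join(rng.choice(list("ABCDEFGHIJ"), size=34))
            brute = set()
            for k in range(2, 9):
                i = 0
                while i + k <= len(s):
                    brute.add(s[i:i + k])
                    i += 1
            assert kmer_set(s, cfg) == brute


class TestOverlapCoefficient:
    def test_identical_sets(self):
        assert overlap_coefficient({"AB", "BC"}, {"AB", "BC"}) == 1.0

    def test_disjoint_sets(self):
        assert overlap_coefficient({"AB"}, {"CD"}) == 0.0

    def test_hand_enumeration(self):
        assert overlap_coefficient({"AB", "BC"}, {"BC", "CD", "DE"}) == 0.5

    def test_empty_set_raises(self):
        with pytest.raises(EmptySetError):
            overlap_coefficient(set(), {"AB"})

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.sets(st.text("ABCD", min_size=2, max_size=3), min_size=1, max_size=12),
        b=st.sets(st.text("ABCD", min_size=2, max_size=3), min_size=1, max_size=12),
    )
    def test_symmetric_and_containment_iff_one(self, a, b):
        s1 = overlap_coefficient(a, b)
        assert s1 == overlap_coefficient(b, a)
        assert 0.0 <= s1 <= 1.0
        assert (s1 == 1.0) == (a <= b or b <= a)


class TestDistanceMatrix:
    def test_zero_diagonal_and_identical_strings(self):
        dm = distance_matrix([("a", "KKKJJHH"), ("b", "KKKJJHH")])
        assert dm.values[0, 0] == 0.0
        assert dm.values[0, 1] == 0.0

    def test_disjoint_alphabets_give_distance_one(self):
        dm = distance_matrix([("a", "AAABBB"), ("b", "XXYYZZ")])
        assert dm.values[0, 1] == 1.0

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(5)
        cfg = KmerConfig(2, 8)
        strings = ["".join(rng.choice(list("ABCDE"), size=20)) for _ in range(3)]
        dm = distance_matrix(list(zip("abc", strings)), cfg)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                si, sj = kmer_set(strings[i], cfg), kmer_set(strings[j], cfg)
                expect = 1.0 - len(si & sj) / min(len(si), len(sj))
                assert dm.values[i, j] == pytest.approx(expect)

    def test_symmetry_property(self):
        rng = np.random.default_rng(6)
        strings = [("s%d" % i, "".join(rng.choice(list("ABCDEFG"), size=15)))
                   for i in range(6)]
        dm = distance_matrix(strings)
        np.testing.assert_array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)
        assert dm.values.min() >= 0.0 and dm.values.max() <= 1.0

    def test_per_k_mean_pooling_option(self):
        cfg = KmerConfig(2, 3, pooling="per-k-mean")
        s1, s2 = "ABCDEF", "ABCXYZ"
        sim2 = overlap_coefficient(kmer_set(s1, KmerConfig(2, 2)),
                                   kmer_set(s2, KmerConfig(2, 2)))
        sim3 = overlap_coefficient(kmer_set(s1, KmerConfig(3, 3)),
                                   kmer_set(s2, KmerConfig(3, 3)))
        assert string_similarity(s1, s2, cfg) == pytest.approx((sim2 + sim3) / 2)

    def test_optional_duplicate_elimination(self):
        items = [("a", "ABAB"), ("b", "ABAB"), ("c", "CDCD")]
        assert len(deduplicate(items)) == 2
        dm = distance_matrix(items, drop_duplicates=True)
        assert len(dm.labels) == 2


class TestEmbedding:
    @staticmethod
    def _two_groups(n_per=6, within=0.05, between=0.95):
        n = 2 * n_per
        d = np.full((n, n), between)
        d[:n_per, :n_per] = within
        d[n_per:, n_per:] = within
        np.fill_diagonal(d, 0.0)
        labels = [f"g1@{i}" for i in range(n_per)] + [f"g2@{i}" for i in range(n_per)]
        return DistanceMatrix(labels, d)

    def test_tight_groups_stay_neighbours_in_2d(self):
        dm = self._two_groups()
        emb = embed_2d(dm, seed=42, perplexity=3)
        xy = emb.coordinates
        for i in range(len(xy)):
            dists = np.linalg.norm(xy - xy[i], axis=1)
            dists[i] = np.inf
            nn = int(np.argmin(dists))
            assert (i < 6) == (nn < 6)

    def test_deterministic_for_fixed_seed(self):
        dm = self._two_groups()
        a = embed_2d(dm, seed=7, perplexity=3).coordinates
        b = embed_2d(dm, seed=7, perplexity=3).coordinates
        np.testing.assert_array_equal(a, b)

    def test_perplexity_must_be_below_item_count(self):
        dm = self._two_groups(n_per=2)  # 4 items... need n=3
        small = DistanceMatrix(dm.labels[:3], dm.values[:3, :3])
        with pytest.raises(ConfigurationError):
            embed_2d(small, perplexity=5)


class TestClusterQuality:
    def test_perfectly_separated_groups_score_one(self):
        dm = TestEmbedding._two_groups(within=0.0, between=1.0)
        groups = ["g1"] * 6 + ["g2"] * 6
        assert cluster_quality(dm, groups) == pytest.approx(1.0)

    def test_label_permutation_baseline_near_zero(self):
        dm = TestEmbedding._two_groups(within=0.05, between=0.95)
        groups = np.array(["g1"] * 6 + ["g2"] * 6)
        rng = np.random.default_rng(8)
        vals = [abs(cluster_quality(dm, list(rng.permutation(groups))))
                for _ in range(20)]
        # exclude permutations that happen to reproduce the true split
        assert np.median(vals) < 0.2

    def test_all_equal_distances_score_zero(self):
        n = 8
        d = np.full((n, n), 0.5)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix([str(i) for i in range(n)], d)
        assert cluster_quality(dm, ["a"] * 4 + ["b"] * 4) == pytest.approx(0.0)

    def test_single_group_raises(self):
        dm = TestEmbedding._two_groups()
        with pytest.raises(ConfigurationError):
            cluster_quality(dm, ["g"] * 12)
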