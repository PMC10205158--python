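"""Lexical similarity constructors and model-level statistics."""

import numpy as np
import networkx as nx
import pytest
from scipy.stats import f_oneway

from lexrsa import (
    AffectiveRatings,
    EmbeddingTable,
    PhonologicalData,
    TaxonomyGraph,
    affective_similarity,
    anova_from_summary,
    embedding_similarity,
    neighbourhood_density_dissimilarity,
    pearson_filon_overlapping_z,
    phonological_similarity,
    wu_palmer_similarity,
)
from lexrsa.lexical import levenshtein_distance


def ratings_from(vda):
    vda = np.asarray(vda, float)
    words = [f"w{i}" for i in range(len(vda))]
    return AffectiveRatings(words, vda[:, 0], vda[:, 1], vda[:, 2])


class TestAffectiveSimilarity:
    def test_identical_words_have_similarity_one(self):
        s = affective_similarity(ratings_from([[2, 3, 4], [2, 3, 4], [6, 6, 6]]))
        assert s.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_three_word_example(self):
        # distances sqrt(108), sqrt(27), sqrt(27); normalized by sqrt(108)
        s = affective_similarity(ratings_from([[1, 1, 1], [7, 7, 7], [4, 4, 4]]))
        assert s.values[0, 1] == pytest.approx(0.0)
        assert s.values[0, 2] == pytest.approx(0.5)
        assert s.values[1, 2] == pytest.approx(0.5)

    def test_most_distant_pair_scores_exactly_zero(self, rng):
        vda = 1 + 6 * rng.random((20, 3))
        s = affective_similarity(ratings_from(vda))
        off = s.values[~np.eye(20, dtype=bool)]
        assert off.min() == pytest.approx(0.0, abs=1e-15)

    def test_shift_invariance_and_scale_equivariance(self, rng):
        vda = 2 + 2 * rng.random((10, 3))
        base = affective_similarity(ratings_from(vda)).values
        shifted = affective_similarity(ratings_from(vda + 0.9)).values
        np.testing.assert_allclose(shifted, base, atol=1e-12)
        scaled = affective_similarity(ratings_from(1 + (vda - 1) * 1.5)).values
        np.testing.assert_allclose(scaled, base, atol=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="normalizer"):
            affective_similarity(ratings_from([[3, 3, 3], [3, 3, 3]]))
        with pytest.raises(ValueError, match="2 words"):
            affective_similarity(ratings_from([[3, 3, 3]]))


class TestEmbeddingSimilarity:
    def test_reference_cosines(self):
        emb = EmbeddingTable(["a", "b", "c", "d"], [[1, 0], [1, 0], [0, 1], [1, 1]])
        s = embedding_similarity(emb)
        assert s.values[0, 1] == pytest.approx(1.0)
        assert s.values[0, 2] == pytest.approx(0.0)
        assert s.values[0, 3] == pytest.approx(0.70711, abs=1e-5)

    def test_zero_norm_row_names_offender(self):
        emb = EmbeddingTable(["ok", "bad"], [[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="bad"):
            embedding_similarity(emb)


def brute_levenshtein(a, b):
    """Naive exponential recursion — the independent oracle."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    cost = a[0] != b[0]
    return min(
        brute_levenshtein(a[1:], b) + 1,
        brute_levenshtein(a, b[1:]) + 1,
        brute_levenshtein(a[1:], b[1:]) + cost,
    )


class TestPhonologicalSimilarity:
    def test_identical_and_single_substitution(self):
        phon = PhonologicalData(["cat", "kat", "rat"], ["kat", "kat", "rat"])
        s = phonological_similarity(phon)
        assert s.values[0, 1] == pytest.approx(1.0)
        assert s.values[0, 2] == pytest.approx(1 - 1 / 3)

    def test_bounded_in_unit_interval(self, rng):
        words = [f"w{i}" for i in range(12)]
        trs = ["".join(rng.choice(list("abc"), size=rng.integers(1, 7))) for _ in words]
        s = phonological_similarity(PhonologicalData(words, trs))
        assert s.values.min() >= 0.0 and s.values.max() <= 1.0

    def test_distance_matches_bruteforce_recursion(self, rng):
        # all pair lengths <= 4 plus a handful of length-5 strings, 3 symbols
        alphabet = list("abc")
        pool = ["".join(rng.choice(alphabet, size=n)) for n in rng.integers(1, 5, 80)]
        pool += ["".join(rng.choice(alphabet, size=5)) for _ in range(8)]
        pairs = rng.choice(len(pool), size=(120, 2))
        for i, j in pairs:
            a, b = pool[i], pool[j]
            assert levenshtein_distance(a, b) == brute_levenshtein(a, b), (a, b)

    def test_empty_transcription_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PhonologicalData(["a", "b"], ["x", ""])


class TestNeighbourhoodDensity:
    def test_absolute_difference_and_orientation(self):
        phon = PhonologicalData(["a", "b", "c"], ["x", "y", "z"], densities=[5, 12, 5])
        d = neighbourhood_density_dissimilarity(phon)
        assert d.orientation == "dissimilarity"
        assert d.values[0, 1] == 7
        assert d.values[0, 2] == 0

    def test_triangle_inequality(self, rng):
        dens = rng.integers(0, 40, size=15)
        words = [f"w{i}" for i in range(15)]
        d = neighbourhood_density_dissimilarity(
            PhonologicalData(words, ["x"] * 15, densities=dens)
        ).values
        for a in range(15):
            for b in range(15):
                for c in range(15):
                    assert d[a, c] <= d[a, b] + d[b, c] + 1e-12


def small_taxonomy():
    t = nx.DiGraph()
    t.add_edges_from([("root", "A"), ("A", "B"), ("A", "C"), ("root", "D"), ("root", "E")])
    return TaxonomyGraph(
        t, "root", {"b": "B", "c": "C", "d": "D", "e": "E", "a": "A"}
    )


class TestWuPalmer:
    def test_self_similarity_is_one(self):
        s = wu_palmer_similarity(small_taxonomy(), ["b", "c"])
        assert s.values[0, 0] == 1.0

    def test_siblings_under_depth2_parent(self):
        # root->A->{B, C}: depths 3, LCS depth 2 -> 2*2/6
        s = wu_palmer_similarity(small_taxonomy(), ["b", "c"])
        assert s.values[0, 1] == pytest.approx(2 / 3)

    def test_depth2_leaves_with_root_lcs(self):
        s = wu_palmer_similarity(small_taxonomy(), ["d", "e"])
        assert s.values[0, 1] == pytest.approx(0.5)

    def test_unmapped_words_listed(self):
        with pytest.raises(KeyError, match="ghost"):
            wu_palmer_similarity(small_taxonomy(), ["b", "ghost"])

    def test_values_in_unit_interval(self, word_bundle):
        s = wu_palmer_similarity(word_bundle.taxonomy, word_bundle.word_set.words)
        assert (s.values > 0).all() and (s.values <= 1).all()


class TestPearsonFilon:
    def test_equal_correlations_give_zero(self):
        r = pearson_filon_overlapping_z(0.3, 0.3, 0.5, 100)
        assert r.z == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_reproduces_reference_comparison(self):
        # affective-co-occurrence 0.065 vs affective-association 0.310,
        # overlap 0.458, 2145 word pairs from 66 words
        r = pearson_filon_overlapping_z(0.065, 0.310, 0.458, 66 * 65 // 2)
        assert r.z == pytest.approx(-11.4, abs=0.1)
        assert r.p_value < 1e-4

    def test_p_monotone_in_abs_z(self):
        zs = [pearson_filon_overlapping_z(0.1 * i, 0.0, 0.2, 50) for i in range(1, 6)]
        ps = [r.p_value for r in zs]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pearson_filon_overlapping_z(1.0, 0.2, 0.1, 50)
        with pytest.raises(ValueError):
            pearson_filon_overlapping_z(0.1, 0.2, 0.1, 3)

    def test_type_one_error_calibrated_under_null(self, rng):
        """Equal population correlations: two-sided rejection at 0.05 ~ 5%."""
        n, reps = 200, 5000
        # trivariate normal with corr(1,2)=corr(1,3)=0.3, corr(2,3)=0.5
        cov = np.array([[1.0, 0.3, 0.3], [0.3, 1.0, 0.5], [0.3, 0.5, 1.0]])
        chol = np.linalg.cholesky(cov)
        rejections = 0
        for _ in range(reps):
            x = rng.standard_normal((n, 3)) @ chol.T
            c = np.corrcoef(x.T)
            r = pearson_filon_overlapping_z(c[0, 1], c[0, 2], c[1, 2], n)
            rejections += r.p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestAnovaFromSummary:
    def test_equal_means_give_zero_f(self):
        r = anova_from_summary([2.0, 2.0], [0.5, 0.7], [10, 10])
        assert r.f == 0.0

    def test_reproduces_reference_arousal_check(self):
        # per-class arousal summaries; printed inputs are rounded -> 2%
        r = anova_from_summary([3.98, 4.23, 4.54], [0.49, 0.79, 1.05], [22, 22, 22])
        assert r.f == pytest.approx(2.62, rel=0.02)
        assert (r.df_between, r.df_within) == (2, 63)

    def test_matches_raw_data_anova(self, rng):
        """Engineer raw samples with exact summaries; compare to scipy."""
        means, sds, ns = [1.0, 1.8, 0.4], [0.6, 1.1, 0.9], [8, 12, 10]
        groups = []
        for m, s, n in zip(means, sds, ns):
            x = rng.standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1)  # exact mean 0, sd 1
            groups.append(m + s * x)
        expected = f_oneway(*groups)
        r = anova_from_summary(means, sds, ns)
        assert r.f == pytest.approx(expected.statistic, rel=1e-10)
        assert r.p_value == pytest.approx(expected.pvalue, rel=1e-8)

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summary([1.0, 2.0], [0.0, 0.0], [5, 5])
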