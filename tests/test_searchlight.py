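"""Searchlight geometry, neural RDMs, (partial) rank correlation, smoothing."""

import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

from lexrsa import (
    ConditionPatterns,
    SearchlightSpec,
    SimilarityMatrix,
    define_searchlights,
    fisher_z_map,
    grey_matter_mask,
    neural_similarity,
    rsa_correlation,
    searchlight_rsa,
    smooth_volume,
    vectorize_rdm,
)


def full_mask(shape, voxel_mm=1.0):
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return grey_matter_mask(np.ones(shape), affine=affine)


def random_model(rng, n, metric="model"):
    a = rng.standard_normal((n, n))
    s = (a + a.T) / 2
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix([f"w{i}" for i in range(n)], s, metric)


class TestDefineSearchlights:
    def test_interior_center_gets_face_neighbours_at_k7(self):
        maps = define_searchlights(full_mask((10, 10, 10)), SearchlightSpec(k=7))
        center = np.array([5, 5, 5])
        c = int(np.flatnonzero((maps.voxel_coords == center).all(axis=1))[0])
        members = maps.voxel_coords[maps.members[c]]
        assert (members[0] == center).all()  # center first
        dists = np.linalg.norm(members - center, axis=1)
        np.testing.assert_array_equal(np.sort(dists), [0, 1, 1, 1, 1, 1, 1])

    def test_k_at_least_mask_size_uses_whole_mask(self):
        maps = define_searchlights(full_mask((3, 3, 3)), SearchlightSpec(k=100))
        assert maps.k == 27
        for c in range(maps.n_centers):
            assert sorted(maps.members[c]) == list(range(27))

    def test_matches_bruteforce_all_pairs_sort(self, rng):
        prob = (rng.random((8, 8, 8)) > 0.4).astype(float)
        prob[4, 4, 4] = 1.0
        mask = grey_matter_mask(prob, threshold=0.5, affine=np.diag([2.0, 2.0, 2.0, 1.0]))
        maps = define_searchlights(mask, SearchlightSpec(k=11))
        coords = maps.voxel_coords * 2.0
        for c in range(0, maps.n_centers, 17):
            d = np.linalg.norm(coords - coords[c], axis=1)
            order = sorted(range(len(d)), key=lambda i: (round(d[i] ** 2, 9), i))[:11]
            np.testing.assert_array_equal(maps.members[c], order)

    def test_deterministic_across_calls(self, rng):
        prob = rng.random((7, 7, 7))
        mask = grey_matter_mask(prob, threshold=0.5)
        a = define_searchlights(mask, SearchlightSpec(k=9))
        b = define_searchlights(mask, SearchlightSpec(k=9))
        np.testing.assert_array_equal(a.members, b.members)


class TestNeuralSimilarity:
    def test_identical_and_orthogonal_patterns(self):
        p = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        s = neural_similarity(p, centring=False)
        assert s.values[0, 1] == pytest.approx(1.0)
        assert s.values[0, 2] == pytest.approx(0.0)

    def test_centred_cosine_equals_row_correlation_on_doubly_centred_data(self, rng):
        x = rng.standard_normal((8, 30))
        x -= x.mean(axis=0, keepdims=True)
        x -= x.mean(axis=1, keepdims=True)  # now centring is a no-op, row means 0
        s = neural_similarity(x, centring=True)
        np.testing.assert_allclose(s.values, np.corrcoef(x), atol=1e-10)

    def test_zero_norm_centred_pattern_flagged(self):
        p = np.ones((3, 4))  # after centring every pattern is zero
        s = neural_similarity(p, centring=True)
        assert np.isnan(s.values[0, 1])


class TestRsaCorrelation:
    def test_model_identical_to_neural_gives_one(self, rng):
        m = random_model(rng, 10)
        assert rsa_correlation(m, m) == pytest.approx(1.0)

    def test_partialling_model_out_of_itself_gives_zero(self, rng):
        m = random_model(rng, 10)
        n = random_model(rng, 10)
        assert rsa_correlation(n, m, covariates=[m]) == pytest.approx(0.0, abs=1e-10)

    def test_single_covariate_matches_closed_form(self, rng):
        neural, model, cov = (random_model(rng, 12, f"m{i}") for i in range(3))
        got = rsa_correlation(neural, model, covariates=[cov])
        rx = rankdata(vectorize_rdm(neural).values)
        ry = rankdata(vectorize_rdm(model).values)
        rz = rankdata(vectorize_rdm(cov).values)
        r_xy = np.corrcoef(rx, ry)[0, 1]
        r_xz = np.corrcoef(rx, rz)[0, 1]
        r_zy = np.corrcoef(rz, ry)[0, 1]
        expected = (r_xy - r_xz * r_zy) / np.sqrt((1 - r_xz**2) * (1 - r_zy**2))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_plain_matches_scipy_spearman(self, rng):
        neural, model = random_model(rng, 9, "a"), random_model(rng, 9, "b")
        expected = spearmanr(
            vectorize_rdm(neural).values, vectorize_rdm(model).values
        ).statistic
        assert rsa_correlation(neural, model) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self, rng):
        n = random_model(rng, 5)
        flat = SimilarityMatrix(n.labels, np.ones((5, 5)), "flat")
        with pytest.raises(ValueError, match="constant"):
            rsa_correlation(n, flat)


def patterns_on(mask, data):
    return ConditionPatterns(
        words=[f"w{i}" for i in range(data.shape[0])],
        data=data,
        affine=mask.affine,
    )


class TestSearchlightRsa:
    def test_planted_rdm_gives_rho_one_everywhere(self, rng):
        """Neighbourhood = whole (small) mask, patterns factor the model."""
        mask = full_mask((3, 3, 3))
        # unit-diagonal PSD model: Gram matrix of unit-norm random vectors
        g = rng.standard_normal((8, 6))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        model = SimilarityMatrix([f"w{i}" for i in range(8)], g @ g.T, "gram")
        vals, vecs = np.linalg.eigh(model.values)
        scores = vecs[:, vals > 1e-10] * np.sqrt(vals[vals > 1e-10])
        pat = np.zeros((8, 27))
        pat[:, : scores.shape[1]] = scores
        maps = define_searchlights(mask, SearchlightSpec(k=27))
        res = searchlight_rsa(
            patterns_on(mask, pat.reshape(8, 3, 3, 3)),
            maps,
            model,
            spec=SearchlightSpec(k=27, centring=False),
        )
        np.testing.assert_allclose(res.values[mask.mask], 1.0, atol=1e-10)

    def test_noise_patterns_give_near_zero_mean_rho(self, rng):
        mask = full_mask((9, 9, 9))
        model = random_model(rng, 20)
        pat = rng.standard_normal((20, 9, 9, 9))
        maps = define_searchlights(mask, SearchlightSpec(k=25))
        res = searchlight_rsa(patterns_on(mask, pat), maps, model,
                              spec=SearchlightSpec(k=25))
        assert maps.n_centers >= 500
        assert abs(np.nanmean(res.values[mask.mask])) < 0.02

    def test_monotone_model_transform_leaves_map_identical(self, rng):
        mask = full_mask((5, 5, 5))
        model = random_model(rng, 10)
        shifted = SimilarityMatrix(
            model.labels, np.sign(model.values) * np.abs(model.values) ** 3, "t"
        )
        # strictly increasing odd transform preserves ranks
        pat = rng.standard_normal((10, 5, 5, 5))
        maps = define_searchlights(mask, SearchlightSpec(k=15))
        a = searchlight_rsa(patterns_on(mask, pat), maps, model, spec=SearchlightSpec(k=15))
        b = searchlight_rsa(patterns_on(mask, pat), maps, shifted, spec=SearchlightSpec(k=15))
        np.testing.assert_array_equal(a.values, b.values)

    def test_invariant_to_common_positive_rescaling(self, rng):
        mask = full_mask((5, 5, 5))
        model = random_model(rng, 10)
        pat = rng.standard_normal((10, 5, 5, 5))
        maps = define_searchlights(mask, SearchlightSpec(k=15))
        a = searchlight_rsa(patterns_on(mask, pat), maps, model, spec=SearchlightSpec(k=15))
        b = searchlight_rsa(patterns_on(mask, 3.25 * pat), maps, model, spec=SearchlightSpec(k=15))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12, equal_nan=True)


class TestFisherZ:
    def test_reference_values_and_odd_symmetry(self, rng):
        mask = full_mask((2, 2, 2))
        vals = np.array([0.0, 0.5, -0.5, 0.9, -0.9, 0.99, 1.0, np.nan]).reshape(2, 2, 2)
        from lexrsa import SubjectRsaMap

        z = fisher_z_map(SubjectRsaMap(values=vals, model="m"))
        flat = z.values.ravel()
        assert flat[0] == 0.0
        assert flat[1] == pytest.approx(0.54931, abs=1e-5)
        assert flat[2] == pytest.approx(-flat[1])
        assert np.isnan(flat[6])  # |rho| = 1 flagged missing


class TestSmoothVolume:
    def test_constant_volume_unchanged_under_mask_renormalization(self):
        vol = np.full((8, 8, 8), 3.7)
        vol[0, 0, 0] = np.nan
        out = smooth_volume(vol, fwhm_mm=4.0)
        np.testing.assert_allclose(out[np.isfinite(vol)], 3.7, atol=1e-9)
        assert np.isnan(out[0, 0, 0])

    def test_small_fwhm_limit_returns_input(self, rng):
        vol = rng.standard_normal((6, 6, 6))
        out = smooth_volume(vol, fwhm_mm=1e-4)
        np.testing.assert_allclose(out, vol, atol=1e-8)

    def test_point_source_mass_conserved(self):
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        out = smooth_volume(vol, fwhm_mm=3.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_volume(np.zeros((3, 3, 3)), fwhm_mm=0.0)
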