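"""Response-specific model: preprocessing, eigenstructure, benchmarks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import floodcyto as fc
from floodcyto.flood import DegenerateMarkerError, FloodModel, RankError


class TestShiftToPositive:
    def test_worked_example(self):
        shifted, shift = fc.shift_to_positive(np.array([[-3.0, 0.0], [2.0, 5.0]]))
        np.testing.assert_array_equal(shifted, [[1.0, 4.0], [6.0, 9.0]])
        assert shift == -4.0

    def test_minimum_already_one_is_unchanged(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        shifted, shift = fc.shift_to_positive(x)
        np.testing.assert_array_equal(shifted, x)
        assert shift == 0.0

    @given(
        arrays(
            float, (5, 3),
            elements=st.floats(-1e6, 1e6, allow_nan=False, width=32),
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_minimum_one_and_differences_preserved(self, x):
        shifted, _ = fc.shift_to_positive(x)
        assert shifted.min() == 1.0
        np.testing.assert_allclose(
            np.diff(shifted, axis=0), np.diff(x, axis=0), atol=1e-6
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fc.shift_to_positive(np.array([[np.nan, 1.0]]))


class TestPreprocess:
    def test_control_self_standardization(self):
        rng = np.random.default_rng(20)
        raw = rng.lognormal(3, 1, size=(500, 4)) * 100
        _, shift = fc.shift_to_positive(raw)
        params = fc.fit_preprocess(raw, ("a", "b", "c", "d"), shift)
        z = fc.preprocess(raw, params)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_two_event_hand_computation(self):
        raw = np.array([[10.0], [1000.0]])
        params = fc.fit_preprocess(raw, ("m",), shift=0.0)
        assert params.mean[0] == pytest.approx(2.0)
        assert params.sd[0] == pytest.approx(np.sqrt(2.0))

    def test_response_pool_gets_nonzero_means(self):
        rng = np.random.default_rng(21)
        ctrl = rng.lognormal(2, 0.5, (300, 3))
        resp = rng.lognormal(3, 0.5, (300, 3))
        _, shift = fc.shift_to_positive(np.vstack([ctrl, resp]))
        params = fc.fit_preprocess(ctrl, ("a", "b", "c"), shift)
        z = fc.preprocess(resp, params)
        assert np.all(np.abs(z.mean(axis=0)) > 0.1)

    def test_zero_variance_marker_named(self):
        raw = np.column_stack([np.full(10, 5.0), np.arange(1.0, 11.0)])
        with pytest.raises(DegenerateMarkerError, match="flat"):
            fc.fit_preprocess(raw, ("flat", "ok"), shift=0.0)


def _oracle_eig(z):
    """Independent dense eigendecomposition via SVD of the centred matrix."""
    zc = z - z.mean(axis=0)
    _, s, vt = np.linalg.svd(zc, full_matrices=False)
    eigval = s**2 / (zc.shape[0] - 1)
    return eigval, vt.T


class TestFitFlood:
    def test_one_dimensional_response(self):
        rng = np.random.default_rng(22)
        n = 400
        ctrl = np.zeros((n, 3))
        ctrl[:, 0] = rng.normal(0, 1, n)
        ctrl[:, 1] = rng.normal(0, 1e-3, n)
        ctrl[:, 2] = rng.normal(0, 1e-3, n)
        resp = np.zeros((n, 3))
        resp[:, 2] = rng.normal(0, 2, n)
        res = fc.fit_flood(ctrl, resp, k_c=1, k_r=1)
        np.testing.assert_allclose(
            np.abs(res.response_loadings[:, 0]), [0, 0, 1], atol=1e-2
        )
        assert res.explained_fractions[0] > 0.999

    def test_small_fixture_matches_eigen_oracle(self):
        ctrl = np.array(
            [[1.0, 2.0, 0.5], [2.0, 1.0, 0.4], [3.0, 3.0, 0.6],
             [4.0, 2.5, 0.7], [2.5, 3.5, 0.3], [3.5, 1.5, 0.5]]
        )
        resp = ctrl[::-1] * 1.3 + 0.2
        res = fc.fit_flood(ctrl, resp, k_c=1, k_r=2)
        # oracle: deflate independently, then dense eigendecomposition
        c_eigval, c_vec = _oracle_eig(ctrl)
        v1 = c_vec[:, [0]]
        proj = np.eye(3) - v1 @ v1.T
        defl = (resp - resp.mean(axis=0)) @ proj
        r_eigval, r_vec = _oracle_eig(defl)
        shares = r_eigval / r_eigval.sum()
        np.testing.assert_allclose(
            res.explained_fractions, shares[:2], atol=1e-8
        )
        for j in range(2):
            dot = abs(res.response_loadings[:, j] @ r_vec[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_injected_direction_recovered_within_5_degrees(self):
        rng = np.random.default_rng(23)
        p, n = 6, 5000
        ctrl = rng.normal(0, 1, (n, p))
        v = np.array([0.5, -0.5, 0.5, 0.3, -0.3, 0.25])
        v /= np.linalg.norm(v)
        resp = rng.normal(0, 1, (n, p)) + np.outer(rng.normal(0, 4, n), v)
        res = fc.fit_flood(ctrl, resp, k_c=1, k_r=2)
        proj = res.deflation
        v_defl = proj @ v
        v_defl /= np.linalg.norm(v_defl)
        cos = abs(v_defl @ res.response_loadings[:, 0])
        assert np.degrees(np.arccos(min(cos, 1.0))) <= 5.0

    def test_rank_errors(self):
        rng = np.random.default_rng(24)
        z = rng.normal(0, 1, (50, 3))
        with pytest.raises(RankError):
            fc.fit_flood(z, z, k_c=2, k_r=2)
        rank1 = np.outer(rng.normal(0, 1, 50), np.ones(3))
        with pytest.raises(RankError):
            fc.fit_flood(rank1, z, k_c=2, k_r=1)

    def test_empty_pool_rejected(self):
        z = np.random.default_rng(0).normal(0, 1, (10, 3))
        with pytest.raises(ValueError):
            FloodModel(z[:0], z, ("a", "b", "c"))


class TestModelInvariants:
    def test_deflation_orthogonality(self, flood_fit):
        res, _ = flood_fit
        defl = res.model.response_z @ res.deflation
        inner = defl @ res.control_loadings
        assert np.abs(inner).max() <= 1e-8

    def test_loading_blocks_orthonormal(self, flood_fit):
        res, _ = flood_fit
        np.testing.assert_allclose(
            res.control_loadings.T @ res.control_loadings,
            np.eye(res.k_c), atol=1e-10,
        )
        np.testing.assert_allclose(
            res.response_loadings.T @ res.response_loadings,
            np.eye(res.k_r), atol=1e-10,
        )
        cross = res.control_loadings.T @ res.response_loadings
        assert np.abs(cross).max() <= 1e-8

    def test_explained_fractions_monotone_and_bounded(self, flood_fit):
        res, _ = flood_fit
        ev = res.explained_fractions
        assert np.all(ev > 0) and np.all(ev <= 1)
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1 + 1e-12

    def test_repeated_fit_is_bit_identical(self):
        rng = np.random.default_rng(25)
        ctrl = rng.normal(0, 1, (300, 5))
        resp = rng.normal(0.5, 1.2, (300, 5))
        a = fc.fit_flood(ctrl, resp, k_c=1, k_r=2)
        b = fc.fit_flood(ctrl, resp, k_c=1, k_r=2)
        np.testing.assert_array_equal(a.response_loadings, b.response_loadings)
        np.testing.assert_array_equal(a.explained_fractions, b.explained_fractions)

    def test_marker_permutation_equivariance(self):
        rng = np.random.default_rng(26)
        ctrl = rng.normal(0, 1, (400, 4))
        resp = rng.normal(0, 1, (400, 4)) + np.outer(
            rng.normal(0, 3, 400), [0.8, 0.1, -0.5, 0.3]
        )
        perm = np.array([2, 0, 3, 1])
        a = fc.fit_flood(ctrl, resp, k_c=1, k_r=1)
        b = fc.fit_flood(ctrl[:, perm], resp[:, perm], k_c=1, k_r=1)
        np.testing.assert_allclose(
            np.abs(b.response_loadings[:, 0]),
            np.abs(a.response_loadings[perm, 0]),
            atol=1e-8,
        )
        np.testing.assert_allclose(a.explained_fractions, b.explained_fractions)

    def test_event_order_equivariance(self):
        rng = np.random.default_rng(27)
        ctrl = rng.normal(0, 1, (200, 4))
        resp = rng.normal(1, 1, (200, 4))
        a = fc.fit_flood(ctrl, resp, k_c=1, k_r=2)
        order = rng.permutation(200)
        b = fc.fit_flood(ctrl[order], resp[order], k_c=1, k_r=2)
        scores_a = a.project(resp)[order]
        scores_b = b.project(resp[order])
        np.testing.assert_allclose(scores_a, scores_b, atol=1e-8)


class TestProjection:
    def test_centered_control_pool_projects_to_zero_mean(self, flood_fit):
        res, _ = flood_fit
        ctrl = res.model.control_z
        scores = res.project(ctrl - ctrl.mean(axis=0))
        assert np.abs(scores.mean(axis=0)).max() < 1e-10

    def test_fixture_scores_match_matrix_product_oracle(self, flood_fit):
        res, _ = flood_fit
        z = res.model.response_z[:100]
        expected = z @ res.deflation @ res.response_loadings
        np.testing.assert_allclose(res.project(z), expected, atol=1e-12)


class TestBenchmarkRegion:
    def test_defining_sample_inside_fraction(self):
        rng = np.random.default_rng(28)
        scores = rng.normal(0, 1, (5000, 2))
        region = fc.benchmark_region(scores, coverage=0.80)
        inside = fc.overlap_fraction(scores, region)
        assert abs(inside - 0.80) <= 1.0 / len(scores) + 1e-12

    def test_radius_approaches_chi2_quantile(self):
        from scipy.stats import chi2

        rng = np.random.default_rng(29)
        scores = rng.normal(0, 1, (200_000, 2))
        region = fc.benchmark_region(scores, coverage=0.80)
        assert region.threshold == pytest.approx(chi2.ppf(0.80, df=2), rel=0.02)

    def test_full_coverage_rejected(self):
        scores = np.random.default_rng(0).normal(0, 1, (100, 2))
        with pytest.raises(ValueError):
            fc.benchmark_region(scores, coverage=1.0)

    def test_too_few_scores_rejected(self):
        scores = np.random.default_rng(0).normal(0, 1, (20, 2))
        with pytest.raises(ValueError):
            fc.benchmark_region(scores)

    def test_singular_covariance_rejected(self):
        base = np.random.default_rng(0).normal(0, 1, 100)
        scores = np.column_stack([base, 2 * base])
        with pytest.raises(ValueError, match="singular"):
            fc.benchmark_region(scores)

    def test_translated_cloud_has_negligible_overlap(self):
        rng = np.random.default_rng(30)
        scores = rng.normal(0, 1, (20_000, 2))
        region = fc.benchmark_region(scores, coverage=0.80)
        shifted = scores + np.array([10.0, 0.0])
        assert fc.overlap_fraction(shifted, region) < 0.01

    def test_empty_score_set_rejected(self):
        region = fc.benchmark_region(
            np.random.default_rng(0).normal(0, 1, (100, 2))
        )
        with pytest.raises(ValueError):
            fc.overlap_fraction(np.empty((0, 2)), region)


class TestEndToEnd:
    def test_exercise_shift_geometry(self, flood_fit):
        """Response loadings mirror the configured biology: the markers that
        rise over the week (CBRM1/5, CD49d, LAIR-1) load together and
        opposite to CD62L on the dominant component."""
        res, _ = flood_fit
        w = dict(zip(res.markers, res.response_loadings[:, 0]))
        up = [w["CBRM1/5"], w["CD49d"], w["LAIR-1"]]
        assert np.sign(up[0]) == np.sign(up[1]) == np.sign(up[2])
        assert np.sign(w["CD62L"]) == -np.sign(up[0])

    def test_control_samples_overlap_benchmark_response_day8_does_not(
        self, flood_fit
    ):
        _, per_sample = flood_fit
        d1 = [v["overlap"] for k, v in per_sample.items() if k[1] == "morning_d1"]
        d8 = [v["overlap"] for k, v in per_sample.items() if k[1] == "morning_d8"]
        assert min(d1) > 0.5
        assert max(d8) < 0.2

    def test_serialization_round_trip(self, flood_fit, tmp_path):
        res, _ = flood_fit
        path = tmp_path / "model.json"
        res.save(path)
        back = fc.FloodResults.load(path)
        np.testing.assert_allclose(back.response_loadings, res.response_loadings)
        np.testing.assert_allclose(back.explained_fractions, res.explained_fractions)
        np.testing.assert_allclose(back.benchmark.threshold, res.benchmark.threshold)
        assert back.params.shift == res.params.shift


class TestBiplotExport:
    def test_files_exist_and_tables_round_trip(self, flood_fit, tmp_path):
        res, per_sample = flood_fit
        one_subject = {k: v for k, v in per_sample.items() if k[0] == "S01"}
        from floodcyto.plotting import export_biplot

        artefacts = export_biplot(res, one_subject, tmp_path)
        assert artefacts["loadings"].exists()
        loadings = pd.read_csv(artefacts["loadings"], sep="\t", index_col="marker")
        np.testing.assert_allclose(
            loadings.to_numpy(), res.response_loadings, atol=1e-12
        )
        for k in one_subject:
            assert artefacts[f"biplot_{k[0]}_{k[1]}"].exists()

    def test_exported_vector_lengths_and_angles(self, flood_fit, tmp_path):
        res, per_sample = flood_fit
        from floodcyto.plotting import export_biplot

        artefacts = export_biplot(
            res, {k: v for k, v in per_sample.items() if k[0] == "S02"}, tmp_path
        )
        loadings = pd.read_csv(
            artefacts["loadings"], sep="\t", index_col="marker"
        ).to_numpy()
        lengths = np.linalg.norm(loadings, axis=1)
        np.testing.assert_allclose(
            lengths, np.linalg.norm(res.response_loadings, axis=1), atol=1e-12
        )
        i, j = 0, 4  # CD35 vs LAIR-1
        cos = loadings[i] @ loadings[j] / (lengths[i] * lengths[j])
        expected = res.response_loadings[i] @ res.response_loadings[j] / (
            lengths[i] * lengths[j]
        )
        assert np.arccos(np.clip(cos, -1, 1)) == pytest.approx(
            np.arccos(np.clip(expected, -1, 1)), abs=1e-12
        )
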