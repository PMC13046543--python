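import numpy as np
import pytest

from dynetfnc import gica
from dynetfnc.imageio import BoldSeries

from conftest import match_components


def _mk_series(data, sid="s0"):
    V = data.shape[1]
    return BoldSeries(
        data=data, tr_seconds=2.0, mask_voxel_indices=np.arange(V),
        grid_shape=(V, 1, 1), subject_id=sid,
    )


class TestReduceAndConcat:
    def test_full_rank_reduction_is_lossless(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 5)) @ rng.standard_normal((5, 50))
        s = _mk_series(X)
        Y, ops = gica.reduce_and_concat([s], n_subject_pcs=5, n_group_pcs=5)
        # projecting back reconstructs the centered data exactly
        Xc = X - X.mean(axis=0)
        U = ops.subject_bases[0]
        np.testing.assert_allclose(U @ (U.T @ Xc), Xc, atol=1e-8)

    def test_concatenated_row_count(self):
        rng = np.random.default_rng(1)
        series = [_mk_series(rng.standard_normal((20, 50)), f"s{i}") for i in range(2)]
        blocks = []
        for s in series:
            X = s.data - s.data.mean(axis=0)
            C = X @ X.T
            w, U = np.linalg.eigh(C)
            blocks.append(U[:, np.argsort(w)[::-1][:5]].T @ X)
        assert np.vstack(blocks).shape == (10, 50)
        Y, ops = gica.reduce_and_concat(series, 5, 8)
        assert Y.shape == (8, 50)

    def test_group_pca_matches_direct_eigendecomposition(self):
        """Group PCA rows must span the top-k eigenvectors of the concatenated
        covariance (|cosine| > 0.999 per component)."""
        rng = np.random.default_rng(2)
        series = [_mk_series(rng.standard_normal((15, 40)), f"s{i}") for i in range(3)]
        Y, ops = gica.reduce_and_concat(series, n_subject_pcs=10, n_group_pcs=4)
        concat = np.vstack(
            [ops.subject_bases[i].T @ (s.data - s.data.mean(axis=0))
             for i, s in enumerate(series)]
        )
        w, Q = np.linalg.eigh(concat @ concat.T)
        top = Q[:, np.argsort(w)[::-1][:4]]
        got = ops.group_basis
        cos = np.abs(np.sum(top * got, axis=0)) / (
            np.linalg.norm(top, axis=0) * np.linalg.norm(got, axis=0)
        )
        assert np.all(cos > 0.999)

    def test_excessive_group_pcs_rejected(self):
        rng = np.random.default_rng(3)
        s = _mk_series(rng.standard_normal((10, 30)))
        with pytest.raises(ValueError):
            gica.reduce_and_concat([s], 5, 6)


class TestInfomax:
    def test_recovers_laplacian_sources(self):
        rng = np.random.default_rng(0)
        S = rng.laplace(size=(2, 5000))
        A = rng.standard_normal((2, 2))
        res = gica.infomax_ica(A @ S, 2, seed=3)
        assert gica.amari_index(res["unmixing"] @ A) < 0.05

    def test_identity_mixing_yields_permutation(self):
        rng = np.random.default_rng(1)
        S = rng.laplace(size=(3, 4000))
        res = gica.infomax_ica(S, 3, seed=2)
        assert gica.amari_index(res["unmixing"]) < 0.05

    def test_run_to_run_stability(self):
        rng = np.random.default_rng(2)
        S = rng.laplace(size=(3, 4000))
        A = rng.standard_normal((3, 3))
        r1 = gica.infomax_ica(A @ S, 3, seed=10)
        r2 = gica.infomax_ica(A @ S, 3, seed=20)
        _, matched = match_components(r1["sources"], r2["sources"])
        assert np.all(matched > 0.95)

    def test_mixed_sub_and_super_gaussian_sources(self):
        rng = np.random.default_rng(3)
        S = np.vstack([rng.laplace(size=4000), rng.uniform(-1, 1, 4000)])
        A = rng.standard_normal((2, 2))
        res = gica.infomax_ica(A @ S, 2, seed=5)
        assert gica.amari_index(res["unmixing"] @ A) < 0.05


class TestAmariIndex:
    def test_zero_for_scaled_permutation(self):
        P = np.array([[0.0, 2.5, 0.0], [0.0, 0.0, -1.0], [3.0, 0.0, 0.0]])
        assert gica.amari_index(P) == 0.0

    def test_positive_for_mixing(self):
        assert gica.amari_index(np.ones((3, 3))) > 0.5


class TestIcasso:
    def test_well_separated_sources_are_stable(self):
        rng = np.random.default_rng(0)
        S = rng.laplace(size=(3, 3000))
        A = rng.standard_normal((6, 3))
        comps = gica.icasso_select(A @ S, 3, n_runs=10, min_cluster_size=8, seed=1)
        assert np.all(comps.stability_iq > 0.9)
        assert not comps.unstable.any()
        _, matched = match_components(comps.spatial_maps, S)
        assert np.all(matched > 0.95)

    def test_default_settings_are_100_runs_min_cluster_80(self):
        import inspect

        sig = inspect.signature(gica.icasso_select)
        assert sig.parameters["n_runs"].default == 100
        assert sig.parameters["min_cluster_size"].default == 80

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            gica.icasso_select(np.eye(4), 2, n_runs=1, min_cluster_size=1)
        with pytest.raises(ValueError):
            gica.icasso_select(np.eye(4), 2, n_runs=5, min_cluster_size=6)


class TestBackReconstruct:
    def test_exact_recovery_when_data_is_product(self):
        rng = np.random.default_rng(0)
        maps = np.linalg.qr(rng.standard_normal((50, 3)))[0].T  # orthonormal rows
        TC = rng.standard_normal((30, 3))
        s = _mk_series(TC @ maps)
        comps = gica.ComponentSet(spatial_maps=maps)
        out = gica.back_reconstruct(comps, None, [s])[0]
        resid = s.data - (s.data - s.data.mean(0)).mean() - out.time_courses @ (
            np.linalg.lstsq(out.time_courses, s.data - s.data.mean(0), rcond=None)[0]
        )
        # recovered TC spans the true TC: correlation after matching ~ 1
        _, matched = match_components(out.time_courses.T, TC.T)
        assert np.all(matched > 0.999)

    def test_subject_mismatch_rejected(self, noiseless_dataset):
        series, truth = noiseless_dataset
        from dynetfnc.gica import ReductionOperators

        ops = ReductionOperators([], np.empty((0, 0)), ["other"])
        comps = gica.ComponentSet(spatial_maps=truth.spatial_sources)
        with pytest.raises(ValueError, match="subject list"):
            gica.back_reconstruct(comps, ops, series)

    def test_noiseless_subject_recovery(self, noiseless_dataset):
        series, truth = noiseless_dataset
        comps = gica.ComponentSet(spatial_maps=truth.spatial_sources)
        out = gica.back_reconstruct(comps, None, series[:1])[0]
        _, matched = match_components(out.time_courses.T, truth.timecourses[0].T)
        assert np.all(matched > 0.999)


class TestEndToEndRecovery:
    def test_pipeline_recovers_sources_at_snr5(self, small_dataset):
        series, truth = small_dataset
        Y, ops = gica.reduce_and_concat(series, 20, 8)
        comps = gica.icasso_select(Y, 4, n_runs=8, min_cluster_size=6, seed=3)
        _, matched = match_components(comps.spatial_maps, truth.spatial_sources)
        assert np.all(matched > 0.9)
        subj = gica.back_reconstruct(comps, ops, series)
        for cs in subj:
            _, m = match_components(cs.spatial_maps, truth.spatial_sources)
            assert np.all(m > 0.8)

    def test_invariance_to_subject_rescaling(self, small_dataset):
        series, truth = small_dataset
        from dynetfnc.imageio import BoldSeries

        scaled = [
            BoldSeries(s.data * (3.0 if i == 0 else 1.0), s.tr_seconds,
                       s.mask_voxel_indices, s.grid_shape, s.subject_id)
            for i, s in enumerate(series)
        ]
        Y1, _ = gica.reduce_and_concat(series, 12, 6)
        Y2, _ = gica.reduce_and_concat(scaled, 12, 6)
        c1 = gica.icasso_select(Y1, 4, n_runs=6, min_cluster_size=4, seed=3)
        c2 = gica.icasso_select(Y2, 4, n_runs=6, min_cluster_size=4, seed=3)
        _, matched = match_components(c1.spatial_maps, c2.spatial_maps)
        assert np.all(matched > 0.95)

    def test_sign_convention_nonnegative_skewness(self, small_dataset):
        from scipy.stats import skew

        series, _ = small_dataset
        Y, _ = gica.reduce_and_concat(series, 12, 6)
        comps = gica.icasso_select(Y, 4, n_runs=6, min_cluster_size=4, seed=3)
        assert np.all(skew(comps.spatial_maps, axis=1) >= 0)


class TestLabelComponents:
    def _comps_and_templates(self):
        rng = np.random.default_rng(0)
        from dynetfnc.synthdata import generate_spatial_sources

        S, _ = generate_spatial_sources((12, 12, 12), 4, 2.0, seed=2)
        templates = {f"net_{i}": S[i] for i in range(3)}
        return S, templates, rng

    def test_self_match_gets_labeled(self):
        S, templates, _ = self._comps_and_templates()
        comps = gica.ComponentSet(spatial_maps=S[:3].copy())
        out = gica.label_components(comps, templates)
        assert out.labels == ["net_0", "net_1", "net_2"]
        assert all(r == pytest.approx(1.0, abs=1e-9) for r, _ in out.template_correlations)

    def test_white_noise_component_is_artifact(self):
        S, templates, rng = self._comps_and_templates()
        noise = rng.standard_normal((1, S.shape[1]))
        comps = gica.ComponentSet(spatial_maps=noise)
        out = gica.label_components(comps, templates, artifact_r_threshold=0.2)
        assert out.labels == ["artifact"]

    def test_default_threshold_is_0_2(self):
        import inspect

        sig = inspect.signature(gica.label_components)
        assert sig.parameters["artifact_r_threshold"].default == 0.2

    def test_gray_matter_energy_rule(self):
        S, templates, _ = self._comps_and_templates()
        gm = np.zeros(S.shape[1], dtype=bool)  # nothing counts as gray matter
        comps = gica.ComponentSet(spatial_maps=S[:2].copy())
        out = gica.label_components(comps, templates, gray_matter_mask=gm)
        assert out.labels == ["artifact", "artifact"]

    def test_empty_template_set_rejected(self):
        comps = gica.ComponentSet(spatial_maps=np.random.default_rng(0).standard_normal((1, 100)))
        with pytest.raises(ValueError, match="empty"):
            gica.label_components(comps, {})
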