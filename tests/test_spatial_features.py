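"""DCPM / TRCA / FBCSP spatial-filter bank."""

import numpy as np
import pytest
import scipy.linalg

import seqmotor as sm
from seqmotor.core_io import EpochSet
from seqmotor.spatial_features import (
    canonical_correlations,
    generalized_eig_descending,
    shrink,
)


def _epochset(data, labels, rate=200.0, tmin=-0.5):
    n_ch = data.shape[1]
    montage = sm.standard_montage(sm.DEFAULT_CHANNELS[:n_ch])
    tmax = tmin + data.shape[2] / rate
    return EpochSet(np.asarray(data, float), np.array(labels, object),
                    tmin, tmax, rate, montage)


@pytest.fixture(scope="module")
def feature_epochs(quiet_recording):
    return sm.prepare_feature_epochs(quiet_recording)


@pytest.fixture(scope="module")
def fitted(feature_epochs):
    return sm.fit_spatial_models(feature_epochs)


class TestPreparation:
    def test_epoch_geometry_and_branches(self, feature_epochs):
        assert feature_epochs.mrcp_branch.n_samples == 400  # 2 s x 200 Hz
        assert feature_epochs.mrcp_branch.rate == 200.0
        assert len(feature_epochs.band_branch) == 3
        assert set(feature_epochs.band_branch) == {(4.0, 8.0), (8.0, 13.0),
                                                   (13.0, 30.0)}

    def test_mrcp_branch_rejects_out_of_band_probe(self, tiny_montage):
        rate = 1000.0
        t = np.arange(int(20 * rate)) / rate
        data = np.tile(np.sin(2 * np.pi * 20.0 * t), (len(tiny_montage), 1))
        rec = sm.ContinuousRecording(data, rate, tiny_montage)
        out = sm.butterworth_filter(sm.resample(rec, 200.0), low=1.0, high=8.0)
        mid = slice(500, out.n_samples - 500)
        assert -20 * np.log10(np.abs(out.data[0, mid]).max()) > 20.0


class TestEigenSolver:
    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_matches_dense_brute_force(self, n):
        rng = np.random.default_rng(n)
        a = rng.normal(size=(n, n))
        a = a + a.T
        c = rng.normal(size=(n, n))
        b = c @ c.T + n * np.eye(n)
        vals, vecs = generalized_eig_descending(a, b)
        # brute-force oracle: scipy.linalg.eig on B^-1 A
        w = np.linalg.eigvals(np.linalg.solve(b, a))
        np.testing.assert_allclose(np.sort(vals), np.sort(w.real), atol=1e-8)
        for j in range(n):
            resid = a @ vecs[:, j] - vals[j] * (b @ vecs[:, j])
            assert np.abs(resid).max() < 1e-8

    def test_singular_b_rejected(self):
        a = np.eye(3)
        b = np.zeros((3, 3))
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            generalized_eig_descending(a, b)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 5))
        a = a + a.T
        b = np.eye(5)
        _, v1 = generalized_eig_descending(a, b)
        _, v2 = generalized_eig_descending(a.copy(), b.copy())
        np.testing.assert_array_equal(v1, v2)
        assert all(v1[np.argmax(np.abs(v1[:, j])), j] > 0
                   for j in range(5))


class TestDcpm:
    def test_first_filter_finds_discriminative_direction(self):
        # two classes differ only along a known spatial direction
        rng = np.random.default_rng(1)
        direction = np.array([0.8, -0.6, 0.0, 0.0])
        t = np.linspace(0, 2 * np.pi, 100)
        bump = np.sin(t)
        trials, labels = [], []
        for i in range(20):
            base = rng.normal(0, 0.01, size=(4, 100))
            if i % 2 == 0:
                trials.append(base + np.outer(direction, bump))
                labels.append("LL")
            else:
                trials.append(base)
                labels.append("RR")
        ep = _epochset(np.stack(trials), labels)
        model = sm.fit_dcpm(ep, shrinkage=0.01, classes=("LL", "RR"))
        w = model.filters["LL"][0]
        cos = abs(w @ direction) / (np.linalg.norm(w) * np.linalg.norm(direction))
        assert cos > 0.99

    def test_identical_class_means_degenerate(self):
        rng = np.random.default_rng(2)
        shared = rng.normal(size=(4, 100))
        trials = np.stack([shared + rng.normal(0, 0.5, size=(4, 100))
                           for _ in range(16)])
        labels = ["LL", "RR"] * 8
        ep = _epochset(trials, labels)
        # class means nearly equal -> between-class scatter ~ 0
        model = sm.fit_dcpm(ep, classes=("LL", "RR"))
        assert model.templates["LL"].shape == (2, 100)

    def test_four_class_model_shapes(self, fitted):
        assert len(fitted.dcpm.classes) == 4
        for cls in fitted.dcpm.classes:
            assert fitted.dcpm.templates[cls].shape == (2, 400)
            assert fitted.dcpm.filters[cls].shape[0] == 2

    def test_self_template_similarity_is_one(self, fitted, feature_epochs):
        """A class's own mean projects to correlation 1 with its template."""
        mean_ll = feature_epochs.mrcp_branch.data[
            feature_epochs.labels == "LL"].mean(axis=0)
        feats = sm.dcpm_transform(fitted.dcpm, mean_ll)
        assert len(feats) == 16
        # first 2 = per-dim Pearson, next 2 = canonical correlations for LL
        np.testing.assert_allclose(feats[:4], 1.0, atol=1e-6)

    def test_dcpm_features_alone_separate_two_classes(self, fitted,
                                                      feature_epochs):
        from sklearn.model_selection import cross_val_score
        from sklearn.svm import SVC

        sel = np.isin(feature_epochs.labels, ("LL", "RR"))
        feats = np.array([sm.dcpm_transform(fitted.dcpm, ep)
                          for ep in feature_epochs.mrcp_branch.data[sel]])
        acc = cross_val_score(SVC(kernel="linear"), feats,
                              feature_epochs.labels[sel].astype(str),
                              cv=5).mean()
        assert acc > 0.9

    def test_grid_mismatch_rejected(self, fitted):
        with pytest.raises(ValueError, match="grid"):
            sm.dcpm_transform(fitted.dcpm, np.zeros((12, 100)))


class TestTrca:
    def test_identical_trials_maximal_reproducibility(self):
        rng = np.random.default_rng(3)
        one = rng.normal(size=(4, 100))
        trials = np.stack([one] * 6 + [rng.normal(size=(4, 100))] * 6)
        labels = ["LL"] * 6 + ["RR"] * 6
        ep = _epochset(trials, labels)
        model = sm.fit_trca(ep, classes=("LL", "RR"))
        feats = sm.trca_transform(model, one)
        assert feats[0] == pytest.approx(1.0, abs=1e-9)

    def test_recovers_shared_component_direction(self):
        # trials share one spatial component + independent noise
        rng = np.random.default_rng(4)
        mixing = np.array([0.2, 0.9, -0.3, 0.1, 0.2])
        shared = np.sin(np.linspace(0, 6 * np.pi, 200))
        trials = np.stack([
            np.outer(mixing, shared) + rng.normal(0, 0.5, size=(5, 200))
            for _ in range(50)
        ])
        ep = _epochset(trials, ["LL"] * 50)
        model = sm.fit_trca(ep, classes=("LL",), shrinkage=0.01)
        w = model.filters["LL"][0]
        # with isotropic noise the leading filter is collinear with the
        # component's spatial pattern
        cos = abs(w @ mixing) / (np.linalg.norm(w) * np.linalg.norm(mixing))
        assert cos > 0.95
        rec = w @ trials.mean(axis=0)
        assert abs(np.corrcoef(rec, shared)[0, 1]) > 0.95

    def test_four_classes_three_components(self, fitted):
        assert len(fitted.trca.classes) == 4
        for cls in fitted.trca.classes:
            assert fitted.trca.filters[cls].shape[0] == 3

    def test_transform_length_four(self, fitted, feature_epochs):
        feats = sm.trca_transform(fitted.trca,
                                  feature_epochs.mrcp_branch.data[0])
        assert len(feats) == 4

    def test_true_class_feature_wins_on_noiseless_trials(self, fitted,
                                                         feature_epochs):
        correct = 0
        order = list(fitted.trca.classes)
        for i in range(0, feature_epochs.n_trials, 5):
            feats = sm.trca_transform(fitted.trca,
                                      feature_epochs.mrcp_branch.data[i])
            correct += order[int(np.argmax(feats))] == feature_epochs.labels[i]
        assert correct == len(range(0, feature_epochs.n_trials, 5))


class TestFbcsp:
    def _two_channel_toy(self, var_a=(4.0, 1.0), var_rest=(1.0, 1.0), n=40):
        rng = np.random.default_rng(5)
        trials, labels = [], []
        for i in range(n):
            if i % 2 == 0:
                sd = np.sqrt(var_a)
                labels.append("LL")
            else:
                sd = np.sqrt(var_rest)
                labels.append("RR")
            trials.append(rng.normal(size=(2, 4000)) * np.array(sd)[:, None])
        return _epochset(np.stack(trials), labels, rate=2000.0)

    def test_closed_form_eigenvalue_without_trace_norm(self):
        """diag(4,1) vs diag(1,1): top filter = channel 1, eigenvalue
        4/(4+1) by the closed form for the generalized eigenproblem."""
        ep = self._two_channel_toy()
        model = sm.fit_fbcsp({(8.0, 13.0): ep}, n_filters=1, shrinkage=0.0,
                             normalize_trace=False, classes=("LL", "RR"))
        val = model.eigenvalues[((8.0, 13.0), "LL")][0]
        w = model.filters[((8.0, 13.0), "LL")][0]
        assert val == pytest.approx(4.0 / 5.0, abs=0.02)
        assert abs(w[0]) > 10 * abs(w[1])

    def test_equal_covariances_give_half_eigenvalues(self):
        ep = self._two_channel_toy(var_a=(1.0, 1.0))
        model = sm.fit_fbcsp({(8.0, 13.0): ep}, n_filters=2, shrinkage=0.0,
                             normalize_trace=False, classes=("LL", "RR"))
        vals = model.eigenvalues[((8.0, 13.0), "LL")]
        np.testing.assert_allclose(vals, 0.5, atol=0.03)

    def test_eigenvalues_lie_in_unit_interval(self, fitted):
        for vals in fitted.csp.eigenvalues.values():
            assert np.all(vals > 0.0) and np.all(vals < 1.0)

    def test_model_dimensions_4x3x3(self, fitted):
        assert len(fitted.csp.classes) == 4
        assert len(fitted.csp.bands) == 3
        assert all(w.shape[0] == 3 for w in fitted.csp.filters.values())

    def test_transform_scale_invariant_length_36(self, fitted,
                                                 feature_epochs):
        band_ep = {b: e.data[0] for b, e in feature_epochs.band_branch.items()}
        feats = sm.fbcsp_transform(fitted.csp, band_ep)
        assert len(feats) == 36
        scaled = sm.fbcsp_transform(
            fitted.csp, {b: 7.5 * e for b, e in band_ep.items()})
        np.testing.assert_allclose(feats, scaled, atol=1e-10)

    def test_alpha_features_dominate_on_alpha_erd_contrast(self,
                                                           tiny_montage):
        """When classes differ only in alpha-band ERD, the alpha-band CSP
        block carries the largest point-biserial separation."""
        from conftest import quiet_params

        sched = sm.make_protocol(1, 40, tasks=("LL", "RR"), seed=12,
                                 key_jitter=0.0, key_jitter_max=0.0)
        params = quiet_params(noise_scale=1.5, mrcp_peak_amp=0.0,
                              beta_amp=0.0, erd_alpha_depth=0.7)
        rec = sm.simulate_dataset(sched, params, tiny_montage, rate=250.0,
                                  seed=12)
        fe = sm.prepare_feature_epochs(rec)
        model = sm.fit_fbcsp(fe.band_branch, classes=("LL", "RR"))
        rows = np.array([
            sm.fbcsp_transform(model, {b: e.data[i]
                                       for b, e in fe.band_branch.items()})
            for i in range(fe.n_trials)
        ])
        y = (fe.labels == "LL").astype(float)
        r = np.array([abs(np.corrcoef(rows[:, j], y)[0, 1])
                      for j in range(rows.shape[1])])
        # 2 classes x 3 bands x 3 filters: features 6..11 are alpha-band
        assert int(np.argmax(r)) in range(6, 12)


class TestAssembledBank:
    def test_feature_matrix_width_56_and_order(self, fitted, feature_epochs):
        fm = sm.extract_features(fitted, feature_epochs)
        assert fm.values.shape == (feature_epochs.n_trials, 56)
        assert len(fm.feature_names) == 56
        assert sum(n.startswith("dcpm/") for n in fm.feature_names) == 16
        assert sum(n.startswith("trca/") for n in fm.feature_names) == 4
        assert sum(n.startswith("fbcsp/") for n in fm.feature_names) == 36
        np.testing.assert_array_equal(fm.labels, feature_epochs.labels)

    def test_refit_is_deterministic(self, feature_epochs):
        a = sm.extract_features(sm.fit_spatial_models(feature_epochs),
                                feature_epochs)
        b = sm.extract_features(sm.fit_spatial_models(feature_epochs),
                                feature_epochs)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invariant_to_consistent_channel_reordering(self, quiet_recording):
        perm = np.random.default_rng(6).permutation(
            len(quiet_recording.montage))
        names = tuple(quiet_recording.montage.names[i] for i in perm)
        montage = sm.standard_montage(names)
        rec_p = sm.ContinuousRecording(quiet_recording.data[perm],
                                       quiet_recording.rate, montage,
                                       quiet_recording.events)
        fe_a = sm.prepare_feature_epochs(quiet_recording)
        fe_b = sm.prepare_feature_epochs(rec_p)
        fa = sm.extract_features(sm.fit_spatial_models(fe_a), fe_a)
        fb = sm.extract_features(sm.fit_spatial_models(fe_b), fe_b)
        np.testing.assert_allclose(fa.values, fb.values, atol=1e-7)

    def test_canonical_correlation_bounds(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(2, 300))
        rho = canonical_correlations(x, x)
        np.testing.assert_allclose(rho, 1.0, atol=1e-6)
        y = rng.normal(size=(2, 300))
        rho = canonical_correlations(x, y)
        assert np.all(rho >= 0.0) and np.all(rho <= 1.0)

    def test_shrinkage_moves_toward_scaled_identity(self):
        c = np.array([[4.0, 1.0], [1.0, 2.0]])
        out = shrink(c, 1.0)
        np.testing.assert_allclose(out, 3.0 * np.eye(2))
        np.testing.assert_allclose(shrink(c, 0.0), c)
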