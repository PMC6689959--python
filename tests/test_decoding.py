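import numpy as np
import pytest

from prepercept import decoding as dec
from prepercept import simulate as sim

from conftest import make_epochs


def separable_epochs(
    n_trials=200, shift=3.0, onset=0.1, noise_sd=1.0, seed=0, n_sensors=12
):
    """Sensor epochs whose face trials carry a smooth mean bump from `onset`."""
    rng = np.random.default_rng(seed)
    fs = 250.0
    t = -1.0 + np.arange(375) / fs
    labels = np.where(rng.random(n_trials) < 0.5, "face", "vase").astype(str)
    topo = rng.standard_normal(n_sensors)
    topo /= np.linalg.norm(topo)
    bump = np.exp(-0.5 * ((t - (onset + 0.15)) / 0.08) ** 2) * (t > onset)
    data = noise_sd * rng.standard_normal((n_trials, n_sensors, t.size))
    face = labels == "face"
    data[face] += shift * noise_sd * topo[None, :, None] * bump[None, None, :]
    return make_epochs(data, fs, labels=labels), topo


class TestZscoreFeatures:
    def test_train_statistics_are_exact(self):
        rng = np.random.default_rng(0)
        tr, te = dec.zscore_features(rng.normal(5, 3, (40, 6)), rng.normal(5, 3, (10, 6)))
        assert np.allclose(tr.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(tr.std(axis=0), 1, atol=1e-10)
        assert te.shape == (10, 6)

    def test_constant_channel_floored_not_nan(self):
        x = np.ones((10, 3))
        x[:, 1] = np.arange(10)
        tr, _ = dec.zscore_features(x)
        assert np.all(np.isfinite(tr))

    def test_affine_transform_leaves_auc_unchanged(self):
        # AUC is rank-based on held-out decision values; per-channel affine
        # rescaling of the inputs is absorbed by the training-fold z-scoring
        ep, _ = separable_epochs(n_trials=120, seed=1)
        res1 = dec.temporal_decode(ep, band_hz=None, compute_patterns=False, seed=0)
        scaled = ep.data * 3.7 + 11.0
        ep2 = make_epochs(scaled, labels=ep.labels)
        res2 = dec.temporal_decode(ep2, band_hz=None, compute_patterns=False, seed=0)
        assert np.allclose(res1.auc, res2.auc, atol=1e-6)


class TestFitLogistic:
    def test_matches_reference_implementation(self):
        # same objective as scikit-learn's LogisticRegression (C=1, L2,
        # unpenalized intercept): coefficients agree to solver precision
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(0)
        X = rng.standard_normal((300, 30))
        y = (X @ rng.standard_normal(30) + rng.standard_normal(300) > 0).astype(int)
        w = dec.fit_logistic(X, y, C=1.0)
        ref = LogisticRegression(C=1.0, max_iter=2000, tol=1e-10).fit(X, y)
        assert np.abs(w[:-1] - ref.coef_[0]).max() < 1e-5
        assert abs(w[-1] - ref.intercept_[0]) < 1e-5

    def test_separable_data_stays_finite(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        w = dec.fit_logistic(X, y, C=1.0)
        assert np.all(np.isfinite(w))

    def test_auc_score_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        y = (rng.random(200) < 0.4).astype(int)
        s = rng.standard_normal(200) + y
        assert dec.auc_score(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestTemporalDecode:
    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(2)
        ep, _ = separable_epochs(n_trials=400, seed=2)
        permuted = rng.permutation(ep.labels)
        ep_null = make_epochs(ep.data, labels=permuted)
        res = dec.temporal_decode(ep_null, compute_patterns=False, seed=0)
        assert 0.45 < res.auc.mean() < 0.55

    def test_informative_signal_decoded_after_onset_only(self):
        ep, _ = separable_epochs(n_trials=200, shift=3.0, seed=3)
        res = dec.temporal_decode(ep, compute_patterns=False, seed=0)
        pre = res.times_s < -0.1
        post = (res.times_s > 0.2) & (res.times_s < 0.35)
        assert res.auc[post].max() > 0.9
        assert abs(res.auc[pre].mean() - 0.5) < 0.05

    def test_fourfold_stratified_fold_sizes(self):
        ep, _ = separable_epochs(n_trials=400, seed=4)
        res = dec.temporal_decode(ep, n_folds=4, band_hz=None, compute_patterns=False)
        counts = np.bincount(res.fold_assignment)
        assert np.array_equal(counts, [100, 100, 100, 100])
        y = ep.labels == "face"
        ratios = [y[res.fold_assignment == k].sum() for k in range(4)]
        assert max(ratios) - min(ratios) <= 1

    def test_no_leakage_canary(self):
        # an artifact present only in one fold's test trials must not lift
        # prestimulus AUC: normalization/fitting never see held-out trials
        ep, _ = separable_epochs(n_trials=200, shift=0.0, seed=5)
        res0 = dec.temporal_decode(ep, band_hz=None, compute_patterns=False, seed=0)
        test_fold = res0.fold_assignment == 0
        data = ep.data.copy()
        face_in_fold = test_fold & (ep.labels == "face")
        data[face_in_fold] += 5.0
        ep_canary = make_epochs(data, labels=ep.labels)
        res = dec.temporal_decode(ep_canary, band_hz=None, compute_patterns=False, seed=0)
        pre = res.times_s < -0.1
        assert abs(res.auc[pre].mean() - 0.5) < 0.06

    def test_single_class_rejected(self):
        ep, _ = separable_epochs(n_trials=40, seed=6)
        ep_bad = make_epochs(ep.data, labels=np.array(["face"] * 40))
        with pytest.raises(ValueError, match="categories"):
            dec.temporal_decode(ep_bad)


class TestHaufePatterns:
    def test_identity_covariance_keeps_direction(self):
        w = np.array([[1.0, 2.0, -1.0]])
        A = dec.haufe_patterns(w, np.eye(3))
        assert np.allclose(A[0], w[0] / np.linalg.norm(w[0]))

    def test_recovers_mixing_direction_under_correlated_noise(self):
        # defining property: with x = a s + correlated noise, the pattern of
        # the trained filter matches a even when the filter itself does not
        rng = np.random.default_rng(7)
        n, n_ch = 4000, 10
        a = rng.standard_normal(n_ch)
        a /= np.linalg.norm(a)
        Q = rng.standard_normal((n_ch, n_ch))
        noise_cov = 0.2 * Q @ Q.T / n_ch
        s = rng.standard_normal(n)
        X = np.outer(s, a) + rng.multivariate_normal(np.zeros(n_ch), noise_cov, size=n)
        y = (s > 0).astype(int)
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0).fit(X, y)
        w = clf.coef_
        cov = np.cov(X.T)
        A = dec.haufe_patterns(w, cov)[0]
        corr_pattern = abs(np.corrcoef(A, a)[0, 1])
        assert corr_pattern > 0.99

    def test_sign_convention(self):
        rng = np.random.default_rng(8)
        w = rng.standard_normal((5, 4))
        covs = np.stack([np.eye(4)] * 5)
        A = dec.haufe_patterns(w, covs)
        assert np.all(np.einsum("tc,tc->t", A, w) >= 0)


class TestProjectToSource:
    def test_zero_pattern_zero_map(self):
        sm = dec.project_to_source(np.zeros((3, 8)), np.ones((5, 8)))
        assert np.allclose(sm.values, 0)

    def test_pinv_identity_on_mixing_column(self):
        mix = sim.default_mixing(20, 3, seed=1)
        filt = np.linalg.pinv(mix)
        sm = dec.project_to_source(mix[:, 1][None, :], filt)
        expected = np.array([0.0, 1.0, 0.0])
        assert np.allclose(sm.values[0], expected, atol=1e-8)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="filter"):
            dec.project_to_source(np.zeros((2, 8)), np.ones((5, 7)))


class TestExtractRoi:
    def test_single_dominant_point(self):
        sm = dec.SourceMap(np.array([0.1, 0.89, 1.0, 0.2]))
        assert list(dec.extract_roi(sm, 0.95)) == [2]

    def test_frac_zero_returns_all(self):
        sm = dec.SourceMap(np.array([0.1, 0.5, 1.0]))
        assert len(dec.extract_roi(sm, 0.0)) == 3

    def test_uniform_map_ties_kept(self):
        sm = dec.SourceMap(np.ones(7))
        assert len(dec.extract_roi(sm, 0.95)) == 7

    def test_windowed_average_changes_selection(self):
        times = np.array([0.0, 0.1, 0.2])
        vals = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        sm = dec.SourceMap(vals)
        early = dec.extract_roi(sm, 0.9, (0.0, 0.1), times)
        late = dec.extract_roi(sm, 0.9, (0.15, 0.25), times)
        assert list(early) == [0]
        assert list(late) == [1]


class TestEndToEndLocalization:
    def test_roi_recovers_true_generators(self):
        # cohort subjects with V1-early / FFA-late evoked bumps: the 95%-max
        # ROI from the windowed source maps should pick the true generator
        hits = 0
        n = 6
        for seed in range(n):
            cfg = sim.SimulationConfig(n_subjects=1, n_trials=150, seed=40 + seed)
            cohort = sim.simulate_cohort(cfg)
            ep = cohort.subjects[0]
            res = dec.temporal_decode(ep, seed=0)
            filt = np.linalg.pinv(cohort.mixing)
            sm = dec.project_to_source(res.patterns, filt)
            roi_early = dec.extract_roi(sm, 0.95, (0.05, 0.12), res.times_s)
            roi_late = dec.extract_roi(sm, 0.95, (0.12, 0.20), res.times_s)
            if sim.V1 in roi_early and sim.FFA in roi_late:
                hits += 1
        assert hits >= 5
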