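"""PCA / PCA-LDA / PLS against eigendecomposition, closed-form and
scikit-learn oracles, plus the grouped-CV selection rules."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression as SkPLS
from sklearn.decomposition import PCA as SkPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis as SkLDA

from aquaferm import (
    PCALDAClassifier,
    PLSRegressor,
    PretreatmentSpec,
    SimParams,
    fit_pca,
    fit_plsr,
    evaluate_plsr,
    make_fold_plan,
    pca_lda_classify,
    regression_vector_peaks,
    select_nrlvs,
    select_nrpcs,
    simulate_experiment,
    top_loading_wavelengths,
)
from aquaferm.chemometrics import iter_folds, r2_score, rmse
from aquaferm.exceptions import AquafermError
from aquaferm.simulate import generating_factor_profiles


class TestPCA:
    def test_rank_one_matrix_explained_by_pc1(self, rng):
        X = np.outer(rng.normal(size=8), rng.normal(size=5))
        model = fit_pca(X, max_pcs=3)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(7, 5))
        model = fit_pca(X)
        back = model.center + model.scores @ model.loadings.T
        assert np.allclose(back, X, atol=1e-8)

    def test_loadings_orthonormal_and_ratios_sorted(self, rng):
        model = fit_pca(rng.normal(size=(10, 6)), max_pcs=5)
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(5), atol=1e-8)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)
        assert model.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(6, 4))
        model = fit_pca(X)
        evals, evecs = np.linalg.eigh(np.cov(X.T, ddof=1))
        order = np.argsort(evals)[::-1]
        for j in range(3):
            v = evecs[:, order[j]]
            assert abs(abs(v @ model.loadings[:, j]) - 1.0) < 1e-8

    def test_matches_sklearn_variance_ratios(self, rng):
        X = rng.normal(size=(12, 7))
        model = fit_pca(X, max_pcs=4)
        sk = SkPCA(n_components=4).fit(X)
        assert np.allclose(model.explained_variance_ratio, sk.explained_variance_ratio_, atol=1e-10)

    def test_deterministic_across_refits(self, rng):
        X = rng.normal(size=(9, 6))
        a, b = fit_pca(X), fit_pca(X)
        assert np.array_equal(a.loadings, b.loadings)
        assert np.array_equal(a.scores, b.scores)


class TestTopLoadingWavelengths:
    def test_single_spike_reported(self):
        X = np.zeros((4, 10))
        X[:, 6] = [1.0, 2.0, 3.0, 4.0]
        wl = 1400.0 + 2 * np.arange(10)
        model = fit_pca(X, max_pcs=1)
        model.wavelengths = wl
        assert top_loading_wavelengths(model, 1, k=1) == [1412.0]

    def test_simulated_pc1_peaks_near_strongest_bands(self, default_experiment):
        spectra, _ = default_experiment
        pre = PretreatmentSpec.from_list([{"savgol": {"window": 43}}, "detrend"]).apply(spectra)
        model = fit_pca(pre, max_pcs=3)
        params = SimParams()
        coeff = np.abs(np.asarray(params.band_ph_coeff))
        strongest = np.asarray(params.band_centers)[np.argsort(coeff)[::-1][:2]]
        reported = top_loading_wavelengths(model, 1, k=2)[:2]
        for w in reported:
            assert np.min(np.abs(strongest - w)) <= 10.0

    def test_k_equal_to_grid_returns_all(self, rng):
        model = fit_pca(rng.normal(size=(5, 8)), max_pcs=2)
        model.wavelengths = np.arange(8, dtype=float)
        assert len(top_loading_wavelengths(model, 1, k=8)) == 8


class TestFoldPlan:
    def test_default_folds_are_replicates(self, default_experiment):
        spectra, _ = default_experiment
        plan = make_fold_plan(spectra)
        assert sorted(np.bincount(plan)[1:]) == [39, 39, 39]
        assert np.array_equal(plan, spectra.meta["replicate"].to_numpy())

    def test_no_scan_block_split(self, default_experiment):
        spectra, _ = default_experiment
        plan = make_fold_plan(spectra)
        blocks = spectra.meta.groupby(["sample_id", "replicate"]).indices
        for idx in blocks.values():
            assert len(set(plan[idx])) == 1

    def test_single_replicate_falls_back_with_warning(self, default_experiment):
        spectra, _ = default_experiment
        one_rep = spectra.subset(times=[0, 4])
        one_rep = one_rep.with_absorbance(
            one_rep.absorbance[one_rep.meta.replicate == 1],
            meta=one_rep.meta[one_rep.meta.replicate == 1],
        )
        with pytest.warns(UserWarning):
            plan = make_fold_plan(one_rep)
        assert set(plan) == {1}


class TestPCALDA:
    def test_strain_subsets_fully_separable(self, default_experiment):
        spectra, _ = default_experiment
        presets = {"BL": [{"savgol": {"window": 21}}], "LS": ["detrend"], "MC": ["msc"]}
        for strain, steps in presets.items():
            sub = PretreatmentSpec.from_list(steps).apply(spectra.subset(culture=strain))
            plan = make_fold_plan(sub)
            labels = sub.meta["time_h"].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nrpcs, table = select_nrpcs(sub, labels, plan, max_pcs=30)
            result = pca_lda_classify(sub, labels, nrpcs, plan)
            assert result.train_accuracy == 100.0
            assert result.cv_accuracy == 100.0
            assert result.confusion.to_numpy().sum() == 45
            assert np.array_equal(np.diag(result.confusion.to_numpy()), [9] * 5)

    def test_permuted_labels_near_chance(self, default_experiment):
        spectra, _ = default_experiment
        sub = PretreatmentSpec.from_list(["detrend"]).apply(spectra.subset(culture="LS"))
        plan = make_fold_plan(sub)
        rng = np.random.default_rng(11)
        labels = sub.meta["time_h"].to_numpy().copy()
        accs = []
        for _ in range(5):
            rng.shuffle(labels)
            res = pca_lda_classify(sub, labels, nrpcs=5, plan=plan)
            accs.append(res.cv_accuracy)
        # 5 balanced classes -> chance 20%; binomial sd over 225 pooled rows ~ 2.7%
        assert 5.0 <= float(np.mean(accs)) <= 40.0

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(9, 6))
        with pytest.raises(AquafermError):
            PCALDAClassifier(n_components=2).fit(X, np.zeros(9))

    def test_agrees_with_sklearn_lda_on_scores(self, rng):
        """Independent oracle: equal-prior sklearn LDA on the same PCA scores
        must assign the same classes."""
        X = rng.normal(size=(24, 8))
        y = np.repeat([0, 1, 2], 8)
        X[y == 1] += 1.5
        X[y == 2, :4] -= 1.2
        clf = PCALDAClassifier(n_components=5).fit(X, y)
        Z = clf.pca_.transform(X)
        sk = SkLDA(solver="lsqr", priors=[1 / 3] * 3).fit(Z, y)
        assert np.array_equal(clf.predict(X), sk.predict(Z))

    def test_two_class_direction_matches_fisher_criterion(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.repeat([0, 1], 10)
        X[y == 1] += [2.0, 1.0]
        clf = PCALDAClassifier(n_components=2).fit(X, y)
        Z = clf.pca_.transform(X)
        m0, m1 = Z[y == 0].mean(axis=0), Z[y == 1].mean(axis=0)
        Sw = np.cov(Z[y == 0].T, ddof=1) * 9 + np.cov(Z[y == 1].T, ddof=1) * 9
        fisher = np.linalg.solve(Sw, m1 - m0)
        axis = clf.canonical_axes_[:, 0]
        cos = abs(fisher @ axis) / (np.linalg.norm(fisher) * np.linalg.norm(axis))
        assert cos == pytest.approx(1.0, abs=1e-8)


class TestSelectNrpcs:
    def test_perfectly_separable_from_two_pcs(self, rng):
        """Exhaustive-candidate oracle: classes separate only in the first two
        latent directions, so validation accuracy is 100% from NrPC=2 on and
        the tie-breaks select exactly 2."""
        n_per = 6
        centers = np.array([[0, 0], [4, 0], [0, 4], [4, 4], [2, 8]], float)
        rows, labels, meta_rows = [], [], []
        for c, mu in enumerate(centers):
            for r in range(n_per):
                z = mu + 0.05 * rng.normal(size=2)
                rows.append(np.r_[z, 0.01 * rng.normal(size=6)])
                labels.append(c)
                meta_rows.append((f"S{c}", "BL", float(c), r % 3 + 1, r // 3 + 1))
        X = np.asarray(rows)
        labels = np.asarray(labels)
        plan = np.asarray([m[3] for m in meta_rows])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nrpcs, table = select_nrpcs(X, labels, plan, max_pcs=6)
        perfect = table[table.cv_accuracy == 100.0]
        assert nrpcs == int(perfect.nrpcs.min()) == 2

    def test_tie_breaks_toward_smaller_candidate(self):
        table = pd.DataFrame(
            {"nrpcs": [1, 2, 3], "train_accuracy": [100.0] * 3, "cv_accuracy": [100.0] * 3,
             "gap": [0.0] * 3}
        )
        best = table.sort_values(["cv_accuracy", "gap", "nrpcs"],
                                 ascending=[False, True, True]).iloc[0]
        assert int(best.nrpcs) == 1

    def test_max_pcs_capped_with_warning(self, rng):
        X = rng.normal(size=(12, 30))
        y = np.repeat([0, 1], 6)
        plan = np.tile([1, 2, 3], 4)
        with pytest.warns(UserWarning, match="capped"):
            nrpcs, table = select_nrpcs(X, y, plan, max_pcs=30)
        assert table.nrpcs.max() <= 7  # min train size 8 -> at most 7 PCs


class TestPLS:
    def test_exact_fit_on_noiseless_three_factor_data(self, rng):
        T = rng.normal(size=(20, 3))
        P = np.linalg.qr(rng.normal(size=(10, 3)))[0]
        X = T @ P.T
        y = T @ [1.0, -2.0, 0.5]
        m = fit_plsr(X, y, nrlv=3)
        assert m.rmsec <= 1e-8
        assert m.r2c == pytest.approx(1.0, abs=1e-10)

    def test_one_lv_on_rank_one_x_equals_ols(self, rng):
        t = rng.normal(size=15)
        p = rng.normal(size=6)
        X = np.outer(t, p)
        y = 2.0 * t + 0.3 + 0.05 * rng.normal(size=15)
        m = fit_plsr(X, y, nrlv=1)
        # brute-force OLS of y on the single score direction
        s = (X - X.mean(axis=0)) @ p / (p @ p)
        beta = (s @ (y - y.mean())) / (s @ s)
        pred_ols = y.mean() + beta * s
        assert np.allclose(m.predictions["fitted"], pred_ols, atol=1e-8)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(AquafermError):
            fit_plsr(rng.normal(size=(8, 4)), np.ones(8), nrlv=1)

    def test_regression_vector_identity(self, rng):
        X = rng.normal(size=(12, 9))
        y = rng.normal(size=12)
        m = fit_plsr(X, y, nrlv=4)
        manual = (X - X.mean(axis=0)) @ m.regression_vector + m.y_center
        assert np.allclose(manual, m.predictions["fitted"], atol=1e-8)

    def test_matches_sklearn_pls_predictions(self, rng):
        X = rng.normal(size=(18, 12))
        y = X[:, 0] - 0.5 * X[:, 3] + 0.1 * rng.normal(size=18)
        ours = fit_plsr(X, y, nrlv=3).predictions["fitted"].to_numpy()
        sk = SkPLS(n_components=3, scale=False).fit(X, y).predict(X).ravel()
        assert np.allclose(ours, sk, atol=1e-8)


class TestSelectNrlvs:
    def test_three_factor_curve_minimal_at_three(self, rng):
        T = rng.normal(size=(24, 3))
        P = np.linalg.qr(rng.normal(size=(12, 3)))[0]
        X = T @ P.T
        y = T @ np.array([1.0, -1.0, 0.8])
        plan = np.tile([1, 2, 3], 8)
        nrlv, curve = select_nrlvs(X, y, plan, max_lv=6)
        assert nrlv == 3
        # rank exhausted beyond 3: later candidates tie and the tie breaks low
        assert np.allclose(curve.rmsecv[curve.nrlv >= 3], curve.rmsecv.min(), atol=1e-10)

    def test_single_candidate(self, rng):
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        nrlv, curve = select_nrlvs(X, y, np.tile([1, 2, 3], 3), max_lv=1)
        assert nrlv == 1 and len(curve) == 1

    def test_pure_noise_selection_in_bounds(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        nrlv, _ = select_nrlvs(X, y, np.tile([1, 2, 3], 4), max_lv=5)
        assert 1 <= nrlv <= 5


class TestEvaluatePlsr:
    def test_metric_definitions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r2_score(y, y) == pytest.approx(1.0)
        assert rmse(y, y) == 0.0
        assert r2_score(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_default_ph_regression_reaches_r2cv(self, default_experiment):
        spectra, ref = default_experiment
        key = ref.set_index(["culture", "time_h", "replicate"])["pH"]
        presets = {"BL": ["detrend"], "LS": ["snv"], "MC": ["snv"]}
        for strain, steps in presets.items():
            sub = PretreatmentSpec.from_list(steps).apply(spectra.subset(culture=strain))
            plan = make_fold_plan(sub)
            y = np.array(
                [key.loc[(c, t, r)] for c, t, r in
                 zip(sub.meta.culture, sub.meta.time_h, sub.meta.replicate)]
            )
            nrlv, _ = select_nrlvs(sub, y, plan)
            model = evaluate_plsr(sub, y, nrlv, plan)
            assert model.r2cv >= 0.96
            assert model.rmsecv >= 0.0

    def test_noiseless_recovery_of_generating_ph_vector(self, noiseless_experiment):
        """Parameter-recovery oracle: on noiseless spectra the PLS pH
        regression is exact and its coefficient vector matches the minimum-
        norm exact solution built from the generating factor profiles."""
        (spectra, ref), params = noiseless_experiment
        key = ref.set_index(["culture", "time_h", "replicate"])["pH"]
        y = np.array(
            [key.loc[(c, t, r)] for c, t, r in
             zip(spectra.meta.culture, spectra.meta.time_h, spectra.meta.replicate)]
        )
        plan = make_fold_plan(spectra)
        nrlv, _ = select_nrlvs(spectra, y, plan, max_lv=4)
        model = evaluate_plsr(spectra, y, nrlv, plan)
        assert model.r2cv > 1 - 1e-6
        prof = generating_factor_profiles(params)
        P = np.column_stack([prof["d_ph"], prof["d_logcfu"]])
        b_true = P @ np.linalg.solve(P.T @ P, np.array([1.0, 0.0]))
        b_fit = model.regression_vector
        cos = (b_fit @ b_true) / (np.linalg.norm(b_fit) * np.linalg.norm(b_true))
        assert cos > 0.99


class TestRegressionVectorPeaks:
    def test_single_spike(self):
        v = np.zeros(20)
        v[7] = -3.0
        assert regression_vector_peaks(v, k=1, wavelengths=1300 + np.arange(20.0)) == [1307.0]

    def test_noiseless_peaks_near_generating_extrema(self, noiseless_experiment):
        (spectra, ref), params = noiseless_experiment
        key = ref.set_index(["culture", "time_h", "replicate"])["pH"]
        y = np.array(
            [key.loc[(c, t, r)] for c, t, r in
             zip(spectra.meta.culture, spectra.meta.time_h, spectra.meta.replicate)]
        )
        model = fit_plsr(spectra, y, nrlv=2)
        prof = generating_factor_profiles(params)
        P = np.column_stack([prof["d_ph"], prof["d_logcfu"]])
        b_true = P @ np.linalg.solve(P.T @ P, np.array([1.0, 0.0]))
        true_peak = prof["wavelengths"][np.argmax(np.abs(b_true))]
        fitted_peak = regression_vector_peaks(model, k=1)[0]
        assert abs(fitted_peak - true_peak) <= params.wavelength_step

    def test_zero_vector_empty(self):
        assert regression_vector_peaks(np.zeros(10), k=3) == []
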