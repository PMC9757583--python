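"""SDM machinery: metrics, splits, learners, importance, committee rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import connectgene as cg
import connectgene.sdm as sdm
from connectgene.core import PointSet, Raster


class TestEvaluatePredictions:
    def test_worked_auc_example(self):
        # brute force over presence-background pairs gives 3/4
        m = cg.evaluate_predictions([1, 1, 0, 0], [0.9, 0.4, 0.5, 0.1])
        assert m.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        m = cg.evaluate_predictions([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert m.auc == 1.0 and m.tss == pytest.approx(1.0)

    def test_all_tied_scores(self):
        m = cg.evaluate_predictions([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3])
        assert m.auc == pytest.approx(0.5)
        assert m.tss == pytest.approx(0.0)

    def test_tss_identity_at_threshold(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        m = cg.evaluate_predictions(labels, scores)
        assert m.tss == pytest.approx(m.sensitivity + m.specificity - 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cg.evaluate_predictions([1, 1, 1], [0.1, 0.2, 0.3])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.ones(8, dtype=int), np.zeros(12, dtype=int)]
        scores = rng.random(20)
        m1 = cg.evaluate_predictions(labels, scores)
        m2 = cg.evaluate_predictions(labels, np.exp(3 * scores))
        assert m1.auc == pytest.approx(m2.auc)
        assert m1.tss == pytest.approx(m2.tss)
        # maxSSS classification is preserved under the transform
        assert np.array_equal(scores >= m1.threshold, np.exp(3 * scores) >= m2.threshold)


class TestSplit:
    def test_exact_stratified_counts(self):
        pts = PointSet(
            np.arange(20), np.arange(20.0), np.zeros(20),
            np.r_[np.ones(10, dtype=int), np.zeros(10, dtype=int)],
        )
        train, test = cg.split_train_test(pts, 0.7, seed=1)
        assert (train.label == 1).sum() == 7 and (train.label == 0).sum() == 7
        assert (test.label == 1).sum() == 3 and (test.label == 0).sum() == 3

    def test_partition_properties_and_determinism(self):
        rng = np.random.default_rng(2)
        pts = PointSet(np.arange(40), rng.random(40), rng.random(40),
                       rng.integers(0, 2, 40))
        pts.label[:2] = [0, 1]
        a1, b1 = cg.split_train_test(pts, 0.6, seed=5)
        a2, b2 = cg.split_train_test(pts, 0.6, seed=5)
        assert np.array_equal(a1.ids, a2.ids) and np.array_equal(b1.ids, b2.ids)
        union = set(a1.ids) | set(b1.ids)
        assert union == set(pts.ids) and not (set(a1.ids) & set(b1.ids))

    def test_too_small_class_rejected(self):
        pts = PointSet(np.arange(4), np.arange(4.0), np.zeros(4), [1, 0, 0, 0])
        with pytest.raises(ValueError):
            cg.split_train_test(pts, 0.7, seed=0)


class TestSampleBackground:
    def test_forced_single_cell(self):
        r = Raster(np.ones((3, 3)))
        rows, cols = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
        keep = ~((rows == 1) & (cols == 1))
        x, y = r.cell_center(rows[keep], cols[keep])
        exclude = PointSet(np.arange(8), x, y)
        bg = cg.sample_background([r], 1, exclude, seed=0)
        rr, cc = r.index_of(bg.x, bg.y)
        assert (rr[0], cc[0]) == (1, 1)

    def test_never_hits_excluded_cells_and_errors_when_full(self):
        r = Raster(np.ones((4, 4)))
        x, y = r.cell_center(np.array([0, 1]), np.array([0, 1]))
        exclude = PointSet(np.array([0, 1]), x, y)
        bg = cg.sample_background([r], 14, exclude, seed=3)
        cells = set(zip(*r.index_of(bg.x, bg.y)))
        assert (0, 0) not in cells and (1, 1) not in cells and len(cells) == 14
        with pytest.raises(ValueError):
            cg.sample_background([r], 15, exclude, seed=3)

    def test_zero_returns_empty(self):
        bg = cg.sample_background([Raster(np.ones((2, 2)))], 0, PointSet([], [], []), 0)
        assert len(bg) == 0


class TestFitSdm:
    def test_separable_covariate_gives_perfect_holdout_auc(self):
        # one covariate fully separates presences from background
        vals = np.linspace(0, 1, 400).reshape(20, 20)
        r = Raster(vals)
        rows, cols = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        hi = vals > 0.7
        rng = np.random.default_rng(1)
        pres_idx = rng.choice(np.nonzero(hi.ravel())[0], 40, replace=False)
        bg_idx = rng.choice(np.nonzero(~hi.ravel())[0], 80, replace=False)
        px, py = r.cell_center(pres_idx // 20, pres_idx % 20)
        bx, by = r.cell_center(bg_idx // 20, bg_idx % 20)
        pres = PointSet(np.arange(40), px, py, np.ones(40, dtype=int))
        bg = PointSet(np.arange(80), bx, by, np.zeros(80, dtype=int))
        X_eval = np.r_[
            vals.ravel()[pres_idx], vals.ravel()[bg_idx]
        ].reshape(-1, 1)
        labels = np.r_[np.ones(40, dtype=int), np.zeros(80, dtype=int)]
        for kind in cg.MODEL_KINDS:
            fit = cg.fit_sdm(kind, pres, bg, [r], {"n_estimators": 50}, seed=2)
            m = cg.evaluate_predictions(labels, fit.predict(X_eval))
            assert m.auc == pytest.approx(1.0), kind

    def test_stochastic_learners_deterministic_given_seed(self, sdm_case):
        layers = sdm_case["layers"]
        train = sdm_case["train"]
        pres = train.subset(np.nonzero(train.label == 1)[0])
        bg = train.subset(np.nonzero(train.label == 0)[0])
        X = sdm_case["X_test"]
        for kind in ("RF", "BRT"):
            f1 = cg.fit_sdm(kind, pres, bg, layers, {"n_estimators": 40}, seed=7)
            f2 = cg.fit_sdm(kind, pres, bg, layers, {"n_estimators": 40}, seed=7)
            assert np.array_equal(f1.predict(X), f2.predict(X))

    def test_predictions_bounded(self, sdm_case):
        X = sdm_case["X_test"]
        for fit in sdm_case["fits"].values():
            p = fit.predict(X)
            assert np.all((p >= 0) & (p <= 1))

    def test_constant_covariate_named_in_error(self):
        r1 = Raster(np.ones((5, 5)) * 2.0)
        r2 = Raster(np.random.default_rng(0).random((5, 5)))
        x, y = r1.cell_center(np.array([0, 1, 2, 3]), np.array([0, 1, 2, 3]))
        pres = PointSet(np.arange(2), x[:2], y[:2], np.ones(2, dtype=int))
        bg = PointSet(np.arange(2), x[2:], y[2:], np.zeros(2, dtype=int))
        with pytest.raises(ValueError, match="flatvar"):
            cg.fit_sdm("GLM", pres, bg, [r1, r2], names=["flatvar", "ok"])

    def test_glm_null_auc_near_half(self):
        # labels carry no signal: holdout AUC hovers around 0.5 on average
        rng = np.random.default_rng(5)
        r = Raster(rng.random((30, 30)))
        aucs = []
        for i in range(25):
            idx = rng.choice(900, 120, replace=False)
            x, y = r.cell_center(idx // 30, idx % 30)
            labels = np.zeros(120, dtype=int)
            labels[rng.choice(120, 40, replace=False)] = 1
            pts = PointSet(np.arange(120), x, y, labels)
            train, test = cg.split_train_test(pts, 0.7, seed=100 + i)
            fit = cg.fit_sdm(
                "GLM",
                train.subset(np.nonzero(train.label == 1)[0]),
                train.subset(np.nonzero(train.label == 0)[0]),
                [r],
                seed=i,
            )
            Xt = sdm.extract_covariates([r], test).to_numpy()
            aucs.append(sdm._auc(test.label, fit.predict(Xt)))
        assert 0.4 <= np.mean(aucs) <= 0.6


class TestCrossValidateSelect:
    def test_separable_data_retains_all_kinds(self, quiet_warnings):
        # one covariate fully separates the classes: every kind passes the gate
        vals = np.linspace(0, 1, 400).reshape(20, 20)
        r = Raster(vals)
        rng = np.random.default_rng(1)
        hi = vals.ravel() > 0.7
        pres_idx = rng.choice(np.nonzero(hi)[0], 40, replace=False)
        bg_idx = rng.choice(np.nonzero(~hi)[0], 80, replace=False)
        idx = np.r_[pres_idx, bg_idx]
        x, y = r.cell_center(idx // 20, idx % 20)
        labels = np.r_[np.ones(40, dtype=int), np.zeros(80, dtype=int)]
        pts = PointSet(np.arange(120), x, y, labels)
        selected, table = cg.cross_validate_select(
            cg.MODEL_KINDS, pts, [r], k=4, seed=3,
            settings={"BRT": {"n_estimators": 60}, "RF": {"n_estimators": 60}},
        )
        assert set(selected) == set(cg.MODEL_KINDS)
        assert bool(table["selected"].all())

    def test_pure_noise_labels_retain_nothing(self, quiet_warnings):
        rng = np.random.default_rng(9)
        r1 = Raster(rng.random((25, 25)))
        r2 = Raster(rng.random((25, 25)))
        retained = 0
        n_rep = 8
        for i in range(n_rep):
            idx = rng.choice(625, 160, replace=False)
            x, y = r1.cell_center(idx // 25, idx % 25)
            labels = np.zeros(160, dtype=int)
            labels[rng.choice(160, 60, replace=False)] = 1
            pts = PointSet(np.arange(160), x, y, labels)
            selected, _ = cg.cross_validate_select(
                ["GLM"], pts, [r1, r2], k=4, seed=200 + i
            )
            retained += len(selected)
        assert retained == 0

    def test_bad_k_rejected(self, sdm_case):
        with pytest.raises(ValueError):
            cg.cross_validate_select(["GLM"], sdm_case["train"], sdm_case["layers"], k=1)


class TestPermutationImportance:
    def test_inert_covariate_has_near_zero_delta_auc(self, sdm_case):
        layers = list(sdm_case["layers"]) + [
            sdm_case["layers"][0].like(
                np.random.default_rng(3).random(sdm_case["layers"][0].shape)
            )
        ]
        train = sdm_case["train"]
        fit = cg.fit_sdm(
            "GLM",
            train.subset(np.nonzero(train.label == 1)[0]),
            train.subset(np.nonzero(train.label == 0)[0]),
            layers,
            seed=4,
        )
        d = cg.permutation_importance(fit, sdm_case["test"], layers, "var3",
                                      n_repeats=20, seed=5)
        assert abs(d) < 0.01

    def test_sole_predictive_covariate_loses_most_of_auc(self, sdm_case):
        fit = sdm_case["fits"]["GLM"]
        test = sdm_case["test"]
        layers = sdm_case["layers"]
        base = sdm._auc(test.label, fit.predict(sdm_case["X_test"]))
        total = sum(
            cg.permutation_importance(fit, test, layers, v, n_repeats=10, seed=6)
            for v in fit.variables
        )
        # permuting all informative covariates accounts for most of AUC - 0.5
        assert total > 0.5 * (base - 0.5)

    def test_unknown_variable_rejected(self, sdm_case):
        with pytest.raises(ValueError):
            cg.permutation_importance(
                sdm_case["fits"]["GLM"], sdm_case["test"], sdm_case["layers"], "nope"
            )


class TestResponseCurve:
    def test_glm_curve_matches_closed_form_logistic(self):
        rng = np.random.default_rng(8)
        r = Raster(rng.random((20, 20)))
        idx = rng.choice(400, 100, replace=False)
        x, y = r.cell_center(idx // 20, idx % 20)
        labels = (r.values.ravel()[idx] > 0.5).astype(int)
        pts = PointSet(np.arange(100), x, y, labels)
        pres = pts.subset(np.nonzero(labels == 1)[0])
        bg = pts.subset(np.nonzero(labels == 0)[0])
        fit = cg.fit_sdm("GLM", pres, bg, [r], seed=0)
        curves = cg.response_curve([fit], [r], "var0", n_grid=25, points=pts)
        grid, resp = curves["GLM"]
        # evaluate the fitted predictor directly on the strip: identical
        assert np.allclose(resp, fit.predict(grid.reshape(-1, 1)))
        # positive monotone response on the dominant covariate
        assert np.all(np.diff(resp) >= -1e-9)

    def test_identical_fits_identical_curves(self, sdm_case):
        fit = sdm_case["fits"]["MAXENT"]
        c = cg.response_curve(
            [fit, fit], sdm_case["layers"], "var0", n_grid=10, points=sdm_case["points"]
        )
        # same kind twice collapses to one entry; evaluate twice instead
        g1, r1 = c["MAXENT"]
        g2, r2 = cg.response_curve(
            [fit], sdm_case["layers"], "var0", n_grid=10, points=sdm_case["points"]
        )["MAXENT"]
        assert np.array_equal(g1, g2) and np.array_equal(r1, r2)


class TestCommitteeEnsemble:
    def _const_fit(self, value: float) -> sdm.SdmFit:
        return sdm.SdmFit(
            kind=f"c{value}", predict_fn=lambda X: np.full(len(X), value), variables=["var0"]
        )

    def test_vote_arithmetic_three_of_five(self):
        r = Raster(np.zeros((2, 2)))
        fits = [self._const_fit(v) for v in (0.9, 0.9, 0.9, 0.1, 0.1)]
        ens = cg.committee_ensemble(fits, [0.5] * 5, [r])
        assert np.allclose(ens.committee.values, 0.6)
        assert np.all(ens.suitable_mask.values == 1.0)

    def test_exact_half_is_unsuitable(self):
        r = Raster(np.zeros((2, 2)))
        fits = [self._const_fit(v) for v in (0.9, 0.9, 0.1, 0.1)]
        ens = cg.committee_ensemble(fits, [0.5] * 4, [r])
        assert np.allclose(ens.committee.values, 0.5)
        assert np.all(ens.suitable_mask.values == 0.0)

    def test_all_against_and_threshold_count_mismatch(self):
        r = Raster(np.zeros((2, 2)))
        fits = [self._const_fit(0.1) for _ in range(5)]
        ens = cg.committee_ensemble(fits, [0.5] * 5, [r])
        assert np.all(ens.committee.values == 0.0)
        with pytest.raises(ValueError):
            cg.committee_ensemble(fits, [0.5] * 4, [r])

    def test_committee_values_on_vote_grid(self, sdm_case):
        fits = list(sdm_case["fits"].values())
        ens = cg.committee_ensemble(
            fits, [f.threshold for f in fits], sdm_case["layers"]
        )
        vals = ens.committee.values[np.isfinite(ens.committee.values)]
        assert set(np.round(np.unique(vals), 9)) <= {0.0, 0.2, 0.4, 0.6, 0.8, 1.0}

    def test_ensemble_recovers_true_suitable_area(self, sdm_case):
        fits = list(sdm_case["fits"].values())
        ens = cg.committee_ensemble(
            fits, [f.threshold for f in fits], sdm_case["layers"]
        )
        truth = sdm_case["suitability"].values > 0.5
        mask = ens.suitable_mask.values > 0
        sensitivity = mask[truth].mean()
        assert sensitivity >= 0.9
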