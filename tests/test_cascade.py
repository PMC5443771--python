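import numpy as np
import pytest

from septfc.cascade import (
    DEFAULT_SPECS,
    LOG2_C_GRID,
    LOG2_GAMMA_GRID,
    SubClassifierSpec,
    cross_validate_10x10,
    features_stage_I,
    fit_cascade,
    fit_stage,
    grid_search,
    partition_folds,
    predict_cascade,
    stage_points,
)
from septfc.components import categorize
from septfc.matching_pursuit import TFC
from septfc.recording import Condition, ValidationError


def make_cat(condition, high, middles=(), lows=(), subject_id="s"):
    """Categorized recording from explicit (time, frequency[, power]) tuples."""
    t, f, p = high
    tfcs = [TFC(t, f, p, 0.8, 1)]
    tfcs += [TFC(tm, fm, 1.0, 0.05, k + 2) for k, (tm, fm) in enumerate(middles)]
    tfcs += [TFC(tl, fl, 0.1, 0.007, k + 2 + len(middles)) for k, (tl, fl) in enumerate(lows)]
    return categorize(tfcs, subject_id=subject_id, condition=condition)


def gaussian_two_class(rng, n_per_class=20, d=3, separation=8.0):
    X = np.vstack([rng.normal(0, 1, (n_per_class, d)), rng.normal(separation, 1, (n_per_class, d))])
    y = np.array(["neg"] * n_per_class + ["pos"] * n_per_class)
    return X, y


def svm_dual_qp(X, y_pm, C, gamma):
    """Independent soft-margin kernel SVM via the dual QP (SLSQP).

    Returns a decision function; deliberately shares no code with the
    package's libsvm-backed classifier.
    """
    from scipy.optimize import minimize

    n = len(y_pm)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-gamma * sq)
    Q = (y_pm[:, None] * y_pm[None, :]) * K

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    res = minimize(
        neg_dual,
        x0=np.full(n, min(C, 1.0) * 0.5),
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y_pm, "jac": lambda a: y_pm}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    alpha = res.x
    sv = (alpha > 1e-6) & (alpha < C - 1e-6)
    dec_no_b = (alpha * y_pm) @ K
    b = float(np.mean(y_pm[sv] - dec_no_b[sv])) if sv.any() else 0.0

    def decide(Xt):
        sqt = ((Xt[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        return np.exp(-gamma * sqt) @ (alpha * y_pm) + b

    return decide


class TestSpecsAndFeatures:
    def test_stage_feature_binding_is_fixed(self):
        assert SubClassifierSpec("I", "a", "b").feature_source == "high"
        assert SubClassifierSpec("II", "a", "b").feature_source == "middle"
        assert SubClassifierSpec("III", "a", "b").feature_source == "low"
        with pytest.raises(ValidationError):
            SubClassifierSpec("IV", "a", "b")

    def test_stage_I_vector_is_high_tfc(self):
        cat = make_cat("normal", (12.9, 50.7, 50.4), middles=[(13, 150)], lows=[(26, 66)])
        np.testing.assert_allclose(features_stage_I(cat), [12.9, 50.7, 50.4])

    def test_stage_I_ignores_small_components(self):
        a = make_cat("C4", (15.0, 35.0, 28.0), middles=[(13, 150), (11, 80)])
        b = make_cat("C4", (15.0, 35.0, 28.0), middles=[(11, 80), (13, 150)], lows=[(40, 50)])
        np.testing.assert_array_equal(features_stage_I(a), features_stage_I(b))

    def test_stage_points_windowed_to_analysis_domain(self):
        cat = make_cat(
            "C4",
            (15.0, 35.0, 28.0),
            lows=[(26.0, 66.0), (80.0, 50.0), (20.0, 5.0), (2.0, 100.0)],
        )
        pts = stage_points(cat, "low")
        assert pts.shape == (1, 2)  # only the in-window component votes
        np.testing.assert_allclose(pts[0], [26.0, 66.0])


class TestFitStage:
    def test_separable_classes_reach_perfect_training_accuracy(self, rng):
        X, y = gaussian_two_class(rng)
        stage = fit_stage(DEFAULT_SPECS[0], X, y, log2_c=0, log2_gamma=-2)
        assert (stage.predict(X) == y).all()

    def test_fitting_is_deterministic(self, rng):
        X, y = gaussian_two_class(rng, separation=1.0)
        Xt = rng.normal(2, 3, (30, 3))
        d1 = fit_stage(DEFAULT_SPECS[0], X, y, 2, -3).decision_values(Xt)
        d2 = fit_stage(DEFAULT_SPECS[0], X, y, 2, -3).decision_values(Xt)
        np.testing.assert_array_equal(d1, d2)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValidationError):
            fit_stage(DEFAULT_SPECS[0], X, np.array(["a"] * 10))

    def test_agrees_with_independent_dual_qp_solver(self, rng):
        # moderate overlap; compare predictions on 100 fresh points
        X, y = gaussian_two_class(rng, n_per_class=20, d=2, separation=2.5)
        log2_c, log2_gamma = 1, -1
        stage = fit_stage(DEFAULT_SPECS[0], X, y, log2_c, log2_gamma)
        Xt = np.vstack(
            [rng.normal(0, 1, (50, 2)), rng.normal(2.5, 1, (50, 2))]
        )
        got = stage.predict(Xt)
        # oracle operates on the same z-scored features
        Xs = stage.transform(X)
        y_pm = np.where(y == "pos", 1.0, -1.0)
        decide = svm_dual_qp(Xs, y_pm, C=2.0**log2_c, gamma=2.0**log2_gamma)
        expected = np.where(decide(stage.transform(Xt)) >= 0, "pos", "neg")
        assert (got == expected).mean() >= 0.98


class TestGridSearch:
    def test_full_grid_has_575_candidates(self):
        assert len(LOG2_C_GRID) * len(LOG2_GAMMA_GRID) == 575
        assert LOG2_C_GRID[0] == -2 and LOG2_C_GRID[-1] == 20
        assert LOG2_GAMMA_GRID[0] == -14 and LOG2_GAMMA_GRID[-1] == 10

    def test_returned_pair_maximizes_surface(self, rng):
        X, y = gaussian_two_class(rng, n_per_class=15, separation=1.5)
        lc, lg, surface = grid_search(DEFAULT_SPECS[0], X, y, folds=3, rng=0)
        assert surface.shape == (23, 25)
        i, j = LOG2_C_GRID.index(lc), LOG2_GAMMA_GRID.index(lg)
        assert surface[i, j] >= surface.max() - 1e-12
        # exhaustive re-evaluation oracle: no pair beats the returned one
        assert not np.any(surface > surface[i, j])

    def test_tie_break_prefers_smallest_c_then_gamma(self, rng):
        # widely separable data: a plateau of perfect pairs exists
        X, y = gaussian_two_class(rng, n_per_class=12, separation=10.0)
        lc, lg, surface = grid_search(DEFAULT_SPECS[0], X, y, folds=2, rng=0)
        best = surface.max()
        perfect = [
            (c, g)
            for i, c in enumerate(LOG2_C_GRID)
            for j, g in enumerate(LOG2_GAMMA_GRID)
            if surface[i, j] >= best - 1e-12
        ]
        assert (lc, lg) == min(perfect)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(8, 2))
        with pytest.raises(ValidationError):
            grid_search(DEFAULT_SPECS[0], X, np.array(["a"] * 8), rng=0)


class TestPredictCascade:
    def _toy_model(self):
        rng = np.random.default_rng(5)
        cats = []
        for i in range(10):
            cats.append(
                make_cat(
                    "normal",
                    (12.9 + rng.normal(0, 1), 50.7 + rng.normal(0, 2), 50.0 + rng.normal(0, 3)),
                    middles=[(35 + rng.normal(0, 2), 25 + rng.normal(0, 3))],
                    lows=[(25 + rng.normal(0, 1), 60 + rng.normal(0, 4))],
                    subject_id=f"n{i}",
                )
            )
        for i in range(6):
            cats.append(
                make_cat(
                    "C4",
                    (15.1 + rng.normal(0, 1), 34.7 + rng.normal(0, 2), 28.0 + rng.normal(0, 2)),
                    middles=[(13.1 + rng.normal(0, 1), 158.7 + rng.normal(0, 4))],
                    lows=[(25.7 + rng.normal(0, 1), 66.4 + rng.normal(0, 4))],
                    subject_id=f"c4{i}",
                )
            )
            cats.append(
                make_cat(
                    "C5",
                    (15.1 + rng.normal(0, 1), 34.7 + rng.normal(0, 2), 28.0 + rng.normal(0, 2)),
                    middles=[(16.9 + rng.normal(0, 1), 105.3 + rng.normal(0, 3))],
                    lows=[(25.0 + rng.normal(0, 1), 70.0 + rng.normal(0, 4))],
                    subject_id=f"c5{i}",
                )
            )
            cats.append(
                make_cat(
                    "C6",
                    (15.1 + rng.normal(0, 1), 34.7 + rng.normal(0, 2), 28.0 + rng.normal(0, 2)),
                    middles=[(13.1 + rng.normal(0, 1), 158.7 + rng.normal(0, 4))],
                    lows=[(18.5 + rng.normal(0, 1), 100.0 + rng.normal(0, 4))],
                    subject_id=f"c6{i}",
                )
            )
        return fit_cascade(cats, rng=0), cats

    def test_normal_short_circuits_at_stage_I(self):
        model, cats = self._toy_model()
        normal = next(c for c in cats if c.condition is Condition.NORMAL)
        assert predict_cascade(model, normal) == "normal"

    def test_c5_stops_at_stage_II(self):
        model, cats = self._toy_model()
        c5 = next(c for c in cats if c.condition is Condition.C5)
        assert predict_cascade(model, c5) == "C5"

    def test_c4_c6_resolved_at_stage_III(self):
        model, cats = self._toy_model()
        preds = {
            cond: predict_cascade(model, next(c for c in cats if c.condition is Condition(cond)))
            for cond in ("C4", "C6")
        }
        assert preds["C4"] == "C4" and preds["C6"] == "C6"

    def test_labels_are_exhaustive_and_exclusive(self):
        model, cats = self._toy_model()
        preds = {predict_cascade(model, c) for c in cats}
        assert preds <= {"normal", "C4", "C5", "C6"}

    def test_empty_middle_set_falls_through_to_stage_III(self):
        model, _ = self._toy_model()
        # C4-like recording with no middle components: stage II cannot vote C5
        cat = make_cat("C4", (15.0, 35.0, 28.0), lows=[(25.7, 66.4)])
        assert predict_cascade(model, cat) in ("C4", "C6")

    def test_model_bundle_round_trip(self, tmp_path):
        model, cats = self._toy_model()
        path = tmp_path / "cascade.joblib"
        model.save(path)
        from septfc.cascade import CascadeModel

        back = CascadeModel.load(path)
        assert (back.stage_i.log2_c, back.stage_i.log2_gamma) == (
            model.stage_i.log2_c, model.stage_i.log2_gamma,
        )
        assert all(predict_cascade(back, c) == predict_cascade(model, c) for c in cats[:6])

    def test_empty_low_set_defaults_to_c4(self):
        model, _ = self._toy_model()
        cat = make_cat("C6", (15.0, 35.0, 28.0), middles=[(13.1, 158.7)])
        # stage II votes not-C5 (C4C6 cluster), stage III has nothing to vote on
        assert predict_cascade(model, cat) == "C4"


class TestCrossValidation:
    def test_partition_sizes_eight_sevens_two_eights(self, rng):
        folds = partition_folds(72, 10, rng)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [7] * 8 + [8] * 2

    def test_each_item_tested_exactly_once(self, rng):
        folds = partition_folds(72, 10, rng)
        seen = np.concatenate(folds)
        assert sorted(seen.tolist()) == list(range(72))

    def test_wrong_composition_rejected(self):
        cats = [make_cat("normal", (12, 50, 50), subject_id=f"n{i}") for i in range(10)]
        with pytest.raises(ValidationError):
            cross_validate_10x10(cats, seed=0)

    def _small_study(self, n_normal=8, n_each=6, seed=3):
        rng = np.random.default_rng(seed)
        cats = []
        for i in range(n_normal):
            cats.append(
                make_cat(
                    "normal",
                    (12.9 + rng.normal(0, 2), 50.7 + rng.normal(0, 4), 50 + rng.normal(0, 8)),
                    middles=[(35 + rng.normal(0, 2), 25 + rng.normal(0, 5))],
                    lows=[(25 + rng.normal(0, 2), 60 + rng.normal(0, 8))],
                    subject_id=f"n{i}",
                )
            )
        spots = {
            "C4": ((13.1, 158.7), (25.7, 66.4)),
            "C5": ((16.9, 105.3), (25.0, 70.0)),
            "C6": ((13.1, 158.7), (18.5, 100.0)),
        }
        for cond, (mid, low) in spots.items():
            for i in range(n_each):
                cats.append(
                    make_cat(
                        cond,
                        (15.1 + rng.normal(0, 2), 34.7 + rng.normal(0, 4), 28 + rng.normal(0, 5)),
                        middles=[(mid[0] + rng.normal(0, 1.5), mid[1] + rng.normal(0, 5))],
                        lows=[(low[0] + rng.normal(0, 1.5), low[1] + rng.normal(0, 5))],
                        subject_id=f"{cond}{i}",
                    )
                )
        return cats

    def test_report_invariants_on_small_study(self):
        cats = self._small_study()
        report = cross_validate_10x10(
            cats, seed=1, n_runs=2, n_folds=5, enforce_composition=False
        )
        assert report.fold_accuracies.shape == (2, 5)
        np.testing.assert_allclose(report.run_means, report.fold_accuracies.mean(axis=1))
        assert report.run_min <= report.overall_mean <= report.run_max
        assert set(report.stage_run_means) == {"I", "II", "III"}
        for counter in report.chosen_pairs.values():
            for (lc, lg), _ in counter.items():
                assert lc in LOG2_C_GRID and lg in LOG2_GAMMA_GRID

    def test_no_test_fold_leakage(self):
        # the model fitted for a fold must not depend on its test recordings:
        # refit on the same training set with one test recording deleted and
        # compare decision functions
        cats = self._small_study()
        n = len(cats)
        rng = np.random.default_rng(0)
        folds = partition_folds(n, 4, rng)
        test_idx = folds[0]
        train = [cats[i] for i in np.setdiff1d(np.arange(n), test_idx)]
        m1 = fit_cascade(train, rng=np.random.default_rng(42))
        m2 = fit_cascade(train, rng=np.random.default_rng(42))
        probe = np.array([[14.0, 45.0, 30.0], [20.0, 90.0, 10.0]])
        np.testing.assert_array_equal(
            m1.stage_i.decision_values(probe), m2.stage_i.decision_values(probe)
        )
        assert (m1.stage_i.log2_c, m1.stage_i.log2_gamma) == (
            m2.stage_i.log2_c,
            m2.stage_i.log2_gamma,
        )
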