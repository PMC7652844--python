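import numpy as np
import pytest
from scipy import optimize, stats as sstats

from eegbeta.classify import (
    ConstrainedAccuracy,
    ModelSpec,
    ResampleConfig,
    ROCCurve,
    auc,
    auc_from_scores,
    balanced_subsample_mean_roc,
    constrained_max_accuracy,
    evaluate_models,
    fit_logistic,
    loocv_scores,
    mean_feature_spec,
    rank_select_channels,
    roc_curve,
)
from eegbeta.errors import ConfigurationError, DegenerateLabelsError
from eegbeta.simulate import SimulationConfig

from conftest import analytic_feature_table


def newton_oracle(X, y, tol=1e-12):
    """Independent maximum-likelihood oracle via direct NLL minimization."""
    Xb = np.hstack([np.ones((len(y), 1)), np.atleast_2d(X.T).T])

    def nll(b):
        eta = Xb @ b
        return np.sum(np.logaddexp(0, eta)) - y @ eta

    res = optimize.minimize(nll, np.zeros(Xb.shape[1]), method="BFGS",
                            options={"gtol": tol})
    return res.x


class TestLogistic:
    def test_intercept_only(self):
        model = fit_logistic(np.empty((4, 0)), np.array([1, 1, 1, 0]))
        assert model.intercept == pytest.approx(np.log(3.0), abs=1e-6)

    def test_constant_feature_balanced(self):
        model = fit_logistic(np.ones((4, 1)), np.array([0, 1, 0, 1]))
        assert abs(model.intercept) < 1e-6
        assert abs(model.coefficients[0]) < 1e-6

    def test_matches_newton_oracle(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 1, 0, 1])
        model = fit_logistic(X, y)
        ref = newton_oracle(X, y)
        assert abs(model.intercept - ref[0]) < 1e-6
        assert abs(model.coefficients[0] - ref[1]) < 1e-6

    def test_separation_flagged(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_logistic(X, y)
        assert model.separation
        assert not model.converged
        p = model.predict_proba(X)
        assert np.all((p > 0) & (p < 1))
        assert p[0] < 0.01 and p[-1] > 0.99

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            fit_logistic(np.ones((3, 1)), np.array([1, 1, 1]))

    def test_string_labels(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        model = fit_logistic(X, np.array(["female", "male", "female", "male"]))
        p = model.predict_proba(X)
        assert p[1] > p[0]  # male is the positive class


class TestROC:
    def test_perfect_separation(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], ["male", "male", "female", "female"])
        assert auc(curve) == pytest.approx(1.0)
        assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))

    def test_all_ties_is_diagonal(self):
        curve = roc_curve([0.5] * 6, ["male"] * 3 + ["female"] * 3)
        assert auc(curve) == pytest.approx(0.5)
        assert len(curve.fpr) == 2  # origin plus one massive diagonal step

    def test_worked_example(self):
        # labels (m,m,f,f), scores (0.9, 0.3, 0.5, 0.1): 3 of 4 pairs concordant
        a = auc_from_scores([0.9, 0.3, 0.5, 0.1], ["male", "male", "female", "female"])
        assert a == pytest.approx(0.75)

    def test_brute_force_pair_count(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            scores = rng.choice(np.linspace(0, 1, 13), size=30)  # with ties
            y = rng.integers(0, 2, size=30)
            if y.min() == y.max():
                continue
            pos, neg = scores[y == 1], scores[y == 0]
            conc = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            expected = (conc + 0.5 * ties) / (len(pos) * len(neg))
            assert auc_from_scores(scores, y, positive=1) == pytest.approx(expected, abs=1e-12)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(8)
        scores = rng.standard_normal(40)
        y = rng.integers(0, 2, size=40)
        a1 = auc_from_scores(scores, y, positive=1)
        a2 = auc_from_scores(np.exp(3 * scores) + 7, y, positive=1)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_label_flip(self):
        rng = np.random.default_rng(9)
        scores = rng.standard_normal(50)
        y = rng.integers(0, 2, size=50)
        a = auc_from_scores(scores, y, positive=1)
        b = auc_from_scores(scores, y, positive=0)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_thresholds_strictly_decreasing(self):
        rng = np.random.default_rng(10)
        curve = roc_curve(rng.random(25), rng.integers(0, 2, 25), positive=1)
        assert np.all(np.diff(curve.thresholds) < 0)

    def test_mann_whitney_equivalence(self):
        rng = np.random.default_rng(11)
        scores = rng.standard_normal(50)
        y = rng.integers(0, 2, size=50)
        u = sstats.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        expected = u / (y.sum() * (50 - y.sum()))
        assert auc_from_scores(scores, y, positive=1) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_labels(self):
        with pytest.raises(DegenerateLabelsError):
            roc_curve([0.1, 0.2], ["male", "male"])


class TestConstrainedAccuracy:
    def test_worked_example(self):
        res = constrained_max_accuracy([0.9, 0.6, 0.5, 0.1],
                                       ["male", "male", "female", "female"])
        assert res.feasible
        assert res.accuracy_pct == pytest.approx(100.0)
        assert 0.5 < res.threshold <= 0.6

    def test_anti_separated_infeasible(self):
        res = constrained_max_accuracy([0.1, 0.2, 0.8, 0.9],
                                       ["male", "male", "female", "female"])
        assert not res.feasible

    def test_all_ties_infeasible(self):
        res = constrained_max_accuracy([0.4] * 6, ["male"] * 3 + ["female"] * 3)
        assert not res.feasible

    def test_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(8, 24))
            scores = rng.choice(np.linspace(0, 1, 9), size=n)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            n_pos, n_neg = y.sum(), n - y.sum()
            best = -1.0
            for t in np.unique(scores):
                pred = scores >= t
                tpr = (pred & (y == 1)).sum() / n_pos
                fpr = (pred & (y == 0)).sum() / n_neg
                if tpr > 0.5 and fpr < 0.5:
                    best = max(best, 100.0 * (pred == y).mean())
            res = constrained_max_accuracy(scores, y, positive=1)
            if best < 0:
                assert not res.feasible
            else:
                assert res.accuracy_pct == pytest.approx(best, abs=1e-9)


class TestBalancedSubsampling:
    def _table(self, effect, n=60, n_f=36, seed=0):
        cfg = SimulationConfig(n_subjects=n, n_female=n_f, duration=61,
                               effect_size=effect, seed=seed)
        t = analytic_feature_table(cfg)
        return t[t.session == "pre"]

    def test_separable_all_iterations_perfect(self):
        t = self._table(effect=12.0)
        X = t[["mean_rel_beta"]].to_numpy()
        cfg = ResampleConfig(n_iterations=10, per_class_n=10)
        curve, aucs = balanced_subsample_mean_roc(X, t["sex"].to_numpy(), cfg)
        assert np.allclose(aucs, 1.0)
        assert auc(curve) == pytest.approx(1.0, abs=0.02)

    def test_null_matches_folded_expectation(self):
        # each iteration refits, so its in-sample AUC folds to max(A, 1 - A);
        # under the null the expected mean is 0.5 + SE * sqrt(2/pi), where SE
        # is the null AUC standard error at the subsample size (half-normal
        # mean). Oracle value computed from that closed form.
        t = self._table(effect=0.0, seed=3)
        X = t[["mean_rel_beta"]].to_numpy()
        per_class = 20
        cfg = ResampleConfig(n_iterations=100, per_class_n=per_class)
        curve, aucs = balanced_subsample_mean_roc(X, t["sex"].to_numpy(), cfg)
        se = np.sqrt((2 * per_class + 1) / (12 * per_class**2))
        expected = 0.5 + se * np.sqrt(2 / np.pi)
        assert abs(aucs.mean() - expected) < 0.03

    def test_single_iteration_equals_its_curve(self):
        t = self._table(effect=1.0, seed=4)
        X = t[["mean_rel_beta"]].to_numpy()
        y = t["sex"].to_numpy()
        cfg = ResampleConfig(n_iterations=1, per_class_n=12, seed=99)
        curve, aucs = balanced_subsample_mean_roc(X, y, cfg)
        assert auc(curve) == pytest.approx(aucs[0], abs=0.02)

    def test_reproducible(self):
        t = self._table(effect=1.0, seed=5)
        X = t[["mean_rel_beta"]].to_numpy()
        y = t["sex"].to_numpy()
        cfg = ResampleConfig(n_iterations=5, per_class_n=12, seed=42)
        c1, a1 = balanced_subsample_mean_roc(X, y, cfg)
        c2, a2 = balanced_subsample_mean_roc(X, y, cfg)
        assert np.array_equal(a1, a2)
        assert np.array_equal(c1.tpr, c2.tpr)

    def test_class_too_small(self):
        t = self._table(effect=1.0)
        X = t[["mean_rel_beta"]].to_numpy()
        with pytest.raises(ConfigurationError):
            balanced_subsample_mean_roc(X, t["sex"].to_numpy(),
                                        ResampleConfig(per_class_n=1000))


class TestLOOCV:
    def test_separation_with_margin(self):
        X = np.concatenate([np.linspace(0, 1, 10), np.linspace(3, 4, 10)])[:, None]
        y = np.array([0] * 10 + [1] * 10)
        scores = loocv_scores(X, y)
        assert auc_from_scores(scores, y, positive=1) == pytest.approx(1.0)

    def test_null_pessimism(self):
        # leave-one-out on an uninformative feature is systematically
        # pessimistic: the training fold's class balance tilts against the
        # held-out label, so pooled AUC falls below 0.5 (null-simulation
        # oracle: with an exactly balanced cohort the intercept difference
        # dominates and the AUC collapses toward 0)
        rng = np.random.default_rng(14)
        aucs = []
        for _ in range(5):
            X = rng.standard_normal((80, 1))
            y = rng.permutation([0] * 40 + [1] * 40)
            aucs.append(auc_from_scores(loocv_scores(X, y), y, positive=1))
        assert np.mean(aucs) < 0.5

    def test_each_subject_scored_once(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((20, 2))
        y = np.array([0, 1] * 10)
        scores = loocv_scores(X, y)
        assert scores.shape == (20,)
        assert np.all((scores > 0) & (scores < 1))

    def test_too_few_per_class(self):
        X = np.random.default_rng(16).standard_normal((5, 1))
        with pytest.raises(DegenerateLabelsError):
            loocv_scores(X, np.array([0, 0, 0, 1, 1]))


class TestRankSelection:
    def test_informative_channel_first(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((60, 5))
        y = np.array([0] * 30 + [1] * 30)
        X[y == 1, 3] += 2.0
        assert rank_select_channels(X, y, 1) == [3]

    def test_k_equals_all_is_identity(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((20, 4))
        y = np.array([0, 1] * 10)
        assert rank_select_channels(X, y, 4) == [0, 1, 2, 3]

    def test_k_out_of_range(self):
        X = np.zeros((10, 3))
        y = np.array([0, 1] * 5)
        with pytest.raises(ConfigurationError):
            rank_select_channels(X, y, 0)
        with pytest.raises(ConfigurationError):
            rank_select_channels(X, y, 4)

    def test_no_leakage_between_folds(self):
        # selection computed on each training fold independently
        rng = np.random.default_rng(19)
        X = rng.standard_normal((30, 6))
        y = np.array([0, 1] * 15)
        sel_full = rank_select_channels(X[:-1], y[:-1], 2)
        sel_other = rank_select_channels(X[1:], y[1:], 2)
        # both are valid selections of size 2 computed on different data
        assert len(sel_full) == len(sel_other) == 2


@pytest.fixture(scope="module")
def cfg_small():
    return ResampleConfig(n_iterations=5, per_class_n=10, seed=0)


class TestEvaluateModels:
    def test_separable_cohort_all_cells_perfect(self, cfg_small):
        cfg = SimulationConfig(n_subjects=40, n_female=20, duration=61,
                               effect_size=14.0, beta_factor_sigma=0.6, seed=6)
        table = analytic_feature_table(cfg, channel_noise=0.001)
        results = evaluate_models(table, cfg_small)
        assert len(results) == 12  # 6 models x 2 sessions
        for r in results:
            assert r.auc == pytest.approx(1.0, abs=0.02), r.model

    def test_null_cohort_overfitting_gap(self, cfg_small):
        cfg = SimulationConfig(n_subjects=50, n_female=25, duration=61,
                               effect_size=0.0, seed=7)
        table = analytic_feature_table(cfg, channel_noise=1.0)
        results = {(r.model, r.scheme): r
                   for r in evaluate_models(table, cfg_small, sessions=("pre",))}
        gap = (results[("all_channels", "in-sample")].auc
               - results[("all_channels", "leave-one-out")].auc)
        assert gap > 0

    def test_missing_session_gives_partial_grid(self, cfg_small):
        cfg = SimulationConfig(n_subjects=30, n_female=15, duration=61, seed=8)
        table = analytic_feature_table(cfg)
        table = table[table.session == "pre"]
        results = evaluate_models(table, cfg_small)
        assert {r.session for r in results} == {"pre"}

    def test_expected_scheme_ordering_on_average(self, cfg_small):
        # in-sample multivariate >= univariate >= loocv multivariate, on average
        gaps_mu, gaps_ul = [], []
        for seed in range(6):
            cfg = SimulationConfig(n_subjects=60, n_female=30, duration=61,
                                   effect_size=0.9, seed=seed)
            table = analytic_feature_table(cfg, channel_noise=0.5, noise_seed=seed)
            res = {(r.model, r.scheme): r
                   for r in evaluate_models(table, cfg_small, sessions=("pre",))}
            multi_in = res[("all_channels", "in-sample")].auc
            uni_in = res[("mean_rel_beta", "in-sample")].auc
            multi_loo = res[("all_channels", "leave-one-out")].auc
            gaps_mu.append(multi_in - uni_in)
            gaps_ul.append(uni_in - multi_loo)
        assert np.mean(gaps_mu) >= 0
        assert np.mean(gaps_ul) >= 0


class TestSpecsAndTypes:
    def test_model_spec_validation(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("m", ("a", "b"), select_k=3)

    def test_resample_config_validation(self):
        with pytest.raises(ConfigurationError):
            ResampleConfig(n_iterations=0)

    def test_roc_curve_invariants_enforced(self):
        with pytest.raises(ValueError):
            ROCCurve(fpr=[0.0, 0.5, 0.3], tpr=[0.0, 0.5, 1.0], thresholds=None)

    def test_mean_spec(self):
        assert mean_feature_spec().features == ("mean_rel_beta",)
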