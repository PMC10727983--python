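"""Classifier protocol: splitting, thresholding, CV training, evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cfrepeat import classify
from cfrepeat.classify import (
    ModelFit,
    SplitSpec,
    auc,
    binomial_ci,
    coefficient_vs_lfc,
    cv_train,
    evaluate_test,
    stratified_split,
    threshold_at_specificity,
)


class TestSplit:
    IDS = [f"s{i}" for i in range(40)]
    Y = [1] * 20 + [0] * 20

    def test_sizes_16_4_per_class(self):
        train, test = stratified_split(self.IDS, self.Y, SplitSpec(seed=0))
        assert len(train) == 32 and len(test) == 8
        case_train = sum(1 for s in train if int(s[1:]) < 20)
        assert case_train == 16

    def test_deterministic_and_seed_sensitive(self):
        a = stratified_split(self.IDS, self.Y, SplitSpec(seed=1))
        b = stratified_split(self.IDS, self.Y, SplitSpec(seed=1))
        c = stratified_split(self.IDS, self.Y, SplitSpec(seed=2))
        assert a == b
        assert set(a[0]) != set(c[0]) and len(c[0]) == len(a[0])

    def test_disjoint_and_total(self):
        train, test = stratified_split(self.IDS, self.Y, SplitSpec(seed=3))
        assert set(train) | set(test) == set(self.IDS)
        assert not set(train) & set(test)


class TestThreshold:
    def test_enumerated_ten_controls(self):
        ctrl = np.arange(0.05, 0.501, 0.05)
        probs = np.concatenate([ctrl, [0.8, 0.9]])
        y = np.array([0] * 10 + [1, 1])
        t = threshold_at_specificity(probs, y, 0.9)
        assert t == pytest.approx((0.45 + 0.50) / 2)
        spec = (probs[y == 0] < t).mean()
        assert spec == 0.9

    def test_all_zero_controls_returns_upper_sentinel(self):
        y = np.array([0] * 12 + [1])
        t = threshold_at_specificity(np.array([0.0] * 12 + [0.7]), y, 0.9)
        assert t == 1.0

    def test_target_one_above_max_control(self):
        ctrl = np.linspace(0.1, 0.6, 12)
        y = np.array([0] * 12 + [1])
        t = threshold_at_specificity(np.concatenate([ctrl, [0.9]]), y, 1.0)
        assert t > ctrl.max()

    def test_few_controls_warns(self, caplog):
        with caplog.at_level("WARNING"):
            threshold_at_specificity(np.array([0.1, 0.2, 0.9]), np.array([0, 0, 1]), 0.9)
        assert "coarse-grained" in caplog.text

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_target(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        probs = rng.random(n + 5)
        y = np.array([0] * n + [1] * 5)
        t_lo = threshold_at_specificity(probs, y, 0.7)
        t_hi = threshold_at_specificity(probs, y, 0.95)
        assert t_hi >= t_lo


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n1, n0 = rng.integers(3, 25, size=2)
            p = np.round(rng.random(n1 + n0), 2)  # rounding forces ties
            y = np.array([1] * n1 + [0] * n0)
            pos, neg = p[y == 1], p[y == 0]
            oracle = np.mean([(a > b) + 0.5 * (a == b) for a in pos for b in neg])
            assert auc(p, y) == pytest.approx(oracle, abs=1e-12)

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(2)
        aucs = []
        for _ in range(200):
            p = rng.random(30)
            y = rng.permutation([1] * 15 + [0] * 15)
            aucs.append(auc(p, y))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


class TestBinomialCI:
    def test_printed_example(self):
        lo, hi = binomial_ci(8, 10)
        assert (lo, hi) == pytest.approx((0.4439, 0.9748), abs=2e-4)

    def test_edge_cases(self):
        assert binomial_ci(10, 10)[1] == 1.0
        assert binomial_ci(0, 10)[0] == 0.0

    def test_matches_statsmodels_beta_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(3, 17), (12, 12), (0, 9), (25, 40)]:
            lo, hi = binomial_ci(k, n)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert (lo, hi) == pytest.approx((slo, shi), abs=1e-10)


def separable_data(n_per=30, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "f1": np.concatenate([rng.normal(0, 1, n_per), rng.normal(6, 1, n_per)]),
            "f2": np.concatenate([rng.normal(0, 1, n_per), rng.normal(6, 1, n_per)]),
            "noise": rng.normal(size=2 * n_per),
        },
        index=[f"s{i}" for i in range(2 * n_per)],
    )
    y = pd.Series([0] * n_per + [1] * n_per, index=X.index)
    return X, y


class TestCvTrain:
    def test_separable_data_perfect_training_auc(self):
        X, y = separable_data()
        model = cv_train(X, y, alpha_grid=(0.5,), folds=5, seed=0)
        assert model.train_metrics["auc"] == 1.0
        nz = model.nonzero_features()
        assert {"f1", "f2"} <= set(nz.index)

    def test_large_lambda_lasso_degenerates_gracefully(self):
        X, y = separable_data(seed=1)
        from cfrepeat.classify import _fit_enet

        Xs = ((X - X.mean()) / X.std(ddof=1)).values
        m = _fit_enet(Xs, y.values, alpha=1.0, lam=100.0)
        assert np.allclose(m.coef_, 0.0)
        p = m.predict_proba(Xs)[:, 1]
        t = threshold_at_specificity(p, y.values, 0.9)
        sens, spec = classify.sensitivity_specificity(p, y.values, t)
        assert spec >= 0.9 and sens == 0.0  # all predictions below threshold

    def test_single_class_training_errors(self):
        X, y = separable_data()
        with pytest.raises(ValueError, match="single class"):
            cv_train(X, pd.Series(1, index=X.index), alpha_grid=(0.5,), folds=3)

    def test_identical_seeds_byte_identical_model_files(self, tmp_path):
        X, y = separable_data(seed=2)
        paths = []
        for run in (1, 2):
            m = cv_train(X, y, alpha_grid=(0.0, 0.5, 1.0), folds=5, seed=42)
            p = tmp_path / f"model{run}.json"
            m.save(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_null_features_no_optimism_leak(self):
        """Pure-noise features: held-out sensitivity stays near the false-positive
        rate implied by the threshold, instead of inheriting training optimism."""
        rng = np.random.default_rng(3)
        sens_list = []
        for rep in range(10):
            n, p = 60, 100
            X = pd.DataFrame(
                rng.normal(size=(n, p)),
                index=[f"s{i}" for i in range(n)],
                columns=[f"f{j}" for j in range(p)],
            )
            y = pd.Series([0] * 30 + [1] * 30, index=X.index)
            train, test = stratified_split(list(X.index), y.values, SplitSpec(seed=rep))
            model = cv_train(X.loc[train], y.loc[train], alpha_grid=(1.0,), folds=5,
                             n_lambda=10, seed=rep)
            res = evaluate_test(model, X.loc[test], y.loc[test])
            sens_list.append(res.sensitivity)
        # at a >=90%-specificity threshold a null model flags few cases
        assert np.mean(sens_list) < 0.5

    def test_model_json_roundtrip(self, tmp_path):
        X, y = separable_data(seed=4)
        m = cv_train(X, y, alpha_grid=(0.5,), folds=4, seed=0)
        p = tmp_path / "m.json"
        m.save(p)
        back = ModelFit.load(p)
        np.testing.assert_allclose(back.predict_proba(X), m.predict_proba(X), atol=1e-12)
        assert back.threshold_90 == m.threshold_90


class TestEvaluate:
    def test_test_equals_train_consistency(self):
        X, y = separable_data(seed=5)
        m = cv_train(X, y, alpha_grid=(0.5,), folds=5, seed=0)
        res = evaluate_test(m, X, y)
        assert res.sensitivity == pytest.approx(m.train_metrics["sensitivity"])
        assert res.auc == pytest.approx(m.train_metrics["auc"])

    def test_planted_signal_high_test_sensitivity(self):
        X, y = separable_data(n_per=50, seed=6)
        train, test = stratified_split(list(X.index), y.values, SplitSpec(seed=0))
        m = cv_train(X.loc[train], y.loc[train], alpha_grid=(0.5,), folds=5, seed=0)
        res = evaluate_test(m, X.loc[test], y.loc[test])
        assert res.sensitivity >= 0.9
        assert res.ci_low <= res.sensitivity <= res.ci_high

    def test_single_class_test_errors(self):
        X, y = separable_data()
        m = cv_train(X, y, alpha_grid=(0.5,), folds=4, seed=0)
        with pytest.raises(ValueError, match="both classes"):
            evaluate_test(m, X.iloc[:5], y.iloc[:5] * 0)


class TestCoefficientVsLfc:
    def make_model(self, beta: dict):
        feats = list(beta)
        return ModelFit(
            alpha=0.5,
            lam=0.1,
            beta=pd.Series(beta),
            intercept=0.0,
            feature_set="x",
            threshold_90=0.5,
        )

    def make_de(self, lfc: dict):
        import pandas as pd

        from cfrepeat.diffexp import DEResult, DesignSpec

        tab = pd.DataFrame(
            {"baseMean": 1.0, "log2FoldChange": pd.Series(lfc), "lfcSE": 0.1,
             "pvalue": 0.001, "padj": 0.001, "converged": True}
        )
        return DEResult(table=tab, design=DesignSpec(), sample_ids=["s"])

    def test_restricted_to_nonzero_repeat_features(self):
        model = self.make_model({"rmsk:A": 1.0, "rmsk:B": 0.0, "G1": 2.0, "rmsk:C": -0.5})
        de = self.make_de({"rmsk:A": 1.5, "rmsk:C": -0.7, "G1": 0.2})
        out = coefficient_vs_lfc(model, de)
        assert sorted(out["feature"]) == ["rmsk:A", "rmsk:C"]
        assert out.attrs["n_total_nonzero"] == 3

    def test_missing_de_feature_gets_nan(self, caplog):
        model = self.make_model({"rmsk:A": 1.0})
        de = self.make_de({"rmsk:Z": 0.5})
        with caplog.at_level("WARNING"):
            out = coefficient_vs_lfc(model, de)
        assert np.isnan(out["log2FoldChange"].iloc[0])

    def test_planted_concordant_signs(self):
        rng = np.random.default_rng(7)
        lfc = {f"rmsk:R{i}": float(rng.choice([-2.0, 2.0])) for i in range(20)}
        beta = {f: l * abs(rng.normal()) + rng.normal(0, 0.1) for f, l in lfc.items()}
        out = coefficient_vs_lfc(self.make_model(beta), self.make_de(lfc))
        agree = np.mean(np.sign(out["beta"]) == np.sign(out["log2FoldChange"]))
        assert agree > 0.8
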