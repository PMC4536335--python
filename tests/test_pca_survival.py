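import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from synergyscreen.pca_survival import (
    SignatureModel,
    SurvivalRecord,
    fit_pc1,
    fix_sign,
    km_estimate,
    logrank_test,
    median_split,
    score_samples,
)
from synergyscreen.signature_screen import ExpressionMatrix
from synergyscreen.synthetic_data import SimulationConfig, gen_expression_phenotype, gen_survival


def _records(times, events, prefix="x"):
    return [
        SurvivalRecord(sample=f"{prefix}{i}", time=float(t), event=int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestFitPC1:
    def test_two_perfectly_correlated_genes(self):
        rng = np.random.default_rng(0)
        g1 = rng.standard_normal(50)
        df = pd.DataFrame([g1, 2 * g1 + 3], index=["G1", "G2"],
                          columns=[f"S{i}" for i in range(50)])
        expr = ExpressionMatrix(df)
        model = fit_pc1(expr)
        assert np.abs(model.weights) == pytest.approx([1 / np.sqrt(2)] * 2)
        scores = score_samples(model, expr)
        assert np.var(scores, ddof=1) == pytest.approx(2.0)

    def test_unit_norm_weights(self, small_expression):
        model = fit_pc1(small_expression)
        assert np.sum(model.weights**2) == pytest.approx(1.0, abs=1e-12)

    def test_score_variance_is_top_eigenvalue(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((3, 40)), index=["A", "B", "C"],
                          columns=[f"S{i}" for i in range(40)])
        expr = ExpressionMatrix(df)
        model = fit_pc1(expr)
        scores = score_samples(model, expr)
        eigvals = np.linalg.eigvalsh(np.corrcoef(df.to_numpy()))
        assert np.var(scores, ddof=1) == pytest.approx(eigvals[-1], rel=1e-9)

    def test_matches_sklearn_loadings(self, small_expression):
        from sklearn.decomposition import PCA

        model = fit_pc1(small_expression)
        X = small_expression.values.to_numpy().T
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = PCA(n_components=1).fit(Z).components_[0]
        ref = ref / np.linalg.norm(ref)
        if np.sign(ref.sum()) < 0:
            ref = -ref
        assert model.weights == pytest.approx(ref, abs=1e-9)

    def test_zero_variance_gene_named(self):
        df = pd.DataFrame([[1.0] * 5, list(range(5))], index=["FLAT", "G1"],
                          columns=[f"S{i}" for i in range(5)])
        with pytest.raises(ValueError, match="FLAT"):
            fit_pc1(ExpressionMatrix(df))

    def test_more_genes_than_samples_allowed(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.standard_normal((20, 5)),
                          index=[f"G{i}" for i in range(20)],
                          columns=[f"S{i}" for i in range(5)])
        model = fit_pc1(ExpressionMatrix(df))
        assert np.sum(model.weights**2) == pytest.approx(1.0, abs=1e-12)


class TestFixSign:
    def _model(self, weights):
        w = np.asarray(weights, float)
        w = w / np.linalg.norm(w)
        k = len(w)
        return SignatureModel(genes=tuple(f"G{i}" for i in range(k)), weights=w,
                              center=np.zeros(k), scale=np.ones(k))

    def test_negative_sum_flipped(self):
        model = fix_sign(self._model([-1.0, -1.0]))
        assert np.all(model.weights > 0)

    def test_positive_sum_unchanged(self):
        model = self._model([1.0, 1.0])
        assert fix_sign(model) is model

    def test_idempotent(self):
        model = self._model([-3.0, 1.0])
        once = fix_sign(model)
        assert fix_sign(once) is once


class TestScoreSamples:
    def test_degenerate_weight_vector(self):
        model = SignatureModel(genes=("G1", "G2"), weights=np.array([1.0, 0.0]),
                               center=np.zeros(2), scale=np.ones(2))
        df = pd.DataFrame([[2.3], [-5.0]], index=["G1", "G2"], columns=["S0"])
        scores = score_samples(model, ExpressionMatrix(df))
        assert scores["S0"] == pytest.approx(2.3)

    def test_negating_weights_negates_scores(self, small_expression):
        model = fit_pc1(small_expression)
        flipped = replace(model, weights=-model.weights)
        s = score_samples(model, small_expression)
        assert score_samples(flipped, small_expression).to_numpy() == pytest.approx(
            (-s).to_numpy()
        )

    def test_training_scores_reproduce_pc1(self, small_expression):
        model = fit_pc1(small_expression)
        X = small_expression.values.to_numpy().T
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        expected = Z @ model.weights
        assert score_samples(model, small_expression).to_numpy() == pytest.approx(
            expected, abs=1e-9
        )

    def test_missing_genes_dropped_and_renormalized(self, small_expression):
        model = fit_pc1(small_expression)
        partial = ExpressionMatrix(small_expression.values.iloc[:6])  # 6 of 10 genes
        scores = score_samples(model, partial)
        assert len(scores) == 20
        assert np.isfinite(scores).all()

    def test_below_half_genes_errors(self, small_expression):
        model = fit_pc1(small_expression)
        partial = ExpressionMatrix(small_expression.values.iloc[:4])
        with pytest.raises(ValueError, match="50%"):
            score_samples(model, partial)


class TestMedianSplit:
    def test_even_count(self):
        groups = median_split(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert list(groups[groups == "low"].index) == ["a", "b"]
        assert list(groups[groups == "high"].index) == ["c", "d"]

    def test_odd_count_median_goes_low(self):
        groups = median_split(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert list(groups[groups == "low"].index) == ["a", "b"]
        assert list(groups[groups == "high"].index) == ["c"]

    def test_degenerate(self):
        with pytest.raises(ValueError, match="degenerate split"):
            median_split(pd.Series([5.0, 5.0, 5.0]))

    def test_balanced_for_distinct_scores(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.standard_normal(101))
        groups = median_split(scores)
        assert abs((groups == "low").sum() - (groups == "high").sum()) <= 1


class TestKaplanMeier:
    def test_no_events(self):
        curve = km_estimate(_records([1, 2, 3, 4], [0, 0, 0, 0]))
        assert curve.event_times.size == 0
        assert curve.survival_at(10.0) == 1.0

    def test_hand_computed_no_censoring(self):
        # deaths at t=1 and t=2 of 4: S = 3/4 then (3/4)(2/3) = 1/2
        curve = km_estimate(_records([1, 2, 3, 4], [1, 1, 0, 0]))
        assert curve.survival_at(1.0) == pytest.approx(0.75)
        assert curve.survival_at(2.0) == pytest.approx(0.5)

    def test_hand_computed_with_censoring(self):
        # death at 1 (of 4), censor at 1.5, death at 2 (of 2): (3/4)*(1/2)
        curve = km_estimate(_records([1, 1.5, 2, 3], [1, 0, 1, 0]))
        assert curve.survival_at(1.0) == pytest.approx(0.75)
        assert curve.survival_at(2.0) == pytest.approx(0.375)

    def test_time_zero_is_one_and_right_continuous(self):
        curve = km_estimate(_records([1, 2, 3, 4], [1, 1, 1, 0]))
        assert curve.survival_at(0.0) == 1.0
        assert curve.survival_at(0.999) == 1.0
        assert curve.survival_at(1.0) == pytest.approx(0.75)  # right-continuous step

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(21)
        times = rng.exponential(5.0, size=40)
        curve = km_estimate(_records(times, np.ones(40)))
        for t in [1.0, 3.0, 7.0]:
            assert curve.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_matches_lifelines(self):
        rng = np.random.default_rng(22)
        times = np.round(rng.exponential(5.0, size=60), 1)  # force ties
        events = rng.integers(0, 2, size=60)
        events[0] = 1
        curve = km_estimate(_records(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.event_times, curve.survival_prob):
            assert s == pytest.approx(float(kmf.predict(t)), abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord(sample="a", time=-1.0, event=1)


def _brute_force_logrank(a, b):
    """First-principles O/E/V tabulation at each distinct event time."""
    ta = np.array([r.time for r in a]); ea = np.array([r.event for r in a])
    tb = np.array([r.time for r in b]); eb = np.array([r.event for r in b])
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O = E = V = 0.0
    for t in times:
        n1, n2 = (ta >= t).sum(), (tb >= t).sum()
        d1, d2 = ((ta == t) & (ea == 1)).sum(), ((tb == t) & (eb == 1)).sum()
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogRank:
    def test_identical_groups(self):
        recs = _records([1, 2, 3, 4], [1, 1, 0, 1])
        stat, p = logrank_test(recs, recs)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_data_matches_brute_force(self):
        a = _records([1, 2], [1, 1], "a")
        b = _records([3, 4], [1, 1], "b")
        stat, _ = logrank_test(a, b)
        assert stat == pytest.approx(_brute_force_logrank(a, b), abs=1e-12)

    def test_random_data_matches_brute_force_and_lifelines(self):
        rng = np.random.default_rng(31)
        a = _records(np.round(rng.exponential(5, 50), 1), rng.integers(0, 2, 50), "a")
        b = _records(np.round(rng.exponential(3, 60), 1), rng.integers(0, 2, 60), "b")
        stat, p = logrank_test(a, b)
        assert stat == pytest.approx(_brute_force_logrank(a, b), abs=1e-10)
        ref = lifelines_logrank(
            [r.time for r in a], [r.time for r in b],
            event_observed_A=[r.event for r in a], event_observed_B=[r.event for r in b],
        )
        assert stat == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(32)
        a = _records(rng.exponential(5, 30), np.ones(30), "a")
        b = _records(rng.exponential(2, 30), np.ones(30), "b")
        assert logrank_test(a, b).statistic == pytest.approx(
            logrank_test(b, a).statistic, abs=1e-12
        )

    def test_no_events_errors(self):
        a = _records([1, 2], [0, 0], "a")
        b = _records([3], [0], "b")
        with pytest.raises(ValueError, match="no events"):
            logrank_test(a, b)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([], _records([1], [1]))

    def test_power_under_hazard_ratio_3(self):
        # n = 200/group, HR = 3: p < 0.05 in >= 95% of 200 seeded replicates
        hits = 0
        low = [f"L{i}" for i in range(200)]
        high = [f"H{i}" for i in range(200)]
        for seed in range(200):
            cfg = SimulationConfig(seed=seed)
            recs = gen_survival(low, high, 3.0, cfg)
            a = [r for r in recs if r.sample.startswith("L")]
            b = [r for r in recs if r.sample.startswith("H")]
            if logrank_test(a, b).p_value < 0.05:
                hits += 1
        assert hits >= 0.95 * 200


class TestSignFlipInvariance:
    def test_downstream_statistics_unchanged(self, small_expression):
        model = fit_pc1(small_expression)
        flipped = replace(model, weights=-model.weights)
        s1, s2 = score_samples(model, small_expression), score_samples(flipped, small_expression)
        g1, g2 = median_split(s1), median_split(s2)
        # membership pattern identical up to label swap
        assert ((g1 == "low") == (g2 == "high")).all()
        cfg = SimulationConfig(seed=9, censoring_rate=0.1)
        recs = gen_survival(list(g1[g1 == "low"].index), list(g1[g1 == "high"].index), 2.0, cfg)
        by = {r.sample: r for r in recs}
        for groups in (g1, g2):
            a = [by[s] for s in groups[groups == "low"].index]
            b = [by[s] for s in groups[groups == "high"].index]
            stat, p = logrank_test(a, b)
        ref_a = [by[s] for s in g1[g1 == "low"].index]
        ref_b = [by[s] for s in g1[g1 == "high"].index]
        assert p == pytest.approx(logrank_test(ref_a, ref_b).p_value, abs=1e-12)


class TestEndToEndRecovery:
    def test_hazard_ratio_2_5_n218(self):
        # planted-signature pipeline on n=218: log-rank p < 0.05 in >= 90% of 100 reps
        hits = 0
        for seed in range(100):
            cfg = SimulationConfig(seed=seed, n_samples=218, n_signal_genes=47,
                                   n_null_genes=103, hazard_ratio=2.5, censoring_rate=0.2)
            expr, ic50, signal = gen_expression_phenotype(cfg)
            model = fit_pc1(expr.restrict(signal))
            groups = median_split(score_samples(model, expr))
            recs = gen_survival(
                list(groups[groups == "low"].index),
                list(groups[groups == "high"].index),
                cfg.hazard_ratio, cfg,
            )
            by = {r.sample: r for r in recs}
            a = [by[s] for s in groups[groups == "low"].index]
            b = [by[s] for s in groups[groups == "high"].index]
            if logrank_test(a, b).p_value < 0.05:
                hits += 1
        assert hits >= 90
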