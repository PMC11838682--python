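"""L1 path, AICc selection, refit, prediction and the raw-variable
benchmark."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from woerisk.binning import Bin, BinningScheme, fit_all
from woerisk.cohort import CohortTable, VariableSpec
from woerisk.model import (
    FittedRiskModel,
    PathPoint,
    aicc,
    default_grid,
    fit_baseline_benchmark,
    fit_pipeline,
    l1_path,
    lambda_max,
    load_model,
    predict,
    save_model,
    select_and_refit,
    woe_design,
)


class TestAicc:
    def test_hand_value(self):
        assert aicc(nll=10, k=3, n=20) == pytest.approx(27.5, abs=1e-12)

    def test_large_n_limit_is_plain_aic(self):
        assert aicc(nll=10, k=1, n=10**9) == pytest.approx(22.0, abs=1e-6)

    def test_degenerate_sample_size_errors(self):
        with pytest.raises(ValueError):
            aicc(nll=1.0, k=9, n=10)


@pytest.fixture(scope="module")
def small_design():
    rng = np.random.default_rng(0)
    n = 80
    X = pd.DataFrame({
        "a": rng.standard_normal(n),
        "b": rng.standard_normal(n),
    })
    z = 0.8 * X["a"].to_numpy() - 0.3
    y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(int)
    return X, y


class TestL1Path:
    def test_lambda_max_gives_null_model(self, small_design):
        X, y = small_design
        lmax = lambda_max(X.to_numpy(), y.astype(float))
        (point,) = l1_path(X, y, grid=[lmax * 1.0001])
        assert np.all(point.coef == 0.0)
        prior = y.mean()
        assert point.intercept == pytest.approx(math.log(prior / (1 - prior)),
                                                abs=1e-3)
        assert point.k == 1

    def test_zero_penalty_matches_generic_convex_optimizer(self, small_design):
        X, y = small_design
        lmax = lambda_max(X.to_numpy(), y.astype(float))
        path = l1_path(X, y, grid=[lmax, 0.0], tol=1e-10)
        got = np.concatenate([[path[-1].intercept], path[-1].coef])

        Xa = np.column_stack([np.ones(len(y)), X.to_numpy()])

        def nll(w):
            z = Xa @ w
            return np.sum(np.logaddexp(0.0, -z * (2 * y - 1)))

        res = optimize.minimize(nll, np.zeros(3), method="BFGS",
                                options={"gtol": 1e-10})
        assert np.allclose(got, res.x, atol=1e-4)

    def test_informative_binary_gets_positive_sign(self):
        rng = np.random.default_rng(1)
        n = 400
        woe = rng.choice([-0.8, 0.8], n)  # WoE coding, positive = risk
        y = (rng.random(n) < 1 / (1 + np.exp(-woe))).astype(int)
        X = pd.DataFrame({"v": woe})
        path = l1_path(X, y, grid=default_grid(X.to_numpy(), y.astype(float),
                                               n_points=20))
        last = path[-1]
        assert last.coef[0] > 0

    def test_support_grows_down_the_path(self, desk_cohort):
        cohort, _ = desk_cohort
        schemes = fit_all(cohort)
        X = woe_design(cohort, schemes)
        path = l1_path(X, cohort.outcome,
                       grid=default_grid(X.to_numpy(),
                                         cohort.outcome.astype(float),
                                         n_points=25))
        assert len(path[0].support) == 0
        assert len(path[-1].support) >= len(path[0].support)


class TestSelectAndRefit:
    def test_dominant_point_chosen(self, small_design):
        X, y = small_design
        n = len(y)
        def mk(lam, nll, coef):
            k = int(np.count_nonzero(coef)) + 1
            return PathPoint(lam=lam, intercept=0.0, coef=np.array(coef),
                             names=("a", "b"), nll=nll, k=k,
                             aicc=aicc(nll, k, n))
        dominant = mk(0.5, 30.0, [0.7, 0.0])
        worse = mk(0.1, 35.0, [0.7, 0.2])
        model = select_and_refit([worse, dominant], X, y)
        assert model.chosen_lambda == 0.5
        assert model.selected == ("a",)

    def test_empty_support_returns_prior_intercept(self, small_design):
        X, y = small_design
        lmax = lambda_max(X.to_numpy(), y.astype(float))
        path = l1_path(X, y, grid=[lmax * 1.01])
        model = select_and_refit(path, X, y)
        assert model.selected == ()
        prior = y.mean()
        assert model.intercept == pytest.approx(math.log(prior / (1 - prior)),
                                                abs=1e-3)


def _scheme(name, edges_woe):
    """Hand-built continuous scheme: [(hi, woe), ...] with last hi=inf."""
    bins = []
    lo = -math.inf
    for hi, woe in edges_woe:
        bins.append(Bin(n_event=1, n_nonevent=1, woe=woe, lo=lo, hi=hi))
        lo = hi
    return BinningScheme(name, "continuous", bins, iv=0.1, smoothing=0.5)


class TestPredict:
    def test_hand_arithmetic(self):
        s1 = _scheme("x1", [(2.0, -0.5), (math.inf, 0.7)])
        s2 = _scheme("x2", [(0.0, 0.2), (math.inf, -0.4)])
        model = FittedRiskModel(
            selected=("x1", "x2"), intercept=0.3,
            weights={"x1": 1.5, "x2": -2.0},
            schemes={"x1": s1, "x2": s2}, l2_strength=1.0)
        values = pd.DataFrame({"x1": [1.0, 3.0, 1.0], "x2": [-1.0, 1.0, 1.0]})
        cohort = CohortTable(["a", "b", "c"], values, np.array([0, 1, 0]),
                             [VariableSpec("x1", "continuous"),
                              VariableSpec("x2", "continuous")])
        out = predict(model, cohort)
        expected_lo = [
            0.3 + 1.5 * -0.5 + (-2.0) * 0.2,
            0.3 + 1.5 * 0.7 + (-2.0) * -0.4,
            0.3 + 1.5 * -0.5 + (-2.0) * -0.4,
        ]
        assert np.allclose(out["log_odds"], expected_lo)
        assert np.allclose(out["probability"],
                           1 / (1 + np.exp(-np.array(expected_lo))))

    def test_intercept_only_prior_probability(self, hand_cohort):
        model = FittedRiskModel(selected=(), intercept=math.log(96 / 59),
                                weights={}, schemes={}, l2_strength=1.0)
        out = predict(model, hand_cohort)
        assert np.allclose(out["probability"], 96 / 155)

    def test_zero_log_odds_is_half(self, hand_cohort):
        model = FittedRiskModel(selected=(), intercept=0.0, weights={},
                                schemes={}, l2_strength=1.0)
        assert np.allclose(predict(model, hand_cohort)["probability"], 0.5)

    def test_missing_selected_variable_errors(self, hand_cohort):
        model = FittedRiskModel(selected=("ghost",), intercept=0.0,
                                weights={"ghost": 1.0},
                                schemes={"ghost": _scheme("ghost", [(math.inf, 0.0)])},
                                l2_strength=1.0)
        with pytest.raises(KeyError, match="ghost"):
            predict(model, hand_cohort)

    def test_invariant_to_variable_order(self, desk_cohort):
        cohort, _ = desk_cohort
        sub = cohort.subset(range(300))
        model = fit_pipeline(sub, grid=default_grid(
            woe_design(sub, fit_all(sub)).to_numpy(),
            sub.outcome.astype(float), n_points=15))
        shuffled = CohortTable(
            subject_ids=list(sub.subject_ids),
            values=sub.values[[s.name for s in sub.specs[::-1]]].copy(),
            outcome=sub.outcome.copy(),
            specs=list(sub.specs[::-1]),
        )
        pd.testing.assert_frame_equal(predict(model, sub),
                                      predict(model, shuffled))


class TestNaiveBayesLimit:
    def test_unit_weights_equal_direct_count_naive_bayes(self, desk_cohort):
        """With w_i = 1 and the prior-odds intercept, the model's log-odds
        equal the naive Bayes log posterior odds obtained by recounting the
        binned training data directly."""
        cohort, _ = desk_cohort
        train = cohort.subset(range(400))
        schemes = fit_all(train)
        names = [s.name for s in train.specs]
        prior = train.outcome.mean()
        model = FittedRiskModel(
            selected=tuple(names), intercept=math.log(prior / (1 - prior)),
            weights={n: 1.0 for n in names}, schemes=schemes, l2_strength=1.0)
        out = predict(model, train)

        # independent oracle: recount bin memberships from raw data
        n_ev = train.outcome.sum()
        n_ne = len(train.outcome) - n_ev
        oracle = np.full(train.n, math.log(prior / (1 - prior)))
        for name in names:
            scheme = schemes[name]
            s, B = scheme.smoothing, len(scheme.bins)
            col = train.values[name]
            for i in range(train.n):
                val = col.iloc[i]
                if pd.isna(val):
                    b = scheme.missing_bin
                else:
                    regular = [x for x in scheme.bins if not x.is_missing]
                    if scheme.kind == "continuous":
                        v = float(val)
                        b = next(x for x in regular if x.lo <= v < x.hi)
                    else:
                        b = next((x for x in regular if str(val) in x.levels),
                                 None)
                oracle[i] += math.log(
                    ((b.n_event + s) / (n_ev + s * B)) /
                    ((b.n_nonevent + s) / (n_ne + s * B)))
        assert np.allclose(out["log_odds"], oracle, atol=1e-9)


@pytest.fixture(scope="module")
def bench_cohort():
    values = pd.DataFrame({
        "c1": [1.0, 2.0, np.nan, 4.0, 8.0, np.nan, 3.0, 2.0],
        "cat": ["a", "b", "c", "a", "b", "c", "a", "b"],
    })
    return CohortTable(
        [f"S{i}" for i in range(8)], values,
        np.array([0, 1, 0, 1, 1, 0, 1, 0]),
        [VariableSpec("c1", "continuous"),
         VariableSpec("cat", "categorical")])


class TestBenchmark:
    def test_standardized_columns(self, bench_cohort):
        bench = fit_baseline_benchmark(bench_cohort)
        D = bench.design(bench_cohort)
        assert abs(D["c1"].mean()) < 1e-9
        assert D["c1"].var(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_imputation_uses_observed_mean(self, bench_cohort):
        bench = fit_baseline_benchmark(bench_cohort)
        obs_mean = np.nanmean([1.0, 2.0, 4.0, 8.0, 3.0, 2.0])
        assert bench.means["c1"] == pytest.approx(obs_mean)
        D = bench.design(bench_cohort)
        # imputed rows sit exactly at the standardized mean (zero)
        assert D["c1"].iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_levels_and_unseen(self, bench_cohort):
        bench = fit_baseline_benchmark(bench_cohort)
        onehots = [c for c in bench.design(bench_cohort).columns
                   if c.startswith("cat=")]
        assert sorted(onehots) == ["cat=a", "cat=b", "cat=c"]
        unseen = CohortTable(
            ["T0"], pd.DataFrame({"c1": [1.0], "cat": ["zzz"]}),
            np.array([1]), bench_cohort.specs)
        D = bench.design(unseen)
        assert D[onehots].to_numpy().sum() == 0.0


def test_model_serialization_roundtrip(tmp_path, desk_cohort):
    cohort, _ = desk_cohort
    sub = cohort.subset(range(400))
    model = fit_pipeline(sub, grid=default_grid(
        woe_design(sub, fit_all(sub)).to_numpy(),
        sub.outcome.astype(float), n_points=15))
    save_model(model, tmp_path / "m.json")
    loaded = load_model(tmp_path / "m.json")
    assert loaded.selected == model.selected
    assert loaded.intercept == model.intercept
    assert loaded.weights == model.weights
    pd.testing.assert_frame_equal(predict(loaded, sub), predict(model, sub))
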