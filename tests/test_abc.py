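"""ABC engine: rejection acceptance, regression model probabilities,
cross-validation, goodness-of-fit and parameter estimation."""

import numpy as np
import pandas as pd
import pytest

from slopeflow.abc import (
    ABCModelChoice,
    ReferenceTable,
    abc_reject,
    build_reference_table,
    cross_validate,
    cross_validate_multi,
    estimate_parameters,
    goodness_of_fit,
    regression_model_probs,
)
from slopeflow.demography import PriorSpec


def _table(labels, stats, params=None):
    stats = np.asarray(stats, dtype=float)
    if params is None:
        params = np.zeros((len(labels), 1))
    return ReferenceTable(
        labels=np.asarray(labels),
        params=np.asarray(params, dtype=float),
        stats=stats,
        param_names=["m"] if np.shape(params)[1] == 1 else ["m", "Ne1"],
        stat_names=[f"s{i}" for i in range(stats.shape[1])],
    )


def _gaussian_table(rng, n=300, shift=0.0, spread=1.0, models=("a", "b")):
    labels, stats = [], []
    for k, m in enumerate(models):
        x = rng.normal(k * shift, spread, size=(n, 3))
        labels += [m] * n
        stats.append(x)
    return _table(np.array(labels), np.vstack(stats))


class TestReferenceTable:
    def test_zero_mad_stat_dropped_with_warning(self, rng):
        stats = np.column_stack([rng.normal(size=20), np.full(20, 7.0)])
        with pytest.warns(UserWarning, match="zero MAD"):
            t = _table(["a"] * 20, stats)
        assert t.standardized().shape[1] == 1

    def test_balanced_build_and_determinism(self):
        kw = dict(
            models=["dn", "ss"],
            n_per_model=10,
            prior=PriorSpec(),
            samples=np.array([4, 4, 4]),
            n_snps=30,
        )
        t1 = build_reference_table(rng=np.random.default_rng(9), **kw)
        t2 = build_reference_table(rng=np.random.default_rng(9), **kw)
        assert t1.n_rows == 20
        assert sorted(t1.labels.tolist()) == ["dn"] * 10 + ["ss"] * 10
        assert np.array_equal(t1.stats, t2.stats)
        assert np.array_equal(t1.params, t2.params)

    def test_csv_round_trip(self, tmp_path, rng):
        t = build_reference_table(
            ["ss"], 5, PriorSpec(), np.array([4, 4]), 20, rng
        )
        t.to_csv(tmp_path / "t.csv", sidecar_path=tmp_path / "t.json")
        back = ReferenceTable.from_csv(tmp_path / "t.csv")
        np.testing.assert_allclose(back.stats, t.stats)
        np.testing.assert_allclose(back.params, t.params)
        assert back.param_names == t.param_names

    def test_island_large_m_concentrates_near_zero_fst(self):
        rng = np.random.default_rng(4)
        from slopeflow.demography import (
            DemographicModel,
            simulate_counts_dataset,
            sumstats_from_counts,
        )

        samples = np.array([6, 6, 6])

        def med_fst(label, m):
            vals = []
            for _ in range(15):
                model = DemographicModel(label, Ne=np.full(3, 1000.0), m=m)
                c, h = simulate_counts_dataset(model, samples, 100, rng)
                vals.append(np.mean(sumstats_from_counts(c, h, samples)[-3:]))
            return np.median(vals)

        assert med_fst("am", 0.05) < med_fst("ss", 0.002)


class TestRejection:
    def test_tol_one_recovers_table_shares(self, rng):
        t = _gaussian_table(rng, n=100)
        _, post = abc_reject(t.stats[0], t, tol=1.0)
        assert post.probabilities == {"a": 0.5, "b": 0.5}

    def test_exact_row_acceptance_one(self, rng):
        t = _gaussian_table(rng, n=50, shift=5.0)
        _, post = abc_reject(t.stats[70], t, tol=1.0 / t.n_rows)
        assert post.probabilities["b"] == 1.0

    def test_hand_built_distances(self):
        stats = np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [10.0]])
        t = _table(["a", "a", "a", "b", "b", "b"], stats)
        idx, post = abc_reject(np.array([0.0]), t, tol=0.5)
        assert sorted(idx.tolist()) == [0, 1, 2]
        assert post.probabilities == {"a": 1.0, "b": 0.0}

    def test_probabilities_sum_to_one(self, rng):
        t = _gaussian_table(rng, n=80, shift=1.0, models=("a", "b", "c"))
        _, post = abc_reject(rng.normal(size=3), t, tol=0.05)
        assert sum(post.probabilities.values()) == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_monotone_rescaling_of_one_stat(self, rng):
        t = _gaussian_table(rng, n=100, shift=2.0)
        obs = rng.normal(size=3)
        idx1, _ = abc_reject(obs, t, tol=0.05)
        stats2 = t.stats.copy()
        stats2[:, 0] = stats2[:, 0] * 37.0 + 5.0
        t2 = _table(t.labels, stats2)
        obs2 = obs.copy()
        obs2[0] = obs2[0] * 37.0 + 5.0
        idx2, _ = abc_reject(obs2, t2, tol=0.05)
        assert sorted(idx1.tolist()) == sorted(idx2.tolist())

    def test_nonfinite_observation_rejected(self, rng):
        t = _gaussian_table(rng)
        with pytest.raises(ValueError):
            abc_reject(np.array([np.nan, 0, 0]), t, tol=0.1)


class TestRegressionProbs:
    def test_symmetric_models_near_half(self, rng):
        t = _gaussian_table(rng, n=400, shift=0.0)
        post = regression_model_probs(np.zeros(3), t, tol=0.25)
        assert post.probabilities["a"] == pytest.approx(0.5, abs=0.15)

    def test_separable_models_confident(self, rng):
        t = _gaussian_table(rng, n=200, shift=12.0, spread=0.5)
        post = regression_model_probs(np.full(3, 0.1), t, tol=0.5)
        assert post.probabilities["a"] > 0.95
        assert sum(post.probabilities.values()) == pytest.approx(1.0, abs=1e-9)

    def test_absent_model_flagged_zero(self, rng):
        t = _gaussian_table(rng, n=100, shift=50.0, models=("a", "b", "c"))
        post = regression_model_probs(np.zeros(3), t, tol=0.1)
        assert post.probabilities["c"] == 0.0
        assert "c" in post.untestable

    def test_invariant_to_duplicating_rows(self, rng):
        t = _gaussian_table(rng, n=60, shift=3.0)
        obs = np.array([0.5, -0.2, 0.1])
        p1 = regression_model_probs(obs, t, tol=0.2).probabilities
        t2 = _table(
            np.concatenate([t.labels, t.labels]),
            np.vstack([t.stats, t.stats]),
        )
        p2 = regression_model_probs(obs, t2, tol=0.2).probabilities
        assert p1["a"] == pytest.approx(p2["a"], abs=1e-6)


class TestCrossValidation:
    def test_identical_models_at_chance(self, rng):
        t = _gaussian_table(rng, n=250, shift=0.0)
        res = cross_validate(t, n_cv=60, tol=0.02, method="rejection", rng=rng)
        assert res.mean_correct == pytest.approx(0.5, abs=0.15)

    def test_separable_models_near_perfect(self, rng):
        t = _gaussian_table(rng, n=150, shift=10.0, spread=0.5)
        for method in ("rejection", "mnlogistic"):
            res = cross_validate(t, n_cv=30, tol=0.05, method=method, rng=rng)
            assert res.mean_correct >= 0.95

    def test_confusion_rows_sum_to_n_cv(self, rng):
        t = _gaussian_table(rng, n=100, shift=1.0, models=("a", "b", "c"))
        res = cross_validate(t, n_cv=25, tol=0.05, method="rejection", rng=rng)
        assert (res.confusion.sum(axis=1) == 25).all()

    def test_unknown_method_rejected(self, rng):
        t = _gaussian_table(rng)
        with pytest.raises(ValueError, match="unknown method"):
            cross_validate(t, n_cv=5, tol=0.1, method="forest", rng=rng)

    def test_multi_matches_single(self, rng):
        t = _gaussian_table(rng, n=120, shift=2.0)
        shared_rng = np.random.default_rng(77)
        multi = cross_validate_multi(t, 30, [("rejection", 0.05)], shared_rng)[0]
        single = cross_validate(
            t, n_cv=30, tol=0.05, method="rejection", rng=np.random.default_rng(77)
        )
        pd.testing.assert_frame_equal(multi.confusion, single.confusion)


class TestGoodnessOfFit:
    def test_far_observation_minimal_p(self, rng):
        t = _gaussian_table(rng, n=200, models=("a",))
        res = goodness_of_fit(np.full(3, 100.0), t, tol=0.05, n_rep=99, rng=rng)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_p_in_unit_interval(self, rng):
        t = _gaussian_table(rng, n=200, models=("a",))
        for _ in range(5):
            res = goodness_of_fit(rng.normal(size=3), t, tol=0.05, n_rep=49, rng=rng)
            assert 0.0 < res.p_value <= 1.0

    def test_requires_single_model(self, rng):
        t = _gaussian_table(rng)
        with pytest.raises(ValueError, match="single-model"):
            goodness_of_fit(np.zeros(3), t, tol=0.05, n_rep=10, rng=rng)

    def test_rejects_bad_n_rep(self, rng):
        t = _gaussian_table(rng, models=("a",))
        with pytest.raises(ValueError):
            goodness_of_fit(np.zeros(3), t, tol=0.05, n_rep=0, rng=rng)


class TestParameterEstimation:
    @staticmethod
    def _prior_table(rng, n=4000):
        prior = PriorSpec()
        m = rng.uniform(*prior.m_bounds, size=n)
        ne = np.exp(rng.uniform(np.log(200), np.log(10_000), size=n))
        stats = rng.normal(size=(n, 3))  # uninformative statistics
        return ReferenceTable(
            labels=np.repeat("ss", n),
            params=np.column_stack([m, ne]),
            stats=stats,
            param_names=["m", "Ne1"],
            stat_names=["s0", "s1", "s2"],
        )

    def test_tol_one_unadjusted_recovers_prior(self, rng):
        t = self._prior_table(rng)
        post = estimate_parameters(
            np.zeros(3), t, tol=1.0, adjust=False, rng=rng
        )
        assert post.median[1] == pytest.approx(np.sqrt(200 * 10_000), rel=0.1)
        assert post.median[0] == pytest.approx(0.0255, rel=0.1)

    def test_intervals_inside_prior_support(self, rng):
        t = self._prior_table(rng, n=2000)
        post = estimate_parameters(np.full(3, 2.0), t, tol=0.1, rng=rng)
        assert 0.001 <= post.lower[0] <= post.median[0] <= post.upper[0] <= 0.05
        assert 200 <= post.lower[1] <= post.median[1] <= post.upper[1] <= 10_000

    def test_degenerate_design_falls_back(self, rng):
        n = 50
        base = np.linspace(-1.0, 1.0, n)
        t = ReferenceTable(
            labels=np.repeat("ss", n),
            params=np.column_stack([np.linspace(0.001, 0.05, n)]),
            stats=np.column_stack([base, 2.0 * base]),  # collinear design
            param_names=["m"],
            stat_names=["s0", "s1"],
        )
        with pytest.warns(UserWarning, match="degenerate"):
            post = estimate_parameters(np.array([0.0, 0.0]), t, tol=1.0, rng=rng)
        assert not post.adjusted


class TestEstimatorInterface:
    def test_sklearn_fit_predict(self, rng):
        X = np.vstack([rng.normal(0, 1, (80, 3)), rng.normal(6, 1, (80, 3))])
        y = np.array(["a"] * 80 + ["b"] * 80)
        clf = ABCModelChoice(tol=0.1, method="rejection").fit(X, y)
        pred = clf.predict(np.array([[0, 0, 0], [6, 6, 6]]))
        assert pred.tolist() == ["a", "b"]
        proba = clf.predict_proba(np.array([[0, 0, 0]]))
        assert proba.shape == (1, 2)
        assert proba.sum() == pytest.approx(1.0)

    def test_get_params_round_trip(self):
        clf = ABCModelChoice(tol=0.01, method="mnlogistic")
        params = clf.get_params()
        assert params["tol"] == 0.01
        clf2 = ABCModelChoice(**params)
        assert clf2.method == "mnlogistic"
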