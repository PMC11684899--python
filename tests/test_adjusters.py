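import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from dosamo import (
    AdjusterSample,
    EvaluatedSolution,
    FeatureSet,
    SolutionSet,
    build_adjuster_samples,
    fit_adjuster,
    make_adjuster,
    predict_overestimation,
    train_adjuster,
    weighted_median,
)
from dosamo.adjusters import samples_from_frame, samples_to_frame


def brute_force_weighted_l1_minimizer(values, weights):
    """The optimum of sum w|v - c| lies on a sample value; enumerate them."""
    values = np.asarray(values)
    weights = np.asarray(weights)
    losses = [(np.sum(weights * np.abs(values - c)), c) for c in sorted(values)]
    best = min(l for l, _ in losses)
    return min(c for l, c in losses if l == pytest.approx(best, abs=1e-12))


def make_samples(fitness, sd, n_features, overest, weights=None):
    n = len(fitness)
    w = weights if weights is not None else np.full(n, 1.0 / n)
    return [
        AdjusterSample(
            original_fitness=float(fitness[i]),
            fitness_sd=float(sd[i]),
            n_features=int(n_features[i]),
            overestimation=float(overest[i]),
            weight=float(w[i]),
        )
        for i in range(n)
    ]


class TestWeightedMedian:
    def test_plain_median(self):
        assert weighted_median([0.1, 0.2, 0.3], [1, 1, 1]) == 0.2

    def test_weighted_example(self):
        assert weighted_median([0.1, 0.2, 0.3], [0.7, 0.2, 0.1]) == 0.1

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-1, 1, allow_nan=False),
                st.floats(0.01, 1, allow_nan=False),
            ),
            min_size=1,
            max_size=10,
        )
    )
    def test_weighted_l1_optimality_property(self, pairs):
        v = np.array([p[0] for p in pairs])
        w = np.array([p[1] for p in pairs])
        c = weighted_median(v, w)
        loss = np.sum(w * np.abs(v - c))
        for cand in v:
            assert loss <= np.sum(w * np.abs(v - cand)) + 1e-12

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 12))
            v = rng.uniform(-0.2, 0.5, size=n).round(3)
            w = rng.uniform(0, 1, size=n).round(3)
            if w.sum() == 0:
                w = np.ones(n)
            assert weighted_median(v, w) == pytest.approx(
                brute_force_weighted_l1_minimizer(v, w)
            )


class TestAdjusterKinds:
    def test_zero_predicts_zero(self):
        model = fit_adjuster("zero", [])
        assert predict_overestimation(model, 0.9, 0.05, 40) == 0.0

    def test_dummy_constant_prediction(self, rng):
        samples = make_samples(
            [0.5, 0.6, 0.7], [0.1, 0.1, 0.1], [3, 5, 7], [0.1, 0.2, 0.3]
        )
        model = fit_adjuster("dummy", samples)
        assert predict_overestimation(model, 0.99, 0.0, 1) == 0.2

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_adjuster("mystery")

    def test_non_zero_kinds_need_samples(self):
        with pytest.raises(ValueError):
            fit_adjuster("dummy", [])

    @pytest.mark.parametrize("kind", ["dummy", "ptree", "rfreg", "svr", "rsvr"])
    def test_fit_deterministic_given_seed(self, kind, rng):
        n = 40
        f = rng.uniform(0.3, 0.95, n)
        samples = make_samples(
            f, rng.uniform(0, 0.1, n), rng.integers(1, 60, n),
            0.3 * f + rng.normal(0, 0.02, n),
        )
        grid = np.column_stack(
            [np.linspace(0.3, 0.95, 9), np.full(9, 0.05), np.linspace(1, 60, 9)]
        )
        p1 = fit_adjuster(kind, samples, seed=11).predict(grid)
        p2 = fit_adjuster(kind, samples, seed=11).predict(grid)
        assert np.array_equal(p1, p2)

    @pytest.mark.parametrize("kind,tol", [("zero", 1e-6), ("dummy", 1e-6),
                                          ("ptree", 0.02), ("rfreg", 0.02)])
    def test_exact_estimation_yields_zero_predictions(self, kind, tol, rng):
        # parsimony-like objective: overestimation identically zero
        n = 60
        samples = make_samples(
            rng.uniform(0.1, 0.9, n), np.zeros(n), rng.integers(1, 80, n),
            np.zeros(n),
        )
        model = fit_adjuster(kind, samples, seed=0)
        grid = np.column_stack(
            [np.linspace(0.1, 0.9, 7), np.zeros(7), np.linspace(1, 80, 7)]
        )
        assert np.all(np.abs(model.predict(grid)) < tol)

    def test_ptree_monotone_in_n_features(self, rng):
        n = 200
        nf = rng.integers(1, 101, n)
        overest = 0.3 * np.sqrt(nf / 100.0)
        samples = make_samples(
            rng.uniform(0.4, 0.9, n), rng.uniform(0, 0.05, n), nf, overest
        )
        model = fit_adjuster("ptree", samples, seed=0)
        grid_nf = np.arange(5, 100, 10)
        preds = model.predict(
            np.column_stack(
                [np.full_like(grid_nf, 0.6, dtype=float),
                 np.full_like(grid_nf, 0.02, dtype=float),
                 grid_nf]
            )
        )
        truth = 0.3 * np.sqrt(grid_nf / 100.0)
        assert np.all(np.abs(preds - truth) < 0.1)

    @pytest.mark.parametrize("kind", ["ptree", "rfreg"])
    def test_parameter_recovery_spearman(self, kind, rng):
        # overestimation is a known monotone function of panel size + noise
        n = 300
        nf = rng.integers(1, 101, n)
        overest = 0.25 * np.sqrt(nf / 100.0) + rng.normal(0, 0.02, n)
        samples = make_samples(
            rng.uniform(0.4, 0.9, n), rng.uniform(0, 0.05, n), nf, overest
        )
        model = fit_adjuster(kind, samples, seed=3)
        grid_nf = np.arange(2, 100, 3)
        preds = model.predict(
            np.column_stack(
                [np.full(grid_nf.shape, 0.65), np.full(grid_nf.shape, 0.02), grid_nf]
            )
        )
        rho = spearmanr(preds, 0.25 * np.sqrt(grid_nf / 100.0)).statistic
        assert rho > 0.9

    def test_rfreg_beats_dummy_on_structured_overestimation(self, rng):
        n = 200
        f = rng.uniform(0.3, 0.95, n)
        overest = 0.4 * f + rng.normal(0, 0.01, n)
        samples = make_samples(f, rng.uniform(0, 0.05, n),
                               rng.integers(1, 40, n), overest)
        train, test = samples[:150], samples[150:]
        X_test = np.array([[s.original_fitness, s.fitness_sd, s.n_features]
                           for s in test])
        y_test = np.array([s.overestimation for s in test])
        w_test = np.array([s.weight for s in test])
        errs = {}
        for kind in ("dummy", "rfreg"):
            model = fit_adjuster(kind, train, seed=0)
            errs[kind] = np.sum(w_test * np.abs(model.predict(X_test) - y_test))
        assert errs["rfreg"] < errs["dummy"]


class TestSampleConstruction:
    def _hof(self, train, test, sizes, m=2):
        sols = [
            EvaluatedSolution(
                FeatureSet(tuple(range(sizes[i])), 100),
                np.asarray(train[i], dtype=float),
                np.full(m, 0.05),
                np.asarray(test[i], dtype=float),
            )
            for i in range(len(train))
        ]
        return SolutionSet(sols)

    def test_single_fold_single_solution(self):
        hof = self._hof([[0.9, 0.5]], [[0.7, 0.5]], [3])
        samples = build_adjuster_samples([hof], None, 0)
        assert len(samples) == 1
        s = samples[0]
        assert (s.original_fitness, s.overestimation, s.weight) == (0.9, pytest.approx(0.2), 1.0)
        assert s.n_features == 3

    def test_per_fold_weights_sum_to_one(self):
        hof1 = self._hof([[0.9, 0.2], [0.4, 0.8]], [[0.8, 0.2], [0.3, 0.8]], [3, 9])
        hof2 = self._hof([[0.6, 0.6]], [[0.5, 0.6]], [5])
        samples = build_adjuster_samples([hof1, hof2], None, 0)
        total_by_fold = {}
        for s in samples:
            total_by_fold[s.fold] = total_by_fold.get(s.fold, 0.0) + s.weight
        assert total_by_fold[0] == pytest.approx(1.0, abs=1e-12)
        assert total_by_fold[1] == pytest.approx(1.0, abs=1e-12)
        assert sum(total_by_fold.values()) == pytest.approx(2.0, abs=1e-12)

    def test_train_equals_test_gives_zero_overestimation(self):
        F = [[0.7, 0.3], [0.2, 0.9]]
        hof = self._hof(F, F, [2, 4])
        samples = build_adjuster_samples([hof], None, 1)
        assert all(s.overestimation == 0.0 for s in samples)
        model = train_adjuster("dummy", 1, [hof])
        assert predict_overestimation(model, 0.5, 0.1, 10) == 0.0

    def test_missing_test_fitness_rejected(self):
        sol = EvaluatedSolution(
            FeatureSet((0,), 10), np.array([0.5, 0.5]), np.array([0.0, 0.0])
        )
        with pytest.raises(ValueError):
            build_adjuster_samples([SolutionSet([sol])], None, 0)

    def test_csv_round_trip(self, rng):
        samples = make_samples(
            rng.uniform(0, 1, 5), rng.uniform(0, 0.1, 5),
            rng.integers(1, 50, 5), rng.normal(0.1, 0.05, 5),
        )
        frame = samples_to_frame(samples)
        back = samples_from_frame(frame)
        assert [
            (s.original_fitness, s.fitness_sd, s.n_features, s.overestimation, s.weight)
            for s in samples
        ] == [
            (s.original_fitness, s.fitness_sd, s.n_features, s.overestimation, s.weight)
            for s in back
        ]
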