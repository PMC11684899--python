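import numpy as np
import pytest
from sklearn.base import clone

from dosamo import (
    ClassificationObjective,
    Dataset,
    DosaConfig,
    DosaMOSelector,
    FeatureSet,
    FitnessEvaluation,
    GAFeatureSelector,
    ObjectiveSpec,
    OptimizerConfig,
    ParsimonyObjective,
    dosa_optimize,
    evaluate_on_holdout,
    ga_optimize,
    nondominated_front,
)
from dosamo.optimizer import get_optimizer


class StubObjective(ObjectiveSpec):
    """Deterministic fitness with a known constant holdout shortfall."""

    kind = "model_metric"

    def __init__(self, name="stub", overestimation=0.0):
        self.name = name
        self.overestimation = overestimation

    def _fitness(self, feature_set):
        # deterministic mid-range function of the mask, away from clip edges
        h = sum(feature_set.indices) % 31
        return 0.3 + 0.4 * (h / 30.0)

    def evaluate(self, feature_set, data, seed):
        return FitnessEvaluation(
            fitness=self._fitness(feature_set), sd=0.01,
            n_features=feature_set.size,
        )

    def evaluate_holdout(self, feature_set, train, holdout):
        return self._fitness(feature_set) - self.overestimation


def same_solution_set(a, b):
    if len(a) != len(b):
        return False
    return all(
        sa.feature_set.indices == sb.feature_set.indices
        and np.array_equal(sa.original_fitness, sb.original_fitness)
        and np.array_equal(sa.fitness_sd, sb.fitness_sd)
        for sa, sb in zip(a.solutions, b.solutions)
    )


@pytest.fixture
def stub_data():
    return Dataset(X=np.zeros((12, 30)), y=np.array([0, 1] * 6))


class TestConfigs:
    def test_population_constraints(self):
        with pytest.raises(ValueError):
            OptimizerConfig(population_size=5)
        with pytest.raises(ValueError):
            OptimizerConfig(generations=0)

    def test_tuning_defaults_to_half_budget(self):
        cfg = DosaConfig(main=OptimizerConfig(population_size=20, generations=10))
        assert cfg.tuning.population_size == 10
        assert cfg.tuning.generations == 5

    def test_k_outer_minimum(self):
        with pytest.raises(ValueError):
            DosaConfig(k_outer=1)

    def test_registry(self):
        assert get_optimizer("nsga2") is ga_optimize
        with pytest.raises(ValueError):
            get_optimizer("simplex")


class TestReferenceGA:
    def test_deterministic_given_seed(self, stub_data):
        cfg = OptimizerConfig(population_size=8, generations=3, seed=5)
        objs = [StubObjective("a"), ParsimonyObjective(cap=30)]
        assert same_solution_set(
            ga_optimize(cfg, objs, stub_data), ga_optimize(cfg, objs, stub_data)
        )

    def test_front_is_nondominated_and_idempotent(self, stub_data):
        cfg = OptimizerConfig(population_size=8, generations=4, seed=2)
        ss = ga_optimize(cfg, [StubObjective("a"), ParsimonyObjective(cap=30)], stub_data)
        F = ss.fitness_matrix()
        assert nondominated_front(F) == set(range(len(ss)))
        assert len(ss) >= 1
        assert all(s.feature_set.size > 0 for s in ss.solutions)

    def test_single_objective_contract(self, stub_data):
        cfg = OptimizerConfig(population_size=6, generations=2, seed=0)
        ss = ga_optimize(cfg, [StubObjective("a")], stub_data)
        assert len(ss) >= 1

    def test_evaluation_budget(self, stub_data):
        cfg = OptimizerConfig(population_size=4, generations=1, seed=0)
        ss = ga_optimize(cfg, [StubObjective("a")], stub_data)
        assert ss.stats["n_evaluations"] <= 4 * (1 + 1)

    def test_budget_bound_holds_generally(self, stub_data):
        cfg = OptimizerConfig(population_size=10, generations=6, seed=1)
        ss = ga_optimize(cfg, [StubObjective("a"), ParsimonyObjective(cap=30)], stub_data)
        assert ss.stats["n_evaluations"] <= 10 * (6 + 1)

    def test_finds_separable_single_feature_solution(self, small_classification):
        data, informative = small_classification
        spec_easy = Dataset(X=data.X.copy(), y=data.y)
        spec_easy.X[:, informative[0]] = data.y * 10.0
        objs = [
            ClassificationObjective("nb", n_bootstrap=30),
            ParsimonyObjective(cap=100),
        ]
        cfg = OptimizerConfig(
            population_size=16, generations=8, init_max_features=5, seed=4
        )
        ss = ga_optimize(cfg, objs, spec_easy)
        F = ss.fitness_matrix()
        sizes = np.array([s.feature_set.size for s in ss.solutions])
        assert np.any((F[:, 0] == 1.0) & (sizes == 1))

    def test_objective_failure_aborts_with_name(self, stub_data, caplog):
        class Exploding(StubObjective):
            def evaluate(self, feature_set, data, seed):
                raise RuntimeError("boom")

        cfg = OptimizerConfig(population_size=4, generations=1, seed=0)
        with caplog.at_level("ERROR", logger="dosamo"):
            with pytest.raises(RuntimeError):
                ga_optimize(cfg, [Exploding("frail")], stub_data)
        assert "frail" in caplog.text


class TestDualStage:
    def test_zero_adjuster_equals_bare_ga(self, stub_data):
        objs = [StubObjective("a", overestimation=0.1), ParsimonyObjective(cap=30)]
        main = OptimizerConfig(population_size=8, generations=3, seed=7)
        bare = ga_optimize(main, objs, stub_data)
        adjusted = dosa_optimize(
            DosaConfig(k_outer=2, main=main, adjuster_kinds="zero"), objs, stub_data
        )
        assert same_solution_set(bare, adjusted)

    def test_constant_overestimation_traced_through_pipeline(self, stub_data):
        shortfall = 0.1
        objs = [StubObjective("a", overestimation=shortfall), ParsimonyObjective(cap=30)]
        main = OptimizerConfig(population_size=8, generations=3, seed=7)
        cfg = DosaConfig(k_outer=2, main=main, adjuster_kinds=["dummy", "dummy"])
        result = dosa_optimize(cfg, objs, stub_data)
        for sol in result.solutions:
            raw = objs[0].evaluate(sol.feature_set, stub_data, 0).fitness
            assert sol.original_fitness[0] == pytest.approx(raw - shortfall, abs=1e-9)

    def test_parsimony_objective_unchanged_by_adjustment(self, stub_data):
        objs = [StubObjective("a", overestimation=0.1), ParsimonyObjective(cap=30)]
        main = OptimizerConfig(population_size=8, generations=2, seed=3)
        cfg = DosaConfig(k_outer=2, main=main, adjuster_kinds=["dummy", "dummy"])
        result = dosa_optimize(cfg, objs, stub_data)
        for sol in result.solutions:
            expected = ParsimonyObjective(cap=30).evaluate(sol.feature_set, stub_data, 0)
            assert sol.original_fitness[1] == pytest.approx(expected.fitness, abs=1e-6)

    def test_tuning_budget_accounting(self, stub_data):
        objs = [StubObjective("a"), ParsimonyObjective(cap=30)]
        main = OptimizerConfig(population_size=8, generations=2, seed=1)
        cfg = DosaConfig(k_outer=2, main=main, adjuster_kinds="zero")
        result = dosa_optimize(cfg, objs, stub_data)
        tuning = cfg.tuning
        assert result.stats["n_evaluations"] <= 8 * 3
        assert (
            result.stats["n_evaluations_tuning"]
            <= cfg.k_outer * tuning.population_size * (tuning.generations + 1)
        )


class TestEvaluateOnHoldout:
    def test_holdout_matrix_contract(self, small_classification, two_objectives):
        data, _ = small_classification
        cfg = OptimizerConfig(population_size=8, generations=2, seed=0)
        ss = ga_optimize(cfg, two_objectives, data)
        X = ss.fitness_matrix()
        Xp = evaluate_on_holdout(ss, data, data, two_objectives)
        assert Xp.shape == X.shape
        assert np.all((Xp >= 0) & (Xp <= 1))
        # parsimony column is identical between train and holdout
        assert np.array_equal(Xp[:, 1], X[:, 1])


class TestEstimatorFacades:
    def test_get_params_clone_and_fit(self, small_classification, two_objectives):
        data, _ = small_classification
        est = GAFeatureSelector(
            objectives=two_objectives, population_size=6, generations=2,
            random_state=0,
        )
        est2 = clone(est)
        assert est2.get_params()["population_size"] == 6
        est2.fit(data.X, data.y)
        assert est2.n_features_in_ == data.n_features
        assert len(est2.solution_set_) >= 1
        support = est2.get_support(0)
        assert est2.transform(data.X, 0).shape[1] == support.sum()

    def test_dosa_selector_fitted_attributes(self, small_classification, two_objectives):
        data, _ = small_classification
        est = DosaMOSelector(
            objectives=two_objectives, adjuster_kind="dummy", k_outer=2,
            population_size=6, generations=2, random_state=1,
        )
        est.fit(data.X, data.y)
        assert len(est.adjusters_) == 2
        assert len(est.fold_hofs_) >= 1
        assert len(est.adjuster_samples_) > 0
        assert est.solution_set_.fitness_matrix().shape[1] == 2

    def test_missing_objectives_rejected(self, small_classification):
        data, _ = small_classification
        with pytest.raises(ValueError):
            GAFeatureSelector().fit(data.X, data.y)
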