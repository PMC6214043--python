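import numpy as np
import pytest

from tdgrn import (
    BatConfig,
    CVFNTRegressor,
    OptimizerConfig,
    bat_optimize,
    evolve_structure,
    fit_target_model,
    flatten_params,
    init_population,
    rmse,
    tree_to_json,
    unflatten_params,
)
from tdgrn.cvfnt import CVFNTNode, CVFNTree
from tdgrn.design import DelayedDesign


def single_neuron_tree(weights, threshold=0j, a=1.0, r=1.0, n_inputs=2):
    kids = [
        CVFNTNode(kind="terminal", input_index=i % n_inputs)
        for i in range(len(weights))
    ]
    root = CVFNTNode(
        kind="function", weights=np.array(weights, complex),
        threshold=threshold, act_a=a, act_r=r, children=kids,
    )
    return CVFNTree(root=root, n_inputs=n_inputs)


def linear_design(rng, m=30):
    """target = 0.5*reg1 + 0.5*reg2 exactly."""
    X = rng.uniform(0, 1, (2, m))
    y = 0.5 * X[0] + 0.5 * X[1]
    return DelayedDesign(
        target_index=2, regulator_indices=(0, 1), lags=(0, 0), inputs=X, target=y
    )


class TestRMSE:
    def test_identical_vectors(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_offset(self):
        assert rmse([0.0, 0.0], [1.0, 1.0]) == 1.0

    def test_closed_form(self):
        assert rmse([0.0, 0.0, 0.0], [3.0, 0.0, 0.0]) == pytest.approx(np.sqrt(3))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse([1.0], [1.0, 2.0])


class TestFlattenUnflatten:
    def test_roundtrip_identity_on_vector(self, rng):
        tree = single_neuron_tree([1 + 2j, -0.5 + 0.1j], threshold=0.3 - 0.2j)
        v = flatten_params(tree)
        v2 = flatten_params(unflatten_params(tree, v))
        np.testing.assert_allclose(v2, v)

    def test_single_plus2_node_length_eight(self):
        tree = single_neuron_tree([1 + 0j, 1 + 0j])
        assert flatten_params(tree).size == 8

    def test_wrong_length_rejected(self):
        tree = single_neuron_tree([1 + 0j, 1 + 0j])
        with pytest.raises(ValueError):
            unflatten_params(tree, np.zeros(5))

    def test_activation_params_clamped(self):
        tree = single_neuron_tree([1 + 0j])
        v = flatten_params(tree)
        v[-2:] = -1.0
        out = unflatten_params(tree, v)
        assert out.root.act_a >= 1e-3 and out.root.act_r >= 1e-3


class TestInitPopulation:
    def test_size_and_validity(self, small_optimizer, rng):
        pop = init_population(small_optimizer, 3, rng)
        assert len(pop) == small_optimizer.pop_size
        for tree in pop:
            tree.validate()
            assert tree.terminal_indices() <= {0, 1, 2}

    def test_deterministic_given_seed(self, small_optimizer):
        p1 = init_population(small_optimizer, 2, np.random.default_rng(7))
        p2 = init_population(small_optimizer, 2, np.random.default_rng(7))
        assert [tree_to_json(t) for t in p1] == [tree_to_json(t) for t in p2]

    def test_each_input_seeded_as_single_input_model(self, small_optimizer, rng):
        pop = init_population(small_optimizer, 4, rng)
        singles = [t.terminal_indices() for t in pop[:4]]
        assert singles == [{0}, {1}, {2}, {3}]


class TestEvolveStructure:
    def test_operators_off_gives_copies_of_parents(self, rng):
        cfg = OptimizerConfig(pop_size=8, crossover_prob=0.0, mutation_prob=0.0)
        pop = init_population(cfg, 2, rng)
        fits = rng.uniform(0, 1, 8)
        nxt = evolve_structure(pop, fits, cfg, rng)
        parent_serials = {tree_to_json(t) for t in pop}
        assert all(tree_to_json(t) in parent_serials for t in nxt)

    def test_elite_preserved(self, rng):
        cfg = OptimizerConfig(pop_size=8)
        pop = init_population(cfg, 2, rng)
        fits = rng.uniform(0, 1, 8)
        nxt = evolve_structure(pop, fits, cfg, rng)
        assert tree_to_json(nxt[0]) == tree_to_json(pop[int(np.argmin(fits))])

    def test_offspring_satisfy_invariants_over_many_generations(self):
        rng = np.random.default_rng(11)
        cfg = OptimizerConfig(pop_size=10, max_depth=4)
        pop = init_population(cfg, 3, rng)
        for _ in range(100):
            fits = rng.uniform(0, 1, len(pop))
            pop = evolve_structure(pop, fits, cfg, rng)
            for tree in pop:
                tree.validate()
                assert tree.depth() <= 4


class TestBatOptimize:
    def test_zero_iterations_is_noop(self, rng):
        tree = single_neuron_tree([1 + 0j, 1 + 0j])
        d = linear_design(rng)
        cfg = BatConfig(n_bats=5, n_iters=0)
        out = bat_optimize(tree, d, "real", cfg, rng)
        np.testing.assert_array_equal(flatten_params(out), flatten_params(tree))

    def test_never_worse_than_input(self, rng):
        d = linear_design(rng)
        cfg = BatConfig(n_bats=6, n_iters=10)
        from tdgrn.optimize import _tree_rmse
        from tdgrn.cvfnt import encode_inputs

        Z = encode_inputs(d, "real")
        for seed in range(10):
            r = np.random.default_rng(seed)
            tree = single_neuron_tree(
                [complex(r.uniform(-1, 1), r.uniform(-1, 1)) for _ in range(2)],
                a=1.0, r=50.0,
            )
            before = _tree_rmse(tree, Z, d.target)
            after = _tree_rmse(bat_optimize(tree, d, "real", cfg, r), Z, d.target)
            assert after <= before + 1e-12

    def test_improves_recoverable_linear_target(self):
        """Refinement finds better parameters on an exactly representable target."""
        cfg = BatConfig(n_bats=10, n_iters=25)
        from tdgrn.optimize import _tree_rmse
        from tdgrn.cvfnt import encode_inputs

        improved = 0
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            d = linear_design(r)
            Z = encode_inputs(d, "real")
            tree = single_neuron_tree(
                [complex(r.uniform(-1, 1), r.uniform(-1, 1)) for _ in range(2)],
                a=1.0, r=100.0,
            )
            before = _tree_rmse(tree, Z, d.target)
            after = _tree_rmse(
                bat_optimize(tree, d, "real", cfg, r), Z, d.target
            )
            improved += after < before
        assert improved >= 18


class TestFitTargetModel:
    def test_identity_target_recovered(self, small_optimizer):
        """target == regulator 0: near-zero RMSE reached in most seeds."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.uniform(0, 1, (2, 30))
            d = DelayedDesign(
                target_index=2, regulator_indices=(0, 1), lags=(0, 0),
                inputs=X, target=X[0],
            )
            tree, trace = fit_target_model(d, "real", small_optimizer, r)
            hits += trace[-1].rmse <= 0.05
        assert hits >= 18

    def test_same_seed_identical_tree_and_trace(self, small_optimizer, rng):
        d = linear_design(rng)
        t1, tr1 = fit_target_model(d, "real", small_optimizer, np.random.default_rng(3))
        t2, tr2 = fit_target_model(d, "real", small_optimizer, np.random.default_rng(3))
        assert tree_to_json(t1) == tree_to_json(t2)
        assert tr1 == tr2

    def test_trace_monotone_without_parsimony(self, rng):
        cfg = OptimizerConfig(
            pop_size=12, max_generations=10, parsimony=0.0,
            bat=BatConfig(n_bats=4, n_iters=5), target_rmse=0.0,
        )
        d = linear_design(rng)
        _, trace = fit_target_model(d, "real", cfg, rng)
        vals = [rec.rmse for rec in trace]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_generative_single_neuron_recovered(self, small_optimizer):
        """Data from a known single-neuron model is fitted to low RMSE."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(200 + seed)
            X = r.uniform(0, 1, (2, 40))
            truth = single_neuron_tree(
                [0.8 + 0.1j, 0j], threshold=0.1 + 0j, a=0.6, r=1.2
            )
            from tdgrn.cvfnt import evaluate_series

            y = evaluate_series(truth, X.T.astype(complex)).real
            d = DelayedDesign(
                target_index=2, regulator_indices=(0, 1), lags=(0, 0),
                inputs=X, target=y,
            )
            _, trace = fit_target_model(d, "real", small_optimizer, r)
            hits += trace[-1].rmse < 0.02
        assert hits > 10


class TestCVFNTRegressor:
    def test_sklearn_contract(self, rng):
        from sklearn.base import clone

        est = CVFNTRegressor(
            pop_size=10, max_generations=5, n_bats=4, bat_iters=5,
            target_rmse=0.02, random_state=0,
        )
        est2 = clone(est)
        X = rng.uniform(0, 1, (25, 2))
        y = X[:, 0]
        est2.fit(X, y)
        assert hasattr(est2, "tree_") and est2.rmse_ >= 0
        pred = est2.predict(X)
        assert pred.shape == (25,)
        assert est2.used_features_ and set(est2.used_features_) <= {0, 1}

    def test_reproducible_fit(self, rng):
        X = rng.uniform(0, 1, (25, 2))
        y = 0.5 * X[:, 0] + 0.5 * X[:, 1]
        kw = dict(pop_size=10, max_generations=5, n_bats=4, bat_iters=5,
                  random_state=42)
        a = CVFNTRegressor(**kw).fit(X, y)
        b = CVFNTRegressor(**kw).fit(X, y)
        assert tree_to_json(a.tree_) == tree_to_json(b.tree_)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
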