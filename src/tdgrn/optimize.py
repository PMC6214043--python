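"""Fit a complex-valued flexible neural tree by evolutionary search.

Structure is searched by tournament genetic programming (subtree-exchange
crossover, three mutation moves, elitism); the continuous parameters of the
better individuals are refined periodically by a bat algorithm operating on
a flattened real vector of the tree's complex weights, thresholds and
activation parameters.  Fitness is the RMSE between the real-projected tree
output and the target series; selection additionally applies a light
parsimony penalty per distinct input used, so inputs that do not pay for
themselves in RMSE are selected away (the reported RMSE stays the raw
error).  The best-so-far selection fitness is monotone non-increasing across
generations; with the penalty disabled this is the best-so-far RMSE itself.

The :class:`CVFNTRegressor` estimator exposes the whole procedure with a
scikit-learn ``fit``/``predict`` surface; the module-level functions are the
thin building blocks it delegates to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .cvfnt import CVFNTNode, CVFNTree, encode_inputs, evaluate_series, random_tree
from .design import DelayedDesign
from .io import BatConfig, OptimizerConfig

__all__ = [
    "FitnessRecord",
    "rmse",
    "init_population",
    "evolve_structure",
    "flatten_params",
    "unflatten_params",
    "bat_optimize",
    "fit_target_model",
    "CVFNTRegressor",
]

PARAM_FLOOR = 1e-3  # lower clamp for activation parameters on unflatten
VELOCITY_CLAMP = 1.0


@dataclass(frozen=True)
class FitnessRecord:
    """Best-so-far fitness snapshot after one generation."""

    rmse: float
    generation: int
    evaluations: int


def rmse(actual, predicted) -> float:
    """Root mean squared error between two equal-length real vectors."""
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {actual.shape[0]} actual vs "
            f"{predicted.shape[0]} predicted"
        )
    if actual.size < 1:
        raise ValueError("need at least one data point")
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def _seed_neuron(
    inputs: tuple[int, ...], rng: np.random.Generator, max_depth: int, n_inputs: int
) -> CVFNTree:
    arity = len(inputs)
    root = CVFNTNode(
        kind="function",
        weights=rng.uniform(-1, 1, arity) + 1j * rng.uniform(-1, 1, arity),
        threshold=complex(rng.uniform(-1, 1), rng.uniform(-1, 1)),
        act_a=float(rng.uniform(0.1, 2.0)),
        act_r=float(rng.uniform(0.1, 2.0)),
        children=[CVFNTNode(kind="terminal", input_index=i) for i in inputs],
    )
    return CVFNTree(root=root, n_inputs=n_inputs, max_depth=max_depth)


def init_population(
    config: OptimizerConfig, n_inputs: int, rng: np.random.Generator
) -> list[CVFNTree]:
    """Initial population: canonical seeds plus grow-method random trees.

    The seeds are one single-input neuron ``+2(z_i, z_i)`` per input and one
    pairwise neuron ``+2(z_i, z_j)`` per input pair (as far as the population
    size allows), so every small terminal subset competes from the start;
    the remainder is random grow trees.
    """
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    pop: list[CVFNTree] = []
    seeds: list[tuple[int, ...]] = [(i, i) for i in range(n_inputs)]
    seeds += [
        (i, j) for i in range(n_inputs) for j in range(i + 1, n_inputs)
    ]
    for inputs in seeds[: config.pop_size]:
        pop.append(_seed_neuron(inputs, rng, config.max_depth, n_inputs))
    while len(pop) < config.pop_size:
        pop.append(
            random_tree(
                n_inputs,
                rng,
                max_depth=config.max_depth,
                function_arities=tuple(config.function_arities),
            )
        )
    return pop


def _tournament(
    population: list[CVFNTree],
    fitnesses: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> CVFNTree:
    idx = rng.integers(len(population), size=k)
    winner = idx[np.argmin(fitnesses[idx])]
    return population[int(winner)]


def _random_node_path(root: CVFNTNode, rng: np.random.Generator) -> list[int]:
    """Child-index path to a uniformly chosen node (empty path = root)."""
    nodes: list[list[int]] = []

    def walk(node: CVFNTNode, path: list[int]) -> None:
        nodes.append(path)
        for i, c in enumerate(node.children):
            walk(c, path + [i])

    walk(root, [])
    return nodes[int(rng.integers(len(nodes)))]


def _get_at(root: CVFNTNode, path: list[int]) -> CVFNTNode:
    node = root
    for i in path:
        node = node.children[i]
    return node


def _set_at(root: CVFNTNode, path: list[int], new: CVFNTNode) -> CVFNTNode:
    if not path:
        return new
    parent = _get_at(root, path[:-1])
    parent.children[path[-1]] = new
    return root


def _prune_to_depth(
    node: CVFNTNode, budget: int, n_inputs: int, rng: np.random.Generator
) -> CVFNTNode:
    """Replace subtrees that overflow the depth budget with random leaves."""
    if budget <= 1 and node.kind == "function":
        return CVFNTNode(kind="terminal", input_index=int(rng.integers(n_inputs)))
    if node.kind == "function":
        node.children = [
            _prune_to_depth(c, budget - 1, n_inputs, rng) for c in node.children
        ]
    return node


def _crossover(
    a: CVFNTree, b: CVFNTree, rng: np.random.Generator
) -> tuple[CVFNTree, CVFNTree]:
    ca, cb = a.copy(), b.copy()
    pa = _random_node_path(ca.root, rng)
    pb = _random_node_path(cb.root, rng)
    sub_a = _get_at(ca.root, pa).copy()
    sub_b = _get_at(cb.root, pb).copy()
    ca.root = _set_at(ca.root, pa, sub_b)
    cb.root = _set_at(cb.root, pb, sub_a)
    for child in (ca, cb):
        child.root = _prune_to_depth(
            child.root, child.max_depth, child.n_inputs, rng
        )
        child.validate()
    return ca, cb


def _mutate(
    tree: CVFNTree,
    rng: np.random.Generator,
    function_arities: tuple[int, ...],
) -> CVFNTree:
    out = tree.copy()
    move = int(rng.integers(3))
    if move == 0:
        # replace a random subtree by a fresh random subtree
        path = _random_node_path(out.root, rng)
        budget = out.max_depth - len(path)
        repl = random_tree(
            out.n_inputs, rng, max_depth=max(budget, 1),
            function_arities=function_arities,
        ).root
        out.root = _set_at(out.root, path, repl)
    elif move == 1:
        # retarget one terminal's input index
        terminals = [
            n for n in out.root.iter_nodes() if n.kind == "terminal"
        ]
        node = terminals[int(rng.integers(len(terminals)))]
        node.input_index = int(rng.integers(out.n_inputs))
    else:
        # redraw one node's parameters
        funcs = [n for n in out.root.iter_nodes() if n.kind == "function"]
        if funcs:
            node = funcs[int(rng.integers(len(funcs)))]
            arity = node.arity
            node.weights = rng.uniform(-1, 1, arity) + 1j * rng.uniform(-1, 1, arity)
            node.threshold = complex(rng.uniform(-1, 1), rng.uniform(-1, 1))
            node.act_a = float(rng.uniform(0.1, 2.0))
            node.act_r = float(rng.uniform(0.1, 2.0))
    out.root = _prune_to_depth(out.root, out.max_depth, out.n_inputs, rng)
    out.validate()
    return out


def evolve_structure(
    population: list[CVFNTree],
    fitnesses,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> list[CVFNTree]:
    """One generation of tournament GP with elitism.

    The best individual is copied unchanged; the rest of the next generation
    comes from tournament selection followed by subtree-exchange crossover
    (probability ``crossover_prob``) and mutation (probability
    ``mutation_prob``).  Offspring overflowing the depth bound are pruned at
    the bound.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    if len(population) != len(fitnesses):
        raise ValueError("population and fitnesses must have equal length")
    elite = population[int(np.argmin(fitnesses))].copy()
    nxt: list[CVFNTree] = [elite]
    arities = tuple(config.function_arities)
    while len(nxt) < config.pop_size:
        p1 = _tournament(population, fitnesses, config.tournament_size, rng)
        p2 = _tournament(population, fitnesses, config.tournament_size, rng)
        if rng.random() < config.crossover_prob:
            c1, c2 = _crossover(p1, p2, rng)
        else:
            c1, c2 = p1.copy(), p2.copy()
        for child in (c1, c2):
            if rng.random() < config.mutation_prob:
                child = _mutate(child, rng, arities)
            if len(nxt) < config.pop_size:
                nxt.append(child)
    return nxt


def _function_nodes(tree: CVFNTree) -> list[CVFNTNode]:
    return [n for n in tree.root.iter_nodes() if n.kind == "function"]


def flatten_params(tree: CVFNTree) -> np.ndarray:
    """Pack all continuous parameters into one real vector.

    Prefix-order over function nodes; per node the layout is
    (Re w_1, Im w_1, ..., Re w_n, Im w_n, Re w0, Im w0, a, r).
    """
    parts: list[float] = []
    for node in _function_nodes(tree):
        for w in node.weights:
            parts.extend((w.real, w.imag))
        parts.extend((node.threshold.real, node.threshold.imag))
        parts.extend((node.act_a, node.act_r))
    return np.asarray(parts, dtype=float)


def unflatten_params(tree: CVFNTree, vector) -> CVFNTree:
    """Exact inverse of :func:`flatten_params` (a, r clamped to >= 1e-3)."""
    vector = np.asarray(vector, dtype=float).ravel()
    out = tree.copy()
    pos = 0
    for node in _function_nodes(out):
        need = 2 * node.arity + 4
        if pos + need > len(vector):
            raise ValueError("parameter vector too short for this tree")
        block = vector[pos : pos + need]
        pos += need
        w = block[: 2 * node.arity]
        node.weights = w[0::2] + 1j * w[1::2]
        node.threshold = complex(block[-4], block[-3])
        node.act_a = float(max(block[-2], PARAM_FLOOR))
        node.act_r = float(max(block[-1], PARAM_FLOOR))
    if pos != len(vector):
        raise ValueError(
            f"parameter vector length {len(vector)} does not match tree ({pos})"
        )
    return out


def _tree_rmse(tree: CVFNTree, Z: np.ndarray, y: np.ndarray) -> float:
    return rmse(y, evaluate_series(tree, Z).real)


def bat_optimize(
    tree: CVFNTree,
    design: DelayedDesign,
    scheme: str,
    bat_config: BatConfig,
    rng: np.random.Generator,
) -> CVFNTree:
    """Refine a tree's continuous parameters with a bat algorithm.

    Standard frequency-tuned swarm: each bat carries a position (a flattened
    parameter vector), a velocity pulled toward the global best with a random
    frequency in ``[f_min, f_max]``, a loudness that decays geometrically on
    acceptance and a pulse rate that gates a local random walk around the
    best.  Bat 0 starts at the input tree's parameters, so the returned tree
    is never worse than the input.
    """
    Z = encode_inputs(design, scheme)
    y = design.target
    return _bat_optimize_vec(tree, Z, y, bat_config, rng)


def _bat_optimize_vec(
    tree: CVFNTree,
    Z: np.ndarray,
    y: np.ndarray,
    cfg: BatConfig,
    rng: np.random.Generator,
) -> CVFNTree:
    x0 = flatten_params(tree)
    if cfg.n_iters <= 0 or x0.size == 0:
        return tree
    dim = x0.size

    def cost(vec: np.ndarray) -> float:
        return _tree_rmse(unflatten_params(tree, vec), Z, y)

    pos = np.empty((cfg.n_bats, dim))
    pos[0] = x0
    pos[1:] = x0 + rng.uniform(-0.5, 0.5, (cfg.n_bats - 1, dim))
    vel = np.zeros((cfg.n_bats, dim))
    loud = np.full(cfg.n_bats, cfg.loudness0)
    pulse = np.full(cfg.n_bats, cfg.pulse0)
    fit = np.array([cost(p) for p in pos])
    best_i = int(np.argmin(fit))
    best_x = pos[best_i].copy()
    best_f = float(fit[best_i])

    for t in range(1, cfg.n_iters + 1):
        mean_loud = float(loud.mean())
        for i in range(cfg.n_bats):
            beta = rng.random()
            freq = cfg.f_min + (cfg.f_max - cfg.f_min) * beta
            vel[i] = np.clip(
                vel[i] + (pos[i] - best_x) * freq, -VELOCITY_CLAMP, VELOCITY_CLAMP
            )
            cand = pos[i] + vel[i]
            if rng.random() > pulse[i]:
                # local walk around the current best, scaled by mean loudness
                cand = best_x + rng.uniform(-1, 1, dim) * mean_loud
            f_cand = cost(cand)
            if f_cand <= fit[i] and rng.random() < loud[i]:
                pos[i] = cand
                fit[i] = f_cand
                loud[i] *= cfg.alpha
                pulse[i] = cfg.pulse0 * (1.0 - np.exp(-cfg.gamma * t))
            if f_cand < best_f:
                best_f = f_cand
                best_x = cand.copy()
    return unflatten_params(tree, best_x)


def fit_target_model(
    design: DelayedDesign,
    scheme: str = "real",
    opt_config: OptimizerConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[CVFNTree, list[FitnessRecord]]:
    """Evolve a CVFNT for one target gene; returns (best tree, fitness trace).

    Alternates one GP generation of structure search with a bat-algorithm
    parameter-refinement phase applied to the top ``param_opt_fraction`` of
    the population every ``param_opt_every`` generations.  Stops at
    ``max_generations`` or when the best RMSE drops to ``target_rmse``.
    Fully reproducible from the supplied rng/seed.
    """
    cfg = opt_config or OptimizerConfig()
    rng = np.random.default_rng(rng)
    Z = encode_inputs(design, scheme)
    y = design.target
    n_inputs = design.n_regulators

    def penalty(tree: CVFNTree) -> float:
        # light parsimony pressure: inputs that do not pay for themselves in
        # RMSE get selected away, keeping the read-off regulator set clean
        return cfg.parsimony * len(tree.terminal_indices())

    population = init_population(cfg, n_inputs, rng)
    evals = 0

    def evaluate(pop: list[CVFNTree]) -> tuple[np.ndarray, np.ndarray]:
        nonlocal evals
        evals += len(pop)
        raw = np.array([_tree_rmse(t, Z, y) for t in pop])
        return raw, raw + np.array([penalty(t) for t in pop])

    raw, fitnesses = evaluate(population)
    best_i = int(np.argmin(fitnesses))
    best_tree = population[best_i].copy()
    best_fit = float(fitnesses[best_i])
    best_rmse = float(raw[best_i])
    trace = [FitnessRecord(rmse=best_rmse, generation=0, evaluations=evals)]

    for gen in range(1, cfg.max_generations + 1):
        if best_rmse <= cfg.target_rmse:
            break
        population = evolve_structure(population, fitnesses, cfg, rng)
        raw, fitnesses = evaluate(population)

        if cfg.param_opt_every > 0 and gen % cfg.param_opt_every == 0:
            n_opt = max(1, int(round(cfg.param_opt_fraction * cfg.pop_size)))
            # refine the best individual of each distinct terminal subset so
            # competing regulator subsets are compared at their tuned optima
            best_of_group: dict[frozenset, int] = {}
            for i, tree in enumerate(population):
                key = frozenset(tree.terminal_indices())
                j = best_of_group.get(key)
                if j is None or fitnesses[i] < fitnesses[j]:
                    best_of_group[key] = i
            chosen = sorted(best_of_group.values(), key=lambda i: fitnesses[i])
            for i in chosen[:n_opt]:
                tuned = _bat_optimize_vec(population[i], Z, y, cfg.bat, rng)
                evals += cfg.bat.n_bats * (cfg.bat.n_iters + 1)
                r_tuned = _tree_rmse(tuned, Z, y)
                if r_tuned <= raw[i]:  # structure unchanged: penalty equal
                    population[i] = tuned
                    raw[i] = r_tuned
                    fitnesses[i] = r_tuned + penalty(tuned)

        gen_best = int(np.argmin(fitnesses))
        if fitnesses[gen_best] < best_fit:
            best_fit = float(fitnesses[gen_best])
            best_rmse = float(raw[gen_best])
            best_tree = population[gen_best].copy()
        trace.append(
            FitnessRecord(rmse=best_rmse, generation=gen, evaluations=evals)
        )
    return best_tree, trace


def write_trace(trace: list[FitnessRecord], path) -> None:
    """Fitness trace as TSV (generation, best_rmse, evaluations)."""
    with open(path, "w") as fh:
        fh.write("generation\tbest_rmse\tevaluations\n")
        for rec in trace:
            fh.write(f"{rec.generation}\t{rec.rmse:.10g}\t{rec.evaluations}\n")


class CVFNTRegressor(RegressorMixin, BaseEstimator):
    """Complex-valued flexible neural tree regressor with evolutionary fitting.

    ``X`` has shape ``(n_samples, n_features)`` — for network inference the
    lag-aligned regulator matrix — and ``y`` is the real target series.
    Structure is fitted by tournament genetic programming, parameters by a
    bat algorithm; see :func:`fit_target_model`.

    Parameters mirror :class:`~tdgrn.io.OptimizerConfig`; ``encoding``
    selects how real inputs are mapped onto complex terminals (``real`` or
    ``phase``).

    Attributes
    ----------
    tree_ : CVFNTree
        Best tree found.
    rmse_ : float
        Training RMSE of ``tree_``.
    trace_ : list of FitnessRecord
        Best-so-far fitness per generation.
    used_features_ : sorted tuple of int
        Input indices that appear as terminals in ``tree_`` (for network
        inference these are the inferred regulators).
    """

    def __init__(
        self,
        pop_size: int = 50,
        max_generations: int = 100,
        crossover_prob: float = 0.7,
        mutation_prob: float = 0.3,
        tournament_size: int = 3,
        param_opt_every: int = 5,
        param_opt_fraction: float = 0.2,
        target_rmse: float = 1e-3,
        parsimony: float = 0.01,
        max_depth: int = 4,
        function_arities: tuple[int, ...] = (2, 3),
        n_bats: int = 30,
        bat_iters: int = 100,
        encoding: str = "real",
        random_state: int | None = None,
    ):
        self.pop_size = pop_size
        self.max_generations = max_generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.tournament_size = tournament_size
        self.param_opt_every = param_opt_every
        self.param_opt_fraction = param_opt_fraction
        self.target_rmse = target_rmse
        self.parsimony = parsimony
        self.max_depth = max_depth
        self.function_arities = function_arities
        self.n_bats = n_bats
        self.bat_iters = bat_iters
        self.encoding = encoding
        self.random_state = random_state

    def _optimizer_config(self) -> OptimizerConfig:
        return OptimizerConfig(
            pop_size=self.pop_size,
            max_generations=self.max_generations,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            tournament_size=self.tournament_size,
            param_opt_every=self.param_opt_every,
            param_opt_fraction=self.param_opt_fraction,
            target_rmse=self.target_rmse,
            parsimony=self.parsimony,
            max_depth=self.max_depth,
            function_arities=tuple(self.function_arities),
            bat=BatConfig(n_bats=self.n_bats, n_iters=self.bat_iters),
        )

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        design = DelayedDesign(
            target_index=-1,
            regulator_indices=tuple(range(X.shape[1])),
            lags=(0,) * X.shape[1],
            inputs=X.T,
            target=y,
        )
        rng = np.random.default_rng(self.random_state)
        self.tree_, self.trace_ = fit_target_model(
            design, self.encoding, self._optimizer_config(), rng
        )
        self.rmse_ = self.trace_[-1].rmse
        self.used_features_ = tuple(sorted(self.tree_.terminal_indices()))
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        if self.encoding == "phase":
            Z = np.cos(np.pi * X) + 1j * np.sin(np.pi * X)
        else:
            Z = X.astype(complex)
        return evaluate_series(self.tree_, Z).real
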