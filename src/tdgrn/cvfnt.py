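"""Complex-valued flexible neural tree (CVFNT) representation and evaluation.

A CVFNT is an expression tree whose internal nodes are complex-weighted
flexible neurons ``+n`` and whose leaves are input genes ``z_i``.  A neuron
with arity ``n`` computes the excitation

    net = w0 + sum_j w_j * z_j          (w_j, w0 complex)

and passes it through the complex Elliot activation

    f(net) = net / (a + |net| / r)      (a, r > 0 real, per node),

whose output modulus is bounded by ``r``.  Trees are evaluated post-order
(children before parent, left to right); evaluation is vectorised over time
points.

Real expression data carry no imaginary part; two encodings onto the complex
terminals are provided: ``real`` (z = x + 0j, the default) and ``phase``
(z = cos(pi x) + j sin(pi x), a unit-circle embedding of values in [0, 1]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .design import DelayedDesign

__all__ = [
    "CVFNTNode",
    "CVFNTree",
    "complex_elliot",
    "evaluate_neuron",
    "evaluate_tree",
    "evaluate_series",
    "encode_inputs",
    "predict_real",
    "random_tree",
    "tree_to_json",
    "tree_from_json",
    "save_tree",
    "load_tree",
]

SERIAL_FORMAT_VERSION = 1


def complex_elliot(net: complex, a: float, r: float) -> complex:
    """Complex Elliot activation ``net / (a + |net| / r)``; |output| < r."""
    if a <= 0 or r <= 0:
        raise ValueError("activation parameters a and r must be positive")
    return net / (a + np.abs(net) / r)


@dataclass
class CVFNTNode:
    """One tree node: a flexible neuron (``function``) or an input leaf."""

    kind: str  # "function" | "terminal"
    input_index: int = -1
    weights: np.ndarray = field(default_factory=lambda: np.zeros(0, complex))
    threshold: complex = 0j
    act_a: float = 1.0
    act_r: float = 1.0
    children: list["CVFNTNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("function", "terminal"):
            raise ValueError(f"unknown node kind {self.kind!r}")
        self.weights = np.asarray(self.weights, dtype=complex)
        if self.kind == "terminal":
            if self.input_index < 0:
                raise ValueError("terminal node needs a non-negative input index")
            if self.children:
                raise ValueError("terminal node cannot have children")
        else:
            if len(self.children) < 1:
                raise ValueError("function node needs children")
            if len(self.weights) != len(self.children):
                raise ValueError(
                    f"arity mismatch: {len(self.weights)} weights for "
                    f"{len(self.children)} children"
                )
            if self.act_a <= 0 or self.act_r <= 0:
                raise ValueError("act_a and act_r must be positive")

    @property
    def arity(self) -> int:
        return len(self.children)

    def depth(self) -> int:
        if self.kind == "terminal":
            return 1
        return 1 + max(c.depth() for c in self.children)

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    def copy(self) -> "CVFNTNode":
        return CVFNTNode(
            kind=self.kind,
            input_index=self.input_index,
            weights=self.weights.copy(),
            threshold=self.threshold,
            act_a=self.act_a,
            act_r=self.act_r,
            children=[c.copy() for c in self.children],
        )


@dataclass
class CVFNTree:
    """A validated CVFNT: root node, input count and depth bound."""

    root: CVFNTNode
    n_inputs: int
    max_depth: int = 4

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.root.depth() > self.max_depth:
            raise ValueError(
                f"tree depth {self.root.depth()} exceeds bound {self.max_depth}"
            )
        for node in self.root.iter_nodes():
            if node.kind == "terminal" and not (
                0 <= node.input_index < self.n_inputs
            ):
                raise ValueError(
                    f"terminal index {node.input_index} out of range "
                    f"[0, {self.n_inputs})"
                )

    def terminal_indices(self) -> set[int]:
        return {
            n.input_index for n in self.root.iter_nodes() if n.kind == "terminal"
        }

    def depth(self) -> int:
        return self.root.depth()

    def n_nodes(self) -> int:
        return sum(1 for _ in self.root.iter_nodes())

    def copy(self) -> "CVFNTree":
        return CVFNTree(
            root=self.root.copy(), n_inputs=self.n_inputs, max_depth=self.max_depth
        )


def evaluate_neuron(node: CVFNTNode, child_outputs) -> complex:
    """Excitation + Elliot activation of one flexible neuron."""
    child_outputs = np.asarray(child_outputs, dtype=complex)
    if node.kind != "function":
        raise ValueError("evaluate_neuron expects a function node")
    if len(child_outputs) != node.arity:
        raise ValueError(
            f"arity mismatch: got {len(child_outputs)} child outputs for a "
            f"+{node.arity} neuron"
        )
    net = node.threshold + np.dot(node.weights, child_outputs)
    return complex_elliot(net, node.act_a, node.act_r)


def _eval_node(node: CVFNTNode, Z: np.ndarray) -> np.ndarray:
    # post-order, vectorised over the time axis of Z (T, n_inputs)
    if node.kind == "terminal":
        return Z[:, node.input_index]
    net = np.full(Z.shape[0], node.threshold, dtype=complex)
    for w, child in zip(node.weights, node.children):
        net += w * _eval_node(child, Z)
    return net / (node.act_a + np.abs(net) / node.act_r)


def evaluate_tree(tree: CVFNTree, input_row) -> complex:
    """Evaluate the tree on one complex input row (length ``n_inputs``)."""
    row = np.asarray(input_row, dtype=complex).reshape(1, -1)
    if row.shape[1] != tree.n_inputs:
        raise ValueError(
            f"expected {tree.n_inputs} inputs, got {row.shape[1]}"
        )
    return complex(_eval_node(tree.root, row)[0])


def evaluate_series(tree: CVFNTree, Z: np.ndarray) -> np.ndarray:
    """Evaluate the tree on a (T, n_inputs) complex matrix; returns length-T vector."""
    Z = np.asarray(Z, dtype=complex)
    if Z.ndim != 2 or Z.shape[1] != tree.n_inputs:
        raise ValueError(f"expected (T, {tree.n_inputs}) input matrix")
    return _eval_node(tree.root, Z)


def encode_inputs(design: DelayedDesign, scheme: str = "real") -> np.ndarray:
    """Map real design inputs onto complex terminals.

    ``real``: z = x + 0j.  ``phase``: z = cos(pi x) + j sin(pi x), which
    requires values in [0, 1] (min-max normalised data).
    Returns a (m_eff, L) complex matrix (time along rows).
    """
    X = design.inputs.T  # (m_eff, L)
    if scheme == "real":
        return X.astype(complex)
    if scheme == "phase":
        if X.min() < 0.0 or X.max() > 1.0:
            raise ValueError("phase encoding requires values in [0, 1]")
        return np.cos(np.pi * X) + 1j * np.sin(np.pi * X)
    raise ValueError(f"unknown encoding scheme {scheme!r}")


def predict_real(
    tree: CVFNTree, design: DelayedDesign, scheme: str = "real"
) -> np.ndarray:
    """Real-valued prediction over the design's output window.

    The complex root output is projected to its real part, which preserves
    sign and ordering against the real target series.
    """
    Z = encode_inputs(design, scheme)
    return evaluate_series(tree, Z).real


def random_tree(
    n_inputs: int,
    rng: np.random.Generator,
    max_depth: int = 4,
    function_arities: tuple[int, ...] = (2, 3),
    p_function: float = 0.6,
) -> CVFNTree:
    """Grow-method random tree: below the depth bound each node is a neuron
    with probability ``p_function``, else a leaf; weights have Re, Im ~
    U(-1, 1) and activation parameters a, r ~ U(0.1, 2)."""

    def grow(depth: int) -> CVFNTNode:
        if depth >= max_depth or rng.random() > p_function:
            return CVFNTNode(kind="terminal", input_index=int(rng.integers(n_inputs)))
        arity = int(rng.choice(function_arities))
        return CVFNTNode(
            kind="function",
            weights=_rand_complex(rng, arity),
            threshold=_rand_complex(rng, 1)[0],
            act_a=float(rng.uniform(0.1, 2.0)),
            act_r=float(rng.uniform(0.1, 2.0)),
            children=[grow(depth + 1) for _ in range(arity)],
        )

    root = grow(1)
    if root.kind == "terminal" and max_depth >= 2 and rng.random() < 0.5:
        # avoid an excess of bare-leaf trees: optionally wrap in a neuron
        arity = int(rng.choice(function_arities))
        root = CVFNTNode(
            kind="function",
            weights=_rand_complex(rng, arity),
            threshold=_rand_complex(rng, 1)[0],
            act_a=float(rng.uniform(0.1, 2.0)),
            act_r=float(rng.uniform(0.1, 2.0)),
            children=[
                CVFNTNode(kind="terminal", input_index=int(rng.integers(n_inputs)))
                for _ in range(arity)
            ],
        )
    return CVFNTree(root=root, n_inputs=n_inputs, max_depth=max_depth)


def _rand_complex(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(-1, 1, n) + 1j * rng.uniform(-1, 1, n)


def _node_to_obj(node: CVFNTNode) -> dict:
    if node.kind == "terminal":
        return {"kind": "terminal", "input_index": node.input_index}
    return {
        "kind": "function",
        "weights": [[w.real, w.imag] for w in node.weights],
        "threshold": [node.threshold.real, node.threshold.imag],
        "act_a": node.act_a,
        "act_r": node.act_r,
        "children": [_node_to_obj(c) for c in node.children],
    }


def _node_from_obj(obj: dict) -> CVFNTNode:
    if obj["kind"] == "terminal":
        return CVFNTNode(kind="terminal", input_index=int(obj["input_index"]))
    return CVFNTNode(
        kind="function",
        weights=np.array([complex(re, im) for re, im in obj["weights"]]),
        threshold=complex(*obj["threshold"]),
        act_a=float(obj["act_a"]),
        act_r=float(obj["act_r"]),
        children=[_node_from_obj(c) for c in obj["children"]],
    )


def tree_to_json(tree: CVFNTree) -> str:
    """Serialise a tree to a JSON text (prefix-order nodes, complex as [re, im])."""
    return json.dumps(
        {
            "format_version": SERIAL_FORMAT_VERSION,
            "n_inputs": tree.n_inputs,
            "max_depth": tree.max_depth,
            "root": _node_to_obj(tree.root),
        }
    )


def tree_from_json(text: str) -> CVFNTree:
    obj = json.loads(text)
    if obj.get("format_version") != SERIAL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported tree format version {obj.get('format_version')!r}"
        )
    return CVFNTree(
        root=_node_from_obj(obj["root"]),
        n_inputs=int(obj["n_inputs"]),
        max_depth=int(obj["max_depth"]),
    )


def save_tree(tree: CVFNTree, path: str | Path) -> None:
    Path(path).write_text(tree_to_json(tree))


def load_tree(path: str | Path) -> CVFNTree:
    return tree_from_json(Path(path).read_text())
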