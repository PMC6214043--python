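"""Synthetic time-delayed regulatory networks and expression time courses.

The generator emulates the scale and structure of short benchmark time
courses (the 6-gene / 50-point DNA-damage-response network, the 5-gene /
21-point synthetic-biology network): a handful of genes, a sparse directed
network with per-edge lags of one or more sampling intervals, smooth driver
dynamics and a nonlinear saturating link from lagged regulator levels to
target expression, plus Gaussian observation noise.

Driver genes (in-degree zero) follow a bounded sinusoid-plus-AR(1) process
in [0, 1]; a regulated gene at time t is

    x_k(t) = clip( 0.5 + link( sum_e w_e * (x_reg(t - lag_e) - 0.5) )
                   + N(0, noise_sd), 0, 1 ),

where ``link`` is the Elliot saturation by default (the same family the tree
model fits, so parameter recovery is well-posed), or a centred linear /
logistic link to exercise model misspecification.  Edge weights are bounded
away from zero so "true edge" is meaningful for recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionDataset, GoldNetwork

__all__ = ["SyntheticSpec", "generate_network", "simulate_expression"]

MIN_WEIGHT = 0.2
LINKS = ("elliot", "linear", "sigmoid")
# Elliot saturation constants for the generative link; r = 0.5 keeps the
# regulated signal inside [0, 1] around the 0.5 baseline.
LINK_A, LINK_R = 0.5, 0.5
# driver AR(1) dynamics: innovation SD and persistence
DRIVER_AR_SD = 0.08
DRIVER_AR_RHO = 0.8


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth network + simulation settings for one synthetic dataset."""

    n_genes: int
    edges: tuple[tuple[int, int, int, float], ...]  # (regulator, target, lag, weight)
    m: int = 50
    noise_sd: float = 0.05
    seed: int = 0
    link: str = "elliot"
    driver_genes: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.m < 10:
            raise ValueError("need at least 10 time points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.link not in LINKS:
            raise ValueError(f"link must be one of {LINKS}")
        seen = set()
        for reg, tgt, lag, w in self.edges:
            if reg == tgt:
                raise ValueError("self-loops are not simulated")
            if not (0 <= reg < self.n_genes and 0 <= tgt < self.n_genes):
                raise ValueError("edge endpoint out of range")
            if lag < 1:
                raise ValueError("edge lags must be >= 1 (influence strictly past)")
            if (reg, tgt) in seen:
                raise ValueError("duplicate edge")
            seen.add((reg, tgt))
        regulated = {tgt for _, tgt, _, _ in self.edges}
        drivers = frozenset(g for g in range(self.n_genes) if g not in regulated)
        object.__setattr__(self, "driver_genes", drivers)

    @property
    def max_lag(self) -> int:
        return max((lag for _, _, lag, _ in self.edges), default=1)

    def gold_network(self, gene_ids) -> GoldNetwork:
        return GoldNetwork(
            edges=frozenset(
                (gene_ids[r], gene_ids[t]) for r, t, _, _ in self.edges
            )
        )


def generate_network(
    n_genes: int,
    n_edges: int,
    tau_max: int = 6,
    rng: np.random.Generator | int | None = None,
    m: int = 50,
    noise_sd: float = 0.05,
    link: str = "elliot",
    seed: int = 0,
) -> SyntheticSpec:
    """Random sparse directed network with per-edge lags and weights.

    Edges are distinct ordered non-self pairs; lags ~ U{1..tau_max}; weights
    ~ U(-1, 1) excluding (-0.2, 0.2) so every true edge carries a detectable
    effect.  Driver genes are those with in-degree zero.
    """
    if n_edges > n_genes * (n_genes - 1):
        raise ValueError("more edges requested than ordered non-self pairs")
    if tau_max < 1:
        raise ValueError("tau_max must be >= 1 to place lagged edges")
    rng = np.random.default_rng(rng)
    pairs = [(a, b) for a in range(n_genes) for b in range(n_genes) if a != b]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    edges = []
    for idx in chosen:
        reg, tgt = pairs[int(idx)]
        lag = int(rng.integers(1, tau_max + 1))
        w = float(rng.uniform(MIN_WEIGHT, 1.0)) * (1 if rng.random() < 0.5 else -1)
        edges.append((reg, tgt, lag, w))
    return SyntheticSpec(
        n_genes=n_genes,
        edges=tuple(edges),
        m=m,
        noise_sd=noise_sd,
        seed=seed,
        link=link,
    )


def _link(values: np.ndarray | float, kind: str):
    if kind == "linear":
        return values
    if kind == "elliot":
        return values / (LINK_A + np.abs(values) / LINK_R)
    # logistic centred at 0, shifted back to a deviation around 0
    return 1.0 / (1.0 + np.exp(-4.0 * values)) - 0.5


def simulate_expression(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, GoldNetwork]:
    """Forward-simulate the spec and return (dataset, gold network).

    Every gene starts on its own sinusoid baseline; from ``max_lag`` on,
    regulated genes follow the lagged link dynamics.  A burn-in of
    ``max_lag`` steps is discarded so emitted regulated values all reflect
    the regulatory dynamics.  All values lie in [0, 1].  Deterministic for a
    fixed spec (the seed lives in the spec).
    """
    rng = np.random.default_rng(spec.seed)
    burn = spec.max_lag
    total = spec.m + burn
    n = spec.n_genes

    amp = rng.uniform(0.2, 0.35, n)
    period = rng.uniform(8.0, 16.0, n)
    phase = rng.uniform(0.0, 2 * np.pi, n)
    t = np.arange(total)
    baseline = 0.5 + amp[:, None] * np.sin(2 * np.pi * t[None, :] / period[:, None]
                                           + phase[:, None])

    x = baseline.copy()
    # smooth stochastic component of the driver trajectories; part of the
    # driver dynamics (deterministic per seed), not observation noise, so
    # lagged copies stay identifiable against the periodic baseline
    drv = sorted(spec.driver_genes)
    if drv:
        eps = rng.normal(0.0, DRIVER_AR_SD, (len(drv), total))
        ar = np.zeros((len(drv), total))
        for k in range(1, total):
            ar[:, k] = DRIVER_AR_RHO * ar[:, k - 1] + eps[:, k]
        x[drv] += ar
    x = np.clip(x, 0.0, 1.0)

    incoming: dict[int, list[tuple[int, int, float]]] = {}
    for reg, tgt, lag, w in spec.edges:
        incoming.setdefault(tgt, []).append((reg, lag, w))

    obs_noise = (
        rng.normal(0.0, spec.noise_sd, (n, total)) if spec.noise_sd > 0 else None
    )
    for k in range(spec.max_lag, total):
        for tgt, parents in incoming.items():
            s = sum(w * (x[reg, k - lag] - 0.5) for reg, lag, w in parents)
            val = 0.5 + _link(s, spec.link)
            if obs_noise is not None:
                val += obs_noise[tgt, k]
            x[tgt, k] = min(max(val, 0.0), 1.0)

    values = x[:, burn:]
    gene_ids = tuple(f"G{i + 1}" for i in range(n))
    dataset = ExpressionDataset(gene_ids=gene_ids, values=values)
    return dataset, spec.gold_network(gene_ids)
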