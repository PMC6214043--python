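"""Lag-aligned regulator/target design matrix for one target gene.

Each candidate regulator enters at its own optimal lag.  Because the tree
model consumes all regulators simultaneously, a single common output window
is used: with lags ``tau_i`` the window starts at ``max(tau_i)`` so that
every lagged regulator value exists.  ``inputs[i][t]`` is regulator ``i``
observed ``lags[i]`` sampling intervals before the target value
``target[t]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ExpressionDataset
from .scoring import CandidateSet

__all__ = ["DelayedDesign", "build_delayed_design"]

MIN_WINDOW = 5


@dataclass(frozen=True)
class DelayedDesign:
    """Lag-aligned inputs (L x m_eff) and target vector (m_eff) for one gene."""

    target_index: int
    regulator_indices: tuple[int, ...]
    lags: tuple[int, ...]
    inputs: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        inputs = np.asarray(self.inputs, dtype=float)
        target = np.asarray(self.target, dtype=float)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "target", target)
        if inputs.ndim != 2:
            raise ValueError("inputs must be 2-D (regulators x time)")
        if inputs.shape[0] != len(self.regulator_indices) or inputs.shape[0] != len(
            self.lags
        ):
            raise ValueError("one input row per regulator/lag required")
        if inputs.shape[1] != len(target):
            raise ValueError("inputs and target must share the output window")
        if not (np.all(np.isfinite(inputs)) and np.all(np.isfinite(target))):
            raise ValueError("design matrix contains non-finite values")

    @property
    def n_regulators(self) -> int:
        return self.inputs.shape[0]

    @property
    def m_eff(self) -> int:
        return self.inputs.shape[1]

    def dump_tsv(self, path: str | Path, gene_ids=None) -> None:
        """Debug dump of the aligned design as TSV (rows: regulators + target)."""
        import pandas as pd

        names = [
            (gene_ids[i] if gene_ids is not None else f"g{i}") + f"(lag {l})"
            for i, l in zip(self.regulator_indices, self.lags)
        ]
        tname = gene_ids[self.target_index] if gene_ids is not None else "target"
        df = pd.DataFrame(
            np.vstack([self.inputs, self.target]), index=names + [tname]
        )
        df.to_csv(Path(path), sep="\t")


def build_delayed_design(
    dataset: ExpressionDataset, candidates: CandidateSet
) -> DelayedDesign:
    """Align each candidate regulator at its lag against the target series.

    The common output window is ``t = max(lags) .. m-1``; ``target[j]`` is
    the target at the window time and ``inputs[i][j]`` the i-th regulator
    ``lags[i]`` steps earlier.  Deterministic; raises if the window would be
    shorter than 5 points (reduce tau_max in that case).
    """
    m = dataset.n_timepoints
    regs = candidates.regulator_indices
    lags = candidates.lags
    if not regs:
        raise ValueError("candidate set is empty")
    max_lag = max(lags)
    m_eff = m - max_lag
    if m_eff < MIN_WINDOW:
        raise ValueError(
            f"output window of {m_eff} points is too short (need >= {MIN_WINDOW}); "
            "use a smaller tau_max"
        )
    inputs = np.empty((len(regs), m_eff))
    for row, (i, lag) in enumerate(zip(regs, lags)):
        start = max_lag - lag
        inputs[row] = dataset.values[i, start : start + m_eff]
    target = dataset.values[candidates.target_index, max_lag:]
    return DelayedDesign(
        target_index=candidates.target_index,
        regulator_indices=tuple(regs),
        lags=tuple(lags),
        inputs=inputs,
        target=target,
    )
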