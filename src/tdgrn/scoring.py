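"""Time-delayed association measures and hybrid candidate-regulator ranking.

Three measures quantify how strongly a putative regulator series ``x``
anticipates a target series ``y`` at lag ``tau`` (the regulator leads: the
pairing is ``x[k]`` against ``y[k + tau]`` on the overlapping window):

* :func:`tdmi` — time-delayed mutual information from an equal-width 2-D
  histogram (natural log, so values are in nats);
* :func:`tdmic` — time-delayed maximal information coefficient, the
  grid-normalised maximal mutual information in [0, 1];
* :func:`tdcc` — time-delayed Pearson correlation in [-1, 1], also used to
  pick each pair's optimal lag.

Per target gene the three measures are each maximised over the lag range,
genes are ranked per measure (rank 1 = strongest association), and the rank
sums are aggregated; the ``L`` genes with the smallest aggregated rank form
the candidate regulator set.  Ranking on three heterogeneous measures rather
than thresholding any single one avoids committing to one association scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import ExpressionDataset, RunConfig

__all__ = [
    "PairScore",
    "CandidateSet",
    "tdmi",
    "tdmic",
    "tdcc",
    "best_lag",
    "hybrid_rank",
    "score_table",
    "HybridRankSelector",
]

MEASURES = ("TDMI", "TDMIC", "TDCC")


@dataclass(frozen=True)
class PairScore:
    """Best value and best lag of one measure for one regulator→target pair."""

    regulator_index: int
    measure: str
    best_value: float
    best_lag: int


@dataclass(frozen=True)
class CandidateSet:
    """Ranked shortlist of candidate regulators for one target gene.

    ``candidates`` holds ``(regulator_index, aggregated_rank, lag)`` triples
    ordered by aggregated rank; ``lag`` is the TDCC-optimal lag for that
    regulator→target pair.
    """

    target_index: int
    candidates: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        idx = [c[0] for c in self.candidates]
        if self.target_index in idx:
            raise ValueError("target cannot be its own candidate regulator")
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate candidate regulator")
        ranks = [c[1] for c in self.candidates]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            raise ValueError("aggregated ranks must be non-decreasing")

    @property
    def regulator_indices(self) -> tuple[int, ...]:
        return tuple(c[0] for c in self.candidates)

    @property
    def lags(self) -> tuple[int, ...]:
        return tuple(c[2] for c in self.candidates)


def _overlap(x: np.ndarray, y: np.ndarray, tau: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if tau < 0:
        raise ValueError("lag must be non-negative")
    m = len(x)
    if tau >= m:
        raise ValueError(f"lag {tau} leaves no overlap on series of length {m}")
    if tau == 0:
        return x, y
    return x[:-tau], y[tau:]


def default_bins(n: int) -> int:
    """Equal-width histogram bin count for an n-point window: max(2, floor(sqrt(n)))."""
    return max(2, int(np.floor(np.sqrt(n))))


def tdmi(x, y, tau: int, bins: int | None = None) -> float:
    """Time-delayed mutual information (nats) between ``x`` and ``y`` at lag ``tau``.

    Pairs ``x[k]`` with ``y[k + tau]`` on the overlapping window and estimates
    MI from an equal-width 2-D histogram with ``bins`` bins per axis
    (default :func:`default_bins` of the overlap length).  ``tau = 0`` gives
    ordinary, symmetric MI.
    """
    xs, ys = _overlap(x, y, tau)
    n = len(xs)
    if n < 3:
        raise ValueError(f"overlap of {n} points is too short for MI (need >= 3)")
    if bins is None:
        bins = default_bins(n)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    joint, _, _ = np.histogram2d(xs, ys, bins=bins)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    denom = px * py
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, pxy / np.where(denom > 0, denom, 1.0), 1.0)
        terms = xlogy(pxy, ratio)
    return float(max(terms.sum(), 0.0))


def _grid_mi_scores(order_counts: np.ndarray, max_bins: int) -> np.ndarray:
    """Best sum_b sum_j c_bj log(c_bj / c_b) over contiguous partitions.

    ``order_counts``: (N, n_labels) one-hot-ish counts of the co-variable
    label for points sorted along the partitioned axis.  Returns, for each
    number of parts k in 1..max_bins, the maximum over partitions into at
    most k contiguous groups of the (unnormalised) negative conditional
    entropy term; dividing by N and adding H(label) gives the mutual
    information.
    """
    n = order_counts.shape[0]
    cum = np.vstack([np.zeros(order_counts.shape[1]), np.cumsum(order_counts, axis=0)])
    # seg[s, e] = score of grouping sorted points s..e-1 into one bin
    counts = np.maximum(cum[None, :, :] - cum[:, None, :], 0.0)  # (n+1, n+1, labels)
    totals = counts.sum(axis=2)
    seg = xlogy(counts, counts).sum(axis=2) - xlogy(totals, totals)
    s_idx, e_idx = np.indices(seg.shape)
    seg[s_idx > e_idx] = -np.inf  # segments must run forward
    best = np.full((max_bins + 1, n + 1), -np.inf)
    best[0, 0] = 0.0
    out = np.full(max_bins + 1, -np.inf)
    for k in range(1, max_bins + 1):
        # best[k, e] = max_s best[k-1, s] + seg[s, e]
        best[k] = np.max(best[k - 1][:, None] + seg, axis=0)
        out[k] = max(out[k - 1], best[k, n])
    return out[1:]


def _equipartition_labels(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-equipartition of ``values`` into ``n_bins`` nearly equal groups."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    splits = np.array_split(np.arange(n), n_bins)
    for b, idx in enumerate(splits):
        labels[order[idx]] = b
    return labels


def _mic(xs: np.ndarray, ys: np.ndarray) -> float:
    n = len(xs)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return 0.0
    grid_budget = max(4.0, n**0.6)
    max_axis = int(grid_budget // 2)
    best = 0.0
    for a, b in ((xs, ys), (ys, xs)):
        # equipartition axis b into nb bins, optimal contiguous partition
        # of axis a by dynamic programming
        for nb in range(2, max_axis + 1):
            na_max = int(grid_budget // nb)
            if na_max < 2:
                break
            labels = _equipartition_labels(b, nb)
            h_label = -xlogy(
                counts := np.bincount(labels, minlength=nb) / n, counts
            ).sum()
            order = np.argsort(a, kind="stable")
            onehot = np.zeros((n, nb))
            onehot[np.arange(n), labels[order]] = 1.0
            scores = _grid_mi_scores(onehot, na_max)  # index k-1 -> k bins
            for na in range(2, na_max + 1):
                mi = h_label + scores[na - 1] / n
                norm = np.log(min(na, nb))
                best = max(best, mi / norm)
    return float(min(max(best, 0.0), 1.0))


def tdmic(x, y, tau: int) -> float:
    """Time-delayed maximal information coefficient in [0, 1].

    Computes the MIC of the lag-shifted pair on the overlapping window of
    length N: the maximum over all grids with ``x_bins * y_bins <= N**0.6``
    (each axis >= 2 bins) of the grid mutual information normalised by
    ``log(min(x_bins, y_bins))``.  One grid axis is rank-equipartitioned and
    the other optimised exactly by dynamic programming over contiguous
    partitions of the sorted points; both orientations are tried.  Constant
    (degenerate) series score 0.
    """
    xs, ys = _overlap(x, y, tau)
    if len(xs) < 4:
        raise ValueError("overlap too short for MIC (need >= 4 points)")
    return _mic(xs, ys)


def tdcc(x, y, tau: int) -> float:
    """Time-delayed Pearson correlation between ``x`` and ``y`` at lag ``tau``.

    Means and variances are computed on the overlapping window itself.
    Returns 0.0 when either windowed series has zero variance.
    """
    xs, ys = _overlap(x, y, tau)
    if len(xs) < 3:
        raise ValueError("overlap too short for correlation (need >= 3 points)")
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = np.sqrt((xs**2).sum() * (ys**2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((xs * ys).sum() / denom, -1.0, 1.0))


def best_lag(x, y, min_lag: int = 0, tau_max: int = 6) -> tuple[int, float]:
    """Lag in ``[min_lag, tau_max]`` maximising ``|tdcc(x, y, tau)|``.

    Ties break toward the smallest lag.  Returns ``(lag, tdcc_at_lag)``
    (the signed correlation at the winning lag).
    """
    if min_lag > tau_max:
        raise ValueError("min_lag must be <= tau_max")
    best_tau = min_lag
    best_abs = -1.0
    best_val = 0.0
    for tau in range(min_lag, tau_max + 1):
        val = tdcc(x, y, tau)
        if abs(val) > best_abs + 1e-12:
            best_abs = abs(val)
            best_val = val
            best_tau = tau
    return best_tau, best_val


class HybridRankSelector(SelectorMixin, BaseEstimator):
    """Select candidate regulators of one target by aggregated measure ranks.

    A scikit-learn selector: ``X`` has shape ``(n_timepoints, n_regulators)``
    with each column a putative regulator's time series, and ``y`` is the
    target gene's series.  For every column the three time-delayed measures
    (TDMI, TDMIC, |TDCC|) are maximised over lags in ``[min_lag, tau_max]``;
    columns are ranked per measure (rank 1 = strongest, ties share the
    smallest rank) and the three ranks summed.  The ``L`` columns with the
    smallest aggregated rank are selected, ties broken by larger TDMIC, then
    larger TDMI, then smaller column index.

    Attributes
    ----------
    support_ : bool array (n_regulators,)
        Mask of selected columns.
    selected_ : int array (L,)
        Selected column indices in aggregated-rank order.
    aggregated_ranks_ : int array (n_regulators,)
        Rank sum over the three measures per column.
    lags_ : int array (n_regulators,)
        TDCC-optimal lag per column.
    scores_ : float array (3, n_regulators)
        Lag-maximised TDMI, TDMIC and |TDCC| per column.
    """

    def __init__(
        self,
        L: int = 2,
        tau_max: int = 6,
        min_lag: int = 0,
        mi_bins: int | None = None,
    ):
        self.L = L
        self.tau_max = tau_max
        self.min_lag = min_lag
        self.mi_bins = mi_bins

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=self.tau_max + 4)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("target series length must match X rows")
        n_reg = X.shape[1]
        if self.L > n_reg:
            raise ValueError(f"L={self.L} exceeds the {n_reg} available regulators")
        lags_range = range(self.min_lag, self.tau_max + 1)
        scores = np.zeros((3, n_reg))
        lags = np.zeros(n_reg, dtype=int)
        for i in range(n_reg):
            xi = X[:, i]
            scores[0, i] = max(tdmi(xi, y, t, self.mi_bins) for t in lags_range)
            scores[1, i] = max(tdmic(xi, y, t) for t in lags_range)
            scores[2, i] = max(abs(tdcc(xi, y, t)) for t in lags_range)
            lags[i], _ = best_lag(xi, y, self.min_lag, self.tau_max)
        # rank 1 = strongest; ties share the smallest rank
        ranks = np.vstack([rankdata(-s, method="min") for s in scores]).astype(int)
        agg = ranks.sum(axis=0)
        order = sorted(
            range(n_reg), key=lambda i: (agg[i], -scores[1, i], -scores[0, i], i)
        )
        selected = np.array(order[: self.L], dtype=int)
        self.scores_ = scores
        self.measure_ranks_ = ranks
        self.aggregated_ranks_ = agg
        self.lags_ = lags
        self.selected_ = selected
        self.support_ = np.zeros(n_reg, dtype=bool)
        self.support_[selected] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


def hybrid_rank(
    dataset: ExpressionDataset, target_index: int, config: RunConfig
) -> CandidateSet:
    """Candidate regulator set of one target gene by hybrid rank aggregation.

    Thin wrapper over :class:`HybridRankSelector`; the target gene itself is
    excluded from the pool, so self-regulation is never proposed.
    """
    n = dataset.n_genes
    if not (0 <= target_index < n):
        raise IndexError(f"target index {target_index} out of range")
    if config.L > n - 1:
        raise ValueError(f"L={config.L} exceeds n-1={n - 1} candidate genes")
    pool = [i for i in range(n) if i != target_index]
    X = dataset.values[pool].T  # (timepoints, regulators)
    y = dataset.values[target_index]
    sel = HybridRankSelector(
        L=config.L, tau_max=config.tau_max, min_lag=config.min_lag,
        mi_bins=config.mi_bins,
    ).fit(X, y)
    candidates = tuple(
        (pool[j], int(sel.aggregated_ranks_[j]), int(sel.lags_[j]))
        for j in sel.selected_
    )
    return CandidateSet(target_index=target_index, candidates=candidates)


def score_table(dataset: ExpressionDataset, config: RunConfig):
    """Full per-pair score table as a DataFrame (one row per target/regulator)."""
    import pandas as pd

    rows = []
    for k in range(dataset.n_genes):
        pool = [i for i in range(dataset.n_genes) if i != k]
        X = dataset.values[pool].T
        y = dataset.values[k]
        sel = HybridRankSelector(
            L=min(config.L, len(pool)), tau_max=config.tau_max,
            min_lag=config.min_lag, mi_bins=config.mi_bins,
        ).fit(X, y)
        for j, i in enumerate(pool):
            rows.append(
                {
                    "target": dataset.gene_ids[k],
                    "regulator": dataset.gene_ids[i],
                    "tdmi": sel.scores_[0, j],
                    "tdmic": sel.scores_[1, j],
                    "tdcc_abs": sel.scores_[2, j],
                    "best_lag": int(sel.lags_[j]),
                    "rank_tdmi": int(sel.measure_ranks_[0, j]),
                    "rank_tdmic": int(sel.measure_ranks_[1, j]),
                    "rank_tdcc": int(sel.measure_ranks_[2, j]),
                    "aggregated_rank": int(sel.aggregated_ranks_[j]),
                    "selected": bool(sel.support_[j]),
                }
            )
    return pd.DataFrame(rows)
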