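import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tdgrn import ExpressionDataset, RunConfig, best_lag, hybrid_rank, tdcc, tdmi, tdmic
from tdgrn.scoring import HybridRankSelector

from conftest import random_walk


def brute_force_mi(x, y, tau, bins):
    """Independent double-loop joint-histogram MI oracle (nats)."""
    xs = np.asarray(x, float)[: len(x) - tau] if tau else np.asarray(x, float)
    ys = np.asarray(y, float)[tau:]
    n = len(xs)
    x_edges = np.linspace(xs.min(), xs.max(), bins + 1)
    y_edges = np.linspace(ys.min(), ys.max(), bins + 1)
    joint = np.zeros((bins, bins))
    for a, b in zip(xs, ys):
        i = min(np.searchsorted(x_edges, a, side="right") - 1, bins - 1)
        j = min(np.searchsorted(y_edges, b, side="right") - 1, bins - 1)
        joint[max(i, 0), max(j, 0)] += 1
    p = joint / n
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if p[i, j] > 0:
                mi += p[i, j] * np.log(p[i, j] / (p[i].sum() * p[:, j].sum()))
    return mi


class TestTDMI:
    def test_identical_ramp_gives_log_bins(self):
        x = np.arange(1.0, 21.0)
        assert tdmi(x, x, 0, bins=4) == pytest.approx(np.log(4), abs=1e-12)

    def test_constant_series_zero(self, rng):
        x = np.ones(20)
        y = rng.normal(0, 1, 20)
        assert tdmi(x, y, 0, bins=4) == pytest.approx(0.0, abs=1e-12)

    def test_lagged_copy_equals_zero_lag_on_overlap(self):
        x = np.arange(1.0, 21.0)
        y = np.concatenate([[0.0, 0.0], x[:-2]])  # y(t) = x(t-2)
        overlap = x[:18]
        assert tdmi(x, y, 2, bins=4) == pytest.approx(
            tdmi(overlap, overlap, 0, bins=4), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("tau", [0, 1, 3])
    def test_matches_brute_force_oracle(self, seed, tau):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(20, 51))
        bins = int(rng.integers(2, 9))
        x = rng.normal(0, 1, m)
        y = 0.5 * np.roll(x, tau) + rng.normal(0, 0.5, m)
        assert tdmi(x, y, tau, bins=bins) == pytest.approx(
            brute_force_mi(x, y, tau, bins), abs=1e-10
        )

    @given(
        xy=hnp.arrays(
            float,
            (2, 25),
            elements=st.floats(-5, 5, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_at_zero_lag_and_nonnegative(self, xy):
        x, y = xy
        a = tdmi(x, y, 0, bins=4)
        b = tdmi(y, x, 0, bins=4)
        assert a >= 0
        assert a == pytest.approx(b, abs=1e-10)

    def test_short_overlap_rejected(self):
        with pytest.raises(ValueError):
            tdmi(np.arange(5.0), np.arange(5.0), 3, bins=2)


class TestTDMIC:
    def test_noiseless_linear_is_one(self):
        x = np.arange(1.0, 21.0)
        assert tdmic(x, 2 * x + 1, 0) == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_zero(self, rng):
        assert tdmic(np.ones(20), rng.normal(0, 1, 20), 0) == 0.0

    def test_noiseless_lagged_square_even_overlap_is_one(self):
        # m=23, tau=3 -> 20-point overlap; an even split attains the bound
        x = np.arange(1.0, 24.0)
        y = np.roll(x**2, 3)
        assert tdmic(x, y, 3) == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_lagged_square_odd_overlap_near_one(self):
        # 17-point overlap only admits a 2x2 grid, which cannot split 17
        # points evenly: the attainable maximum is H(9/17, 8/17)/log 2
        x = np.arange(1.0, 21.0)
        y = np.roll(x**2, 3)
        p = 9 / 17
        bound = -(p * np.log(p) + (1 - p) * np.log(1 - p)) / np.log(2)
        assert tdmic(x, y, 3) == pytest.approx(bound, abs=1e-9)

    @pytest.mark.parametrize(
        "fn", [np.sqrt, np.exp, lambda v: -3 * v, lambda v: v**3]
    )
    def test_monotone_functional_relations_score_one(self, fn):
        x = np.linspace(0.5, 3.0, 20)
        assert tdmic(x, fn(x), 0) == pytest.approx(1.0, abs=1e-9)

    @given(
        xy=hnp.arrays(
            float,
            (2, 24),
            elements=st.floats(-10, 10, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, xy):
        v = tdmic(xy[0], xy[1], 0)
        assert 0.0 <= v <= 1.0


class TestTDCC:
    def test_self_correlation_one(self, rng):
        x = random_walk(rng, 30)
        assert tdcc(x, x, 0) == pytest.approx(1.0)

    def test_sign_flip(self, rng):
        x = random_walk(rng, 30)
        assert tdcc(x, -x, 0) == pytest.approx(-1.0)

    def test_noiseless_lag3_copy(self, rng):
        x = random_walk(rng, 40)
        y = np.roll(x, 3)
        assert tdcc(x, y, 3) == pytest.approx(1.0)

    def test_matches_numpy_pearson_on_overlap(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        for tau in (0, 2, 5):
            expected = np.corrcoef(x[: 30 - tau], y[tau:])[0, 1]
            assert tdcc(x, y, tau) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_returns_zero(self, rng):
        assert tdcc(np.ones(20), rng.normal(0, 1, 20), 0) == 0.0


class TestBestLag:
    @pytest.mark.parametrize("lag", range(7))
    def test_recovers_true_lag_noiseless(self, lag):
        rng = np.random.default_rng(42)
        x = random_walk(rng, 60)
        y = np.roll(x, lag)
        got, val = best_lag(x[6:], y[6:], 0, 6)
        assert got == lag
        assert val == pytest.approx(1.0)

    def test_identity_prefers_zero(self, rng):
        x = random_walk(rng, 30)
        got, val = best_lag(x, x, 0, 6)
        assert got == 0 and val == pytest.approx(1.0)

    def test_tie_breaks_to_min_lag(self, rng):
        x = random_walk(rng, 30)
        y = np.ones(30)  # all lags give tdcc 0
        assert best_lag(x, y, 2, 6)[0] == 2

    def test_hit_rate_non_increasing_in_noise(self):
        """More observation noise never helps lag identification."""
        sigmas = (0.0, 0.5, 1.0, 2.0)
        rates = []
        for sigma in sigmas:
            hits = 0
            for rep in range(50):
                rng = np.random.default_rng(1000 + rep)
                x = random_walk(rng, 56)
                lag = int(rng.integers(1, 7))
                y = np.roll(x, lag) + rng.normal(0, sigma, 56)
                hits += best_lag(x[6:], y[6:], 0, 6)[0] == lag
            rates.append(hits / 50)
        assert rates[0] == 1.0
        assert all(a >= b - 0.02 for a, b in zip(rates, rates[1:]))
        assert rates[-1] < rates[0]


class TestHybridRank:
    def _driver_dataset(self, seed=3):
        """Target gD is a noiseless lag-2 copy of gA; gB, gC independent noise."""
        rng = np.random.default_rng(seed)
        a = random_walk(rng, 40)
        target = np.roll(a, 2)
        b = rng.normal(0, 1, 40)
        c = rng.normal(0, 1, 40)
        return ExpressionDataset(("gA", "gB", "gC", "gD"), np.vstack([a, b, c, target]))

    def test_driver_heads_candidate_set_with_perfect_ranks(self):
        ds = self._driver_dataset()
        cfg = RunConfig(tau_max=6, L=2)
        cand = hybrid_rank(ds, 3, cfg)
        assert cand.regulator_indices[0] == 0
        assert cand.candidates[0][1] == 3  # rank 1 on all three measures
        assert cand.lags[0] == 2

    def test_L_equals_n_minus_1_returns_all(self, toy_dataset):
        cfg = RunConfig(tau_max=4, L=3)
        cand = hybrid_rank(toy_dataset, 0, cfg)
        assert sorted(cand.regulator_indices) == [1, 2, 3]

    def test_target_never_its_own_candidate(self, toy_dataset):
        cfg = RunConfig(tau_max=4, L=3)
        for k in range(toy_dataset.n_genes):
            cand = hybrid_rank(toy_dataset, k, cfg)
            assert k not in cand.regulator_indices

    @pytest.mark.parametrize("seed", range(5))
    def test_returns_exactly_L_distinct_non_target(self, seed):
        rng = np.random.default_rng(seed)
        values = np.cumsum(rng.normal(0, 0.1, (6, 30)), axis=1)
        ds = ExpressionDataset(tuple(f"g{i}" for i in range(6)), values)
        cfg = RunConfig(tau_max=3, L=2)
        cand = hybrid_rank(ds, seed % 6, cfg)
        assert len(set(cand.regulator_indices)) == 2

    def test_L_too_large_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            hybrid_rank(toy_dataset, 0, RunConfig(tau_max=3, L=4))

    def test_selector_sklearn_surface(self, rng):
        X = np.cumsum(rng.normal(0, 0.1, (30, 5)), axis=0)
        y = np.roll(X[:, 2], 1)
        sel = HybridRankSelector(L=2, tau_max=4).fit(X, y)
        assert sel.get_support().sum() == 2
        assert sel.transform(X).shape == (30, 2)
        assert 2 in sel.selected_
        params = sel.get_params()
        assert params["L"] == 2 and params["tau_max"] == 4
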