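"""The HSIC-VSIO selector: WBMS sampling, importance, frequencies, iteration."""

import numpy as np
import pytest

from specfuse import (
    KernelSpec,
    VSIOConfig,
    run_hsic_vsio,
    top_model_frequencies,
    update_weights,
    wavelength_importance,
    wbms_sample,
)
from specfuse.errors import DegenerateInputError, ParameterError, ShapeError
from specfuse.vsio import normalize_importance


class TestWbms:
    def test_unit_weight_gives_full_column(self):
        m = wbms_sample(np.array([1.0, 0.5]), 20, seed=0)
        assert m[:, 0].sum() == 20

    def test_zero_weight_gives_empty_column(self):
        m = wbms_sample(np.array([0.0, 1.0]), 20, seed=0)
        assert m[:, 0].sum() == 0

    def test_half_weight_exact_count(self):
        m = wbms_sample(np.full(3, 0.5), 1000, seed=1)
        assert (m.sum(axis=0) == 500).all()

    def test_seed_determinism(self):
        w = np.linspace(0.2, 0.9, 10)
        a = wbms_sample(w, 50, seed=42)
        b = wbms_sample(w, 50, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_all_zero_weights_hard_error(self):
        with pytest.raises(ParameterError, match="all-zero rows"):
            wbms_sample(np.zeros(4), 20, seed=0)

    def test_rows_never_empty(self, rng):
        m = wbms_sample(np.full(30, 0.2), 40, seed=3)
        assert m.any(axis=1).all()


class TestNormalizeImportance:
    def test_arithmetic(self):
        np.testing.assert_allclose(normalize_importance(np.array([2.0, 4.0])), [0.5, 1.0])

    def test_uniform_stays_uniform(self):
        np.testing.assert_allclose(normalize_importance(np.ones(3)), np.ones(3))

    def test_random_vectors(self, rng):
        t = rng.uniform(0.1, 5.0, 20)
        np.testing.assert_allclose(normalize_importance(t), t / t.max(), atol=1e-14)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_importance(np.zeros(5))


class TestTopModelFrequencies:
    def test_always_present_variable(self):
        b = np.ones((10, 2), dtype=int)
        q = top_model_frequencies(b, np.arange(10.0), sigma=0.5)
        np.testing.assert_allclose(q, [1.0, 1.0])

    def test_eq7_arithmetic(self, rng):
        # M = 1000, sigma = 0.1 -> pool of 100; a channel in 50 of them -> 0.5
        m, p = 1000, 3
        b = np.zeros((m, p), dtype=int)
        b[:, 0] = 1  # ensure no empty consideration
        scores = rng.permutation(m).astype(float)
        pool_rows = np.argsort(scores, kind="stable")[:100]
        b[pool_rows[:50], 1] = 1
        q = top_model_frequencies(b, scores, sigma=0.1)
        assert q[1] == pytest.approx(0.5)
        assert q[2] == 0.0
        assert q[0] == 1.0

    def test_pool_too_small_rejected(self):
        with pytest.raises(ParameterError):
            top_model_frequencies(np.ones((10, 2), int), np.arange(10.0), sigma=0.01)


class TestUpdateWeights:
    def test_arithmetic(self):
        np.testing.assert_allclose(
            update_weights(np.array([0.8]), np.array([0.4])), [0.6]
        )
        np.testing.assert_allclose(
            update_weights(np.array([1.0]), np.array([0.0])), [0.5]
        )

    def test_equal_inputs_fixed_point(self, rng):
        t = rng.uniform(size=8)
        np.testing.assert_allclose(update_weights(t, t), t)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            update_weights(np.ones(3), np.ones(4))


def _planted(rng, n=40, p=15, informative=(4,), slope=1.0, noise=0.3):
    """y linear in the informative channels, all others pure noise."""
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    for j in informative:
        X[:, j] = slope * y + noise * rng.normal(size=n)
    return X, y


class TestWavelengthImportance:
    def test_nonnegative(self, rng):
        X, y = _planted(rng)
        t = wavelength_importance(X, y, n_lv=5, seed=0)
        assert np.all(t >= 0)

    def test_duplicated_column_is_redundant(self, rng):
        X, y = _planted(rng, p=10, informative=(2,))
        X = np.column_stack([X, X[:, 2]])  # channel 10 duplicates channel 2
        t = wavelength_importance(X, y, n_lv=5, seed=0)
        assert abs(t[10] - 1.0) < 0.05

    def test_single_informative_channel_found(self):
        hits = 0
        for trial in range(20):
            rng = np.random.default_rng(1000 + trial)
            X, y = _planted(rng, informative=(7,), noise=0.15)
            t = wavelength_importance(X, y, n_lv=5, seed=trial)
            hits += int(np.argmax(t) == 7)
        assert hits >= 18

    def test_perfect_fit_raises(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        X = np.column_stack([y, 2 * y])
        with pytest.raises(DegenerateInputError, match="perfect"):
            wavelength_importance(X, y, n_lv=1, residual_mode="training")


class TestRunHsicVsio:
    @staticmethod
    def _cfg(**kw):
        base = dict(M=60, sigma=0.1, K=10, n_lv=5, cv_folds=5, seed=0)
        base.update(kw)
        return VSIOConfig(**base)

    def test_k_equals_p_selects_everything(self, rng):
        X, y = _planted(rng, p=12)
        res = run_hsic_vsio(X, y, self._cfg(K=12))
        np.testing.assert_array_equal(res.selected, np.arange(12))

    def test_trace_strictly_decreasing_until_last(self, rng):
        X, y = _planted(rng, n=50, p=30, informative=(3, 11, 20), noise=0.4)
        res = run_hsic_vsio(X, y, self._cfg(seed=5))
        trace = res.rmsecv_trace
        assert np.all(np.diff(trace[:-1]) < 0)

    def test_full_reproducibility(self, rng):
        X, y = _planted(rng, n=45, p=25, informative=(2, 9))
        a = run_hsic_vsio(X, y, self._cfg(seed=7))
        b = run_hsic_vsio(X, y, self._cfg(seed=7))
        for field in ("importance_raw", "importance_norm", "frequencies",
                      "weights", "rmsecv_trace", "selected", "best_model_channels"):
            np.testing.assert_array_equal(getattr(a, field), getattr(b, field))

    def test_bounded_outputs(self, rng):
        X, y = _planted(rng, n=45, p=25, informative=(2, 9))
        res = run_hsic_vsio(X, y, self._cfg(seed=3))
        assert np.all((res.frequencies >= 0) & (res.frequencies <= 1))
        assert np.all((res.weights >= 0) & (res.weights <= 1))
        assert res.selected.size == 10

    def test_k_larger_than_p_rejected(self, rng):
        X, y = _planted(rng, p=8)
        with pytest.raises(ParameterError):
            run_hsic_vsio(X, y, self._cfg(K=9))

    def test_enrichment_on_planted_signal(self):
        """Mean final weight over informative channels exceeds the noise-channel
        mean in >= 9 of 10 seeded runs (sign test, p < 0.05)."""
        informative = (3, 10, 17, 24)
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            X, y = _planted(rng, n=50, p=30, informative=informative, noise=0.5)
            res = run_hsic_vsio(X, y, self._cfg(seed=seed, K=8))
            mask = np.zeros(30, bool)
            mask[list(informative)] = True
            wins += int(res.weights[mask].mean() > res.weights[~mask].mean())
        assert wins >= 9

    def test_null_selection_is_uniform(self):
        """With y independent of X, hits of a fixed channel subset in the
        selection match the uniform-random rate (normal-approx bound)."""
        p, k_sel, n_seeds = 40, 10, 20
        subset = set(range(0, 40, 4))  # 10 fixed channels
        hits = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(3000 + seed)
            X = rng.normal(size=(45, p))
            y = rng.normal(size=45)
            res = run_hsic_vsio(X, y, self._cfg(seed=seed, K=k_sel))
            hits += len(subset & set(res.selected.tolist()))
        # hypergeometric per seed: mean 2.5, var ~1.44 -> 20 seeds: 50 +- 5.4
        assert abs(hits - 50) < 17  # ~3 sigma
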