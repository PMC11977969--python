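"""Preprocessing operators: baselines, scatter correction, smoothing, scaling."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from specfuse import (
    Modality,
    PreprocessPipeline,
    PreprocessStep,
    SpectrumSet,
    airpls_baseline,
    apply_pipeline,
    make_preset,
    minmax_scale,
    msc,
    savgol,
    snv,
)
from specfuse.errors import (
    CompatibilityError,
    DegenerateInputError,
    NumericError,
    ParameterError,
)


def _set(intens, axis=None):
    intens = np.atleast_2d(np.asarray(intens, dtype=float))
    n, p = intens.shape
    axis = np.arange(p, dtype=float) if axis is None else axis
    return SpectrumSet([f"s{i}" for i in range(n)], Modality.SERS, axis,
                       intens, np.linspace(1e-6, 1e-4, n))


class TestAirpls:
    def test_zero_spectrum_fixed_point(self):
        base, corr = airpls_baseline(np.zeros(50), lam=1e4)
        np.testing.assert_allclose(base, 0, atol=1e-12)
        np.testing.assert_allclose(corr, 0, atol=1e-12)

    def test_pure_ramp_fully_removed(self):
        # linear trends are in the null space of the second-difference penalty
        x = np.linspace(0.0, 10.0, 200)
        base, corr = airpls_baseline(x, lam=1e5)
        assert np.max(np.abs(corr)) < 0.01 * np.ptp(x)

    def test_peak_on_ramp_preserved(self):
        t = np.linspace(0, 1, 400)
        ramp = 2.0 * t
        peak = np.exp(-((t - 0.5) ** 2) / (2 * 0.01**2))
        base, corr = airpls_baseline(ramp + peak, lam=1e5)
        apex = corr[np.argmax(corr)]
        assert abs(apex - 1.0) < 0.05

    def test_baseline_stays_below_signal(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 300)
        signal = 0.5 + t + np.exp(-((t - 0.3) ** 2) / (2 * 0.02**2))
        signal += 0.7 * np.exp(-((t - 0.7) ** 2) / (2 * 0.03**2))
        signal += rng.normal(0, 0.002, t.size)
        base, _ = airpls_baseline(signal, lam=1e5)
        frac_below = np.mean(base <= signal + 0.02)
        assert frac_below > 0.95

    def test_errors(self):
        with pytest.raises(NumericError):
            airpls_baseline(np.array([1.0, np.nan, 2.0, 3.0, 4.0]))
        with pytest.raises(ParameterError):
            airpls_baseline(np.ones(20), lam=0.0)


class TestMsc:
    def test_reference_spectrum_unchanged(self, rng):
        ref = rng.normal(size=30)
        s = _set(np.vstack([ref, ref]))
        out = msc(s, reference=ref)
        np.testing.assert_allclose(out.intensities[0], ref, atol=1e-10)

    def test_affine_distortion_inverted(self, rng):
        ref = rng.normal(size=40)
        s = _set(np.vstack([ref, 2.0 * ref + 5.0]))
        out = msc(s, reference=ref)
        np.testing.assert_allclose(out.intensities[1], ref, atol=1e-10)

    def test_twenty_affine_distortions_collapse(self, rng):
        base = np.sin(np.linspace(0, 6, 80)) + 2
        rows = [rng.uniform(0.5, 2) * base + rng.uniform(-1, 1) for _ in range(20)]
        out = msc(_set(np.vstack(rows)), reference=base)
        d = out.intensities - base
        assert np.sqrt(np.mean(d**2)) < 1e-8

    def test_matches_closed_form_ols(self, rng):
        ref = rng.normal(size=25)
        x = 1.7 * ref - 0.3 + rng.normal(0, 0.1, 25)
        out = msc(_set(x), reference=ref)
        # closed-form simple regression of x on ref
        rc = ref - ref.mean()
        b = float(rc @ (x - x.mean())) / float(rc @ rc)
        a = x.mean() - b * ref.mean()
        np.testing.assert_allclose(out.intensities[0], (x - a) / b, atol=1e-10)

    def test_degenerate_slope(self, rng):
        ref = rng.normal(size=20)
        with pytest.raises(DegenerateInputError):
            msc(_set(np.zeros(20) + 3.0), reference=ref)


class TestSnv:
    def test_moments(self, rng):
        out = snv(rng.normal(2, 5, size=100))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std(ddof=1) - 1) < 1e-12

    def test_affine_invariance(self, rng):
        x = rng.normal(size=60)
        np.testing.assert_allclose(snv(3.2 * x + 7), snv(x), atol=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            snv(np.full(10, 4.2))


class TestSavgol:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(savgol(np.full(50, 3.3)), np.full(50, 3.3), atol=1e-12)

    def test_quadratic_reproduced(self):
        t = np.linspace(-1, 1, 101)
        y = 2 * t**2 - t + 0.5
        np.testing.assert_allclose(savgol(y, 11, 2), y, atol=1e-10)

    def test_noise_shrink_matches_kernel_norm(self, rng):
        # smoothing white noise shrinks its sd by the kernel l2-norm exactly
        x = rng.normal(size=20000)
        out = savgol(x, 11, 2)
        expected = np.linalg.norm(savgol_coeffs(11, 2))
        assert expected < 0.6
        assert abs(out[100:-100].std() - expected) < 0.02

    def test_window_too_large(self):
        with pytest.raises(ParameterError):
            savgol(np.ones(9), 11, 2)


class TestMinmax:
    def test_arithmetic(self):
        out = minmax_scale(_set([[1.0, 3.0, 5.0]]), mode="per-spectrum")
        np.testing.assert_allclose(out.intensities[0], [0, 0.5, 1])

    def test_idempotent(self, rng):
        s = _set(rng.uniform(size=(4, 9)))
        once = minmax_scale(s)
        twice = minmax_scale(once)
        np.testing.assert_allclose(once.intensities, twice.intensities, atol=1e-12)

    def test_per_set_uses_global_bounds(self):
        s = _set([[0.0, 1.0], [1.0, 3.0]])
        out = minmax_scale(s, mode="per-set")
        np.testing.assert_allclose(out.intensities, [[0, 1 / 3], [1 / 3, 1]])

    def test_constant_spectrum_rejected(self):
        with pytest.raises(DegenerateInputError):
            minmax_scale(_set([[2.0, 2.0, 2.0]]), mode="per-spectrum")


class TestPipeline:
    def test_empty_pipeline_identity(self, small_set):
        pipe = PreprocessPipeline([])
        cal, pred = apply_pipeline(pipe, small_set, small_set)
        np.testing.assert_array_equal(cal.intensities, small_set.intensities)
        np.testing.assert_array_equal(pred.intensities, small_set.intensities)

    def test_chain_equals_manual_sequence(self, rng):
        s = _set(rng.uniform(0.1, 1.0, size=(5, 40)))
        pipe = PreprocessPipeline(
            [PreprocessStep("SAVGOL", {"window": 7, "order": 2}), PreprocessStep("SNV")]
        )
        cal, _ = apply_pipeline(pipe, s)
        manual = np.vstack([snv(savgol(row, 7, 2)) for row in s.intensities])
        np.testing.assert_allclose(cal.intensities, manual, atol=1e-12)

    def test_msc_reference_fitted_on_calibration_only(self, rng):
        # a sentinel reference injected via params must be used for both sets
        ref = np.linspace(1.0, 2.0, 30)
        pipe = PreprocessPipeline([PreprocessStep("MSC", {"reference": ref})])
        cal = _set(rng.uniform(1, 2, size=(4, 30)))
        pred = _set(rng.uniform(5, 9, size=(3, 30)))  # very different mean
        out_cal, out_pred = apply_pipeline(pipe, cal, pred)
        for i, row in enumerate(pred.intensities):
            b, a = np.polyfit(ref, row, 1)
            np.testing.assert_allclose(out_pred.intensities[i], (row - a) / b, atol=1e-10)

    def test_per_set_minmax_bounds_from_calibration(self, rng):
        pipe = PreprocessPipeline([PreprocessStep("MINMAX", {"mode": "per-set"})])
        cal = _set(np.array([[0.0, 1.0, 2.0]]))
        pred = _set(np.array([[4.0, 5.0, 6.0]]))
        _, out_pred = apply_pipeline(pipe, cal, pred)
        # prediction values beyond calibration bounds are clipped at 1
        np.testing.assert_allclose(out_pred.intensities[0], [1.0, 1.0, 1.0])

    def test_axis_mismatch_rejected(self, small_set):
        other = _set(np.ones((2, 4)), axis=np.arange(4.0))
        with pytest.raises(CompatibilityError):
            apply_pipeline(make_preset(), small_set, other)

    def test_history_is_appended(self, rng):
        s = _set(rng.uniform(0.1, 1.0, size=(6, 30)))
        cal, _ = apply_pipeline(make_preset("sg-snv-msc"), s)
        kinds = [h.split(":")[0] for h in cal.history]
        assert kinds == ["savgol", "snv", "msc", "minmax"]
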