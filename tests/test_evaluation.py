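"""Directional-response metrics, similarity testing and stiffness fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posturesim import (MuscleParams, baseline_activation, cosine_similarity,
                        fit_stiffness, integrated_response, normalize_signed,
                        normalize_unit_max, random_similarity_null,
                        relative_stiffness, synth_torque_angle)


def make_trace(onset=500.0, T=1000.0, dt=1.0):
    t = np.arange(0.0, T + dt / 2, dt)
    return t


class TestBaseline:
    def test_constant_trace(self):
        t = make_trace()
        assert baseline_activation(t, np.full(t.size, 0.2), 500.0) == \
            pytest.approx(0.2)

    def test_window_is_strictly_pre_onset(self):
        t = make_trace()
        trace = np.where(t < 500.0, 0.2, 0.5)
        assert baseline_activation(t, trace, 500.0) == pytest.approx(0.2)

    def test_ramp_matches_analytic_mean(self):
        t = make_trace()
        trace = 1e-3 * t  # linear ramp
        # mean of the ramp over [350, 450] ms is the midpoint value
        assert baseline_activation(t, trace, 500.0) == pytest.approx(0.4)

    def test_insufficient_history_raises(self):
        t = np.arange(400.0, 1000.0)
        with pytest.raises(ValueError):
            baseline_activation(t, np.zeros(t.size), 500.0)


class TestIntegratedResponse:
    def test_zero_for_trace_at_baseline(self):
        t = make_trace()
        trace = np.full(t.size, 0.3)
        assert integrated_response(t, trace, 500.0, 0.3) == 0.0

    def test_rectangular_excess(self):
        t = make_trace()
        trace = np.full(t.size, 0.25)
        # 0.05 above baseline over the whole 200 ms window -> 0.01 s
        assert integrated_response(t, trace, 500.0, 0.20) == \
            pytest.approx(0.01, rel=1e-9)

    def test_half_sine_bump_closed_form(self):
        t = make_trace(dt=0.1)
        lo, hi = 570.0, 770.0
        peak = 0.08
        bump = np.where((t >= lo) & (t <= hi),
                        peak * np.sin(np.pi * (t - lo) / (hi - lo)), 0.0)
        got = integrated_response(t, 0.1 + bump, 500.0, 0.1)
        expected = 2 * peak * 0.2 / np.pi  # area of half sine, s
        assert got == pytest.approx(expected, abs=1e-6)

    def test_short_trace_raises(self):
        t = np.arange(0.0, 600.0)
        with pytest.raises(ValueError):
            integrated_response(t, np.zeros(t.size), 500.0, 0.0)


class TestNormalizations:
    def test_unit_max(self):
        v = np.array([7.30e-3, 3.0e-3, 0.0, -1.0e-3] + [0.0] * 8)
        out = normalize_unit_max(v)
        assert out[0] == 1.0
        assert out[1] == pytest.approx(3.0 / 7.30)
        assert out[3] == 0.0  # negative entries clipped

    def test_unit_max_scale_invariant(self):
        v = np.random.default_rng(0).uniform(0.1, 1.0, 12)
        assert np.allclose(normalize_unit_max(v), normalize_unit_max(5.0 * v))

    def test_unit_max_degenerate(self):
        with pytest.raises(ValueError):
            normalize_unit_max(np.full(12, -1.0))

    def test_signed_endpoints(self):
        v = np.linspace(2.0, 5.0, 12)
        out = normalize_signed(v)
        assert out.min() == pytest.approx(-1.0)
        assert out.max() == pytest.approx(1.0)

    @given(scale=st.floats(0.1, 10.0), shift=st.floats(-5.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_signed_affine_invariant(self, scale, shift):
        v = np.arange(12.0)
        assert np.allclose(normalize_signed(v),
                           normalize_signed(scale * v + shift), atol=1e-9)

    def test_signed_degenerate(self):
        with pytest.raises(ValueError):
            normalize_signed(np.full(12, 0.5))


class TestCosineSimilarity:
    def test_identical_vectors(self):
        v = np.random.default_rng(1).normal(size=12)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_and_opposite(self):
        a = np.array([1.0, 0.0])
        assert cosine_similarity(a, [0.0, 1.0]) == pytest.approx(0.0)
        assert cosine_similarity(a, -a) == pytest.approx(-1.0)

    def test_positive_scaling_invariance(self):
        v = np.random.default_rng(2).normal(size=12)
        assert cosine_similarity(v, 3.7 * v) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(12), np.ones(12))


class TestSimilarityNull:
    def test_mean_near_zero_and_theoretical_std(self):
        # components U[-1,1] against any reference: std ~ 1/sqrt(12) = 0.289
        ref = np.random.default_rng(3).uniform(-1, 1, 12)
        null = random_similarity_null(ref, n=100_000, seed=42)
        assert abs(null.mean) < 3 * null.std / np.sqrt(null.n) * 5
        assert null.std == pytest.approx(1 / np.sqrt(12), abs=5e-3)

    def test_cumulative_prob_at_mean(self):
        null = random_similarity_null(np.ones(12), n=10_000, seed=0)
        assert null.cumulative_prob(null.mean) == pytest.approx(0.5)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            random_similarity_null(np.ones(12), n=10)


class TestStiffnessFit:
    def test_noiseless_exact_recovery(self):
        K, B, I, C = 2.5, 0.08, 1.5e-3, -4.0
        T, th, t = synth_torque_angle(K, B, I, C, duration=1.0, dt=1e-3,
                                      noise_sd=0.0, seed=5)
        fit = fit_stiffness(T, th, 1e-3, m=72.0, g=9.80665, h=0.914)
        assert fit.K == pytest.approx(K, abs=1e-8)
        assert fit.B == pytest.approx(B, abs=1e-8)
        assert fit.I == pytest.approx(I, abs=1e-8)
        assert fit.C == pytest.approx(C, abs=1e-8)

    def test_noisy_recovery_within_three_se(self):
        K, B, I, C = 2.5, 0.08, 1.5e-3, -4.0
        sd = 0.05
        T, th, t = synth_torque_angle(K, B, I, C, duration=2.0, dt=1e-3,
                                      noise_sd=sd, seed=11)
        fit = fit_stiffness(T, th, 1e-3, m=72.0, g=9.80665, h=0.914)
        # standard error of K from the design matrix
        thd = np.gradient(th, 1e-3, edge_order=2)
        thdd = np.gradient(thd, 1e-3, edge_order=2)
        X = np.column_stack([th, thd, thdd, np.ones(th.size)])[2:-2]
        cov = sd**2 * np.linalg.inv(X.T @ X)
        assert abs(fit.K - K) < 3 * np.sqrt(cov[0, 0])
        assert fit.residual_rms == pytest.approx(sd, rel=0.2)

    def test_constant_angle_is_singular(self):
        T = np.random.default_rng(0).normal(size=100)
        with pytest.raises(np.linalg.LinAlgError):
            fit_stiffness(T, np.full(100, 3.0), 1e-3, 72.0, 9.80665, 0.914)


class TestReferenceCsv:
    def test_round_trip(self, tmp_path):
        import pandas as pd

        from posturesim.evaluation import read_reference_csv
        dirs = np.arange(0, 360, 30)
        vec = np.cos(np.deg2rad(dirs - 90.0))
        p = tmp_path / "ref.csv"
        pd.DataFrame({"direction_deg": dirs, "SOL": vec}).to_csv(p,
                                                                 index=False)
        got_dirs, vectors = read_reference_csv(p)
        assert np.array_equal(got_dirs, dirs.astype(float))
        assert np.allclose(vectors["SOL"], vec)

    def test_requires_twelve_rows(self, tmp_path):
        import pandas as pd

        from posturesim.evaluation import read_reference_csv
        p = tmp_path / "bad.csv"
        pd.DataFrame({"direction_deg": [0, 30], "SOL": [0.1, 0.2]}).to_csv(
            p, index=False)
        with pytest.raises(ValueError, match="12"):
            read_reference_csv(p)


class TestRelativeStiffness:
    @pytest.mark.parametrize("K, expected", [
        (1.17, 0.208),
        (3.73, 0.662),
        (4.55, 0.808),
    ])
    def test_reference_values(self, K, expected):
        rs = relative_stiffness(K, m=72.0, g=9.80665, h=0.914)
        assert round(rs, 3) == expected

    def test_critical_stiffness_is_unity(self):
        m, g, h = 80.0, 9.80665, 1.0
        K_deg = (m * g * h / 2.0) * np.pi / 180.0
        assert relative_stiffness(K_deg, m, g, h) == pytest.approx(1.0)
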