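"""Generators: augmentation identity, ground-truth spectra, OU statistics."""

import numpy as np
import pytest
from scipy.linalg import expm, solve_lyapunov

from lintwin import (
    MouSpec,
    NonlinearBenchmark,
    koopman_matrix,
    lowpass_filter,
    make_grouped_mode_signals,
    random_nonlinear_benchmark,
    random_stable_generator,
    simulate_mou,
    simulate_nonlinear,
)
from lintwin.connectivity import cosine_similarity_rows, upper_triangle


class TestNonlinearBenchmark:
    def test_decoupled_scalar_decays_exponentially(self):
        spec = NonlinearBenchmark(
            Cx=np.array([[-1.0]]),
            Cy=np.array([[-2.0]]),
            Cyx=np.array([[0.0]]),
            x0=np.array([1.0]),
            y0=np.array([0.0]),
            dt_sample=0.05,
            n_steps=100,
        )
        times, omega, aug = simulate_nonlinear(spec)
        assert np.allclose(omega[1], 0.0)
        # Euler at dt/100 tracks e^{-t} to first order
        assert np.allclose(omega[0], np.exp(-times), rtol=5e-3)

    def test_augmented_dimension_and_identity(self):
        spec = random_nonlinear_benchmark(dx=5, dy=10, n_steps=200, seed=0)
        _, omega, aug = simulate_nonlinear(spec)
        assert aug.shape[0] == 20
        assert omega.shape[0] == 15
        z = aug[5:10]
        assert np.max(np.abs(z - aug[:5] ** 2)) < 1e-10

    def test_unstable_spec_rejected(self):
        with pytest.raises(ValueError, match="stable"):
            NonlinearBenchmark(
                Cx=np.array([[-1.0]]),
                Cy=np.array([[0.5]]),
                Cyx=np.array([[0.0]]),
                x0=np.ones(1),
                y0=np.ones(1),
                dt_sample=0.1,
                n_steps=10,
            )

    def test_nondiagonal_cx_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            NonlinearBenchmark(
                Cx=np.array([[-1.0, 0.3], [0.0, -2.0]]),
                Cy=np.array([[-1.0]]),
                Cyx=np.zeros((1, 2)),
                x0=np.ones(2),
                y0=np.ones(1),
                dt_sample=0.1,
                n_steps=10,
            )


class TestKoopmanMatrix:
    def test_scalar_blocks_give_three_eigenvalues(self):
        spec = NonlinearBenchmark(
            Cx=np.array([[-1.5]]),
            Cy=np.array([[-0.7]]),
            Cyx=np.array([[1.0]]),
            x0=np.ones(1),
            y0=np.zeros(1),
            dt_sample=0.05,
            n_steps=10,
        )
        truth = koopman_matrix(spec)
        assert sorted(truth.eigenvalues.real) == pytest.approx([-3.0, -1.5, -0.7])

    def test_dimension_and_block_spectrum(self):
        spec = random_nonlinear_benchmark(dx=5, dy=10, seed=3)
        truth = koopman_matrix(spec)
        assert truth.K.shape == (20, 20)
        direct = np.sort_complex(np.linalg.eigvals(truth.K))
        assert np.allclose(np.sort_complex(truth.eigenvalues), direct, atol=1e-8)

    def test_generator_matches_finite_differences(self):
        # d/dt [x; z; y] == K [x; z; y] along the integrated trajectory
        spec = random_nonlinear_benchmark(dx=3, dy=4, dt_sample=0.01, n_steps=400, seed=1)
        truth = koopman_matrix(spec)
        times, _, aug = simulate_nonlinear(spec)
        deriv = np.gradient(aug, spec.dt_sample, axis=1)[:, 10:-10]
        predicted = (truth.K @ aug)[:, 10:-10]
        scale = np.max(np.abs(deriv))
        assert np.max(np.abs(deriv - predicted)) < 5e-3 * scale


class TestMou:
    def test_noiseless_matches_matrix_exponential(self):
        A = random_stable_generator(d=4, seed=2)
        x0 = np.ones(4)
        spec = MouSpec(A, 0.0, 0.1, 50, seed=0)
        times, X = simulate_mou(spec, x0=x0)
        exact = np.stack([expm(A * t) @ x0 for t in times], axis=1)
        assert np.allclose(X, exact, atol=2e-3)

    def test_scalar_stationary_variance(self):
        a, s = 1.0, 0.7
        spec = MouSpec(np.array([[-a]]), s, 0.1, 200_000, seed=5)
        _, X = simulate_mou(spec)
        assert np.var(X) == pytest.approx(s**2 / (2 * a), rel=0.05)

    def test_covariance_solves_lyapunov_equation(self):
        A = random_stable_generator(d=10, seed=0)
        spec = MouSpec(A, 1.0, 0.1, 100_000, seed=3)
        _, X = simulate_mou(spec)
        sigma = solve_lyapunov(A, -np.eye(10))
        emp = np.cov(X)
        assert np.linalg.norm(emp - sigma) / np.linalg.norm(sigma) < 0.1

    def test_error_shrinks_with_sample_size(self):
        A = random_stable_generator(d=5, seed=7)
        sigma = solve_lyapunov(A, -np.eye(5))
        errs = []
        for n in (1_000, 10_000, 100_000):
            _, X = simulate_mou(MouSpec(A, 1.0, 0.1, n, seed=11))
            errs.append(np.linalg.norm(np.cov(X) - sigma) / np.linalg.norm(sigma))
        assert errs[2] < errs[0]

    def test_bit_reproducible_under_seed(self):
        spec = MouSpec(random_stable_generator(d=3, seed=1), 1.0, 0.1, 500, seed=42)
        _, X1 = simulate_mou(spec)
        _, X2 = simulate_mou(spec)
        assert np.array_equal(X1, X2)

    def test_unstable_generator_rejected(self):
        with pytest.raises(ValueError, match="stable"):
            MouSpec(np.array([[0.1]]), 1.0, 0.1, 10)


class TestLowpass:
    def test_constant_passes_unchanged(self):
        x = np.full((2, 500), 3.7)
        assert np.allclose(lowpass_filter(x, 1.0, 0.1), x)

    def test_stopband_attenuation(self):
        dt, cutoff = 0.01, 1.0
        t = np.arange(5000) * dt
        x = np.sin(10 * cutoff * t)[None, :]
        y = lowpass_filter(x, cutoff, dt)
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert rms(y) < 0.05 * rms(x)

    def test_passband_flatness(self):
        dt, cutoff = 0.01, 1.0
        t = np.arange(20000) * dt
        x = np.sin(0.05 * cutoff * t)[None, :]
        y = lowpass_filter(x, cutoff, dt)
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert rms(y) == pytest.approx(rms(x), rel=0.02)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(np.zeros((1, 100)), cutoff=40.0, dt=0.1)


class TestGroupedModeSignals:
    def test_rank_one_signal_fully_correlated(self):
        loading = np.ones((6, 1))
        _, X, _ = make_grouped_mode_signals(
            np.array([-0.5 + 0j]), loading, ["a"] * 6, duration=2000.0, dt=0.5, seed=0
        )
        fc = np.corrcoef(X)
        assert np.all(fc > 0.999)

    def test_orthogonal_loadings_uncorrelated(self):
        loading = np.eye(3)
        _, X, _ = make_grouped_mode_signals(
            np.array([-0.5, -0.7, -0.3], dtype=complex),
            loading,
            ["a", "b", "c"],
            duration=20000.0,
            dt=0.5,
            seed=1,
        )
        fc = np.corrcoef(X)
        off = upper_triangle(fc)
        assert np.max(np.abs(off)) < 0.1

    def test_fc_matches_loading_cosine_similarity(self):
        rng = np.random.default_rng(0)
        loading = rng.standard_normal((12, 4))
        poles = np.array([-0.3 + 0.2j, -0.5 + 0j, -0.4 + 0.5j, -0.6 + 0.1j])
        dt = 0.5
        _, X, _ = make_grouped_mode_signals(
            poles, loading, ["a"] * 12, duration=10_000 * dt, dt=dt, seed=2
        )
        fc = np.corrcoef(X)
        sc = cosine_similarity_rows(loading)
        r = np.corrcoef(upper_triangle(fc), upper_triangle(sc))[0, 1]
        assert r > 0.9

    def test_unstable_pole_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_grouped_mode_signals(
                np.array([0.1 + 0j]), np.ones((2, 1)), ["a", "a"], 10.0, 0.5
            )
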