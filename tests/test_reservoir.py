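"""Reservoir construction and open/closed-loop integration."""

import numpy as np
import pytest
from scipy.linalg import expm, solve_lyapunov

from lintwin import (
    ReservoirModel,
    make_input_matrix,
    make_reservoir,
    make_ring_matrix,
    simulate_closed_loop,
    simulate_open_loop,
)
from conftest import random_stable_closed_loop


class TestRingMatrix:
    def test_two_unit_ring(self):
        W = make_ring_matrix(2, 0.5)
        assert np.array_equal(W, [[0.0, 0.5], [0.5, 0.0]])
        assert sorted(np.linalg.eigvals(W).real) == pytest.approx([-0.5, 0.5])

    def test_three_unit_ring_roots_of_unity(self):
        W = make_ring_matrix(3, 1.0)
        eig = np.sort_complex(np.linalg.eigvals(W))
        expected = np.sort_complex(np.exp(2j * np.pi * np.arange(3) / 3))
        assert np.allclose(eig, expected, atol=1e-12)

    @pytest.mark.parametrize("N,rho", [(50, 0.5), (500, 0.5), (100, 0.9)])
    def test_spectral_radius_and_sparsity(self, N, rho):
        W = make_ring_matrix(N, rho)
        assert np.count_nonzero(W) == N
        assert np.max(np.abs(np.linalg.eigvals(W))) == pytest.approx(rho, abs=1e-10)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_ring_matrix(1, 0.5)


class TestInputMatrix:
    def test_sample_standard_deviation(self):
        Win = make_input_matrix(1000, 1000, gin=1.0, seed=0)
        assert 0.995 < Win.std() < 1.005

    def test_seed_reproducibility(self):
        a = make_input_matrix(50, 3, 0.7, seed=9)
        b = make_input_matrix(50, 3, 0.7, seed=9)
        assert np.array_equal(a, b)


class TestOpenLoop:
    def test_zero_input_zero_state(self):
        model = make_reservoir(N=20, M=2, seed=0)
        traj = simulate_open_loop(model, np.zeros((2, 30)), dt_sample=0.1)
        assert np.allclose(traj.states, 0.0)

    def test_constant_input_relaxes_to_fixed_point(self):
        # W = 0: each unit relaxes to Win @ omega0 with time constant tau
        N, M, tau = 8, 2, 0.5
        Win = make_input_matrix(N, M, 1.0, seed=1)
        model = ReservoirModel(
            W=np.zeros((N, N)), Win=Win, tau=tau, rho=0.5, gin=1.0
        )
        omega0 = np.array([1.0, -0.5])
        omega = np.tile(omega0[:, None], (1, 200))
        traj = simulate_open_loop(model, omega, dt_sample=0.1, transient=0.0)
        assert np.allclose(traj.states[:, -1], Win @ omega0, rtol=1e-3)

    def test_sinusoid_low_pass_gain(self):
        # single leaky unit: steady-state amplitude gain 1/sqrt(1+(w tau)^2)
        tau, w = 1.0, 3.0
        model = ReservoirModel(
            W=np.zeros((1, 1)), Win=np.ones((1, 1)), tau=tau, rho=0.5, gin=1.0
        )
        dt = 0.02
        t = np.arange(4000) * dt
        omega = np.sin(w * t)[None, :]
        traj = simulate_open_loop(model, omega, dt, transient=0.0)
        steady = traj.states[0, 2000:]
        gain = steady.max()
        assert gain == pytest.approx(1.0 / np.sqrt(1.0 + (w * tau) ** 2), rel=2e-2)

    def test_matches_convolution_form(self, rng):
        # noiseless solution equals the exponential-kernel convolution
        N, M, tau, dt = 12, 3, 0.3, 0.05
        W = random_stable_closed_loop(N, tau, rng)
        Win = rng.standard_normal((N, M))
        model = ReservoirModel(W=W, Win=Win, tau=tau, rho=0.5, gin=1.0)
        T = 60
        omega = np.cumsum(rng.standard_normal((M, T)), axis=1) * 0.1
        traj = simulate_open_loop(model, omega, dt, transient=0.0)
        # reference: dense quadrature of Eq. r(t) = int e^{(W-I)(t-s)/tau} Win w(s) ds
        sub = 100
        h = dt / sub
        A = (W - np.eye(N)) / tau
        P = expm(A * h)
        r = np.zeros(N)
        ref = np.zeros((N, T))
        for k in range(T - 1):
            for j in range(sub):
                b = j / sub
                w = (1 - b) * omega[:, k] + b * omega[:, k + 1]
                r = P @ r + h * (Win @ w) / tau
            ref[:, k + 1] = r
        scale = np.max(np.abs(ref))
        assert np.max(np.abs(traj.states - ref)) < 1e-3 * scale

    def test_substep_and_aggregated_paths_agree(self, rng):
        model = make_reservoir(N=15, M=2, tau=0.5, seed=3)
        omega = rng.standard_normal((2, 25))
        a = simulate_open_loop(model, omega, 0.1, transient=0.0, method="aggregated")
        b = simulate_open_loop(model, omega, 0.1, transient=0.0, method="substep")
        assert np.allclose(a.states, b.states, atol=1e-10)

    def test_first_order_convergence_in_substep(self, rng):
        model = make_reservoir(N=10, M=2, tau=0.5, seed=4)
        omega = rng.standard_normal((2, 20))
        coarse = simulate_open_loop(model, omega, 0.1, transient=0.0, substeps=50)
        fine = simulate_open_loop(model, omega, 0.1, transient=0.0, substeps=200)
        finest = simulate_open_loop(model, omega, 0.1, transient=0.0, substeps=800)
        e1 = np.max(np.abs(coarse.states - finest.states))
        e2 = np.max(np.abs(fine.states - finest.states))
        assert e2 < e1 / 2.5  # ~first order: 4x substeps -> ~4x smaller error

    def test_nonfinite_input_rejected(self):
        model = make_reservoir(N=5, M=1, seed=0)
        bad = np.ones((1, 10))
        bad[0, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            simulate_open_loop(model, bad, 0.1)

    def test_transient_flagging(self):
        model = make_reservoir(N=5, M=1, seed=0)
        traj = simulate_open_loop(model, np.ones((1, 50)), 0.1, transient=2.0)
        assert traj.learning_mask.sum() == 30

    def test_stochastic_bit_reproducible(self):
        model = make_reservoir(N=10, M=1, gamma=0.5, seed=0)
        omega = np.zeros((1, 40))
        a = simulate_open_loop(model, omega, 0.1, rng=77)
        b = simulate_open_loop(model, omega, 0.1, rng=77)
        assert np.array_equal(a.states, b.states)


class TestClosedLoop:
    def test_diagonal_deterministic_decay(self):
        W = np.diag([0.5, -0.2])
        tau = 1.0
        traj = simulate_closed_loop(W, np.array([1.0, 1.0]), tau, 0.0, 0.1, 50)
        expected = np.exp(np.outer(np.diag(W) - 1.0, traj.times) / tau)
        # Euler chain at substep dt/100: first-order accurate
        assert np.allclose(traj.states, expected, rtol=5e-3)

    def test_scalar_ou_stationary_variance(self):
        # W=0, tau=1, gamma=1: stationary variance gamma^2/(2 tau (1-w)) = 0.5
        traj = simulate_closed_loop(
            np.zeros((1, 1)), np.zeros(1), 1.0, 1.0, 0.1, 200_000, rng=8
        )
        assert np.var(traj.states[0, 1000:]) == pytest.approx(0.5, rel=0.05)

    def test_covariance_matches_lyapunov_solution(self, rng):
        N, tau, gamma = 10, 1.0, 0.8
        W = random_stable_closed_loop(N, tau, rng)
        traj = simulate_closed_loop(W, np.zeros(N), tau, gamma, 0.2, 100_000, rng=5)
        drift = (W - np.eye(N)) / tau
        sigma = solve_lyapunov(drift, -((gamma / tau) ** 2) * np.eye(N))
        emp = np.cov(traj.states[:, 500:])
        assert np.linalg.norm(emp - sigma) / np.linalg.norm(sigma) < 0.1

    def test_eigenbasis_propagation_identity(self, rng):
        # the integrated trajectory equals the decoupled modal evolution
        # of the one-sample propagator: r_k = Q D^k Q^-1 r0
        N, tau, dt, sub = 30, 0.7, 0.05, 100
        W = random_stable_closed_loop(N, tau, rng)
        r0 = rng.standard_normal(N)
        traj = simulate_closed_loop(W, r0, tau, 0.0, dt, 40, substeps=sub)
        M1 = np.eye(N) + (dt / sub) * (W - np.eye(N)) / tau
        A = np.linalg.matrix_power(M1, sub)
        lam, Q = np.linalg.eig(A)
        v0 = np.linalg.solve(Q, r0.astype(complex))
        ref = np.real(Q @ (lam[:, None] ** np.arange(40)[None, :] * v0[:, None]))
        assert np.max(np.abs(traj.states - ref)) < 1e-6 * np.max(np.abs(ref))
        # and tracks the exact matrix exponential to integrator accuracy
        from scipy.linalg import expm

        exact = np.stack(
            [expm((W - np.eye(N)) * t / tau) @ r0 for t in traj.times], axis=1
        )
        assert np.max(np.abs(traj.states - exact)) < 5e-3 * np.max(np.abs(exact))

    def test_divergence_flagged_and_truncated(self):
        W = np.array([[3.0]])  # strongly unstable closed loop
        with pytest.warns(RuntimeWarning):
            traj = simulate_closed_loop(W, np.array([1.0]), 0.1, 0.0, 1.0, 50)
        assert traj.status == "diverged"
        assert traj.n_samples < 50

    def test_unstable_warns_but_runs(self):
        W = np.array([[1.2]])
        with pytest.warns(RuntimeWarning, match="stationary"):
            traj = simulate_closed_loop(W, np.array([1e-3]), 1.0, 0.0, 0.1, 20)
        assert traj.status == "ok"
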