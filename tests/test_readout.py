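"""Ridge readout, loop closure, response kernels, AR prediction."""

import numpy as np
import pytest
from scipy.linalg import expm

from lintwin import (
    ar_predict,
    close_loop,
    fit_readout,
    green_kernel,
    kernel_modes,
    make_reservoir,
    simulate_closed_loop,
    simulate_open_loop,
    train_twin,
)


class TestFitReadout:
    def test_identity_states_recover_targets(self, rng):
        Omega = rng.standard_normal((3, 6))
        assert np.allclose(fit_readout(np.eye(6), Omega, 0.0), Omega)

    def test_construct_and_recover_linear_map(self, rng):
        R = rng.standard_normal((8, 100))
        C = rng.standard_normal((3, 8))
        Wout = fit_readout(R, C @ R, 0.0)
        assert np.allclose(Wout, C, atol=1e-8)

    def test_ridge_shrinkage_monotone(self, rng):
        R = rng.standard_normal((10, 50))
        Omega = rng.standard_normal((2, 50))
        norms = [
            np.linalg.norm(fit_readout(R, Omega, beta))
            for beta in (0.0, 1.0, 100.0, 1e4)
        ]
        assert norms == sorted(norms, reverse=True)

    def test_normal_equations_satisfied(self, rng):
        R = rng.standard_normal((20, 60))
        Omega = rng.standard_normal((4, 60))
        beta = 0.3
        Wout = fit_readout(R, Omega, beta)
        lhs = Wout @ (R @ R.T + beta * np.eye(20))
        rhs = Omega @ R.T
        assert np.linalg.norm(lhs - rhs) < 1e-8 * np.linalg.norm(rhs)

    def test_rank_deficient_beta_zero_gives_min_norm(self, rng):
        # duplicate rows: RR^T singular; min-norm solution still consistent
        base = rng.standard_normal((4, 30))
        R = np.vstack([base, base])
        Omega = rng.standard_normal((2, 30))
        Wout = fit_readout(R, Omega, 0.0)
        resid = Omega - Wout @ R
        best = Omega - fit_readout(base, Omega, 0.0) @ base
        assert np.linalg.norm(resid) <= np.linalg.norm(best) + 1e-8

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            fit_readout(np.zeros((3, 10)), np.zeros((2, 11)))


class TestCloseLoop:
    def test_zero_readout_keeps_reservoir(self):
        model = make_reservoir(N=10, M=2, seed=0)
        twin = close_loop(model, np.zeros((2, 10)))
        assert np.array_equal(twin.W_tilde, model.W)

    def test_update_rank_bounded_by_observables(self, rng):
        model = make_reservoir(N=30, M=1, seed=1)
        Wout = rng.standard_normal((1, 30))
        twin = close_loop(model, Wout)
        assert np.linalg.matrix_rank(twin.W_tilde - model.W) == 1

    def test_open_closed_loop_equivalence_on_linear_teacher(self, rng):
        # teacher: 2-D damped oscillation; after learning, the autonomous
        # readout continues the signal with high fidelity
        A = np.array([[-0.1, 1.0], [-1.0, -0.1]])
        dt, T = 0.05, 400
        times = np.arange(T) * dt
        x0 = np.array([1.0, 0.0])
        omega = np.stack([expm(A * t) @ x0 for t in times], axis=1)
        model = make_reservoir(N=200, M=2, rho=0.5, tau=0.1, gin=1 / np.sqrt(2), seed=2)
        traj = simulate_open_loop(model, omega, dt, transient=0.7)
        twin = train_twin(model, traj)
        n_cont = 100
        cont_times = times[-1] + dt * np.arange(1, n_cont + 1)
        true_cont = np.stack([expm(A * t) @ x0 for t in cont_times], axis=1)
        fut = simulate_closed_loop(twin.W_tilde, twin.r_end, 0.1, 0.0, dt, n_cont + 1)
        pred = twin.Wout @ fut.states[:, 1:]
        for j in range(2):
            assert np.corrcoef(pred[j], true_cont[j])[0, 1] > 0.99

    def test_forecast_error_decreases_with_reservoir_size(self, rng):
        # 8-D mixed-oscillator teacher learned through a noisy reservoir:
        # the autonomous continuation error shrinks over the size ladder
        # 50/200/500 (capacity + noise averaging)
        from scipy.linalg import block_diag

        from lintwin import MouSpec, simulate_mou

        blocks = [
            np.array([[a, -b], [b, a]])
            for a, b in [(-0.2, 0.9), (-0.35, 1.7), (-0.15, 2.6), (-0.5, 0.4)]
        ]
        Q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        A = Q @ block_diag(*blocks) @ Q.T
        dt = 0.05
        x0 = rng.standard_normal(8)
        _, full = simulate_mou(MouSpec(A, 0.0, dt, 500, seed=0), x0=x0)
        omega, cont = full[:, :400], full[:, 400:]
        errs = []
        for N in (50, 200, 500):
            per_real = []
            for ri in range(3):
                model = make_reservoir(
                    N=N, M=8, rho=0.5, tau=0.1, gin=1 / np.sqrt(8), gamma=0.01, seed=5
                )
                traj = simulate_open_loop(
                    model, omega, dt, transient=0.7,
                    rng=np.random.default_rng([9, ri]),
                )
                twin = train_twin(model, traj)
                clean = simulate_open_loop(
                    make_reservoir(N=N, M=8, rho=0.5, tau=0.1, gin=1 / np.sqrt(8), seed=5),
                    omega, dt, transient=0.7,
                )
                fut = simulate_closed_loop(
                    twin.W_tilde, clean.states[:, -1], 0.1, 0.0, dt, 101
                )
                pred = twin.Wout @ fut.states[:, 1:]
                per_real.append(np.linalg.norm(pred - cont) / np.linalg.norm(cont))
            errs.append(np.mean(per_real))
        assert errs[1] < errs[0] and errs[2] < errs[0]


class TestGreenKernel:
    def test_zero_lag_equals_wout_win(self, rng):
        model = make_reservoir(N=20, M=3, seed=0)
        Wout = rng.standard_normal((3, 20))
        G = green_kernel(model, Wout, [0.0])
        assert np.allclose(G[0], Wout @ model.Win, atol=1e-12)

    def test_eigen_sum_matches_matrix_exponential(self, rng):
        model = make_reservoir(N=30, M=2, tau=0.4, seed=1)
        Wout = rng.standard_normal((2, 30))
        s_grid = np.linspace(0.0, 2.0, 9)
        Ge = green_kernel(model, Wout, s_grid, method="expm")
        Gs = green_kernel(model, Wout, s_grid, method="eig")
        assert np.max(np.abs(Ge - Gs)) < 1e-8

    def test_kernel_modes_sum_to_zero_lag(self, rng):
        model = make_reservoir(N=25, M=2, seed=2)
        Wout = rng.standard_normal((2, 25))
        km = kernel_modes(model, Wout)
        assert np.allclose(km.J.sum(axis=0).real, Wout @ model.Win, atol=1e-9)
        # conjugate pairing of modes for a real matrix
        assert np.allclose(np.sort(km.eigenvalues.imag), -np.sort(km.eigenvalues.imag)[::-1])

    def test_kernel_decays_for_contractive_reservoir(self, rng):
        model = make_reservoir(N=40, M=2, rho=0.5, tau=0.2, seed=3)
        Wout = rng.standard_normal((2, 40))
        s_grid = np.linspace(0.0, 3.0, 16)
        G = green_kernel(model, Wout, s_grid)
        norms = np.linalg.norm(G, axis=(1, 2))
        assert norms[-1] < 1e-2 * norms[0]


class TestArPredict:
    def test_zero_history_predicts_zero(self, rng):
        G = rng.standard_normal((5, 2, 2))
        assert np.allclose(ar_predict(G, np.arange(5) * 0.1, np.zeros((2, 10))), 0.0)

    def test_matches_readout_on_reservoir_state(self, rng):
        # AR convolution of the kernel over input history reproduces Wout r(t)
        model = make_reservoir(N=30, M=2, rho=0.5, tau=0.2, seed=4)
        dt = 0.02
        T = 600
        t = np.arange(T) * dt
        omega = np.stack([np.sin(1.3 * t), np.cos(0.7 * t)], axis=0)
        traj = simulate_open_loop(model, omega, dt, transient=0.0)
        Wout = rng.standard_normal((2, 30))
        s_grid = np.arange(0, 300) * dt  # kernel support ~ 6 s >> tau/(1-rho)
        G = green_kernel(model, Wout, s_grid)
        pred = ar_predict(G, s_grid, omega, tau=0.2)
        direct = Wout @ traj.states[:, -1]
        assert np.allclose(pred, direct, rtol=2e-2, atol=1e-3)

    def test_short_history_rejected(self, rng):
        G = rng.standard_normal((50, 2, 2))
        with pytest.raises(ValueError, match="shorter"):
            ar_predict(G, np.arange(50) * 0.1, np.zeros((2, 10)))
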