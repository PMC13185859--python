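"""Ridge readout learning, loop closure and the autoregressive kernel.

The readout is the exact ridge solution
:math:`W_{out} = \\Omega R^T (R R^T + \\beta I)^{-1}` mapping reservoir
states ``R`` to target observables ``Omega``.  Feeding the readout back
as input updates the recurrent matrix to
:math:`\\tilde W = W + W_{in} W_{out}` (a rank-``M`` update), turning
the driven reservoir into an autonomous generative model.

The same readout also defines the response kernel (Green function)

.. math:: G(s) = W_{out}\\, e^{(W - I) s / \\tau}\\, W_{in}
              = \\sum_n J_n e^{(\\lambda_n - 1) s / \\tau}

whose exponential modes make the reservoir an order-``N``
continuous-time autoregressive model
:math:`\\omega(t) = \\int_0^\\infty G(s)\\,\\omega(t - s)\\,ds`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, expm

from .reservoir import ReservoirModel, Trajectory

__all__ = [
    "TrainedTwin",
    "KernelDecomposition",
    "fit_readout",
    "training_arrays",
    "close_loop",
    "train_twin",
    "green_kernel",
    "kernel_modes",
    "ar_predict",
]


def fit_readout(R: np.ndarray, Omega: np.ndarray, beta: float = 0.0) -> np.ndarray:
    """Exact ridge solution of the readout regression.

    For ``beta > 0`` solves the normal equations
    ``Wout (R R^T + beta I) = Omega R^T`` through a symmetric
    positive-definite factorisation.  For ``beta = 0`` the minimum-norm
    least-squares solution is returned, which is the ``beta -> 0`` limit
    of the ridge estimator and remains well defined when ``R R^T`` is
    numerically rank deficient (the typical situation when a large
    reservoir is driven by a smooth low-dimensional signal).
    """
    R = np.asarray(R, dtype=float)
    Omega = np.asarray(Omega, dtype=float)
    if R.ndim != 2 or Omega.ndim != 2 or R.shape[1] != Omega.shape[1]:
        raise ValueError("R and Omega must be 2-D with equal column counts")
    if R.shape[1] < 1:
        raise ValueError("need at least one training sample")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if beta > 0:
        G = R @ R.T + beta * np.eye(R.shape[0])
        c = cho_factor(G, lower=True)
        return cho_solve(c, R @ Omega.T).T
    sol, *_ = np.linalg.lstsq(R.T, Omega.T, rcond=None)
    return sol.T


def training_arrays(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Extract ``(R, Omega)`` from an open-loop run, dropping the transient."""
    if traj.inputs is None:
        raise ValueError("trajectory has no inputs; run the reservoir in open loop")
    m = traj.learning_mask
    return traj.states[:, m], traj.inputs[:, m]


@dataclass(frozen=True)
class TrainedTwin:
    """Reservoir + learned readout: the generative digital twin.

    ``r_start`` is the reservoir state at the beginning of the learning
    window (the point from which the autonomous twin replays the
    learned signal; mode residues are referenced there), ``r_end`` the
    state at its end (where forecast continuations start).
    """

    model: ReservoirModel
    Wout: np.ndarray
    W_tilde: np.ndarray
    r_start: np.ndarray | None = None
    r_end: np.ndarray | None = None

    @property
    def tau(self) -> float:
        return self.model.tau


def close_loop(
    model: ReservoirModel, Wout: np.ndarray, r_start=None, r_end=None
) -> TrainedTwin:
    """Form the closed-loop matrix ``W_tilde = W + Win @ Wout``.

    The update has rank at most ``M`` (the number of observables).
    """
    Wout = np.asarray(Wout, dtype=float)
    if Wout.shape != (model.M, model.N):
        raise ValueError(f"Wout must have shape (M={model.M}, N={model.N})")
    W_tilde = model.W + model.Win @ Wout
    return TrainedTwin(
        model=model, Wout=Wout, W_tilde=W_tilde, r_start=r_start, r_end=r_end
    )


def train_twin(model: ReservoirModel, traj: Trajectory, beta: float = 0.0) -> TrainedTwin:
    """Fit the readout on an open-loop trajectory and close the loop."""
    R, Omega = training_arrays(traj)
    Wout = fit_readout(R, Omega, beta=beta)
    return close_loop(
        model, Wout, r_start=R[:, 0].copy(), r_end=traj.states[:, -1].copy()
    )


# ---------------------------------------------------------------------------
# response kernel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelDecomposition:
    """Eigen-modes of the response kernel: ``G(s) = sum_n J_n e^{(l_n-1)s/tau}``."""

    eigenvalues: np.ndarray  # (N,) complex
    J: np.ndarray  # (N, M, M) rank-1 complex matrices
    tau: float


def kernel_modes(model: ReservoirModel, Wout: np.ndarray) -> KernelDecomposition:
    """Rank-1 kernel weights ``J_n = Wout |Q_n><Q_n^-1| Win``.

    Requires a diagonalisable reservoir matrix; the sum of all ``J_n``
    equals ``Wout @ Win`` (the ``s = 0`` kernel value).
    """
    lam, Q = np.linalg.eig(model.W)
    cond = np.linalg.cond(Q)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"reservoir matrix is numerically defective (eigenvector cond {cond:.3g}); "
            "use the matrix-exponential kernel path instead"
        )
    Qi = np.linalg.inv(Q)
    left = np.asarray(Wout, dtype=complex) @ Q  # (M, N)
    right = Qi @ model.Win.astype(complex)  # (N, M)
    J = left.T[:, :, None] * right[:, None, :]  # (N, M, M)
    return KernelDecomposition(eigenvalues=lam, J=J, tau=model.tau)


def green_kernel(
    model: ReservoirModel,
    Wout: np.ndarray,
    s_grid: np.ndarray,
    method: str = "expm",
) -> np.ndarray:
    """Evaluate the response kernel ``G(s)`` on a grid of lags.

    ``method="expm"`` uses the matrix exponential directly (always
    available); ``method="eig"`` sums the exponential eigen-modes and
    requires a diagonalisable ``W``.  Both paths agree to numerical
    precision, and ``G(0) = Wout @ Win`` exactly.
    """
    s_grid = np.atleast_1d(np.asarray(s_grid, dtype=float))
    M = model.M
    out = np.empty((s_grid.size, M, M))
    if method == "eig":
        km = kernel_modes(model, Wout)
        phases = np.exp(
            s_grid[:, None] * ((km.eigenvalues - 1.0) / model.tau)[None, :]
        )  # (S, N)
        return np.einsum("sn,njk->sjk", phases, km.J).real
    if method != "expm":
        raise ValueError(f"unknown method {method!r}")
    A = (model.W - np.eye(model.N)) / model.tau
    for i, s in enumerate(s_grid):
        out[i] = np.asarray(Wout) @ expm(A * s) @ model.Win
    return out


def ar_predict(
    G: np.ndarray, s_grid: np.ndarray, omega_history: np.ndarray, tau: float = 1.0
) -> np.ndarray:
    """One-sample autoregressive prediction by kernel convolution.

    ``G`` has shape ``(S, M, M)`` on the lag grid ``s_grid`` (uniform,
    ascending, starting at 0); ``omega_history`` has shape ``(M, T)``
    with the most recent sample last.  Returns
    ``(1/tau) int G(s) omega(t - s) ds`` evaluated by the trapezoidal
    rule, which approximates the readout's output at the final time.
    The ``1/tau`` Jacobian comes from the change of variables in the
    exact solution of the driven dynamics; the kernel itself is kept in
    the conventional form ``G(0) = Wout @ Win``.
    """
    G = np.asarray(G)
    s_grid = np.asarray(s_grid, dtype=float)
    omega_history = np.asarray(omega_history, dtype=float)
    S = s_grid.size
    if omega_history.shape[1] < S:
        raise ValueError(
            f"history of {omega_history.shape[1]} samples shorter than "
            f"kernel support ({S} lags)"
        )
    ds = s_grid[1] - s_grid[0]
    if not np.allclose(np.diff(s_grid), ds):
        raise ValueError("s_grid must be uniform")
    # omega at lags s_grid: reversed tail of the history
    lagged = omega_history[:, -1 : -S - 1 : -1]  # (M, S)
    integrand = np.einsum("sjk,ks->js", G, lagged)
    w = np.full(S, ds)
    w[0] = w[-1] = 0.5 * ds
    return (integrand @ w) / tau
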