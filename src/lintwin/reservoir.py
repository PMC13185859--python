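"""Fixed linear reservoirs and their open- and closed-loop dynamics.

A linear recurrent network (lRNN) with state :math:`r(t)` obeys

.. math:: \\tau \\dot r = W r + W_{in}\\,\\omega(t) - r + \\eta(t)

where ``W`` is a fixed ring-connectivity matrix with spectral radius
``rho``, ``Win`` couples the ``M`` observed channels into the ``N``
units, and ``eta`` is optional unit-wise white noise of intensity
``gamma``.  In closed loop the input is replaced by the network's own
readout, giving the autonomous dynamics
:math:`\\tau \\dot r = (\\tilde W - I) r + \\eta` with
:math:`\\tilde W = W + W_{in} W_{out}` — a multivariate
Ornstein–Uhlenbeck process when ``gamma > 0``.

Integration uses the Euler–Maruyama chain on a sub-step grid of
``substeps`` steps per sampling interval (default 100).  Because the
dynamics are linear, the chain over one sampling interval is itself an
affine Gaussian map; the default ``"aggregated"`` method pre-computes
that map (state propagator, two input quadrature matrices for linearly
interpolated inputs, and the exact accumulated noise covariance) and
advances one full sample per iteration.  Its law is identical to the
step-by-step chain; the ``"substep"`` method performs the literal loop
and is kept as an independent reference path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ReservoirModel",
    "Trajectory",
    "make_ring_matrix",
    "make_input_matrix",
    "make_reservoir",
    "simulate_open_loop",
    "simulate_closed_loop",
]

#: state-norm ceiling beyond which a trajectory is declared divergent
DIVERGENCE_GUARD = 1e8


def make_ring_matrix(N: int, rho: float) -> np.ndarray:
    """Ring (cyclic shift) coupling matrix with spectral radius ``rho``.

    The only non-zero entries are ``W[i, i+1] = W[N-1, 0] = rho``, so the
    matrix is ``rho`` times a cyclic permutation and all eigenvalues lie
    on the circle of radius ``rho``.
    """
    if N < 2:
        raise ValueError(f"ring reservoir needs N >= 2, got {N}")
    if rho <= 0:
        raise ValueError("spectral radius rho must be positive")
    W = np.zeros((N, N))
    idx = np.arange(N - 1)
    W[idx, idx + 1] = rho
    W[N - 1, 0] = rho
    return W


def make_input_matrix(
    N: int, M: int, gin: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """I.i.d. Gaussian input couplings with standard deviation ``gin``."""
    if gin <= 0:
        raise ValueError("input scale gin must be positive")
    rng = np.random.default_rng(seed)
    return gin * rng.standard_normal((N, M))


@dataclass(frozen=True)
class ReservoirModel:
    """A fixed reservoir: coupling matrices plus dynamical constants.

    Parameters mirror the standard echo-state construction: ``rho`` is
    the spectral radius used to build the ring matrix ``W`` (``rho < 1``
    gives integrable response kernels), ``tau`` the unit time constant
    in seconds, ``gin`` the input-coupling scale and ``gamma`` the
    endogenous white-noise intensity.
    """

    W: np.ndarray
    Win: np.ndarray
    tau: float
    rho: float
    gin: float
    gamma: float = 0.0
    seed: int = 0

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def M(self) -> int:
        return self.Win.shape[1]

    def __post_init__(self):
        if self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if self.Win.shape[0] != self.W.shape[0]:
            raise ValueError("Win must have N rows")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


def make_reservoir(
    N: int,
    M: int,
    rho: float = 0.5,
    tau: float = 1.0,
    gin: float = 1.0,
    gamma: float = 0.0,
    seed: int = 0,
) -> ReservoirModel:
    """Build the standard ring reservoir with Gaussian input couplings."""
    W = make_ring_matrix(N, rho)
    Win = make_input_matrix(N, M, gin, seed=seed)
    return ReservoirModel(W=W, Win=Win, tau=tau, rho=rho, gin=gin, gamma=gamma, seed=seed)


@dataclass
class Trajectory:
    """Uniformly sampled trajectory of reservoir states.

    ``states`` has shape ``(N, T)``; ``inputs`` holds the driving
    observables for open-loop runs (``None`` for autonomous runs).
    Samples with ``times < transient`` are flagged for exclusion from
    readout learning; ``status`` is ``"diverged"`` when the state norm
    exceeded the overflow guard, in which case the trajectory is
    truncated at the last finite sample.
    """

    times: np.ndarray
    states: np.ndarray
    inputs: Optional[np.ndarray] = None
    dt: float = 1.0
    transient: float = 0.0
    status: str = "ok"

    @property
    def learning_mask(self) -> np.ndarray:
        return self.times >= self.transient

    @property
    def n_samples(self) -> int:
        return self.states.shape[1]


# ---------------------------------------------------------------------------
# Euler–Maruyama sample-interval aggregation
# ---------------------------------------------------------------------------


def _one_step_matrix(W_drift: np.ndarray, h: float) -> np.ndarray:
    # single Euler sub-step propagator  r -> (I + h A) r
    return np.eye(W_drift.shape[0]) + h * W_drift


def _chain_propagator(M1: np.ndarray, substeps: int) -> np.ndarray:
    return np.linalg.matrix_power(M1, substeps)


def _input_quadrature(
    M1: np.ndarray, Win: np.ndarray, tau: float, h: float, substeps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate input maps for one sampling interval.

    With linear interpolation of the input between samples, the chained
    sub-steps give ``r_{k+1} = A r_k + B0 w_k + B1 w_{k+1}``; this
    returns ``(B0, B1)``.
    """
    C = (h / tau) * Win
    B0 = np.zeros_like(Win)
    B1 = np.zeros_like(Win)
    for j in range(substeps - 1, -1, -1):
        b = j / substeps
        B0 = B0 + (1.0 - b) * C
        B1 = B1 + b * C
        if j > 0:
            C = M1 @ C
    return B0, B1


def _chain_noise_cov(M1: np.ndarray, var_sub: float, substeps: int) -> np.ndarray:
    """Covariance of the accumulated sub-step noise over one interval.

    Exact for the Euler–Maruyama chain: each sub-step injects isotropic
    noise of variance ``var_sub`` which is then propagated by the
    remaining sub-steps.  Computed by binary composition, so the cost is
    logarithmic in ``substeps``.
    """
    n = M1.shape[0]
    # (P, S) for a block of k sub-steps: r -> P r + xi, cov(xi) = S
    cur = (M1, var_sub * np.eye(n))
    acc: tuple[np.ndarray, np.ndarray] | None = None
    k = substeps
    while k:
        if k & 1:
            if acc is None:
                acc = cur
            else:
                # apply `cur` after `acc`
                acc = (cur[0] @ acc[0], cur[0] @ acc[1] @ cur[0].T + cur[1])
        k >>= 1
        if k:
            cur = (cur[0] @ cur[0], cur[0] @ cur[1] @ cur[0].T + cur[1])
    assert acc is not None
    return acc[1]


def _noise_factor(S: np.ndarray) -> np.ndarray:
    # robust matrix square root of the (PSD) accumulated noise covariance
    S = 0.5 * (S + S.T)
    try:
        return np.linalg.cholesky(S + 1e-300 * np.eye(S.shape[0]))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(S)
        return V * np.sqrt(np.clip(w, 0.0, None))


# ---------------------------------------------------------------------------
# open loop
# ---------------------------------------------------------------------------


def simulate_open_loop(
    model: ReservoirModel,
    omega: np.ndarray,
    dt_sample: float,
    transient: float = 20.0,
    substeps: int = 100,
    rng: int | np.random.Generator | None = None,
    method: str = "aggregated",
) -> Trajectory:
    """Drive the reservoir with the observables ``omega`` (shape M x T).

    The state starts at zero and is integrated with the Euler–Maruyama
    scheme at sub-step ``dt_sample / substeps``, linearly interpolating
    the input between samples.  When ``model.gamma > 0`` each unit also
    receives independent white noise.  Samples earlier than
    ``transient`` seconds are flagged for exclusion from learning.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != model.M:
        raise ValueError(f"omega must have shape (M={model.M}, T)")
    if not np.all(np.isfinite(omega)):
        raise ValueError("omega contains non-finite values")
    if model.rho >= 1.0:
        import warnings

        warnings.warn(
            "spectral radius >= 1: echo-state property not guaranteed",
            RuntimeWarning,
            stacklevel=2,
        )
    N, T = model.N, omega.shape[1]
    h = dt_sample / substeps
    W_drift = (model.W - np.eye(N)) / model.tau
    gamma = model.gamma
    gen = np.random.default_rng(model.seed if rng is None else rng)
    times = np.arange(T) * dt_sample
    states = np.zeros((N, T))

    if method == "substep":
        r = np.zeros(N)
        sq = gamma * np.sqrt(h) / model.tau
        for k in range(T - 1):
            for j in range(substeps):
                b = j / substeps
                w = (1.0 - b) * omega[:, k] + b * omega[:, k + 1]
                r = r + h * (W_drift @ r + model.Win @ w / model.tau)
                if gamma > 0:
                    r = r + sq * gen.standard_normal(N)
            states[:, k + 1] = r
        return Trajectory(times, states, omega, dt_sample, transient)

    if method != "aggregated":
        raise ValueError(f"unknown method {method!r}")

    M1 = _one_step_matrix(W_drift, h)
    A = _chain_propagator(M1, substeps)
    B0, B1 = _input_quadrature(M1, model.Win, model.tau, h, substeps)
    drive = B0 @ omega[:, :-1] + B1 @ omega[:, 1:]
    if gamma > 0:
        S = _chain_noise_cov(M1, gamma**2 * h / model.tau**2, substeps)
        drive = drive + _noise_factor(S) @ gen.standard_normal((N, T - 1))
    r = np.zeros(N)
    for k in range(T - 1):
        r = A @ r + drive[:, k]
        states[:, k + 1] = r
    return Trajectory(times, states, omega, dt_sample, transient)


# ---------------------------------------------------------------------------
# closed loop
# ---------------------------------------------------------------------------


def simulate_closed_loop(
    W_tilde: np.ndarray,
    r0: np.ndarray,
    tau: float,
    gamma: float,
    dt_sample: float,
    n_samples: int,
    rng: int | np.random.Generator | None = None,
    substeps: int = 100,
    method: str = "aggregated",
) -> Trajectory:
    """Autonomous (optionally stochastic) run under the learned matrix.

    Integrates :math:`\\tau dr = (\\tilde W - I) r\\,dt + d\\eta` from
    ``r0`` for ``n_samples`` samples.  With ``gamma = 0`` this is the
    deterministic relaxation; otherwise a multivariate OU process.  A
    trajectory whose norm exceeds the overflow guard is truncated and
    returned with ``status="diverged"``.
    """
    W_tilde = np.asarray(W_tilde, dtype=float)
    N = W_tilde.shape[0]
    r0 = np.asarray(r0, dtype=float).reshape(N)
    h = dt_sample / substeps
    W_drift = (W_tilde - np.eye(N)) / tau
    ev_max = np.max(np.linalg.eigvals(W_drift).real)
    if ev_max >= 0:
        import warnings

        warnings.warn(
            f"closed-loop drift has max Re eigenvalue {ev_max:.3g} >= 0; "
            "stationary statistics do not exist",
            RuntimeWarning,
            stacklevel=2,
        )
    gen = np.random.default_rng(rng)
    times = np.arange(n_samples) * dt_sample
    states = np.zeros((N, n_samples))
    states[:, 0] = r0

    if method == "substep":
        r = r0.copy()
        sq = gamma * np.sqrt(h) / tau
        status = "ok"
        for k in range(1, n_samples):
            for _ in range(substeps):
                r = r + h * (W_drift @ r)
                if gamma > 0:
                    r = r + sq * gen.standard_normal(N)
            if not np.all(np.isfinite(r)) or np.linalg.norm(r) > DIVERGENCE_GUARD:
                return Trajectory(
                    times[:k], states[:, :k], None, dt_sample, 0.0, "diverged"
                )
            states[:, k] = r
        return Trajectory(times, states, None, dt_sample, 0.0, status)

    if method != "aggregated":
        raise ValueError(f"unknown method {method!r}")

    M1 = _one_step_matrix(W_drift, h)
    A = _chain_propagator(M1, substeps)
    L = None
    if gamma > 0:
        S = _chain_noise_cov(M1, gamma**2 * h / tau**2, substeps)
        L = _noise_factor(S)
        noise = L @ gen.standard_normal((N, n_samples - 1))
    r = r0.copy()
    for k in range(1, n_samples):
        r = A @ r
        if L is not None:
            r = r + noise[:, k - 1]
        if not np.all(np.isfinite(r)) or np.linalg.norm(r) > DIVERGENCE_GUARD:
            return Trajectory(times[:k], states[:, :k], None, dt_sample, 0.0, "diverged")
        states[:, k] = r
    return Trajectory(times, states, None, dt_sample, 0.0, "ok")
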