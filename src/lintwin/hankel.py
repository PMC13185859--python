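"""Hankel dynamic mode decomposition (delay-embedded DMD).

Reference spectral estimator used for comparison with the stochastic
reservoir route.  The observations are stacked into a block-Hankel
matrix of memory length ``q`` (columns are delay-embedded states, the
first block-row the raw observations); a best-fit linear one-step map
is estimated on a rank-truncated SVD basis of the embedded snapshots,
and its eigenvalues are mapped to continuous-time generator poles via
the principal branch of the logarithm, ``sigma = log(lambda) / dt``.

Known limitation: frequencies beyond the Nyquist rate alias into the
principal branch, and heavy low-pass filtering drives the estimated
discrete eigenvalues toward the unit circle, collapsing the recovered
decay rates toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HankelConfig", "DmdResult", "build_hankel", "hdmd_spectrum"]


@dataclass(frozen=True)
class HankelConfig:
    """Delay length ``q``, retained SVD energy and sampling interval."""

    q: int = 5
    energy: float = 0.99999
    dt: float = 1.0

    def __post_init__(self):
        if self.q < 1:
            raise ValueError("memory length q must be >= 1")
        if not 0 < self.energy <= 1:
            raise ValueError("energy must lie in (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def build_hankel(omega: np.ndarray, q: int) -> np.ndarray:
    """Block-Hankel (time-delay) matrix of memory length ``q``.

    Column ``k`` stacks ``omega(t_k), ..., omega(t_{k+q-1})``; the
    result has shape ``(q M, K_total - q + 1)``.
    """
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    M, K_total = omega.shape
    if K_total < q + 1:
        raise ValueError(f"series of {K_total} samples too short for q={q}")
    K = K_total - q + 1
    H = np.empty((q * M, K))
    for j in range(q):
        H[j * M : (j + 1) * M, :] = omega[:, j : j + K]
    return H


@dataclass(frozen=True)
class DmdResult:
    """Spectrum of the reduced one-step operator.

    ``discrete_eigs`` are eigenvalues of the rank-``r`` operator;
    ``poles`` are the generator estimates ``log(lambda) / dt``
    (principal branch).
    """

    discrete_eigs: np.ndarray
    poles: np.ndarray
    reduced_operator: np.ndarray
    rank: int


def hdmd_spectrum(omega: np.ndarray, config: HankelConfig) -> DmdResult:
    """Estimate generator poles by DMD on the delay embedding.

    The embedded snapshots ``H0`` (columns ``1..K-1`` of the Hankel
    matrix) and ``H1`` (columns ``2..K``) define the best-fit map
    ``H1 ~= K H0``; the operator is represented on the leading ``r``
    left singular vectors of ``H0``, with ``r`` the smallest rank
    retaining the configured fraction of squared singular-value energy.
    """
    H = build_hankel(omega, config.q)
    if np.allclose(H, H[:, :1]):
        # constant (or zero-variance) series: single unit eigenvalue
        if np.ptp(H) == 0 and np.allclose(H, 0):
            raise ValueError("zero-variance data: DMD spectrum undefined")
        return DmdResult(
            discrete_eigs=np.array([1.0 + 0j]),
            poles=np.array([0.0 + 0j]),
            reduced_operator=np.array([[1.0 + 0j]]),
            rank=1,
        )
    H0, H1 = H[:, :-1], H[:, 1:]
    U, s, Vt = np.linalg.svd(H0, full_matrices=False)
    energy = np.cumsum(s**2) / np.sum(s**2)
    r = int(np.searchsorted(energy, config.energy) + 1)
    r = min(r, s.size)
    Ur, sr, Vr = U[:, :r], s[:r], Vt[:r, :].T
    A_red = Ur.T @ H1 @ Vr / sr[None, :]
    lam = np.linalg.eigvals(A_red)
    with np.errstate(divide="ignore", invalid="ignore"):
        poles = np.log(lam.astype(complex)) / config.dt
    return DmdResult(discrete_eigs=lam, poles=poles, reduced_operator=A_red, rank=r)
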