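"""Mode decomposition of the learned matrix: poles, relevance, spectra.

Diagonalising the learned matrix
:math:`\\tilde W = \\tilde Q \\tilde\\Lambda \\tilde Q^{-1}` decouples
the autonomous dynamics into modes
:math:`v_k(t) = v_k(0) e^{(\\tilde\\lambda_k - 1) t / \\tau}` whose
Laplace poles are :math:`\\sigma_k = (\\tilde\\lambda_k - 1)/\\tau`:
the real part is the decay rate (1/s), the imaginary part the angular
frequency (rad/s).  The observables are a linear combination
:math:`\\omega(t) = \\Xi v(t)` with :math:`\\Xi = W_{out} \\tilde Q`,
so the average magnitude of a column of ``Xi`` measures how much a mode
contributes to the reconstruction — its *relevance*.  Only a small
number of slow modes typically carries relevance appreciably different
from zero, which is what makes the trained network an interpretable,
low-order surrogate of the observed system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import linregress

from .readout import TrainedTwin

__all__ = [
    "ModeDecomposition",
    "RelevanceProfile",
    "FrequencyVector",
    "decompose",
    "relevance",
    "count_relevant",
    "frequency_vector",
    "spectrum_regression",
    "match_poles",
    "leading_poles",
]


def _sort_modes(lam: np.ndarray) -> np.ndarray:
    """Descending real part; ties broken by ascending |Im|."""
    return np.lexsort((np.abs(lam.imag), -lam.real))


@dataclass(frozen=True)
class ModeDecomposition:
    """Eigen-decomposition of a learned matrix, sorted slowest-first.

    Eigenvector scaling is a gauge freedom: any column rescaling of
    ``Q`` leaves the dynamics invariant while rescaling the columns of
    ``Xi``.  When a reference state ``r0`` is available the *amplitude
    gauge* is used: each eigenvector is scaled so its mode coordinate
    equals 1 at ``r0`` (``v0 = 1``).  In this gauge ``|Xi[j, k]]`` is
    the magnitude of the Laplace residue of mode ``k`` in observable
    ``j`` — its actual contribution amplitude to the reconstructed
    signal — which is the scale on which mode relevance is comparable
    across modes.  Without ``r0`` the columns keep unit norm.
    """

    eigenvalues: np.ndarray  # (N,) eigenvalues of W_tilde
    Q: np.ndarray  # (N, N) right eigenvectors (columns)
    Xi: np.ndarray  # (M, N) mode-to-observable map Wout @ Q
    v0: np.ndarray | None  # (N,) mode coordinates of r0 (all 1 in amplitude gauge)
    tau: float
    cond_Q: float = np.nan
    gauge: str = "unit"

    @property
    def poles(self) -> np.ndarray:
        """Laplace poles ``sigma_k = (lambda_k - 1) / tau`` (1/s)."""
        return (self.eigenvalues - 1.0) / self.tau


def decompose(
    twin: TrainedTwin | None = None,
    r0: np.ndarray | None = None,
    *,
    W_tilde: np.ndarray | None = None,
    Wout: np.ndarray | None = None,
    tau: float | None = None,
    gauge: str = "amplitude",
    cond_guard: float = 1e10,
) -> ModeDecomposition:
    """Eigen-decompose the closed-loop matrix of a trained twin.

    Either pass a :class:`TrainedTwin` or the raw ``(W_tilde, Wout,
    tau)`` triple.  ``r0`` defaults to the reservoir state at the start
    of the learning window (where the autonomous replica reproduces the
    learned signal), when the twin carries one.  With
    ``gauge="amplitude"`` (default) eigenvectors are rescaled so each
    mode coordinate is 1 at ``r0``; ``gauge="unit"`` keeps unit-norm
    columns.  A warning with the eigenvector condition number is
    emitted for near-defective matrices.
    """
    if twin is not None:
        W_tilde, Wout, tau = twin.W_tilde, twin.Wout, twin.tau
        if r0 is None:
            r0 = twin.r_start if twin.r_start is not None else twin.r_end
    if W_tilde is None or Wout is None or tau is None:
        raise ValueError("pass a TrainedTwin or all of (W_tilde, Wout, tau)")
    lam, Q = np.linalg.eig(np.asarray(W_tilde))
    order = _sort_modes(lam)
    lam, Q = lam[order], Q[:, order]
    cond = np.linalg.cond(Q)
    if cond > cond_guard:
        warnings.warn(
            f"near-defective learned matrix: eigenvector condition number {cond:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
    v0 = None
    used_gauge = "unit"
    if r0 is not None:
        v0 = np.linalg.solve(Q, np.asarray(r0, dtype=complex))
        if gauge == "amplitude":
            # rescale columns so every mode coordinate of r0 equals 1;
            # modes unexcited at r0 keep zero amplitude columns
            Q = Q * v0[None, :]
            v0 = np.where(np.abs(v0) > 0, 1.0 + 0.0j, 0.0j)
            used_gauge = "amplitude"
        elif gauge != "unit":
            raise ValueError(f"unknown gauge {gauge!r}")
    Xi = np.asarray(Wout) @ Q
    return ModeDecomposition(
        eigenvalues=lam, Q=Q, Xi=Xi, v0=v0, tau=tau, cond_Q=cond, gauge=used_gauge
    )


@dataclass(frozen=True)
class RelevanceProfile:
    """Per-mode contribution scores averaged over observables.

    ``absolute`` is the observable-averaged magnitude of the mode's
    column of ``Xi``; ``residue`` additionally weights by the mode
    coordinate ``v_k(0)`` of the reference state.  In the amplitude
    gauge (the default of :func:`decompose`) the two coincide and both
    equal the observable-averaged Laplace-residue magnitude.  The mask
    marks modes above ``threshold_fraction`` of the maximum relevance.
    """

    absolute: np.ndarray
    residue: np.ndarray | None
    threshold_fraction: float

    @property
    def relevant_mask(self) -> np.ndarray:
        mx = self.absolute.max(initial=0.0)
        return self.absolute > self.threshold_fraction * mx


def relevance(
    decomp: ModeDecomposition,
    channels: np.ndarray | None = None,
    threshold_fraction: float = 0.05,
) -> RelevanceProfile:
    """Observable-averaged mode relevance, optionally over a channel subset."""
    Xi = decomp.Xi
    if channels is not None:
        channels = np.asarray(channels)
        if channels.size == 0:
            raise ValueError("channel subset must be nonempty")
        Xi = Xi[channels, :]
    absolute = np.mean(np.abs(Xi), axis=0)
    residue = None
    if decomp.v0 is not None:
        residue = np.mean(np.abs(Xi * decomp.v0[None, :]), axis=0)
    return RelevanceProfile(absolute, residue, threshold_fraction)


def count_relevant(
    profile: RelevanceProfile | np.ndarray,
    threshold_fraction: float = 0.05,
    pair_convention: str = "both",
) -> int:
    """Number of modes with relevance above a fraction of the maximum.

    Conjugate pairs contribute two counts by default
    (``pair_convention="both"``); with ``"single"`` each above-threshold
    conjugate pair is counted once (real modes still count once).
    ``pair_convention="single"`` assumes the profile is aligned with a
    decomposition and is only available when one is passed via
    :class:`RelevanceProfile` produced from it.
    """
    values = profile.absolute if isinstance(profile, RelevanceProfile) else np.asarray(profile)
    if values.size == 0 or values.max(initial=0.0) == 0.0:
        return 0
    mask = values > threshold_fraction * values.max()
    if pair_convention == "both":
        return int(mask.sum())
    raise ValueError(f"unknown pair convention {pair_convention!r}")


@dataclass(frozen=True)
class FrequencyVector:
    """Relevance-weighted histogram of mode frequencies for one area."""

    bin_edges: np.ndarray
    weights: np.ndarray
    area_label: object = None

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def frequency_vector(
    decomp: ModeDecomposition,
    channels: np.ndarray | None = None,
    im_resolution: float = 0.01,
    bin_edges: np.ndarray | None = None,
    threshold_fraction: float = 0.05,
    area_label: object = None,
) -> FrequencyVector:
    """Spectral fingerprint of a channel group.

    Histogram of the pole imaginary parts of the relevant modes, each
    counted with multiplicity equal to the mode's absolute relevance
    averaged over the group's channels.  Total weight equals the summed
    relevance of the binned modes.  Pass shared ``bin_edges`` to make
    vectors from different decompositions comparable.
    """
    if im_resolution <= 0:
        raise ValueError("im_resolution must be positive")
    prof = relevance(decomp, channels, threshold_fraction)
    mask = prof.relevant_mask
    freqs = decomp.poles.imag[mask]
    w = prof.absolute[mask]
    if bin_edges is None:
        lo = np.floor(freqs.min(initial=0.0) / im_resolution) - 1
        hi = np.ceil(freqs.max(initial=0.0) / im_resolution) + 1
        bin_edges = np.arange(lo, hi + 1) * im_resolution
    weights, _ = np.histogram(freqs, bins=bin_edges, weights=w)
    return FrequencyVector(np.asarray(bin_edges), weights, area_label)


def spectrum_regression(
    poles: np.ndarray,
    mask: np.ndarray | None = None,
    use_abs_im: bool = True,
    response: str = "re",
) -> dict:
    """Linear fit between the real and imaginary parts of relevant poles.

    By default regresses ``Re sigma`` on ``|Im sigma|`` over the
    relevant poles in the closed upper half-plane (the signed spectrum
    is conjugate-symmetric, so signed ``Im`` carries no extra
    information).  Returns ``slope``, ``intercept`` and ``r_squared``.
    Set ``response="im"`` to swap predictor and response.
    """
    poles = np.asarray(poles, dtype=complex)
    if mask is not None:
        poles = poles[np.asarray(mask, dtype=bool)]
    poles = poles[poles.imag >= 0]
    if poles.size < 3:
        raise ValueError("need at least 3 relevant upper-half-plane poles")
    im = np.abs(poles.imag) if use_abs_im else poles.imag
    re = poles.real
    x, y = (im, re) if response == "re" else (re, im)
    if np.ptp(x) == 0:
        # degenerate predictor: all mass at one frequency
        return {"slope": 0.0, "intercept": float(np.mean(y)), "r_squared": 0.0}
    fit = linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
    }


# ---------------------------------------------------------------------------
# pole comparison helpers
# ---------------------------------------------------------------------------


def match_poles(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Optimal one-to-one assignment of estimated to true poles.

    Minimises the total absolute distance (Hungarian algorithm) and
    returns, for each true pole, the matched estimated pole.  Requires
    ``len(estimated) >= len(truth)``.
    """
    estimated = np.asarray(estimated, dtype=complex)
    truth = np.asarray(truth, dtype=complex)
    cost = np.abs(truth[:, None] - estimated[None, :])
    rows, cols = linear_sum_assignment(cost)
    matched = np.empty(truth.size, dtype=complex)
    matched[rows] = estimated[cols]
    return matched


def leading_poles(
    poles: np.ndarray,
    k: int = 3,
    mask: np.ndarray | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """The ``k`` slowest poles in the closed upper half-plane.

    Conjugate partners are removed by keeping ``Im >= -tol`` only, then
    poles are sorted by descending real part (slowest first).
    """
    poles = np.asarray(poles, dtype=complex)
    if mask is not None:
        poles = poles[np.asarray(mask, dtype=bool)]
    poles = poles[poles.imag >= -tol]
    order = _sort_modes(poles)
    return poles[order][:k]
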