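"""Functional connectivity, its dynamics, and mode-based approximations.

FC is the matrix of pairwise Pearson correlations of channel signals
over a time window.  FCD tracks how the windowed FC itself evolves: its
entries are correlations between the vectorised upper triangles of FC
matrices computed in time-shifted windows.  Distributions of FCD values
from two sources (e.g. data and a generative twin) are compared with
the Jensen–Shannon distance, the square root of the base-2 JS
divergence, bounded in [0, 1].

When a trained twin's observables decompose into a few uncorrelated
unit-variance modes, channel covariance reduces to the inner product of
the channels' mode-loading rows, so FC is approximated by the cosine
similarity of the rows of the mode map — computed here from the
relevant-mode columns only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon

__all__ = [
    "FcMatrix",
    "FcdMatrix",
    "functional_connectivity",
    "fcd",
    "jensen_shannon_distance",
    "cosine_similarity_rows",
    "fc_from_modes",
    "upper_triangle",
]


@dataclass(frozen=True)
class FcMatrix:
    values: np.ndarray
    window: tuple[float, float]  # (start time, length), seconds


@dataclass(frozen=True)
class FcdMatrix:
    values: np.ndarray
    window_length: float
    shift: float


def upper_triangle(A: np.ndarray) -> np.ndarray:
    """Vectorised strict upper triangle (the standard FC/FCD summary)."""
    A = np.asarray(A)
    i, j = np.triu_indices(A.shape[0], k=1)
    return A[i, j]


def functional_connectivity(
    X: np.ndarray, window: tuple[int, int] | None = None
) -> FcMatrix:
    """Pairwise Pearson correlation over a sample window.

    ``window`` is a ``(start, stop)`` sample slice (whole series by
    default, needing at least 3 samples).  Zero-variance channels yield
    NaN rows/columns, flagging the undefined correlations.
    """
    X = np.asarray(X, dtype=float)
    if window is not None:
        X = X[:, window[0] : window[1]]
    if X.shape[1] < 3:
        raise ValueError("FC window must contain at least 3 samples")
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C[sd == 0, :] = np.nan
    C[:, sd == 0] = np.nan
    np.fill_diagonal(C, 1.0)
    return FcMatrix(values=C, window=(0.0 if window is None else float(window[0]), float(X.shape[1])))


def fcd(
    X: np.ndarray,
    dt: float,
    window_length: float = 75.0,
    shift: float = 12.5,
) -> FcdMatrix:
    """Functional connectivity dynamics matrix.

    Sliding windows of ``window_length`` seconds start at multiples of
    ``shift``; entry ``(a, b)`` is the Pearson correlation between the
    vectorised upper triangles of the FCs in windows ``a`` and ``b``.
    """
    X = np.asarray(X, dtype=float)
    w = int(round(window_length / dt))
    s = int(round(shift / dt))
    if w < 3 or s < 1:
        raise ValueError("window too short for the sampling interval")
    T = X.shape[1]
    starts = list(range(0, T - w + 1, s))
    if not starts:
        raise ValueError(
            f"series of {T} samples shorter than one window of {w} samples"
        )
    vecs = np.array(
        [upper_triangle(functional_connectivity(X[:, a : a + w]).values) for a in starts]
    )
    F = np.corrcoef(vecs)
    F = np.atleast_2d(F)
    np.fill_diagonal(F, 1.0)
    return FcdMatrix(values=F, window_length=window_length, shift=shift)


def jensen_shannon_distance(
    values_a: np.ndarray, values_b: np.ndarray, n_bins: int = 50
) -> float:
    """Jensen–Shannon distance between two empirical distributions.

    Both samples are histogrammed on shared equal-width bins spanning
    the pooled range; the base-2 JS distance (square root of the
    divergence) lies in [0, 1], reaching 1 for disjoint supports.
    Degenerate single-point distributions give 0 with a warning.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("need nonempty value sets")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        import warnings

        warnings.warn("degenerate distributions (single value); JSd set to 0", RuntimeWarning)
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(jensenshannon(pa, pb, base=2))


def cosine_similarity_rows(Z: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between rows.

    Complex rows are treated as real vectors by stacking real and
    imaginary parts (for conjugate-pair mode columns the products are
    real up to numerical noise anyway).  Zero rows give NaN entries.
    """
    Z = np.asarray(Z)
    if np.iscomplexobj(Z):
        Z = np.hstack([Z.real, Z.imag])
    norms = np.linalg.norm(Z, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = (Z @ Z.T) / np.outer(norms, norms)
    S[norms == 0, :] = np.nan
    S[:, norms == 0] = np.nan
    return S


def fc_from_modes(Z: np.ndarray) -> np.ndarray:
    """Mode-based FC approximation: cosine similarity of mode-map rows.

    ``Z`` maps relevant-mode projections to channels (one row per
    channel, one column per retained mode).  Valid when the retained
    modes are approximately uncorrelated with comparable variances.
    """
    return cosine_similarity_rows(Z)
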