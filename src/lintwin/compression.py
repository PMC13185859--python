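"""Block-wise PCA compression of grouped channels.

Voxel-level signals are compressed area by area: a PCA is fitted on the
learning window of each channel group and the smallest number of
components capturing a target explained variance (99.5% by default) is
retained, giving a block projection ``P0``.  A second, full PCA ``P1``
orthogonalises the stacked compressed signals, and a diagonal
normalisation ``Nmat`` (reciprocal of each compressed row's maximum
absolute value on the learning window) equalises the peak input
strength of every observable entering a reservoir.  The composite
forward map is ``P = Nmat @ P1 @ P0`` and the inverse
``P0.T @ P1.T @ Nmat^-1`` restores channel-level signals on the
retained subspace; per-channel learning-window means are removed before
projecting and restored on inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["CompressionTransform", "fit_transform", "residual_whiteness"]


@dataclass
class CompressionTransform:
    P0: np.ndarray  # (m, L) block rows of per-area principal axes
    P1: np.ndarray  # (m, m) orthogonal second-stage rotation
    norm: np.ndarray  # (m,) diagonal of Nmat
    means: np.ndarray  # (L,) per-channel learning-window means
    group_labels: np.ndarray  # (L,) area label per channel
    components_per_area: dict
    ev_target: float

    @property
    def n_observables(self) -> int:
        return self.P0.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (self.norm[:, None]) * (self.P1 @ (self.P0 @ (X - self.means[:, None])))

    def inverse(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        return self.P0.T @ (self.P1.T @ (Y / self.norm[:, None])) + self.means[:, None]


def fit_transform(
    X: np.ndarray,
    group_labels: np.ndarray,
    learning_slice: slice | None = None,
    ev_target: float = 0.995,
) -> tuple[CompressionTransform, np.ndarray]:
    """Fit the block-PCA compression on the learning window.

    ``X`` has shape ``(L, T)`` (channels by time), ``group_labels`` one
    area label per channel.  Returns the fitted transform and the
    compressed observables for the full series.  Raises on
    zero-variance channel blocks (PCA undefined there).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(group_labels)
    if labels.size != X.shape[0]:
        raise ValueError("one group label per channel required")
    if not 0 < ev_target <= 1:
        raise ValueError("ev_target must lie in (0, 1]")
    learn = X[:, learning_slice] if learning_slice is not None else X
    if learn.shape[1] < 2:
        raise ValueError("learning window must contain at least 2 samples")

    means = learn.mean(axis=1)
    centered = learn - means[:, None]
    areas = list(dict.fromkeys(labels.tolist()))  # preserve order
    blocks, counts = [], {}
    row_groups = []
    for a in areas:
        idx = np.where(labels == a)[0]
        block = centered[idx, :]
        if np.allclose(block.std(axis=1), 0):
            raise ValueError(f"area {a!r} has zero-variance channels only")
        n_max = min(idx.size, block.shape[1])
        pca = PCA(n_components=n_max)
        pca.fit(block.T)
        ev = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(ev, ev_target - 1e-12) + 1)
        k = min(k, n_max)
        axes = pca.components_[:k]  # (k, |idx|)
        blocks.append((idx, axes))
        counts[a] = k
        row_groups.extend([a] * k)

    m = sum(counts.values())
    P0 = np.zeros((m, X.shape[0]))
    row = 0
    for idx, axes in blocks:
        P0[row : row + axes.shape[0], idx] = axes
        row += axes.shape[0]

    Y0 = P0 @ centered
    # orthogonalisation: full PCA (all components) of the stacked
    # compressed signals, as an uncentered rotation so the map stays linear
    C = Y0 @ Y0.T
    w, U = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    P1 = U[:, order].T  # (m, m) orthogonal
    Y1 = P1 @ Y0
    peak = np.max(np.abs(Y1), axis=1)
    if np.any(peak == 0):
        peak = np.where(peak == 0, 1.0, peak)
    norm = 1.0 / peak

    tf = CompressionTransform(
        P0=P0,
        P1=P1,
        norm=norm,
        means=means,
        group_labels=labels,
        components_per_area=counts,
        ev_target=ev_target,
    )
    return tf, tf.transform(X)


def residual_whiteness(
    X: np.ndarray,
    X_reconstructed: np.ndarray,
    group_labels: np.ndarray,
    window: slice | None = None,
) -> dict:
    """Per-area score ``1 - cor(residual, signal)``.

    A score of 1 means the information lost by compression is
    uncorrelated with the signal (i.e. looks like white noise); 0 means
    the residual *is* the signal.  Zero-variance residuals score 1 by
    convention.
    """
    X = np.asarray(X, dtype=float)
    Xr = np.asarray(X_reconstructed, dtype=float)
    if X.shape != Xr.shape:
        raise ValueError("original and reconstruction must have equal shapes")
    labels = np.asarray(group_labels)
    if window is not None:
        X, Xr = X[:, window], Xr[:, window]
    resid = X - Xr
    scores = {}
    for a in dict.fromkeys(labels.tolist()):
        idx = np.where(labels == a)[0]
        vals = []
        for i in idx:
            if resid[i].std() == 0 or X[i].std() == 0:
                vals.append(1.0)
            else:
                vals.append(1.0 - np.corrcoef(resid[i], X[i])[0, 1])
        scores[a] = float(np.mean(vals))
    return scores
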