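"""Discriminating areas and subjects from spectral fingerprints.

Frequency vectors (relevance-weighted histograms of mode frequencies)
are treated as feature vectors.  Two complementary linear analyses are
provided: a generalized-eigenvalue LDA projecting the features onto the
directions that best separate the classes, and minimum-norm
least-squares decoders mapping features to one-hot class labels, whose
coefficient rows reveal which frequencies distinguish each class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .connectivity import cosine_similarity_rows

__all__ = [
    "FeatureTable",
    "DecoderSet",
    "one_hot",
    "lda_project",
    "fit_decoders",
    "decoder_similarity",
]


@dataclass(frozen=True)
class FeatureTable:
    """Feature matrix ``F`` (D x S) with one-hot labels ``Y`` (C x S)."""

    F: np.ndarray
    Y: np.ndarray
    label_names: list

    def __post_init__(self):
        if self.F.shape[1] != self.Y.shape[1]:
            raise ValueError("F and Y must have equal sample counts")
        if not np.allclose(self.Y.sum(axis=0), 1):
            raise ValueError("Y columns must be one-hot")


def one_hot(labels) -> tuple[np.ndarray, list]:
    """One-hot encode labels; returns ``(Y, label_names)``."""
    labels = np.asarray(labels)
    names = list(dict.fromkeys(labels.tolist()))
    Y = np.zeros((len(names), labels.size))
    for i, name in enumerate(names):
        Y[i, labels == name] = 1.0
    return Y, names


def lda_project(
    F: np.ndarray, labels, k: int = 3, reg: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Linear discriminant projection via the generalized eigenproblem.

    Solves ``Sb l = lambda Sw l`` for between- and within-class scatter
    and returns ``(L, projected)`` with ``L`` of shape ``(D, k)``
    holding the top-``k`` discriminant directions and
    ``projected = L.T @ F``.  The within-class scatter is ridge
    regularised by ``reg * trace(Sw)/D`` when (near) singular, the
    standard remedy for high-dimensional, few-sample panels.
    """
    F = np.asarray(F, dtype=float)
    labels = np.asarray(labels)
    D, S = F.shape
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    mu = F.mean(axis=1)
    Sw = np.zeros((D, D))
    Sb = np.zeros((D, D))
    for c in classes:
        idx = np.where(labels == c)[0]
        if idx.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        Fc = F[:, idx]
        mc = Fc.mean(axis=1)
        d = Fc - mc[:, None]
        Sw += d @ d.T
        Sb += idx.size * np.outer(mc - mu, mc - mu)
    ridge = reg * (np.trace(Sw) / D if np.trace(Sw) > 0 else 1.0)
    Sw_reg = Sw + ridge * np.eye(D)
    w, V = eigh(Sb, Sw_reg)
    order = np.argsort(w)[::-1][:k]
    L = V[:, order]
    return L, L.T @ F


@dataclass(frozen=True)
class DecoderSet:
    """Least-squares decoders and their per-class training accuracy."""

    Wdec: np.ndarray  # (C, D)
    per_class_accuracy: np.ndarray  # (C,)
    similarity: np.ndarray  # (C, C) cosine similarity of decoder rows


def fit_decoders(table: FeatureTable) -> DecoderSet:
    """Minimum-norm least-squares decoders ``W = Y F^+``.

    The per-class accuracy is the fraction of class-``k`` samples whose
    decoder output ``y_hat_k`` attains the row maximum (in-sample, the
    quantity the decoder coefficients are interpreted against; use a
    held-out table for generalisation estimates).
    """
    F, Y = table.F, table.Y
    if F.shape[1] < Y.shape[0]:
        raise ValueError("need at least as many samples as classes")
    Wdec = Y @ np.linalg.pinv(F)
    scores = Wdec @ F  # (C, S)
    pred = np.argmax(scores, axis=0)
    true = np.argmax(Y, axis=0)
    acc = np.array(
        [np.mean(pred[true == c] == c) if np.any(true == c) else np.nan
         for c in range(Y.shape[0])]
    )
    return DecoderSet(Wdec=Wdec, per_class_accuracy=acc,
                      similarity=cosine_similarity_rows(Wdec))


def decoder_similarity(rows: np.ndarray) -> np.ndarray:
    """Cosine similarity between decoder rows (or mean frequency vectors)."""
    return cosine_similarity_rows(rows)
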