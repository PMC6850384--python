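"""Principal-coordinates embedding of trait dissimilarities.

Gower dissimilarities of fuzzy-coded traits are generally non-Euclidean,
so classical scaling produces negative eigenvalues.  Two standard
treatments are provided: an additive (Cailliez) correction that inflates
off-diagonal distances just enough to make the matrix Euclidean, used for
the evenness index which needs true coordinates; and the signed
real/imaginary decomposition, used by the dispersion index which only
needs squared distances to a centroid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix

__all__ = ["pcoa_embed", "dual_embedding", "cailliez_constant"]

_EPS = 1e-10


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=0)
    return a - row[None, :] - row[:, None] + a.mean()


def cailliez_constant(d: np.ndarray) -> float:
    """Smallest constant c such that d_ij + c (i != j) is Euclidean.

    Computed as the largest real eigenvalue of the 2n x 2n block matrix
    [[0, 2*D1], [-I, -4*D2]] where D1 and D2 are the double-centred
    matrices of -d^2/2 and -d/2 respectively.
    """
    n = d.shape[0]
    delta1 = _gower_center(d)
    a2 = -0.5 * d
    row = a2.mean(axis=0)
    delta2 = a2 - row[None, :] - row[:, None] + a2.mean()
    block = np.block([
        [np.zeros((n, n)), 2.0 * delta1],
        [-np.eye(n), -4.0 * delta2],
    ])
    eig = np.linalg.eigvals(block)
    return float(max(eig.real.max(), 0.0))


@dataclass(frozen=True)
class Embedding:
    coords: np.ndarray          # n x k coordinates
    eigvals: np.ndarray         # retained (positive) eigenvalues
    correction: float           # Cailliez constant applied (0 if none)
    ids: tuple


def pcoa_embed(dm: DistanceMatrix, tol: float = 1e-8) -> Embedding:
    """Classical scaling with automatic additive correction.

    If the input distances are already Euclidean (no eigenvalue below
    ``-tol`` relative to the largest), no correction is applied and the
    pairwise Euclidean distances in the embedding reproduce the input
    within numerical precision.  Otherwise the Cailliez constant is added
    to all off-diagonal distances first, and the embedding reproduces the
    corrected distances.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("embedding needs at least 2 taxa")
    corr = 0.0
    b = _gower_center(d)
    w, v = np.linalg.eigh(b)
    scale = max(abs(w).max(), 1.0)
    if w.min() < -tol * scale:
        corr = cailliez_constant(d)
        d = d + corr
        np.fill_diagonal(d, 0.0)
        b = _gower_center(d)
        w, v = np.linalg.eigh(b)
        scale = max(abs(w).max(), 1.0)
    keep = w > tol * scale
    if not keep.any():
        warnings.warn("degenerate distance matrix (all points coincide)", stacklevel=2)
        return Embedding(np.zeros((n, 1)), np.zeros(1), corr, tuple(dm.ids))
    order = np.argsort(w[keep])[::-1]
    w_pos = w[keep][order]
    coords = (v[:, keep][:, order]) * np.sqrt(w_pos)[None, :]
    return Embedding(coords, w_pos, corr, tuple(dm.ids))


def dual_embedding(dm: DistanceMatrix, tol: float = 1e-8):
    """Real and imaginary coordinate blocks of a non-Euclidean matrix.

    Returns ``(real_coords, imag_coords)`` where squared distances
    decompose as ``d^2 = |dx_real|^2 - |dx_imag|^2``; the imaginary block
    collects axes of negative eigenvalues (scaled by sqrt(-lambda)).
    """
    d = np.asarray(dm.data, dtype=float)
    b = _gower_center(d)
    w, v = np.linalg.eigh(b)
    scale = max(abs(w).max(), 1.0)
    pos = w > tol * scale
    neg = w < -tol * scale
    real = v[:, pos] * np.sqrt(w[pos])[None, :]
    imag = v[:, neg] * np.sqrt(-w[neg])[None, :]
    if real.size == 0:
        real = np.zeros((d.shape[0], 1))
    return real, imag
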