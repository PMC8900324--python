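"""Single-level discrete wavelet decomposition of gene coverage, per-gene
PCA of the detail coefficients, and protocol-separability categories.

The high-frequency (detail) band of a one-level symlet-5 transform of
normalized per-gene coverage carries systematic, protocol-specific
texture; projecting each gene's detail coefficients across a cohort of
samples onto two principal components yields per-sample (PC1, PC2)
scores that downstream classification consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pywt
from scipy.optimize import linprog

from .errors import ValidationError

__all__ = [
    "WaveletDecomposition",
    "PCScores",
    "dwt_single_level",
    "reconstruct",
    "per_gene_pca",
    "categorize_separation",
]


@dataclass
class WaveletDecomposition:
    """One-level DWT of a coverage vector: approximation + detail bands."""

    approximation: np.ndarray
    detail: np.ndarray
    wavelet_name: str = "sym5"
    boundary_mode: str = "symmetric"
    input_length: int | None = None


def dwt_single_level(
    signal: Sequence[float] | np.ndarray,
    wavelet: str = "sym5",
    mode: str = "symmetric",
) -> WaveletDecomposition:
    """One-level DWT.  The signal must be at least as long as the
    wavelet's decomposition filter (10 taps for sym5); shorter genes
    should be excluded by the caller.
    """
    x = np.asarray(signal, dtype=float)
    w = pywt.Wavelet(wavelet)
    if x.size < w.dec_len:
        raise ValidationError(
            f"signal length {x.size} < filter length {w.dec_len}; exclude this gene"
        )
    cA, cD = pywt.dwt(x, w, mode=mode)
    return WaveletDecomposition(cA, cD, wavelet, mode, input_length=x.size)


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse one-level DWT, trimmed to the original signal length."""
    x = pywt.idwt(dec.approximation, dec.detail, dec.wavelet_name, mode=dec.boundary_mode)
    if dec.input_length is not None:
        x = x[: dec.input_length]
    return x


@dataclass
class PCScores:
    """Per-sample projections of one gene's detail coefficients.

    ``scores`` is samples x 2 (PC1, PC2), mean-centered per component;
    ``explained_variance`` holds the two variance fractions.
    ``components`` (2 x n_coefficients) and ``mean`` allow projecting
    new samples: score = (x - mean) @ components.T.
    """

    gene_id: str
    sample_ids: list[str]
    scores: np.ndarray
    explained_variance: tuple[float, float]
    components: np.ndarray | None = None
    mean: np.ndarray | None = None

    def pc(self, sample_id: str) -> tuple[float, float]:
        i = self.sample_ids.index(sample_id)
        return float(self.scores[i, 0]), float(self.scores[i, 1])


def per_gene_pca(
    detail_matrix: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    gene_id: str = "",
) -> PCScores:
    """PCA (centering only, no variance scaling) of a samples x
    coefficients matrix; returns top-2 scores.

    Sign convention: each component's loading vector is oriented so that
    its largest-magnitude entry is positive, making scores reproducible
    across runs and platforms.
    """
    X = np.asarray(detail_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValidationError("need a 2-D matrix with at least 3 samples")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(X.shape[0])]
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValidationError("rank-0 matrix: identical rows have no principal axes")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(2, len(s))
    scores = np.zeros((X.shape[0], 2))
    components = np.zeros((2, X.shape[1]))
    ev = [0.0, 0.0]
    total_var = float((s**2).sum())
    for i in range(k):
        v = Vt[i]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        components[i] = v
        scores[:, i] = Xc @ v
        ev[i] = float(s[i] ** 2 / total_var) if total_var > 0 else 0.0
    return PCScores(gene_id, list(sample_ids), scores, (ev[0], ev[1]),
                    components=components, mean=mean)


def _linearly_separable(X: np.ndarray, y: np.ndarray) -> bool:
    """Exact feasibility check for a strictly separating hyperplane.

    Solves: find (w, b) with y_i (w.x_i + b) >= 1 for all i.  Any
    strictly separating hyperplane can be rescaled into this form, so
    feasibility is equivalent to strict linear separability.
    """
    n, d = X.shape
    sign = np.where(y, 1.0, -1.0)
    A_ub = -(sign[:, None] * np.hstack([X, np.ones((n, 1))]))
    b_ub = -np.ones(n)
    res = linprog(
        c=np.zeros(d + 1),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(None, None)] * (d + 1),
        method="highs",
    )
    return res.status == 0


def categorize_separation(
    scores: PCScores, labels: Mapping[str, str]
) -> str:
    """Categorise a gene by how its PC scores separate the two protocols.

    Returns ``"PC1_separable"`` when a threshold on PC1 alone perfectly
    partitions the labels, ``"plane_separable"`` when a linear boundary
    in the (PC1, PC2) plane achieves zero training error, else
    ``"not_separable"``.
    """
    y = np.array([labels[s] for s in scores.sample_ids])
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError("need exactly two protocol labels")
    mask = y == classes[0]
    pc1 = scores.scores[:, 0]
    if pc1[mask].max() < pc1[~mask].min() or pc1[~mask].max() < pc1[mask].min():
        return "PC1_separable"
    if _linearly_separable(scores.scores[:, :2], mask):
        return "plane_separable"
    return "not_separable"
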