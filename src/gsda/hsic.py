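"""Hilbert-Schmidt independence criterion (HSIC) estimators.

Two estimators are provided:

* :func:`hsic` -- the general biased empirical HSIC over two sample sets,
  ``tr(K H L H) / (m - 1)**2``, with linear, polynomial or RBF kernels.
* :func:`simplified_hsic` -- the projection form used inside the GSDA
  objective: for a linear score ``s = X w`` and a group vector ``g`` with
  linear kernels on both sides the trace collapses to the scalar
  ``(s_centered . g)**2``.  No ``1/(m-1)**2`` factor is applied by default;
  the dependence hyperparameter absorbs the scale.

Public functions take samples-by-features arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import ClassVar

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["KernelSpec", "gram_matrix", "hsic", "simplified_hsic"]


@dataclass(frozen=True)
class KernelSpec:
    """A kernel function specification.

    Parameters
    ----------
    name
        One of ``"linear"``, ``"rbf"``, ``"polynomial"``.
    bandwidth
        RBF bandwidth sigma (> 0); the kernel is
        ``exp(-||x - y||^2 / (2 sigma^2))``.
    degree, offset
        Polynomial kernel ``(x . y + offset) ** degree`` with integer
        ``degree >= 1``.
    """

    name: str = "linear"
    bandwidth: float = 1.0
    degree: int = 2
    offset: float = 1.0

    _VALID: ClassVar[tuple] = ("linear", "rbf", "polynomial")

    def __post_init__(self) -> None:
        if self.name not in self._VALID:
            raise ValueError(f"unknown kernel {self.name!r}; expected one of {self._VALID}")
        if self.name == "rbf" and not self.bandwidth > 0:
            raise ValueError("rbf bandwidth must be > 0")
        if self.name == "polynomial":
            if int(self.degree) != self.degree or self.degree < 1:
                raise ValueError("polynomial degree must be an integer >= 1")


def gram_matrix(samples: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Return the m-by-m Gram matrix of ``samples`` (m rows) under ``kernel``."""
    X = np.asarray(samples, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("samples must be a 2-D samples-by-features array")
    if kernel.name == "linear":
        return X @ X.T
    if kernel.name == "rbf":
        sq = cdist(X, X, metric="sqeuclidean")
        return np.exp(-sq / (2.0 * kernel.bandwidth**2))
    # polynomial
    return (X @ X.T + kernel.offset) ** kernel.degree


def hsic(
    samples_x: np.ndarray,
    samples_y: np.ndarray,
    kernel_x: KernelSpec | None = None,
    kernel_y: KernelSpec | None = None,
) -> float:
    """Empirical HSIC between two paired sample sets.

    Computes ``tr(K H L H) / (m - 1)**2`` where ``K`` and ``L`` are the Gram
    matrices of the two sets and ``H = I - (1/m) 11^T`` is the centering
    matrix.  Nonnegative for PSD kernels; zero iff the empirical dependence
    under the chosen kernels vanishes.

    Parameters
    ----------
    samples_x, samples_y
        Arrays with the same number of rows ``m >= 2``; 1-D inputs are
        treated as single-feature columns.
    kernel_x, kernel_y
        Kernel specifications; default linear.
    """
    X = np.asarray(samples_x, dtype=float)
    Y = np.asarray(samples_y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    m = X.shape[0]
    if m < 2:
        raise ValueError(f"need at least 2 samples, got {m}")
    if Y.shape[0] != m:
        raise ValueError(f"row-count mismatch: {m} vs {Y.shape[0]}")
    K = gram_matrix(X, kernel_x or KernelSpec())
    L = gram_matrix(Y, kernel_y or KernelSpec())
    # H K H done by double-centering; cheaper and more accurate than forming H.
    Kc = K - K.mean(axis=0, keepdims=True)
    Kc -= Kc.mean(axis=1, keepdims=True)
    value = float(np.sum(Kc * L)) / (m - 1) ** 2
    # tiny negative values arise from round-off only
    return max(value, 0.0) if value > -1e-12 else value


def simplified_hsic(
    w: np.ndarray,
    X: np.ndarray,
    g: np.ndarray,
    normalize: bool = False,
) -> float:
    """Simplified HSIC between the linear projection ``X w`` and group vector ``g``.

    Evaluates the quadratic form ``w^T X^T H L H X w`` with ``L`` the outer
    product of ``g`` with itself, which collapses to
    ``((s - mean(s)) . g)**2`` for the score vector ``s = X w``.  The m-by-m
    matrices are never materialised.

    Parameters
    ----------
    w
        Weight vector, length matching the number of columns of ``X``.
    X
        Samples-by-features design (m rows).  Note the written form of the
        estimator uses the transposed features-by-samples orientation; the
        value is identical.
    g
        Length-m group vector (any real encoding; centering makes the value
        invariant to adding a constant).
    normalize
        If True, divide by ``(m - 1)**2`` for scale comparability across
        sample sizes.  Off by default.
    """
    w = np.asarray(w, dtype=float)
    X = np.asarray(X, dtype=float)
    g = np.asarray(g, dtype=float)
    if X.ndim != 2 or X.shape[1] != w.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape} vs w length {w.shape[0]}")
    if g.shape[0] != X.shape[0]:
        raise ValueError(f"shape mismatch: X has {X.shape[0]} rows, g has {g.shape[0]}")
    s = X @ w
    sc = s - s.mean()
    value = float(sc @ g) ** 2
    if normalize:
        value /= (X.shape[0] - 1) ** 2
    return value
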