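"""NIPALS principal component analysis.

NIPALS (nonlinear iterative partial least squares) extracts principal
components one at a time by alternating power iteration and deflation,
which is the standard chemometric route when the band count far exceeds
the cell count.  The matrix is column-mean-centered first; projections of
new spectra subtract the stored column mean, so train and test live in
the same coordinate frame.

Determinism conventions: the score vector is initialized from the column
of the working residual with maximal variance, and every loading's sign
is fixed so that its largest-magnitude element is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ValidationError

__all__ = ["PCAModel", "fit_nipals", "project"]

logger = logging.getLogger(__name__)

DEFAULT_K = 7


@dataclass
class PCAModel:
    """Frozen result of a NIPALS fit.

    loadings
        (n_bands, k) orthonormal loading vectors, one column per component.
    col_mean
        (n_bands,) column means subtracted before extraction.
    scores_train
        (n, k) training scores (may be ``None`` for deserialized models).
    explained_var
        (k,) fraction of total (centered) variance per component.
    converged / n_iter
        per-component convergence flags and iteration counts.
    """

    loadings: np.ndarray
    col_mean: np.ndarray
    explained_var: np.ndarray
    scores_train: Optional[np.ndarray] = None
    converged: Optional[np.ndarray] = None
    n_iter: Optional[np.ndarray] = None

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_bands(self) -> int:
        return self.loadings.shape[0]


def fit_nipals(
    X: np.ndarray,
    k: int = DEFAULT_K,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> PCAModel:
    """Extract ``k`` principal components of ``X`` (n x B) by NIPALS.

    Components are extracted sequentially with deflation; an iteration
    converges when the relative L2 change of the score vector drops below
    ``tol``.  Hitting ``max_iter`` is not fatal: the component is kept,
    flagged unconverged, and a warning is logged.

    Requires ``n >= 2`` and ``1 <= k <= min(n - 1, B)``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D matrix")
    n, B = X.shape
    if n < 2:
        raise ValidationError("need at least 2 rows to fit PCA")
    kmax = min(n - 1, B)
    if not 1 <= k <= kmax:
        raise ValidationError(f"k={k} out of range [1, {kmax}] for a {n}x{B} matrix")

    col_mean = X.mean(axis=0)
    R = X - col_mean
    total_var = float(np.sum(R * R))
    if total_var == 0.0:
        raise ValidationError("matrix has zero variance after centering")

    loadings = np.empty((B, k))
    scores = np.empty((n, k))
    explained = np.empty(k)
    converged = np.zeros(k, dtype=bool)
    iters = np.zeros(k, dtype=np.int64)

    for j in range(k):
        col_var = R.var(axis=0)
        t = R[:, int(np.argmax(col_var))].copy()
        if not np.any(t):
            raise ValidationError(
                f"residual rank exhausted at component {j + 1}; lower k"
            )
        for it in range(1, max_iter + 1):
            p = R.T @ t / (t @ t)
            p /= np.linalg.norm(p)
            t_new = R @ p
            delta = np.linalg.norm(t_new - t) / np.linalg.norm(t_new)
            t = t_new
            if delta < tol:
                converged[j] = True
                break
        iters[j] = it
        if not converged[j]:
            logger.warning(
                "NIPALS component %d did not converge in %d iterations "
                "(last relative score change %.3e)",
                j + 1,
                max_iter,
                delta,
            )
        # sign convention: largest-|.| loading element positive
        imax = int(np.argmax(np.abs(p)))
        if p[imax] < 0:
            p = -p
            t = -t
        loadings[:, j] = p
        scores[:, j] = t
        explained[j] = float(t @ t) / total_var
        R = R - np.outer(t, p)

    return PCAModel(
        loadings=loadings,
        col_mean=col_mean,
        explained_var=explained,
        scores_train=scores,
        converged=converged,
        n_iter=iters,
    )


def project(model: PCAModel, spectra: np.ndarray) -> np.ndarray:
    """Project spectra onto the fitted PC space: ``(S - col_mean) @ loadings``.

    Accepts a single spectrum (B,) or a matrix (m, B); returns (k,) or
    (m, k) accordingly.
    """
    S = np.asarray(spectra, dtype=np.float64)
    single = S.ndim == 1
    if single:
        S = S[None, :]
    if S.ndim != 2 or S.shape[1] != model.n_bands:
        raise ValidationError(
            f"spectra have {S.shape[-1]} bands but the model expects {model.n_bands}"
        )
    T = (S - model.col_mean) @ model.loadings
    return T[0] if single else T
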