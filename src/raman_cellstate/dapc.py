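"""Discriminant analysis of principal components (DAPC).

A two-class Fisher linear discriminant fitted on PC scores.  The F1 axis
is the direction w ∝ S_w^{-1} (mu2 - mu1) maximizing between-class over
within-class scatter; the LDA score of a cell is the projection of its PC
score vector onto F1.  Per-class Gaussian parameters (mean, covariance,
prior) are stored alongside, in the manner of quadratic discriminant
analysis, so that class log-probabilities can be evaluated per spectrum
(used by the pixel-wise colorizer).

``loo_error`` estimates the classification error by leave-one-out
cross-validation, refitting the PCA inside every fold by default so no
information leaks from the held-out cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .core import SpectraDataset, ValidationError
from .nipals import fit_nipals, project

__all__ = [
    "DiscriminantModel",
    "fit_discriminant",
    "lda_score",
    "classify",
    "qda_log_prob",
    "qda_posterior",
    "loo_error",
]

DEFAULT_REG_EPS = 1e-3


@dataclass
class DiscriminantModel:
    """Two-class Fisher discriminant with per-class Gaussian statistics.

    ``class_names`` is the ordered pair (first, second); the F1 sign is
    fixed so the second-listed class (e.g. "activated") has the higher
    mean LDA score.  ``threshold`` is the midpoint of the projected class
    means.  ``means``/``covs``/``priors`` are stacked in class order;
    covariances carry the shrinkage (1-eps)*S + eps*tr(S)/k*I.
    """

    class_names: Tuple[str, str]
    f1: np.ndarray
    threshold: float
    means: np.ndarray  # (2, k)
    covs: np.ndarray  # (2, k, k)
    priors: np.ndarray  # (2,)
    reg_eps: float = DEFAULT_REG_EPS

    @property
    def k(self) -> int:
        return self.f1.shape[0]


def _resolve_classes(labels: np.ndarray, class_order) -> Tuple[str, str]:
    present: dict = {}
    for lab in labels:
        present.setdefault(str(lab), None)
    names = list(present)
    if class_order is not None:
        order = [str(c) for c in class_order]
        if sorted(order) != sorted(names) or len(order) != 2:
            raise ValidationError(
                f"class_order {order} does not match labels present {names}"
            )
        return order[0], order[1]
    if len(names) != 2:
        raise ValidationError(f"expected exactly 2 classes, found {names}")
    return names[0], names[1]


def _shrink(cov: np.ndarray, eps: float) -> np.ndarray:
    k = cov.shape[0]
    return (1.0 - eps) * cov + eps * (np.trace(cov) / k) * np.eye(k)


def fit_discriminant(
    scores: np.ndarray,
    labels: Sequence,
    class_order: Optional[Sequence[str]] = None,
    reg_eps: float = DEFAULT_REG_EPS,
) -> DiscriminantModel:
    """Fit the Fisher F1 axis and per-class Gaussian statistics.

    ``scores`` is the (n, k) PC score matrix; ``labels`` must contain
    exactly two classes.  ``class_order`` fixes which class is "second"
    (higher mean F1 score); by default classes are taken in order of first
    appearance in ``labels``.
    """
    T = np.asarray(scores, dtype=np.float64)
    if T.ndim == 1:
        T = T[:, None]
    labels = np.asarray([str(v) for v in labels])
    if labels.shape[0] != T.shape[0]:
        raise ValidationError("labels must align with score rows")
    c1, c2 = _resolve_classes(labels, class_order)
    k = T.shape[1]

    means, covs, counts = [], [], []
    Sw = np.zeros((k, k))
    for c in (c1, c2):
        Tc = T[labels == c]
        if Tc.shape[0] < 2:
            raise ValidationError(f"class {c!r} needs at least 2 members")
        mu = Tc.mean(axis=0)
        D = Tc - mu
        Sw += D.T @ D
        cov = np.atleast_2d(np.cov(Tc, rowvar=False, ddof=1))
        covs.append(_shrink(cov, reg_eps))
        means.append(mu)
        counts.append(Tc.shape[0])
    means = np.vstack(means)
    covs = np.stack(covs)
    priors = np.asarray(counts, dtype=np.float64)
    priors /= priors.sum()

    d = means[1] - means[0]
    try:
        w = np.linalg.solve(Sw, d)
    except np.linalg.LinAlgError:
        Sw_r = _shrink(Sw, reg_eps)
        try:
            w = np.linalg.solve(Sw_r, d)
        except np.linalg.LinAlgError:
            raise ValidationError("pooled within-class scatter singular after regularization")
    nrm = np.linalg.norm(w)
    if nrm == 0.0:
        raise ValidationError("degenerate discriminant: class means coincide")
    w /= nrm
    if means[1] @ w < means[0] @ w:
        w = -w
    threshold = 0.5 * float(means[0] @ w + means[1] @ w)

    for c, cov in zip((c1, c2), covs):
        if np.min(np.linalg.eigvalsh(cov)) <= 0:
            raise ValidationError(f"class {c!r} covariance not positive definite after shrinkage")

    return DiscriminantModel(
        class_names=(c1, c2),
        f1=w,
        threshold=threshold,
        means=means,
        covs=covs,
        priors=priors,
        reg_eps=reg_eps,
    )


def _check_dim(model: DiscriminantModel, T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=np.float64)
    single = T.ndim == 1
    if single:
        T = T[None, :]
    if T.shape[1] != model.k:
        raise ValidationError(f"scores have dimension {T.shape[1]}, model expects {model.k}")
    return T


def lda_score(model: DiscriminantModel, scores: np.ndarray) -> np.ndarray:
    """Project PC scores onto the F1 axis (returns scalar per row)."""
    T = np.asarray(scores, dtype=np.float64)
    single = T.ndim == 1
    T = _check_dim(model, T)
    s = T @ model.f1
    return float(s[0]) if single else s


def classify(model: DiscriminantModel, scores: np.ndarray) -> np.ndarray:
    """Label by side of the F1 threshold.

    Scores above the threshold get the second-listed (higher-mean) class.
    Exact ties go to the class with the higher prior; if priors tie too,
    to the first-listed class.
    """
    T = np.asarray(scores, dtype=np.float64)
    single = T.ndim == 1
    s = np.atleast_1d(lda_score(model, T))
    c1, c2 = model.class_names
    tie_class = c2 if model.priors[1] > model.priors[0] else c1
    out = np.where(s > model.threshold, c2, np.where(s < model.threshold, c1, tie_class))
    return out[0] if single else out


def qda_log_prob(model: DiscriminantModel, score_vec: np.ndarray) -> np.ndarray:
    """Per-class log prior + Gaussian log-density of PC score vectors.

    Returns an array of shape (2,) for a single vector or (m, 2) for a
    matrix, columns ordered as ``model.class_names``.
    """
    T = np.asarray(score_vec, dtype=np.float64)
    single = T.ndim == 1
    T = _check_dim(model, T)
    if not np.all(np.isfinite(T)):
        raise ValidationError("non-finite values in score vectors")
    cols = []
    for i in range(2):
        lp = stats.multivariate_normal.logpdf(T, mean=model.means[i], cov=model.covs[i])
        cols.append(np.atleast_1d(lp) + np.log(model.priors[i]))
    out = np.column_stack(cols)
    return out[0] if single else out


def qda_posterior(model: DiscriminantModel, score_vec: np.ndarray) -> np.ndarray:
    """Class posterior probabilities (log-sum-exp normalized)."""
    lp = np.atleast_2d(qda_log_prob(model, score_vec))
    post = np.exp(lp - logsumexp(lp, axis=1, keepdims=True))
    return post[0] if np.asarray(score_vec).ndim == 1 else post


def loo_error(
    dataset: Union[SpectraDataset, np.ndarray],
    labels: Optional[Sequence] = None,
    k: int = 7,
    mode: str = "refit",
    tol: float = 1e-8,
    max_iter: int = 500,
    class_order: Optional[Sequence[str]] = None,
    reg_eps: float = DEFAULT_REG_EPS,
) -> float:
    """Leave-one-out error of the PCA + Fisher-discriminant chain.

    Accepts either a :class:`SpectraDataset` or a bare ``(X, labels)``
    pair.  ``mode="refit"`` (default) refits NIPALS on each fold's
    training rows so the held-out cell never influences the PC space;
    ``mode="fixed"`` fits the PCA once on all rows and refits only the
    discriminant per fold.  Deterministic for fixed input.
    """
    if isinstance(dataset, SpectraDataset):
        X, y = dataset.X, dataset.labels
    else:
        if labels is None:
            raise ValidationError("labels required when passing a bare matrix")
        X, y = np.asarray(dataset, dtype=np.float64), labels
    y = np.asarray([str(v) for v in y])
    n = X.shape[0]
    if n < 4:
        raise ValidationError("leave-one-out needs at least 4 samples")
    c1, c2 = _resolve_classes(y, class_order)
    for c in (c1, c2):
        if int((y == c).sum()) < 2:
            raise ValidationError(f"class {c!r} needs at least 2 members for LOO")
    if mode not in ("refit", "fixed"):
        raise ValueError(f"unknown LOO mode {mode!r}")

    fixed_pca = None
    if mode == "fixed":
        fixed_pca = fit_nipals(X, k=k, tol=tol, max_iter=max_iter)

    errors = 0
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        if mode == "refit":
            pca = fit_nipals(X[tr], k=k, tol=tol, max_iter=max_iter)
            T_tr = pca.scores_train
        else:
            pca = fixed_pca
            T_tr = project(pca, X[tr])
        disc = fit_discriminant(T_tr, y[tr], class_order=(c1, c2), reg_eps=reg_eps)
        pred = classify(disc, project(pca, X[i]))
        if pred != y[i]:
            errors += 1
    return errors / n
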