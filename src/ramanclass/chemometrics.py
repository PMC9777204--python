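"""PCA, the PCA-LDA quadratic classifier, and PLS-DA.

Two supervised classifiers operate on pre-processed spectra:

* **PCA-LDA** — spectra are projected onto a truncated principal-component
  basis (study default 10 PCs) and scored per class k by the quadratic
  discriminant

      L_ik = (x_i - xbar_k)' S_pooled^{-1} (x_i - xbar_k) - 2 ln(pi_k)

  where x_i are the PC scores of spectrum i, xbar_k the class-mean scores,
  S_pooled the pooled within-class covariance in PC space and pi_k the class
  prior. The spectrum is assigned to the class minimising L_ik. A separate
  1-D discriminant projection (leading generalized eigenvector of the
  between- vs pooled within-class scatter) is exposed for score plots and
  score-level ANOVA.

* **PLS-DA** — partial least squares regression of an indicator-coded class
  matrix on the (centred) spectra with a fixed number of latent variables
  (study defaults: 6 two-class, 8 four-group). The predicted response is
  yhat = X b (plus intercept restored after centring); a binary model
  assigns the positive class iff yhat >= 0.5, a multi-class model by argmax
  over coding columns.

Argmin/argmax ties are broken by declared class order with a warning, for
determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from sklearn.cross_decomposition import PLSRegression

from .spectral_io import SpectraSet

__all__ = [
    "PCAModel",
    "PCALDAModel",
    "PLSDAModel",
    "ScoreVector",
    "fit_pca",
    "pca_transform",
    "fit_pca_lda",
    "pca_lda_score",
    "lda_projection",
    "fit_plsda",
    "plsda_predict",
]


def _as_matrix_labels(data, labels):
    """Accept either (SpectraSet, None) or (matrix, labels)."""
    if isinstance(data, SpectraSet):
        return data.intensities, list(data.class_labels)
    if labels is None:
        raise ValueError("labels are required when passing a raw matrix")
    X = np.asarray(data, dtype=float)
    labels = [str(l) for l in labels]
    if X.shape[0] != len(labels):
        raise ValueError(f"{X.shape[0]} rows but {len(labels)} labels")
    return X, labels


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Mean-centred SVD principal-component model.

    ``loadings`` rows are orthonormal; ``scores = (X - mean) @ loadings.T``;
    ``explained_variance`` holds the fraction of total variance per PC,
    non-increasing.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray          # (n_pcs, p)
    scores: np.ndarray            # (n, n_pcs)
    explained_variance: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[0]


def fit_pca(X: np.ndarray, n_pcs: int) -> PCAModel:
    """Fit a PCA by singular value decomposition of the centred matrix."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_pcs = min(n - 1, p)
    if not 1 <= n_pcs <= max_pcs:
        raise ValueError(
            f"n_pcs={n_pcs} outside valid range [1, {max_pcs}] for a "
            f"{n}x{p} matrix"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if not np.any(s > 1e-12 * max(n, p)):
        raise ValueError("matrix is constant; PCA is undefined")
    var = s**2
    explained = var[:n_pcs] / var.sum()
    loadings = Vt[:n_pcs]
    # Deterministic sign convention: largest-|.| element of each PC positive.
    for j in range(n_pcs):
        k = np.argmax(np.abs(loadings[j]))
        if loadings[j, k] < 0:
            loadings[j] = -loadings[j]
    scores = Xc @ loadings.T
    return PCAModel(mean_spectrum=mean, loadings=loadings, scores=scores,
                    explained_variance=explained)


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project new spectra into the model's PC space."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean_spectrum.size:
        raise ValueError(
            f"spectra have {X.shape[1]} points; model expects "
            f"{model.mean_spectrum.size}"
        )
    return (X - model.mean_spectrum) @ model.loadings.T


# ---------------------------------------------------------------------------
# PCA-LDA
# ---------------------------------------------------------------------------

@dataclass
class PCALDAModel:
    pca: PCAModel
    classes: tuple[str, ...]
    class_means: np.ndarray       # (K, n_pcs)
    pooled_covariance: np.ndarray  # (n_pcs, n_pcs)
    priors: np.ndarray            # (K,)
    _chol: np.ndarray = field(repr=False, default=None)

    @property
    def n_pcs(self) -> int:
        return self.pca.n_pcs


@dataclass
class ScoreVector:
    """Per-class scores (PCA-LDA L_ik or PLS-DA yhat) plus the assignment."""

    classes: tuple[str, ...]
    scores: np.ndarray            # (n, K) or (n, n_coding_columns)
    assigned_class: list[str]


def fit_pca_lda(data, labels=None, n_pcs: int = 10,
                priors: str = "proportional") -> PCALDAModel:
    """PCA followed by LDA statistics (class means, pooled covariance,
    priors) computed in PC-score space.

    ``priors="proportional"`` uses training class proportions (default);
    ``"uniform"`` uses 1/K.
    """
    X, labels = _as_matrix_labels(data, labels)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("PCA-LDA needs at least 2 classes")
    counts = {c: labels.count(c) for c in classes}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"every class needs >= 2 spectra; too small: {small}")
    pca = fit_pca(X, n_pcs)
    Z = pca.scores
    n, K = Z.shape[0], len(classes)
    means = np.vstack([Z[[l == c for l in labels]].mean(axis=0)
                       for c in classes])
    pooled = np.zeros((n_pcs, n_pcs))
    for k, c in enumerate(classes):
        Zk = Z[[l == c for l in labels]] - means[k]
        pooled += Zk.T @ Zk
    pooled /= n - K
    try:
        chol = np.linalg.cholesky(pooled)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is singular; refit with fewer PCs"
        ) from exc
    if priors == "proportional":
        pri = np.array([counts[c] / n for c in classes])
    elif priors == "uniform":
        pri = np.full(K, 1.0 / K)
    else:
        raise ValueError(f"unknown priors option {priors!r}")
    return PCALDAModel(pca=pca, classes=classes, class_means=means,
                       pooled_covariance=pooled, priors=pri, _chol=chol)


def _assign(scores: np.ndarray, classes: tuple[str, ...],
            pick: str) -> list[str]:
    """Row-wise argmin/argmax with first-in-order tie break and warning."""
    best = scores.argmin(axis=1) if pick == "min" else scores.argmax(axis=1)
    extreme = scores[np.arange(scores.shape[0]), best]
    ties = (scores == extreme[:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} tied classification score(s); "
            "assigned to the first class in declared order",
            stacklevel=3,
        )
    return [classes[b] for b in best]


def pca_lda_score(model: PCALDAModel, spectra) -> ScoreVector:
    """Quadratic discriminant scores L_ik for each class; argmin assigns."""
    X = spectra.intensities if isinstance(spectra, SpectraSet) else spectra
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = pca_transform(model.pca, X)
    K = len(model.classes)
    L = np.empty((Z.shape[0], K))
    for k in range(K):
        d = (Z - model.class_means[k]).T            # (n_pcs, n)
        y = sla.solve_triangular(model._chol, d, lower=True)
        L[:, k] = (y**2).sum(axis=0) - 2.0 * np.log(model.priors[k])
    return ScoreVector(classes=model.classes, scores=L,
                       assigned_class=_assign(L, model.classes, "min"))


def lda_projection(model: PCALDAModel, spectra, n_axes: int = 1) -> np.ndarray:
    """Project PC scores onto the leading discriminant axes.

    The axes are generalized eigenvectors of (between-class scatter, pooled
    within-class scatter); at most K-1 are available. Returns an
    (n, n_axes) array used for score plots, box plots and score-level
    ANOVA/MANOVA.
    """
    K = len(model.classes)
    max_axes = K - 1
    if not 1 <= n_axes <= max_axes:
        raise ValueError(f"n_axes must be in [1, {max_axes}] for {K} classes")
    X = spectra.intensities if isinstance(spectra, SpectraSet) else spectra
    Z = pca_transform(model.pca, np.atleast_2d(np.asarray(X, dtype=float)))
    grand = (model.priors[:, None] * model.class_means).sum(axis=0)
    Sb = np.zeros_like(model.pooled_covariance)
    for k in range(K):
        d = (model.class_means[k] - grand)[:, None]
        Sb += model.priors[k] * (d @ d.T)
    eigvals, eigvecs = sla.eigh(Sb, model.pooled_covariance)
    order = np.argsort(eigvals)[::-1][:n_axes]
    W = eigvecs[:, order]
    # Fix sign: first class mean projects negative on axis 1 (plot stability).
    proj_means = model.class_means @ W
    for j in range(W.shape[1]):
        if proj_means[0, j] > 0:
            W[:, j] = -W[:, j]
    return Z @ W


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    n_lvs: int
    classes: tuple[str, ...]
    coding_columns: tuple[str, ...]
    regression_vectors: np.ndarray   # b, (p, n_coding_columns)
    intercept: np.ndarray            # (n_coding_columns,)
    decision_rule: str               # "threshold-0.5" or "argmax"


def _class_coding(labels: list[str], classes: tuple[str, ...]) -> tuple[np.ndarray, tuple[str, ...]]:
    if len(classes) == 2:
        # single 0/1 column indicating the second (positive) class
        y = np.array([[1.0 if l == classes[1] else 0.0] for l in labels])
        return y, (classes[1],)
    y = np.array([[1.0 if l == c else 0.0 for c in classes] for l in labels])
    return y, classes


def fit_plsda(data, labels=None, n_lvs: int = 6) -> PLSDAModel:
    """Latent-variable (NIPALS) regression of the class coding on spectra.

    Classes are sorted; with two classes the coding is a single 0/1 column
    for the second class and the decision rule is yhat >= 0.5, otherwise
    one column per class and argmax. X and Y are centred inside the fit and
    the intercept restored at prediction, so the exposed regression vectors
    b satisfy yhat = X b + intercept.
    """
    X, labels = _as_matrix_labels(data, labels)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if not 1 <= n_lvs <= rank:
        raise ValueError(
            f"n_lvs={n_lvs} exceeds the rank ({rank}) of the centred matrix"
        )
    Y, coding = _class_coding(labels, classes)
    pls = PLSRegression(n_components=n_lvs, scale=False)
    pls.fit(X, Y)
    b = pls.coef_.T                       # (p, n_coding)
    # Predicting the zero spectrum recovers the full intercept (the fit
    # centres X and Y internally; yhat = X b + intercept).
    intercept = pls.predict(np.zeros((1, X.shape[1]))).ravel().astype(float)
    rule = "threshold-0.5" if len(classes) == 2 else "argmax"
    return PLSDAModel(n_lvs=n_lvs, classes=classes, coding_columns=coding,
                      regression_vectors=b, intercept=intercept,
                      decision_rule=rule)


def plsda_predict(model: PLSDAModel, spectra) -> ScoreVector:
    """Predicted response yhat = X b (+ intercept) and class assignment."""
    X = spectra.intensities if isinstance(spectra, SpectraSet) else spectra
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.regression_vectors.shape[0]:
        raise ValueError(
            f"spectra have {X.shape[1]} points; model expects "
            f"{model.regression_vectors.shape[0]}"
        )
    yhat = X @ model.regression_vectors + model.intercept
    if model.decision_rule == "threshold-0.5":
        on_boundary = yhat[:, 0] == 0.5
        if on_boundary.any():
            warnings.warn(
                f"{int(on_boundary.sum())} predicted response(s) exactly at "
                "the 0.5 boundary; assigned to the positive class",
                stacklevel=2,
            )
        assigned = [model.classes[1] if v >= 0.5 else model.classes[0]
                    for v in yhat[:, 0]]
    else:
        assigned = _assign(yhat, model.classes, "max")
    return ScoreVector(classes=model.classes, scores=yhat,
                       assigned_class=assigned)
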