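"""PC-LDA recognition model.

Spectra are projected onto a small number of principal components of the
binned feature matrix (default 25) and classified by linear discriminant
analysis in that subspace: a Gaussian class-conditional model with pooled
within-class covariance. Class posteriors play the role of the recognition
"reliability" score — a prediction is *reported* only when the maximum
posterior reaches the threshold (default 0.75).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.special import logsumexp

from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_PCS = 25
DEFAULT_RIDGE = 1e-6
DEFAULT_THRESHOLD = 0.75


@dataclass
class PCAResult:
    """Mean-centred SVD subspace: orthonormal loadings + variance fractions."""

    mean: np.ndarray                      # (d,)
    loadings: np.ndarray                  # (d, k), orthonormal columns
    explained_variance_ratio: np.ndarray  # (k,), non-increasing
    scores: np.ndarray                    # (n, k)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.loadings


@dataclass
class LDAResult:
    """Pooled-covariance Gaussian discriminant fitted on PC scores."""

    classes: list
    class_means: np.ndarray  # (C, k)
    pooled_cov: np.ndarray   # (k, k), ridge-regularised
    priors: np.ndarray       # (C,), sums to 1
    ld_axes: np.ndarray      # (k, C-1) generalized eigenvectors for plotting


@dataclass
class PCLDAModel:
    """Fitted PCA subspace + linear discriminant classifier."""

    pca: PCAResult
    lda: LDAResult
    n_pcs: int
    bin_labels: np.ndarray | None = None

    @property
    def classes(self) -> list:
        return self.lda.classes

    # -- plain-text (JSON) serialization -------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "format": "iknife-pclda",
            "version": 1,
            "n_pcs": self.n_pcs,
            "mean": self.pca.mean.tolist(),
            "loadings": self.pca.loadings.tolist(),
            "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
            "classes": list(self.lda.classes),
            "class_means": self.lda.class_means.tolist(),
            "pooled_cov": self.lda.pooled_cov.tolist(),
            "priors": self.lda.priors.tolist(),
            "ld_axes": self.lda.ld_axes.tolist(),
            "bin_labels": None if self.bin_labels is None else np.asarray(self.bin_labels).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PCLDAModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "iknife-pclda":
            raise ValueError(f"{path} is not an iknife PC-LDA model file")
        pca = PCAResult(
            mean=np.asarray(payload["mean"]),
            loadings=np.asarray(payload["loadings"]),
            explained_variance_ratio=np.asarray(payload["explained_variance_ratio"]),
            scores=np.empty((0, payload["n_pcs"])),
        )
        lda = LDAResult(
            classes=payload["classes"],
            class_means=np.asarray(payload["class_means"]),
            pooled_cov=np.asarray(payload["pooled_cov"]),
            priors=np.asarray(payload["priors"]),
            ld_axes=np.asarray(payload["ld_axes"]),
        )
        bins = payload.get("bin_labels")
        return cls(pca=pca, lda=lda, n_pcs=payload["n_pcs"],
                   bin_labels=None if bins is None else np.asarray(bins))


@dataclass
class RecognitionResult:
    """Thresholded class call for one burn."""

    burn_id: str
    predicted: str
    posteriors: dict
    reliability: float
    reported: bool
    threshold: float = DEFAULT_THRESHOLD


def fit_pca(X: np.ndarray, n_pcs: int = DEFAULT_N_PCS) -> PCAResult:
    """Mean-centred SVD with a deterministic sign convention.

    Loadings are the right singular vectors; each column's first
    non-negligible element is made positive so refits are reproducible.
    ``n_pcs`` beyond the matrix rank is reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows to fit a PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(n, d) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    k = min(n_pcs, rank)
    if k < n_pcs:
        warnings.warn(f"n_pcs reduced from {n_pcs} to matrix rank {k}", stacklevel=2)
    loadings = Vt[:k].T.copy()
    for j in range(k):
        col = loadings[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            loadings[:, j] = -col
    total_var = float((s ** 2).sum())
    evr = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PCAResult(mean=mean, loadings=loadings,
                     explained_variance_ratio=evr, scores=Xc @ loadings)


def fit_lda(scores: np.ndarray, labels, ridge: float = DEFAULT_RIDGE,
            priors: str | np.ndarray = "equal") -> LDAResult:
    """Gaussian LDA on PC scores: class means, pooled covariance, priors.

    The pooled within-class covariance gets a ridge ``ridge * mean(diag)``
    to stay positive-definite when the PC count approaches the row count.
    LD axes for plotting are the top generalized eigenvectors of the
    between-class scatter against the pooled covariance.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    k = scores.shape[1]

    means = np.zeros((len(classes), k))
    pooled = np.zeros((k, k))
    counts = np.zeros(len(classes), dtype=int)
    for ci, c in enumerate(classes):
        rows = scores[labels == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
        counts[ci] = rows.shape[0]
        means[ci] = rows.mean(axis=0)
        centred = rows - means[ci]
        pooled += centred.T @ centred
    pooled /= (scores.shape[0] - len(classes))
    # absolute fallback keeps the matrix PD when within-class scatter is exactly 0
    scale = np.trace(pooled) / k if np.trace(pooled) > 0 else 1.0
    pooled = pooled + ridge * scale * np.eye(k)

    if isinstance(priors, str):
        if priors == "equal":
            pr = np.full(len(classes), 1.0 / len(classes))
        elif priors == "proportional":
            pr = counts / counts.sum()
        else:
            raise ValueError(f"unknown priors rule {priors!r}")
    else:
        pr = np.asarray(priors, dtype=float)
        pr = pr / pr.sum()

    grand = (counts[:, None] * means).sum(axis=0) / counts.sum()
    between = np.zeros((k, k))
    for ci in range(len(classes)):
        diff = (means[ci] - grand)[:, None]
        between += counts[ci] * (diff @ diff.T)
    vals, vecs = eigh(between, pooled)
    order = np.argsort(vals)[::-1]
    ld_axes = vecs[:, order[: len(classes) - 1]]

    return LDAResult(classes=classes, class_means=means, pooled_cov=pooled,
                     priors=pr, ld_axes=ld_axes)


def fit_pclda(matrix: FeatureMatrix, n_pcs: int = DEFAULT_N_PCS,
              ridge: float = DEFAULT_RIDGE,
              priors: str | np.ndarray = "equal") -> PCLDAModel:
    """Fit the full recognition model on a preprocessed feature matrix."""
    pca = fit_pca(matrix.values(), n_pcs)
    lda = fit_lda(pca.scores, matrix.metadata["tissue_class"].to_numpy(),
                  ridge=ridge, priors=priors)
    return PCLDAModel(pca=pca, lda=lda, n_pcs=pca.loadings.shape[1],
                      bin_labels=matrix.intensities.columns.to_numpy())


def _log_posteriors(model: PCLDAModel, z: np.ndarray) -> np.ndarray:
    """Unnormalised Gaussian log-posteriors of one PC-space point."""
    cov = model.lda.pooled_cov
    L = np.linalg.cholesky(cov)
    out = np.empty(len(model.classes))
    for ci in range(len(model.classes)):
        diff = z - model.lda.class_means[ci]
        sol = np.linalg.solve(L, diff)
        out[ci] = np.log(model.lda.priors[ci]) - 0.5 * float(sol @ sol)
    return out


def predict(model: PCLDAModel, vector: np.ndarray,
            threshold: float = DEFAULT_THRESHOLD,
            burn_id: str = "") -> RecognitionResult:
    """Classify one binned, normalised spectrum vector.

    Posterior(class) is proportional to prior x Gaussian density with the
    class mean and pooled covariance; the call is reported when the top
    posterior reaches the threshold.
    """
    vector = np.asarray(vector, dtype=float).ravel()
    if vector.shape[0] != model.pca.mean.shape[0]:
        raise ValueError(
            f"vector length {vector.shape[0]} does not match model bin count {model.pca.mean.shape[0]}"
        )
    z = model.pca.transform(vector)[0]
    logp = _log_posteriors(model, z)
    post = np.exp(logp - logsumexp(logp))
    best = int(np.argmax(post))
    reliability = float(post[best])
    return RecognitionResult(
        burn_id=burn_id,
        predicted=model.classes[best],
        posteriors={c: float(p) for c, p in zip(model.classes, post)},
        reliability=reliability,
        reported=reliability >= threshold,
        threshold=threshold,
    )


def predict_matrix(model: PCLDAModel, matrix: FeatureMatrix,
                   threshold: float = DEFAULT_THRESHOLD) -> list[RecognitionResult]:
    """Classify every row of a feature matrix."""
    return [
        predict(model, row, threshold=threshold, burn_id=str(burn))
        for burn, row in zip(matrix.intensities.index, matrix.values())
    ]
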