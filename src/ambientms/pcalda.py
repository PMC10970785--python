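"""Supervised PCA-LDA fingerprint model as a scikit-learn-style estimator.

The model reduces mean-centred (optionally normalized) binned spectra to
``n_pc`` principal components — capped by the one-fifth-of-data-points rule —
then solves Fisher's generalized eigenproblem in score space to obtain
``n_classes - 1`` linear discriminant axes. Per-class centroids and
(ridge-regularized) covariances in LD space drive Mahalanobis-distance
posterior probabilities for classification.

Conventions, chosen for bit-reproducibility:

* every PCA loading and LD axis is oriented so its largest-magnitude
  coefficient is positive;
* within-class scatter is pooled (standard Fisher formulation) for axis
  estimation, while per-class covariances are retained for scoring;
* LD axes are scaled so the pooled within-class covariance in LD space is
  the identity (generalized eigenvectors, B-orthonormal).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, ClassifierMixin

from .preprocessing import normalize_matrix

__all__ = [
    "max_pca_components",
    "ld_dimensions",
    "PCALDAClassifier",
    "fit_pcalda",
    "scree",
    "loading_ranks",
]


def max_pca_components(n_events: int, n_bins: int, n_classes: int) -> int:
    """Maximum admissible PCA component count.

    One-fifth of the number of data points, further capped by the degrees of
    freedom (events minus classes) and the number of bins, never below 1.
    """
    if n_events <= n_classes:
        raise ValueError("need more events than classes")
    return max(1, min(n_events // 5, n_events - n_classes, n_bins))


def ld_dimensions(n_classes: int) -> int:
    """Number of linear discriminant dimensions: classes minus one."""
    if n_classes < 2:
        raise ValueError("LDA requires at least 2 classes")
    return n_classes - 1


def _fix_signs(A: np.ndarray) -> np.ndarray:
    """Orient each column so its largest-magnitude coefficient is positive."""
    A = A.copy()
    for j in range(A.shape[1]):
        i = int(np.argmax(np.abs(A[:, j])))
        if A[i, j] < 0:
            A[:, j] = -A[:, j]
    return A


class PCALDAClassifier(ClassifierMixin, BaseEstimator):
    """PCA-LDA tissue classifier with Mahalanobis-probability assignment.

    Parameters
    ----------
    n_pc : int or "fifth"
        Number of principal components; "fifth" applies the
        one-fifth-of-data-points cap at fit time. An integer request is
        still clipped to the admissible maximum.
    n_ld : int or None
        Number of discriminant axes; None means classes minus one (clipped
        to n_pc).
    ridge : float
        Relative ridge added to the pooled within-class scatter before the
        generalized eigensolve (times trace/dim).
    cov_ridge : float
        Relative ridge added to each per-class LD-space covariance so that
        Mahalanobis distances are always defined.
    normalization : {"tic", "nonzero_median", "none"}
        Row normalization applied inside fit/predict, so prediction-time
        spectra are treated exactly like training spectra.
    threshold : float
        Minimum posterior probability for a classified call (no-call below).
    outlier_quantile : float
        Chi-square quantile (dof = n_ld) above which a point is an outlier
        with respect to every class.
    priors : sequence of float or None
        Class prior probabilities (None = uniform).
    feature_subset : sequence of int or None
        Bin indices the model is restricted to (sparse analysis);
        normalization is computed within the subset.
    """

    def __init__(self, n_pc="fifth", n_ld=None, ridge=1e-6, cov_ridge=1e-6,
                 normalization="tic", threshold=0.95, outlier_quantile=0.999,
                 priors=None, feature_subset=None):
        self.n_pc = n_pc
        self.n_ld = n_ld
        self.ridge = ridge
        self.cov_ridge = cov_ridge
        self.normalization = normalization
        self.threshold = threshold
        self.outlier_quantile = outlier_quantile
        self.priors = priors
        self.feature_subset = feature_subset

    # ------------------------------------------------------------------ fit

    def fit(self, X, y, specimens=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (events x bins)")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y disagree on the number of events")
        self.n_features_in_ = X.shape[1]
        if self.feature_subset is not None:
            self.feature_subset_ = np.asarray(self.feature_subset, dtype=int)
            X = X[:, self.feature_subset_]
        else:
            self.feature_subset_ = None

        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            small = classes[counts < 2]
            raise ValueError(f"classes with < 2 events: {list(small)}")
        self.classes_ = classes
        n, p = X.shape
        k = classes.size

        Xn = normalize_matrix(X, self.normalization)
        self.mean_ = Xn.mean(axis=0)
        Xc = Xn - self.mean_

        cap = max_pca_components(n, p, k)
        if self.n_pc == "fifth" or self.n_pc is None:
            n_pc = cap
        else:
            n_pc = max(1, min(int(self.n_pc), n - k, p))
        n_ld = ld_dimensions(k) if self.n_ld is None else int(self.n_ld)
        n_ld = max(1, min(n_ld, k - 1, n_pc))

        # PCA by SVD of the centred matrix. Components below the effective
        # numerical rank (e.g. the zero-variance direction induced by the
        # TIC sum constraint) are never retained: they would hand LDA
        # spurious zero-within-variance axes.
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        eigvals = s ** 2 / max(n - 1, 1)
        self.total_variance_ = float(eigvals.sum())
        rank_tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        effective_rank = int(np.sum(s > rank_tol))
        n_pc = max(1, min(n_pc, effective_rank))
        self.pca_loadings_ = _fix_signs(Vt[:n_pc].T)
        self.pca_eigenvalues_ = eigvals[:n_pc]
        T = Xc @ self.pca_loadings_

        # Fisher LDA in PCA-score space: maximize between- over pooled
        # within-class scatter via the generalized eigenproblem.
        grand = T.mean(axis=0)
        Sw = np.zeros((n_pc, n_pc))
        Sb = np.zeros((n_pc, n_pc))
        class_means = np.zeros((k, n_pc))
        for c in range(k):
            Tc = T[y_idx == c]
            mc = Tc.mean(axis=0)
            class_means[c] = mc
            R = Tc - mc
            Sw += R.T @ R
            d = (mc - grand)[:, None]
            Sb += counts[c] * (d @ d.T)
        lam = self.ridge * np.trace(Sw) / n_pc if np.trace(Sw) > 0 else self.ridge
        Sw_reg = Sw + (lam + 1e-300) * np.eye(n_pc)
        try:
            w, V = scipy.linalg.eigh(Sb, Sw_reg)
        except scipy.linalg.LinAlgError as err:  # pragma: no cover
            raise ValueError("within-class scatter is degenerate beyond the "
                             "ridge's reach") from err
        order = np.argsort(w)[::-1][:n_ld]
        self.ld_axes_ = _fix_signs(V[:, order])
        self.ld_eigenvalues_ = w[order]
        self.n_pc_ = n_pc
        self.n_ld_ = n_ld

        Z = T @ self.ld_axes_
        self.centroids_ = class_means @ self.ld_axes_
        covs, logdets, chols = [], [], []
        for c in range(k):
            Zc = Z[y_idx == c]
            C = np.cov(Zc, rowvar=False, ddof=1).reshape(n_ld, n_ld)
            C = C + (self.cov_ridge * np.trace(C) / n_ld + 1e-12) * np.eye(n_ld)
            covs.append(C)
            L = np.linalg.cholesky(C)
            chols.append(L)
            logdets.append(2.0 * float(np.sum(np.log(np.diag(L)))))
        self.covariances_ = covs
        self.log_dets_ = np.array(logdets)
        self._chol = chols

        if self.priors is None:
            self.priors_ = np.full(k, 1.0 / k)
        else:
            pr = np.asarray(self.priors, dtype=float)
            self.priors_ = pr / pr.sum()
        summary = {"n_events": int(n),
                   "per_class": {str(c): int(counts[i])
                                 for i, c in enumerate(classes)}}
        if specimens is not None:
            specimens = np.asarray(specimens)
            summary["per_specimen"] = {str(s): int((specimens == s).sum())
                                       for s in np.unique(specimens)}
        self.training_summary_ = summary
        return self

    # ----------------------------------------------------------- projection

    def _check_fitted(self):
        if not hasattr(self, "ld_axes_"):
            raise ValueError("model is not fitted")

    def _prepare(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError("binning mismatch: expected "
                             f"{self.n_features_in_} bins, got {X.shape[1]}")
        if self.feature_subset_ is not None:
            X = X[:, self.feature_subset_]
        return normalize_matrix(X, self.normalization) - self.mean_

    def pca_transform(self, X) -> np.ndarray:
        self._check_fitted()
        return self._prepare(X) @ self.pca_loadings_

    def transform(self, X) -> np.ndarray:
        """Project spectra to LD-space coordinates."""
        self._check_fitted()
        return self._prepare(X) @ self.pca_loadings_ @ self.ld_axes_

    # ------------------------------------------------------------- scoring

    def mahalanobis_sq(self, X) -> np.ndarray:
        """Per-class squared Mahalanobis distances, shape (n, n_classes)."""
        self._check_fitted()
        Z = self.transform(X)
        d2 = np.empty((Z.shape[0], self.classes_.size))
        for c, L in enumerate(self._chol):
            diff = (Z - self.centroids_[c]).T
            sol = scipy.linalg.solve_triangular(L, diff, lower=True)
            d2[:, c] = (sol ** 2).sum(axis=0)
        return d2

    def predict_log_proba(self, X) -> np.ndarray:
        from .classify import class_log_posteriors
        d2 = self.mahalanobis_sq(X)
        return class_log_posteriors(d2, log_dets=self.log_dets_,
                                    priors=self.priors_)

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        """Plain argmax-posterior class assignment (no thresholding).

        Ties break toward the first class in ascending label order.
        """
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def classify(self, X, event_ids=None, threshold=None, outlier_quantile=None):
        """Thresholded classification with no-call statuses.

        Returns a list of :class:`~ambientms.classify.ClassPrediction`; see
        :func:`ambientms.classify.predict_events`.
        """
        from .classify import predict_events
        return predict_events(self, X, event_ids=event_ids,
                              threshold=threshold,
                              outlier_quantile=outlier_quantile)


def fit_pcalda(X, y, n_pc="fifth", n_ld=None, ridge=1e-6,
               **kwargs) -> PCALDAClassifier:
    """Functional wrapper: fit a :class:`PCALDAClassifier` and return it."""
    return PCALDAClassifier(n_pc=n_pc, n_ld=n_ld, ridge=ridge, **kwargs).fit(X, y)


def scree(model: PCALDAClassifier) -> np.ndarray:
    """Explained-variance fractions of the retained principal components.

    Fractions are eigenvalue over total variance of the centred data, so
    they are nonincreasing and sum to at most 1.
    """
    model._check_fitted()
    if model.total_variance_ <= 0:
        return np.zeros_like(model.pca_eigenvalues_)
    return model.pca_eigenvalues_ / model.total_variance_


def loading_ranks(model: PCALDAClassifier) -> list[tuple[int, float]]:
    """Rank bins by their contribution to class discrimination.

    Importance of a bin is the Euclidean norm, over LD axes, of its weight
    in the composite PCA-then-LD projection. Sorted descending; ties break
    by ascending bin index. Bin indices refer to the model's input space
    (feature_subset is mapped back to original bins).
    """
    model._check_fitted()
    W = model.pca_loadings_ @ model.ld_axes_  # (bins_in_model, n_ld)
    importance = np.linalg.norm(W, axis=1)
    if model.feature_subset_ is not None:
        bins = model.feature_subset_
    else:
        bins = np.arange(importance.size)
    order = np.lexsort((bins, -importance))
    return [(int(bins[i]), float(importance[i])) for i in order]
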