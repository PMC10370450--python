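"""Multiclass kNN classification in latent space with novelty rejection.

Each internal node of the hierarchy carries one multiclass kNN classifier
over its direct children.  A query cell can be *rejected* instead of
labeled, for one of three reasons evaluated in this order:

``distance``
    the mean distance to the cell's nearest training neighbors exceeds a
    threshold fitted as the 99th percentile of the same statistic over the
    training cells (self excluded) -- the cell sits far from everything the
    classifier has seen;
``reconstruction``
    the squared error of projecting the cell onto a reduced PCA basis of
    the training data and back exceeds a threshold fitted by nested
    cross-validation to yield a target false-negative rate (default 0.5%)
    on held-out inliers -- the cell is off the training manifold;
``posterior``
    the largest neighbor-vote fraction falls below a threshold (default
    0.5) -- the label is ambiguous rather than novel.

Distance and reconstruction rejections signal a potentially new cell type;
posterior rejection signals ambiguity between known types.  All
comparisons are strict, so equality with a threshold accepts.

The number of neighbors defaults to 50 and, with ``dynamic_neighbors``
enabled, is automatically decreased to the size of the smallest class so
that small cell types can still win a vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import StateError, ValidationError

REJECTED = "REJECTED"

#: chunk size (query rows) for pairwise-distance blocks
_CHUNK = 2048


def effective_k(requested_k: int, child_class_sizes, dynamic: bool) -> int:
    """Neighbor count actually used by a node's classifier.

    With ``dynamic`` on, k shrinks to the smallest class size across the
    direct children so minority cell types are not outvoted by construction.
    """
    sizes = list(child_class_sizes)
    if not sizes:
        raise ValueError("child_class_sizes must be non-empty")
    if requested_k < 1 or any(s < 1 for s in sizes):
        raise ValueError("requested_k and all class sizes must be >= 1")
    if dynamic:
        return min(requested_k, min(sizes))
    return requested_k


def _knn_search(Q: np.ndarray, X: np.ndarray, k: int, metric: str = "euclidean",
                exclude_self: bool = False):
    """Exact k nearest training rows for each query row.

    Ties at the k-th position are broken by training-row index (stable
    argsort), making results independent of training-row permutation up to
    that declared tie-break.  Returns (indices, distances), each (m, k).
    """
    m = Q.shape[0]
    idx = np.empty((m, k), dtype=np.intp)
    dist = np.empty((m, k), dtype=np.float64)
    for start in range(0, m, _CHUNK):
        stop = min(start + _CHUNK, m)
        D = cdist(Q[start:stop], X, metric=metric)
        if exclude_self:
            rows = np.arange(start, stop)
            D[np.arange(stop - start), rows] = np.inf
        order = np.argsort(D, axis=1, kind="stable")[:, :k]
        idx[start:stop] = order
        dist[start:stop] = np.take_along_axis(D, order, axis=1)
    return idx, dist


def fit_distance_threshold(train_X: np.ndarray, k_effective: int,
                           metric: str = "euclidean") -> float:
    """99th percentile of training cells' mean distance to their own
    ``k_effective`` nearest neighbors (self excluded).

    Uses linear interpolation between order statistics, pinned so the
    threshold is bit-reproducible.
    """
    n = train_X.shape[0]
    if n <= k_effective:
        raise ValueError(f"need n > k (got n={n}, k={k_effective})")
    _, dist = _knn_search(train_X, train_X, k_effective, metric, exclude_self=True)
    mean_dist = dist.mean(axis=1)
    return float(np.percentile(mean_dist, 99, method="linear"))


@dataclass
class PCABasis:
    """Frozen linear encoder/decoder used by the reconstruction criterion."""

    components: np.ndarray  # (rank, d)
    mean: np.ndarray  # (d,)

    def reconstruction_error(self, X: np.ndarray) -> np.ndarray:
        """Squared error ||x - decode(encode(x))||^2 per row.

        A full-rank basis is the identity map, so its error is returned as
        exactly zero rather than accumulated rounding noise.
        """
        if self.components.shape[0] == self.components.shape[1]:
            return np.zeros(X.shape[0])
        Z = (X - self.mean) @ self.components.T
        Xr = Z @ self.components + self.mean
        return np.square(X - Xr).sum(axis=1)


def _fit_pca(X: np.ndarray, variance_kept: float) -> PCABasis:
    max_rank = min(X.shape[0], X.shape[1])
    if variance_kept >= 1.0:
        pca = PCA(n_components=max_rank)
    else:
        # smallest rank whose cumulative explained variance >= variance_kept
        pca = PCA(n_components=min(variance_kept, 1.0 - 1e-12))
    pca.fit(X)
    return PCABasis(components=pca.components_, mean=pca.mean_)


def fit_reconstruction_threshold(
    train_X: np.ndarray,
    train_y: np.ndarray,
    fn_rate: float = 0.005,
    n_folds: int = 5,
    variance_kept: float = 0.9,
    random_state: int = 0,
) -> tuple[float, PCABasis]:
    """Fit the reconstruction-error threshold by nested cross-validation.

    Per outer fold: fit a PCA basis (retaining ``variance_kept`` of the
    variance) on the training part, record the (1 - fn_rate) quantile of
    held-out squared reconstruction errors; the threshold is the median of
    the per-fold quantiles, i.e. the error that misrejects ``fn_rate`` of
    genuine inliers.  The returned basis is refit on all cells.
    """
    if not 0.0 < fn_rate < 1.0:
        raise ValueError("fn_rate must lie strictly between 0 and 1")
    n = train_X.shape[0]
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} cells (got {n})")
    train_y = np.asarray(train_y)
    _, counts = np.unique(train_y, return_counts=True)
    if counts.min() >= n_folds:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=random_state)
        splits = splitter.split(train_X, train_y)
    else:  # classes too small to stratify
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=random_state)
        splits = splitter.split(train_X)
    fold_quantiles = []
    for tr, te in splits:
        basis = _fit_pca(train_X[tr], variance_kept)
        errors = basis.reconstruction_error(train_X[te])
        fold_quantiles.append(np.quantile(errors, 1.0 - fn_rate, method="linear"))
    tau = float(np.median(fold_quantiles))
    return tau, _fit_pca(train_X, variance_kept)


class KNNRejectClassifier(ClassifierMixin, BaseEstimator):
    """Exact multiclass kNN with three fitted rejection thresholds.

    Parameters
    ----------
    k : int, default 50
        Requested neighbor count.
    dynamic_neighbors : bool, default True
        Shrink k to the smallest class size.
    tau_posterior : float, default 0.5
        Minimum winning vote fraction; below it the prediction is rejected
        as ambiguous.
    fn_rate : float, default 0.005
        Target inlier false-negative rate of the reconstruction criterion.
    variance_kept : float, default 0.9
        Fraction of variance retained by the reconstruction PCA basis
        (>= 1 keeps every component, disabling the criterion in effect).
    n_folds : int, default 5
        Outer folds of the nested CV fitting the reconstruction threshold.
    metric : str, default "euclidean"
        Distance metric in the latent space.
    reject_distance, reject_reconstruction, reject_posterior : bool
        Independent ablation switches; with all three off no cell is ever
        rejected.
    random_state : int, default 0
        Seeds the CV fold assignment.

    Attributes
    ----------
    classes_ : ndarray of class names, lexicographically sorted
    k_effective_ : int
    tau_distance_ : float
    tau_reconstruction_ : float
    pca_basis_ : PCABasis
    """

    def __init__(self, k=50, dynamic_neighbors=True, tau_posterior=0.5,
                 fn_rate=0.005, variance_kept=0.9, n_folds=5,
                 metric="euclidean", reject_distance=True,
                 reject_reconstruction=True, reject_posterior=True,
                 random_state=0):
        self.k = k
        self.dynamic_neighbors = dynamic_neighbors
        self.tau_posterior = tau_posterior
        self.fn_rate = fn_rate
        self.variance_kept = variance_kept
        self.n_folds = n_folds
        self.metric = metric
        self.reject_distance = reject_distance
        self.reject_reconstruction = reject_reconstruction
        self.reject_posterior = reject_posterior
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be (n, d) with one label per row")
        if not np.isfinite(X).all():
            raise ValidationError("X contains non-finite values")
        if not 0.0 <= self.tau_posterior <= 1.0:
            raise ValueError("tau_posterior must lie in [0, 1]")
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.shape[0] < 2:
            raise ValidationError(
                "degenerate node: a classifier needs at least 2 classes"
            )
        counts = np.bincount(y_idx)
        self.classes_ = classes.astype(object)
        self.k_effective_ = effective_k(self.k, counts, self.dynamic_neighbors)
        self.train_X_ = X
        self.train_y_ = y_idx
        self.tau_distance_ = fit_distance_threshold(X, self.k_effective_, self.metric)
        self.tau_reconstruction_, self.pca_basis_ = fit_reconstruction_threshold(
            X, y_idx, self.fn_rate, self.n_folds, self.variance_kept,
            self.random_state,
        )
        return self

    # ------------------------------------------------------------- predict

    def _check_query(self, Q):
        if not hasattr(self, "classes_"):
            raise StateError("classifier is not fitted")
        Q = np.asarray(Q, dtype=np.float64)
        if Q.ndim != 2 or Q.shape[1] != self.train_X_.shape[1]:
            raise ValidationError(
                f"query dimension {Q.shape} does not match training "
                f"dimension {self.train_X_.shape[1]}"
            )
        return Q

    def classify(self, Q) -> dict:
        """Full per-cell record: labels, rejection flags and reasons,
        posteriors, mean neighbor distance, reconstruction error.

        Posteriors are always returned, also for rejected cells.  On tied
        maximal posteriors the class with the smallest summed neighbor
        distance wins; a residual tie goes to the lexicographically
        smallest class name.
        """
        Q = self._check_query(Q)
        m, k = Q.shape[0], self.k_effective_
        n_classes = self.classes_.shape[0]
        idx, dist = _knn_search(Q, self.train_X_, k, self.metric)
        neighbor_classes = self.train_y_[idx]  # (m, k)

        posterior = np.zeros((m, n_classes))
        class_dist = np.zeros((m, n_classes))
        for c in range(n_classes):
            mask = neighbor_classes == c
            posterior[:, c] = mask.sum(axis=1) / k
            class_dist[:, c] = np.where(mask, dist, 0.0).sum(axis=1)

        best_post = posterior.max(axis=1)
        # tie-break: max posterior, then smallest summed neighbor distance,
        # then smallest class index (classes_ is sorted)
        pred = np.empty(m, dtype=np.intp)
        for i in range(m):
            tied = np.flatnonzero(posterior[i] == best_post[i])
            if tied.shape[0] > 1:
                tied = tied[class_dist[i, tied] == class_dist[i, tied].min()]
            pred[i] = tied[0]

        mean_dist = dist.mean(axis=1)
        recon_err = self.pca_basis_.reconstruction_error(Q)

        rejected = np.zeros(m, dtype=bool)
        reasons = np.full(m, "", dtype=object)
        # evaluation order: distance, reconstruction, posterior; the first
        # firing criterion is reported
        if self.reject_distance:
            fire = ~rejected & (mean_dist > self.tau_distance_)
            reasons[fire] = "distance"
            rejected |= fire
        if self.reject_reconstruction:
            fire = ~rejected & (recon_err > self.tau_reconstruction_)
            reasons[fire] = "reconstruction"
            rejected |= fire
        if self.reject_posterior:
            fire = ~rejected & (best_post < self.tau_posterior)
            reasons[fire] = "posterior"
            rejected |= fire

        labels = self.classes_[pred].astype(object)
        return {
            "labels": labels,
            "rejected": rejected,
            "reasons": reasons,
            "posterior": posterior,
            "best_posterior": best_post,
            "mean_distance": mean_dist,
            "reconstruction_error": recon_err,
        }

    def predict(self, Q):
        """Class names, with ``"REJECTED"`` where a rejection criterion fired."""
        out = self.classify(Q)
        labels = out["labels"].copy()
        labels[out["rejected"]] = REJECTED
        return labels

    def predict_proba(self, Q):
        return self.classify(Q)["posterior"]


def fit_node_classifier(class_arrays: dict[str, np.ndarray],
                        **params) -> KNNRejectClassifier:
    """Fit a node's classifier from per-child training pools.

    ``class_arrays`` maps each child display name to the (n_i, d) matrix of
    cells housed at or below that child.
    """
    for name, arr in class_arrays.items():
        if arr.shape[0] == 0:
            raise ValidationError(f"class {name!r} has no training cells")
    if len(class_arrays) < 2:
        raise ValidationError("degenerate node: fewer than 2 child classes")
    X = np.vstack(list(class_arrays.values()))
    y = np.concatenate(
        [np.full(a.shape[0], name, dtype=object) for name, a in class_arrays.items()]
    )
    return KNNRejectClassifier(**params).fit(X, y)
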