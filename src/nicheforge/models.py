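"""The five niche-model algorithms as scikit-learn-style estimators.

All estimators implement ``fit(X, y)`` with ``y`` in {0 presence-absent, 1
presence} and ``suitability(X)`` returning a continuous score. The two
presence-only methods (BIOCLIM envelope, Domain/Gower) use only the rows with
y == 1; GLM, SVM and random forest are discriminative and use both classes.
SVM margin scores are unbounded: ``needs_raster_normalization`` marks
estimators whose scores are mapped to [0, 1] by range normalization over the
full prediction raster rather than per point (rank order, hence AUC/TSS, is
unaffected).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted

from .grid import Raster, RasterStack

ALGORITHMS = ("bioclim", "domain", "glm", "svm", "rf")


def _check_Xy(X, y):
    X = check_array(X, dtype=np.float64, ensure_all_finite=True)
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y length mismatch")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary 0/1")
    return X, y.astype(int)


class BioclimEnvelope(BaseEstimator):
    """Classical percentile climate envelope (presence-only).

    For each variable the fitted percentile of a query value is
    p = (c_less + 0.5 * c_equal) / n over the training presences (mid-rank
    convention); the per-variable score is 2 * min(p, 1 - p), so the median
    scores 1 and anything outside the training range scores 0. The overall
    suitability is the minimum over variables: the envelope is only as good
    as its worst axis. Rank-based, hence invariant to monotone transforms.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        if y is not None:
            X = X[np.asarray(y).astype(int) == 1]
        if X.shape[0] < 2:
            raise ValueError("BIOCLIM requires at least 2 training presences")
        self.train_sorted_ = [np.sort(X[:, j]) for j in range(X.shape[1])]
        self.n_features_in_ = X.shape[1]
        return self

    def suitability(self, X) -> np.ndarray:
        check_is_fitted(self, "train_sorted_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        n = self.train_sorted_[0].size
        scores = np.empty((X.shape[0], self.n_features_in_))
        for j, col in enumerate(self.train_sorted_):
            less = np.searchsorted(col, X[:, j], side="left")
            leq = np.searchsorted(col, X[:, j], side="right")
            p = (less + 0.5 * (leq - less)) / n
            scores[:, j] = 2.0 * np.minimum(p, 1.0 - p)
        return scores.min(axis=1)

    @property
    def needs_raster_normalization(self) -> bool:
        return False


class DomainGower(BaseEstimator):
    """Domain: similarity to the nearest training presence in Gower distance.

    Gower distance to a training point is the mean over variables of the
    absolute difference scaled by that variable's training range (a
    zero-range variable contributes 0 when equal, else 1). Suitability is
    ``max(0, 1 - min_B d)``: 1 at any training point, 0 beyond one full
    average range.
    """

    #: queries are scored against training points in blocks of this many rows
    chunk_size: int = 2048

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        if y is not None:
            X = X[np.asarray(y).astype(int) == 1]
        if X.shape[0] < 1:
            raise ValueError("Domain requires at least 1 training presence")
        self.train_points_ = X
        self.ranges_ = X.max(axis=0) - X.min(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def suitability(self, X) -> np.ndarray:
        check_is_fitted(self, "train_points_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        r = self.ranges_
        zero = r == 0
        safe_r = np.where(zero, 1.0, r)
        out = np.empty(X.shape[0])
        for start in range(0, X.shape[0], self.chunk_size):
            q = X[start:start + self.chunk_size]
            diff = np.abs(q[:, None, :] - self.train_points_[None, :, :])
            terms = diff / safe_r
            if zero.any():
                terms[:, :, zero] = (diff[:, :, zero] != 0).astype(float)
            d = terms.mean(axis=2).min(axis=1)
            out[start:start + q.shape[0]] = np.maximum(0.0, 1.0 - d)
        return out

    @property
    def needs_raster_normalization(self) -> bool:
        return False


class GlmNicheModel(BaseEstimator):
    """Binomial GLM with logit link and linear terms, fit by maximum likelihood."""

    def __init__(self, max_iter: int = 1000):
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        if len(np.unique(y)) < 2:
            raise ValueError("GLM requires both classes in training data")
        # C=inf disables regularization: plain maximum-likelihood logit
        self.model_ = LogisticRegression(C=np.inf, solver="lbfgs",
                                         max_iter=self.max_iter)
        self.model_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def suitability(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(check_array(X, dtype=np.float64))[:, 1]

    @property
    def needs_raster_normalization(self) -> bool:
        return False


class SvmNicheModel(BaseEstimator):
    """Radial-kernel support vector machine scored by its signed margin.

    The decision-function value is unbounded, so the raster projection step
    range-normalizes it to [0, 1]; pointwise calls return the raw margin.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale", random_state: int = 0):
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        if len(np.unique(y)) < 2:
            raise ValueError("SVM requires both classes in training data")
        self.model_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                          random_state=self.random_state)
        self.model_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def suitability(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.decision_function(check_array(X, dtype=np.float64))

    @property
    def needs_raster_normalization(self) -> bool:
        return True


class RandomForestNicheModel(BaseEstimator):
    """Bagged classification trees; score = fraction of trees voting presence."""

    def __init__(self, n_estimators: int = 500, random_state: int = 0):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        if len(np.unique(y)) < 2:
            raise ValueError("random forest requires both classes in training data")
        self.model_ = RandomForestClassifier(n_estimators=self.n_estimators,
                                             random_state=self.random_state)
        self.model_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def suitability(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(check_array(X, dtype=np.float64))[:, 1]

    @property
    def needs_raster_normalization(self) -> bool:
        return False


def make_model(algorithm: str, seed: int = 0, rf_trees: int = 500) -> BaseEstimator:
    """Instantiate one of the five algorithms by name."""
    if algorithm == "bioclim":
        return BioclimEnvelope()
    if algorithm == "domain":
        return DomainGower()
    if algorithm == "glm":
        return GlmNicheModel()
    if algorithm == "svm":
        return SvmNicheModel(random_state=seed)
    if algorithm == "rf":
        return RandomForestNicheModel(n_estimators=rf_trees, random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def predict_raster(model: BaseEstimator, stack: RasterStack,
                   var_names: list[str]) -> Raster:
    """Project a fitted model cell-wise onto a stack; nodata propagates.

    Estimators flagged ``needs_raster_normalization`` are range-normalized
    over the valid cells of the projection.
    """
    valid = stack.valid_flat_indices
    X = stack.values_at_cells(valid, var_names)
    scores = np.asarray(model.suitability(X), dtype=np.float64)
    if getattr(model, "needs_raster_normalization", False):
        lo, hi = scores.min(), scores.max()
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
        else:
            scores = np.full_like(scores, 0.5)
    out = np.full(stack.grid.n_cells, np.nan)
    out[valid] = scores
    return Raster(grid=stack.grid, values=out.reshape(stack.grid.shape))
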