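"""Diagnostic panel search with a radial-kernel SVM, and 2D clustering.

Leave-one-out cross-validation (LOOCV) over a cost x gamma grid: for each
grid point every sample is predicted once by an SVM trained on the other
n-1 samples, with feature standardization computed inside each training
fold so no information leaks from the held-out sample.  Panel search adds
features greedily (or exhaustively) to maximize LOOCV accuracy, mirroring
the search for a minimal gene panel that separates cases from controls.

Also provides two-dimensional hierarchical clustering of samples with a
misclassification count against the known groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import sklearn
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.svm import SVC

from .exceptions import ValidationError

__all__ = [
    "SvmConfig",
    "PanelResult",
    "loocv_svm",
    "search_feature_panel",
    "hierarchical_cluster",
    "cluster_misclassification",
    "SvmPanelModel",
]


def _default_cost_grid() -> tuple[float, ...]:
    return tuple(2.0 ** np.arange(-5, 16, 2))  # 2^-5 .. 2^15, x4 steps


def _default_gamma_grid() -> tuple[float, ...]:
    return tuple(2.0 ** np.arange(-15, 4, 2))  # 2^-15 .. 2^3, x4 steps


@dataclass(frozen=True)
class SvmConfig:
    """Radial-kernel SVM tuning grid."""

    cost_grid: tuple[float, ...] = field(default_factory=_default_cost_grid)
    gamma_grid: tuple[float, ...] = field(default_factory=_default_gamma_grid)
    seed: int = 0

    def __post_init__(self):
        if len(self.cost_grid) == 0 or len(self.gamma_grid) == 0:
            raise ValidationError("grids must be non-empty")
        if min(self.cost_grid) <= 0 or min(self.gamma_grid) <= 0:
            raise ValidationError("grid values must be positive")


@dataclass
class PanelResult:
    """Outcome of an SVM LOOCV evaluation or panel search."""

    feature_ids: list[str]
    loocv_accuracy: float
    per_sample_predictions: pd.Series
    chosen_cost: float
    chosen_gamma: float
    per_size: dict[int, "PanelResult"] | None = None

    def summary(self) -> str:
        return (
            f"SVM panel: {', '.join(map(str, self.feature_ids))}\n"
            f"  LOOCV accuracy : {self.loocv_accuracy:.3f}\n"
            f"  cost / gamma   : {self.chosen_cost:g} / {self.chosen_gamma:g}"
        )


def _validate_features(features, labels):
    x = np.asarray(
        features.to_numpy() if isinstance(features, pd.DataFrame) else features,
        dtype=float,
    )
    if x.ndim != 2:
        raise ValidationError("feature matrix must be 2-D (samples x features)")
    if np.isnan(x).any():
        raise ValidationError("feature matrix contains missing values")
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("labels contain a single class")
    if classes.size > 2:
        raise ValidationError("only two-class problems are supported")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValidationError("each class needs at least 2 samples")
    return x, y


def _loocv_folds(x: np.ndarray):
    """Per-fold standardized train/test views and squared-distance matrices."""
    n = x.shape[0]
    folds = []
    for i in range(n):
        tr = np.delete(x, i, axis=0)
        mu, sd = tr.mean(axis=0), tr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        trs = (tr - mu) / sd
        tes = (x[i] - mu) / sd
        d_tr = squareform(pdist(trs, "sqeuclidean"))
        d_te = ((trs - tes) ** 2).sum(axis=1)
        folds.append((d_tr, d_te))
    return folds


def loocv_svm(features, labels, config: SvmConfig | None = None) -> PanelResult:
    """Tuned radial-kernel SVM evaluated by leave-one-out cross-validation.

    For every (cost, gamma) grid point the full LOOCV accuracy is
    computed; the returned result carries the grid point with maximal
    accuracy (ties: smallest cost, then smallest gamma) and its
    per-sample predictions.
    """
    config = config or SvmConfig()
    x, y = _validate_features(features, labels)
    n = x.shape[0]
    index = (
        features.index
        if isinstance(features, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    names = (
        [str(c) for c in features.columns]
        if isinstance(features, pd.DataFrame)
        else [str(j) for j in range(x.shape[1])]
    )
    folds = _loocv_folds(x)
    idx_all = np.arange(n)
    best = None  # (correct, cost, gamma, preds)
    with sklearn.config_context(assume_finite=True):
        for cost in sorted(config.cost_grid):
            for gamma in sorted(config.gamma_grid):
                preds = np.empty(n, dtype=y.dtype)
                errors = 0
                # abort once this grid point provably cannot beat the best
                max_errors = n if best is None else n - best[0] - 1
                aborted = False
                for i in range(n):
                    d_tr, d_te = folds[i]
                    ytr = y[idx_all != i]
                    clf = SVC(C=cost, kernel="precomputed")
                    clf.fit(np.exp(-gamma * d_tr), ytr)
                    pred = clf.predict(np.exp(-gamma * d_te)[None, :])[0]
                    preds[i] = pred
                    if pred != y[i]:
                        errors += 1
                        if errors > max_errors:
                            aborted = True
                            break
                if aborted:
                    continue
                correct = n - errors
                if best is None or correct > best[0]:
                    best = (correct, cost, gamma, preds.copy())
                    if errors == 0:
                        # scanned in ascending (cost, gamma) order, so the
                        # first perfect point is the tie-rule winner
                        break
            if best is not None and best[0] == n:
                break
    correct, cost, gamma, preds = best
    return PanelResult(
        feature_ids=names,
        loocv_accuracy=correct / n,
        per_sample_predictions=pd.Series(preds, index=index),
        chosen_cost=float(cost),
        chosen_gamma=float(gamma),
    )


def _majority_fraction(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    return counts.max() / counts.sum()


def search_feature_panel(
    features: pd.DataFrame,
    labels,
    config: SvmConfig | None = None,
    max_size: int = 6,
    mode: str = "greedy",
) -> PanelResult:
    """Search for a small feature panel maximizing LOOCV accuracy.

    ``greedy`` forward selection adds, at each step, the feature (in
    lexicographic order on ties) that maximizes the LOOCV accuracy of the
    extended panel; it stops at accuracy 1.0, at ``max_size``, or when no
    addition improves the accuracy (which keeps the accuracy path
    monotonically non-decreasing).  ``exhaustive`` evaluates every subset
    of each size up to ``max_size`` (candidate count must be <= 30) and
    returns the overall best, with the per-size winners attached.
    """
    config = config or SvmConfig()
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features, dtype=float))
        features.columns = [str(c) for c in features.columns]
    candidates = sorted(map(str, features.columns))
    features = features.loc[:, candidates]
    if max_size > len(candidates):
        raise ValidationError("max_size exceeds the number of candidate features")
    if max_size < 1:
        raise ValidationError("max_size must be at least 1")
    _, y = _validate_features(features, labels)

    if mode == "greedy":
        selected: list[str] = []
        best_result = None
        while len(selected) < max_size:
            round_best = None
            for cand in candidates:
                if cand in selected:
                    continue
                res = loocv_svm(features[selected + [cand]], labels, config)
                if round_best is None or res.loocv_accuracy > round_best.loocv_accuracy:
                    round_best = res
            if round_best is None:
                break
            if (
                best_result is not None
                and round_best.loocv_accuracy <= best_result.loocv_accuracy
            ):
                break  # no improvement: keep the shorter panel
            selected = list(round_best.feature_ids)
            best_result = round_best
            if best_result.loocv_accuracy == 1.0:
                break
        result = best_result
    elif mode == "exhaustive":
        if len(candidates) > 30:
            raise ValidationError("exhaustive mode requires <= 30 candidates")
        per_size: dict[int, PanelResult] = {}
        result = None
        for size in range(1, max_size + 1):
            size_best = None
            for combo in combinations(candidates, size):
                res = loocv_svm(features[list(combo)], labels, config)
                if size_best is None or res.loocv_accuracy > size_best.loocv_accuracy:
                    size_best = res
            per_size[size] = size_best
            if result is None or size_best.loocv_accuracy > result.loocv_accuracy:
                result = size_best
        result.per_size = per_size
    else:
        raise ValidationError(f"unknown mode: {mode!r}")

    if result.loocv_accuracy <= _majority_fraction(np.asarray(labels)):
        warnings.warn(
            "panel accuracy does not exceed the majority-class proportion; "
            "the selected features carry no detectable signal"
        )
    return result


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "average",
) -> tuple[list, pd.Series]:
    """Agglomerative clustering of samples (columns) of a feature matrix.

    ``distance`` is ``"correlation"`` (one minus Pearson) or
    ``"euclidean"``.  Returns the dendrogram leaf ordering of sample IDs
    and the 2-cluster assignment from cutting the tree.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if distance == "correlation":
        if np.any(x.std(axis=1) == 0):
            raise ValidationError(
                "correlation distance undefined for constant samples"
            )
        d = pdist(x, metric="correlation")
    elif distance == "euclidean":
        d = pdist(x, metric="euclidean")
    else:
        raise ValidationError(f"unknown distance: {distance!r}")
    z = hierarchy.linkage(d, method=linkage)
    order = [matrix.columns[i] for i in hierarchy.leaves_list(z)]
    assignment = hierarchy.fcluster(z, t=2, criterion="maxclust")
    return order, pd.Series(assignment, index=matrix.columns, name="cluster")


def cluster_misclassification(assignment: pd.Series, truth: pd.Series) -> int:
    """Misclassified samples under the best cluster-to-group mapping.

    Each cluster is assigned one of the two true group labels (the two
    bijective mappings are tried, the better one kept); a sample is
    misclassified when its true label differs from its cluster's label.
    """
    if set(assignment.index) != set(truth.index):
        raise ValidationError("assignment and truth must cover the same samples")
    truth = truth.loc[assignment.index]
    clusters = sorted(assignment.unique())
    groups = sorted(truth.unique())
    if len(clusters) == 1:
        # degenerate single cluster: best mapping labels it by majority
        return int(len(truth) - truth.value_counts().max())
    if len(clusters) != 2 or len(groups) != 2:
        raise ValidationError("expected 2 clusters and 2 true groups")
    m1 = {clusters[0]: groups[0], clusters[1]: groups[1]}
    m2 = {clusters[0]: groups[1], clusters[1]: groups[0]}
    err1 = int((assignment.map(m1) != truth).sum())
    err2 = int((assignment.map(m2) != truth).sum())
    return min(err1, err2)


class SvmPanelModel:
    """Panel search wrapper: features (samples x genes) plus binary labels."""

    def __init__(self, features: pd.DataFrame, labels, config: SvmConfig | None = None):
        self.features = features
        self.labels = labels
        self.config = config or SvmConfig()

    def fit(self, max_size: int = 6, mode: str = "greedy") -> PanelResult:
        return search_feature_panel(
            self.features, self.labels, self.config, max_size, mode
        )
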