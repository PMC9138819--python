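"""Feature-weighted rotation forest.

The classifier has two stages. First, every feature is scored by the
chi-square statistic of its (discretized) value x class contingency table,

    chi2(F) = sum_i sum_j (O_ij - E_ij)^2 / E_ij,
    O_ij = count(F = v_i and C = c_j),  E_ij = count(F = v_i) count(C = c_j) / N,

features are ranked by descending weight and the lowest-weight fraction is
removed. Second, a rotation forest is grown on the retained features: for
each of L trees the features are randomly partitioned into K subsets of
near-equal size; per subset a full PCA is fitted on a bootstrap sample of
round(r * N) training rows; the K square loading blocks are assembled into a
block-diagonal rotation matrix R_i (columns re-ordered to the original
feature order); and a CART tree is fitted on X R_i. A test sample's class
confidence is the average of the trees' leaf class frequencies on their
rotated inputs, and prediction takes the class of highest confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier


@dataclass(frozen=True)
class ChiSquareWeights:
    """Per-feature chi-square weights plus the discretization edges used."""

    weights: np.ndarray
    bin_edges: list[np.ndarray | None]

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", weights)
        if (weights < 0).any():
            raise ValueError("chi-square weights must be non-negative")
        if len(self.bin_edges) != weights.size:
            raise ValueError("bin_edges length must match weight count")


def discretize(X: np.ndarray, n_bins: int = 5,
               ) -> tuple[np.ndarray, list[np.ndarray | None]]:
    """Bin continuous columns into equal-frequency categories.

    Columns with at most two distinct values (fingerprint bits, constants)
    pass through as integer codes with ``None`` edges. Continuous columns are
    cut at interior quantiles into at most ``n_bins`` categories; duplicate
    quantiles collapse, so heavily tied columns get fewer bins. Deterministic.

    Returns the categorical code matrix and the per-column interior bin edges.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    X = np.asarray(X, dtype=float)
    codes = np.empty(X.shape, dtype=np.int32)
    edges_out: list[np.ndarray | None] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        distinct = np.unique(col)
        if distinct.size <= 2:
            codes[:, j] = np.searchsorted(distinct, col)
            edges_out.append(None)
        else:
            qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
            edges = np.unique(qs)
            codes[:, j] = np.searchsorted(edges, col, side="left")
            edges_out.append(edges)
    return codes, edges_out


def apply_bin_edges(X: np.ndarray, bin_edges: list[np.ndarray | None],
                    binary_levels: list[np.ndarray | None]) -> np.ndarray:
    """Re-bin new data with edges learned at fit time (internal helper)."""
    X = np.asarray(X, dtype=float)
    codes = np.empty(X.shape, dtype=np.int32)
    for j in range(X.shape[1]):
        if bin_edges[j] is None:
            codes[:, j] = np.searchsorted(binary_levels[j], X[:, j])
        else:
            codes[:, j] = np.searchsorted(bin_edges[j], X[:, j], side="left")
    return codes


def chi2_weights(Xcat: np.ndarray, y: np.ndarray,
                 bin_edges: list[np.ndarray | None] | None = None) -> ChiSquareWeights:
    """Chi-square statistic of each categorical feature against the class.

    For feature F with observed counts O_ij over value-class cells and
    independence expectations E_ij = row_i * col_j / N, the weight is
    sum (O_ij - E_ij)^2 / E_ij; cells with E_ij = 0 contribute nothing.
    Requires both classes present.
    """
    Xcat = np.asarray(Xcat)
    y = np.asarray(y)
    if Xcat.shape[0] != y.size:
        raise ValueError("Xcat row count must equal label count")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("chi-square weighting needs both classes present")
    N = y.size
    y_codes = np.searchsorted(classes, y)
    class_counts = np.bincount(y_codes, minlength=classes.size).astype(float)
    weights = np.empty(Xcat.shape[1], dtype=float)
    for j in range(Xcat.shape[1]):
        values, v_codes = np.unique(Xcat[:, j], return_inverse=True)
        obs = np.zeros((values.size, classes.size))
        np.add.at(obs, (v_codes, y_codes), 1.0)
        value_counts = obs.sum(axis=1)
        expected = np.outer(value_counts, class_counts) / N
        with np.errstate(invalid="ignore", divide="ignore"):
            cells = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
        weights[j] = cells.sum()
    if bin_edges is None:
        bin_edges = [None] * Xcat.shape[1]
    return ChiSquareWeights(weights=weights, bin_edges=bin_edges)


def select_features(w: ChiSquareWeights, keep_fraction: float) -> np.ndarray:
    """Indices of the ceil(keep_fraction * n) highest-weight features.

    Ties break toward the lower original index; the result is sorted
    ascending so column order is stable downstream.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    n = w.weights.size
    k = math.ceil(keep_fraction * n)
    # stable sort on negated weights: equal weights keep index order
    order = np.argsort(-w.weights, kind="stable")
    return np.sort(order[:k])


def _subset_pca(block: np.ndarray) -> np.ndarray:
    """Full PCA loading matrix of a (bootstrap) sample block.

    Eigendecomposition of the population covariance gives a complete
    orthonormal basis even when rows < columns or variance vanishes, so the
    loading block is always square and orthonormal. Components are ordered
    by descending eigenvalue; each eigenvector's sign is fixed so its
    largest-magnitude entry is positive.
    """
    centered = block - block.mean(axis=0)
    cov = centered.T @ centered / block.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvecs = eigvecs[:, order]
    flips = np.sign(eigvecs[np.abs(eigvecs).argmax(axis=0), np.arange(eigvecs.shape[1])])
    flips[flips == 0] = 1.0
    return eigvecs * flips


class FeatureWeightedRotationForest:
    """Chi-square feature weighting + rotation-forest ensemble (binary).

    Parameters
    ----------
    n_subsets : int
        K, the number of feature subsets each rotation is built from.
    bootstrap_fraction : float
        r in (0, 1]: each subset's PCA is fitted on a bootstrap sample of
        round(r * N) training rows drawn with replacement.
    n_trees : int
        L, the ensemble size.
    chi2_keep : float
        Fraction of features retained after chi-square ranking (1.0 keeps all).
    n_bins : int
        Equal-frequency bins used to discretize continuous features for the
        chi-square stage; binary columns are left untouched.
    seed : int
        Drives feature partitioning, bootstraps, and tree randomness.

    Tuned defaults (K, r, L) = (16, 0.8, 21).
    """

    def __init__(self, n_subsets: int = 16, bootstrap_fraction: float = 0.8,
                 n_trees: int = 21, chi2_keep: float = 1.0, n_bins: int = 5,
                 seed: int = 0):
        self.n_subsets = n_subsets
        self.bootstrap_fraction = bootstrap_fraction
        self.n_trees = n_trees
        self.chi2_keep = chi2_keep
        self.n_bins = n_bins
        self.seed = seed

    def get_params(self) -> dict:
        return {
            "n_subsets": self.n_subsets,
            "bootstrap_fraction": self.bootstrap_fraction,
            "n_trees": self.n_trees,
            "chi2_keep": self.chi2_keep,
            "n_bins": self.n_bins,
            "seed": self.seed,
        }

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FeatureWeightedRotationForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per label")
        if np.unique(y).size < 2:
            raise ValueError("training labels must contain both classes")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

        self.n_features_in_ = X.shape[1]
        codes, edges = discretize(X, n_bins=self.n_bins)
        self.bin_edges_ = edges
        self.binary_levels_ = [
            np.unique(X[:, j]) if edges[j] is None else None
            for j in range(X.shape[1])
        ]
        self.chi2_ = chi2_weights(codes, y, bin_edges=edges)
        self.retained_ = select_features(self.chi2_, self.chi2_keep)
        F = self.retained_.size
        if self.n_subsets > F:
            raise ValueError(
                f"n_subsets={self.n_subsets} exceeds retained feature count {F}"
            )

        Xr = X[:, self.retained_]
        N = X.shape[0]
        n_boot = max(1, round(self.bootstrap_fraction * N))
        rng = np.random.default_rng(self.seed)
        self.rotations_: list[np.ndarray] = []
        self.partitions_: list[list[np.ndarray]] = []
        self.trees_: list[DecisionTreeClassifier] = []
        for _ in range(self.n_trees):
            perm = rng.permutation(F)
            partition = [np.sort(part) for part in np.array_split(perm, self.n_subsets)]
            R = np.zeros((F, F))
            for idx in partition:
                sample = rng.integers(0, N, size=n_boot)
                R[np.ix_(idx, idx)] = _subset_pca(Xr[sample][:, idx])
            tree = DecisionTreeClassifier(
                criterion="gini", random_state=int(rng.integers(0, 2**31 - 1))
            )
            tree.fit(Xr @ R, y)
            self.rotations_.append(R)
            self.partitions_.append(partition)
            self.trees_.append(tree)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "trees_"):
            raise RuntimeError("model is not fitted")

    def predict_confidence(self, X: np.ndarray) -> np.ndarray:
        """Average tree class probabilities on rotated inputs; rows sum to 1.

        ``X`` must have the original (pre-selection) feature width; the
        retained columns are selected internally.
        """
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} columns, got {X.shape}"
            )
        Xr = X[:, self.retained_]
        conf = np.zeros((X.shape[0], 2))
        for tree, R in zip(self.trees_, self.rotations_):
            proba = tree.predict_proba(Xr @ R)
            for k, cls in enumerate(tree.classes_):
                conf[:, int(cls)] += proba[:, k]
        return conf / self.n_trees

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class of highest confidence; an exact 0.5/0.5 tie yields class 0."""
        conf = self.predict_confidence(X)
        return (conf[:, 1] > conf[:, 0]).astype(int)

    def save(self, path: str | Path) -> None:
        """Serialize the fitted model to one archive; loading reproduces
        predictions bit-identically."""
        self._check_fitted()
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "FeatureWeightedRotationForest":
        model = joblib.load(Path(path))
        if not isinstance(model, FeatureWeightedRotationForest):
            raise TypeError(f"{path} does not contain a FeatureWeightedRotationForest")
        return model
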