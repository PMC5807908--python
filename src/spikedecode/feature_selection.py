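"""Filter-based feature ranking criteria.

Five criteria map a :class:`~spikedecode.preprocessing.FeatureTable` to an
ordered :class:`FeatureRanking` (best feature first):

* ``wilcoxon`` -- paired signed-rank test of movement vs baseline rate per
  feature; features kept only if p < 0.001 with a positive median
  difference, ranked by decreasing median difference.  The kept list may
  be shorter than the feature count.
* ``relative_importance`` -- variance across movement classes of the
  class-mean movement-only rate (movement minus baseline).
* ``pca`` -- principal components of the mean-centered matrix, ranked by
  explained-variance fraction; a transform, not a subset selector, so its
  "features" are component projections.
* ``mim`` -- mutual information I(C;Y) between the (discretized) feature
  value and the class label, in bits.
* ``random`` -- uniform random permutation, the control condition.

Ties are always broken by ascending feature index (stable sort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .preprocessing import FeatureTable
from .synthetic import REST_LABEL

METHODS = ("wilcoxon", "relative_importance", "pca", "mim", "random")


@dataclass
class MIEstimatorConfig:
    """Discretization used by the plug-in mutual-information estimator."""

    n_bins: int = 10
    binning: str = "quantile"  # or "equal-width"
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.binning not in ("quantile", "equal-width"):
            raise ValueError(f"unknown binning {self.binning!r}")


@dataclass
class FeatureRanking:
    """An ordered subset of feature column indices with criterion scores."""

    method: str
    order: np.ndarray  # column indices into the source table, best first
    scores: np.ndarray | None  # aligned with order, non-increasing
    feature_ids: list[str]
    n_source_features: int
    transform: object | None = None  # fitted PCA for method == "pca"
    extras: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature_id": self.feature_ids,
                "score": self.scores if self.scores is not None else np.nan,
                "method": self.method,
            }
        )


def _stable_descending(scores: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Order candidate indices by descending score, ties by ascending index."""
    order = np.argsort(-scores[candidates], kind="stable")
    return candidates[order]


def rank_wilcoxon(table: FeatureTable, alpha: float = 0.001) -> FeatureRanking:
    """Keep features firing significantly above baseline during movement.

    Per feature, the per-trial paired differences (movement-epoch mean
    minus same-trial baseline mean, movement trials only) are tested with
    the Wilcoxon signed-rank test.  Features with p < ``alpha`` and a
    positive median difference are kept, ranked by decreasing median
    difference.  Features whose differences are identically zero are
    excluded (the test is undefined).
    """
    mv = table.y != REST_LABEL
    if not mv.any():
        raise ValueError("no movement trials in table")
    diffs = table.X[mv] - table.baseline_X[mv]
    kept, medians, pvalues = [], [], []
    for f in range(table.n_features):
        d = diffs[:, f]
        if np.allclose(d, 0.0):
            continue
        try:
            res = stats.wilcoxon(d)
        except ValueError:
            continue
        med = float(np.median(d))
        if res.pvalue < alpha and med > 0:
            kept.append(f)
            medians.append(med)
            pvalues.append(float(res.pvalue))
    kept = np.asarray(kept, dtype=int)
    med_arr = np.full(table.n_features, -np.inf)
    if kept.size:
        med_arr[kept] = medians
    order = _stable_descending(med_arr, kept)
    return FeatureRanking(
        method="wilcoxon",
        order=order,
        scores=med_arr[order],
        feature_ids=[table.feature_ids[i] for i in order],
        n_source_features=table.n_features,
        extras={"pvalues": dict(zip(kept.tolist(), pvalues))},
    )


def relative_importance_scores(table: FeatureTable) -> np.ndarray:
    """Inter-movement variance of class-mean movement-only firing rates.

    m[t, f] = X[t, f] - baseline_X[t, f] over movement trials; the score of
    feature f is the variance (ddof=1) across classes of the class means of
    m, i.e. how differently the feature modulates for different movements.
    """
    mv = table.y != REST_LABEL
    labels = table.y[mv]
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("relative importance needs >= 2 movement classes")
    m = table.X[mv] - table.baseline_X[mv]
    class_means = np.empty((classes.size, table.n_features))
    for i, c in enumerate(classes):
        rows = labels == c
        if not rows.any():
            raise ValueError(f"class {c} has no trials")
        class_means[i] = m[rows].mean(axis=0)
    return class_means.var(axis=0, ddof=1)


def rank_relative_importance(table: FeatureTable) -> FeatureRanking:
    scores = relative_importance_scores(table)
    order = _stable_descending(scores, np.arange(table.n_features))
    return FeatureRanking(
        method="relative_importance",
        order=order,
        scores=scores[order],
        feature_ids=[table.feature_ids[i] for i in order],
        n_source_features=table.n_features,
    )


def discretize(values: np.ndarray, config: MIEstimatorConfig) -> np.ndarray:
    """Map continuous values to bin codes per the estimator config."""
    values = np.asarray(values, dtype=float)
    if config.binning == "quantile":
        edges = np.quantile(values, np.linspace(0, 1, config.n_bins + 1))
    else:
        edges = np.linspace(values.min(), values.max(), config.n_bins + 1)
    edges = np.unique(edges)[1:-1]  # interior edges; duplicates collapse
    return np.digitize(values, edges)


def mutual_information(
    values: np.ndarray,
    labels: np.ndarray,
    config: MIEstimatorConfig | None = None,
) -> float:
    """Plug-in estimate of I(C;Y) = H(C) - H(C|Y) in bits.

    ``C`` is the discretized feature value, ``Y`` the class label.  The
    estimate is non-negative and bounded by min(H(C), H(Y)).
    """
    if config is None:
        config = MIEstimatorConfig()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels must have equal length")
    if values.shape[0] < config.n_bins:
        raise ValueError(
            f"need at least n_bins={config.n_bins} samples, got {values.shape[0]}"
        )
    c = discretize(values, config)
    _, c_codes = np.unique(c, return_inverse=True)
    _, y_codes = np.unique(labels, return_inverse=True)
    n = values.shape[0]
    joint = np.zeros((c_codes.max() + 1, y_codes.max() + 1))
    np.add.at(joint, (c_codes, y_codes), 1.0)
    p_joint = joint / n
    p_c = p_joint.sum(axis=1)
    p_y = p_joint.sum(axis=0)

    def _h(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum() / np.log(config.log_base))

    mi = _h(p_c) + _h(p_y) - _h(p_joint.ravel())
    return max(mi, 0.0)


def rank_mim(
    table: FeatureTable, config: MIEstimatorConfig | None = None
) -> FeatureRanking:
    """Rank every feature by mutual information with the class label."""
    scores = np.array(
        [mutual_information(table.X[:, f], table.y, config) for f in range(table.n_features)]
    )
    order = _stable_descending(scores, np.arange(table.n_features))
    return FeatureRanking(
        method="mim",
        order=order,
        scores=scores[order],
        feature_ids=[table.feature_ids[i] for i in order],
        n_source_features=table.n_features,
    )


def rank_pca(table: FeatureTable, n_components: int | None = None) -> FeatureRanking:
    """Principal components of mean-centered X, ranked by explained variance.

    The returned "features" are component projections; the fitted
    transform is retained so unseen rows can be projected with the same
    loadings.  In cross-validated decoding the transform is re-fitted on
    each training partition to avoid leakage.
    """
    if table.n_trials < 2:
        raise ValueError("PCA needs at least 2 rows")
    X = table.X
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("PCA undefined for zero-variance data")
    if n_components is None:
        n_components = min(table.n_trials - 1, table.n_features)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    scores = pca.explained_variance_ratio_
    order = np.arange(len(scores))
    return FeatureRanking(
        method="pca",
        order=order,
        scores=scores,
        feature_ids=[f"PC{i + 1}" for i in order],
        n_source_features=table.n_features,
        transform=pca,
    )


def rank_random(table: FeatureTable, seed: int = 0) -> FeatureRanking:
    """Uniform random permutation of all features (control condition)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(table.n_features)
    return FeatureRanking(
        method="random",
        order=order,
        scores=None,
        feature_ids=[table.feature_ids[i] for i in order],
        n_source_features=table.n_features,
    )


def rank_features(
    table: FeatureTable,
    method: str,
    seed: int = 0,
    mi_config: MIEstimatorConfig | None = None,
    alpha: float = 0.001,
) -> FeatureRanking:
    """Dispatch to the requested ranking criterion."""
    if method == "wilcoxon":
        return rank_wilcoxon(table, alpha=alpha)
    if method == "relative_importance":
        return rank_relative_importance(table)
    if method == "pca":
        return rank_pca(table)
    if method == "mim":
        return rank_mim(table, mi_config)
    if method == "random":
        return rank_random(table, seed=seed)
    raise ValueError(f"unknown ranking method {method!r}; choose from {METHODS}")
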