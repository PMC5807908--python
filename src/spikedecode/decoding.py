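"""One-vs-one RBF-SVM decoding with nested cross-validation.

The classifier follows the standard multiclass decomposition: for k
classes, k(k-1)/2 binary soft-margin SVMs with Gaussian kernel
``K(x, x') = exp(-||x - x'||^2 / (2 sigma^2))`` are trained, and a test
point is assigned the class winning the most pairwise votes (vote ties
go to the lowest class index).  The binary quadratic-programming solver
is delegated to libsvm via scikit-learn; the one-vs-one vote counting and
tie-break are implemented here on top of its pairwise decision values.

Hyperparameters (kernel width sigma and box constraint C) are chosen by
exhaustive grid search over exponentially spaced values inside a nested
cross-validation: an outer 10-fold split estimates accuracy, and each
outer training partition is split 3-fold to pick (sigma, C); the whole
scheme is repeated with re-randomized folds.  Features are z-scored with
training-fold statistics before the kernel is applied.

The statsmodels-style surface is :class:`DecodingModel` (built from a
FeatureTable and a ranking criterion) whose :meth:`~DecodingModel.fit`
sweeps the feature count and returns :class:`DecodingResults`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._seeding import derive_seed
from .feature_selection import (
    FeatureRanking,
    MIEstimatorConfig,
    rank_features,
)
from .preprocessing import FeatureTable

_DEFAULT_GRID = tuple(10.0**e for e in range(-5, 6))


@dataclass
class SVMConfig:
    """Grid, fold and repeat settings for nested-CV decoding."""

    sigma_grid: tuple[float, ...] = _DEFAULT_GRID
    c_grid: tuple[float, ...] = _DEFAULT_GRID
    k_outer: int = 10
    k_inner: int = 3
    n_repeats: int = 20
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.sigma_grid) or any(v <= 0 for v in self.c_grid):
            raise ValueError("grid values must be strictly positive")
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("fold counts must be >= 2")


class OneVsOneSVM:
    """k(k-1)/2 pairwise RBF SVMs with majority voting.

    ``sigma`` parameterizes the Gaussian kernel exp(-||x-x'||^2/(2 sigma^2)),
    mapped to libsvm's gamma = 1/(2 sigma^2); ``c_box`` is the soft-margin
    box constraint.
    """

    def __init__(self, sigma: float, c_box: float):
        if sigma <= 0 or c_box <= 0:
            raise ValueError("sigma and c_box must be positive")
        self.sigma = float(sigma)
        self.c_box = float(c_box)
        self._svc = SVC(
            C=self.c_box,
            kernel="rbf",
            gamma=1.0 / (2.0 * self.sigma**2),
            decision_function_shape="ovo",
        )
        self.classes_: np.ndarray | None = None

    @property
    def n_machines(self) -> int:
        k = len(self.classes_)
        return k * (k - 1) // 2

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneVsOneSVM":
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes to train")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise RuntimeError("classifier is not fitted")
        k = len(self.classes_)
        df = self._svc.decision_function(X)
        if k == 2:
            # binary decision_function is positive for classes_[1]; flip to
            # the pairwise "positive votes the first class" convention
            df = -df.reshape(-1, 1)
        votes = np.zeros((X.shape[0], k), dtype=int)
        for m, (i, j) in enumerate(itertools.combinations(range(k), 2)):
            pos = df[:, m] > 0
            votes[pos, i] += 1
            votes[~pos, j] += 1
        # argmax returns the first (lowest class index) on vote ties
        return self.classes_[np.argmax(votes, axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == y))


def train_ovo_svm(
    X_train: np.ndarray, y_train: np.ndarray, sigma: float, c_box: float
) -> OneVsOneSVM:
    """Fit the one-vs-one RBF SVM at fixed hyperparameters."""
    return OneVsOneSVM(sigma=sigma, c_box=c_box).fit(X_train, y_train)


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _project(
    table: FeatureTable,
    ranking: FeatureRanking,
    n_features: int,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Top-n feature matrices for one fold.

    For subset criteria this slices the ranked columns; for PCA the
    loadings are re-fitted on the training rows only and both partitions
    are projected onto the first n components.
    """
    if ranking.method == "pca":
        from sklearn.decomposition import PCA

        n_max = min(len(train_idx) - 1, table.n_features)
        pca = PCA(n_components=min(n_features, n_max), svd_solver="full")
        tr = pca.fit_transform(table.X[train_idx])
        te = pca.transform(table.X[test_idx])
        return tr, te
    cols = ranking.order[:n_features]
    return table.X[np.ix_(train_idx, cols)], table.X[np.ix_(test_idx, cols)]


def _grid_search(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig,
    seed: int,
) -> tuple[float, float]:
    """Pick (sigma, c_box) by inner stratified k-fold accuracy.

    Ties keep the first grid entry in (sigma, c) iteration order.
    """
    inner = StratifiedKFold(n_splits=config.k_inner, shuffle=True, random_state=seed)
    splits = list(inner.split(X, y))
    best = (-1.0, config.sigma_grid[0], config.c_grid[0])
    for sigma in config.sigma_grid:
        for c in config.c_grid:
            accs = []
            for tr, te in splits:
                Xtr, Xte = X[tr], X[te]
                if config.standardize:
                    Xtr, Xte = _standardize(Xtr, Xte)
                clf = OneVsOneSVM(sigma, c).fit(Xtr, y[tr])
                accs.append(clf.score(Xte, y[te]))
            acc = float(np.mean(accs))
            if acc > best[0]:
                best = (acc, sigma, c)
    return best[1], best[2]


def nested_cv_accuracy(
    table: FeatureTable,
    ranking: FeatureRanking | None,
    n_features: int,
    config: SVMConfig | None = None,
    method: str | None = None,
    rank_in_fold: bool = False,
    mi_config: MIEstimatorConfig | None = None,
    collect_confusion: bool = False,
) -> dict:
    """Cross-validated accuracy using the top-n ranked features.

    Outer stratified ``k_outer``-fold splits (repeated ``n_repeats`` times
    with re-randomized folds) estimate accuracy; each outer training
    partition runs an inner ``k_inner``-fold grid search for (sigma, C),
    is refitted whole at the chosen parameters, and is scored on the
    held-out fold.  With ``rank_in_fold=True`` the ranking itself is also
    recomputed inside each outer training partition.

    Returns a dict with ``mean``, ``se``, ``per_fold``, ``best_params``
    and optionally ``confusion`` (rows = true classes).
    """
    if config is None:
        config = SVMConfig()
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if ranking is None and not rank_in_fold:
        raise ValueError("supply a ranking or set rank_in_fold with a method")
    if rank_in_fold and method is None:
        method = ranking.method if ranking is not None else None
        if method is None:
            raise ValueError("rank_in_fold requires the ranking method name")
    if ranking is not None and not rank_in_fold and n_features > max(len(ranking), 1):
        raise ValueError(
            f"n_features={n_features} exceeds ranking length {len(ranking)}"
        )

    y = table.y
    classes = np.unique(y)
    fold_accs: list[float] = []
    best_params: list[tuple[float, float]] = []
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    class_pos = {c: i for i, c in enumerate(classes)}

    for rep in range(config.n_repeats):
        outer_seed = derive_seed(config.seed, "outer", rep)
        outer = StratifiedKFold(
            n_splits=config.k_outer, shuffle=True, random_state=outer_seed
        )
        for fold, (tr, te) in enumerate(outer.split(table.X, y)):
            fold_ranking = ranking
            if rank_in_fold:
                fold_ranking = rank_features(
                    table.select_rows(tr),
                    method,
                    seed=derive_seed(config.seed, "rank", rep, fold),
                    mi_config=mi_config,
                )
                if len(fold_ranking) == 0:
                    fold_accs.append(np.nan)
                    continue
            n_use = min(n_features, max(len(fold_ranking), 1))
            Xtr, Xte = _project(table, fold_ranking, n_use, tr, te)
            if config.standardize:
                Xtr_s, Xte_s = _standardize(Xtr, Xte)
            else:
                Xtr_s, Xte_s = Xtr, Xte
            sigma, c = _grid_search(
                Xtr_s, y[tr], config, derive_seed(config.seed, "inner", rep, fold)
            )
            clf = OneVsOneSVM(sigma, c).fit(Xtr_s, y[tr])
            pred = clf.predict(Xte_s)
            fold_accs.append(float(np.mean(pred == y[te])))
            best_params.append((sigma, c))
            if collect_confusion:
                for t, p in zip(y[te], pred):
                    confusion[class_pos[t], class_pos[p]] += 1

    accs = np.asarray(fold_accs, dtype=float)
    valid = accs[~np.isnan(accs)]
    out = {
        "mean": float(valid.mean()),
        "se": float(valid.std(ddof=1) / np.sqrt(valid.size)) if valid.size > 1 else 0.0,
        "per_fold": accs.tolist(),
        "best_params": best_params,
    }
    if collect_confusion:
        out["confusion"] = pd.DataFrame(confusion, index=classes, columns=classes)
    return out


def holdout_accuracy(
    table: FeatureTable,
    ranking: FeatureRanking,
    n_features: int,
    config: SVMConfig | None = None,
    test_fraction: float = 0.3,
) -> float:
    """Single stratified train/test split (70/30 by default).

    An alternative to the nested scheme for quick estimates: the grid is
    chosen by inner k-fold on the training split, then the refitted
    classifier is scored once on the held-out split.
    """
    from sklearn.model_selection import train_test_split

    if config is None:
        config = SVMConfig()
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    idx = np.arange(table.n_trials)
    tr, te = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=table.y,
        random_state=derive_seed(config.seed, "holdout"),
    )
    Xtr, Xte = _project(table, ranking, n_features, tr, te)
    if config.standardize:
        Xtr, Xte = _standardize(Xtr, Xte)
    sigma, c = _grid_search(
        Xtr, table.y[tr], config, derive_seed(config.seed, "holdout-inner")
    )
    clf = OneVsOneSVM(sigma, c).fit(Xtr, table.y[tr])
    return clf.score(Xte, table.y[te])


@dataclass
class DecodingResults:
    """Accuracy-vs-feature-count curve and the selected operating point.

    ``optimal_n`` is the smallest feature count attaining the maximum of
    the accuracy curve.
    """

    method: str
    mode: str
    n_grid: list[int]
    accuracies: list[float]
    ses: list[float]
    optimal_n: int
    accuracy_at_optimal: float
    se_at_optimal: float
    per_fold_accuracy: list[float]
    best_params: list[tuple[float, float]]
    confusion: pd.DataFrame | None = None
    n_source_features: int = 0

    @property
    def accuracy_curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_features": self.n_grid, "accuracy": self.accuracies, "se": self.ses}
        )

    def summary(self) -> str:
        lines = [
            "Decoding results",
            "================",
            f"ranking criterion : {self.method}",
            f"feature mode      : {self.mode}",
            f"features available: {self.n_source_features}",
            f"optimal n features: {self.optimal_n}",
            (
                f"accuracy at optimum: {100 * self.accuracy_at_optimal:.2f}"
                f" +/- {100 * self.se_at_optimal:.2f} %"
            ),
            "",
            "accuracy curve (n, mean %, se %):",
        ]
        for n, a, s in zip(self.n_grid, self.accuracies, self.ses):
            lines.append(f"  {n:4d}  {100 * a:6.2f}  {100 * s:5.2f}")
        return "\n".join(lines)

    def plot_curve(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        n = np.asarray(self.n_grid)
        acc = 100 * np.asarray(self.accuracies)
        se = 100 * np.asarray(self.ses)
        ax.errorbar(n, acc, yerr=se, marker="o", capsize=2, label=self.method)
        ax.axvline(self.optimal_n, ls="--", color="grey", lw=0.8)
        ax.set_xlabel("number of features")
        ax.set_ylabel("cross-validated accuracy (%)")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "mode": self.mode,
            "n_grid": list(map(int, self.n_grid)),
            "accuracies": self.accuracies,
            "ses": self.ses,
            "optimal_n": int(self.optimal_n),
            "accuracy_at_optimal": self.accuracy_at_optimal,
            "se_at_optimal": self.se_at_optimal,
            "best_params": [[float(s), float(c)] for s, c in self.best_params],
        }


# spec-facing alias: the result type of a decode run
DecodeResult = DecodingResults


def _optimal_index(accuracies: np.ndarray) -> int:
    """Smallest index attaining the curve maximum."""
    return int(np.argmax(accuracies))


def feature_count_sweep(
    table: FeatureTable,
    ranking: FeatureRanking,
    config: SVMConfig | None = None,
    n_grid: list[int] | None = None,
    rank_in_fold: bool = False,
    mi_config: MIEstimatorConfig | None = None,
    mode: str | None = None,
) -> DecodingResults:
    """Incrementally grow the feature count and cross-validate each size.

    ``n_grid`` defaults to every count 1..len(ranking); a coarser grid can
    be supplied to trade resolution for runtime.  The optimal count is the
    smallest grid entry attaining the maximum mean accuracy; the confusion
    matrix is accumulated at that operating point.
    """
    if config is None:
        config = SVMConfig()
    if len(ranking) == 0:
        raise ValueError("ranking is empty")
    p = len(ranking)
    if n_grid is None:
        n_grid = list(range(1, p + 1))
    n_grid = sorted({int(n) for n in n_grid if 1 <= n <= p})
    if not n_grid:
        raise ValueError("no valid feature counts to sweep")

    means, ses = [], []
    for n in n_grid:
        res = nested_cv_accuracy(
            table,
            ranking,
            n,
            config=config,
            rank_in_fold=rank_in_fold,
            method=ranking.method,
            mi_config=mi_config,
        )
        means.append(res["mean"])
        ses.append(res["se"])

    i_opt = _optimal_index(np.asarray(means))
    optimal_n = n_grid[i_opt]
    final = nested_cv_accuracy(
        table,
        ranking,
        optimal_n,
        config=config,
        rank_in_fold=rank_in_fold,
        method=ranking.method,
        mi_config=mi_config,
        collect_confusion=True,
    )
    return DecodingResults(
        method=ranking.method,
        mode=mode or table.mode,
        n_grid=n_grid,
        accuracies=means,
        ses=ses,
        optimal_n=optimal_n,
        accuracy_at_optimal=final["mean"],
        se_at_optimal=final["se"],
        per_fold_accuracy=final["per_fold"],
        best_params=final["best_params"],
        confusion=final["confusion"],
        n_source_features=table.n_features,
    )


class DecodingModel:
    """Feature-ranked SVM decoder for one session's feature table.

    Parameters
    ----------
    table
        Trials x features matrix with labels (rest included).
    method
        Ranking criterion: wilcoxon, relative_importance, pca, mim, random.
    config
        Nested-CV and grid settings; defaults follow the full protocol
        (10 outer folds, 3 inner folds, 20 repeats, decadal 1e-5..1e5 grid).
    rank_in_fold
        Recompute the ranking inside every outer training partition
        (strict leakage control) instead of once on the full table.
    """

    def __init__(
        self,
        table: FeatureTable,
        method: str = "mim",
        config: SVMConfig | None = None,
        mi_config: MIEstimatorConfig | None = None,
        rank_in_fold: bool = False,
        seed: int | None = None,
    ):
        self.table = table
        self.method = method
        self.config = config if config is not None else SVMConfig()
        if seed is not None:
            self.config = replace(self.config, seed=seed)
        self.mi_config = mi_config
        self.rank_in_fold = rank_in_fold

    @classmethod
    def from_session(
        cls, session, mode: str = "single-unit", scalarize: bool = True, **kwargs
    ) -> "DecodingModel":
        from .preprocessing import make_feature_table

        return cls(make_feature_table(session, mode=mode, scalarize=scalarize), **kwargs)

    def rank(self) -> FeatureRanking:
        return rank_features(
            self.table,
            self.method,
            seed=derive_seed(self.config.seed, "ranking", self.method),
            mi_config=self.mi_config,
        )

    def fit(self, n_grid: list[int] | None = None) -> DecodingResults:
        ranking = self.rank()
        return feature_count_sweep(
            self.table,
            ranking,
            config=self.config,
            n_grid=n_grid,
            rank_in_fold=self.rank_in_fold,
            mi_config=self.mi_config,
        )
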