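"""Functional studies: robustness to simulated failure and longevity.

Chronically implanted arrays lose recordable units over time, so a
practical ranking criterion must tolerate random disappearance of raw
features.  :func:`simulated_failure` removes a random subset of raw
features (floor(level * p) survivors per retained-fraction level, the
floor matching survivor counts of 9/96 and 35/350 at the 10% level),
re-runs ranking and the feature-count sweep on the survivors, and
aggregates accuracy over dropout repeats.  :func:`longevity_study` runs
the full pipeline independently per session across a multi-day schedule;
nothing (rankings, hyperparameters) is shared between sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._seeding import derive_seed
from .decoding import DecodingResults, SVMConfig, feature_count_sweep
from .feature_selection import MIEstimatorConfig, rank_features
from .preprocessing import FeatureTable, make_feature_table
from .synthetic import Session, SessionConfig, generate_session

DEFAULT_LEVELS = tuple(np.round(np.arange(1.0, 0.05, -0.1), 1))


def survivor_count(level: float, n_features: int) -> int:
    """Number of features surviving a dropout level (floor convention)."""
    return int(np.floor(level * n_features))


@dataclass
class FailureCurve:
    """Accuracy mean +/- SE per retained-fraction level for one method/mode."""

    method: str
    mode: str
    levels: list[float]
    mean: list[float]
    se: list[float]
    n_survivors: list[int]
    per_repeat: dict[float, list[float]] = field(default_factory=dict)
    baseline: DecodingResults | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "n_survivors": self.n_survivors,
                "accuracy": self.mean,
                "se": self.se,
                "method": self.method,
                "mode": self.mode,
            }
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(
            100 * np.asarray(self.levels),
            100 * np.asarray(self.mean),
            yerr=100 * np.asarray(self.se),
            marker="o",
            capsize=2,
            label=f"{self.method} ({self.mode})",
        )
        ax.set_xlabel("retained features (%)")
        ax.set_ylabel("accuracy (%)")
        ax.legend()
        return ax


def simulated_failure(
    table: FeatureTable,
    method: str,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    n_repeats: int = 20,
    seed: int = 0,
    svm_config: SVMConfig | None = None,
    n_grid: list[int] | None = None,
    drop: str = "random",
    mi_config: MIEstimatorConfig | None = None,
) -> FailureCurve:
    """Accuracy after randomly dropping raw features, per retained level.

    Per level and repeat, floor(level * p) raw features survive; ranking
    and the feature-count sweep are re-run on the survivors and the
    accuracy at the (survivor-capped) optimal count is recorded.  With
    ``drop="tail"`` the survivors are instead the top-ranked features of
    the intact table (dropping from the ranked list's tail).
    """
    if svm_config is None:
        svm_config = SVMConfig()
    if drop not in ("random", "tail"):
        raise ValueError(f"unknown drop mode {drop!r}")
    p = table.n_features
    rng = np.random.default_rng(derive_seed(seed, "failure", method, table.mode))

    full_ranking = rank_features(
        table, method, seed=derive_seed(seed, "rank-full", method), mi_config=mi_config
    )
    baseline = feature_count_sweep(
        table, full_ranking, config=svm_config, n_grid=n_grid, mi_config=mi_config
    )

    out_levels, out_mean, out_se, out_nsurv = [], [], [], []
    per_repeat: dict[float, list[float]] = {}
    for level in levels:
        n_surv = survivor_count(level, p)
        if n_surv < 1:
            warnings.warn(f"level {level} keeps no features; skipped", stacklevel=2)
            continue
        if level >= 1.0:
            accs = [baseline.accuracy_at_optimal]
        else:
            accs = []
            for rep in range(n_repeats):
                if drop == "random":
                    cols = np.sort(rng.choice(p, size=n_surv, replace=False))
                else:
                    cols = np.sort(full_ranking.order[:n_surv])
                sub = table.select_columns(cols)
                ranking = rank_features(
                    sub,
                    method,
                    seed=derive_seed(seed, "rank", method, level, rep),
                    mi_config=mi_config,
                )
                if len(ranking) == 0:
                    accs.append(np.nan)
                    continue
                grid = None
                if n_grid is not None:
                    grid = [min(n, len(ranking)) for n in n_grid]
                res = feature_count_sweep(
                    sub, ranking, config=svm_config, n_grid=grid, mi_config=mi_config
                )
                accs.append(res.accuracy_at_optimal)
        accs_arr = np.asarray(accs, dtype=float)
        valid = accs_arr[~np.isnan(accs_arr)]
        out_levels.append(float(level))
        out_nsurv.append(n_surv)
        out_mean.append(float(valid.mean()))
        out_se.append(
            float(valid.std(ddof=1) / np.sqrt(valid.size)) if valid.size > 1 else 0.0
        )
        per_repeat[float(level)] = accs_arr.tolist()

    return FailureCurve(
        method=method,
        mode=table.mode,
        levels=out_levels,
        mean=out_mean,
        se=out_se,
        n_survivors=out_nsurv,
        per_repeat=per_repeat,
        baseline=baseline,
    )


def make_longevity_schedule(
    base_config: SessionConfig,
    n_sessions: int = 47,
    span_days: int = 142,
    unit_retention_final: float = 0.5,
    effect_retention_final: float = 0.7,
    start_units: int | None = None,
) -> list[tuple[int, SessionConfig]]:
    """Session configs along a linear unit-loss and SNR-decline schedule.

    Day indices are spread evenly over ``span_days``; the isolated-unit
    count declines linearly to ``unit_retention_final`` of its starting
    value and the tuning effect size to ``effect_retention_final``,
    emulating chronic degradation of the electrode-tissue interface.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if start_units is None:
        start_units = base_config.n_units
    if start_units is None:
        start_units = 142
    days = np.unique(np.round(np.linspace(0, span_days, n_sessions)).astype(int))
    while days.size < n_sessions:  # collisions only when n_sessions > span_days
        days = np.append(days, days[-1] + 1)
    schedule = []
    for i, day in enumerate(days[:n_sessions]):
        frac = day / span_days if span_days > 0 else 0.0
        n_units = max(
            int(round(start_units * (1 - (1 - unit_retention_final) * frac))),
            base_config.n_electrodes,
        )
        effect = base_config.effect_size * (1 - (1 - effect_retention_final) * frac)
        cfg = replace(
            base_config,
            n_units=n_units,
            effect_size=float(effect),
            seed=derive_seed(base_config.seed, "longevity", i),
        )
        schedule.append((int(day), cfg))
    return schedule


def longevity_study(
    sessions: list[Session] | list[tuple[int, SessionConfig]],
    methods: tuple[str, ...] = ("wilcoxon", "relative_importance", "pca", "mim", "random"),
    modes: tuple[str, ...] = ("single-unit", "multi-unit"),
    svm_config: SVMConfig | None = None,
    n_grid: list[int] | None = None,
    seed: int = 0,
    mi_config: MIEstimatorConfig | None = None,
) -> pd.DataFrame:
    """Run the full pipeline independently on every session.

    Accepts generated Sessions or (day_index, SessionConfig) pairs (the
    latter are generated on the fly).  Returns one row per session x
    method x mode with the optimal feature count and its accuracy.
    Sessions without successful trials are skipped with a warning.
    """
    if not sessions:
        raise ValueError("need at least one session")
    rows = []
    for item in sessions:
        if isinstance(item, Session):
            session = item
        else:
            day, cfg = item
            session = generate_session(cfg, day_index=day, session_id=f"day-{day}")
        if not any(e.success for e in session.events):
            warnings.warn(f"{session.session_id}: no successful trials; skipped",
                          stacklevel=2)
            continue
        for mode in modes:
            table = make_feature_table(session, mode=mode)
            for method in methods:
                ranking = rank_features(
                    table,
                    method,
                    seed=derive_seed(seed, session.session_id, mode, method),
                    mi_config=mi_config,
                )
                if len(ranking) == 0:
                    warnings.warn(
                        f"{session.session_id}: {method} kept no features; skipped",
                        stacklevel=2,
                    )
                    continue
                grid = None
                if n_grid is not None:
                    grid = [min(n, len(ranking)) for n in n_grid]
                res = feature_count_sweep(
                    table, ranking, config=svm_config, n_grid=grid, mi_config=mi_config
                )
                rows.append(
                    {
                        "session_id": session.session_id,
                        "day_index": session.day_index,
                        "method": method,
                        "mode": mode,
                        "n_features": table.n_features,
                        "optimal_n": res.optimal_n,
                        "accuracy": res.accuracy_at_optimal,
                        "se": res.se_at_optimal,
                    }
                )
    return pd.DataFrame(rows)


def pairwise_method_tests(
    accuracies: dict[str, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sample t-tests between all method pairs, Bonferroni-corrected."""
    methods = list(accuracies)
    pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1 :]]
    n_tests = len(pairs)
    rows = []
    for a, b in pairs:
        x, y = np.asarray(accuracies[a]), np.asarray(accuracies[b])
        if np.array_equal(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(x, y)
        p_adj = min(float(p) * n_tests, 1.0)
        rows.append(
            {
                "method_a": a,
                "method_b": b,
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def kruskal_by_level(
    curves: dict[str, FailureCurve], alpha: float = 0.05
) -> pd.DataFrame:
    """Kruskal-Wallis test across methods at each shared failure level."""
    methods = list(curves)
    shared = sorted(
        set.intersection(*(set(c.per_repeat) for c in curves.values())), reverse=True
    )
    rows = []
    for level in shared:
        groups = [np.asarray(curves[m].per_repeat[level]) for m in methods]
        groups = [g[~np.isnan(g)] for g in groups]
        try:
            h, p = stats.kruskal(*groups)
        except ValueError:  # all values identical, or a group too small
            h, p = np.nan, np.nan
        rows.append(
            {
                "level": level,
                "H": float(h) if h == h else np.nan,
                "p": float(p) if p == p else np.nan,
                "significant": bool(p < alpha) if p == p else False,
            }
        )
    return pd.DataFrame(rows)


def summarize(
    decode_results: list[DecodingResults] | None = None,
    failure_curves: dict[str, FailureCurve] | None = None,
    longevity: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Tabular report: per-method operating points plus significance tests."""
    if not any(x is not None for x in (decode_results, failure_curves, longevity)):
        raise ValueError("nothing to summarize")
    report: dict[str, pd.DataFrame] = {}
    if decode_results:
        report["optimal_features"] = pd.DataFrame(
            {
                "method": [r.method for r in decode_results],
                "mode": [r.mode for r in decode_results],
                "optimal_n": [r.optimal_n for r in decode_results],
                "accuracy": [r.accuracy_at_optimal for r in decode_results],
                "se": [r.se_at_optimal for r in decode_results],
            }
        )
        accs = {
            f"{r.method}/{r.mode}": np.asarray(r.per_fold_accuracy)
            for r in decode_results
        }
        report["pairwise_tests"] = pairwise_method_tests(accs, alpha=alpha)
    if failure_curves:
        report["failure"] = pd.concat(
            [c.to_frame() for c in failure_curves.values()], ignore_index=True
        )
        report["kruskal_by_level"] = kruskal_by_level(failure_curves, alpha=alpha)
    if longevity is not None:
        report["longevity"] = longevity
    return report
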