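"""Spike timestamps -> 20 Hz firing rates -> trial feature tables.

The rate-estimation chain mirrors standard microelectrode-array practice:

1. timestamps are binned at 600 Hz;
2. a 300 ms boxcar moving average stepped every 33.3 ms (20 bins) yields
   an intermediate rate series at 30 samples/s;
3. a zero-phase 4th-order low-pass Butterworth at 10 Hz is applied before
   polyphase resampling to exactly 20 Hz (negative filter ripple is
   clipped to zero -- rates are physically non-negative).

Per trial, a movement epoch (450 ms before to 1,000 ms after switch
closure; 29 samples) and a baseline epoch (2,500-1,000 ms before closure;
30 samples) are cut from every feature's rate series.  A feature is
either one isolated unit ("single-unit" mode) or the merged spike trains
of one electrode ("multi-unit" mode).  The default feature table holds
one scalar per (trial, feature): the mean rate over the epoch; the full
29-sample vector per feature is available for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic import BASELINE_WINDOW, MOVE_WINDOW, Session, TrialEvent

logger = logging.getLogger(__name__)

BIN_RATE = 600.0  # Hz, timestamp downsampling rate
BOXCAR_WIDTH_S = 0.3
BOXCAR_STEP_BINS = 20  # 20 bins of 1/600 s = 33.33 ms
INTERMEDIATE_RATE = BIN_RATE / BOXCAR_STEP_BINS  # 30 samples/s
OUTPUT_RATE = 20.0  # Hz
BUTTER_ORDER = 4
BUTTER_CUTOFF_HZ = 10.0

N_MOVE_SAMPLES = 29  # 1.45 s at 20 Hz
N_BASELINE_SAMPLES = 30  # 1.5 s at 20 Hz

SINGLE_UNIT = "single-unit"
MULTI_UNIT = "multi-unit"


@dataclass
class RateSeries:
    """A 20 Hz firing-rate series for one feature."""

    values: np.ndarray
    t0: float
    feature_id: str
    mode: str = SINGLE_UNIT

    @property
    def dt(self) -> float:
        return 1.0 / OUTPUT_RATE

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.dt


@dataclass
class EpochSet:
    """Per-trial movement and baseline rate segments for all features."""

    movement: np.ndarray  # (n_trials, n_features, N_MOVE_SAMPLES)
    baseline: np.ndarray  # (n_trials, n_features, N_BASELINE_SAMPLES)
    labels: np.ndarray  # (n_trials,)
    trial_ids: np.ndarray
    feature_ids: list[str]
    mode: str

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for w, arr in (("movement", self.movement), ("baseline", self.baseline)):
            nt, nf, ns = arr.shape
            t_idx, f_idx, s_idx = np.meshgrid(
                np.arange(nt), np.arange(nf), np.arange(ns), indexing="ij"
            )
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": self.trial_ids[t_idx.ravel()],
                        "feature_id": np.asarray(self.feature_ids)[f_idx.ravel()],
                        "window": w,
                        "sample_index": s_idx.ravel(),
                        "rate": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class FeatureTable:
    """Trials x features matrix of epoch firing rates with labels.

    ``X`` holds movement-epoch values, ``baseline_X`` the matching
    baseline-epoch values; ``y`` includes the rest class (label 0).
    """

    X: np.ndarray
    baseline_X: np.ndarray
    y: np.ndarray
    feature_ids: list[str]
    mode: str
    trial_ids: np.ndarray | None = None
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.X.shape != self.baseline_X.shape:
            raise ValueError("X and baseline_X must have identical shapes")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("row count of X must equal length of y")
        if self.trial_ids is None:
            self.trial_ids = np.arange(1, self.X.shape[0] + 1)

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def select_rows(self, idx: np.ndarray) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            X=self.X[idx],
            baseline_X=self.baseline_X[idx],
            y=self.y[idx],
            feature_ids=list(self.feature_ids),
            mode=self.mode,
            trial_ids=self.trial_ids[idx],
            feature_meta=self.feature_meta,
        )

    def select_columns(self, idx: np.ndarray) -> "FeatureTable":
        idx = np.asarray(idx)
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.iloc[idx].reset_index(drop=True)
        return FeatureTable(
            X=self.X[:, idx],
            baseline_X=self.baseline_X[:, idx],
            y=self.y,
            feature_ids=[self.feature_ids[i] for i in idx],
            mode=self.mode,
            trial_ids=self.trial_ids,
            feature_meta=meta,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_ids)
        df.insert(0, "label", self.y)
        df.insert(0, "trial_id", self.trial_ids)
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9f")


def bin_spikes(
    timestamps: np.ndarray, duration: float, bin_rate: float = BIN_RATE
) -> np.ndarray:
    """Count spikes in 1/bin_rate-second bins; the total count is preserved."""
    ts = np.asarray(timestamps, dtype=float)
    if ts.size and np.any(np.diff(ts) < 0):
        raise ValueError("timestamps must be sorted")
    if ts.size and (ts[0] < 0 or ts[-1] > duration):
        raise ValueError("timestamps must lie within [0, duration]")
    n_bins = int(np.ceil(duration * bin_rate))
    if n_bins < 1:
        raise ValueError("duration too short for one bin")
    idx = np.minimum((ts * bin_rate).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins).astype(float)


def boxcar_rate(
    counts: np.ndarray,
    window_s: float = BOXCAR_WIDTH_S,
    step_bins: int = BOXCAR_STEP_BINS,
    bin_rate: float = BIN_RATE,
) -> tuple[np.ndarray, float]:
    """Centered 300 ms boxcar moving average emitted every 33.3 ms.

    Returns the intermediate rate series (spikes/s) and the time of its
    first sample.  Bins outside the recording are treated as empty.
    """
    counts = np.asarray(counts, dtype=float)
    window_bins = int(round(window_s * bin_rate))
    if window_bins < 1:
        raise ValueError("boxcar window shorter than one bin")
    n = counts.size
    half = window_bins // 2
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    centers = np.arange(0, n, step_bins)
    lo = np.maximum(centers - half, 0)
    hi = np.minimum(centers + window_bins - half, n)
    sums = csum[hi] - csum[lo]
    rate = sums / window_s
    t0 = (centers[0] + 0.5) / bin_rate
    return rate, t0


def smooth_decimate(
    rate: np.ndarray, t0: float = 0.0, in_rate: float = INTERMEDIATE_RATE
) -> tuple[np.ndarray, float]:
    """Zero-phase 4th-order 10 Hz Butterworth, then resample to 20 Hz.

    DC gain is exactly 1; output values are clipped at zero.
    """
    rate = np.asarray(rate, dtype=float)
    b, a = signal.butter(BUTTER_ORDER, BUTTER_CUTOFF_HZ, fs=in_rate, btype="low")
    padlen = 3 * max(len(a), len(b))
    if rate.size <= 3 * padlen:
        raise ValueError(
            f"series of {rate.size} samples is too short to filter (needs > {3 * padlen})"
        )
    smoothed = signal.filtfilt(b, a, rate)
    up, down = 2, 3  # 30 -> 20 samples/s
    out = signal.resample_poly(smoothed, up, down)
    return np.maximum(out, 0.0), t0


def rate_series(
    timestamps: np.ndarray, duration: float, feature_id: str, mode: str = SINGLE_UNIT
) -> RateSeries:
    """Full chain: timestamps -> 600 Hz counts -> boxcar -> 20 Hz RateSeries."""
    counts = bin_spikes(timestamps, duration)
    interm, t0 = boxcar_rate(counts)
    values, t0 = smooth_decimate(interm, t0)
    return RateSeries(values=values, t0=t0, feature_id=feature_id, mode=mode)


def session_rate_series(session: Session, mode: str = SINGLE_UNIT) -> list[RateSeries]:
    """Rate series per isolated unit, or per electrode with merged trains."""
    if mode == SINGLE_UNIT:
        return [
            rate_series(session.spikes[u.unit_id], session.duration, f"unit{u.unit_id}", mode)
            for u in session.units
        ]
    if mode == MULTI_UNIT:
        out = []
        for e in session.electrode_ids:
            merged = np.sort(
                np.concatenate(
                    [session.spikes[u.unit_id] for u in session.units if u.electrode_id == e]
                )
            )
            out.append(rate_series(merged, session.duration, f"elec{e}", mode))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def extract_epochs(
    series: list[RateSeries], events: list[TrialEvent]
) -> EpochSet:
    """Cut movement (29-sample) and baseline (30-sample) epochs per trial.

    Unsuccessful trials are ignored; trials with insufficient preceding
    data are skipped with a logged warning.
    """
    if not series:
        raise ValueError("no rate series supplied")
    values = np.stack([s.values for s in series])  # (n_features, n_samples)
    t0 = series[0].t0
    fs = OUTPUT_RATE
    n_samples = values.shape[1]

    move, base, labels, trial_ids = [], [], [], []
    for e in events:
        if not e.success:
            continue
        c = e.switch_closure_time
        i_move = int(round((c + MOVE_WINDOW[0] - t0) * fs))
        i_base = int(round((c + BASELINE_WINDOW[0] - t0) * fs))
        if i_base < 0 or i_move + N_MOVE_SAMPLES > n_samples:
            logger.warning(
                "trial %s skipped: insufficient rate data around closure %.3f s",
                e.trial_id,
                c,
            )
            continue
        move.append(values[:, i_move : i_move + N_MOVE_SAMPLES])
        base.append(values[:, i_base : i_base + N_BASELINE_SAMPLES])
        labels.append(e.label)
        trial_ids.append(e.trial_id)
    if not move:
        raise ValueError("no usable trials in epoch extraction")
    return EpochSet(
        movement=np.stack(move),
        baseline=np.stack(base),
        labels=np.asarray(labels),
        trial_ids=np.asarray(trial_ids),
        feature_ids=[s.feature_id for s in series],
        mode=series[0].mode,
    )


def build_feature_table(epochs: EpochSet, scalarize: bool = True) -> FeatureTable:
    """Collapse epochs to one scalar (mean rate) per trial and feature.

    With ``scalarize=False`` the full 29-sample movement vectors are kept,
    columns grouped per feature; baseline columns repeat the baseline mean
    so that paired tests remain defined.
    """
    if epochs.movement.size == 0:
        raise ValueError("empty epoch set")
    meta = pd.DataFrame({"feature_id": epochs.feature_ids, "mode": epochs.mode})
    if scalarize:
        X = epochs.movement.mean(axis=2)
        baseline_X = epochs.baseline.mean(axis=2)
        ids = list(epochs.feature_ids)
    else:
        nt, nf, ns = epochs.movement.shape
        X = epochs.movement.transpose(0, 1, 2).reshape(nt, nf * ns)
        baseline_X = np.repeat(epochs.baseline.mean(axis=2), ns, axis=1)
        ids = [f"{f}:s{s}" for f in epochs.feature_ids for s in range(ns)]
        meta = pd.DataFrame(
            {
                "feature_id": ids,
                "mode": epochs.mode,
                "parent": np.repeat(epochs.feature_ids, ns),
            }
        )
    return FeatureTable(
        X=X,
        baseline_X=baseline_X,
        y=epochs.labels,
        feature_ids=ids,
        mode=epochs.mode,
        trial_ids=epochs.trial_ids,
        feature_meta=meta,
    )


def make_feature_table(
    session: Session, mode: str = SINGLE_UNIT, scalarize: bool = True
) -> FeatureTable:
    """Session -> rates -> epochs -> FeatureTable, in one call."""
    series = session_rate_series(session, mode)
    epochs = extract_epochs(series, session.events)
    return build_feature_table(epochs, scalarize=scalarize)
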