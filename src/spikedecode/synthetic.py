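"""Synthetic sessions of movement-tuned Poisson spike trains.

Emulates a cued finger-movement task recorded on a 96-electrode
microelectrode array: the subject waits 1,000-3,000 ms for a visual cue,
has up to 2,000 ms to react by closing the cued switch, and holds it for
500 ms.  Each isolated unit fires as an inhomogeneous Poisson process
whose rate is its baseline rate outside movement and baseline x gain
inside the movement window (450 ms before to 1,000 ms after switch
closure).  Rest epochs are scheduled like trials but leave every unit at
baseline, giving the classifier an explicit 11th "rest" class.

Sessions are fully determined by a :class:`SessionConfig` and its seed,
and serialize to plain CSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

REST_LABEL = 0

# movement window relative to switch closure, seconds
MOVE_WINDOW = (-0.45, 1.0)
# baseline window relative to switch closure, seconds
BASELINE_WINDOW = (-2.5, -1.0)

# mean +/- SD of isolated-unit counts per session on a 96-electrode array
UNIT_COUNT_MEAN = 142.2
UNIT_COUNT_SD = 36.3

# quiet time inserted after each trial's movement tail so that the next
# trial's baseline window never overlaps a movement window
_POST_MOVE_S = MOVE_WINDOW[1]
_PRE_GAP_S = 1.5
_REACT_MIN_S = 0.25


class InvalidConfigError(ValueError):
    """Raised when a SessionConfig violates its invariants."""


@dataclass(frozen=True)
class UnitSpec:
    """One isolated neuron: its electrode, baseline rate and per-class gains."""

    unit_id: int
    electrode_id: int
    baseline_rate: float
    movement_gain: tuple[float, ...]

    @property
    def informative(self) -> bool:
        return any(g != 1.0 for g in self.movement_gain)

    def __post_init__(self) -> None:
        if not np.isfinite(self.baseline_rate) or self.baseline_rate < 0:
            raise InvalidConfigError(
                f"baseline_rate must be finite and >= 0, got {self.baseline_rate}"
            )
        if any(g < 0 for g in self.movement_gain):
            raise InvalidConfigError("movement gains must be >= 0")


@dataclass(frozen=True)
class TrialEvent:
    trial_id: int
    label: int  # 1..n movement classes, REST_LABEL for rest epochs
    cue_time: float
    switch_closure_time: float
    success: bool = True


@dataclass
class SessionConfig:
    """Parameters of one synthetic recording session.

    ``n_units=None`` draws round(Normal(142.2, 36.3)) clipped to at least
    ``n_electrodes``.  ``informative_fraction`` of the units receive
    movement gains drawn in [1, effect_size]; the rest are untuned.
    ``dominant_rate``, when set, adds one untuned high-rate unit to every
    electrode so that multi-unit features are masked by untuned spiking.
    """

    n_electrodes: int = 96
    n_units: int | None = None
    movement_classes: int = 10
    trials_per_class: int = 20
    rest_trials: int = 30
    wait_range_ms: tuple[float, float] = (1000.0, 3000.0)
    react_max_ms: float = 2000.0
    hold_ms: float = 500.0
    informative_fraction: float = 0.2
    effect_size: float = 3.0
    baseline_rate_mean: float = 10.0
    baseline_rate_shape: float = 2.0
    dominant_rate: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_electrodes < 1 or self.movement_classes < 1:
            raise InvalidConfigError("n_electrodes and movement_classes must be >= 1")
        if self.trials_per_class < 0 or self.rest_trials < 0:
            raise InvalidConfigError("trial counts must be >= 0")
        if self.n_units is not None and self.n_units < self.n_electrodes:
            raise InvalidConfigError(
                f"n_units={self.n_units} < n_electrodes={self.n_electrodes}"
            )
        lo, hi = self.wait_range_ms
        if lo > hi or lo < 0:
            raise InvalidConfigError(f"invalid wait_range_ms {self.wait_range_ms}")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise InvalidConfigError("informative_fraction must be in [0, 1]")
        if self.effect_size < 0 or self.baseline_rate_mean <= 0:
            raise InvalidConfigError("effect_size/baseline_rate_mean out of range")


@dataclass
class Session:
    """Spike timestamps per unit plus the trial event table."""

    units: list[UnitSpec]
    spikes: dict[int, np.ndarray]  # unit_id -> sorted timestamps, seconds
    events: list[TrialEvent]
    duration: float
    config: SessionConfig | None = None
    day_index: int = 0
    session_id: str = "session-0"

    @property
    def electrode_ids(self) -> list[int]:
        return sorted({u.electrode_id for u in self.units})

    def spikes_frame(self) -> pd.DataFrame:
        rows = []
        for u in self.units:
            ts = self.spikes[u.unit_id]
            rows.append(
                pd.DataFrame(
                    {
                        "unit_id": u.unit_id,
                        "electrode_id": u.electrode_id,
                        "timestamp_s": ts,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=["unit_id", "electrode_id", "timestamp_s"])
        return pd.concat(rows, ignore_index=True)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": [e.trial_id for e in self.events],
                "label": [e.label for e in self.events],
                "cue_time_s": [e.cue_time for e in self.events],
                "switch_closure_time_s": [e.switch_closure_time for e in self.events],
                "success": [e.success for e in self.events],
            }
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.spikes_frame().to_csv(
            directory / "spikes.csv", index=False, float_format="%.9f"
        )
        self.events_frame().to_csv(
            directory / "events.csv", index=False, float_format="%.9f"
        )
        meta = {
            "duration": self.duration,
            "day_index": self.day_index,
            "session_id": self.session_id,
            "units": [
                {
                    "unit_id": u.unit_id,
                    "electrode_id": u.electrode_id,
                    "baseline_rate": u.baseline_rate,
                    "movement_gain": list(u.movement_gain),
                }
                for u in self.units
            ],
            "config": asdict(self.config) if self.config is not None else None,
        }
        (directory / "session.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "Session":
        directory = Path(directory)
        meta = json.loads((directory / "session.json").read_text())
        units = [
            UnitSpec(
                unit_id=u["unit_id"],
                electrode_id=u["electrode_id"],
                baseline_rate=u["baseline_rate"],
                movement_gain=tuple(u["movement_gain"]),
            )
            for u in meta["units"]
        ]
        spikes_df = pd.read_csv(directory / "spikes.csv")
        spikes = {
            u.unit_id: np.sort(
                spikes_df.loc[spikes_df["unit_id"] == u.unit_id, "timestamp_s"].to_numpy()
            )
            for u in units
        }
        events_df = pd.read_csv(directory / "events.csv")
        events = [
            TrialEvent(
                trial_id=int(r.trial_id),
                label=int(r.label),
                cue_time=float(r.cue_time_s),
                switch_closure_time=float(r.switch_closure_time_s),
                success=bool(r.success),
            )
            for r in events_df.itertuples()
        ]
        cfg = meta.get("config")
        config = None
        if cfg is not None:
            cfg["wait_range_ms"] = tuple(cfg["wait_range_ms"])
            config = SessionConfig(**cfg)
        return cls(
            units=units,
            spikes=spikes,
            events=events,
            duration=float(meta["duration"]),
            config=config,
            day_index=int(meta.get("day_index", 0)),
            session_id=str(meta.get("session_id", "session-0")),
        )


def draw_n_units(
    rng: np.random.Generator,
    mean: float = UNIT_COUNT_MEAN,
    sd: float = UNIT_COUNT_SD,
    minimum: int = 1,
) -> int:
    """Draw a session's isolated-unit count, clipped from below."""
    return max(int(round(rng.normal(mean, sd))), int(minimum))


def make_unit_population(
    config: SessionConfig, rng: np.random.Generator | None = None
) -> list[UnitSpec]:
    """Assign units to electrodes and draw baseline rates and tuning gains.

    Every electrode receives at least one unit, surplus units are placed
    uniformly at random, and at least one electrode always carries two or
    more units (motor-cortex electrodes commonly pick up several neurons).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_units = config.n_units
    if n_units is None:
        n_units = draw_n_units(rng, minimum=config.n_electrodes)
    if n_units < config.n_electrodes:
        raise InvalidConfigError(
            f"n_units={n_units} < n_electrodes={config.n_electrodes}"
        )

    electrodes = np.empty(n_units, dtype=int)
    electrodes[: config.n_electrodes] = np.arange(1, config.n_electrodes + 1)
    extra = n_units - config.n_electrodes
    if extra > 0:
        electrodes[config.n_electrodes :] = rng.integers(1, config.n_electrodes + 1, extra)
    else:
        # n_units == n_electrodes: double up one electrode to honor the
        # multiple-units-per-electrode structure (one electrode stays silent)
        if n_units >= 2:
            electrodes[-1] = electrodes[0]

    rates = rng.gamma(
        shape=config.baseline_rate_shape,
        scale=config.baseline_rate_mean / config.baseline_rate_shape,
        size=n_units,
    )

    n_informative = int(round(config.informative_fraction * n_units))
    informative_idx = set(rng.choice(n_units, size=n_informative, replace=False).tolist())
    gains = np.ones((n_units, config.movement_classes))
    for i in sorted(informative_idx):
        gains[i] = 1.0 + (config.effect_size - 1.0) * rng.uniform(
            0.0, 1.0, config.movement_classes
        )

    units = [
        UnitSpec(
            unit_id=i + 1,
            electrode_id=int(electrodes[i]),
            baseline_rate=float(rates[i]),
            movement_gain=tuple(gains[i]),
        )
        for i in range(n_units)
    ]

    if config.dominant_rate is not None:
        next_id = n_units + 1
        for e in range(1, config.n_electrodes + 1):
            units.append(
                UnitSpec(
                    unit_id=next_id,
                    electrode_id=e,
                    baseline_rate=float(config.dominant_rate),
                    movement_gain=tuple(np.ones(config.movement_classes)),
                )
            )
            next_id += 1
    return units


def _poisson_homogeneous(
    rng: np.random.Generator, rate: float, t0: float, t1: float
) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def _simulate_unit(
    rng: np.random.Generator,
    unit: UnitSpec,
    duration: float,
    windows: list[tuple[float, float, float]],
) -> np.ndarray:
    """Piecewise-constant-rate Poisson train over [0, duration].

    ``windows`` lists (start, stop, gain) movement windows; outside them the
    unit fires at baseline.  Implemented as baseline superposition with
    thinning (gain < 1) or additive extra spikes (gain > 1), which is exact
    for piecewise-constant rates.
    """
    base = _poisson_homogeneous(rng, unit.baseline_rate, 0.0, duration)
    keep = np.ones(base.size, dtype=bool)
    extras = []
    for start, stop, gain in windows:
        if gain == 1.0:
            continue
        if gain < 1.0:
            inside = (base >= start) & (base < stop)
            keep[inside] &= rng.uniform(size=int(inside.sum())) < gain
        else:
            extra_rate = unit.baseline_rate * (gain - 1.0)
            extras.append(_poisson_homogeneous(rng, extra_rate, start, stop))
    parts = [base[keep]] + extras
    return np.sort(np.concatenate(parts)) if len(parts) > 1 else parts[0]


def _draw_timing(
    rng: np.random.Generator, config: SessionConfig, t_start: float
) -> tuple[float, float]:
    """Cue and switch-closure times for a trial beginning at ``t_start``."""
    wait = rng.uniform(*config.wait_range_ms) / 1000.0
    react = rng.uniform(_REACT_MIN_S, min(0.8, config.react_max_ms / 1000.0))
    cue = t_start + wait
    closure = cue + react
    return cue, closure


def simulate_trial(
    units: list[UnitSpec],
    label: int,
    timing: tuple[float, float],
    seed: int | np.random.Generator = 0,
) -> tuple[dict[int, np.ndarray], TrialEvent]:
    """Simulate one isolated trial.

    ``timing`` is (cue_time, switch_closure_time) relative to the segment
    start; spikes are generated over [0, closure + 1.0 s + 1.5 s].  During
    the movement window each unit's rate is baseline x gain[label]; rest
    trials (label 0) stay at baseline throughout.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cue, closure = timing
    if closure <= cue and label != REST_LABEL:
        raise ValueError("switch closure must follow the cue")
    n_classes = len(units[0].movement_gain) if units else 0
    if label != REST_LABEL and not 1 <= label <= n_classes:
        raise ValueError(f"invalid movement label {label}")
    duration = closure + _POST_MOVE_S + _PRE_GAP_S
    event = TrialEvent(trial_id=0, label=label, cue_time=cue, switch_closure_time=closure)
    spikes = {}
    for u in units:
        windows = []
        if label != REST_LABEL:
            gain = u.movement_gain[label - 1]
            windows = [(closure + MOVE_WINDOW[0], closure + MOVE_WINDOW[1], gain)]
        spikes[u.unit_id] = _simulate_unit(rng, u, duration, windows)
    return spikes, event


def generate_session(
    config: SessionConfig,
    seed: int | None = None,
    day_index: int = 0,
    session_id: str | None = None,
) -> Session:
    """Generate a full session: unit population, event schedule, spike trains.

    The schedule interleaves ``trials_per_class`` successful trials of each
    movement class with ``rest_trials`` rest epochs in shuffled order, with
    inter-trial quiet gaps long enough that each trial's baseline window
    (2.5-1.0 s before closure) is free of the previous movement window.
    """
    config.validate()
    master = config.seed if seed is None else seed
    rng_pop = np.random.default_rng([master, 1])
    rng_sched = np.random.default_rng([master, 2])
    rng_spk = np.random.default_rng([master, 3])

    units = make_unit_population(config, rng_pop)

    labels = np.repeat(
        np.arange(1, config.movement_classes + 1), config.trials_per_class
    )
    labels = np.concatenate([labels, np.full(config.rest_trials, REST_LABEL)])
    rng_sched.shuffle(labels)

    events: list[TrialEvent] = []
    t = _PRE_GAP_S + abs(BASELINE_WINDOW[0])
    for i, label in enumerate(labels):
        cue, closure = _draw_timing(rng_sched, config, t)
        events.append(
            TrialEvent(
                trial_id=i + 1,
                label=int(label),
                cue_time=cue,
                switch_closure_time=closure,
                success=True,
            )
        )
        t = closure + _POST_MOVE_S + _PRE_GAP_S
    duration = t + _PRE_GAP_S

    spikes: dict[int, np.ndarray] = {}
    for u in units:
        windows = []
        for e in events:
            if e.label == REST_LABEL:
                continue
            gain = u.movement_gain[e.label - 1]
            if gain != 1.0:
                windows.append(
                    (
                        e.switch_closure_time + MOVE_WINDOW[0],
                        e.switch_closure_time + MOVE_WINDOW[1],
                        gain,
                    )
                )
        spikes[u.unit_id] = _simulate_unit(rng_spk, u, duration, windows)

    if session_id is None:
        session_id = f"session-{master}"
    return Session(
        units=units,
        spikes=spikes,
        events=events,
        duration=duration,
        config=config,
        day_index=day_index,
        session_id=session_id,
    )
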