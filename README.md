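# spikedecode

Feature selection and SVM decoding of finger movements from
microelectrode-array spike recordings.

Decoding dexterous finger movements from motor-cortex spikes is a
high-dimensional classification problem: a 96-electrode array yields ~96
multi-unit features or a few hundred single-unit features, while a session
contributes only a couple of hundred trials. `spikedecode` is for
neural-engineering researchers who want a tested, reproducible pipeline to
compare **filter-based feature-selection criteria** — Wilcoxon signed-rank
ranking, relative importance (inter-movement variance), PCA, mutual
information maximization (MIM), and a random control — feeding a
**one-vs-one RBF-kernel SVM** with nested cross-validation, on synthetic
sessions of movement-tuned Poisson spike trains (no proprietary recordings
required).

## The model in brief

Each isolated unit fires as an inhomogeneous Poisson process: rate
`r(t) = b` at baseline and `b·g_c` during the movement window (−450 ms to
+1,000 ms around switch closure) of a class-`c` trial. Spike timestamps are
binned at 600 Hz, smoothed with a 300 ms boxcar stepped every 33.3 ms,
low-passed with a zero-phase 4th-order Butterworth at 10 Hz, and resampled
to 20 Hz. Per trial, the mean rate over the movement epoch (and over a
baseline epoch 2,500–1,000 ms before closure) gives one scalar per feature.
A criterion ranks the features; a `k`-class one-vs-one SVM —
`k(k−1)/2` binary machines with kernel `K(x,x′) = exp(−‖x−x′‖²/2σ²)`,
`(σ, C)` grid-searched over `10⁻⁵…10⁵` in a 10-fold outer / 3-fold inner
nested cross-validation — is evaluated at increasing feature counts, and
the smallest count attaining maximum accuracy is the operating point.
Robustness is probed by randomly deleting raw features
(`floor(level · p)` survivors per level) and longevity by running the
pipeline independently over a 47-session, 142-day schedule.

The closed-form motivation for selecting features at all is also included:
the normal mass inside the mean ± 1 SD region, `chi2.cdf(1, d)`, collapses
from 68.27% (d=1) to 0.18% (d=8), and the expected nearest-edge distance
`D(d, n) = ½·(1/n)^(1/d)` approaches its maximum 0.5 as `d` grows.

## Worked example

```python
import spikedecode as sd

config = sd.SessionConfig(
    n_electrodes=6, n_units=16, movement_classes=4,
    trials_per_class=10, rest_trials=8,
    informative_fraction=0.4, effect_size=3.0, seed=42,
)
session = sd.generate_session(config)
print(f"{len(session.units)} units on {len(session.electrode_ids)} electrodes, "
      f"{len(session.events)} trials, {session.duration:.0f} s")

model = sd.DecodingModel.from_session(
    session, mode="single-unit", method="mim",
    config=sd.SVMConfig(sigma_grid=(0.1, 1.0, 10.0), c_grid=(1.0, 100.0),
                        k_outer=5, k_inner=2, n_repeats=2, seed=0),
)
results = model.fit(n_grid=[1, 2, 4, 8, 16])
print(results.summary())
```

prints

```
16 units on 6 electrodes, 48 trials, 249 s
Decoding results
================
ranking criterion : mim
feature mode      : single-unit
features available: 16
optimal n features: 8
accuracy at optimum: 87.56 +/- 3.32 %

accuracy curve (n, mean %, se %):
     1   45.78   6.13
     2   72.00   3.94
     4   86.67   3.40
     8   87.56   3.32
    16   77.11   4.57
```

Reading this: with 16 single-unit features of which ~40% are
movement-tuned, MIM-ranked subsets peak at 8 features (87.6% accuracy on
the 5-class problem, chance 20%); adding the remaining mostly-untuned
features *hurts* (77.1% with all 16) — the curse of dimensionality the
ranking is there to defeat. `results.plot_curve()` draws the curve, and
`sd.simulated_failure(...)`, `sd.longevity_study(...)` and
`sd.summarize(...)` run the robustness and longevity studies on the same
objects. The closed forms are plain functions:

```python
>>> sd.gaussian_mass_within_1sd(8)
0.001751622556290824
>>> sd.expected_distance(100, 10_000)
0.4560054196779549
```

## Command line

A YAML config plus one master seed determine every output byte:

```sh
spikedecode simulate  -c config.yaml --seed 1 -o out   # synthetic session (CSV)
spikedecode decode    -c config.yaml --seed 1 -o out   # accuracy curves per method/mode
spikedecode failure   -c config.yaml --seed 1 -o out   # simulated-failure curves
spikedecode longevity -c config.yaml --seed 1 -o out   # multi-session study
spikedecode dimtable  --dmax 100 -o out/dim.csv        # dimensionality table
```

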