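"""Closed-form curse-of-dimensionality quantities.

As the dimension of a feature space grows, the probability mass of a
standard multivariate normal contained in the "mean +/- 1 SD" region
collapses toward zero, while the expected distance from a uniformly
sampled point to the edge of the unit hypercube climbs toward its maximum
of 0.5.  Both effects make fixed-size samples increasingly sparse, which
is the motivation for selecting a small feature subset before training a
kernel classifier on microelectrode-array firing rates.

Two conventions for the "mean +/- 1 SD" region are exposed:

* the ellipsoid of Mahalanobis distance <= 1, whose enclosed mass is the
  chi-square CDF with ``d`` degrees of freedom evaluated at 1;
* the axis-aligned hypercube ``[-1, 1]^d``, whose mass is the univariate
  mass 0.682689... raised to the power ``d``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _check_dim(d: int) -> int:
    d = int(d)
    if d < 1:
        raise ValueError(f"dimension must be >= 1, got {d}")
    return d


def gaussian_mass_within_1sd(d: int) -> float:
    """Mass of a standard d-variate normal inside the unit Mahalanobis ellipsoid.

    Equals ``chi2.cdf(1, df=d)``; strictly decreasing in ``d``
    (0.6827 at d=1, 0.3935 at d=2, 0.0018 at d=8).
    """
    return float(stats.chi2.cdf(1.0, df=_check_dim(d)))


def hypercube_mass_within_1sd(d: int) -> float:
    """Mass of a standard d-variate normal inside the cube [-1, 1]^d.

    All coordinates are independent, so this is (2*Phi(1) - 1)**d.
    """
    d = _check_dim(d)
    univariate = 2.0 * stats.norm.cdf(1.0) - 1.0
    return float(univariate**d)


def expected_distance(d: int, n: int) -> float:
    """Average distance from a sample point to the edge of the unit hypercube.

    For ``n`` points spread over a ``d``-dimensional unit cube the expected
    nearest-edge distance is ``(1/2) * (1/n)**(1/d)``.  It increases with
    ``d`` (for n > 1) and asymptotes to the maximum possible value 0.5.
    """
    d = _check_dim(d)
    n = int(n)
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    return 0.5 * (1.0 / n) ** (1.0 / d)


def dim_table(d_max: int = 100, n: int = 10_000) -> pd.DataFrame:
    """Tabulate all three quantities for d = 1 .. d_max."""
    ds = np.arange(1, _check_dim(d_max) + 1)
    return pd.DataFrame(
        {
            "d": ds,
            "gaussian_mass": [gaussian_mass_within_1sd(d) for d in ds],
            "hypercube_mass": [hypercube_mass_within_1sd(d) for d in ds],
            "expected_distance": [expected_distance(d, n) for d in ds],
        }
    )
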