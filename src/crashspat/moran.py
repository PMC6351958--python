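"""Global Moran's I for per-segment counts, with a z-score for clustering.

Moran's I with unstandardized binary weights w_ij:

    I = n / S0 * sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2

where S0 = sum_{i != j} w_ij. Under the null of no spatial structure,
E[I] = -1/(n-1); the variance is available in closed form under either the
normality assumption or the randomization (permutation) assumption, and the
z-score is (I - E[I]) / sqrt(Var[I]). Randomization is the default here, as
is standard for counts; for a chain the two variances are very close.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adjacency import WeightMatrix
from .errors import CrashspatError


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    variance_I: float
    z: float
    n: int
    null_model: str


def _deviations(y, w: WeightMatrix):
    y = np.asarray(y, dtype=float)
    if y.size != w.n:
        raise CrashspatError("y length must match the weight matrix")
    d = y - y.mean()
    ss = float(d @ d)
    if ss == 0:
        raise CrashspatError("y is constant; Moran's I denominator is zero")
    return d, ss


def morans_i(y, w: WeightMatrix) -> float:
    """Moran's I statistic with unstandardized binary weights."""
    d, ss = _deviations(y, w)
    s0 = w.total_weight
    cross = float(d @ w.w @ d)
    return w.n / s0 * cross / ss


def morans_z(y, w: WeightMatrix, null_model: str = "randomization") -> MoranResult:
    """Moran's I with its null expectation, variance, and z-score.

    ``null_model`` selects the closed-form variance: ``"normality"`` assumes
    the y_i are i.i.d. Gaussian; ``"randomization"`` conditions on the
    observed values and randomizes their assignment to segments.
    """
    n = w.n
    if n < 3:
        raise CrashspatError("Moran variance formulas need n >= 3")
    d, ss = _deviations(y, w)
    i_obs = morans_i(y, w)
    e_i = -1.0 / (n - 1)

    wm = w.w
    s0 = w.total_weight
    s1 = 0.5 * float(((wm + wm.T) ** 2).sum())
    s2 = float(((wm.sum(axis=0) + wm.sum(axis=1)) ** 2).sum())

    if null_model == "normality":
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - e_i**2
    elif null_model == "randomization":
        b2 = n * float((d**4).sum()) / ss**2
        num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
            (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
        )
        var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i**2
    else:
        raise CrashspatError(f"unknown null model {null_model!r}")
    if var <= 0:
        raise CrashspatError("null variance is non-positive; degenerate weights")
    z = (i_obs - e_i) / np.sqrt(var)
    return MoranResult(
        I=i_obs, expected_I=e_i, variance_I=var, z=float(z), n=n, null_model=null_model
    )
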