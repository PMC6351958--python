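"""Spatial weights and adjacent-segment ("spillover") covariates.

The study network is a single freeway chain: segment i is a first-order
neighbour of i-1 and i+1 only, with binary 0/1 proximity weights. Spillover
covariates transfer the observed risk factors of the neighbouring segments
onto the targeted segment:

* continuous factors (curvature, grade) use the length-weighted mean of the
  two neighbours, and the single neighbour's value at the chain endpoints;
* binary factors (bridge, ramp) use an any-neighbour indicator, again
  copying the single neighbour at the endpoints.

A Pearson screen then drops any adjacent variable that is too strongly
correlated (|r| > 0.6 by default) with its targeted-segment counterpart,
since the pair would carry nearly the same information into the regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import CrashspatError


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric binary first-order proximity weights with zero diagonal."""

    n: int
    w: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if w.shape != (self.n, self.n):
            raise CrashspatError(f"weight matrix must be {self.n}x{self.n}")
        if not np.array_equal(w, w.T):
            raise CrashspatError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise CrashspatError("weight matrix must have a zero diagonal")
        if not np.isin(w, (0.0, 1.0)).all():
            raise CrashspatError("weights must be binary 0/1")
        object.__setattr__(self, "w", w)

    @property
    def degrees(self) -> np.ndarray:
        """Number of neighbours of each segment (row sums)."""
        return self.w.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """Sum of all weights, counting both directions: 2(n-1) on a chain."""
        return float(self.w.sum())


def build_chain_weights(n: int) -> WeightMatrix:
    """First-order 0/1 weights for a linear chain of ``n`` segments."""
    if n < 2:
        raise CrashspatError("a chain needs at least 2 segments")
    w = np.zeros((n, n))
    idx = np.arange(n - 1)
    w[idx, idx + 1] = 1.0
    w[idx + 1, idx] = 1.0
    return WeightMatrix(n=n, w=w)


def adjacent_continuous(x, lengths) -> np.ndarray:
    """Length-weighted neighbour mean of a continuous factor on a chain.

    Interior segments average their two neighbours' values weighted by the
    neighbours' lengths; the first and last segments take their single
    neighbour's value unchanged.
    """
    x = np.asarray(x, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    n = x.size
    if n < 2 or lengths.size != n:
        raise CrashspatError("need n >= 2 values with matching lengths")
    if np.any(lengths <= 0):
        raise CrashspatError("lengths must be strictly positive")
    out = np.empty(n)
    out[0] = x[1]
    out[-1] = x[-2]
    if n > 2:
        lw = lengths[:-2] * x[:-2] + lengths[2:] * x[2:]
        out[1:-1] = lw / (lengths[:-2] + lengths[2:])
    return out


def adjacent_binary(b) -> np.ndarray:
    """Any-neighbour indicator of a binary factor on a chain.

    Interior segments are 1 iff at least one of their two neighbours is 1;
    endpoints copy their single neighbour.
    """
    b = np.asarray(b)
    n = b.size
    if n < 2:
        raise CrashspatError("need n >= 2 values")
    if not np.isin(b, (0, 1)).all():
        raise CrashspatError("input must be binary 0/1")
    b = b.astype(int)
    out = np.empty(n, dtype=int)
    out[0] = b[1]
    out[-1] = b[-2]
    if n > 2:
        out[1:-1] = ((b[:-2] + b[2:]) >= 1).astype(int)
    return out


def adjacent_continuous_graph(x, lengths, w: WeightMatrix) -> np.ndarray:
    """Length-weighted neighbour mean on an arbitrary first-order graph.

    Extension beyond the chain rule: every segment (endpoints included)
    averages over all its graph neighbours with length weights. On a chain
    this differs from :func:`adjacent_continuous` only in that it is the
    same rule at the endpoints (a single neighbour's weighted mean is its
    value, so the two agree there too).
    """
    x = np.asarray(x, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise CrashspatError("lengths must be strictly positive")
    num = w.w @ (lengths * x)
    den = w.w @ lengths
    if np.any(den == 0):
        raise CrashspatError("every segment needs at least one neighbour")
    return num / den


@dataclass
class SpilloverSet:
    """Adjacent-segment covariates plus the names surviving the screen."""

    curvature_adj: np.ndarray
    grade_adj: np.ndarray
    bridge_adj: np.ndarray
    ramp_adj: np.ndarray
    retained: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "curvature_adj": self.curvature_adj,
                "grade_adj": self.grade_adj,
                "bridge_adj": self.bridge_adj,
                "ramp_adj": self.ramp_adj,
            }
        )


def correlation_screen(columns, threshold: float = 0.6):
    """Pearson screen between adjacent variables and their counterparts.

    Parameters
    ----------
    columns : Mapping[str, array-like] or DataFrame
        Named per-segment vectors; adjacent variables are those whose name
        ends in ``_adj`` and whose base name is also present.
    threshold : float
        Magnitude cut; a pair is flagged when |r| > threshold (strict).

    Returns
    -------
    retained : list of str
        Column names surviving the screen (the ``_adj`` member of each
        flagged base/adjacent pair is dropped, never the targeted one).
    flagged : list of (str, str, float)
        All column pairs with |r| above the threshold, with their r.
    """
    if isinstance(columns, pd.DataFrame):
        columns = {c: columns[c].to_numpy() for c in columns.columns}
    names = list(columns)
    if len(names) < 2:
        raise CrashspatError("need at least two columns to screen")
    arrays = {}
    for name in names:
        v = np.asarray(columns[name], dtype=float)
        if np.std(v) == 0:
            raise CrashspatError(f"column {name!r} has zero variance; correlation undefined")
        arrays[name] = v

    flagged = []
    dropped = set()
    for a, b in combinations(names, 2):
        r = float(np.corrcoef(arrays[a], arrays[b])[0, 1])
        if abs(r) > threshold:
            flagged.append((a, b, r))
            for adj, base in ((a, b), (b, a)):
                if adj.endswith("_adj") and adj[: -len("_adj")] == base:
                    dropped.add(adj)
    retained = [n for n in names if n not in dropped]
    return retained, flagged


def build_spillover(table: pd.DataFrame, threshold: float = 0.6) -> SpilloverSet:
    """Compute the four adjacent variables for a segment table and screen them.

    ``retained`` lists the adjacent-variable names that survive the Pearson
    screen against their targeted-segment counterparts.
    """
    lengths = table["length"].to_numpy()
    out = SpilloverSet(
        curvature_adj=adjacent_continuous(table["curvature"].to_numpy(), lengths),
        grade_adj=adjacent_continuous(table["grade"].to_numpy(), lengths),
        bridge_adj=adjacent_binary(table["bridge"].to_numpy()),
        ramp_adj=adjacent_binary(table["ramp"].to_numpy()),
    )
    cols = {
        "curvature": table["curvature"].to_numpy(),
        "grade": table["grade"].to_numpy(),
        "bridge": table["bridge"].to_numpy(),
        "ramp": table["ramp"].to_numpy(),
        "curvature_adj": out.curvature_adj,
        "grade_adj": out.grade_adj,
        "bridge_adj": out.bridge_adj,
        "ramp_adj": out.ramp_adj,
    }
    # constant columns (e.g. no bridges anywhere) cannot be screened; keep them
    screenable = {k: v for k, v in cols.items() if np.std(np.asarray(v, float)) > 0}
    retained, _ = correlation_screen(screenable, threshold=threshold)
    adj_names = ["curvature_adj", "grade_adj", "bridge_adj", "ramp_adj"]
    out.retained = [n for n in adj_names if n in retained or n not in screenable]
    return out
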