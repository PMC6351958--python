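"""Read, validate, and write per-segment tables for a linear freeway network.

A *segment table* is a :class:`pandas.DataFrame` with one row per freeway
segment, in chain order (segment ids 1..n, consecutive). Required columns:

``segment_id``
    integer label 1..n; positional order along the chain.
``length``
    segment length in km, strictly positive.
``curvature``
    horizontal curvature in 0.1 km^-1, non-negative.
``grade``
    vertical grade in %, non-negative.
``bridge``, ``ramp``
    binary {0, 1} indicators.
``aadt``
    annual average daily traffic in passenger-car units/day (optional when
    ``dvkt`` is supplied).
``dvkt``
    daily vehicle kilometres travelled, on the 10^3 km*pcu scale
    (computed from ``aadt`` and ``length`` when absent).
``crash_count``
    observed crash count, non-negative integer.

Validation also derives ``log_dvkt = log(1000 * dvkt)``, the log crash
exposure in raw km*pcu units. DVKT itself is stored on the 10^3 scale for
readability; because exposure enters the models as ``beta0 * log(DVKT)``
with an estimated coefficient, the scale choice only shifts the intercept,
and the raw-unit convention keeps intercepts on the scale practitioners
report for freeway data of this kind.
"""

from __future__ import annotations

import json
import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError, OrderingError, CrashspatError

REQUIRED_COLUMNS = (
    "segment_id",
    "length",
    "curvature",
    "grade",
    "bridge",
    "ramp",
    "crash_count",
)

#: Columns written by :func:`write_segments` (aadt kept when present).
_OUTPUT_COLUMNS = REQUIRED_COLUMNS[:-1] + ("aadt", "dvkt", "crash_count")


def compute_dvkt(aadt, length):
    """Daily vehicle kilometres travelled, on the 10^3 km*pcu scale.

    DVKT is the product of AADT (pcu/day) and segment length (km); dividing
    by 1000 expresses it in the 10^3 km*pcu units used throughout.

    Parameters
    ----------
    aadt : float or array-like
        Annual average daily traffic, pcu/day, > 0.
    length : float or array-like
        Segment length in km, > 0.
    """
    aadt = np.asarray(aadt, dtype=float)
    length = np.asarray(length, dtype=float)
    if np.any(aadt <= 0) or np.any(length <= 0):
        raise CrashspatError("aadt and length must be strictly positive")
    out = aadt * length / 1000.0
    return float(out) if out.ndim == 0 else out


def validate_segments(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a segment table in place and return it with derived columns.

    Checks the schema, the value invariants, and the 1..n chain ordering;
    fills ``dvkt`` from ``aadt`` when missing and derives ``log_dvkt``.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if "aadt" not in df.columns and "dvkt" not in df.columns:
        raise SchemaError("need at least one of 'aadt' or 'dvkt'")

    df = df.copy()
    numeric_cols = [c for c in df.columns if c in _OUTPUT_COLUMNS]
    for col in numeric_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValidationError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = vals.to_numpy(dtype=float)

    ids = df["segment_id"].to_numpy()
    n = len(df)
    if n == 0:
        raise ValidationError("segment table is empty")
    if not np.array_equal(ids, np.arange(1, n + 1)):
        raise OrderingError(
            "segment ids must be consecutive 1..n in chain order; "
            f"got {ids[:5].astype(int).tolist()}..."
        )
    df["segment_id"] = ids.astype(int)

    def _check(col, cond, msg):
        ok = cond(df[col].to_numpy())
        if not ok.all():
            row = int(np.argmax(~ok))
            raise ValidationError(f"column {col!r} {msg} at row {row}")

    _check("length", lambda v: v > 0, "must be strictly positive")
    _check("curvature", lambda v: v >= 0, "must be non-negative")
    _check("grade", lambda v: v >= 0, "must be non-negative")
    for col in ("bridge", "ramp"):
        _check(col, lambda v: np.isin(v, (0.0, 1.0)), "must be binary 0/1")
        df[col] = df[col].astype(int)
    cc = df["crash_count"].to_numpy()
    if not ((cc >= 0) & (cc == np.floor(cc))).all():
        row = int(np.argmax(~((cc >= 0) & (cc == np.floor(cc)))))
        raise ValidationError(
            f"column 'crash_count' must be a non-negative integer at row {row}"
        )
    df["crash_count"] = cc.astype(int)

    if "dvkt" not in df.columns:
        df["dvkt"] = compute_dvkt(df["aadt"].to_numpy(), df["length"].to_numpy())
    _check("dvkt", lambda v: v > 0, "must be strictly positive")
    if "aadt" in df.columns:
        _check("aadt", lambda v: v > 0, "must be strictly positive")

    # exposure in raw km*pcu units; see module docstring for the scale choice
    df["log_dvkt"] = np.log(df["dvkt"].to_numpy() * 1000.0)
    return df


def read_segments(path, **csv_kwargs) -> pd.DataFrame:
    """Read a segment table from CSV and validate it.

    Extra keyword arguments are passed to :func:`pandas.read_csv`.
    """
    df = pd.read_csv(path, **csv_kwargs)
    return validate_segments(df)


def write_segments(df: pd.DataFrame, path) -> None:
    """Write a segment table to CSV (UTF-8, '.' decimal, with header)."""
    cols = [c for c in _OUTPUT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def write_fit_summary(summary, path, fmt=None) -> None:
    """Write a :class:`~crashspat.assessment.FitSummary` to CSV or JSON.

    CSV output has one row per parameter (posterior mean, SD, 90%/95%
    credible bounds, significance marker) followed by a DIC block; JSON
    mirrors the same structure. ``fmt`` defaults to the file extension.
    """
    if not summary.parameters:
        raise CrashspatError("fit summary has no parameters to write")
    fmt = fmt or (str(path).rsplit(".", 1)[-1].lower() if "." in str(path) else "csv")
    rows = []
    for name, p in summary.parameters.items():
        rows.append(
            {
                "parameter": name,
                "mean": p["mean"],
                "sd": p["sd"],
                "ci90_low": p["ci90"][0],
                "ci90_high": p["ci90"][1],
                "ci95_low": p["ci95"][0],
                "ci95_high": p["ci95"][1],
                "significance": p["significance"],
            }
        )
    if fmt == "json":
        payload = {
            "parameters": rows,
            "dic": dict(summary.dic) if summary.dic else None,
            "eta": summary.eta,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
        return
    frame = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        frame.to_csv(fh, index=False, float_format="%.10g")
        if summary.dic:
            fh.write("# DIC block\n")
            for key in ("D_bar", "D_hat", "p_D", "DIC"):
                fh.write(f"# {key},{summary.dic[key]:.10g}\n")
        if summary.eta is not None:
            fh.write(f"# eta,{summary.eta:.10g}\n")


def read_fit_summary(path):
    """Read back a CSV fit summary written by :func:`write_fit_summary`.

    Returns ``(parameters_frame, dic_dict, eta)``; the DIC block and eta are
    ``None`` when absent. Round-trips values to at least 6 significant
    digits (they are written with 10).
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body = [ln for ln in lines if not ln.startswith("#")]
    extras = [ln[1:].strip() for ln in lines if ln.startswith("#")]
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(body)))
    dic, eta = {}, None
    for ln in extras:
        if "," not in ln:
            continue
        key, val = ln.split(",", 1)
        if key == "eta":
            eta = float(val)
        elif key in ("D_bar", "D_hat", "p_D", "DIC"):
            dic[key] = float(val)
    return frame, (dic or None), eta
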