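"""The 97-dimension time/frequency feature bank computed per window.

Thirteen single-axis statistics are applied to seven axes — accelerometer
x/y/z plus the per-sample acceleration magnitude m (orientation
independent), and gyro x/y/z — giving 91 features, plus Pearson
correlations for the three accelerometer axis pairs and the three gyro
axis pairs (6), for 97 in total.

Estimator conventions (population moments, mean-removed one-sided DFT,
linear-interpolation quantiles) are documented per feature below; any
consistent convention preserves the classification geometry.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from henrec.signals_io import magnitude
from henrec.windowing import WindowInstance

#: Single-axis feature symbols in canonical order.
SYMBOLS = (
    "MIN", "MAX", "MEAN", "SD", "SKEW", "KURT", "IQR",
    "MAD", "MedAD", "MCRS", "ENGY", "ENTR", "DOMIF",
)

#: Axis names in canonical order; acc_m is derived per sample from acc x/y/z.
AXES = ("acc_x", "acc_y", "acc_z", "acc_m", "gyr_x", "gyr_y", "gyr_z")

_CORR_PAIRS = (
    ("acc_x", "acc_y"), ("acc_x", "acc_z"), ("acc_y", "acc_z"),
    ("gyr_x", "gyr_y"), ("gyr_x", "gyr_z"), ("gyr_y", "gyr_z"),
)

SUBSET_IDS = (
    "ALL", "ACC", "GYR", "WO_M_FROM_ALL", "WO_M_FROM_ACC",
    "BANERJEE4", "DERAKHSHANI31",
)


def feature_names(subset_id: str = "ALL") -> list[str]:
    """Ordered feature names for a subset (axis-major, then CORR pairs)."""
    all_names = [f"{ax}__{sym}" for ax in AXES for sym in SYMBOLS] + [
        f"{a}_{b.split('_')[1]}__CORR" for a, b in _CORR_PAIRS
    ]
    if subset_id == "ALL":
        return all_names
    if subset_id == "ACC":
        return [n for n in all_names if n.startswith("acc")]
    if subset_id == "GYR":
        return [n for n in all_names if n.startswith("gyr")]
    if subset_id == "WO_M_FROM_ALL":
        return [n for n in all_names if not n.startswith("acc_m__")]
    if subset_id == "WO_M_FROM_ACC":
        return [
            n for n in all_names
            if n.startswith("acc") and not n.startswith("acc_m__")
        ]
    if subset_id == "BANERJEE4":
        return ["acc_x__ENTR", "acc_x__MEAN", "acc_y__ENTR", "acc_y__MEAN"]
    if subset_id == "DERAKHSHANI31":
        stats = ("SKEW", "KURT", "MEAN", "SD", "VAR", "MIN", "MAX", "ENTR", "ENGY")
        names = [f"acc_{ax}__{s}" for ax in "xyz" for s in stats]
        names += ["acc_xy__COV", "acc_xz__COV", "acc_yz__COV", "acc__ASM"]
        return names
    raise ValueError(f"unknown subset id {subset_id!r}")


def _axis_features(s: np.ndarray, sf: float) -> dict[str, float]:
    """The 13 single-axis statistics of one window channel."""
    n = s.size
    mean = s.mean()
    c = s - mean
    m2 = np.mean(c**2)
    sd = np.sqrt(m2)
    if m2 > 0:
        skew = np.mean(c**3) / m2**1.5
        kurt = np.mean(c**4) / m2**2 - 3.0  # excess kurtosis
    else:
        skew = 0.0
        kurt = 0.0
    q1, q3 = np.quantile(s, [0.25, 0.75])  # linear interpolation
    mad = np.mean(np.abs(c))
    med = np.median(s)
    medad = np.median(np.abs(s - med))
    # mean crossings: sign alternations of the centered signal, zero -> +
    nonneg = c >= 0
    mcrs = int(np.count_nonzero(nonneg[1:] != nonneg[:-1]))
    # one-sided DFT of the mean-removed signal, bins 1..N/2 (DC excluded)
    spec = np.fft.rfft(c)[1:]
    power = np.abs(spec) ** 2
    total = power.sum()
    engy = total / n
    if total > 0:
        p = power / total
        nz = p[p > 0]
        entr = float(-np.sum(nz * np.log(nz)))
        k = int(np.argmax(np.abs(spec))) + 1  # ties -> lowest bin
        domif = k * sf / n
    else:
        entr = 0.0
        domif = 0.0
    return {
        "MIN": float(s.min()), "MAX": float(s.max()), "MEAN": float(mean),
        "SD": float(sd), "SKEW": float(skew), "KURT": float(kurt),
        "IQR": float(q3 - q1), "MAD": float(mad), "MedAD": float(medad),
        "MCRS": float(mcrs), "ENGY": float(engy), "ENTR": entr,
        "DOMIF": float(domif),
    }


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 when either signal has zero variance."""
    ca, cb = a - a.mean(), b - b.mean()
    va, vb = np.mean(ca**2), np.mean(cb**2)
    if va == 0 or vb == 0:
        return 0.0
    return float(np.mean(ca * cb) / np.sqrt(va * vb))


def _window_axes(window: WindowInstance) -> dict[str, np.ndarray]:
    x = window.samples
    axes = {
        "acc_x": x[:, 0], "acc_y": x[:, 1], "acc_z": x[:, 2],
        "gyr_x": x[:, 3], "gyr_y": x[:, 4], "gyr_z": x[:, 5],
    }
    axes["acc_m"] = magnitude(axes["acc_x"], axes["acc_y"], axes["acc_z"])
    return axes


def compute_features(window: WindowInstance, sf: float) -> dict[str, float]:
    """Compute the full 97-feature vector of one window.

    ``sf`` is the sampling frequency of the window's samples (needed to
    express the dominant frequency in Hz). Returns an ordered mapping
    following :func:`feature_names`.
    """
    if not np.all(np.isfinite(window.samples)):
        raise ValueError(
            f"non-finite sample in window (hen {window.hen_id}, "
            f"behavior {window.behavior}, start {window.start_s})"
        )
    if window.samples.shape[0] < 8:
        raise ValueError("window must have at least 8 samples")
    axes = _window_axes(window)
    out: dict[str, float] = {}
    for ax in AXES:
        stats = _axis_features(axes[ax], sf)
        for sym in SYMBOLS:
            out[f"{ax}__{sym}"] = stats[sym]
    for a, b in _CORR_PAIRS:
        name = f"{a}_{b.split('_')[1]}__CORR"
        out[name] = _pearson(axes[a], axes[b])
    return out


def subset_features(fv: Mapping[str, float], subset_id: str) -> dict[str, float]:
    """Project an ALL vector onto a named subset, preserving canonical order.

    ACC keeps the 4 accelerometer axes (52) plus the 3 acc correlations
    (55); GYR keeps the 3 gyro axes (39) plus 3 gyr correlations (42).
    Removing the magnitude-axis features is ambiguous in print, so both
    readings are exposed: ``WO_M_FROM_ALL`` (97-13=84) and
    ``WO_M_FROM_ACC`` (55-13=42).
    """
    names = feature_names(subset_id)
    missing = [n for n in names if n not in fv]
    if missing:
        raise ValueError(f"input vector lacks features {missing[:3]}... for {subset_id}")
    return {n: fv[n] for n in names}


def literature_features(window: WindowInstance, sf: float, which: str) -> dict[str, float]:
    """Feature sets from prior poultry-accelerometry work, for comparison.

    ``BANERJEE4``: frequency entropy and mean of accelerometer x and y.
    ``DERAKHSHANI31``: nine statistics (SKEW, KURT, MEAN, SD, VAR, MIN,
    MAX, ENTR, ENGY) on each accelerometer axis (27), population covariance
    of the three axis pairs (3), and the average signal magnitude ASM (1).
    """
    if which == "BANERJEE4":
        full = compute_features(window, sf)
        return {n: full[n] for n in feature_names("BANERJEE4")}
    if which == "DERAKHSHANI31":
        axes = _window_axes(window)
        out: dict[str, float] = {}
        per_axis: dict[str, dict[str, float]] = {}
        for ax in ("acc_x", "acc_y", "acc_z"):
            stats = _axis_features(axes[ax], sf)
            stats["VAR"] = stats["SD"] ** 2
            per_axis[ax] = stats
        for ax in "xyz":
            for s in ("SKEW", "KURT", "MEAN", "SD", "VAR", "MIN", "MAX", "ENTR", "ENGY"):
                out[f"acc_{ax}__{s}"] = per_axis[f"acc_{ax}"][s]
        for a, b in (("x", "y"), ("x", "z"), ("y", "z")):
            sa, sb = axes[f"acc_{a}"], axes[f"acc_{b}"]
            cov = float(np.mean((sa - sa.mean()) * (sb - sb.mean())))
            out[f"acc_{a}{b}__COV"] = cov
        out["acc__ASM"] = float(axes["acc_m"].mean())
        return out
    raise ValueError(f"unknown literature subset {which!r}")


def feature_matrix(
    windows,
    sf: float,
    subset_id: str = "ALL",
):
    """Feature table for a window list: (DataFrame of features, metadata).

    Returns a pandas DataFrame with one row per window in input order and
    columns ``hen_id, behavior, start_s`` followed by the subset's feature
    columns.
    """
    import pandas as pd

    rows = []
    for w in windows:
        if subset_id in ("BANERJEE4", "DERAKHSHANI31"):
            fv = literature_features(w, sf, subset_id)
        else:
            fv = subset_features(compute_features(w, sf), subset_id)
        rows.append({"hen_id": w.hen_id, "behavior": w.behavior, "start_s": w.start_s, **fv})
    cols = ["hen_id", "behavior", "start_s"] + feature_names(subset_id)
    return pd.DataFrame(rows, columns=cols)
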