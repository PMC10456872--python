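"""Per-subject index inventory: sub-space statistics + polygon morphology.

For each vascular driver (SBP, DBP) and each sub-space z ∈ {u, nc, d},
26 indices are computed from the normalized Δ-series:

* 8 per ΔBBI and 8 per ΔTT — mean (m), standard deviation (sd),
  kurtosis (K, non-excess), skewness (Sk), interquartile range (IQR),
  coefficient of variation (CV, %), sub-space occupancy probability (p),
  and mean absolute deviation from the sub-space mean (d);
* 10 joint morphology indices of the (ΔBBI, ΔTT) containment polygon —
  area A, area per kept point An, area per vertex Av, vertex count n,
  mean sample–centroid distance dc, mean vertex angle θ, mean centroid
  angle β, their difference θβ, mean per-triangle occupancy pr, and
  mean triangle area Ar.

Together with 6 global descriptive statistics for each of ΔSBP and ΔDBP
this yields the fixed 168-entry feature vector per subject.  Indices
that cannot be computed (empty or degenerate sub-space) are carried as
NaN, never imputed.
"""

from __future__ import annotations

import logging
from collections import OrderedDict

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .delta import LABELS, DeltaSeries, SubspacePartition, align_triplet
from .geometry import PolygonModel

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "STAT_KEYS",
    "MORPH_KEYS",
    "subspace_stats",
    "occupancy_and_distance",
    "subspace_indices",
    "assemble_features",
    "characterize_subject",
    "feature_frame",
]

DRIVERS = ("SBP", "DBP")
SERIES_XY = ("BBI", "TT")

#: statistic suffixes in canonical order (mean, sd, kurtosis, skewness,
#: interquartile range, coefficient of variation)
STAT_KEYS = ("m", "sd", "K", "Sk", "IQR", "CV")
#: per-series extras: occupancy probability and mean distance
PD_KEYS = ("p", "d")
#: joint morphology suffixes in canonical order
MORPH_KEYS = ("A", "An", "Av", "n", "dc", "θ", "β", "θβ", "pr", "Ar")


def _build_feature_names() -> list[str]:
    names: list[str] = []
    for drv in DRIVERS:
        for z in LABELS:
            for xy in SERIES_XY:
                for s in STAT_KEYS + PD_KEYS:
                    names.append(f"{drv}-∆{xy}{s}-{z}")
            for s in MORPH_KEYS:
                names.append(f"{drv}-∆BBI_TT{s}-{z}")
    for drv in DRIVERS:
        for s in STAT_KEYS:
            names.append(f"∆{drv}{s}")
    return names


#: canonical ordering of the 168 feature names
FEATURE_NAMES: tuple[str, ...] = tuple(_build_feature_names())
assert len(FEATURE_NAMES) == 168


def subspace_stats(values: np.ndarray) -> dict[str, float]:
    """Descriptive statistics of a Δ-sample vector.

    Returns mean, sample SD (n−1), non-excess kurtosis, skewness,
    IQR (linear-interpolation quantiles) and CV = sd/m·100.  Entries
    that need more data than supplied (sd: ≥2, K/Sk: ≥4) or divide by a
    zero mean (CV) come back NaN.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    nan = float("nan")
    out = dict.fromkeys(STAT_KEYS, nan)
    if x.size == 0:
        return out
    out["m"] = float(x.mean())
    if x.size >= 2:
        out["sd"] = float(x.std(ddof=1))
        q1, q3 = np.percentile(x, [25, 75])
        out["IQR"] = float(q3 - q1)
        if out["m"] != 0:
            out["CV"] = out["sd"] / out["m"] * 100.0
        else:
            logger.debug("CV undefined: zero mean")
    if x.size >= 4 and x.std() > 0:
        out["K"] = float(sstats.kurtosis(x, fisher=False, bias=True))
        out["Sk"] = float(sstats.skew(x, bias=True))
    return out


def occupancy_and_distance(
    values: np.ndarray, n_total: int, points: np.ndarray, centroid: tuple[float, float]
) -> tuple[float, float, float]:
    """Occupancy probability, mean deviation, and centroid distance.

    Returns ``(p, d, dc)`` where p = |sub-space| / n, d = mean absolute
    deviation of the sub-space's ΔX values from their own mean, and dc =
    mean Euclidean distance of the sub-space's (ΔBBI, ΔTT) points to the
    sub-space polygon centroid.  An empty sub-space yields NaN for all
    three.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0 or n_total == 0:
        return float("nan"), float("nan"), float("nan")
    p = x.size / n_total
    d = float(np.abs(x - x.mean()).mean())
    c = np.asarray(centroid, dtype=float)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.size == 0 or not np.all(np.isfinite(c)):
        dc = float("nan")
    else:
        dc = float(np.linalg.norm(pts - c, axis=1).mean())
    return float(p), d, dc


def subspace_indices(
    driver: str,
    z: str,
    dbbi_vals: np.ndarray,
    dtt_vals: np.ndarray,
    points: np.ndarray,
    n_total: int,
    containment: float = 0.95,
) -> dict[str, float]:
    """All 26 indices of one (driver, sub-space) cell."""
    model = PolygonModel.fit(points, containment)
    out: dict[str, float] = {}
    for xy, vals in (("BBI", dbbi_vals), ("TT", dtt_vals)):
        stats = subspace_stats(vals)
        for s in STAT_KEYS:
            out[f"{driver}-∆{xy}{s}-{z}"] = stats[s]
        p, d, _ = occupancy_and_distance(vals, n_total, points, model.centroid)
        out[f"{driver}-∆{xy}p-{z}"] = p
        out[f"{driver}-∆{xy}d-{z}"] = d

    nan = float("nan")
    if model.degenerate:
        morph = dict.fromkeys(MORPH_KEYS, nan)
    else:
        _, _, dc = occupancy_and_distance(dbbi_vals, n_total, points, model.centroid)
        theta, beta = model.mean_theta_deg, model.mean_beta_deg
        morph = {
            "A": model.area,
            "An": model.area / model.kept.shape[0],
            "Av": model.area / model.n_vertices,
            "n": float(model.n_vertices),
            "dc": dc,
            "θ": theta,
            "β": beta,
            "θβ": theta - beta,
            "pr": model.mean_occupancy,
            "Ar": model.mean_triangle_area,
        }
    for s in MORPH_KEYS:
        out[f"{driver}-∆BBI_TT{s}-{z}"] = morph[s]
    return out


def assemble_features(
    per_driver: dict[str, dict[str, dict[str, float]]],
    global_stats: dict[str, dict[str, float]],
) -> "OrderedDict[str, float]":
    """Assemble the canonical 168-entry feature vector.

    Parameters
    ----------
    per_driver : {driver: {z: {name: value}}}
        Output of :func:`subspace_indices` per driver and sub-space.
    global_stats : {driver: {stat: value}}
        Global descriptive statistics of ΔSBP and ΔDBP.

    Missing entries are carried as NaN; the schema (names and order) is
    fixed regardless of which cells could be computed.
    """
    flat: dict[str, float] = {}
    for drv, blocks in per_driver.items():
        for cell in blocks.values():
            flat.update(cell)
    for drv, stats in global_stats.items():
        for s in STAT_KEYS:
            flat[f"∆{drv}{s}"] = stats.get(s, float("nan"))
    return OrderedDict((name, flat.get(name, float("nan"))) for name in FEATURE_NAMES)


def characterize_subject(
    deltas: dict[str, DeltaSeries],
    partitions: dict[str, SubspacePartition],
    containment: float = 0.95,
    driver_deltas: dict[str, DeltaSeries] | None = None,
) -> "OrderedDict[str, float]":
    """Compute the full 168-index vector from normalized Δ-series.

    Parameters
    ----------
    deltas : dict with keys "BBI", "TT", "SBP", "DBP"
        Normalized Δ-series on the shared 0.25 Hz grid.
    partitions : dict with keys "SBP", "DBP"
        Sub-space partitions of the two drivers.
    driver_deltas : optional dict with keys "SBP", "DBP"
        Unnormalized driver Δ-series for the 12 global descriptive
        statistics (z-scoring fixes mean/SD at 0/1, which would make
        those entries vacuous).  Falls back to ``deltas``.
    """
    dbbi, dtt = deltas["BBI"], deltas["TT"]
    per_driver: dict[str, dict[str, dict[str, float]]] = {}
    for drv in DRIVERS:
        part = partitions[drv]
        point_sets = align_triplet(part, dbbi, dtt)
        blocks: dict[str, dict[str, float]] = {}
        for z in LABELS:
            idx = part.index_sets[z]
            blocks[z] = subspace_indices(
                drv, z,
                dbbi.values[idx], dtt.values[idx],
                point_sets[z], part.n, containment,
            )
        per_driver[drv] = blocks
    src = driver_deltas if driver_deltas is not None else deltas
    global_stats = {drv: subspace_stats(src[drv].values) for drv in DRIVERS}
    return assemble_features(per_driver, global_stats)


def feature_frame(rows: dict[str, dict[str, float]], groups: dict[str, str] | None = None,
                  ) -> pd.DataFrame:
    """Stack per-subject feature dicts into a subject × index DataFrame.

    The frame is indexed by subject_id with columns in canonical order;
    a ``group`` column is appended when labels are given.
    """
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=list(FEATURE_NAMES))
    df.index.name = "subject_id"
    if groups is not None:
        df["group"] = pd.Series(groups)
    return df
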