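"""Δ-series construction and vascular-change sub-space partitioning.

The variability analysis works on first differences of the resampled
event series, ΔX_n = X_{n+1} − X_n, z-scored per subject.  A vascular
driver series (ΔSBP or ΔDBP) is split into three sub-spaces by the
threshold

    Th = α · (max ΔXv − min ΔXv) / 2,      α = 0.15 by default:

"up" (ΔXv > Th, rising pressure), "no change" (−Th ≤ ΔXv ≤ Th, boundary
inclusive) and "down" (ΔXv < −Th, falling pressure).  The cardiac and
respiratory responses (ΔBBI, ΔTT) are then read off at the sample
indices of each sub-space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signals import EventSeries

__all__ = [
    "DeltaSeries",
    "SubspacePartition",
    "LABELS",
    "delta",
    "normalize",
    "vascular_threshold",
    "partition",
    "align_triplet",
]

#: sub-space labels: up / no-change / down
LABELS = ("u", "nc", "d")


@dataclass
class DeltaSeries:
    """First-difference series, optionally z-scored (normalized units)."""

    kind: str  # e.g. "ΔBBI", "ΔTT", "ΔSBP", "ΔDBP"
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class SubspacePartition:
    """Per-sample sub-space labels for one vascular driver."""

    driver: str  # "SBP" or "DBP"
    threshold: float
    alpha: float
    labels: np.ndarray  # array of "u" / "nc" / "d"
    index_sets: dict[str, np.ndarray]

    @property
    def n(self) -> int:
        return self.labels.size


def delta(series: EventSeries | np.ndarray, kind: str | None = None) -> DeltaSeries:
    """Difference between consecutive events: values[i] = X[i+1] − X[i]."""
    if isinstance(series, EventSeries):
        x = series.values
        kind = kind or f"Δ{series.kind}"
    else:
        x = np.asarray(series, dtype=float)
        kind = kind or "ΔX"
    if x.size < 2:
        raise ValueError("need at least 2 samples to difference")
    return DeltaSeries(kind, np.diff(x))


def normalize(d: DeltaSeries, ddof: int = 1) -> DeltaSeries:
    """Z-score a Δ-series (zero mean, unit variance, per subject).

    Raises
    ------
    ValueError
        For a constant Δ-series (zero variance).
    """
    sd = d.values.std(ddof=ddof) if d.n > ddof else 0.0
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"constant delta series: {d.kind}")
    z = (d.values - d.values.mean()) / sd
    return replace(d, values=z, normalized=True)


def vascular_threshold(delta_v: DeltaSeries, alpha: float = 0.15) -> float:
    """No-change band half-width Th = α·(max Δ − min Δ)/2."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    hi, lo = delta_v.values.max(), delta_v.values.min()
    if hi == lo:
        raise ValueError("degenerate driver series: max equals min")
    return alpha * (hi - lo) / 2.0


def partition(delta_v: DeltaSeries, th: float, driver: str | None = None,
              alpha: float = float("nan")) -> SubspacePartition:
    """Label each driver sample up / nc / down relative to ±``th``.

    Samples exactly at ±th belong to the no-change band (boundary
    inclusive on both sides).
    """
    if not th > 0:
        raise ValueError("threshold must be positive")
    v = delta_v.values
    labels = np.full(v.size, "nc", dtype=object)
    labels[v > th] = "u"
    labels[v < -th] = "d"
    index_sets = {z: np.flatnonzero(labels == z) for z in LABELS}
    if driver is None:
        driver = delta_v.kind.lstrip("Δ∆")
    return SubspacePartition(driver, th, alpha, labels.astype(str), index_sets)


def align_triplet(
    part: SubspacePartition, dbbi: DeltaSeries, dtt: DeltaSeries
) -> dict[str, np.ndarray]:
    """Per-label (ΔBBI, ΔTT) point sets aligned on the common grid.

    Returns a dict mapping each label to an (n_z, 2) array.  All three
    series must share the same resampled grid length.
    """
    if dbbi.n != part.n or dtt.n != part.n:
        raise ValueError("unsynchronized series: lengths differ")
    pts = np.column_stack([dbbi.values, dtt.values])
    return {z: pts[idx] for z, idx in part.index_sets.items()}
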