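"""Raw physiological records and beat/breath event-series extraction.

Turns multi-channel recordings (ECG in mV, continuous arterial blood
pressure in mmHg, respiratory flow in arbitrary units) into the four
synchronized event series the downstream variability analysis consumes:

* BBI — beat-to-beat interval, time between consecutive R peaks (ms)
* SBP / DBP — per-beat maximum / minimum of the pressure wave (mmHg)
* TT — total respiratory cycle time, interval between breath onsets (s)

Event series are resampled onto uniform 1 Hz grids by linear
interpolation and decimated to 0.25 Hz (anti-alias low-pass, keep every
4th sample) so that cardiac, vascular and respiratory activity share one
common time base.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "PhysioRecord",
    "EventSeries",
    "detrend_and_clean",
    "clean_event_series",
    "detect_rpeaks",
    "extract_bbi",
    "extract_sbp_dbp",
    "extract_tt",
    "resample_series",
    "common_span",
    "read_physio_csv",
    "write_event_series_csv",
    "read_event_series_csv",
]

#: physiological bounds on an inter-beat interval, seconds
BBI_BOUNDS_S = (0.25, 3.0)


@dataclass
class PhysioRecord:
    """A raw multi-channel recording at a single sampling rate.

    Parameters
    ----------
    channels : dict of str -> ndarray
        Sample vectors in physical units (ECG mV, BP mmHg, RF a.u.).
        All channels must have identical length.
    fs : float
        Sampling rate in Hz, > 0.
    subject_id : str
        Opaque subject identifier.
    """

    channels: dict[str, np.ndarray]
    fs: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channels:
            raise ValueError("record has no channels")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {v.size for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have the same length")
        if lengths == {0}:
            raise ValueError("channels are empty")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class EventSeries:
    """One beat- or breath-indexed series, optionally on a uniform grid.

    ``kind`` is one of ``{"BBI", "SBP", "DBP", "TT"}``; values carry the
    kind's units (BBI ms, SBP/DBP mmHg, TT s).  ``grid_hz`` is ``None``
    for event-indexed series and 1.0 or 0.25 after resampling.
    """

    kind: str
    values: np.ndarray
    timestamps: np.ndarray
    grid_hz: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.shape != self.timestamps.shape:
            raise ValueError("values and timestamps must have equal length")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.kind}: non-finite values")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError(f"{self.kind}: timestamps must be strictly increasing")
        if self.kind in ("BBI", "TT") and self.values.size and np.any(self.values <= 0):
            raise ValueError(f"{self.kind}: values must be strictly positive")

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# cleaning

def _interpolate_mask(x: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Replace masked samples by linear interpolation between good neighbours."""
    if not bad.any():
        return x
    good = ~bad
    out = x.copy()
    idx = np.arange(x.size)
    # edges fall back to the nearest good sample (np.interp clamps)
    out[bad] = np.interp(idx[bad], idx[good], x[good])
    return out


def detrend_and_clean(record: PhysioRecord, n_sd: float = 3.0) -> PhysioRecord:
    """Remove each channel's linear trend and repair amplitude outliers.

    The least-squares linear trend is subtracted per channel; samples
    whose absolute deviation from the (post-detrend) channel mean is at
    least ``n_sd`` standard deviations are treated as artifacts and
    replaced by linear interpolation between their neighbours, keeping
    the uniform sampling grid intact.

    Raises
    ------
    ValueError
        If a channel is constant ("degenerate channel").
    """
    cleaned: dict[str, np.ndarray] = {}
    for name, x in record.channels.items():
        if x.size < 2 or np.ptp(x) == 0:
            raise ValueError(f"degenerate channel: {name!r}")
        y = sps.detrend(x, type="linear")
        sd = y.std()
        if sd == 0:
            raise ValueError(f"degenerate channel: {name!r}")
        bad = np.abs(y - y.mean()) >= n_sd * sd
        frac = bad.mean()
        if frac > 0.20:
            warnings.warn(
                f"channel {name!r}: {frac:.1%} of samples flagged as outliers",
                stacklevel=2,
            )
        if bad.all():
            raise ValueError(f"degenerate channel: {name!r}")
        cleaned[name] = _interpolate_mask(y, bad)
        logger.debug("channel %s: replaced %d outlier samples", name, int(bad.sum()))
    return replace(record, channels=cleaned)


def clean_event_series(series: EventSeries, n_sd: float = 3.0) -> EventSeries:
    """Apply the same ``n_sd``-SD edit rule to an extracted event series.

    Outlying events (ectopy, detection glitches) are replaced by linear
    interpolation over event index, preserving the event count.
    """
    x = series.values
    if x.size < 3 or x.std() == 0:
        return series
    bad = np.abs(x - x.mean()) >= n_sd * x.std()
    if bad.all() or not bad.any():
        return series
    return replace(series, values=_interpolate_mask(x, bad))


# ---------------------------------------------------------------------------
# event detection

def detect_rpeaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-peak times (s) with a Pan–Tompkins-style detector.

    Band-pass (5–15 Hz) → differentiate → square → 150 ms moving-window
    integration → peak picking with a refractory distance of 250 ms,
    followed by refinement of each fiducial point to the local maximum
    of the band-passed ECG.

    Parameters
    ----------
    ecg : ndarray
        ECG samples (any consistent amplitude unit).
    fs : float
        Sampling rate, >= 100 Hz.

    Returns
    -------
    ndarray
        Strictly increasing R-peak times in seconds.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz for QRS detection")
    if ecg.size < 2 * fs:
        raise ValueError("need at least 2 s of ECG")
    if np.ptp(ecg) == 0:
        raise ValueError("no QRS detected")

    nyq = fs / 2
    b, a = sps.butter(2, [5 / nyq, 15 / nyq], btype="band")
    bp = sps.filtfilt(b, a, ecg)
    deriv = np.gradient(bp)
    sq = deriv * deriv
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    height = 0.2 * np.percentile(mwi, 99)
    if height <= 0:
        raise ValueError("no QRS detected")
    locs, _ = sps.find_peaks(mwi, height=height, distance=int(round(0.25 * fs)))
    if locs.size == 0:
        raise ValueError("no QRS detected")

    # refine each detection to the nearest band-passed extremum
    half = int(round(0.10 * fs))
    refined = []
    for p in locs:
        lo, hi = max(0, p - half), min(ecg.size, p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    peaks = np.unique(refined)
    times = peaks / fs

    if times.size >= 2:
        ibi = np.diff(times)
        n_out = int(np.sum((ibi < BBI_BOUNDS_S[0]) | (ibi > BBI_BOUNDS_S[1])))
        if n_out:
            logger.warning("%d inter-beat intervals outside %s s", n_out, BBI_BOUNDS_S)
    return times


def extract_bbi(rpeak_times: np.ndarray) -> EventSeries:
    """Beat-to-beat intervals (ms) from R-peak times; needs >= 3 peaks."""
    t = np.asarray(rpeak_times, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 R peaks to form a BBI series")
    return EventSeries("BBI", np.diff(t) * 1000.0, t[1:])


def extract_sbp_dbp(
    bp: np.ndarray, fs: float, rpeak_times: np.ndarray
) -> tuple[EventSeries, EventSeries]:
    """Per-beat systolic (max) and diastolic (min) pressure, in mmHg.

    Beat window *i* spans [t_i, t_{i+1}); windows containing no sample
    are skipped with a warning.  Each value is stamped at its window
    start.
    """
    bp = np.asarray(bp, dtype=float)
    t = np.asarray(rpeak_times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 R peaks to define a beat window")
    n = bp.size
    if t[0] < 0 or t[-1] > n / fs:
        raise ValueError("R-peak times outside the BP record span")
    sbp_v, dbp_v, stamps = [], [], []
    for t0, t1 in zip(t[:-1], t[1:]):
        i0, i1 = int(np.ceil(t0 * fs)), int(np.ceil(t1 * fs))
        seg = bp[i0:min(i1, n)]
        if seg.size == 0:
            warnings.warn(f"beat window [{t0:.3f}, {t1:.3f}) s has no BP samples", stacklevel=2)
            continue
        sbp_v.append(seg.max())
        dbp_v.append(seg.min())
        stamps.append(t0)
    stamps_a = np.asarray(stamps)
    return (
        EventSeries("SBP", np.asarray(sbp_v), stamps_a),
        EventSeries("DBP", np.asarray(dbp_v), stamps_a),
    )


def extract_tt(rf: np.ndarray, fs: float, cutoff_hz: float = 1.0) -> EventSeries:
    """Total respiratory cycle times (s) from a respiratory-flow signal.

    Breath onsets are the negative-to-positive zero crossings of the
    mean-removed, low-passed (``cutoff_hz``) flow; TT[i] is the interval
    between consecutive onsets.
    """
    rf = np.asarray(rf, dtype=float)
    if rf.size < 4 or np.ptp(rf) == 0:
        raise ValueError("fewer than 2 breath onsets found")
    b, a = sps.butter(4, cutoff_hz / (fs / 2), btype="low")
    x = sps.filtfilt(b, a, rf - rf.mean())
    neg = x[:-1] < 0
    pos = x[1:] >= 0
    idx = np.flatnonzero(neg & pos)
    if idx.size < 2:
        raise ValueError("fewer than 2 breath onsets found")
    # sub-sample refinement by linear interpolation across the crossing
    frac = x[idx] / (x[idx] - x[idx + 1])
    onsets = (idx + frac) / fs
    return EventSeries("TT", np.diff(onsets), onsets[1:])


# ---------------------------------------------------------------------------
# resampling

def common_span(series: list[EventSeries]) -> tuple[float, float]:
    """Synchronization span: latest first event to earliest last event."""
    start = max(s.timestamps[0] for s in series)
    end = min(s.timestamps[-1] for s in series)
    if end <= start:
        raise ValueError("series do not overlap in time")
    return start, end


def resample_series(
    series: EventSeries,
    target_hz: float,
    span: tuple[float, float] | None = None,
) -> EventSeries:
    """Resample an event series onto a uniform 1 Hz or 0.25 Hz grid.

    1 Hz: linear interpolation of (timestamp, value) onto an integer-
    second grid covering ``span`` (default: the series' own span).
    0.25 Hz: built from the 1 Hz grid by zero-phase FIR low-pass
    (8th order, 0.1 Hz cutoff) then keeping every 4th sample, so that
    cardiac-band power cannot alias into the respiratory analysis.
    """
    if target_hz not in (1.0, 0.25):
        raise ValueError("target rate must be 1.0 or 0.25 Hz")
    if series.grid_hz == target_hz:
        return replace(series)
    if len(series) < 2:
        raise ValueError("need at least 2 events to resample")

    if target_hz == 1.0:
        t0, t1 = span if span is not None else (series.timestamps[0], series.timestamps[-1])
        grid = t0 + np.arange(int(np.floor(t1 - t0)) + 1, dtype=float)
        vals = np.interp(grid, series.timestamps, series.values)
        return EventSeries(series.kind, vals, grid, grid_hz=1.0)

    base = series if series.grid_hz == 1.0 else resample_series(series, 1.0, span)
    taps = sps.firwin(9, 0.1, fs=1.0)  # 8th-order FIR, 0.1 Hz cutoff
    v = base.values
    padlen = min(3 * len(taps), v.size - 1)
    filt = sps.filtfilt(taps, [1.0], v, padlen=padlen)
    vals = filt[::4]
    grid = base.timestamps[::4]
    return EventSeries(series.kind, vals, grid, grid_hz=0.25)


# ---------------------------------------------------------------------------
# readers / writers

def read_physio_csv(path, fs: float | None = None, subject_id: str = "") -> PhysioRecord:
    """Read a raw record from CSV with columns time_s, ecg, bp, rf."""
    df = pd.read_csv(path)
    required = {"time_s", "ecg", "bp", "rf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if fs is None:
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        if dt <= 0:
            raise ValueError(f"{path}: cannot infer sampling rate")
        fs = 1.0 / dt
    channels = {c: df[c].to_numpy(dtype=float) for c in ("ecg", "bp", "rf")}
    return PhysioRecord(channels, fs=fs, subject_id=subject_id)


def write_event_series_csv(series: list[EventSeries], path, subject_id: str = "") -> None:
    """Write event series as tidy CSV (subject_id, kind, t_s, value)."""
    frames = [
        pd.DataFrame(
            {
                "subject_id": subject_id,
                "kind": s.kind,
                "t_s": s.timestamps,
                "value": s.values,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_event_series_csv(path) -> dict[str, dict[str, EventSeries]]:
    """Read tidy event-series CSV back into {subject_id: {kind: EventSeries}}."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, EventSeries]] = {}
    for (sid, kind), grp in df.groupby(["subject_id", "kind"], sort=False):
        grp = grp.sort_values("t_s")
        out.setdefault(str(sid), {})[str(kind)] = EventSeries(
            str(kind), grp["value"].to_numpy(), grp["t_s"].to_numpy()
        )
    return out
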