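"""Coupled synthetic cardiorespiratory-vascular records with ground truth.

Emulates resting supine recordings (default 15 min) of ECG, continuous
blood pressure and respiratory flow, at the beat/breath level:

* per-beat systolic pressure is an AR(1) process around a set point with
  a respiratory modulation;
* the heart period responds to the previous beat's pressure deviation
  with a configurable baroreflex gain (pressure rise → interval
  lengthening) plus respiratory sinus arrhythmia and AR(1) noise;
* breath cycle lengths are jittered around a mean period, and respond to
  the change in mean systolic pressure between consecutive breaths with
  a group-specific gain — the "respiratory response to pressure falls"
  that separates dilated-cardiomyopathy-like subjects from controls.

Both couplings are first-order linear: the simplest mechanism that
produces the sub-space-dependent contrasts the analysis measures.  Group
effects (``tt_effect``, ``brs_effect``) are expressed in units of the
between-subject SD of the downstream index they move (SBP-∆TTm-d and
SBP-∆BBIsd-nc respectively), via calibration constants frozen in this
module, so "a 1-SD group difference" is well defined end to end.

Raw waveforms (optional) are rendered from the event-level ground truth:
template QRS/T complexes at beat times, per-beat pressure pulses hitting
the injected SBP/DBP exactly, and a phase-continuous respiratory
oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .signals import EventSeries, PhysioRecord

__all__ = [
    "SubjectParams",
    "GroupEffects",
    "SimConfig",
    "GroundTruth",
    "Cohort",
    "simulate_subject",
    "simulate_subject_series",
    "simulate_cohort",
    "TT_EFFECT_UNIT",
    "BRS_EFFECT_UNIT",
]

# Calibration constants fixed once from a reference run of the default
# (control-like) cohort through the full pipeline: the gain increment
# that shifts the target index by one between-subject SD.
#: breath-period gain increment (s per standardized SBP change) per
#: 1-SD shift (downwards) of the SBP-∆TTm-d index
TT_EFFECT_UNIT = 0.115
#: baroreflex gain increment (ms/mmHg) per 1-SD shift (downwards) of the
#: SBP-∆BBIsd-nc index
BRS_EFFECT_UNIT = 2.2


@dataclass
class SubjectParams:
    """Physiological parameters of one simulated subject (units noted)."""

    mean_bbi_ms: float = 900.0      # mean heart period
    bbi_noise_ms: float = 25.0      # AR(1) innovation SD of the heart period
    bbi_phi: float = 0.8            # AR(1) coefficient, heart period
    rsa_gain_ms: float = 25.0       # respiratory sinus arrhythmia amplitude
    brs_gain_ms_per_mmhg: float = 4.0  # baroreflex gain (SBP rise → BBI rise)
    sbp_set_mmhg: float = 120.0     # systolic set point
    sbp_noise_mmhg: float = 3.0     # AR(1) innovation SD of SBP
    sbp_phi: float = 0.8            # AR(1) coefficient, SBP
    sbp_resp_mmhg: float = 1.5      # respiratory modulation of SBP
    pulse_pressure_mmhg: float = 40.0
    dbp_noise_mmhg: float = 1.5     # i.i.d. DBP jitter
    resp_period_s: float = 3.6      # mean breath cycle
    resp_period_sd_s: float = 0.25  # breath-to-breath jitter SD
    tt_sbp_gain_s: float = 0.0      # breath-period response to SBP change

    def validate(self) -> None:
        if self.mean_bbi_ms <= 250:
            raise ValueError("non-physiological config: mean BBI must exceed 250 ms")
        if self.resp_period_s <= 0.5:
            raise ValueError("non-physiological config: breath period too short")


@dataclass
class GroupEffects:
    """Group-specific deviations, in downstream-index SD units."""

    tt_effect: float = 0.0   # respiratory response to SBP falls
    brs_effect: float = 0.0  # baroreflex ΔBBI–ΔSBP coupling


@dataclass
class SimConfig:
    """Cohort-level simulation configuration."""

    seed: int = 0
    n_per_group: dict[str, int] = field(default_factory=lambda: {"A": 20, "B": 20})
    groups: dict[str, GroupEffects] = field(default_factory=dict)
    duration_s: float = 900.0
    fs: float = 250.0
    params: SubjectParams = field(default_factory=SubjectParams)
    #: between-subject SDs of the set points that vary across people
    subject_sd: dict[str, float] = field(
        default_factory=lambda: {
            "mean_bbi_ms": 40.0,
            "sbp_set_mmhg": 8.0,
            "resp_period_s": 0.3,
        }
    )

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("rates and durations must be positive")
        labels = list(self.n_per_group)
        if len(set(labels)) != len(labels) or not labels:
            raise ValueError("group labels must be distinct and non-empty")
        for g in labels:
            self.groups.setdefault(g, GroupEffects())


@dataclass
class GroundTruth:
    """Per-subject generative truth behind the emitted signals."""

    subject_id: str
    group: str
    beat_times_s: np.ndarray
    bbi_ms: np.ndarray
    sbp_mmhg: np.ndarray
    dbp_mmhg: np.ndarray
    breath_onsets_s: np.ndarray
    tt_s: np.ndarray
    effects: GroupEffects
    params: SubjectParams


def _draw_subject_params(
    base: SubjectParams, effects: GroupEffects,
    subject_sd: dict[str, float], rng: np.random.Generator,
) -> SubjectParams:
    p = SubjectParams(**asdict(base))
    for name, sd in subject_sd.items():
        setattr(p, name, getattr(p, name) + sd * rng.normal())
    p.tt_sbp_gain_s = base.tt_sbp_gain_s + effects.tt_effect * TT_EFFECT_UNIT
    p.brs_gain_ms_per_mmhg = (
        base.brs_gain_ms_per_mmhg + effects.brs_effect * BRS_EFFECT_UNIT
    )
    p.validate()
    return p


def _simulate_events(
    p: SubjectParams, duration_s: float, rng: np.random.Generator
) -> tuple[np.ndarray, ...]:
    """Forward-simulate beats and breaths; returns event-level arrays."""
    beat_t: list[float] = [0.0]
    bbi: list[float] = []
    sbp: list[float] = []
    dbp: list[float] = []
    onsets: list[float] = [0.0]
    tts: list[float] = []

    tt_cur = max(1.0, p.resp_period_s + p.resp_period_sd_s * rng.normal())
    prev_win_mean = 0.0
    win_sum, win_n = 0.0, 0
    sbp_dev = 0.0
    bbi_ar = 0.0
    innov_bbi = p.bbi_noise_ms * np.sqrt(max(0.0, 1 - p.bbi_phi**2))
    innov_sbp = p.sbp_noise_mmhg * np.sqrt(max(0.0, 1 - p.sbp_phi**2))

    t = 0.0
    while t < duration_s:
        # close any breath cycle that ended before the current beat
        while t >= onsets[-1] + tt_cur:
            onsets.append(onsets[-1] + tt_cur)
            tts.append(tt_cur)
            win_mean = win_sum / win_n if win_n else prev_win_mean
            u = (win_mean - prev_win_mean) / max(p.sbp_noise_mmhg, 1e-9)
            prev_win_mean = win_mean
            win_sum, win_n = 0.0, 0
            tt_cur = p.resp_period_s + p.resp_period_sd_s * rng.normal() \
                + p.tt_sbp_gain_s * u
            tt_cur = float(np.clip(tt_cur, 1.0, 3 * p.resp_period_s))
        phase = (t - onsets[-1]) / tt_cur

        s = p.sbp_set_mmhg + sbp_dev + p.sbp_resp_mmhg * np.sin(2 * np.pi * phase)
        db = s - p.pulse_pressure_mmhg + p.dbp_noise_mmhg * rng.normal()
        sbp.append(s)
        dbp.append(db)
        win_sum += s - p.sbp_set_mmhg
        win_n += 1

        interval = (
            p.mean_bbi_ms
            + p.brs_gain_ms_per_mmhg * sbp_dev
            + p.rsa_gain_ms * np.sin(2 * np.pi * phase)
            + bbi_ar
        )
        interval = float(np.clip(interval, 300.0, 3000.0))
        bbi.append(interval)
        t += interval / 1000.0
        beat_t.append(t)

        bbi_ar = p.bbi_phi * bbi_ar + innov_bbi * rng.normal()
        sbp_dev = p.sbp_phi * sbp_dev + innov_sbp * rng.normal()

    return (
        np.asarray(beat_t),
        np.asarray(bbi),
        np.asarray(sbp),
        np.asarray(dbp),
        np.asarray(onsets),
        np.asarray(tts),
    )


def _truth_to_series(gt: GroundTruth) -> dict[str, EventSeries]:
    """Event series exactly as the extraction stage would stamp them."""
    return {
        "BBI": EventSeries("BBI", gt.bbi_ms, gt.beat_times_s[1:]),
        "SBP": EventSeries("SBP", gt.sbp_mmhg, gt.beat_times_s[:-1]),
        "DBP": EventSeries("DBP", gt.dbp_mmhg, gt.beat_times_s[:-1]),
        "TT": EventSeries("TT", gt.tt_s, gt.breath_onsets_s[1:]),
    }


def simulate_subject_series(
    config: SimConfig, group: str, seed: int, subject_id: str = "S00",
) -> tuple[dict[str, EventSeries], GroundTruth]:
    """Simulate one subject at the event level (no raw waveforms)."""
    rng = np.random.default_rng(seed)
    effects = config.groups.get(group, GroupEffects())
    p = _draw_subject_params(config.params, effects, config.subject_sd, rng)
    beat_t, bbi, sbp, dbp, onsets, tts = _simulate_events(p, config.duration_s, rng)
    gt = GroundTruth(subject_id, group, beat_t, bbi, sbp, dbp, onsets, tts, effects, p)
    return _truth_to_series(gt), gt


def _render_ecg(t: np.ndarray, beat_times: np.ndarray) -> np.ndarray:
    ecg = np.zeros_like(t)
    for bt in beat_times:
        ecg += 1.0 * np.exp(-0.5 * ((t - bt) / 0.010) ** 2)       # R wave
        ecg += 0.25 * np.exp(-0.5 * ((t - bt - 0.18) / 0.04) ** 2)  # T wave
    return ecg


def _render_bp(
    t: np.ndarray, beat_times: np.ndarray, sbp: np.ndarray, dbp: np.ndarray
) -> np.ndarray:
    bp = np.full_like(t, dbp[-1] if dbp.size else 80.0)
    for i in range(len(sbp)):
        t0, t1 = beat_times[i], beat_times[i + 1]
        m = (t >= t0) & (t < t1)
        if not m.any():
            continue
        u = (t[m] - t0) / (t1 - t0)
        bp[m] = dbp[i] + (sbp[i] - dbp[i]) * np.sin(np.pi * u**0.8)
    return bp


def _render_rf(t: np.ndarray, onsets: np.ndarray, tts: np.ndarray) -> np.ndarray:
    phase = np.zeros_like(t)
    for k in range(len(tts)):
        m = (t >= onsets[k]) & (t < onsets[k + 1])
        phase[m] = (t[m] - onsets[k]) / tts[k]
    tail = t >= onsets[-1]
    last_tt = tts[-1] if tts.size else 3.6
    phase[tail] = (t[tail] - onsets[-1]) / last_tt
    return np.sin(2 * np.pi * phase)


def simulate_subject(
    config: SimConfig, group: str, seed: int, subject_id: str = "S00",
) -> tuple[PhysioRecord, GroundTruth]:
    """Simulate one subject including raw ECG/BP/RF waveforms.

    Same seed → identical record; the ground truth carries the beat and
    breath times and the injected per-beat pressures.
    """
    series, gt = simulate_subject_series(config, group, seed, subject_id)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    channels = {
        "ecg": _render_ecg(t, gt.beat_times_s[:-1]),
        "bp": _render_bp(t, gt.beat_times_s, gt.sbp_mmhg, gt.dbp_mmhg),
        "rf": _render_rf(t, gt.breath_onsets_s, gt.tt_s),
    }
    return PhysioRecord(channels, fs=config.fs, subject_id=subject_id), gt


@dataclass
class Cohort:
    """A simulated cohort: event series, labels and generative truth."""

    series: dict[str, dict[str, EventSeries]]
    labels: pd.Series
    truths: dict[str, GroundTruth]


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate every subject of every group at the event level.

    Subject seeds are spawned deterministically from ``config.seed``, so
    the cohort is reproducible and subjects are independent.
    """
    if min(config.n_per_group.values()) < 2:
        raise ValueError("need at least 2 subjects per group")
    ss = np.random.SeedSequence(config.seed)
    n_total = sum(config.n_per_group.values())
    child_seeds = ss.generate_state(n_total)
    series: dict[str, dict[str, EventSeries]] = {}
    labels: dict[str, str] = {}
    truths: dict[str, GroundTruth] = {}
    i = 0
    for group, n in config.n_per_group.items():
        for k in range(n):
            sid = f"{group}-{k:02d}"
            s, gt = simulate_subject_series(config, group, int(child_seeds[i]), sid)
            series[sid] = s
            labels[sid] = group
            truths[sid] = gt
            i += 1
    return Cohort(series, pd.Series(labels, name="group"), truths)
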