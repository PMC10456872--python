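"""End-to-end orchestration: extract → Δ/partition → features → classify.

The stages are pure functions over the domain objects; this module wires
them together with a config, deterministic seeding, JSON-lines logging
and a manifest (config hash + SHA-256 checksum per artifact) so a rerun
with the same config is byte-identical for the deterministic stages.
Feature extraction never sees group labels — they are joined only at the
classification stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import signals as sig
from .delta import delta as diff_series, normalize, partition, vascular_threshold
from .features import FEATURE_NAMES, characterize_subject
from .simulate import Cohort, GroupEffects, SimConfig, SubjectParams, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "extract_record",
    "series_to_features",
    "cohort_features",
    "run_pipeline",
    "load_config",
]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    alpha: float = 0.15
    containment: float = 0.95
    rho_max: float = 0.7
    paper_mode: bool = False
    seed: int = 0
    grid: dict[str, tuple] | None = None
    kernels: tuple[str, ...] = clf.KERNELS
    max_pairs: int | None = 10
    control_label: str = "CON"
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    simulate: SimConfig | None = None
    series_csv: str | None = None
    groups_csv: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if not 0 < self.containment <= 1:
            raise ValueError("containment must lie in (0, 1]")


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML (nested simulate block supported)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    if sim is not None:
        params = SubjectParams(**sim.pop("params", {}))
        groups = {k: GroupEffects(**v) for k, v in sim.pop("groups", {}).items()}
        sim = SimConfig(params=params, groups=groups, **sim)
    comparisons = [tuple(c) for c in raw.pop("comparisons", [])]
    kernels = tuple(raw.pop("kernels", clf.KERNELS))
    return RunConfig(simulate=sim, comparisons=comparisons, kernels=kernels, **raw)


# ---------------------------------------------------------------------------
# stages

def extract_record(record: sig.PhysioRecord) -> dict[str, sig.EventSeries]:
    """Raw record → the four edited event series (BBI, SBP, DBP, TT)."""
    clean = sig.detrend_and_clean(record)
    rpeaks = sig.detect_rpeaks(clean.channels["ecg"], clean.fs)
    bbi = sig.extract_bbi(rpeaks)
    # BP extrema need physical units; detrending removes the offset, so
    # extrema are taken from the original (outlier-repaired) pressure trace
    bp_raw = record.channels["bp"]
    bp = sig._interpolate_mask(
        bp_raw,
        np.abs(bp_raw - bp_raw.mean()) >= 3 * bp_raw.std()
        if bp_raw.std() > 0 else np.zeros(bp_raw.size, bool),
    )
    sbp, dbp = sig.extract_sbp_dbp(bp, record.fs, rpeaks)
    tt = sig.extract_tt(clean.channels["rf"], clean.fs)
    return {
        "BBI": sig.clean_event_series(bbi),
        "SBP": sig.clean_event_series(sbp),
        "DBP": sig.clean_event_series(dbp),
        "TT": sig.clean_event_series(tt),
    }


def series_to_features(
    series: dict[str, sig.EventSeries],
    alpha: float = 0.15,
    containment: float = 0.95,
) -> dict[str, float]:
    """One subject's 168-index vector from its four event series.

    All four series are linearly interpolated onto a shared 1 Hz grid
    spanning their common support, decimated to 0.25 Hz, differenced and
    z-scored; both vascular drivers are partitioned at the α threshold
    and the full index inventory is computed.
    """
    span = sig.common_span([series[k] for k in ("BBI", "SBP", "DBP", "TT")])
    grids = {
        k: sig.resample_series(sig.resample_series(series[k], 1.0, span), 0.25)
        for k in ("BBI", "SBP", "DBP", "TT")
    }
    raw = {k: diff_series(g) for k, g in grids.items()}
    deltas = {k: normalize(d) for k, d in raw.items()}
    partitions = {}
    for drv in ("SBP", "DBP"):
        th = vascular_threshold(deltas[drv], alpha)
        partitions[drv] = partition(deltas[drv], th, driver=drv, alpha=alpha)
    return characterize_subject(
        deltas, partitions, containment,
        driver_deltas={"SBP": raw["SBP"], "DBP": raw["DBP"]},
    )


def cohort_features(
    cohort_series: dict[str, dict[str, sig.EventSeries]],
    alpha: float = 0.15,
    containment: float = 0.95,
) -> pd.DataFrame:
    """Feature table (subject × 168 indices) for a whole cohort.

    Group labels are deliberately not an argument: this stage never
    reads them.
    """
    rows = {}
    for sid, series in cohort_series.items():
        try:
            rows[sid] = series_to_features(series, alpha, containment)
        except ValueError as exc:
            raise ValueError(f"feature stage failed for subject {sid!r}: {exc}") from exc
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(FEATURE_NAMES))
    df.index.name = "subject_id"
    return df


# ---------------------------------------------------------------------------
# full run

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict[str, clf.ClassificationResults]:
    """Execute every stage and write features, reports and a manifest.

    Inputs come either from ``config.simulate`` or from tidy CSV files
    (``series_csv`` + ``groups_csv`` with columns subject_id, group).
    Returns the per-comparison results keyed by "A-vs-B".
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    artifacts: list[Path] = []

    def stage(name: str, t0: float) -> None:
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"stage": name, "elapsed_s": round(time.time() - t0, 3)}) + "\n")

    t0 = time.time()
    if config.simulate is not None:
        cohort: Cohort = simulate_cohort(config.simulate)
        series, labels = cohort.series, cohort.labels
        labels.rename_axis("subject_id").to_csv(out / "groups.csv")
        artifacts.append(out / "groups.csv")
    elif config.series_csv is not None:
        p = Path(config.series_csv)
        if not p.exists():
            raise FileNotFoundError(f"series input not found: {p}")
        series = sig.read_event_series_csv(p)
        gp = Path(config.groups_csv) if config.groups_csv else None
        if gp is None or not gp.exists():
            raise FileNotFoundError(f"groups input not found: {gp}")
        labels = pd.read_csv(gp).set_index("subject_id")["group"]
    else:
        raise ValueError("config must set either simulate or series_csv")
    stage("input", t0)

    t0 = time.time()
    feats = cohort_features(series, config.alpha, config.containment)
    feats.to_csv(out / "features.csv")
    artifacts.append(out / "features.csv")
    (out / "feature_schema.json").write_text(json.dumps(list(FEATURE_NAMES), ensure_ascii=False, indent=0))
    artifacts.append(out / "feature_schema.json")
    stage("features", t0)

    results: dict[str, clf.ClassificationResults] = {}
    for a, b in config.comparisons:
        t0 = time.time()
        res = clf.model_search(
            feats, labels, (a, b),
            mode="paper" if config.paper_mode else "honest",
            grid=config.grid, kernels=config.kernels, max_pairs=config.max_pairs,
            control_label=config.control_label, rho_max=config.rho_max,
        )
        key = f"{a}-vs-{b}"
        results[key] = res
        rp = out / f"report_{key}.json"
        rp.write_text(json.dumps(res.to_dict(), indent=2, ensure_ascii=False))
        artifacts.append(rp)
        sp = out / f"screening_{key}.csv"
        res.screening.to_csv(sp)
        artifacts.append(sp)
        stage(f"classify:{key}", t0)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
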