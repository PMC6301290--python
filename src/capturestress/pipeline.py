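"""End-to-end orchestration: simulate → features → classify → model → report.

A single YAML/dict config drives every stage; it is schema-validated before
any stage runs, and all outputs are deterministic given identical config and
seeds. Stage outputs (features, labels, metrics, model report) are plain
CSV with headers and are consumable independently.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as csio
from .classify import CutoffCriteria, exercise_metrics, label_event
from .features import features_to_frame, vectorial_sum, window_features
from .models import (DEFAULT_COVARIATES, fit_endpoint_models,
                     logratio_transform, render_significance_text,
                     significance_table)
from .physio import PhCorrection, correct_ph, validate_panel
from .synthetic import (BoutModelConfig, SPECIES_CONFIGS, simulate_study)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline config failed schema validation."""


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    data_dir: Path
    out_dir: Path
    dialect: str = "default"
    window_s: float = 10.0
    overlap: float = 0.5
    criteria: CutoffCriteria = field(default_factory=CutoffCriteria)
    ph_correction: PhCorrection = field(default_factory=PhCorrection)
    responses: tuple = csio.PANEL_FIELDS
    species: Optional[str] = None
    level_mode: str = "cluster"
    seed: int = 0
    n_sims: int = 1000

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)
        if self.dialect not in csio.DIALECTS:
            raise ConfigError(f"unknown dialect {self.dialect!r}")
        if not 0 <= self.overlap < 1:
            raise ConfigError("overlap must be in [0, 1)")
        if self.window_s < 10:
            raise ConfigError("window_s must be ≥ 10")
        unknown = set(self.responses) - set(csio.PANEL_FIELDS)
        if unknown:
            raise ConfigError(f"unknown response(s): {sorted(unknown)}")


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config.

    Required keys: data_dir, out_dir, cutoffs{high_amp_g, low_amp_g,
    cycle_s}. Optional: dialect, window_s, overlap, ph_correction{mode,
    slope}, responses, species, level_mode, seed, n_sims.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("data_dir", "out_dir", "cutoffs"):
        if key not in raw:
            raise ConfigError(f"config missing required key {key!r}")
    cut = raw.pop("cutoffs")
    try:
        criteria = CutoffCriteria(**cut)
    except TypeError as e:
        raise ConfigError(f"bad cutoffs block: {e}") from None
    ph = raw.pop("ph_correction", None)
    corr = PhCorrection(**ph) if ph else PhCorrection()
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "responses" in raw:
        raw["responses"] = tuple(raw["responses"])
    return PipelineConfig(criteria=criteria, ph_correction=corr, **raw)


def compute_features(cfg: PipelineConfig) -> pd.DataFrame:
    """Stage: VS conversion + windowed features for every trace CSV."""
    dialect = csio.DIALECTS[cfg.dialect]
    frames = []
    paths = sorted(p for p in cfg.data_dir.glob("*.csv")
                   if p.name not in ("deployment.csv",))
    if not paths:
        raise FileNotFoundError(f"no accelerometer CSVs in {cfg.data_dir}")
    for path in paths:
        trace = csio.read_accel_csv(path, dialect)
        vst = vectorial_sum(trace)
        wins = window_features(vst, cfg.window_s, cfg.overlap)
        frames.append(features_to_frame(trace.event_id, wins))
    return pd.concat(frames, ignore_index=True)


def classify_events(cfg: PipelineConfig,
                    records) -> tuple[pd.DataFrame, list]:
    """Stage: per-individual clustering + level assignment + metrics."""
    dialect = csio.DIALECTS[cfg.dialect]
    durations = {r.event_id: r.capture_duration_min for r in records}
    label_rows, metrics = [], []
    for path in sorted(cfg.data_dir.glob("*.csv")):
        if path.name == "deployment.csv":
            continue
        trace = csio.read_accel_csv(path, dialect)
        if trace.event_id not in durations:
            raise KeyError(f"classify: no deployment record for "
                           f"{trace.event_id!r}")
        vst = vectorial_sum(trace)
        wins = window_features(vst, cfg.window_s, cfg.overlap)
        labeled = label_event(vst, wins, cfg.criteria, seed=cfg.seed,
                              level_mode=cfg.level_mode)
        m = exercise_metrics(labeled, vst, durations[trace.event_id])
        metrics.append(m)
        label_rows.append(pd.DataFrame({
            "event_id": trace.event_id,
            "time_s": vst.time_s,
            "level": labeled.second_levels,
        }))
    return pd.concat(label_rows, ignore_index=True), metrics


def model_endpoints(cfg: PipelineConfig, records, metrics) -> pd.DataFrame:
    """Stage: assemble the modelling frame and fit every endpoint."""
    dep = csio.deployment_frame(records)
    for r in records:
        validate_panel(r.panel)
    if cfg.ph_correction.mode != "identity":
        dep["ph37"] = [
            correct_ph(p, s, cfg.ph_correction) if pd.notna(p) else np.nan
            for p, s in zip(dep["ph37"], dep["sst_c"])]
    mdf = pd.DataFrame([{
        "event_id": m.event_id,
        "logit_p_low": logratio_transform(m.p_low),
        "capture_duration_min": m.capture_duration_min,
    } for m in metrics])
    data = dep.drop(columns=["capture_duration_min"]).merge(
        mdf, on="event_id", how="inner")
    species = cfg.species
    if species is None:
        present = data["species"].unique()
        if len(present) == 1:
            species = str(present[0])
    fits = fit_endpoint_models(data, cfg.responses, species=species,
                               covariates=DEFAULT_COVARIATES,
                               n_sims=cfg.n_sims, seed=cfg.seed)
    return significance_table(fits)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the output paths. Idempotent given seeds."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    log_path = cfg.out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: "
                                           "%(message)s"))
    root = logging.getLogger("capturestress")
    root.addHandler(handler)
    try:
        from . import __version__
        root.info("capturestress %s; seed=%d; n_sims=%d",
                  __version__, cfg.seed, cfg.n_sims)
        stage = "read-deployment"
        records = csio.read_deployment_table(cfg.data_dir / "deployment.csv")
        stage = "features"
        feats = compute_features(cfg)
        feats.to_csv(cfg.out_dir / "features.csv", index=False)
        stage = "classify"
        labels, metrics = classify_events(cfg, records)
        labels.to_csv(cfg.out_dir / "labels.csv", index=False)
        csio.write_metrics_table(metrics, cfg.out_dir / "metrics.csv")
        stage = "model"
        table = model_endpoints(cfg, records, metrics)
        table.to_csv(cfg.out_dir / "model_report.csv", index=False)
        (cfg.out_dir / "model_report.txt").write_text(
            render_significance_text(table))
    except Exception as e:
        root.error("stage %s failed: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    finally:
        root.removeHandler(handler)
        handler.close()
    return {name: cfg.out_dir / f"{name}" for name in
            ("features.csv", "labels.csv", "metrics.csv",
             "model_report.csv", "model_report.txt", "run.log")}


def simulate_inputs(cfg: PipelineConfig, n_sharks: int,
                    species: str = "nurse",
                    bout_cfg: Optional[BoutModelConfig] = None) -> None:
    """Stage: generate a synthetic study into the configured data_dir."""
    physio_cfg = SPECIES_CONFIGS[species]()
    simulate_study(n_sharks, bout_cfg or BoutModelConfig(), physio_cfg,
                   cfg.seed, cfg.data_dir)
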