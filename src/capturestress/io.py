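"""Readers and writers for logger traces, deployment tables and derived tables.

All tabular interchange is CSV. Accelerometer traces follow a configurable
dialect; the shipped default mimics a HOBO Pendant G export re-expressed as
seconds from event start. Missing blood-panel cells are preserved as missing
(``None`` on records, empty cells on disk) — readers never impute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: hard range of the logger, g; values beyond are clipped on read
CLIP_G = 3.0

#: regulatory limit on capture duration, minutes (sets were cut at 4.5 h)
MAX_CAPTURE_DURATION_MIN = 270.0

VALID_SPECIES = ("nurse", "caribbean_reef", "other")

PANEL_FIELDS = (
    "ph37",
    "lactate_mmol_l",
    "glucose_mmol_l",
    "haematocrit_pct",
    "sodium_mmol_l",
    "potassium_mmol_l",
    "chloride_mmol_l",
    "calcium_mmol_l",
)


class SchemaError(ValueError):
    """A required column is absent or a file does not match its dialect."""


@dataclass(frozen=True)
class CsvDialect:
    """Column layout of an accelerometer CSV.

    Parameters
    ----------
    skip_rows : header/preamble lines to drop before the column header.
    time_col, x_col, y_col, z_col : column names after the preamble.
    """

    skip_rows: int = 0
    time_col: str = "time_s"
    x_col: str = "x_g"
    y_col: str = "y_g"
    z_col: str = "z_g"


#: plain dialect used by this package's own writers
DEFAULT_DIALECT = CsvDialect()

#: HOBOware-style export: two preamble lines, verbose column names
HOBO_DIALECT = CsvDialect(
    skip_rows=1,
    time_col="Time, s",
    x_col="X Accel, g",
    y_col="Y Accel, g",
    z_col="Z Accel, g",
)

DIALECTS = {"default": DEFAULT_DIALECT, "hobo": HOBO_DIALECT}


@dataclass
class AccelTrace:
    """One capture event's tri-axial acceleration, in g, at ~1 Hz."""

    event_id: str
    time_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.time_s)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("x, y, z and time_s must have equal length")
        if n and np.any(self.time_s < 0):
            raise ValueError("timestamps must be non-negative")
        if n > 1:
            bad = np.nonzero(np.diff(self.time_s) <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"timestamps must be strictly increasing; first violation "
                    f"at row {bad[0] + 1} (t={self.time_s[bad[0] + 1]!r})"
                )

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class PhysioPanel:
    """Blood endpoints for one shark; every field optional (assay failures)."""

    ph37: Optional[float] = None
    lactate_mmol_l: Optional[float] = None
    glucose_mmol_l: Optional[float] = None
    haematocrit_pct: Optional[float] = None
    sodium_mmol_l: Optional[float] = None
    potassium_mmol_l: Optional[float] = None
    chloride_mmol_l: Optional[float] = None
    calcium_mmol_l: Optional[float] = None


@dataclass
class DeploymentRecord:
    """One shark: identity, covariates, capture duration and blood panel."""

    event_id: str
    species: str
    tl_cm: float
    sst_c: float
    capture_duration_min: float
    panel: PhysioPanel = field(default_factory=PhysioPanel)


@dataclass(frozen=True)
class ValidationRanges:
    """Plausibility limits applied when reading a deployment table."""

    sst_c: tuple = (15.0, 35.0)
    max_capture_duration_min: float = MAX_CAPTURE_DURATION_MIN


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")


def read_accel_csv(path, dialect: CsvDialect = DEFAULT_DIALECT,
                   event_id: Optional[str] = None) -> AccelTrace:
    """Read one trace; out-of-range samples are clipped to ±3 g with a warning.

    Raises :class:`SchemaError` on missing columns and ``ValueError`` on
    non-monotone timestamps (via :class:`AccelTrace` validation).
    """
    path = Path(path)
    df = pd.read_csv(path, skiprows=dialect.skip_rows)
    _require_columns(df, [dialect.time_col, dialect.x_col, dialect.y_col,
                          dialect.z_col], path)
    xyz = df[[dialect.x_col, dialect.y_col, dialect.z_col]].to_numpy(float)
    n_clipped = int(np.count_nonzero(np.abs(xyz) > CLIP_G))
    if n_clipped:
        logger.warning("%s: clipped %d sample value(s) to ±%.1f g",
                       path.name, n_clipped, CLIP_G)
        xyz = np.clip(xyz, -CLIP_G, CLIP_G)
    return AccelTrace(
        event_id=event_id or path.stem,
        time_s=df[dialect.time_col].to_numpy(float),
        x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2],
    )


def write_accel_csv(trace: AccelTrace, path,
                    dialect: CsvDialect = DEFAULT_DIALECT) -> None:
    path = Path(path)
    df = pd.DataFrame({
        dialect.time_col: trace.time_s,
        dialect.x_col: trace.x,
        dialect.y_col: trace.y,
        dialect.z_col: trace.z,
    })
    with open(path, "w") as fh:
        for _ in range(dialect.skip_rows):
            fh.write(f"# {trace.event_id}\n")
        df.to_csv(fh, index=False)


_DEPLOY_COLS = ["event_id", "species", "tl_cm", "sst_c",
                "capture_duration_min", *PANEL_FIELDS]


def read_deployment_table(path,
                          ranges: ValidationRanges = ValidationRanges(),
                          ) -> list[DeploymentRecord]:
    """Read the per-shark deployment/physiology table.

    Empty blood-panel cells become ``None`` on the record, never zero.
    Out-of-range covariates raise ``ValueError`` naming the record.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["event_id", "species", "tl_cm", "sst_c",
                          "capture_duration_min"], path)
    records = []
    for _, row in df.iterrows():
        eid = str(row["event_id"])
        species = str(row["species"])
        if species not in VALID_SPECIES:
            raise ValueError(f"{eid}: unknown species {species!r}; "
                             f"expected one of {VALID_SPECIES}")
        dur = float(row["capture_duration_min"])
        if not (0 < dur <= ranges.max_capture_duration_min):
            raise ValueError(
                f"{eid}: capture_duration_min={dur} outside "
                f"(0, {ranges.max_capture_duration_min}]")
        sst = float(row["sst_c"])
        lo, hi = ranges.sst_c
        if not (lo <= sst <= hi):
            raise ValueError(f"{eid}: sst_c={sst} outside [{lo}, {hi}]")
        tl = float(row["tl_cm"])
        if tl <= 0:
            raise ValueError(f"{eid}: tl_cm must be positive, got {tl}")
        panel_kwargs = {}
        for name in PANEL_FIELDS:
            if name in df.columns and pd.notna(row[name]):
                panel_kwargs[name] = float(row[name])
        records.append(DeploymentRecord(
            event_id=eid, species=species, tl_cm=tl, sst_c=sst,
            capture_duration_min=dur, panel=PhysioPanel(**panel_kwargs)))
    return records


def write_deployment_table(records: Sequence[DeploymentRecord], path) -> None:
    rows = []
    for r in records:
        row = {"event_id": r.event_id, "species": r.species, "tl_cm": r.tl_cm,
               "sst_c": r.sst_c, "capture_duration_min": r.capture_duration_min}
        for f in fields(r.panel):
            row[f.name] = getattr(r.panel, f.name)
        rows.append(row)
    pd.DataFrame(rows, columns=_DEPLOY_COLS).to_csv(path, index=False)


METRICS_COLUMNS = ["event_id", "p_low", "p_med", "p_high",
                   "capture_duration_min", "mean_fight_intensity_g_min"]


def write_metrics_table(metrics: Sequence, path) -> None:
    """Write per-event exercise metrics (fixed, documented column set)."""
    rows = [{
        "event_id": m.event_id,
        "p_low": m.p_low,
        "p_med": m.p_med,
        "p_high": m.p_high,
        "capture_duration_min": m.capture_duration_min,
        "mean_fight_intensity_g_min": m.mean_fight_intensity_g_min,
    } for m in metrics]
    pd.DataFrame(rows, columns=METRICS_COLUMNS).to_csv(path, index=False)


def read_metrics_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, METRICS_COLUMNS, path)
    return df


def deployment_frame(records: Sequence[DeploymentRecord]) -> pd.DataFrame:
    """Records as a DataFrame (panel fields as NaN-preserving columns)."""
    rows = []
    for r in records:
        row = {"event_id": r.event_id, "species": r.species, "tl_cm": r.tl_cm,
               "sst_c": r.sst_c, "capture_duration_min": r.capture_duration_min}
        for f in fields(r.panel):
            v = getattr(r.panel, f.name)
            row[f.name] = np.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows, columns=_DEPLOY_COLS)
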