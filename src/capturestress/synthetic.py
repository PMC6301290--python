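"""Synthetic capture events and blood panels with known ground truth.

Two linked generators drive every end-to-end test in the package:

* a bout-structured accelerometer model — a per-second three-state Markov
  chain over {low, med, high} exercise intensity; within a bout the
  vectorial-sum signal is baseline + A/2 + (A/2)·sin(2πt/T + φ) with the
  peak-to-trough range A and period T drawn from level-specific
  distributions, decomposed onto a fixed random logger orientation,
  quantized to the logger resolution (0.025 g) and clipped to ±3 g;
* a linear physiology model — each blood endpoint is a linear function of
  logit(p_low), capture duration, SST and total length plus Gaussian noise,
  with default coefficients calibrated so species-level endpoint means and
  sds match published descriptive statistics for nurse and Caribbean reef
  sharks.

Struggling is front-loaded by default: a time-decaying multiplier inflates
the weight of the high-intensity state at the event start and at bout
transitions, so short capture events are struggle-dominated and mean fight
intensity declines with capture duration. The chain is simulated at the
embedded-jump level (geometric sojourns + jump draws), which is exactly
equivalent in distribution to per-second stepping when front-loading is off.

All randomness flows from one master seed through ``numpy`` SeedSequence
spawning; per-event streams are documented child indices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ExerciseMetrics, LEVELS
from .io import (AccelTrace, DeploymentRecord, PhysioPanel, PANEL_FIELDS,
                 write_accel_csv, write_deployment_table)
from .models import logratio_transform

# ---------------------------------------------------------------------------
# bout model


def bout_transition_matrix(sojourn_s: Sequence[float] = (600.0, 300.0, 120.0),
                           jump: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-second matrix from mean bout durations and jump preferences.

    Defaults encode minutes-long resting bouts (10 min), shorter aggravated
    swimming (5 min) and brief struggles (2 min); on leaving a state the
    next level is drawn from ``jump`` (row-normalised, zero diagonal). The
    implied stationary occupancy of the default is ≈ (0.62, 0.31, 0.07)
    low/med/high.
    """
    sojourn = np.asarray(sojourn_s, dtype=float)
    if sojourn.shape != (3,) or np.any(sojourn < 1):
        raise ValueError("sojourn_s must be 3 means ≥ 1 s")
    J = (np.array([[0.0, 0.7, 0.3], [0.7, 0.0, 0.3], [0.5, 0.5, 0.0]])
         if jump is None else np.asarray(jump, dtype=float))
    if J.shape != (3, 3) or np.any(np.diag(J) != 0) or np.any(J < 0):
        raise ValueError("jump must be 3×3, non-negative, zero diagonal")
    J = J / J.sum(axis=1, keepdims=True)
    exit_p = 1.0 / sojourn
    P = J * exit_p[:, None]
    np.fill_diagonal(P, 1.0 - exit_p)
    return P


def reversible_transition_matrix(stationary: Sequence[float],
                                 switch_rate: float = 0.004) -> np.ndarray:
    """Row-stochastic per-second matrix with the given stationary law.

    P[i, j] = ε·π[j] for i ≠ j and P[i, i] = 1 − ε·(1 − π[i]); detailed
    balance holds, so ``stationary`` is exact. Mean sojourn in state i is
    1 / (ε·(1 − π[i])) seconds.
    """
    pi = np.asarray(stationary, dtype=float)
    if pi.shape != (3,) or not math.isclose(pi.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("stationary must be 3 probabilities summing to 1")
    P = switch_rate * np.tile(pi, (3, 1))
    np.fill_diagonal(P, 1.0 - switch_rate * (1.0 - pi))
    return P


@dataclass
class BoutModelConfig:
    """Parameters of the synthetic capture-event accelerometer model.

    ``amplitude_dist``/``cycle_dist`` give (mean, sd) of the per-bout
    peak-to-trough range (g) and oscillation period (s) per level. Defaults
    straddle the classification cutoffs (0.05 g, 0.25 g, 5 s) with ≥ 3-sd
    separation between adjacent level amplitudes after logger quantization.
    Bout structure defaults to mean sojourns of 10/5/2 minutes in
    low/med/high (see :func:`bout_transition_matrix`), giving stationary
    occupancy ≈ (0.62, 0.31, 0.07).
    """

    transition_matrix: np.ndarray = field(
        default_factory=bout_transition_matrix)
    amplitude_dist: dict = field(default_factory=lambda: {
        "low": (0.01, 0.003), "med": (0.15, 0.03), "high": (0.50, 0.07)})
    cycle_dist: dict = field(default_factory=lambda: {
        "low": (8.0, 2.0), "med": (3.5, 0.8), "high": (3.0, 0.5)})
    # draws are clipped so each level's oscillation stays inside its
    # defining regime after 1-Hz discretization: the high state is defined
    # by sub-5-s cycling (spacing ≤ 4 samples), and periods below ~2.5 s
    # alias at 1 Hz (near 2 s the sampled oscillation can vanish entirely)
    cycle_clip: dict = field(default_factory=lambda: {
        "low": (2.5, None), "med": (2.5, None), "high": (2.5, 4.0)})
    baseline_g: float = 1.0
    sample_rate_hz: float = 1.0
    quantization_g: float = 0.025
    clip_g: float = 3.0
    duration_min_range: tuple = (2.57, 264.88)
    front_loaded: bool = True
    front_boost: float = 30.0
    front_tau_s: float = 300.0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (3, 3) or np.any(P < 0):
            raise ValueError("transition_matrix must be 3×3, non-negative")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition_matrix rows must sum to 1 ± 1e-12")
        self.transition_matrix = P
        amps = [self.amplitude_dist[l][0] for l in LEVELS]
        if not amps[0] < amps[1] < amps[2]:
            raise ValueError("amplitude means must be ordered low < med < high")
        for d in (self.amplitude_dist, self.cycle_dist):
            for l in LEVELS:
                m, s = d[l]
                if m <= 0 or s < 0:
                    raise ValueError(f"invalid distribution for {l!r}: "
                                     f"mean {m}, sd {s}")
        if self.quantization_g <= 0:
            raise ValueError("quantization_g must be positive")
        lo, hi = self.duration_min_range
        if not 0 < lo <= hi:
            raise ValueError("invalid duration range")


@dataclass
class TruthRecord:
    """Ground truth for one synthetic capture event."""

    event_id: str
    levels: np.ndarray            # true level name per second
    p_low: float
    p_med: float
    p_high: float
    duration_min: float

    def __post_init__(self) -> None:
        if len(self.levels) == 0:
            raise ValueError("empty level sequence")


def _stationary(P: np.ndarray) -> np.ndarray:
    """Stationary law via the null space of (Pᵀ − I)."""
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _front_modifier(cfg: BoutModelConfig, t: float) -> float:
    if not cfg.front_loaded:
        return 1.0
    return 1.0 + cfg.front_boost * math.exp(-t / cfg.front_tau_s)


def _simulate_level_segments(cfg: BoutModelConfig, n_seconds: int,
                             rng: np.random.Generator) -> list[tuple]:
    """[(state, start_s, length_s), ...] covering [0, n_seconds).

    Embedded-jump simulation: sojourns are geometric with the per-second
    stay probability; the next state is drawn from the off-diagonal row,
    with the high-state weight multiplied by the front-load modifier
    evaluated at the jump time.
    """
    P = cfg.transition_matrix
    pi = _stationary(P)
    w0 = pi.copy()
    w0[2] *= _front_modifier(cfg, 0.0)
    state = int(rng.choice(3, p=w0 / w0.sum()))
    segments, t = [], 0
    while t < n_seconds:
        stay = P[state, state]
        if stay >= 1.0:
            length = n_seconds - t
        else:
            length = int(min(rng.geometric(1.0 - stay), n_seconds - t))
        segments.append((state, t, length))
        t += length
        if t >= n_seconds:
            break
        w = P[state].copy()
        w[state] = 0.0
        w[2] *= _front_modifier(cfg, float(t))
        state = int(rng.choice(3, p=w / w.sum()))
    return segments


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.standard_normal(3)
        norm = np.linalg.norm(v)
        if norm > 1e-6:
            return v / norm


def simulate_capture_event(cfg: BoutModelConfig, seed,
                           duration_min: Optional[float] = None,
                           event_id: str = "event",
                           ) -> tuple[AccelTrace, TruthRecord]:
    """One synthetic capture event: quantized tri-axial trace + truth.

    ``seed`` may be an int or a ``numpy`` Generator. The hidden per-second
    level follows the configured Markov chain; the vectorial-sum target is
    decomposed onto a fixed random logger orientation, quantized and
    clipped, so the recorded VS matches the target to within quantization
    error.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if duration_min is None:
        lo, hi = cfg.duration_min_range
        duration_min = float(rng.uniform(lo, hi))
    n = max(1, int(round(duration_min * 60.0 * cfg.sample_rate_hz)))
    segments = _simulate_level_segments(cfg, n, rng)

    dt = 1.0 / cfg.sample_rate_hz
    time_s = np.arange(n) * dt
    vs = np.empty(n)
    levels = np.empty(n, dtype=object)
    for state, start, length in segments:
        name = LEVELS[state]
        am, asd = cfg.amplitude_dist[name]
        cm, csd = cfg.cycle_dist[name]
        A = max(float(rng.normal(am, asd)), 0.0)
        lo, hi = cfg.cycle_clip.get(name, (0.5, None))
        T = float(np.clip(rng.normal(cm, csd), lo, hi if hi else np.inf))
        phi = float(rng.uniform(0.0, 2.0 * math.pi))
        t = time_s[start:start + length]
        vs[start:start + length] = (cfg.baseline_g + A / 2.0
                                    + (A / 2.0) * np.sin(2 * math.pi * t / T
                                                         + phi))
        levels[start:start + length] = name

    u = _random_unit_vector(rng)
    xyz = vs[:, None] * u[None, :]
    xyz = np.round(xyz / cfg.quantization_g) * cfg.quantization_g
    xyz = np.clip(xyz, -cfg.clip_g, cfg.clip_g)

    trace = AccelTrace(event_id=event_id, time_s=time_s,
                       x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2])
    p_low = float(np.count_nonzero(levels == "low")) / n
    p_med = float(np.count_nonzero(levels == "med")) / n
    truth = TruthRecord(event_id=event_id, levels=levels.astype(str),
                        p_low=p_low, p_med=p_med,
                        p_high=1.0 - p_low - p_med,
                        duration_min=duration_min)
    return trace, truth


# ---------------------------------------------------------------------------
# physiology model


@dataclass(frozen=True)
class EndpointModel:
    """Linear response model for one blood endpoint.

    ``target_mean`` is the endpoint mean the generator aims for at the
    covariate means; the intercept is derived from it. Slopes are per unit
    of logit(p_low), minute, °C and cm respectively.
    """

    target_mean: float
    beta_plow: float = 0.0
    beta_duration: float = 0.0
    beta_sst: float = 0.0
    beta_tl: float = 0.0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be ≥ 0")


@dataclass(frozen=True)
class CovariateModel:
    """Draw distributions for the per-shark covariates."""

    sst_mean_c: float = 27.5
    sst_sd_c: float = 2.1
    sst_range_c: tuple = (15.0, 35.0)
    tl_mean_cm: float = 206.7
    tl_sd_cm: float = 27.1
    duration_min_range: tuple = (2.57, 264.88)
    logit_plow_mean: float = 0.115
    logit_plow_sd: float = 0.57


@dataclass
class PhysioResponseConfig:
    """Species-level physiology generator: endpoint models + covariates."""

    species: str = "nurse"
    endpoints: dict = field(default_factory=dict)
    covariates: CovariateModel = field(default_factory=CovariateModel)

    def intercept(self, name: str) -> float:
        """Intercept implied by the target mean at the covariate means."""
        m = self.endpoints[name]
        c = self.covariates
        e_dur = 0.5 * (c.duration_min_range[0] + c.duration_min_range[1])
        return (m.target_mean
                - m.beta_plow * c.logit_plow_mean
                - m.beta_duration * e_dur
                - m.beta_sst * c.sst_mean_c
                - m.beta_tl * c.tl_mean_cm)

    def coefficients(self, name: str) -> dict:
        m = self.endpoints[name]
        return {"intercept": self.intercept(name),
                "logit_p_low": m.beta_plow,
                "capture_duration_min": m.beta_duration,
                "sst_c": m.beta_sst, "tl_cm": m.beta_tl}


def nurse_config() -> PhysioResponseConfig:
    """Nurse-shark calibration: pH rises with logit(p_low) and duration;
    glucose and potassium rise with SST; potassium falls with length."""
    return PhysioResponseConfig(
        species="nurse",
        endpoints={
            "calcium_mmol_l": EndpointModel(4.91, residual_sd=0.98),
            "chloride_mmol_l": EndpointModel(247.41, residual_sd=16.43),
            "sodium_mmol_l": EndpointModel(255.94, residual_sd=35.13),
            "potassium_mmol_l": EndpointModel(5.88, beta_sst=0.53,
                                              beta_tl=-0.015,
                                              residual_sd=0.75),
            "glucose_mmol_l": EndpointModel(19.97, beta_sst=1.265,
                                            residual_sd=4.69),
            "ph37": EndpointModel(7.41, beta_plow=0.065,
                                  beta_duration=8e-4, residual_sd=0.05),
            "lactate_mmol_l": EndpointModel(1.13, residual_sd=0.82),
            "haematocrit_pct": EndpointModel(17.42, residual_sd=4.41),
        },
        covariates=CovariateModel(sst_mean_c=27.51, sst_sd_c=2.14,
                                  tl_mean_cm=206.68, tl_sd_cm=27.06,
                                  logit_plow_mean=0.115, logit_plow_sd=0.57),
    )


def reef_config() -> PhysioResponseConfig:
    """Caribbean-reef calibration: lactate rises and chloride falls with
    capture duration; no exercise effect on pH."""
    return PhysioResponseConfig(
        species="caribbean_reef",
        endpoints={
            "calcium_mmol_l": EndpointModel(5.51, residual_sd=1.07),
            "chloride_mmol_l": EndpointModel(235.29, beta_duration=-0.125,
                                             residual_sd=9.18),
            "sodium_mmol_l": EndpointModel(269.67, residual_sd=39.29),
            "potassium_mmol_l": EndpointModel(6.34, residual_sd=1.44),
            "glucose_mmol_l": EndpointModel(10.39, residual_sd=3.43),
            "ph37": EndpointModel(7.30, residual_sd=0.18),
            "lactate_mmol_l": EndpointModel(8.62, beta_duration=0.075,
                                            residual_sd=4.98),
            "haematocrit_pct": EndpointModel(20.32, residual_sd=5.74),
        },
        covariates=CovariateModel(sst_mean_c=26.58, sst_sd_c=2.01,
                                  tl_mean_cm=148.97, tl_sd_cm=31.34,
                                  duration_min_range=(2.57, 179.58),
                                  logit_plow_mean=0.020, logit_plow_sd=0.50),
    )


SPECIES_CONFIGS = {"nurse": nurse_config, "caribbean_reef": reef_config}

_NONNEG_FIELDS = {"lactate_mmol_l", "glucose_mmol_l", "calcium_mmol_l",
                  "potassium_mmol_l", "sodium_mmol_l", "chloride_mmol_l"}


def _endpoint_value(cfg: PhysioResponseConfig, name: str, logit_plow: float,
                    duration_min: float, sst_c: float, tl_cm: float,
                    rng: np.random.Generator) -> float:
    m = cfg.endpoints[name]
    mu = (cfg.intercept(name) + m.beta_plow * logit_plow
          + m.beta_duration * duration_min + m.beta_sst * sst_c
          + m.beta_tl * tl_cm)
    v = mu + (rng.normal(0.0, m.residual_sd) if m.residual_sd > 0 else 0.0)
    if name in _NONNEG_FIELDS:
        v = max(v, 0.0)
    elif name == "haematocrit_pct":
        v = min(max(v, 0.0), 100.0)
    return float(v)


def simulate_physiology(metrics: ExerciseMetrics, covariates: tuple,
                        cfg: PhysioResponseConfig, seed) -> PhysioPanel:
    """Blood panel for one shark from its exercise metrics and covariates.

    ``covariates`` is (SST °C, TL cm); a missing (None/NaN) covariate raises
    a ``ValueError`` naming the field. With residual sd 0 every endpoint
    equals its linear predictor exactly.
    """
    sst_c, tl_cm = covariates
    for name, v in (("sst_c", sst_c), ("tl_cm", tl_cm)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing covariate: {name}")
    if not (0 <= metrics.p_low <= 1):
        raise ValueError("p_low must be a proportion")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lp = logratio_transform(metrics.p_low)
    values = {name: _endpoint_value(cfg, name, lp,
                                    metrics.capture_duration_min,
                                    float(sst_c), float(tl_cm), rng)
              for name in cfg.endpoints}
    return PhysioPanel(**{k: values[k] for k in PANEL_FIELDS if k in values})


def draw_covariates(n: int, cov: CovariateModel,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Per-shark covariate draws (used directly for model-calibration tests)."""
    sst = np.clip(rng.normal(cov.sst_mean_c, cov.sst_sd_c, n),
                  *cov.sst_range_c)
    tl = np.maximum(rng.normal(cov.tl_mean_cm, cov.tl_sd_cm, n), 30.0)
    dur = rng.uniform(*cov.duration_min_range, n)
    lp = rng.normal(cov.logit_plow_mean, cov.logit_plow_sd, n)
    return pd.DataFrame({"logit_p_low": lp, "capture_duration_min": dur,
                         "sst_c": sst, "tl_cm": tl})


def simulate_endpoint_table(covs: pd.DataFrame, cfg: PhysioResponseConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Endpoint draws for a covariate table (one row per shark)."""
    out = covs.copy()
    for name in cfg.endpoints:
        out[name] = [
            _endpoint_value(cfg, name, r.logit_p_low, r.capture_duration_min,
                            r.sst_c, r.tl_cm, rng)
            for r in covs.itertuples()]
    return out


# ---------------------------------------------------------------------------
# whole-study simulation


@dataclass
class StudyPaths:
    accel_paths: list
    deployment_path: Path
    truth_path: Path


def simulate_study(n_sharks: int, bout_cfg: BoutModelConfig,
                   physio_cfg: PhysioResponseConfig, seed: int,
                   out_dir) -> tuple[StudyPaths, list[TruthRecord]]:
    """Simulate a field study and write it in the formats the readers consume.

    Writes one accelerometer CSV per shark, a deployment/physiology table,
    and a JSON truth sidecar (run-length-encoded level sequences plus the
    generating coefficients). Blood panels are generated from the *true*
    p_low of each event, so downstream recovery is testable end to end.
    """
    if n_sharks < 1:
        raise ValueError("n_sharks must be ≥ 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    # child 0..n-1: per-event traces; child n: covariates; child n+1: panels
    children = ss.spawn(n_sharks + 2)
    cov_rng = np.random.default_rng(children[n_sharks])
    panel_rng = np.random.default_rng(children[n_sharks + 1])
    covs = draw_covariates(n_sharks, physio_cfg.covariates, cov_rng)

    records, truths, accel_paths = [], [], []
    for i in range(n_sharks):
        eid = f"event_{i + 1:03d}"
        rng = np.random.default_rng(children[i])
        trace, truth = simulate_capture_event(bout_cfg, rng, event_id=eid)
        path = out_dir / f"{eid}.csv"
        write_accel_csv(trace, path)
        accel_paths.append(path)
        truths.append(truth)
        metrics = ExerciseMetrics(
            event_id=eid, p_low=truth.p_low, p_med=truth.p_med,
            p_high=truth.p_high, capture_duration_min=truth.duration_min,
            mean_fight_intensity_g_min=0.0)
        panel = simulate_physiology(
            metrics, (covs.sst_c[i], covs.tl_cm[i]), physio_cfg, panel_rng)
        records.append(DeploymentRecord(
            event_id=eid, species=physio_cfg.species,
            tl_cm=float(covs.tl_cm[i]), sst_c=float(covs.sst_c[i]),
            capture_duration_min=truth.duration_min, panel=panel))

    deployment_path = out_dir / "deployment.csv"
    write_deployment_table(records, deployment_path)
    truth_path = out_dir / "truth.json"
    _write_truth_json(truths, physio_cfg, truth_path)
    return StudyPaths(accel_paths, deployment_path, truth_path), truths


def _rle(levels: np.ndarray) -> list:
    runs, prev, count = [], None, 0
    for v in levels:
        if v == prev:
            count += 1
        else:
            if prev is not None:
                runs.append([prev, count])
            prev, count = v, 1
    runs.append([prev, count])
    return runs


def _write_truth_json(truths: Sequence[TruthRecord],
                      cfg: PhysioResponseConfig, path: Path) -> None:
    payload = {
        "coefficients": {name: cfg.coefficients(name)
                         for name in cfg.endpoints},
        "residual_sd": {name: cfg.endpoints[name].residual_sd
                        for name in cfg.endpoints},
        "events": [{
            "event_id": t.event_id,
            "duration_min": t.duration_min,
            "p_low": t.p_low, "p_med": t.p_med, "p_high": t.p_high,
            "levels_rle": _rle(t.levels),
        } for t in truths],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth_json(path) -> list[TruthRecord]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for ev in payload["events"]:
        levels = np.concatenate([np.repeat(name, count)
                                 for name, count in ev["levels_rle"]])
        out.append(TruthRecord(event_id=ev["event_id"], levels=levels,
                               p_low=ev["p_low"], p_med=ev["p_med"],
                               p_high=ev["p_high"],
                               duration_min=ev["duration_min"]))
    return out
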