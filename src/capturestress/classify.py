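"""Per-individual exercise-intensity classification and exercise metrics.

Each capture event is segmented independently: window features (amplitude,
cycle) are z-scored within the individual, clustered with k-means (k = 3,
collapsing for degenerate events — not every animal exhibits all three
levels), and each cluster is mapped to an intensity level by cutoff rules on
its median features:

* high   — amplitude > 0.25 g and cycle < 5 s
* medium — 0.05 g < amplitude < 0.25 g (any cycle), or amplitude > 0.25 g
           with cycle > 5 s
* low    — amplitude < 0.05 g

Boundary equalities (amplitude exactly 0.05 or 0.25 g, cycle exactly 5 s)
fall to medium, the conservative middle. Cutoffs are applied to cluster
medians by default (cluster-then-assign); a window-level mode applies them
to each window directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .features import FeatureWindow, VSTrace, feature_matrix

logger = logging.getLogger(__name__)

LEVELS = ("low", "med", "high")
LOW, MED, HIGH = 0, 1, 2


@dataclass(frozen=True)
class CutoffCriteria:
    """Amplitude/cycle cutoffs separating the three intensity levels."""

    high_amp_g: float = 0.25
    low_amp_g: float = 0.05
    cycle_s: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.low_amp_g < self.high_amp_g:
            raise ValueError("require 0 < low_amp_g < high_amp_g")
        if self.cycle_s <= 0:
            raise ValueError("cycle_s must be positive")


def classify_amplitude_cycle(amplitude_g: float, cycle_s: float,
                             criteria: CutoffCriteria = CutoffCriteria(),
                             ) -> str:
    """Apply the cutoff rules to one (amplitude, cycle) pair."""
    if amplitude_g > criteria.high_amp_g and cycle_s < criteria.cycle_s:
        return "high"
    if amplitude_g < criteria.low_amp_g:
        return "low"
    return "med"


@dataclass
class LabeledEvent:
    """Classification output for one capture event."""

    event_id: str
    windows: list
    window_levels: np.ndarray       # str level per window
    second_levels: np.ndarray       # str level per second of the trace
    cluster_ids: np.ndarray         # int cluster per window
    cluster_levels: dict            # cluster id -> level
    k_used: int


@dataclass
class ExerciseMetrics:
    """Per-event activity budget and fight intensity.

    Proportions sum to 1 exactly (p_high is computed as the complement).
    ``mean_fight_intensity_g_min`` is the sum of VS samples over the event
    divided by capture duration in minutes.
    """

    event_id: str
    p_low: float
    p_med: float
    p_high: float
    capture_duration_min: float
    mean_fight_intensity_g_min: float


class IntensityClassifier(ClusterMixin, BaseEstimator):
    """k-means segmentation of one individual's windows into intensity levels.

    Fit per capture event on X of shape (n_windows, 2) with columns
    (amplitude_g, cycle_s). Features are z-scored per individual on
    (amplitude, log cycle) before clustering; k collapses to the number of
    distinct feature points when fewer than ``n_clusters``.

    Parameters
    ----------
    n_clusters : target number of clusters (3 intensity levels).
    criteria : cutoff rules mapping cluster medians to levels.
    cluster_features : "log_amplitude" (default) clusters on z-scored
        log(amplitude + low_amp_g) alone — the cutoffs are multiplicatively
        spaced, the log keeps the wide high-intensity range from absorbing
        two clusters, and the offset (the smallest decision threshold,
        0.05 g) compresses sub-threshold amplitude differences such as
        logger quantization noise in resting bouts. The cycle axis still
        decides high vs medium via the cutoffs; its no-cycle sentinel
        (common in resting bouts) would otherwise dominate a 2-D feature
        space and absorb a cluster of its own. "amplitude" and
        "amplitude_cycle" (z-scored amplitude, log cycle) are available
        alternatives.
    level_mode : "cluster" applies cutoffs to cluster medians (default);
        "window" applies them to each window independently.
    n_init, random_state : passed to k-means; fixed seed gives a
        deterministic assignment.

    Attributes
    ----------
    cluster_ids_ : cluster index per window.
    cluster_levels_ : mapping cluster index -> level name.
    labels_ : level name per window.
    n_clusters_ : k actually used.
    """

    def __init__(self, n_clusters: int = 3,
                 criteria: Optional[CutoffCriteria] = None,
                 cluster_features: str = "log_amplitude",
                 level_mode: str = "cluster",
                 n_init: int = 10,
                 random_state: Optional[int] = None):
        self.n_clusters = n_clusters
        self.criteria = criteria
        self.cluster_features = cluster_features
        self.level_mode = level_mode
        self.random_state = random_state
        self.n_init = n_init

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_windows, 2): amplitude_g, cycle_s")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        if np.any(X[:, 1] <= 0):
            raise ValueError("cycle_s must be positive")
        criteria = self.criteria or CutoffCriteria()
        n = X.shape[0]

        if self.cluster_features == "log_amplitude":
            Z = np.log(X[:, :1] + criteria.low_amp_g)
        elif self.cluster_features == "amplitude":
            Z = X[:, :1].copy()
        elif self.cluster_features == "amplitude_cycle":
            Z = np.column_stack([X[:, 0], np.log(X[:, 1])])
        else:
            raise ValueError(
                f"unknown cluster_features {self.cluster_features!r}")
        mu, sd = Z.mean(axis=0), Z.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Z - mu) / sd

        k = min(self.n_clusters, np.unique(Z, axis=0).shape[0])
        if k < self.n_clusters:
            logger.warning("only %d distinct feature point(s); collapsing "
                           "k from %d to %d", k, self.n_clusters, k)
        if k == 1:
            ids = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=self.n_init,
                        random_state=self.random_state)
            ids = km.fit_predict(Z)
            # canonical cluster order: ascending median amplitude, so the
            # labelling is invariant to k-means' internal index permutation
            order = np.argsort([np.median(X[ids == c, 0]) for c in range(k)],
                               kind="stable")
            relabel = np.empty(k, dtype=int)
            relabel[order] = np.arange(k)
            ids = relabel[ids]

        if self.level_mode == "window":
            levels = np.array([classify_amplitude_cycle(a, c, criteria)
                               for a, c in X])
            cluster_levels = {}
        elif self.level_mode == "cluster":
            cluster_levels = {}
            for c in range(k):
                med = np.median(X[ids == c], axis=0)
                cluster_levels[c] = classify_amplitude_cycle(
                    med[0], med[1], criteria)
            levels = np.array([cluster_levels[c] for c in ids])
        else:
            raise ValueError(f"unknown level_mode {self.level_mode!r}")

        self.cluster_ids_ = ids
        self.cluster_levels_ = cluster_levels
        self.labels_ = levels
        self.n_clusters_ = k
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_event(features: Sequence[FeatureWindow], k: int = 3,
                  seed: Optional[int] = None) -> np.ndarray:
    """Cluster one event's windows; returns cluster ids (canonical order)."""
    clf = IntensityClassifier(n_clusters=k, random_state=seed).fit(
        feature_matrix(features))
    return clf.cluster_ids_


def _expand_to_seconds(windows: Sequence[FeatureWindow],
                       window_levels: np.ndarray,
                       time_s: np.ndarray) -> np.ndarray:
    """Per-sample labels; overlapping windows resolved later-window-wins."""
    out = np.empty(len(time_s), dtype=object)
    for w, lev in zip(windows, window_levels):
        mask = (time_s >= w.start_s - 1e-9) & (time_s < w.end_s - 1e-9)
        out[mask] = lev
    # any trailing samples past the last window inherit its level
    if len(windows):
        out[time_s >= windows[-1].end_s - 1e-9] = window_levels[-1]
    if any(v is None for v in out):
        raise ValueError("windows do not cover the trace")
    return out.astype(str)


def assign_levels(cluster_ids: np.ndarray,
                  features: Sequence[FeatureWindow],
                  criteria: CutoffCriteria = CutoffCriteria(),
                  vs: Optional[VSTrace] = None,
                  event_id: str = "") -> LabeledEvent:
    """Map clusters to levels via cutoffs on cluster medians.

    If ``vs`` is given, per-second labels are produced by expanding window
    labels over the trace (later window wins on overlap).
    """
    cluster_ids = np.asarray(cluster_ids, dtype=int)
    X = feature_matrix(features)
    cluster_levels = {}
    for c in np.unique(cluster_ids):
        med = np.median(X[cluster_ids == c], axis=0)
        cluster_levels[int(c)] = classify_amplitude_cycle(med[0], med[1],
                                                          criteria)
    window_levels = np.array([cluster_levels[int(c)] for c in cluster_ids])
    second_levels = (_expand_to_seconds(features, window_levels, vs.time_s)
                     if vs is not None else np.array([], dtype=str))
    return LabeledEvent(event_id=event_id or (vs.event_id if vs else ""),
                        windows=list(features),
                        window_levels=window_levels,
                        second_levels=second_levels,
                        cluster_ids=cluster_ids,
                        cluster_levels=cluster_levels,
                        k_used=len(cluster_levels))


def label_event(vs: VSTrace, features: Sequence[FeatureWindow],
                criteria: CutoffCriteria = CutoffCriteria(),
                k: int = 3, seed: Optional[int] = None,
                level_mode: str = "cluster") -> LabeledEvent:
    """Cluster + assign in one step for a single event."""
    clf = IntensityClassifier(n_clusters=k, criteria=criteria,
                              level_mode=level_mode,
                              random_state=seed).fit(feature_matrix(features))
    if level_mode == "window":
        second = _expand_to_seconds(features, clf.labels_, vs.time_s)
        return LabeledEvent(event_id=vs.event_id, windows=list(features),
                            window_levels=clf.labels_, second_levels=second,
                            cluster_ids=clf.cluster_ids_,
                            cluster_levels=clf.cluster_levels_,
                            k_used=clf.n_clusters_)
    return assign_levels(clf.cluster_ids_, features, criteria or
                         CutoffCriteria(), vs=vs, event_id=vs.event_id)


def level_proportions(second_levels: np.ndarray) -> tuple[float, float, float]:
    """(p_low, p_med, p_high) summing to exactly 1."""
    n = len(second_levels)
    if n == 0:
        raise ValueError("empty label set")
    p_low = float(np.count_nonzero(second_levels == "low")) / n
    p_med = float(np.count_nonzero(second_levels == "med")) / n
    return p_low, p_med, 1.0 - p_low - p_med


def exercise_metrics(labeled: LabeledEvent, vs: VSTrace,
                     capture_duration_min: float) -> ExerciseMetrics:
    """Activity budget plus mean fight intensity for one event."""
    if capture_duration_min <= 0:
        raise ValueError("capture duration must be positive")
    if len(labeled.second_levels) != len(vs.vs):
        raise ValueError("labels do not cover the trace")
    p_low, p_med, p_high = level_proportions(labeled.second_levels)
    mfi = float(vs.vs.sum()) / capture_duration_min
    return ExerciseMetrics(event_id=labeled.event_id, p_low=p_low,
                           p_med=p_med, p_high=p_high,
                           capture_duration_min=capture_duration_min,
                           mean_fight_intensity_g_min=mfi)
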