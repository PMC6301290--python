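"""Vectorial-sum conversion and windowed amplitude/cycle feature extraction.

The vectorial sum VS = sqrt(x² + y² + z²) is the orientation-free activity
proxy used for loggers whose mounting cannot be standardised across animals.
Features are computed on sliding windows of the VS series:

* ``amplitude``: peak-to-trough range of VS within the window, in g. Range
  (not half-range, not baseline-removed magnitude) is the definition used
  throughout, because only range makes the 0.05 g cutoff meaningful against
  the ~1 g static gravity baseline.
* ``cycle_s``: mean interval between successive local maxima of the
  mean-removed VS whose prominence exceeds a configured fraction of the
  window amplitude. Windows with fewer than two qualifying peaks carry the
  no-cycle sentinel, mapped to the window length (always > the 5 s cutoff).

The default window is 10 s with 50% overlap: the shortest window that can
still distinguish sub-5-s cycling from slower signal at 1 Hz (two peak
intervals of a just-sub-cutoff cycle fit inside it), chosen because every
second a boundary-spanning window covers inherits the more intense level,
so longer windows systematically erode resting time at bout boundaries.

At 1 Hz sampling, cycles shorter than 2 s are unresolvable (Nyquist); cycle
estimates below 2 s are floored at 2 s and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import AccelTrace

logger = logging.getLogger(__name__)

#: shortest resolvable oscillation period at 1 Hz sampling, s
MIN_CYCLE_S = 2.0


@dataclass
class VSTrace:
    """Per-sample vectorial-sum magnitude for one event."""

    event_id: str
    time_s: np.ndarray
    vs: np.ndarray

    def __len__(self) -> int:
        return len(self.vs)


@dataclass
class FeatureWindow:
    """Amplitude/cycle features on the half-open window [start_s, end_s)."""

    start_s: float
    end_s: float
    amplitude_g: float
    cycle_s: float
    n_samples: int
    has_cycle: bool
    cycle_floored: bool = False


def vectorial_sum(trace: AccelTrace) -> VSTrace:
    """VS[i] = sqrt(x[i]² + y[i]² + z[i]²), in g."""
    vs = np.sqrt(trace.x ** 2 + trace.y ** 2 + trace.z ** 2)
    return VSTrace(event_id=trace.event_id, time_s=trace.time_s, vs=vs)


def _window_cycle(vs_win: np.ndarray, dt: float, amplitude: float,
                  prominence_frac: float, window_s: float) -> tuple:
    """Mean peak spacing of the mean-removed signal; sentinel -> window_s."""
    if amplitude <= 0:
        return window_s, False, False
    detrended = vs_win - vs_win.mean()
    peaks, _ = find_peaks(detrended, prominence=prominence_frac * amplitude)
    if len(peaks) < 2:
        return window_s, False, False
    cycle = float(np.mean(np.diff(peaks)) * dt)
    if cycle < MIN_CYCLE_S:
        return MIN_CYCLE_S, True, True
    return cycle, True, False


def window_features(vst: VSTrace, window_s: float = 10.0,
                    overlap: float = 0.5,
                    prominence_frac: float = 0.25) -> list[FeatureWindow]:
    """Tile the VS series with overlapping windows and featurise each.

    Windows are [start, start + window_s) with stride window_s·(1 − overlap);
    the final window is anchored at the trace end so every sample is covered.
    A trace shorter than one window yields a single full-trace window (with a
    logged warning).
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    n = len(vst)
    if n == 0:
        raise ValueError("empty trace")
    t0, t_end = vst.time_s[0], vst.time_s[-1]
    dt = (t_end - t0) / (n - 1) if n > 1 else 1.0
    if window_s < 10:
        raise ValueError("window_s must be ≥ 10 s for cycle estimation at 1 Hz")

    span = t_end - t0 + dt
    if span <= window_s:
        logger.warning("%s: trace (%.0f s) shorter than window (%.0f s); "
                       "using a single full-trace window",
                       vst.event_id, span, window_s)
        starts = [t0]
    else:
        stride = window_s * (1.0 - overlap)
        starts = list(np.arange(t0, t_end - window_s + dt / 2, stride))
        last = t_end - window_s + dt  # anchor final window at trace end
        if not starts or last - starts[-1] > 1e-9:
            starts.append(last)

    out = []
    for s in starts:
        e = s + window_s if span > window_s else t_end + dt
        mask = (vst.time_s >= s - 1e-9) & (vst.time_s < e - 1e-9)
        vs_win = vst.vs[mask]
        if vs_win.size == 0:
            continue
        amp = float(vs_win.max() - vs_win.min())
        cycle, has_cycle, floored = _window_cycle(
            vs_win, dt, amp, prominence_frac, window_s)
        out.append(FeatureWindow(start_s=float(s), end_s=float(e),
                                 amplitude_g=amp, cycle_s=cycle,
                                 n_samples=int(vs_win.size),
                                 has_cycle=has_cycle, cycle_floored=floored))
    return out


def features_to_frame(event_id: str,
                      windows: Sequence[FeatureWindow]) -> pd.DataFrame:
    return pd.DataFrame({
        "event_id": event_id,
        "start_s": [w.start_s for w in windows],
        "end_s": [w.end_s for w in windows],
        "amplitude_g": [w.amplitude_g for w in windows],
        "cycle_s": [w.cycle_s for w in windows],
        "n_samples": [w.n_samples for w in windows],
        "has_cycle": [w.has_cycle for w in windows],
    })


def feature_matrix(windows: Sequence[FeatureWindow]) -> np.ndarray:
    """(n_windows, 2) array of (amplitude_g, cycle_s) — classifier input."""
    return np.array([[w.amplitude_g, w.cycle_s] for w in windows], float)
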