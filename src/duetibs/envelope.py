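"""Amplitude-envelope phase locking between two brains.

The inter-brain synchrony measure is the phase-locking value (PLV) between
the two players' band-limited *amplitude envelopes*:

1. band-pass each player's EEG in a canonical band (delta 1-3, theta 4-7,
   alpha 8-12, beta 13-30, gamma 30-40 Hz; two-pass Butterworth, 4th order),
2. take the magnitude of the analytic (Hilbert) signal -> amplitude envelope,
3. band-pass the envelope in the 1-3 Hz range of the musical tempi
   (96 bpm = 1.6 Hz ... 150 bpm = 2.5 Hz) and take its analytic phase,
4. within a sliding window (width 2 s, step 100 ms) compute, per trial and
   homologous electrode pair,

       PLV_(w,n) = (1/T) | sum_t exp(i (theta1 - theta2)) |,

5. average over ROI channel pairs, then over trials per condition.

Window timestamps are window *centers*: a significant run of centers
[7.7, 8.3] s therefore reflects data from 6.7 to 9.3 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .design import CELL_ORDER, cell_index
from .io import DyadEpochs
from .montage import roi_indices

BANDS = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}

#: Envelope re-filtering range covering the performed and planned tempi (Hz).
TEMPO_BAND = (1.0, 3.0)


def bpm_to_hz(bpm: float) -> float:
    """Convert a musical tempo in beats per minute to its rate in Hz."""
    if bpm <= 0:
        raise ValueError("bpm must be positive")
    return bpm / 60.0


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

MASTOID_LABELS = ("M1", "M2", "A1", "A2", "TP9", "TP10")


def preprocess(
    raw1: np.ndarray,
    raw2: np.ndarray,
    sfreq: float,
    events: np.ndarray,
    ch_names: list[str],
    conditions=None,
    tmin: float = -1.0,
    tmax: float = 16.0,
) -> DyadEpochs:
    """Filter, re-reference and epoch a continuous dual recording.

    Applies a zero-phase 0.5-95 Hz Butterworth band-pass and a 45-55 Hz
    band-stop (both 3rd order, two-pass), re-references to the linked-mastoid
    average when mastoid channels are present (synthetic data are generated
    reference-free and skip this), and cuts epochs ``tmin..tmax`` around each
    cue event (sample indices in ``events``).
    """
    raw1 = np.asarray(raw1, float)
    raw2 = np.asarray(raw2, float)
    events = np.asarray(events, int)
    if raw1.shape != raw2.shape:
        raise ValueError("player recordings differ in shape")
    if raw1.shape[0] != len(ch_names):
        raise ValueError("channel count does not match labels")
    if events.size == 0:
        raise ValueError("no cue events supplied")

    sos_bp = butter(3, (0.5, 95.0), btype="bandpass", fs=sfreq, output="sos")
    sos_notch = butter(3, (45.0, 55.0), btype="bandstop", fs=sfreq, output="sos")

    def clean(x):
        x = sosfiltfilt(sos_bp, x, axis=-1)
        return sosfiltfilt(sos_notch, x, axis=-1)

    raw1, raw2 = clean(raw1), clean(raw2)

    upper = [c.upper() for c in ch_names]
    mastoids = [i for i, c in enumerate(upper) if c in MASTOID_LABELS]
    if len(mastoids) >= 2:
        keep_idx = [i for i in range(len(upper)) if i not in mastoids]
        for arr in (raw1, raw2):
            ref = arr[mastoids].mean(axis=0)
            arr -= ref
        raw1, raw2 = raw1[keep_idx], raw2[keep_idx]
        ch_names = [ch_names[i] for i in keep_idx]

    n0 = int(round(-tmin * sfreq))
    n1 = int(round(tmax * sfreq))
    times = np.arange(-n0, n1) / sfreq
    epochs = []
    for arr in (raw1, raw2):
        trials = []
        for s in events:
            if s - n0 < 0 or s + n1 > arr.shape[-1]:
                raise ValueError(f"event at sample {s} leaves epoch out of range")
            trials.append(arr[:, s - n0:s + n1])
        epochs.append(np.stack(trials))

    if conditions is None:
        conditions = pd.DataFrame(index=range(len(events)))
    return DyadEpochs(epochs[0], epochs[1], sfreq, list(ch_names), times,
                      conditions)


# ---------------------------------------------------------------------------
# envelopes and phases
# ---------------------------------------------------------------------------

def band_envelope(data: np.ndarray, band: str, sfreq: float) -> np.ndarray:
    """Amplitude envelope of one canonical frequency band.

    Band-pass (two-pass Butterworth, 4th order) then magnitude of the
    analytic signal, computed over the whole epoch so that the padding before
    and after the analysis range absorbs filter transients.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if hi >= sfreq / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({sfreq / 2} Hz)")
    sos = butter(4, (lo, hi), btype="bandpass", fs=sfreq, output="sos")
    filtered = sosfiltfilt(sos, np.asarray(data, float), axis=-1)
    return np.abs(hilbert(filtered, axis=-1))


def envelope_phase(envelope: np.ndarray, sfreq: float) -> np.ndarray:
    """Phase (radians, in (-pi, pi]) of the 1-3 Hz-filtered envelope."""
    sos = butter(4, TEMPO_BAND, btype="bandpass", fs=sfreq, output="sos")
    filtered = sosfiltfilt(sos, np.asarray(envelope, float), axis=-1)
    return np.angle(hilbert(filtered, axis=-1))


# ---------------------------------------------------------------------------
# sliding-window PLV
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window layout over the trial.

    Windows are half-open ``[t0, t0 + width)`` and carry their *center* time
    as timestamp.  The default grid (width 2 s, step 0.1 s, from 1 s to
    14.2 s) yields 113 windows with centers 2.0, 2.1, ..., 13.2 s.
    """

    width: float = 2.0
    step: float = 0.1
    start: float = 1.0
    end: float = 14.2

    @property
    def n_windows(self) -> int:
        return int(np.floor((self.end - self.width - self.start) / self.step + 1e-9)) + 1

    @property
    def centers(self) -> np.ndarray:
        return self.start + self.width / 2 + self.step * np.arange(self.n_windows)

    def onsets(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_windows)

    def n_samples(self, sfreq: float) -> int:
        return int(round(self.width * sfreq))

    def start_indices(self, times: np.ndarray, sfreq: float) -> np.ndarray:
        """Sample index of each window onset; errors if the grid leaves the epoch."""
        idx = np.round((self.onsets() - times[0]) * sfreq).astype(int)
        T = self.n_samples(sfreq)
        if idx.min() < 0 or idx.max() + T > times.size:
            raise ValueError("window grid exceeds the epoch time range")
        return idx

    def coverage(self, center_lo: float, center_hi: float) -> tuple[float, float]:
        """Data range (s) contributing to a run of window centers."""
        return (center_lo - self.width / 2, center_hi + self.width / 2)


@dataclass
class PLVSeries:
    """Windowed PLV per trial (and, optionally, per homologous channel pair)."""

    values: np.ndarray            # (n_trials, [n_channels,] n_windows)
    centers: np.ndarray
    band: str = ""
    ch_names: list = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.values.shape[-1]


def sliding_plv(
    phase1: np.ndarray,
    phase2: np.ndarray,
    sfreq: float,
    times: np.ndarray,
    grid: WindowGrid | None = None,
    band: str = "",
    ch_names=None,
) -> PLVSeries:
    """Windowed phase-locking value between two phase series.

    ``phase1``/``phase2`` are (..., n_samples) arrays of envelope phases on
    the shared ``times`` axis; the trailing axis is windowed.  Uses a
    cumulative-sum of unit phasors, equivalent to the direct per-window mean
    resultant.
    """
    grid = grid or WindowGrid()
    phase1 = np.asarray(phase1, float)
    phase2 = np.asarray(phase2, float)
    if phase1.shape != phase2.shape:
        raise ValueError("phase arrays differ in shape")
    starts = grid.start_indices(times, sfreq)
    T = grid.n_samples(sfreq)

    z = np.exp(1j * (phase1 - phase2))
    csum = np.cumsum(z, axis=-1)
    ends = starts + T - 1
    upper = csum[..., ends]
    lower = np.where(starts > 0, csum[..., np.maximum(starts - 1, 0)], 0.0)
    plv = np.abs(upper - lower) / T
    return PLVSeries(np.minimum(plv, 1.0), grid.centers, band=band,
                     ch_names=list(ch_names) if ch_names is not None else [])


def roi_average(plv: PLVSeries, roi: str) -> np.ndarray:
    """Average a channel-resolved PLV series over a named ROI.

    Returns (n_trials, n_windows): the ROI mean per trial; condition averaging
    happens afterwards (ROI first, then trials, per condition).
    """
    if plv.values.ndim != 3:
        raise ValueError("roi_average expects (n_trials, n_channels, n_windows)")
    idx = roi_indices(roi, plv.ch_names)
    return plv.values[:, idx, :].mean(axis=1)


def condition_means(trial_values: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Average trial-level values (n_trials, n_windows) into the 4 design cells.

    Returns (4, n_windows) in the canonical :data:`~duetibs.design.CELL_ORDER`.
    """
    trial_values = np.asarray(trial_values, float)
    cells = np.asarray(cells, int)
    out = np.empty((4, trial_values.shape[-1]))
    for c in range(4):
        mask = cells == c
        if not mask.any():
            raise ValueError(f"no trials in design cell {CELL_ORDER[c]}")
        out[c] = trial_values[mask].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def band_power(
    epochs: DyadEpochs,
    band: str,
    window: tuple[float, float],
    roi: str = "GLOBAL",
) -> np.ndarray:
    """Mean band power per design cell within a data time window.

    Power is the mean squared amplitude envelope over the window's samples,
    the ROI's channels, both players, and the cell's trials.  ``window`` is a
    (t_lo, t_hi) data range in seconds.  Returns 4 values in canonical cell
    order.
    """
    t_lo, t_hi = window
    mask = (epochs.times >= t_lo) & (epochs.times < t_hi)
    if not mask.any():
        raise ValueError("power window outside the epoch")
    idx = roi_indices(roi, epochs.ch_names)
    cells = np.array([
        cell_index(r["tempo_condition"], r["familiarity"])
        for _, r in epochs.conditions.iterrows()
    ])
    power_trials = np.zeros(epochs.n_trials)
    for data in (epochs.data1, epochs.data2):
        env = band_envelope(data[:, idx, :], band, epochs.sfreq)
        power_trials += (env[..., mask] ** 2).mean(axis=(1, 2))
    power_trials /= 2.0
    return np.array([power_trials[cells == c].mean() for c in range(4)])
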