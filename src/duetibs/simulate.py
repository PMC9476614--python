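"""Synthetic dyad sessions with known ground truth.

Two coupled generators emulate the duet paradigm:

* :func:`simulate_keystrokes` produces both players' keystroke onsets from a
  first-order linear phase-correction model with an anticipatory tempo bias —
  each player's internal beat period drifts toward the cued phrase-2 tempo
  already during phrase 1 and the pause, which reproduces the characteristic
  sign pattern of duet asynchronies (up-down cues lead early/negative,
  down-up late/positive, congruent cues near zero).

* :func:`simulate_dual_eeg` produces 29-channel dual EEG in which each
  frequency band's carrier (band-limited Gaussian noise) is amplitude-modulated
  at the beat rate.  Inter-brain coupling is injected on the *envelope
  modulation phase*: the between-player phase offset is redrawn each beat from
  a von Mises(0, kappa) distribution, so the envelope phase-locking value rises
  monotonically with the concentration kappa (kappa = 0 gives independent
  envelope phases, kappa -> inf perfect locking).

:func:`simulate_envelope_phase_session` is a light-weight shortcut that emits
ROI-level envelope *phase* series directly (skipping carrier synthesis), for
calibration and power studies of the cluster statistics at scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from scipy.special import i0e, i1e

from .design import (
    BASE_BPM, CELL_ORDER, SEGMENT_EDGES, Timeline, cell_index, make_design,
)
from .io import DyadEpochs
from .montage import CHANNELS

BEAT_HZ = BASE_BPM / 60.0          # 2 Hz beat rate of phrase 1 / pause
BASE_PERIOD = 60.0 / BASE_BPM      # 0.5 s

# Deterministic pseudo-chorale scores: 7 crotchets per phrase, melody (player
# 1, right hand) and bassline (player 2, left hand).  Only pitch identity
# matters downstream (key-error checks), not musical quality.
_MELODY_STEPS = {
    "A": (0, 2, 4, 5, 4, 2, 0), "B": (4, 2, 0, 2, 4, 5, 7),
    "C": (7, 5, 4, 2, 0, 2, 4), "D": (0, 4, 2, 5, 4, 7, 5),
}


def score_pitches(piece: str, player: int, phrase: int) -> list[int]:
    """MIDI pitches of the 7 crotchets of one phrase for one player."""
    steps = _MELODY_STEPS[piece]
    if phrase == 2:
        steps = tuple(reversed(steps))
    base = 72 if player == 1 else 48
    return [base + s for s in steps]


@dataclass
class SimParams:
    """Parameters of the synthetic dyad generators.

    Timing model
    ------------
    motor_noise_sigma : ms
        Standard deviation of Gaussian timing noise added to every produced
        inter-onset interval.
    anticipation_bias : ms per beat
        Rate at which a player's internal beat period drifts from 500 ms
        toward the cued phrase-2 period during phrase 1 and the pause.
    adaptation_gain : in [0, 1)
        First-order phase-correction gain applied to the last heard
        between-player asynchrony (active only while players hear each other,
        i.e. during phrase 1).

    EEG model
    ---------
    modulation_depth : in [0, 1]
        Depth d of the beat-rate amplitude modulation m(t) = 1 + d cos(...).
    coupling_kappa : mapping
        ``(band, segment) -> kappa`` where kappa is a float or a dict keyed by
        condition level (``congruent``/``incongruent`` or
        ``familiar``/``unfamiliar``).  ``math.inf`` means perfect locking;
        unspecified entries default to 0 (no coupling).
    noise_exponent
        Slope of the 1/f^a background added per channel.
    mod_phase_drift : radians
        Stationary spread of the beat-anchored slow wander of the modulation
        phase (mean-reverting at beat resolution).
    seg_mod_gain
        Per-segment scaling of the modulation depth (the beat modulation is
        absent before the metronome and weaker in the pause).
    """

    n_pairs: int = 14
    trials_per_cell: int = 48
    sfreq: float = 500.0
    modulation_depth: float = 0.8
    coupling_kappa: dict = field(default_factory=dict)
    noise_exponent: float = 1.0
    motor_noise_sigma: float = 10.0
    anticipation_bias: float = 0.5
    adaptation_gain: float = 0.25
    rng_seed: int = 0
    bands: tuple = ("gamma",)
    noise_scale: float = 0.3
    mod_phase_drift: float = 0.5
    seg_mod_gain: dict = field(default_factory=lambda: {
        "cue": 0.0, "metronome": 1.0, "phrase1": 1.0, "pause": 0.7, "phrase2": 1.0,
    })
    sources: dict = None

    def __post_init__(self):
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if not 0.0 <= self.adaptation_gain < 1.0:
            raise ValueError(
                "adaptation_gain must lie in [0, 1): gains >= 1 make the "
                "phase-correction loop unstable"
            )
        if self.motor_noise_sigma < 0:
            raise ValueError("motor_noise_sigma must be >= 0")
        for key, val in self.coupling_kappa.items():
            vals = val.values() if isinstance(val, dict) else [val]
            if any(v < 0 for v in vals):
                raise ValueError(f"negative coupling kappa for {key}")
        if self.sources is None:
            self.sources = {
                "broad": {ch: 1.0 for ch in CHANNELS},
                "posterior_right": {ch: 1.0 for ch in ("C4", "CP2", "CP6", "P4", "P8")},
            }
        for name, topo in self.sources.items():
            unknown = [ch for ch in topo if ch.upper() not in CHANNELS]
            if unknown:
                raise ValueError(
                    f"unknown channel label(s) {unknown} in topography {name!r}"
                )

    def kappa(self, band: str, segment: str, tempo: str, familiarity: str) -> float:
        """Resolve the coupling concentration for one band/segment/condition."""
        val = self.coupling_kappa.get((band, segment), 0.0)
        if isinstance(val, dict):
            for key in (tempo, familiarity):
                if key in val:
                    return float(val[key])
            raise ValueError(
                f"condition-dependent kappa for {(band, segment)} resolves "
                f"neither tempo={tempo!r} nor familiarity={familiarity!r}"
            )
        return float(val)


def _trial_rng(seed: int, pair: int, trial: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(pair), int(trial), stream])
    )


# ---------------------------------------------------------------------------
# keystroke timing
# ---------------------------------------------------------------------------

def _period_schedule(instruction: str, beta_s: float, n_beats: int) -> np.ndarray:
    """Internal beat period for beats 1..n_beats of phrase 1 + pause.

    Drifts from 500 ms toward the cued phrase-2 period (400 ms for "up",
    625 ms for "down") by ``beta_s`` seconds per beat, clipped at the target.
    """
    target = 0.4 if instruction == "up" else 0.625
    direction = np.sign(target - BASE_PERIOD)
    k = np.arange(1, n_beats + 1)
    drift = direction * np.minimum(beta_s * k, abs(target - BASE_PERIOD))
    return BASE_PERIOD + drift


def simulate_keystrokes(design_row, params: SimParams):
    """Simulate both players' keystrokes for one trial.

    Returns two keystroke DataFrames (player 1, player 2) with columns
    ``player, trial, phrase, position, onset_s, pitch, piece``.  Each phrase
    contains 7 crotchets (the 8th beat is a rest); the 8 pause beats are
    internally timed without auditory feedback, as is the muted phrase 2.
    """
    row = design_row
    beta = params.anticipation_bias / 1000.0
    sigma = params.motor_noise_sigma / 1000.0
    alpha = params.adaptation_gain
    rng = _trial_rng(params.rng_seed, row["pair"], row["trial"], 1)

    periods = [
        _period_schedule(row["instruction_p1"], beta, 17),
        _period_schedule(row["instruction_p2"], beta, 17),
    ]
    targets = [
        0.4 if row["instruction_p1"] == "up" else 0.625,
        0.4 if row["instruction_p2"] == "up" else 0.625,
    ]
    last_metronome = Timeline().metronome_onset + 3 * BASE_PERIOD  # 2.5 s

    # beats 1..16: phrase-1 strokes (1..7), rest (8), pause beats (9..16)
    onsets = np.zeros((2, 24))
    prev = np.array([last_metronome, last_metronome])
    for beat in range(1, 17):
        noise = rng.normal(0.0, sigma, 2) if sigma > 0 else np.zeros(2)
        nxt = np.empty(2)
        for p in range(2):
            correction = 0.0
            # mutual phase correction only while both heard the previous
            # stroke: beats 2..8 follow audible phrase-1 strokes 1..7
            if alpha > 0 and 2 <= beat <= 8:
                correction = alpha * (prev[1 - p] - prev[p])
            nxt[p] = prev[p] + periods[p][beat - 1] + correction + noise[p]
        onsets[:, beat - 1] = nxt
        prev = nxt
    # phrase 2: internally timed (audio muted).  The entry interval (beat 17)
    # is still one beat of the drifted internal period; the in-phrase IKIs
    # run at the cued target tempo.
    for beat in range(17, 24):
        noise = rng.normal(0.0, sigma, 2) if sigma > 0 else np.zeros(2)
        for p in range(2):
            period = periods[p][16] if beat == 17 else targets[p]
            onsets[p, beat - 1] = prev[p] + period + noise[p]
        prev = onsets[:, beat - 1]

    frames = []
    for p in (1, 2):
        rows = []
        for pos in range(1, 8):  # phrase 1
            rows.append((p, row["trial"], 1, pos, onsets[p - 1, pos - 1],
                         score_pitches(row["piece"], p, 1)[pos - 1], row["piece"]))
        for pos in range(1, 8):  # phrase 2 (beats 17..23)
            rows.append((p, row["trial"], 2, pos, onsets[p - 1, 15 + pos],
                         score_pitches(row["piece"], p, 2)[pos - 1], row["piece"]))
        frames.append(pd.DataFrame(
            rows, columns=["player", "trial", "phrase", "position",
                           "onset_s", "pitch", "piece"]
        ))
    return frames[0], frames[1]


def simulate_keystroke_session(design: pd.DataFrame, params: SimParams) -> pd.DataFrame:
    """Simulate keystrokes for every trial of a design table.

    Returns one long table in the keystroke-CSV schema (both players).
    """
    out = []
    for _, row in design.iterrows():
        s1, s2 = simulate_keystrokes(row, params)
        for s, self_i, other_i in ((s1, "instruction_p1", "instruction_p2"),
                                   (s2, "instruction_p2", "instruction_p1")):
            s = s.copy()
            s["pair"] = row["pair"]
            s["familiarity"] = row["familiarity"]
            s["instruction_self"] = row[self_i]
            s["instruction_other"] = row[other_i]
            out.append(s)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# dual EEG
# ---------------------------------------------------------------------------

BAND_EDGES = {
    "delta": (1.0, 3.0), "theta": (4.0, 7.0), "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0), "gamma": (30.0, 40.0),
}


def _segment_of(t: np.ndarray) -> np.ndarray:
    """Segment name per time point."""
    names = np.full(t.shape, "phrase2", dtype=object)
    for name, (lo, hi) in SEGMENT_EDGES.items():
        names[(t >= lo) & (t < hi)] = name
    return names


def _beat_phase_pair(times, beat_times, segments_at_beats, kappa_of_segment, drift,
                     rng):
    """Modulation phases of the two players on the sample grid.

    Player 2's phase wanders slowly *around the beat* (mean-reverting AR(1)
    at beat resolution, so trial-averaged envelopes keep their beat-locked
    periodicity); player 1 tracks it with a per-beat von Mises(0, kappa)
    offset.  Both are linearly interpolated to the sample grid.
    """
    n_beats = len(beat_times)
    rho = 0.9
    innov = rng.normal(0.0, drift * np.sqrt(1 - rho ** 2), n_beats)
    walk = np.empty(n_beats)
    walk[0] = rng.normal(0.0, drift)
    for b in range(1, n_beats):
        walk[b] = rho * walk[b - 1] + innov[b]
    delta = np.empty(n_beats)
    for i, seg in enumerate(segments_at_beats):
        kap = kappa_of_segment(seg)
        delta[i] = 0.0 if math.isinf(kap) else rng.vonmises(0.0, kap) if kap > 0 \
            else rng.uniform(-np.pi, np.pi)
    phi2 = np.interp(times, beat_times, walk)
    phi1 = phi2 + np.interp(times, beat_times, delta)
    return phi1, phi2, delta


def simulate_dual_eeg(design: pd.DataFrame, params: SimParams) -> DyadEpochs:
    """Simulate one pair's dual EEG epochs for all trials of ``design``.

    Per band, each latent source is band-limited Gaussian noise whose
    amplitude is modulated at the beat rate with a player-specific modulation
    phase; channels are topography-weighted source mixtures plus 1/f
    background noise.  The drawn per-beat phase offsets are retrievable from
    ``DyadEpochs.sim_truth`` for oracle tests.
    """
    pairs = design["pair"].unique()
    if len(pairs) != 1:
        raise ValueError("simulate_dual_eeg expects the design rows of one pair")
    sf = params.sfreq
    highest = max(BAND_EDGES[b][1] for b in params.bands)
    if sf <= 2 * highest:
        raise ValueError(f"sfreq {sf} too low for band edge {highest} Hz")

    times = np.arange(-1.0, 16.0, 1.0 / sf)
    n_samp = times.size
    n_ch = len(CHANNELS)
    beat_times = np.arange(-1.0, 16.0 + BASE_PERIOD, BASE_PERIOD)
    beat_segments = _segment_of(beat_times)
    seg_gain_samples = np.array(
        [params.seg_mod_gain.get(s, 1.0) for s in _segment_of(times)])

    # topography weight matrix per source
    src_names = list(params.sources)
    W = np.zeros((len(src_names), n_ch))
    for si, name in enumerate(src_names):
        for ch, w in params.sources[name].items():
            W[si, CHANNELS.index(ch.upper())] = w

    sos = {b: butter(4, BAND_EDGES[b], btype="bandpass", fs=sf, output="sos")
           for b in params.bands}

    n_trials = len(design)
    data = np.zeros((2, n_trials, n_ch, n_samp))
    truth_offsets = {}
    for ti, (_, row) in enumerate(design.iterrows()):
        rng = _trial_rng(params.rng_seed, row["pair"], row["trial"], 2)
        chan = np.zeros((2, n_ch, n_samp))
        for band in params.bands:
            def kap_of(seg, band=band):
                return params.kappa(band, seg, row["tempo_condition"],
                                    row["familiarity"])
            phi1, phi2, delta = _beat_phase_pair(
                times, beat_times, beat_segments, kap_of,
                params.mod_phase_drift, rng)
            truth_offsets[(int(row["trial"]), band)] = delta
            mods = [
                1.0 + params.modulation_depth * seg_gain_samples
                * np.cos(2 * np.pi * BEAT_HZ * times - phi)
                for phi in (phi1, phi2)
            ]
            for p in range(2):
                carriers = sosfiltfilt(
                    sos[band], rng.standard_normal((len(src_names), n_samp)),
                    axis=-1)
                # normalize carrier RMS so band amplitudes are comparable
                rms = np.sqrt(np.mean(carriers ** 2, axis=-1, keepdims=True))
                carriers /= np.maximum(rms, 1e-30)
                chan[p] += W.T @ (carriers * mods[p])
        for p in range(2):
            chan[p] += params.noise_scale * _one_over_f_noise(
                rng, n_ch, n_samp, sf, params.noise_exponent)
        data[:, ti] = chan

    return DyadEpochs(
        data[0], data[1], sf, list(CHANNELS), times,
        design.reset_index(drop=True),
        sim_truth={"phase_offsets": truth_offsets, "params": params},
    )


def _one_over_f_noise(rng, n_ch, n_samp, sf, exponent) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent."""
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sf)
    amp = np.ones_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal((n_ch, freqs.size))
                  + 1j * rng.standard_normal((n_ch, freqs.size)))
    x = np.fft.irfft(spec, n=n_samp, axis=-1)
    x /= np.std(x, axis=-1, keepdims=True)
    return x


def ground_truth(design: pd.DataFrame, params: SimParams) -> pd.DataFrame:
    """Tabulate the injected coupling and timing effects.

    One row per (band, segment, tempo_condition, familiarity) with the
    resolved kappa, plus the timing parameters, exactly as the simulators
    consume them.
    """
    rows = []
    for band in params.bands:
        for segment in SEGMENT_EDGES:
            for tempo, familiarity in CELL_ORDER:
                rows.append({
                    "band": band, "segment": segment,
                    "tempo_condition": tempo, "familiarity": familiarity,
                    "kappa": params.kappa(band, segment, tempo, familiarity),
                    "anticipation_bias_ms_per_beat": params.anticipation_bias,
                    "adaptation_gain": params.adaptation_gain,
                    "motor_noise_sigma_ms": params.motor_noise_sigma,
                    "modulation_depth": params.modulation_depth,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROI-level envelope-phase sessions (for statistics calibration at scale)
# ---------------------------------------------------------------------------

@dataclass
class PhaseSession:
    """Envelope-phase series of one dyad.

    ``theta1``/``theta2`` are (n_trials, n_samples) ROI-level phase arrays on
    ``times`` — or (n_trials, n_channels, n_samples) channel-resolved arrays
    with ``ch_names`` set.  ``cells`` holds the canonical condition-cell id
    (0..3) per trial.
    """

    pair: int
    theta1: np.ndarray
    theta2: np.ndarray
    times: np.ndarray
    sfreq: float
    cells: np.ndarray
    design: pd.DataFrame = None
    ch_names: list = None


def coupling_weight(kappa: float) -> float:
    """Map a von Mises concentration to a [0, 1] coupling weight.

    Uses the mean resultant length I1(kappa)/I0(kappa): 0 at kappa = 0,
    monotone, 1 in the perfect-locking limit.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if math.isinf(kappa):
        return 1.0
    return float(i1e(kappa) / i0e(kappa))


def simulate_envelope_phase_session(
    n_pairs: int = 14,
    trials_per_cell: int = 36,
    kappa_by_segment: dict | None = None,
    sfreq: float = 50.0,
    seed: int = 0,
    coupling_mode: str = "dyadic",
    phase_drift: float = 1.0,
    t_start: float = 1.0,
    t_end: float = 14.2,
) -> list[PhaseSession]:
    """Simulate ROI-level envelope-phase series for a whole session.

    ``kappa_by_segment`` maps segment name -> kappa (float or per-condition
    dict, as in :class:`SimParams`); omitted segments get kappa 0.

    ``coupling_mode='dyadic'`` injects dyad- and trial-specific coupling:
    each player's envelope phase diffuses around the beat with per-beat
    volatility ``phase_drift``, decomposed into a shared (dyadic) and a
    private diffusion component mixed with weight lambda = I1(k)/I0(k).
    Because each player's *marginal* phase statistics are identical across
    conditions by construction, only real partners show the condition
    effect — cross-paired (surrogate) players see exactly the same phase-
    difference law in every condition.  ``'common'`` instead locks every
    player independently to the common beat grid with per-beat von Mises(0,
    kappa) jitter: that locking (and its condition dependence) is shared by
    all players, so surrogate pairs inherit the effect — the positive
    control for the surrogate analysis.
    """
    if coupling_mode not in ("dyadic", "common"):
        raise ValueError("coupling_mode must be 'dyadic' or 'common'")
    kappa_by_segment = kappa_by_segment or {}
    design = make_design(n_pairs, trials_per_cell, seed)
    times = np.arange(t_start, t_end, 1.0 / sfreq)
    beat_times = np.arange(t_start, t_end + BASE_PERIOD, BASE_PERIOD)
    beat_segments = _segment_of(beat_times)
    n_beats = beat_times.size
    base = 2 * np.pi * BEAT_HZ * times

    def resolve(seg, tempo, familiarity):
        val = kappa_by_segment.get(seg, 0.0)
        if isinstance(val, dict):
            for key in (tempo, familiarity):
                if key in val:
                    return float(val[key])
            raise ValueError(f"kappa for segment {seg!r} resolves no condition")
        return float(val)

    sessions = []
    for pair, sub in design.groupby("pair"):
        sub = sub.sort_values("trial").reset_index(drop=True)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7919, int(pair)]))
        n_trials = len(sub)
        theta1 = np.empty((n_trials, times.size))
        theta2 = np.empty((n_trials, times.size))
        cells = np.array([cell_index(r["tempo_condition"], r["familiarity"])
                          for _, r in sub.iterrows()])
        for ti, (_, row) in enumerate(sub.iterrows()):
            kappas = np.array([
                resolve(s, row["tempo_condition"], row["familiarity"])
                for s in beat_segments
            ])
            if coupling_mode == "dyadic":
                lam = np.array([coupling_weight(k) for k in kappas])
                # shared and private per-beat diffusion increments; the mix
                # keeps each player's marginal increment variance constant
                shared = rng.normal(0.0, phase_drift, n_beats)
                priv1 = rng.normal(0.0, phase_drift, n_beats)
                priv2 = rng.normal(0.0, phase_drift, n_beats)
                w1 = np.cumsum(np.sqrt(lam) * shared + np.sqrt(1 - lam) * priv1)
                w2 = np.cumsum(np.sqrt(lam) * shared + np.sqrt(1 - lam) * priv2)
                start1, start2 = rng.uniform(-np.pi, np.pi, 2)
                theta1[ti] = base + np.interp(times, beat_times, start1 + w1)
                theta2[ti] = base + np.interp(times, beat_times, start2 + w2)
            else:  # common: each player locked to the beat grid on its own
                def draw_offsets():
                    d = np.empty(n_beats)
                    for i, kap in enumerate(kappas):
                        if math.isinf(kap):
                            d[i] = 0.0
                        elif kap > 0:
                            d[i] = rng.vonmises(0.0, kap)
                        else:
                            d[i] = rng.uniform(-np.pi, np.pi)
                    return d

                theta1[ti] = base + np.interp(times, beat_times, draw_offsets())
                theta2[ti] = base + np.interp(times, beat_times, draw_offsets())
        sessions.append(PhaseSession(
            pair=int(pair),
            theta1=np.angle(np.exp(1j * theta1)),
            theta2=np.angle(np.exp(1j * theta2)),
            times=times, sfreq=sfreq, cells=cells, design=sub,
        ))
    return sessions
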