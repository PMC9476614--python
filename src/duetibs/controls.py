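"""Control analyses: baseline PLV, surrogate pairs, and power confounds.

* Baseline PLV re-pairs *trials within each dyad* at random (derangements)
  and re-runs the PLV pipeline; it captures locking driven by the temporal
  structure common to all trials (shared 120 bpm beat) rather than by
  trial-specific interaction.

* Surrogate pairs combine player 1 of one dyad with player 2 of a *different*
  dyad, matching trials of the same design cell and equalizing trial counts
  (deleting spare player-2 trials, or duplicating its first trials, so the
  surrogate analysis has exactly the statistical power of the real one).
  Locking specific to the real interaction disappears in surrogate pairs;
  locking inherited from the shared task structure does not.

* The power confound check verifies that a PLV effect is not accompanied by a
  band-power difference between conditions in the same ROI/window.
"""

from __future__ import annotations

import numpy as np

from .envelope import WindowGrid, band_power, roi_average, sliding_plv
from .simulate import PhaseSession
from .stats import PermutationConfig, paired_t, permutation_test

_CELL_CONTRASTS = {
    # cell order: cong-fam, cong-unfam, incong-fam, incong-unfam
    "TEMPO": ([0, 1], [2, 3]),
    "FAMILIARITY": ([0, 2], [1, 3]),
}


def random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of 0..n-1 with no fixed point."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def baseline_plv(
    session: PhaseSession,
    grid: WindowGrid | None = None,
    n_rep: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Baseline PLV time course of one dyad from within-dyad trial re-pairing.

    Player 1's trial i is paired with player 2's trial sigma(i), sigma a
    random derangement, the windowed PLV recomputed, and the result averaged
    over trials and ``n_rep`` derangements.  Returns (n_windows,).
    """
    grid = grid or WindowGrid()
    n_trials = session.theta1.shape[0]
    if n_trials < 2:
        raise ValueError("baseline PLV needs at least 2 kept trials")
    rng = np.random.default_rng(seed)
    acc = 0.0
    for _ in range(n_rep):
        sigma = random_derangement(n_trials, rng)
        plv = sliding_plv(session.theta1, session.theta2[sigma],
                          session.sfreq, session.times, grid)
        acc = acc + plv.values.mean(axis=0)
    return acc / n_rep


def compare_to_baseline(condition_plv: np.ndarray, baseline: np.ndarray):
    """Pointwise paired t of a condition PLV series against baseline PLV.

    ``condition_plv``: (n_pairs, n_windows) condition means per pair;
    ``baseline``: (n_pairs, n_windows).  Returns (t_series, p_series),
    uncorrected — the per-window "circles" of the figures.
    """
    condition_plv = np.asarray(condition_plv, float)
    baseline = np.asarray(baseline, float)
    if condition_plv.shape != baseline.shape:
        raise ValueError("condition and baseline arrays must align")
    n_windows = condition_plv.shape[1]
    t = np.empty(n_windows)
    p = np.empty(n_windows)
    for w in range(n_windows):
        t[w], p[w], _ = paired_t(condition_plv[:, w], baseline[:, w])
    return t, p


# ---------------------------------------------------------------------------
# surrogate pairs
# ---------------------------------------------------------------------------

def align_surrogate_cell(idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
    """Equalize player-2 trial indices of one design cell to player 1's count.

    Spare player-2 trials are deleted; a deficit is filled by duplicating
    player 2's first trials in order (cycling if needed).  Returns the
    player-2 indices aligned one-to-one with ``idx1``.
    """
    n1, n2 = len(idx1), len(idx2)
    if n2 == 0:
        raise ValueError("surrogate cell has no player-2 trials")
    if n2 >= n1:
        return idx2[:n1]
    reps = idx2[np.arange(n1 - n2) % n2]
    return np.concatenate([idx2, reps])


def make_surrogate_dataset(
    sessions: list[PhaseSession],
    seed: int | None = None,
) -> list[PhaseSession]:
    """Build surrogate dyads by cross-pairing players of different real pairs.

    Player 1 of pair k is paired with player 2 of pair pi(k), where pi is a
    cyclic shift by default or a seeded random derangement of pair identities
    — either way no real pair survives.  Within each design cell trials are
    matched condition-wise and counts equalized to player 1's
    (:func:`align_surrogate_cell`).
    """
    n = len(sessions)
    if n < 2:
        raise ValueError("surrogate pairing needs at least 2 real pairs")
    if seed is None:
        partner = (np.arange(n) + 1) % n          # cyclic shift
    else:
        partner = random_derangement(n, np.random.default_rng(seed))

    surrogates = []
    for k in range(n):
        s1, s2 = sessions[k], sessions[int(partner[k])]
        rows1, rows2 = [], []
        for c in range(4):
            idx1 = np.flatnonzero(s1.cells == c)
            idx2 = np.flatnonzero(s2.cells == c)
            rows1.append(idx1)
            rows2.append(align_surrogate_cell(idx1, idx2))
        order1 = np.concatenate(rows1)
        order2 = np.concatenate(rows2)
        surrogates.append(PhaseSession(
            pair=s1.pair,
            theta1=s1.theta1[order1],
            theta2=s2.theta2[order2],
            times=s1.times, sfreq=s1.sfreq,
            cells=s1.cells[order1],
            design=s1.design.iloc[order1].reset_index(drop=True),
        ))
    return surrogates


def session_plv_data(sessions: list[PhaseSession],
                     grid: WindowGrid | None = None,
                     roi: str | None = None) -> list:
    """Trial-level windowed PLV with cell labels, per pair.

    Channel-resolved sessions are ROI-averaged (``roi`` required then).
    Output feeds :func:`duetibs.stats.permutation_test`.
    """
    grid = grid or WindowGrid()
    out = []
    for s in sessions:
        plv = sliding_plv(s.theta1, s.theta2, s.sfreq, s.times, grid,
                          ch_names=s.ch_names)
        values = plv.values
        if values.ndim == 3:
            if roi is None:
                raise ValueError("channel-resolved session needs a roi")
            values = roi_average(plv, roi)
        out.append((values, s.cells))
    return out


def surrogate_cluster_analysis(
    sessions: list[PhaseSession],
    config: PermutationConfig | None = None,
    grid: WindowGrid | None = None,
    seed: int | None = None,
    roi: str | None = None,
) -> dict:
    """Run the full PLV + cluster permutation pipeline on surrogate pairs."""
    surrogate = make_surrogate_dataset(sessions, seed=seed)
    return permutation_test(session_plv_data(surrogate, grid, roi), config)


# ---------------------------------------------------------------------------
# power confound
# ---------------------------------------------------------------------------

def power_confound_check(
    epochs_by_pair: list,
    band: str,
    window: tuple[float, float],
    roi: str = "GLOBAL",
) -> dict:
    """Paired t-tests on band power between conditions, per effect.

    ``epochs_by_pair``: one :class:`~duetibs.io.DyadEpochs` per pair.
    ``window`` is the data time range (s) of the significant PLV cluster.
    Returns per effect a dict with t, p, df over pairs.
    """
    cell_power = np.stack([
        band_power(ep, band, window, roi) for ep in epochs_by_pair
    ])                                          # (n_pairs, 4)
    report = {}
    for eff, (side_a, side_b) in _CELL_CONTRASTS.items():
        a = cell_power[:, side_a].mean(axis=1)
        b = cell_power[:, side_b].mean(axis=1)
        t, p, df = paired_t(a, b)
        report[eff] = {"t": t, "p": p, "df": df}
    return report
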