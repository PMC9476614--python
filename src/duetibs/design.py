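"""Trial design and trial timeline of the duet paradigm.

Each pair of pianists performs short two-phrase duets.  A 2 x 2 within-pair
factorial design crosses

* TEMPO: both players are cued to speed up or slow down for the second phrase
  (congruent) or receive opposite cues (incongruent);
* FAMILIARITY: the piece's other part was practiced by the partner (familiar)
  or not (unfamiliar).

Piece-to-familiarity assignment is counterbalanced: half of the pairs learn
pieces A and B bimanually (familiar) and C, D unimanually, the other half the
opposite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PIECES = ("A", "B", "C", "D")
#: Beats-per-minute of the second phrase for each cue direction.
PHRASE2_BPM = {"up": 150.0, "down": 96.0}
BASE_BPM = 120.0

#: Canonical ordering of the four design cells used throughout the package.
CELL_ORDER = (
    ("congruent", "familiar"),
    ("congruent", "unfamiliar"),
    ("incongruent", "familiar"),
    ("incongruent", "unfamiliar"),
)


def cell_index(tempo: str, familiarity: str) -> int:
    """Map (tempo_condition, familiarity) to the canonical cell id 0..3."""
    return CELL_ORDER.index((tempo, familiarity))


@dataclass(frozen=True)
class Timeline:
    """Event timing of one trial, in seconds from cue onset.

    Phrase 1 and the pause are played/kept at 120 bpm (beat period 0.5 s):
    the metronome counts 4 beats, each phrase and the pause span 8 beats.
    Phrase 2 runs at the cued tempo, ending after 8 beats: 14.2 s for the fast
    (150 bpm) and 16 s for the slow (96 bpm) instruction.
    """

    cue_onset: float = 0.0
    metronome_onset: float = 1.0
    phrase1_onset: float = 3.0
    pause_onset: float = 7.0
    phrase2_onset: float = 11.0
    beat_period: float = 60.0 / BASE_BPM

    def phrase2_end(self, bpm: float) -> float:
        return self.phrase2_onset + 8 * 60.0 / bpm

    def segment(self, t: float) -> str:
        """Name of the trial segment containing time ``t``."""
        if t < self.metronome_onset:
            return "cue"
        if t < self.phrase1_onset:
            return "metronome"
        if t < self.pause_onset:
            return "phrase1"
        if t < self.phrase2_onset:
            return "pause"
        return "phrase2"


#: Segment boundaries (s) shared by the simulators.
SEGMENT_EDGES = {
    "cue": (-1.0, 1.0),
    "metronome": (1.0, 3.0),
    "phrase1": (3.0, 7.0),
    "pause": (7.0, 11.0),
    "phrase2": (11.0, 16.0),
}

DESIGN_COLUMNS = [
    "pair", "trial", "piece", "familiarity",
    "instruction_p1", "instruction_p2", "tempo_condition",
    "phrase2_bpm_p1", "phrase2_bpm_p2",
]


def make_design(n_pairs: int, trials_per_cell: int, seed: int) -> pd.DataFrame:
    """Build the randomized trial schedule for all pairs.

    Within each TEMPO x FAMILIARITY cell the two cue patterns (up-up/down-down
    or up-down/down-up) and the two eligible pieces are balanced as evenly as
    ``trials_per_cell`` allows, then the trial order is shuffled per pair.

    Parameters
    ----------
    n_pairs
        Number of dyads; must be even so that piece counterbalancing
        (half the pairs learn A,B bimanually, half C,D) is exact.
    trials_per_cell
        Trials in each of the four cells for every pair (48 in the full
        paradigm, i.e. 192 trials per pair).
    seed
        Seeds the per-pair order shuffling; identical seeds give identical
        schedules.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if n_pairs % 2:
        raise ValueError(
            "n_pairs must be even: piece counterbalancing assigns half of the "
            "pairs to learn pieces A,B bimanually and half to learn C,D"
        )
    if trials_per_cell < 1:
        raise ValueError("trials_per_cell must be >= 1")

    rng = np.random.default_rng(seed)
    rows = []
    for pair in range(1, n_pairs + 1):
        # counterbalancing: odd pair ids learn A,B bimanually (familiar)
        familiar_pieces = ("A", "B") if pair % 2 else ("C", "D")
        unfamiliar_pieces = ("C", "D") if pair % 2 else ("A", "B")
        pair_rows = []
        for tempo, familiarity in CELL_ORDER:
            pieces = familiar_pieces if familiarity == "familiar" else unfamiliar_pieces
            patterns = (
                [("up", "up"), ("down", "down")] if tempo == "congruent"
                else [("up", "down"), ("down", "up")]
            )
            # balanced sub-assignment of cue pattern x piece within the cell
            combos = [(pat, pc) for pat in patterns for pc in pieces]
            for k in range(trials_per_cell):
                (i1, i2), piece = combos[k % len(combos)]
                pair_rows.append(
                    (pair, piece, familiarity, i1, i2, tempo,
                     PHRASE2_BPM[i1], PHRASE2_BPM[i2])
                )
        order = rng.permutation(len(pair_rows))
        for trial, j in enumerate(order, start=1):
            pr = pair_rows[j]
            rows.append((pr[0], trial) + pr[1:])

    df = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    return df


def validate_design(design: pd.DataFrame) -> None:
    """Check the TrialDesign invariants; raise ``ValueError`` on violation."""
    congruent = design["instruction_p1"] == design["instruction_p2"]
    if not ((design["tempo_condition"] == "congruent") == congruent).all():
        raise ValueError("tempo_condition inconsistent with cue instructions")
    for col in ("phrase2_bpm_p1", "phrase2_bpm_p2"):
        instr = design["instruction_p1" if col.endswith("p1") else "instruction_p2"]
        expected = instr.map(PHRASE2_BPM)
        if not (design[col] == expected).all():
            raise ValueError(f"{col} inconsistent with instruction")
    counts = design.groupby(["pair", "tempo_condition", "familiarity"]).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced TEMPO x FAMILIARITY cells")
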