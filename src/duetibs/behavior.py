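"""Behavioral synchrony and mutual-adaptation measures from keystrokes.

All measures operate on score-position-matched ("complementary") keystrokes
of the two players.  The sign convention for signed asynchronies is
player 1 minus player 2 (negative = player 1 early).  Normalization removes,
per pair, the across-trial mean signed asynchrony separately for each
keystroke position and piece, to account for metric position and key
spacing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scipy.stats import pearsonr

#: Clamp on |r| before the Fisher z-transform, keeping z finite.
R_CLAMP = 1.0 - 1e-10

#: Target phrase-2 inter-keystroke interval (s) per cue direction.
TARGET_IKI = {"up": 0.4, "down": 0.625}
BASE_IKI = 0.5


# ---------------------------------------------------------------------------
# trial validity
# ---------------------------------------------------------------------------

def validate_trial(stream1: pd.DataFrame, stream2: pd.DataFrame,
                   design_row, tol: float = 0.5) -> bool:
    """Keep a trial only if both players played correctly.

    A trial is valid when both players produced all 7 correct-pitch
    keystrokes in each phrase, and each player's mean phrase-2 IKI moved at
    least a fraction ``tol`` of the way from 500 ms toward the cued target
    IKI (400 ms for "up", 625 ms for "down") — a direction-plus-magnitude
    tempo-change criterion.
    """
    from .simulate import score_pitches

    t1 = stream1["trial"].unique()
    t2 = stream2["trial"].unique()
    if len(t1) != 1 or len(t2) != 1 or t1[0] != t2[0]:
        raise ValueError("streams belong to different trials")

    for stream, player, instr_col in (
        (stream1, 1, "instruction_p1"), (stream2, 2, "instruction_p2"),
    ):
        for phrase in (1, 2):
            sub = stream[stream["phrase"] == phrase].sort_values("position")
            if list(sub["position"]) != list(range(1, 8)):
                return False
            expected = score_pitches(design_row["piece"], player, phrase)
            if list(sub["pitch"]) != expected:
                return False
        instr = design_row[instr_col]
        ikis = np.diff(
            stream[stream["phrase"] == 2].sort_values("position")["onset_s"])
        progress = (ikis.mean() - BASE_IKI) / (TARGET_IKI[instr] - BASE_IKI)
        if progress < tol:
            return False
    return True


# ---------------------------------------------------------------------------
# asynchronies
# ---------------------------------------------------------------------------

def signed_asynchronies(stream1: pd.DataFrame, stream2: pd.DataFrame) -> pd.DataFrame:
    """Signed onset differences at score-matched positions.

    Returns one row per (trial, phrase, position) present in *both* streams,
    with ``asynchrony_s`` = onset(player 1) - onset(player 2).
    """
    key = ["trial", "phrase", "position"]
    merged = stream1.merge(stream2, on=key, suffixes=("_1", "_2"))
    if merged.empty:
        raise ValueError("no common score positions between the two streams")
    out = merged[key].copy()
    out["asynchrony_s"] = merged["onset_s_1"] - merged["onset_s_2"]
    if "piece_1" in merged:
        out["piece"] = merged["piece_1"]
    return out


def normalize_asynchronies(table: pd.DataFrame,
                           by=("piece", "phrase", "position")) -> pd.DataFrame:
    """Subtract the across-trial mean asynchrony per keystroke position and piece.

    Idempotent; after normalization every (position, piece) cell has
    across-trial mean zero.  The table must carry the grouping columns (a
    per-pair table; apply per pair when concatenated).
    """
    if table.empty:
        raise ValueError("empty asynchrony table")
    by = [c for c in by if c in table.columns]
    out = table.copy()
    out["asynchrony_s"] = table["asynchrony_s"] - table.groupby(
        by)["asynchrony_s"].transform("mean")
    return out


def phrase_half_accuracy(table: pd.DataFrame, half: str) -> float:
    """Mean absolute normalized asynchrony over one half of phrase 1.

    ``half='first'`` averages keystroke positions 1-3, ``'second'`` positions
    5-7; the central 4th keystroke is omitted.  Expects a (normalized)
    asynchrony table of one pair/condition subset; averaging over trials and
    positions is a plain mean of absolute values.
    """
    positions = {"first": (1, 2, 3), "second": (5, 6, 7)}
    if half not in positions:
        raise ValueError(f"unknown phrase half {half!r}; use 'first' or 'second'")
    sub = table[(table["phrase"] == 1)
                & table["position"].isin(positions[half])]
    if sub.empty:
        raise ValueError("no phrase-1 keystrokes in the requested half")
    return float(sub["asynchrony_s"].abs().mean())


# ---------------------------------------------------------------------------
# adaptation and planning-outcome measures
# ---------------------------------------------------------------------------

def lag0_adaptation(stream1: pd.DataFrame, stream2: pd.DataFrame) -> float:
    """Fisher-z of the zero-lag correlation of phrase-1 IKI series.

    More negative values indicate stronger mutual (compensatory) adaptation.
    Requires complete phrase-1 IKI series (6 intervals each) with nonzero
    variance; degenerate series raise ``ValueError`` so the trial can be
    flagged and excluded from averaging.
    """
    ikis = []
    for stream in (stream1, stream2):
        sub = stream[stream["phrase"] == 1].sort_values("position")
        iki = np.diff(sub["onset_s"].to_numpy())
        if iki.size < 3:
            raise ValueError("need at least 3 phrase-1 IKIs per player")
        ikis.append(iki)
    if len(ikis[0]) != len(ikis[1]):
        raise ValueError("phrase-1 IKI series differ in length")
    if np.std(ikis[0]) == 0 or np.std(ikis[1]) == 0:
        raise ValueError("zero-variance IKI series")
    r = float(pearsonr(ikis[0], ikis[1]).statistic)
    r = float(np.clip(r, -R_CLAMP, R_CLAMP))
    return float(np.arctanh(r))


def entry_asynchrony(stream1: pd.DataFrame, stream2: pd.DataFrame) -> float:
    """Absolute asynchrony (s) of the first keystroke after the pause."""
    onsets = []
    for stream in (stream1, stream2):
        sub = stream[(stream["phrase"] == 2) & (stream["position"] == 1)]
        if len(sub) != 1:
            raise ValueError("missing phrase-2 entry keystroke")
        onsets.append(float(sub["onset_s"].iloc[0]))
    return abs(onsets[0] - onsets[1])


def iki_difference_phrase2(stream1: pd.DataFrame, stream2: pd.DataFrame) -> float:
    """Mean absolute difference (s) between the players' phrase-2 IKIs.

    IKIs are matched by the score position of the interval's endpoint;
    computed over the intervals available in both streams.
    """
    series = []
    for stream in (stream1, stream2):
        sub = stream[stream["phrase"] == 2].sort_values("position")
        pos = sub["position"].to_numpy()
        onset = sub["onset_s"].to_numpy()
        # only use intervals between consecutive score positions
        good = np.diff(pos) == 1
        series.append(dict(zip(pos[1:][good], np.diff(onset)[good])))
    common = sorted(set(series[0]) & set(series[1]))
    if not common:
        raise ValueError("no common phrase-2 IKIs")
    return float(np.mean([abs(series[0][p] - series[1][p]) for p in common]))


# ---------------------------------------------------------------------------
# session-level tables
# ---------------------------------------------------------------------------

def split_players(session: pd.DataFrame, pair: int, trial: int):
    """Extract the two per-player streams of one trial from a session table."""
    sub = session[(session["pair"] == pair) & (session["trial"] == trial)]
    return (sub[sub["player"] == 1].copy(), sub[sub["player"] == 2].copy())


def trial_measures(session: pd.DataFrame, design: pd.DataFrame,
                   tol: float = 0.5) -> pd.DataFrame:
    """Per-trial behavioral measures for a whole session.

    Returns one row per valid trial: lag-0 adaptation z, mean absolute
    normalized asynchrony of the first and second phrase-1 halves, entry
    asynchrony and phrase-2 IKI difference, plus condition labels.  Trials
    failing validity or with degenerate IKI series get NaN in the affected
    column (``valid`` is False for excluded trials).
    """
    async_tables = []
    rows = []
    for _, drow in design.iterrows():
        s1, s2 = split_players(session, drow["pair"], drow["trial"])
        if s1.empty or s2.empty:
            continue
        valid = validate_trial(s1, s2, drow, tol=tol)
        rec = {
            "pair": drow["pair"], "trial": drow["trial"],
            "piece": drow["piece"], "familiarity": drow["familiarity"],
            "tempo_condition": drow["tempo_condition"], "valid": valid,
        }
        if valid:
            table = signed_asynchronies(s1, s2)
            table["pair"] = drow["pair"]
            async_tables.append(table)
            try:
                rec["adaptation_z"] = lag0_adaptation(s1, s2)
            except ValueError:
                rec["adaptation_z"] = np.nan
            try:
                rec["entry_asynchrony_s"] = entry_asynchrony(s1, s2)
            except ValueError:
                rec["entry_asynchrony_s"] = np.nan
            try:
                rec["iki_difference_s"] = iki_difference_phrase2(s1, s2)
            except ValueError:
                rec["iki_difference_s"] = np.nan
        rows.append(rec)
    measures = pd.DataFrame(rows)
    if not async_tables:
        return measures

    asyncs = pd.concat(async_tables, ignore_index=True)
    normalized = (
        asyncs.groupby("pair", group_keys=False)[asyncs.columns]
        .apply(normalize_asynchronies)
    )
    for half, col in (("first", "asynchrony_first_half_s"),
                      ("second", "asynchrony_second_half_s")):
        per_trial = (
            normalized[(normalized["phrase"] == 1)]
            .groupby(["pair", "trial"])
            .apply(lambda t, h=half: phrase_half_accuracy(t, h),
                   include_groups=False)
            .rename(col)
        )
        measures = measures.merge(per_trial.reset_index(),
                                  on=["pair", "trial"], how="left")
    return measures


def behavior_anova(measures: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """2 x 2 rmANOVA (TEMPO x FAMILIARITY) on a per-trial behavioral measure.

    Averages the measure into each pair's four design cells and reuses the
    within-pairs ANOVA of the statistics module.  Returns one row per effect
    with F, p and df.
    """
    from .design import cell_index
    from .stats import EFFECTS, rmanova_2x2

    valid = measures[measures["valid"]].dropna(subset=[outcome])
    cells = (
        valid.assign(cell=[
            cell_index(t, f) for t, f in
            zip(valid["tempo_condition"], valid["familiarity"])
        ])
        .pivot_table(index="pair", columns="cell", values=outcome)
    )
    if cells.isna().any().any() or cells.shape[1] != 4:
        raise ValueError("every pair needs data in all four design cells")
    F, p = rmanova_2x2(cells.to_numpy())
    n = len(cells)
    return pd.DataFrame({
        "outcome": outcome, "effect": list(EFFECTS),
        "F": [float(F[e]) for e in EFFECTS],
        "p": [float(p[e]) for e in EFFECTS],
        "df1": 1, "df2": n - 1,
    })


def condition_summary(measures: pd.DataFrame) -> pd.DataFrame:
    """Average the per-trial measures into the 2 x 2 design per pair."""
    valid = measures[measures["valid"]]
    value_cols = [c for c in valid.columns if c.endswith(("_z", "_s"))]
    return (
        valid.groupby(["pair", "tempo_condition", "familiarity"])[value_cols]
        .mean()
        .reset_index()
    )
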