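"""Behavioral synchrony measures: hand-computed oracles and invariances."""

import numpy as np
import pandas as pd
import pytest

from duetibs import (
    SimParams, entry_asynchrony, iki_difference_phrase2, lag0_adaptation,
    normalize_asynchronies, phrase_half_accuracy, signed_asynchronies,
    simulate_keystrokes, validate_trial,
)
from duetibs.behavior import R_CLAMP, trial_measures

from conftest import make_streams


# ---------------------------------------------------------------------------
# validity
# ---------------------------------------------------------------------------

class TestValidateTrial:
    def test_noise_free_trial_is_valid(self, quiet_trial):
        s1, s2, row = quiet_trial
        assert validate_trial(s1, s2, row) is True

    def test_missing_position_invalidates(self, quiet_trial):
        s1, s2, row = quiet_trial
        broken = s1[~((s1["phrase"] == 1) & (s1["position"] == 4))]
        assert validate_trial(broken, s2, row) is False

    def test_wrong_pitch_invalidates(self, quiet_trial):
        s1, s2, row = quiet_trial
        wrong = s1.copy()
        wrong.loc[wrong.index[0], "pitch"] += 1
        assert validate_trial(wrong, s2, row) is False

    def test_missed_tempo_change_invalidates(self, quiet_trial):
        """A player cued "up" whose phrase-2 IKIs stay at 500 ms fails."""
        s1, s2, row = quiet_trial
        flat = s1.copy()
        ph2 = flat["phrase"] == 2
        entry = flat.loc[ph2 & (flat["position"] == 1), "onset_s"].iloc[0]
        flat.loc[ph2, "onset_s"] = entry + 0.5 * (
            flat.loc[ph2, "position"] - 1)
        assert validate_trial(flat, s2, row) is False

    def test_mismatched_trials_error(self, quiet_trial):
        s1, s2, row = quiet_trial
        other = s2.copy()
        other["trial"] = 99
        with pytest.raises(ValueError, match="different trials"):
            validate_trial(s1, other, row)


# ---------------------------------------------------------------------------
# asynchronies
# ---------------------------------------------------------------------------

class TestSignedAsynchronies:
    def test_identical_streams_zero(self, quiet_trial):
        s1, _, _ = quiet_trial
        assert np.allclose(signed_asynchronies(s1, s1)["asynchrony_s"], 0.0)

    def test_constant_shift(self, quiet_trial):
        s1, _, _ = quiet_trial
        shifted = s1.copy()
        shifted["onset_s"] += 0.015
        table = signed_asynchronies(shifted, s1)
        assert np.allclose(table["asynchrony_s"], 0.015)

    def test_hand_built_case(self):
        s1, s2 = make_streams([1.00, 1.52, 2.01], [1.01, 1.50, 2.05])
        got = signed_asynchronies(s1, s2)["asynchrony_s"].to_numpy()
        assert got == pytest.approx([-0.01, 0.02, -0.04])

    def test_no_common_positions_error(self):
        s1, s2 = make_streams([1.0, 1.5], [1.0, 1.5])
        s2["position"] += 10
        with pytest.raises(ValueError, match="common"):
            signed_asynchronies(s1, s2)


class TestNormalization:
    @staticmethod
    def _table(values, position=1, piece="A"):
        return pd.DataFrame({
            "trial": np.arange(1, len(values) + 1), "phrase": 1,
            "position": position, "piece": piece,
            "asynchrony_s": np.asarray(values, float),
        })

    def test_hand_computed_mean_subtraction(self):
        out = normalize_asynchronies(self._table([0.010, -0.004]))
        assert out["asynchrony_s"].to_numpy() == pytest.approx([0.007, -0.007])

    def test_identical_values_become_zero(self):
        out = normalize_asynchronies(self._table([0.02, 0.02, 0.02]))
        assert np.allclose(out["asynchrony_s"], 0.0)

    def test_single_trial_cell_becomes_zero(self):
        out = normalize_asynchronies(self._table([0.33]))
        assert out["asynchrony_s"].iloc[0] == pytest.approx(0.0)

    def test_idempotent(self):
        table = pd.concat([self._table([0.01, -0.02, 0.005], position=p)
                           for p in (1, 2)], ignore_index=True)
        once = normalize_asynchronies(table)
        twice = normalize_asynchronies(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_cell_means_zero_per_position_and_piece(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "trial": np.repeat(np.arange(8), 6),
            "phrase": 1,
            "position": np.tile(np.arange(1, 7), 8),
            "piece": np.repeat(["A", "B"], 24),
            "asynchrony_s": rng.normal(0, 0.02, 48),
        })
        out = normalize_asynchronies(table)
        cell_means = out.groupby(["piece", "position"])["asynchrony_s"].mean()
        assert np.allclose(cell_means, 0.0, atol=1e-15)

    def test_empty_table_error(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_asynchronies(self._table([]).iloc[:0])


class TestPhraseHalves:
    @staticmethod
    def _table():
        return pd.DataFrame({
            "trial": np.repeat([1, 2], 7),
            "phrase": 1,
            "position": np.tile(np.arange(1, 8), 2),
            "asynchrony_s": [0.01, -0.02, 0.03, 0.99, 0.01, 0.01, -0.04,
                             0.02, 0.02, -0.02, -0.99, 0.0, -0.03, 0.03],
        })

    def test_hand_computed_halves(self):
        table = self._table()
        first = phrase_half_accuracy(table, "first")
        second = phrase_half_accuracy(table, "second")
        assert first == pytest.approx(np.mean([0.01, 0.02, 0.03, 0.02, 0.02, 0.02]))
        assert second == pytest.approx(np.mean([0.01, 0.01, 0.04, 0.0, 0.03, 0.03]))

    def test_fourth_keystroke_omitted(self):
        table = self._table()
        altered = table.copy()
        altered.loc[altered["position"] == 4, "asynchrony_s"] = 123.0
        for half in ("first", "second"):
            assert phrase_half_accuracy(altered, half) == \
                phrase_half_accuracy(table, half)

    def test_zero_data_zero_accuracy(self):
        table = self._table()
        table["asynchrony_s"] = 0.0
        assert phrase_half_accuracy(table, "first") == 0.0

    def test_unknown_half_label(self):
        with pytest.raises(ValueError, match="unknown phrase half"):
            phrase_half_accuracy(self._table(), "middle")


# ---------------------------------------------------------------------------
# adaptation and planning outcome
# ---------------------------------------------------------------------------

class TestLag0Adaptation:
    def test_affine_series_hits_clamp_ceiling(self, quiet_trial):
        """IKIs differing by a constant correlate at r=1 -> clamped z."""
        s1 = quiet_trial[0].copy()
        rng = np.random.default_rng(1)
        ph1 = s1["phrase"] == 1
        s1.loc[ph1, "onset_s"] += np.cumsum(rng.normal(0, 0.01, ph1.sum()))
        s2 = s1.copy()
        s2.loc[ph1, "onset_s"] += 0.05 * (s2.loc[ph1, "position"] - 1)
        z = lag0_adaptation(s1, s2)
        assert z == pytest.approx(np.arctanh(R_CLAMP))

    def test_matches_brute_force_pearson(self):
        iki1 = np.array([0.48, 0.52, 0.50, 0.47, 0.55, 0.49, 0.51])
        iki2 = np.array([0.51, 0.49, 0.52, 0.50, 0.46, 0.53, 0.48])
        s1, s2 = make_streams(1.0 + np.cumsum(iki1), 1.0 + np.cumsum(iki2))
        x, y = np.diff(np.cumsum(iki1)), np.diff(np.cumsum(iki2))
        r = np.corrcoef(x, y)[0, 1]
        assert lag0_adaptation(s1, s2) == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_independent_ikis_mean_z_near_zero(self):
        rng = np.random.default_rng(7)
        zs = []
        for _ in range(400):
            s1, s2 = make_streams(1 + np.cumsum(0.5 + rng.normal(0, 0.02, 7)),
                                  1 + np.cumsum(0.5 + rng.normal(0, 0.02, 7)))
            zs.append(lag0_adaptation(s1, s2))
        zs = np.array(zs)
        assert abs(zs.mean()) < 4 * zs.std(ddof=1) / np.sqrt(len(zs))

    def test_zero_variance_flagged(self, quiet_trial):
        s1, s2, _ = quiet_trial  # noise-free: constant IKIs
        with pytest.raises(ValueError, match="zero-variance"):
            lag0_adaptation(s1, s2)

    def test_stronger_adaptation_gives_more_negative_z(self):
        """Higher phase-correction gain -> more negative lag-0 correlation."""
        zs = {}
        for gain in (0.05, 0.5):
            params = SimParams(motor_noise_sigma=8.0, anticipation_bias=0.0,
                               adaptation_gain=gain, rng_seed=21)
            vals = []
            for trial in range(1, 301):
                row = pd.Series({
                    "pair": 1, "trial": trial, "piece": "A",
                    "familiarity": "familiar", "instruction_p1": "up",
                    "instruction_p2": "up", "tempo_condition": "congruent",
                })
                vals.append(lag0_adaptation(*simulate_keystrokes(row, params)))
            zs[gain] = np.mean(vals)
        assert zs[0.5] < zs[0.05]


class TestPlanningOutcome:
    def test_identical_entries_zero(self, quiet_trial):
        s1, _, _ = quiet_trial
        assert entry_asynchrony(s1, s1) == 0.0

    def test_entry_hand_arithmetic(self):
        s1, s2 = make_streams([11.00], [11.08], phrase=2)
        assert entry_asynchrony(s1, s2) == pytest.approx(0.08)

    def test_missing_entry_flagged(self, quiet_trial):
        s1, s2, _ = quiet_trial
        no_entry = s2[~((s2["phrase"] == 2) & (s2["position"] == 1))]
        with pytest.raises(ValueError, match="entry"):
            entry_asynchrony(s1, no_entry)

    def test_iki_difference_fast_vs_slow(self):
        """150 vs 96 bpm noise-free: |400 - 625| ms = 225 ms."""
        s1, s2 = make_streams(11 + 0.400 * np.arange(7),
                              11 + 0.625 * np.arange(7), phrase=2)
        assert iki_difference_phrase2(s1, s2) == pytest.approx(0.225)

    def test_identical_tempi_zero(self):
        s1, s2 = make_streams(11 + 0.4 * np.arange(7),
                              11.05 + 0.4 * np.arange(7), phrase=2)
        assert iki_difference_phrase2(s1, s2) == pytest.approx(0.0)

    def test_missing_keystroke_uses_common_ikis(self):
        s1, s2 = make_streams(11 + 0.4 * np.arange(7),
                              11 + 0.5 * np.arange(7), phrase=2)
        s2 = s2[s2["position"] != 4]  # drops IKIs ending at 4 and 5
        assert iki_difference_phrase2(s1, s2) == pytest.approx(0.1)


# ---------------------------------------------------------------------------
# invariances and session-level behavior
# ---------------------------------------------------------------------------

def test_player_swap_antisymmetry():
    rng = np.random.default_rng(3)
    s1, s2 = make_streams(3 + np.cumsum(0.5 + rng.normal(0, 0.02, 7)),
                          3 + np.cumsum(0.5 + rng.normal(0, 0.02, 7)))
    t12 = signed_asynchronies(s1, s2)["asynchrony_s"].to_numpy()
    t21 = signed_asynchronies(s2, s1)["asynchrony_s"].to_numpy()
    assert t12 == pytest.approx(-t21)
    assert lag0_adaptation(s1, s2) == pytest.approx(lag0_adaptation(s2, s1))
    p1, p2 = make_streams(11 + np.cumsum(0.4 + rng.normal(0, 0.01, 7)),
                          11 + np.cumsum(0.62 + rng.normal(0, 0.01, 7)),
                          phrase=2)
    assert iki_difference_phrase2(p1, p2) == iki_difference_phrase2(p2, p1)
    assert entry_asynchrony(p1, p2) == entry_asynchrony(p2, p1)


def test_fisher_z_monotone_in_r():
    rs = np.linspace(-0.99, 0.99, 21)
    zs = np.arctanh(rs)
    assert (np.diff(zs) > 0).all()


def test_behavior_anova_detects_tempo_effect():
    """The entry-asynchrony TEMPO effect reaches the 2x2 rmANOVA report."""
    from duetibs import SimParams, make_design, simulate_keystroke_session
    from duetibs.behavior import behavior_anova
    design = make_design(8, 6, seed=17)
    params = SimParams(motor_noise_sigma=8.0, anticipation_bias=0.8,
                       adaptation_gain=0.25, rng_seed=17)
    measures = trial_measures(simulate_keystroke_session(design, params),
                              design)
    report = behavior_anova(measures, "entry_asynchrony_s")
    by_effect = report.set_index("effect")
    assert by_effect.loc["TEMPO", "p"] < 0.01
    assert (by_effect["df2"] == 7).all()
    assert by_effect.loc["FAMILIARITY", "F"] < by_effect.loc["TEMPO", "F"]


def test_trial_measures_behavioral_condition_pattern():
    """Congruent trials have smaller entry asynchrony and IKI differences."""
    from duetibs import make_design, simulate_keystroke_session
    design = make_design(4, 6, seed=13)
    params = SimParams(motor_noise_sigma=8.0, anticipation_bias=0.8,
                       adaptation_gain=0.25, rng_seed=13)
    session = simulate_keystroke_session(design, params)
    measures = trial_measures(session, design)
    valid = measures[measures["valid"]]
    assert len(valid) > 0.9 * len(measures)
    by_tempo = valid.groupby("tempo_condition")[
        ["entry_asynchrony_s", "iki_difference_s"]].mean()
    assert by_tempo.loc["congruent", "entry_asynchrony_s"] < \
        by_tempo.loc["incongruent", "entry_asynchrony_s"]
    assert by_tempo.loc["congruent", "iki_difference_s"] < \
        by_tempo.loc["incongruent", "iki_difference_s"]
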