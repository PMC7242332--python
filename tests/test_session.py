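"""Session engine: schedules, timing, closed loop, QC, typing speed."""

import numpy as np
import pytest

import eogspeller as eg
from eogspeller.session import SessionRecord, TrialRecord
from eogspeller.speller import SpellerLayout
from eogspeller.synthetic import TrialPhases


class TestSchedule:
    def test_default_schedule_is_balanced_20(self):
        sched = eg.make_training_schedule(seed=0)
        assert len(sched) == 20
        assert sched.count("yes") == 10 and sched.count("no") == 10

    def test_seeded_order(self):
        assert eg.make_training_schedule(3) == eg.make_training_schedule(3)

    def test_parameterized_counts(self):
        assert len(eg.make_training_schedule(0, n_yes=5, n_no=5)) == 10


class TestTrainingSession:
    def test_20_trials_at_9s_last_3_minutes(self):
        sched = eg.make_training_schedule(0)
        source = eg.SyntheticEOGSource(seed=0)
        record, feats, labels, table = eg.run_training_session(sched, source)
        assert record.duration_s == pytest.approx(180.0)
        assert record.duration_min == pytest.approx(3.0)
        assert len(table) == 20 and len(feats) == 20

    def test_20s_trials_stay_under_7_minutes(self):
        phases = TrialPhases(baseline_s=3, stimulus_s=4, response_s=11,
                             feedback_s=2)
        assert phases.trial_s == 20.0
        sched = eg.make_training_schedule(0)
        source = eg.SyntheticEOGSource(phases=phases, seed=0)
        record, *_ = eg.run_training_session(sched, source, phases=phases)
        assert record.duration_min <= 7.0

    def test_neutral_feedback_logged(self):
        sched = eg.make_training_schedule(0, n_yes=5, n_no=5)
        record, *_ = eg.run_training_session(sched, eg.SyntheticEOGSource(seed=1))
        assert all(t.payload == "Danke" for t in record.trials)
        assert all(t.predicted_label is None for t in record.trials)

    def test_exhausted_source_flags_partial_record(self):
        sched = eg.make_training_schedule(0)
        source = eg.SyntheticEOGSource(seed=0, n_max=7)
        record, feats, *_ = eg.run_training_session(sched, source)
        assert not record.complete and len(feats) == 7


class TestFeedbackSession:
    def test_high_amplitude_accuracy_over_seeds(self, strong_model):
        accs = []
        for s in range(10):
            record = eg.run_feedback_session(
                strong_model, eg.make_training_schedule(s),
                eg.SyntheticEOGSource(amplitude=200.0, seed=50 + s))
            accs.append(eg.session_accuracy(record))
        assert np.mean(accs) >= 0.9

    def test_one_prediction_per_trial(self, strong_model):
        record = eg.run_feedback_session(
            strong_model, eg.make_training_schedule(1),
            eg.SyntheticEOGSource(seed=1))
        assert len(record.trials) == 20
        assert all(t.predicted_label in ("yes", "no") for t in record.trials)

    def test_near_zero_amplitude_near_chance(self, strong_model):
        """A strong model on (near) signal-free trials: accuracy falls in
        the pooled binomial band around 0.5."""
        correct = total = 0
        for s in range(5):
            record = eg.run_feedback_session(
                strong_model, eg.make_training_schedule(s),
                eg.SyntheticEOGSource(amplitude=0.0, seed=70 + s))
            for t in record.trials:
                correct += t.predicted_label == t.true_label
                total += 1
        from scipy.stats import binom
        lo, hi = binom.ppf([0.025, 0.975], total, 0.5)
        assert lo <= correct <= hi

    def test_unvalidated_model_rejected(self, strong_model):
        import dataclasses
        bad = dataclasses.replace(strong_model, cv_accuracy=0.5)
        assert not bad.validated
        with pytest.raises(ValueError):
            eg.run_feedback_session(bad, eg.make_training_schedule(0),
                                    eg.SyntheticEOGSource(seed=0))


def oracle_question_count(layout, target):
    """Independent hand-trace of the error-free walk: for each character,
    skip preceding sectors (1 question each), double-yes the sector,
    skip preceding letters, double-yes the letter; then decline every
    sector and double-yes the quit prompt."""
    q = 0
    for ch in target:
        si, li = layout.locate(ch)
        q += si + 2 + li + 2
    return q + len(layout.sectors) + 2


class TestSpellingSession:
    def test_error_free_copy_matches_trace_oracle(self, layout):
        user = eg.SimulatedUser("ICH BIN", layout)
        rec = eg.run_spelling_session(layout, user, mode="copy",
                                      target="ICH BIN")
        assert rec.final_string == "ICH BIN"
        assert len(rec.trials) == oracle_question_count(layout, "ICH BIN")

    def test_word_prediction_completes_target_with_trailing_space(
            self, layout, corpus_model):
        user = eg.SimulatedUser("ICH BIN", layout)
        rec = eg.run_spelling_session(layout, user, mode="copy",
                                      target="ICH BIN",
                                      ngram_model=corpus_model)
        assert rec.final_string == "ICH BIN "
        assert len(rec.trials) < oracle_question_count(layout, "ICH BIN")

    def test_immediate_quit_gives_empty_string(self, layout):
        answers = ["no"] * len(layout.sectors) + ["yes", "yes"]
        rec = eg.replay_spelling_session(layout, answers)
        assert rec.final_string == "" and rec.complete
        assert len(rec.trials) == len(layout.sectors) + 2

    def test_copy_mode_requires_target(self, layout):
        with pytest.raises(ValueError):
            eg.run_spelling_session(layout, None, mode="copy")

    def test_question_limit_flags_incomplete(self, layout):
        user = eg.SimulatedUser("XYZ XYZ", layout)
        rec = eg.run_spelling_session(layout, user, mode="copy", target="XYZ XYZ",
                                      question_limit=5)
        assert not rec.complete and len(rec.trials) == 5

    def test_10pct_errors_still_reach_target_mostly(self, layout, corpus_model):
        """With a 10% answer-error rate and backspace corrections, the
        target is reached in >= 80% of seeded runs."""
        target = "ICH BIN"
        ok = 0
        n = 100
        for s in range(n):
            user = eg.SimulatedUser(target, layout, error_rate=0.10, seed=s)
            rec = eg.run_spelling_session(layout, user, mode="copy",
                                          target=target,
                                          ngram_model=corpus_model)
            ok += rec.final_string.rstrip() == target
        assert ok >= 0.8 * n

    def test_eog_answer_channel_spells_through_classifier(self, strong_model,
                                                          layout, corpus_model):
        user = eg.SimulatedUser("JA", layout)
        channel = eg.EOGAnswerChannel(user, strong_model,
                                      eg.SyntheticEOGSource(amplitude=200.0,
                                                            seed=5))
        rec = eg.run_spelling_session(layout, channel, mode="copy", target="JA",
                                      ngram_model=corpus_model)
        assert rec.final_string.rstrip() == "JA"


class TestSessionQC:
    def _spelling_record(self, n_trials=20, answers=("yes", "no"),
                         n_letters=3, **flags):
        trials = [TrialRecord(question_kind="sector",
                              predicted_label=answers[i % len(answers)])
                  for i in range(n_trials)]
        return SessionRecord(session_type="copy_spelling", trials=trials,
                             n_letters_selected=n_letters, **flags)

    def test_rules_apply_in_order(self):
        cases = [
            (self._spelling_record(code_error=True), "code_error"),
            (self._spelling_record(noisy_signal=True), "noisy_signal"),
            (self._spelling_record(n_trials=14), "terminated_before_15_trials"),
            (self._spelling_record(n_letters=0), "no_letter_selected"),
            (self._spelling_record(answers=("yes",)), "single_class_answers"),
            (self._spelling_record(answers=("no",)), "single_class_answers"),
        ]
        for record, reason in cases:
            included, why = eg.session_qc(record)
            assert not included and why == reason

    def test_first_matching_rule_wins(self):
        record = self._spelling_record(n_trials=10, code_error=True)
        assert eg.session_qc(record) == (False, "code_error")

    def test_clean_record_included(self):
        assert eg.session_qc(self._spelling_record()) == (True, None)


class TestTheoreticalTypingSpeed:
    def test_single_letter_single_sector_hand_trace(self):
        """1 sector, 1 letter, 9 s trials: double-yes sector + double-yes
        letter = 4 questions -> 60*1/(4*9) = 1.67 char/min."""
        toy = SpellerLayout(sectors=(("A",),), special_sector=None)
        speed = eg.theoretical_typing_speed(toy, "A", trial_seconds=9.0)
        assert speed == pytest.approx(60 / 36, abs=1e-9)

    def test_prediction_speeds_up_corpus_dominant_sentence(self, layout,
                                                           corpus_model):
        with_pred = eg.theoretical_typing_speed(layout, "ICH BIN", 9.0,
                                                corpus_model)
        without = eg.theoretical_typing_speed(layout, "ICH BIN", 9.0, None)
        assert with_pred > without

    def test_doubling_trial_time_halves_speed(self, layout):
        v9 = eg.theoretical_typing_speed(layout, "HALLO", 9.0)
        v18 = eg.theoretical_typing_speed(layout, "HALLO", 18.0)
        assert v9 == pytest.approx(2 * v18)

    def test_unspellable_character_rejected(self, layout):
        with pytest.raises(ValueError):
            eg.theoretical_typing_speed(layout, "A1", 9.0)

    def test_nonpositive_duration_rejected(self, layout):
        with pytest.raises(ValueError):
            eg.theoretical_typing_speed(layout, "A", 0.0)


def test_session_record_json_roundtrip(tmp_path, layout):
    user = eg.SimulatedUser("AB", layout)
    rec = eg.run_spelling_session(layout, user, mode="copy", target="AB")
    rec.to_json(tmp_path / "log.json")
    import json
    payload = json.loads((tmp_path / "log.json").read_text())
    assert payload["final_string"] == rec.final_string
    assert len(payload["trials"]) == len(rec.trials)
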