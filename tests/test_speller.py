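"""Speller FSM: scanning, single-no/double-yes, string editing, replay."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eogspeller as eg
from eogspeller.speller import (BACKSPACE, DELETE_WORD, SPACE, SpellerLayout,
                                SpellerState, apply_answer, apply_character,
                                next_question, spell_feedback)

TOY = SpellerLayout(sectors=(("A", "B"), ("C", SPACE)), special_sector=1)


def walk(layout, answers, state=None, predictor=None):
    """Apply an answer sequence; return (state, all events)."""
    state = state or SpellerState()
    events = []
    for a in answers:
        state, ev = apply_answer(state, layout, a, predictor)
        events.extend(ev)
    return state, events


class TestLayout:
    def test_special_characters_must_live_in_special_sector(self):
        with pytest.raises(ValueError):
            SpellerLayout(sectors=((SPACE, "A"), ("B",)), special_sector=1)

    def test_duplicate_characters_rejected(self):
        with pytest.raises(ValueError):
            SpellerLayout(sectors=(("A", "B"), ("B",)), special_sector=None)

    def test_default_layout_covers_the_alphabet(self, layout):
        assert layout.alphabet == set("ABCDEFGHIJKLMNOPQRSTUVWXYZ ")
        assert DELETE_WORD in layout.sectors[layout.special_sector]

    def test_roundtrip_json(self, layout, tmp_path):
        layout.to_json(tmp_path / "l.json")
        assert SpellerLayout.from_file(tmp_path / "l.json") == layout


class TestQuestions:
    def test_fresh_state_asks_sector_zero(self):
        q = next_question(SpellerState(), TOY)
        assert (q.kind, q.payload) == ("sector", 0)

    def test_question_is_stable_without_state_change(self):
        s = SpellerState()
        assert next_question(s, TOY) == next_question(s, TOY)

    def test_confirmed_sector_leads_to_first_letter(self):
        s, _ = walk(TOY, ["yes", "yes"])
        q = next_question(s, TOY)
        assert (q.kind, q.payload) == ("letter", "A")

    def test_declining_all_sectors_reaches_quit_prompt(self):
        s, _ = walk(TOY, ["no", "no"])
        assert next_question(s, TOY).kind == "quit"

    def test_finished_state_rejected(self):
        s, _ = walk(TOY, ["no", "no", "yes", "yes"])
        assert s.finished
        with pytest.raises(ValueError):
            next_question(s, TOY)


class TestTransitions:
    def test_single_no_advances_sector(self):
        s, _ = walk(TOY, ["no"])
        assert (s.level, s.cursor) == ("sector_scan", 1)

    def test_unconfirmed_yes_advances_like_no(self):
        s, _ = walk(TOY, ["yes", "no"])
        assert (s.level, s.cursor) == ("sector_scan", 1)
        assert not s.awaiting_confirmation

    def test_no_selection_from_single_yes(self):
        """A lone 'yes' never selects: confirmation is always required."""
        s, events = walk(TOY, ["yes"])
        assert s.awaiting_confirmation and events == []
        # a single yes inside the letter scan selects nothing either
        s2, events2 = walk(TOY, ["yes", "yes", "yes"])
        assert s2.current_string == ""
        assert all(e.kind != "selected_char" for e in events2)

    def test_double_yes_selects_letter(self):
        s, events = walk(TOY, ["yes", "yes", "yes", "yes"])
        assert s.current_string == "A"
        assert any(e.kind == "selected_char" for e in events)

    def test_declining_all_letters_reaches_exit_prompt(self):
        s, _ = walk(TOY, ["yes", "yes", "no", "no"])
        assert next_question(s, TOY).kind == "exit-sector"

    def test_exit_prompt_no_restarts_letters_from_first(self):
        s, _ = walk(TOY, ["yes", "yes", "no", "no", "no"])
        assert (s.level, s.cursor) == ("letter_scan", 0)

    def test_confirmed_exit_resumes_from_next_sector(self):
        s, _ = walk(TOY, ["yes", "yes", "no", "no", "yes", "yes"])
        assert (s.level, s.cursor) == ("sector_scan", 1)

    def test_confirmed_exit_from_last_sector_asks_quit(self):
        s, _ = walk(TOY, ["no", "yes", "yes", "no", "no", "yes", "yes"])
        assert s.level == "quit_prompt"

    def test_quit_prompt_no_restarts_sector_scan(self):
        s, _ = walk(TOY, ["no", "no", "no"])
        assert (s.level, s.cursor) == ("sector_scan", 0)

    def test_confirmed_quit_finishes(self):
        s, events = walk(TOY, ["no", "no", "yes", "yes"])
        assert s.finished
        assert any(e.kind == "quit" for e in events)


class TestApplyCharacter:
    @pytest.mark.parametrize("current,char,expected", [
        ("HALL", BACKSPACE, "HAL"),
        ("", BACKSPACE, ""),
        ("ICH BIN", DELETE_WORD, "ICH "),
        ("ICH BIN ", DELETE_WORD, "ICH "),
        ("BIN", DELETE_WORD, ""),
        ("", DELETE_WORD, ""),
        ("AB", SPACE, "AB "),
        ("AB", "C", "ABC"),
    ])
    def test_editing_rules(self, current, char, expected):
        assert apply_character(current, char) == expected


class TestSpellFeedback:
    def test_incomplete_trailing_word_is_spelled(self):
        fb = spell_feedback("ICH B")
        assert fb.words == ("ICH",) and fb.spelled == ("B",)

    def test_trailing_space_means_complete(self):
        fb = spell_feedback("ICH ")
        assert fb.words == ("ICH",) and fb.spelled == ()

    def test_empty_string(self):
        fb = spell_feedback("")
        assert fb.words == () and fb.spelled == ()


class TestWordProposal:
    def test_accept_replaces_prefix_with_word_and_space(self):
        s = SpellerState(current_string="ICH BI")
        s2 = eg.accept_word_proposal(s, "BIN")
        assert s2.current_string == "ICH BIN "

    def test_accept_on_empty_prefix_appends(self):
        s = SpellerState(current_string="ICH ")
        assert eg.accept_word_proposal(s, "BIN").current_string == "ICH BIN "

    def test_missing_proposal_rejected(self):
        with pytest.raises(ValueError):
            eg.accept_word_proposal(SpellerState(), None)

    def test_rejected_proposal_restarts_sector_scan(self, toy_model):
        predictor = lambda s: eg.propose(toy_model, s)
        # select 'B' (sector 0, letter B): predictor proposes a word
        s, events = walk(TOY, ["yes", "yes", "no", "yes", "yes"],
                         predictor=predictor)
        assert s.level == "word_proposal"
        before = s.current_string
        s, events = walk(TOY, ["no"], state=s, predictor=predictor)
        assert s.current_string == before
        assert (s.level, s.cursor) == ("sector_scan", 0)
        assert any(e.kind == "word_rejected" for e in events)

    def test_confirmed_proposal_updates_string(self, toy_model):
        predictor = lambda s: eg.propose(toy_model, s)
        s, _ = walk(TOY, ["yes", "yes", "no", "yes", "yes"], predictor=predictor)
        assert s.proposed_word == "BIN"  # only b-word in the toy corpus
        s, events = walk(TOY, ["yes", "yes"], state=s, predictor=predictor)
        assert s.current_string == "BIN "
        assert any(e.kind == "word_accepted" for e in events)


@given(st.lists(st.sampled_from(["yes", "no"]), max_size=60))
@settings(max_examples=200, deadline=None)
def test_transition_is_pure_and_total(answers):
    """Any yes/no sequence is accepted until quit; replaying it yields an
    identical state (pure transition function)."""
    def run():
        s = SpellerState()
        for a in answers:
            if s.finished:
                break
            s, _ = apply_answer(s, TOY, a)
        return s

    assert run() == run()


def test_replay_of_logged_answers_reproduces_string(layout, corpus_model):
    user = eg.SimulatedUser("HALLO DU", layout, error_rate=0.2, seed=3)
    rec = eg.run_spelling_session(layout, user, mode="copy", target="HALLO DU",
                                  ngram_model=corpus_model)
    answers = [t.predicted_label for t in rec.trials]
    replay = eg.replay_spelling_session(layout, answers,
                                        ngram_model=corpus_model)
    assert replay.final_string == rec.final_string
    assert len(replay.trials) == len(rec.trials)


def test_single_wrong_no_still_reaches_target(layout):
    """One erroneous 'no' (skipping the needed sector) only delays the
    walk: scanning wraps around and the target is still reached."""

    class OneError:
        def __init__(self):
            self.user = eg.SimulatedUser("AB", layout)
            self.fired = False

        def answer(self, question, state):
            ans = self.user.answer(question, state)
            if not self.fired and ans == "yes":
                self.fired = True
                return "no"
            return ans

    rec = eg.run_spelling_session(layout, OneError(), mode="copy", target="AB")
    assert rec.final_string.rstrip() == "AB"
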