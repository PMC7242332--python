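"""Auditory sector-scanning speller with single-no/double-yes selection.

Letters are grouped in ordered sectors, plus one special sector holding
"space", "backspace" and optionally "delete the word".  Every item is
offered auditorily as a yes/no question.  A single "no" skips to the next
item; a "yes" re-asks the same item as a confirmation and only a second
"yes" selects it (guarding against false positives).  Declining every
sector leads to a quit prompt; declining every letter of a sector leads
to an exit-sector prompt.  After a selected letter the word predictor may
interject a word proposal, confirmed the same way.

The transition function is pure: ``apply_answer(state, answer)`` maps an
immutable state and an answer to a new state plus emitted events, so a
logged answer sequence replays to an identical final string.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Optional

import yaml

YES, NO = "yes", "no"

SPACE = "SPACE"
BACKSPACE = "BACKSPACE"
DELETE_WORD = "DELETE_WORD"
SPECIAL_CHARS = (SPACE, BACKSPACE, DELETE_WORD)

Level = Literal["sector_scan", "letter_scan", "word_proposal",
                "quit_prompt", "exit_prompt"]

#: Optional word predictor: current string -> proposed word or None.
Predictor = Optional[Callable[[str], Optional[str]]]


# ----------------------------------------------------------------------
# layout
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SpellerLayout:
    """Ordered sectors of characters with at most one special sector.

    ``sectors`` is a tuple of tuples of character tokens: single letters
    A-Z plus the special tokens SPACE, BACKSPACE, DELETE_WORD, which must
    all live in the sector at index ``special_sector``.  The special
    sector must contain at least SPACE (it may also hold letters, as in
    small test layouts); ``special_sector=None`` builds a letters-only
    layout with no special characters.
    """

    sectors: tuple[tuple[str, ...], ...]
    special_sector: int | None

    def __post_init__(self) -> None:
        if not self.sectors:
            raise ValueError("layout needs at least one sector")
        if self.special_sector is not None and not (
                0 <= self.special_sector < len(self.sectors)):
            raise ValueError("special_sector index out of range")
        seen: set[str] = set()
        for i, sector in enumerate(self.sectors):
            if not sector:
                raise ValueError(f"sector {i} is empty")
            for ch in sector:
                if ch in seen:
                    raise ValueError(f"duplicate character {ch!r} in layout")
                seen.add(ch)
                if ch in SPECIAL_CHARS:
                    if i != self.special_sector:
                        raise ValueError(
                            f"special character {ch!r} outside the special sector"
                        )
                elif not (len(ch) == 1 and "A" <= ch <= "Z"):
                    raise ValueError(f"invalid character token {ch!r}")
        if self.special_sector is not None:
            if SPACE not in self.sectors[self.special_sector]:
                raise ValueError("special sector must contain SPACE")

    @property
    def alphabet(self) -> set[str]:
        """Spellable characters: the letters, plus ' ' when the layout
        offers a SPACE key."""
        letters = {ch for sector in self.sectors for ch in sector
                   if ch not in SPECIAL_CHARS}
        has_space = any(SPACE in sector for sector in self.sectors)
        return letters | ({" "} if has_space else set())

    def locate(self, char: str) -> tuple[int, int]:
        """(sector index, letter index) of a character token; space may be
        given as ' ' or SPACE."""
        token = SPACE if char == " " else char
        for i, sector in enumerate(self.sectors):
            if token in sector:
                return i, sector.index(token)
        raise KeyError(f"character {char!r} not in layout")

    @classmethod
    def from_dict(cls, payload: dict) -> "SpellerLayout":
        sectors = tuple(tuple(str(c).upper() for c in s) for s in payload["sectors"])
        special = payload.get("special_sector")
        return cls(sectors=sectors,
                   special_sector=None if special is None else int(special))

    @classmethod
    def from_file(cls, path: str | Path) -> "SpellerLayout":
        """Load a layout from JSON or YAML (JSON being valid YAML)."""
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"sectors": [list(s) for s in self.sectors],
             "special_sector": self.special_sector}, indent=1))


def default_layout() -> SpellerLayout:
    """The bundled 4-sector alphabetic example layout."""
    path = Path(__file__).parent / "data" / "default_layout.json"
    return SpellerLayout.from_file(path)


# ----------------------------------------------------------------------
# state, questions, events
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SpellerState:
    """Immutable speller state; advance it with :func:`apply_answer`."""

    current_string: str = ""
    level: Level = "sector_scan"
    cursor: int = 0
    sector: int | None = None          # sector being letter-scanned
    awaiting_confirmation: bool = False
    proposed_word: str | None = None
    finished: bool = False


@dataclass(frozen=True)
class Question:
    """One auditory yes/no question."""

    kind: Literal["sector", "letter", "word", "quit", "exit-sector"]
    payload: object = None


@dataclass(frozen=True)
class Event:
    """Something the speller did in response to a confirmed answer."""

    kind: str
    payload: object = None


def next_question(state: SpellerState, layout: SpellerLayout) -> Question:
    """The question the speller asks in ``state`` (pure; re-asking without
    a state change yields the same question)."""
    if state.finished:
        raise ValueError("speller already finished")
    if state.level == "sector_scan":
        return Question("sector", state.cursor)
    if state.level == "letter_scan":
        assert state.sector is not None
        return Question("letter", layout.sectors[state.sector][state.cursor])
    if state.level == "word_proposal":
        return Question("word", state.proposed_word)
    if state.level == "quit_prompt":
        return Question("quit")
    if state.level == "exit_prompt":
        return Question("exit-sector", state.sector)
    raise AssertionError(f"unknown level {state.level}")


# ----------------------------------------------------------------------
# string editing
# ----------------------------------------------------------------------

def apply_character(current: str, char: str) -> str:
    """Apply one confirmed character selection to the current string.

    Letters and SPACE append; BACKSPACE removes the last character (no-op
    on an empty string); DELETE_WORD removes the trailing (partial or
    complete) word together with its trailing space, leaving any
    preceding words and their separating space intact.
    """
    if char == SPACE or char == " ":
        return current + " "
    if char == BACKSPACE:
        return current[:-1]
    if char == DELETE_WORD:
        if not current:
            return current
        trimmed = current[:-1] if current.endswith(" ") else current
        cut = trimmed.rfind(" ")
        return trimmed[: cut + 1] if cut >= 0 else ""
    return current + char


@dataclass(frozen=True)
class Feedback:
    """Auditory string feedback: completed words are read out verbatim,
    the trailing incomplete word is spelled letter by letter."""

    words: tuple[str, ...]
    spelled: tuple[str, ...]


def spell_feedback(current: str) -> Feedback:
    parts = current.split(" ")
    complete = tuple(p for p in parts[:-1] if p)
    trailing = parts[-1]
    return Feedback(words=complete, spelled=tuple(trailing))


def accept_word_proposal(state: SpellerState, word: str) -> SpellerState:
    """Replace the trailing incomplete prefix with ``word`` plus a space."""
    if word is None:
        raise ValueError("no word proposed")
    cut = state.current_string.rfind(" ")
    stem = state.current_string[: cut + 1] if cut >= 0 else ""
    return replace(state, current_string=stem + word + " ")


# ----------------------------------------------------------------------
# transition function
# ----------------------------------------------------------------------

def _advance_sector(state: SpellerState, layout: SpellerLayout) -> SpellerState:
    nxt = state.cursor + 1
    if nxt >= len(layout.sectors):
        return replace(state, level="quit_prompt", cursor=0,
                       awaiting_confirmation=False)
    return replace(state, cursor=nxt, awaiting_confirmation=False)


def _advance_letter(state: SpellerState, layout: SpellerLayout) -> SpellerState:
    assert state.sector is not None
    nxt = state.cursor + 1
    if nxt >= len(layout.sectors[state.sector]):
        return replace(state, level="exit_prompt", cursor=0,
                       awaiting_confirmation=False)
    return replace(state, cursor=nxt, awaiting_confirmation=False)


def _restart(state: SpellerState) -> SpellerState:
    return replace(state, level="sector_scan", cursor=0, sector=None,
                   awaiting_confirmation=False, proposed_word=None)


def _after_selection(state: SpellerState, char: str,
                     predictor: Predictor) -> tuple[SpellerState, list[Event]]:
    """Shared tail of a confirmed character selection: update the string,
    emit feedback, consult the word predictor."""
    new_string = apply_character(state.current_string, char)
    events = [Event("selected_char", char),
              Event("string_feedback", spell_feedback(new_string))]
    state = replace(state, current_string=new_string)
    proposal = None
    if predictor is not None and char not in (BACKSPACE, DELETE_WORD):
        proposal = predictor(new_string)
    if proposal:
        state = replace(state, level="word_proposal", proposed_word=proposal,
                        cursor=0, sector=None, awaiting_confirmation=False)
        events.append(Event("word_proposed", proposal))
    else:
        state = _restart(state)
    return state, events


def apply_answer(state: SpellerState, layout: SpellerLayout, answer: str,
                 predictor: Predictor = None) -> tuple[SpellerState, list[Event]]:
    """Advance the speller by one answered question.

    Pure transition: (state, answer) fully determines the result.  An
    unconfirmed "yes" (yes then no) is treated as a non-selection and
    scanning advances past the item; for prompts it counts as a "no".
    Returns the new state and the events emitted by the transition.
    """
    if answer not in (YES, NO):
        raise ValueError(f"answer must be 'yes' or 'no', got {answer!r}")
    if state.finished:
        raise ValueError("speller already finished")
    yes = answer == YES

    if state.level == "sector_scan":
        if not state.awaiting_confirmation:
            if yes:
                return replace(state, awaiting_confirmation=True), []
            return _advance_sector(state, layout), []
        if yes:  # confirmed: enter the sector
            new = replace(state, level="letter_scan", sector=state.cursor,
                          cursor=0, awaiting_confirmation=False)
            return new, [Event("selected_sector", state.cursor)]
        return _advance_sector(state, layout), []

    if state.level == "letter_scan":
        if not state.awaiting_confirmation:
            if yes:
                return replace(state, awaiting_confirmation=True), []
            return _advance_letter(state, layout), []
        if yes:  # confirmed character selection
            assert state.sector is not None
            char = layout.sectors[state.sector][state.cursor]
            return _after_selection(
                replace(state, awaiting_confirmation=False), char, predictor)
        return _advance_letter(state, layout), []

    if state.level == "exit_prompt":
        if not state.awaiting_confirmation:
            if yes:
                return replace(state, awaiting_confirmation=True), []
            return replace(state, level="letter_scan", cursor=0,
                           awaiting_confirmation=False), []
        if yes:  # confirmed exit: resume sector scan after the current one
            assert state.sector is not None
            resumed = replace(state, level="sector_scan", cursor=state.sector,
                              sector=None, awaiting_confirmation=False)
            return _advance_sector(resumed, layout), [Event("exited_sector",
                                                            state.sector)]
        return replace(state, level="letter_scan", cursor=0,
                       awaiting_confirmation=False), []

    if state.level == "quit_prompt":
        if not state.awaiting_confirmation:
            if yes:
                return replace(state, awaiting_confirmation=True), []
            return _restart(state), []
        if yes:
            return replace(state, finished=True,
                           awaiting_confirmation=False), [Event("quit")]
        return _restart(state), []

    if state.level == "word_proposal":
        if not state.awaiting_confirmation:
            if yes:
                return replace(state, awaiting_confirmation=True), []
            return _restart(state), [Event("word_rejected", state.proposed_word)]
        if yes:
            word = state.proposed_word
            accepted = accept_word_proposal(
                replace(state, awaiting_confirmation=False), word)
            events = [Event("word_accepted", word),
                      Event("string_feedback",
                            spell_feedback(accepted.current_string))]
            return _restart(accepted), events
        return _restart(state), [Event("word_rejected", state.proposed_word)]

    raise AssertionError(f"unknown level {state.level}")
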