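"""Session orchestration: training, feedback and spelling sessions.

Four session types mirror the clinical protocol.  Training and feedback
sessions present 20 known-answer questions (10 yes / 10 no, random
order); training collects features without classifying (neutral "Danke"
feedback), feedback classifies each trial online and announces the
prediction.  Copy and free spelling sessions run the speller state
machine in closed loop: each speller question is answered by an answer
source — a simulated user (optionally error-injecting), a simulated user
routed through synthetic EOG + the classifier, or a logged answer
sequence — until a confirmed quit or the question limit.

Each trial occupies baseline + stimulus + response + feedback phases; the
default phase split gives the 9 s minimum trial, and per-patient response
windows stretch trials up to 20 s, so a 20-question session lasts 3 to
about 6.7 minutes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from . import speller as sp
from .classification import TrainedModel, classify_trial
from .prediction import NGramModel, propose
from .signals import (DEFAULT_FEATURE_CHANNELS, FeatureVector, trial_features)
from .synthetic import NO, YES, TrialPhases, TrialSpec, generate_trial

SESSION_TYPES = ("training", "feedback", "copy_spelling", "free_spelling")

DEFAULT_QUESTION_LIMIT = 500


# ----------------------------------------------------------------------
# records
# ----------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One answered question within a session."""

    question_kind: str
    payload: object = None
    true_label: str | None = None
    predicted_label: str | None = None
    duration_s: float = 9.0
    resulting_string: str | None = None


@dataclass
class SessionRecord:
    """Outcome of one session of any type."""

    session_type: str
    trials: list[TrialRecord] = field(default_factory=list)
    final_string: str = ""
    target_string: str | None = None
    code_error: bool = False
    noisy_signal: bool = False
    complete: bool = True
    n_letters_selected: int = 0

    def __post_init__(self) -> None:
        if self.session_type not in SESSION_TYPES:
            raise ValueError(f"unknown session type {self.session_type!r}")

    @property
    def duration_s(self) -> float:
        return float(sum(t.duration_s for t in self.trials))

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["duration_s"] = self.duration_s
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


# ----------------------------------------------------------------------
# schedules and EOG sources
# ----------------------------------------------------------------------

def make_training_schedule(seed: int = 0, n_yes: int = 10,
                           n_no: int = 10) -> list[str]:
    """Known-answer question schedule: n_yes + n_no labels in seeded
    random order (default the 10+10 training/feedback session)."""
    if n_yes < 0 or n_no < 0:
        raise ValueError("question counts must be >= 0")
    labels = [YES] * n_yes + [NO] * n_no
    np.random.default_rng(seed).shuffle(labels)
    return labels


class EOGSource(Protocol):
    """Produces one EOG trial recording for an intended answer label."""

    def next_trial(self, label: str): ...


class SyntheticEOGSource:
    """Synthetic trial source with fixed amplitude/noise parameters.

    ``n_max`` optionally limits the number of trials the source can
    produce (an exhausted source flags the session record incomplete).
    """

    def __init__(self, amplitude: float = 200.0, noise_sd: float = 5.0,
                 phases: TrialPhases | None = None, seed: int = 0,
                 n_max: int | None = None):
        self.template = TrialSpec(amplitude=amplitude, noise_sd=noise_sd,
                                  phases=phases or TrialPhases())
        self.rng = np.random.default_rng(seed)
        self.n_max = n_max
        self.produced = 0

    def next_trial(self, label: str):
        if self.n_max is not None and self.produced >= self.n_max:
            raise StopIteration("EOG source exhausted")
        self.produced += 1
        return generate_trial(replace(self.template, label=label),
                              trial_id=0, rng=self.rng)


# ----------------------------------------------------------------------
# training and feedback sessions
# ----------------------------------------------------------------------

def run_training_session(
    schedule: Sequence[str], source: EOGSource,
    phases: TrialPhases | None = None,
    feature_mode: str = "minmax",
    channels: tuple[str, ...] = DEFAULT_FEATURE_CHANNELS,
) -> tuple[SessionRecord, list[FeatureVector], list[str], pd.DataFrame]:
    """Collect features for every scheduled trial; no classification.

    Feedback to the user is the neutral acknowledgement ("Danke"), logged
    as the trial payload.  Returns the record, feature vectors, labels
    and a tidy feature table.  If the EOG source runs out mid-session the
    partial record is flagged incomplete.
    """
    phases = phases or TrialPhases()
    record = SessionRecord(session_type="training")
    feats: list[FeatureVector] = []
    labels: list[str] = []
    rows = []
    for i, label in enumerate(schedule):
        try:
            rec = source.next_trial(label)
        except StopIteration:
            record.complete = False
            break
        fv = trial_features(rec, 0, mode=feature_mode, channels=channels)
        feats.append(fv)
        labels.append(label)
        record.trials.append(TrialRecord(
            question_kind="known_answer", payload="Danke", true_label=label,
            duration_s=phases.trial_s))
        rows.append({"trial_id": i, "label": label, **fv.as_dict()})
    record.final_string = ""
    return record, feats, labels, pd.DataFrame(rows)


def run_feedback_session(
    model: TrainedModel, schedule: Sequence[str], source: EOGSource,
    phases: TrialPhases | None = None,
) -> SessionRecord:
    """Classify every scheduled trial online; the prediction is the
    feedback.  Requires a validated (above-chance) model."""
    if not model.validated:
        raise ValueError("model failed the chance-level gate; "
                         "feedback sessions require a validated model")
    phases = phases or TrialPhases()
    record = SessionRecord(session_type="feedback")
    for label in schedule:
        try:
            rec = source.next_trial(label)
        except StopIteration:
            record.complete = False
            break
        fv = trial_features(rec, 0, mode=model.feature_mode,
                            channels=model.channels)
        pred = classify_trial(model, fv)
        record.trials.append(TrialRecord(
            question_kind="known_answer", payload=pred, true_label=label,
            predicted_label=pred, duration_s=phases.trial_s))
    return record


def session_accuracy(record: SessionRecord) -> float:
    pairs = [(t.true_label, t.predicted_label) for t in record.trials
             if t.true_label is not None and t.predicted_label is not None]
    if not pairs:
        raise ValueError("no labelled predictions in record")
    return float(np.mean([t == p for t, p in pairs]))


# ----------------------------------------------------------------------
# simulated users / answer channels
# ----------------------------------------------------------------------

class SimulatedUser:
    """Target-directed answer policy with optional answer errors.

    Answers "yes" exactly when the current question advances the shortest
    speller path toward ``target`` (including corrective backspaces once
    the string has diverged); answers the quit prompt "yes" once the
    target is reached.  With ``error_rate`` > 0 each produced answer is
    flipped independently with that probability (seeded).
    """

    def __init__(self, target: str, layout: sp.SpellerLayout,
                 error_rate: float = 0.0, seed: int = 0):
        self.target = target.upper()
        self.layout = layout
        self.error_rate = error_rate
        self.rng = np.random.default_rng(seed)
        bad = set(self.target) - layout.alphabet
        if bad:
            raise ValueError(f"target contains unspellable characters {bad!r}")

    # -- policy --------------------------------------------------------

    def reached(self, current: str) -> bool:
        return current in (self.target, self.target + " ")

    def _desired(self, current: str) -> str | None:
        """Next character token to select, or None when the target is
        reached and quitting is desired."""
        if self.reached(current):
            return None
        if self.target.startswith(current):
            ch = self.target[len(current)]
            return sp.SPACE if ch == " " else ch
        return sp.BACKSPACE

    def intended_answer(self, question: sp.Question, state: sp.SpellerState) -> str:
        desired = self._desired(state.current_string)
        if question.kind == "quit":
            return sp.YES if desired is None else sp.NO
        if desired is None:
            # target reached: decline everything until the quit prompt
            return sp.NO if question.kind != "quit" else sp.YES
        if question.kind == "sector":
            return sp.YES if desired in self.layout.sectors[question.payload] else sp.NO
        if question.kind == "letter":
            return sp.YES if question.payload == desired else sp.NO
        if question.kind == "exit-sector":
            in_sector = desired in self.layout.sectors[state.sector]
            return sp.NO if in_sector else sp.YES
        if question.kind == "word":
            accepted = sp.accept_word_proposal(state, question.payload)
            new = accepted.current_string
            on_track = (self.target + " ").startswith(new)
            return sp.YES if on_track else sp.NO
        raise ValueError(f"unknown question kind {question.kind!r}")

    def answer(self, question: sp.Question, state: sp.SpellerState) -> str:
        ans = self.intended_answer(question, state)
        if self.error_rate > 0 and self.rng.random() < self.error_rate:
            ans = sp.NO if ans == sp.YES else sp.YES
        return ans


class EOGAnswerChannel:
    """Routes a user's intended answers through synthetic EOG + classifier.

    The user intends "yes" or "no"; the channel generates an EOG trial of
    that label from ``source`` and returns what the validated ``model``
    classifies — so answer errors arise from signal noise and classifier
    imperfection rather than from an explicit error rate.
    """

    def __init__(self, user: SimulatedUser, model: TrainedModel,
                 source: EOGSource):
        if not model.validated:
            raise ValueError("model failed the chance-level gate")
        self.user = user
        self.model = model
        self.source = source

    def answer(self, question: sp.Question, state: sp.SpellerState) -> str:
        intended = self.user.answer(question, state)
        rec = self.source.next_trial(intended)
        fv = trial_features(rec, 0, mode=self.model.feature_mode,
                            channels=self.model.channels)
        return classify_trial(self.model, fv)


class LoggedAnswers:
    """Replays a recorded answer sequence (raises StopIteration when
    exhausted)."""

    def __init__(self, answers: Sequence[str]):
        self._it = iter(list(answers))

    def answer(self, question: sp.Question, state: sp.SpellerState) -> str:
        return next(self._it)


# ----------------------------------------------------------------------
# spelling sessions
# ----------------------------------------------------------------------

def run_spelling_session(
    layout: sp.SpellerLayout,
    answer_source,
    mode: str = "copy",
    target: str | None = None,
    ngram_model: NGramModel | None = None,
    phases: TrialPhases | None = None,
    question_limit: int = DEFAULT_QUESTION_LIMIT,
    model: TrainedModel | None = None,
) -> SessionRecord:
    """Run the closed spelling loop until a confirmed quit.

    ``answer_source`` is anything with ``answer(question, state)``
    returning "yes"/"no".  Copy mode requires a target (stored in the
    record for later comparison; the loop itself never peeks at it).  A
    word predictor is active when ``ngram_model`` is given.  If ``model``
    is passed it must be validated (the chance gate also guards spelling).
    Hitting ``question_limit`` flags the record incomplete.
    """
    if mode not in ("copy", "free"):
        raise ValueError("mode must be 'copy' or 'free'")
    if mode == "copy" and not target:
        raise ValueError("copy spelling requires a target string")
    if model is not None and not model.validated:
        raise ValueError("model failed the chance-level gate")
    phases = phases or TrialPhases()
    predictor = (lambda s: propose(ngram_model, s)) if ngram_model else None

    session_type = "copy_spelling" if mode == "copy" else "free_spelling"
    record = SessionRecord(session_type=session_type,
                           target_string=target.upper() if target else None)
    state = sp.SpellerState()
    try:
        for _ in range(question_limit):
            question = sp.next_question(state, layout)
            answer = answer_source.answer(question, state)
            state, events = sp.apply_answer(state, layout, answer, predictor)
            record.trials.append(TrialRecord(
                question_kind=question.kind, payload=question.payload,
                predicted_label=answer, duration_s=phases.trial_s,
                resulting_string=state.current_string))
            for ev in events:
                if ev.kind == "selected_char":
                    record.n_letters_selected += 1
                elif ev.kind == "word_accepted":
                    record.n_letters_selected += 1
            if state.finished:
                break
        else:
            record.complete = False
    except StopIteration:
        record.complete = False
    record.final_string = state.current_string
    return record


def replay_spelling_session(layout: sp.SpellerLayout, answers: Sequence[str],
                            ngram_model: NGramModel | None = None,
                            question_limit: int = DEFAULT_QUESTION_LIMIT,
                            ) -> SessionRecord:
    """Deterministically re-run a logged answer sequence."""
    return run_spelling_session(layout, LoggedAnswers(answers), mode="free",
                                ngram_model=ngram_model,
                                question_limit=question_limit)


# ----------------------------------------------------------------------
# QC and theoretical speed
# ----------------------------------------------------------------------

MIN_TRIALS = 15


def session_qc(record: SessionRecord) -> tuple[bool, str | None]:
    """A-priori session exclusion rules, applied in order.

    A session is excluded if (1) a code error occurred, (2) the signal
    was noisy, (3) it terminated before 15 trials, (4) no letter was
    selected, or (5) all answers were classified as only "yes" or only
    "no".  Returns (included, reason); the first matching rule wins.
    """
    if record.code_error:
        return False, "code_error"
    if record.noisy_signal:
        return False, "noisy_signal"
    if len(record.trials) < MIN_TRIALS:
        return False, "terminated_before_15_trials"
    if record.session_type in ("copy_spelling", "free_spelling") \
            and record.n_letters_selected == 0:
        return False, "no_letter_selected"
    answers = {t.predicted_label for t in record.trials
               if t.predicted_label is not None}
    if len(answers) == 1:
        return False, "single_class_answers"
    return True, None


def theoretical_typing_speed(layout: sp.SpellerLayout, sentence: str,
                             trial_seconds: float = 9.0,
                             ngram_model: NGramModel | None = None) -> float:
    """Typing speed (chars/min) of an error-free user spelling
    ``sentence``, counting questions up to target completion.

    speed = len(final string) / (questions x trial_seconds / 60).  The
    final quit sequence is not counted.  Raises for unspellable
    characters or non-positive trial duration.
    """
    if trial_seconds <= 0:
        raise ValueError("trial_seconds must be positive")
    target = sentence.upper()
    user = SimulatedUser(target, layout, error_rate=0.0)
    predictor = (lambda s: propose(ngram_model, s)) if ngram_model else None
    state = sp.SpellerState()
    questions = 0
    while not user.reached(state.current_string):
        question = sp.next_question(state, layout)
        answer = user.answer(question, state)
        state, _ = sp.apply_answer(state, layout, answer, predictor)
        questions += 1
        if questions > 100_000:  # unreachable for valid targets
            raise RuntimeError("speller failed to reach the target")
    chars = len(state.current_string)
    return chars / (questions * trial_seconds / 60.0)
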