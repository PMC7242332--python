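"""Synthetic EOG trial, session, and longitudinal-dataset generation.

Emulates the statistical structure of yes/no EOG trials in late-stage ALS
patients: a "yes" answer is a voluntary horizontal eye movement producing
a smooth deflection of opposite polarity on the two lateral channels
(LO1 up, LO2 down), so the differential channel LO1 - LO2 peaks at the
configured amplitude; a "no" answer is the absence of eye movement, i.e.
noise only.  Longitudinal generation emulates the progressive decline of
eye-movement amplitude (from roughly ±200 µV down to ±30 µV) seen as the
disease approaches the completely locked-in state.

The model is deliberately simple: a raised-cosine pulse (band-limited,
surviving a 0.1-35 Hz passband) over white Gaussian channel noise, with
an optional 50 Hz mains component to exercise the notch filter.  It is
not a physiological saccade model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .recording import CHANNELS, EOGRecording, Marker, concatenate

YES, NO = "yes", "no"


@dataclass(frozen=True)
class TrialPhases:
    """Per-trial phase durations in seconds; the sum is the trial duration.

    Defaults give the 9 s minimum trial: 2 s silent baseline, 2 s auditory
    stimulus, 4 s response window, 1 s feedback.
    """

    baseline_s: float = 2.0
    stimulus_s: float = 2.0
    response_s: float = 4.0
    feedback_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "stimulus_s", "response_s", "feedback_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.response_s <= 0:
            raise ValueError("response_s must be positive")

    @property
    def trial_s(self) -> float:
        return self.baseline_s + self.stimulus_s + self.response_s + self.feedback_s


@dataclass(frozen=True)
class TrialSpec:
    """Parameters of one synthetic trial.

    amplitude is the peak of the horizontal differential deflection in µV
    (each lateral channel carries ±amplitude/2); noise_sd is the white
    noise sd per channel in µV; mains_amplitude adds a 50 Hz sinusoid of
    that amplitude (µV) to every channel.
    """

    label: str = YES
    amplitude: float = 200.0
    noise_sd: float = 5.0
    sample_rate: float = 500.0
    phases: TrialPhases = field(default_factory=TrialPhases)
    pulse_width_s: float = 1.0
    mains_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in (YES, NO):
            raise ValueError(f"label must be 'yes' or 'no', got {self.label!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.pulse_width_s <= 0:
            raise ValueError("pulse_width_s must be positive")
        if self.pulse_width_s > self.phases.response_s:
            raise ValueError("pulse must fit inside the response window")


def _raised_cosine(n_samples: int, rate: float, width_s: float,
                   center_s: float) -> np.ndarray:
    """Unit-peak raised-cosine pulse of given width centered at center_s."""
    t = np.arange(n_samples) / rate
    out = np.zeros(n_samples)
    inside = np.abs(t - center_s) <= width_s / 2
    out[inside] = 0.5 * (1 + np.cos(2 * np.pi * (t[inside] - center_s) / width_s))
    return out


def generate_trial(spec: TrialSpec, trial_id: int = 0,
                   rng: np.random.Generator | None = None) -> EOGRecording:
    """Generate one trial as a four-channel recording with phase markers.

    A yes trial injects a raised-cosine deflection (+amplitude/2 on LO1,
    -amplitude/2 on LO2, default width 1 s) centered in the response
    window, so the LO1-LO2 differential peaks at ~amplitude.  A no trial
    (or amplitude 0) contains noise only.  Vertical channels (SO1/IO1)
    carry noise only.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    rate = spec.sample_rate
    ph = spec.phases
    n = int(round(ph.trial_s * rate))
    noise = rng.normal(0.0, spec.noise_sd, size=(len(CHANNELS), n))
    data = {c: noise[i] for i, c in enumerate(CHANNELS)}
    if spec.mains_amplitude:
        t = np.arange(n) / rate
        mains = spec.mains_amplitude * np.sin(2 * np.pi * 50.0 * t)
        for c in CHANNELS:
            data[c] = data[c] + mains

    resp_start = int(round((ph.baseline_s + ph.stimulus_s) * rate))
    if spec.label == YES and spec.amplitude > 0:
        center_s = (ph.baseline_s + ph.stimulus_s) + ph.response_s / 2
        pulse = spec.amplitude / 2 * _raised_cosine(n, rate, spec.pulse_width_s, center_s)
        data["LO1"] = data["LO1"] + pulse
        data["LO2"] = data["LO2"] - pulse

    feed_start = resp_start + int(round(ph.response_s * rate))
    markers = [
        Marker(0, trial_id, "baseline"),
        Marker(int(round(ph.baseline_s * rate)), trial_id, "stimulus"),
        Marker(resp_start, trial_id, "response"),
        Marker(min(feed_start, n - 1), trial_id, "feedback"),
    ]
    return EOGRecording(sample_rate=rate, data=data, markers=markers)


def generate_session(n_yes: int, n_no: int, template: TrialSpec | None = None,
                     seed: int = 0) -> tuple[EOGRecording, list[str]]:
    """Generate one session: n_yes + n_no trials in seeded random order.

    A default training/feedback session has 10 yes and 10 no questions.
    Returns the concatenated recording (trial ids 0..n-1 in presentation
    order) and the label sequence in presentation order.
    """
    if n_yes < 0 or n_no < 0:
        raise ValueError("trial counts must be >= 0")
    template = template or TrialSpec()
    rng = np.random.default_rng(seed)
    labels = [YES] * n_yes + [NO] * n_no
    rng.shuffle(labels)
    trials = [
        generate_trial(replace(template, label=lab), trial_id=i, rng=rng)
        for i, lab in enumerate(labels)
    ]
    if not trials:
        empty = {c: np.zeros(0) for c in CHANNELS}
        return EOGRecording(template.sample_rate, empty), []
    return concatenate(trials), labels


def generate_longitudinal(
    visit_amplitudes: Sequence[float],
    trials_per_visit: tuple[int, int] = (10, 10),
    template: TrialSpec | None = None,
    seed: int = 0,
) -> list[tuple[int, EOGRecording, list[str]]]:
    """Generate one session per visit with per-visit yes-trial amplitude.

    Emulates longitudinal amplitude decay (e.g. amplitudes
    [200, 100, 40, 30] µV across visits) with fixed noise.  Returns
    (visit_index, recording, labels) tuples.
    """
    if len(visit_amplitudes) == 0:
        raise ValueError("need at least one visit amplitude")
    if any(a <= 0 for a in visit_amplitudes):
        raise ValueError("visit amplitudes must be positive")
    template = template or TrialSpec()
    n_yes, n_no = trials_per_visit
    rng = np.random.default_rng(seed)
    out = []
    for v, amp in enumerate(visit_amplitudes):
        visit_seed = int(rng.integers(0, 2**31 - 1))
        rec, labels = generate_session(
            n_yes, n_no, replace(template, amplitude=float(amp)), seed=visit_seed
        )
        out.append((v, rec, labels))
    return out
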