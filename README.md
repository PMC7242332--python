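# eogspeller

A simulation and analysis toolkit for an **auditory, electrooculogram
(EOG)-driven yes/no communication system** for people with late-stage
amyotrophic lateral sclerosis (ALS) who are transitioning from the
locked-in state (residual eye movement, no gaze fixation) to the
completely locked-in state. Such patients cannot use eye trackers or
visual spellers; what remains is a binary channel: *move the eyes* for
"yes", *don't move* for "no", recorded as a horizontal EOG deflection.

The package is aimed at BCI/assistive-communication researchers who want
to study, stress-test or extend this paradigm in simulation: every stage
of the online system is implemented and can be driven end to end with
synthetic signals.

## What it implements

- **Synthetic EOG generation** (`synthetic`): 4-channel recordings
  (SO1/IO1 vertical, LO1/LO2 horizontal, 500 Hz, µV). A yes trial is a
  raised-cosine deflection of opposite polarity on LO1/LO2 so the
  differential EOGL−EOGR peaks at a configurable amplitude
  (±30…±300 µV); a no trial is noise only. Sessions (10 yes + 10 no
  questions, randomized) and longitudinal visit series with decaying
  amplitude emulate the clinical protocol and disease progression.
- **Online preprocessing** (`signals`): linear-phase FIR band-pass
  0.1–35 Hz with a 50 Hz band-stop, removal of the first 50 samples
  (startup transient), per-channel z-standardization of the response
  window; features per channel are max/min amplitude with their times of
  occurrence, or the amplitude range max−min.
- **Chance-gated classification** (`classification`): an SVM (RBF
  kernel) validated by stratified 5-fold cross-validation and deployed
  only if its CV accuracy exceeds the *upper chance threshold* — the
  smallest accuracy k/n with exact binomial tail
  P(X ≥ k | n, ½) ≤ α. For n = 20 trials and α = 0.05 this is
  15/20 = **0.75**.
- **Auditory speller** (`speller`): letters grouped in sectors plus a
  special sector (space, backspace, delete-word). Selection uses the
  single-no/double-yes rule: one "no" skips an item, "yes" re-asks it
  and only a confirming second "yes" selects. Quit and exit-sector
  prompts follow the same confirmation. Pure transition function —
  logged answer sequences replay bit-exactly.
- **Word prediction** (`prediction`): corpus normalization
  (ä→ae, ö→oe, ü→ue, ß→ss), unigram/bigram/trigram conditional frequency
  tables, strict highest-order backoff, and the half-sum rule: a word is
  proposed only if its frequency f exceeds half the sum of all candidate
  frequencies, f > Σf/2 (at most one word can qualify).
- **Session engine** (`session`): training, feedback, copy- and
  free-spelling sessions; trial phases baseline/stimulus/response/
  feedback summing to 9–20 s; simulated users (optionally error-injecting
  or routed through synthetic EOG + classifier); the five a-priori
  session exclusion rules.
- **Evaluation** (`evaluation`): confusion matrix and ROC-space point per
  feedback session (TPR = TP/(TP+FN), FPR = FP/(FP+TN)), typing speed in
  char/min, information transfer rate (1 bit per binary question:
  60/9 s = **6.7 bits/min**), and the yes-vs-no Mann–Whitney U test on
  per-trial amplitude ranges for longitudinal decline.

## Worked example

```python
import eogspeller as eg
from eogspeller.synthetic import TrialSpec

# 1. a synthetic training session and a chance-gated classifier
schedule = eg.make_training_schedule(seed=0)          # 10 yes + 10 no
source   = eg.SyntheticEOGSource(amplitude=200.0, noise_sd=5.0, seed=0)
record, feats, labels, _ = eg.run_training_session(schedule, source)
model = eg.train_model(feats, labels, seed=0)
print(model.cv_accuracy, model.chance_threshold, model.validated)
# 1.0 0.75 True     -> CV accuracy beats the 15/20 chance bound: deployable

# 2. closed-loop copy spelling with word prediction
layout, corpus = eg.default_layout(), eg.default_corpus_model()
user = eg.SimulatedUser("ICH BIN", layout)
rec = eg.run_spelling_session(layout, user, mode="copy",
                              target="ICH BIN", ngram_model=corpus)
print(rec.final_string, len(rec.trials))
# 'ICH BIN ' 27     -> 27 questions; the predictor completed both words

# 3. speed and information transfer
print(eg.theoretical_typing_speed(layout, "ICH BIN", 9.0, corpus))  # 2.54
print(eg.theoretical_typing_speed(layout, "ICH BIN", 9.0, None))    # 0.75
print(eg.information_transfer_rate(9.0))                            # 6.67
```

The numbers mean: with 9-second trials the binary channel carries
6.7 bits/min; spelling "ICH BIN" letter by letter runs at 0.75 char/min,
and the n-gram predictor — which proposes "ICH" and "BIN" as soon as they
dominate the candidate set — more than triples that to 2.54 char/min.

Narrative scripts in `examples/` cover each capability (synthetic
trials, training + gating, spelling sessions, word prediction,
longitudinal decline); each prints the quantities it computes. A thin
CLI (`eogspeller simulate-session|train-model|run-feedback|run-speller|qc`)
wraps the same functions for shell use.

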