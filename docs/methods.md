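# Methods

## The paradigm being simulated

The system gives a binary communication channel to people whose only
remaining voluntary act is a small horizontal eye movement. Every
interaction is one auditorily presented yes/no question (a *trial*):
baseline (silence), stimulus (the spoken question), a response window in
which the user moves (yes) or does not move (no) the eyes, and feedback.
Four periorbital electrodes are recorded at 500 Hz: SO1/IO1 (vertical)
and LO1/LO2 (horizontal); the differential EOGL−EOGR concentrates the
horizontal deflection and cancels common-mode noise. On top of the
binary channel sit (a) known-answer training/feedback sessions used to
fit and check a classifier, and (b) an auditory speller that turns
sequences of yes/no answers into text, accelerated by an n-gram word
predictor.

## Synthetic signal model

`synthetic.generate_trial` draws white Gaussian noise per channel
(default sd 5 µV) and, for yes trials, adds a raised-cosine pulse
(default width 1 s) centered in the response window: +A/2 on LO1, −A/2
on LO2, so the differential peaks at the configured amplitude A. An
optional 50 Hz sinusoid emulates mains pickup and exercises the notch
stage. Defaults (4 s response window inside a 9 s trial; amplitudes
stepped from ±200 down to ±30 µV in longitudinal runs; 10 + 10 trials
per session) follow the clinical protocol the package models.

What the generator deliberately does **not** model: saccade kinematics,
blinks and other artifacts, drift/electrode impedance changes,
trial-to-trial latency jitter of the response, or EEG background. Two
consequences matter for interpreting test results. First, because the
pulse's timing and shape are deterministic, *any* positive amplitude is
in principle detectable — in simulation, classification only falls to
chance when the residual deflection is exactly zero, whereas real
performance decays gradually with amplitude and noise. Passing tests
therefore demonstrate the pipeline's correctness and its qualitative
amplitude–performance relationship, not clinical effect sizes. Second,
the per-trial amplitude-range statistic (max − min of the filtered
differential) has a noise floor of roughly 16 µV at the default noise
level, so it overestimates configured amplitudes near ±30–40 µV; the
statistic is reported honestly rather than noise-corrected.

## Online preprocessing

The response window is filtered with a causal linear-phase FIR chain:
a 101-tap windowed-sinc band-pass 0.1–35 Hz convolved with a 101-tap
band-stop 48–52 Hz (Hamming windows, 500 Hz). With 101 taps the
transition bands are a few Hz wide: attenuation immediately above 0 Hz
is limited (accepted — the pulse energy sits well above 0.1 Hz), and
most of the ~70 dB rejection at 50 Hz comes from the low-pass edge, the
explicit notch adding margin. The first 50 output samples are discarded
as the startup transient, then each channel is z-scored (population sd)
over the window. A zero-variance channel raises an explicit
degenerate-input error.

Features per channel: either (max, min, t_max, t_min) with times in
seconds from window onset and ties broken by the earliest sample, or the
range max − min. The default channel set is the horizontal differential
only; any subset of {SO1, IO1, LO1, LO2, LO1-LO2} can be configured.
The rationale: the discriminative signal is horizontal, and at 20-trial
training sizes the vertical channels contribute pure-noise feature
dimensions that only degrade small-sample fits.

## Classification and the chance gate

An SVM with RBF kernel (C = 1, gamma = 'scale', i.e. 1/(n_features·var),
matching common library defaults), preceded by a training-set z-scaler,
is fitted on all trials of the training pool; reported accuracy is the
mean over seeded, stratified 5-fold cross-validation. Training requires
both classes with ≥ 5 trials each. The model may drive feedback or
spelling only if CV accuracy *strictly exceeds* the upper chance
threshold: the smallest k/n with exact binomial tail
P(X ≥ k | n, ½) ≤ α (α = 0.05 by default; 0.75 for n = 20). For very
small n no k qualifies; the function then returns 1.0, which the strict
inequality makes unpassable — the honest semantics for sample sizes that
cannot beat chance at the requested level.

## Speller state machine

Selection is single-no/double-yes at both the sector and the letter
level; the quit prompt (after the last sector is declined), the
exit-sector prompt (after the last letter is declined) and word
proposals use the same confirmation. Choices the protocol leaves open,
fixed here: an unconfirmed "yes" (yes, then no) is a non-selection and
scanning advances past the item (for prompts it counts as "no");
a confirmed exit-sector resumes the sector scan at the sector after the
current one (reaching the quit prompt if that was the last);
"delete the word" removes the trailing partial or complete word
*including* its trailing space; strings are uppercase A–Z plus space.
The transition function is pure and total over valid states, so replay
of a logged answer sequence is bit-exact — this is also how session logs
are re-validated.

## Word prediction

The corpus is normalized (lowercase; ä→ae, ö→oe, ü→ue, ß→ss;
punctuation stripped; sentences split on ./!/?; n-grams never cross
sentence boundaries). After every confirmed letter or space selection
the predictor collects vocabulary words matching the current incomplete
prefix (all words if the last word is complete), scored at the highest
n-gram order with any contextual match — trigram on the last two
complete words, else bigram on the last one, else unigram — never mixing
orders. A word is proposed iff its raw frequency strictly exceeds half
the candidate total; at most one word can satisfy this, no smoothing is
applied. Accepting a proposal replaces the prefix with the word plus a
space; rejecting it (single "no") restarts the sector scan. The bundled
corpus is a small synthetic German fixture with deliberately skewed
frequencies; real deployments should supply a large general corpus via
`build_model_from_file`.

## Session engine and metrics

Default trial phases are 2/2/4/1 s (baseline/stimulus/response/feedback,
9 s total); a 3/4/11/2 s split realizes the 20 s upper bound. A
20-question session thus spans 3 to about 6.7 minutes. Spelling sessions
run until a confirmed quit or a question limit (default 500, guaranteeing
termination of Monte-Carlo runs). The simulated user answers "yes"
exactly when the question advances the shortest path to its target
(including corrective backspaces once the string has diverged) and
quits once the target is reached; an error rate flips each answer
independently. Routing intended answers through synthetic EOG plus the
classifier (`EOGAnswerChannel`) replaces the explicit error rate with
signal-level errors.

Typing speed counts selection events (confirmed characters, including
ones later deleted, and accepted word proposals) per minute of session
time. Theoretical typing speed simulates an error-free user and counts
questions only up to target completion, excluding the final quit
sequence — consistent with a hand trace of the minimal walk (1 sector /
1 letter / 9 s trials: 4 questions → 1.67 char/min). The information
transfer rate uses the 1-bit-per-binary-question convention with no
error-rate correction: 60/trial_seconds bits/min, 6.7 at 9 s.

Session exclusion applies five a-priori rules in order: code error,
noisy signal, fewer than 15 trials, no letter selected, all answers in a
single class. The first matching rule is reported.

The amplitude-decline statistic compares yes vs no per-trial amplitude
ranges with a two-sided Mann–Whitney U test: exact null distribution
when min(n₁, n₂) ≤ 8 and no ties, the tie-corrected normal approximation
otherwise; stars at 0.05/0.01/0.001. ROC points are computed per
feedback session, not pooled.

## Problem sizes and numerical choices

Tests and the acceptance script use the protocol-sized problems
throughout: 20-trial sessions, 10-seed sweeps over amplitudes
{30, 40, 100, 200} µV with independent 20-trial held-out sessions,
50 random toy layouts for the speller-trace equivalence, and 1,000
random frequency maps for the proposal-uniqueness property. Chance-level
behavior is asserted on accuracy pooled across seeds (n = 200 trials)
against the exact central 95% binomial band. Standardization tolerances
are 1e−9; filter linearity holds to numerical precision; tie-breaks are
always earliest-sample / first-matching-rule.

## Known limitations

- The synthetic generator's determinism makes low-amplitude trials more
  separable than clinical data would be (see above); absolute accuracies
  at 30–40 µV should not be read as clinical predictions.
- The FIR chain's 0.1 Hz high-pass edge is nominal at 101 taps; true
  drift suppression would need a far longer filter than the 50-sample
  trim convention accommodates.
- Word prediction uses raw counts with strict thresholding; no
  smoothing, no per-user corpus adaptation.
- BrainVision loading returns the four EOG channels without trial
  markers (annotation schemes are recording-specific) and requires the
  optional `mne` dependency.
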