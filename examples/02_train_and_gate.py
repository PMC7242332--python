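"""Train the yes/no SVM on one synthetic training session and gate it.

The model is only allowed to drive feedback/spelling sessions if its
5-fold cross-validated accuracy exceeds the upper chance threshold: the
smallest k/n with exact binomial tail P(X >= k | n, 1/2) <= 0.05, which
for 20 trials is 15/20 = 0.75.
"""

import eogspeller as eg
from eogspeller.synthetic import TrialSpec

schedule = eg.make_training_schedule(seed=0)      # 10 yes + 10 no, shuffled
source = eg.SyntheticEOGSource(amplitude=200.0, noise_sd=5.0, seed=0)
record, feats, labels, table = eg.run_training_session(schedule, source)
print(f"training session: {len(record.trials)} trials, "
      f"{record.duration_min:.0f} min")

model = eg.train_model(feats, labels, seed=0)
print(f"cv accuracy      {model.cv_accuracy:.3f}")
print(f"chance threshold {model.chance_threshold:.3f}  "
      f"(n={model.n_training_trials}, alpha={model.alpha})")
print(f"validated        {model.validated}")

# the validated model classifies a feedback session online
feedback = eg.run_feedback_session(model, eg.make_training_schedule(seed=1),
                                   eg.SyntheticEOGSource(amplitude=200.0, seed=1))
pt = eg.session_roc(feedback)
print(f"feedback session: accuracy {eg.session_accuracy(feedback):.2f}, "
      f"TPR {pt.tpr:.2f}, FPR {pt.fpr:.2f} "
      f"({'above' if pt.above_diagonal else 'on/below'} the ROC diagonal)")
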