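"""Longitudinal amplitude decline and its statistical footprint.

One session per visit with decaying yes-trial amplitude (200 -> 30 uV)
emulates progressive loss of oculomotor control. Per visit, the
amplitude ranges of yes vs no trials are compared with a two-sided
Mann-Whitney U test; classification accuracy collapses to chance once no
residual deflection remains.
"""

import numpy as np

import eogspeller as eg
from eogspeller.synthetic import TrialSpec

visits = eg.generate_longitudinal([200, 100, 40, 30], seed=5)
summary = eg.decline_summary(visits)
print(summary.round(3).to_string(index=False))
print("(stars: * p<0.05, ** p<0.01, *** p<0.001)")

# accuracy across the decay, plus the no-movement endpoint
for amp in (200.0, 40.0, 0.0):
    rec_tr, l_tr = eg.generate_session(10, 10, TrialSpec(amplitude=amp), seed=8)
    rec_te, l_te = eg.generate_session(10, 10, TrialSpec(amplitude=amp), seed=9)
    model = eg.train_model([eg.trial_features(rec_tr, t)
                            for t in rec_tr.trial_ids], l_tr, seed=0)
    acc = eg.held_out_accuracy(model, [eg.trial_features(rec_te, t)
                                       for t in rec_te.trial_ids], l_te)
    print(f"amplitude {amp:5.0f} uV: held-out accuracy {acc:.2f}"
          + ("  (no residual eye movement -> chance)" if amp == 0 else ""))
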