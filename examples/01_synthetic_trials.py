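"""Generate synthetic yes/no EOG trials and inspect the horizontal channel.

A "yes" is a voluntary horizontal eye movement: opposite-polarity
deflections on the lateral channels LO1/LO2 whose differential peaks at
the configured amplitude. A "no" is noise only. The amplitude range of
the filtered differential is the statistic tracked as eye control decays.
"""

import numpy as np

import eogspeller as eg
from eogspeller.synthetic import TrialSpec

yes = eg.generate_trial(TrialSpec(label="yes", amplitude=200.0, seed=1))
no = eg.generate_trial(TrialSpec(label="no", seed=2))

win = yes.response_window(0)
diff = eg.horizontal_channel(win["LO1"], win["LO2"])
print(f"yes trial: differential peak      {np.abs(diff).max():7.1f} uV "
      "(configured 200 uV)")
print(f"yes trial: amplitude range        {eg.amplitude_range_per_trial(yes, 0):7.1f} uV")
print(f"no  trial: amplitude range        {eg.amplitude_range_per_trial(no, 0):7.1f} uV "
      "(noise floor)")

# a full 20-question session (10 yes / 10 no, randomized order)
session, labels = eg.generate_session(10, 10, TrialSpec(amplitude=200.0), seed=3)
print(f"session: {len(labels)} trials, {session.duration / 60:.0f} min, "
      f"labels start {labels[:5]}")
# session.to_csv("session.csv")  # CSV + .markers.json sidecar
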