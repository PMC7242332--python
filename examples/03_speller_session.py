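"""Closed-loop copy spelling with the sector-scanning auditory speller.

A simulated user answers each yes/no question so as to spell the target;
one "no" skips an item, two consecutive "yes" answers select it. The
n-gram predictor proposes dominant completions, which shortens the
session considerably.
"""

import eogspeller as eg

layout = eg.default_layout()
corpus = eg.default_corpus_model()
target = "ICH BIN"

user = eg.SimulatedUser(target, layout, error_rate=0.0)
record = eg.run_spelling_session(layout, user, mode="copy", target=target,
                                 ngram_model=corpus)
print(f"final string  {record.final_string!r}")
print(f"questions     {len(record.trials)}  "
      f"({record.duration_min:.1f} min at 9 s/question)")
print(f"typing speed  {eg.typing_speed(record):.2f} char/min")

included, reason = eg.session_qc(record)
print(f"session QC    {'included' if included else 'excluded: ' + reason}")

for pred in (corpus, None):
    speed = eg.theoretical_typing_speed(layout, target, 9.0, pred)
    tag = "with" if pred else "without"
    print(f"theoretical speed {tag} word prediction: {speed:.2f} char/min")
# word prediction pays off once the corpus makes a continuation dominant
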