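"""N-gram word prediction: normalization, backoff, half-sum threshold.

The corpus is normalized to the speller's A-Z alphabet (ae/oe/ue/ss for
the German graphemes). Completion candidates for the current incomplete
word are scored at the highest n-gram order with a contextual match
(trigram -> bigram -> unigram), and a word is proposed only when its
frequency strictly exceeds half the sum over all candidates.
"""

import eogspeller as eg

print("normalize:", eg.normalize_text("Ich bin müde. Die Straße!"))

corpus = "ich bin hier. ich bin froh. du bist hier."
model = eg.build_model(eg.normalize_text(corpus))

print("trigram  (ich, bin) ->", eg.candidate_words(model, ("ich", "bin"), ""))
print("backoff  (xx, bin)  ->", eg.candidate_words(model, ("xx", "bin"), ""))
print("unigram  prefix 'd' ->", eg.candidate_words(model, ("xx", "yy"), "d"))

print("probable {hallo:3, haus:1} ->", eg.probable_word({"hallo": 3, "haus": 1}))
print("probable {a:1, b:1}        ->", eg.probable_word({"a": 1, "b": 1}))

# full prediction step on the speller's current string
big = eg.default_corpus_model()
for current in ("ICH B", "ICH M", "X"):
    print(f"propose({current!r}) -> {eg.propose(big, current)!r}")
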