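"""Generate a synthetic two-cohort user-post corpus and inspect its shape.

The generator emulates the statistical structure of a depression-screening
corpus: balanced depressed/control cohorts, overdispersed per-user post
counts (depressed users post less and write shorter posts), and a minority
of "signal" posts drawing tokens from a depression lexicon at much higher
prevalence in the depressed cohort.
"""

import numpy as np

from deprisk import corpus_io, synthetic

cfg = synthetic.preset("strong", n_users_per_class=50, seed=42)
corpus = synthetic.generate_corpus(cfg)
lexicon, background = synthetic.make_lexicon(cfg)

corpus_io.write_corpus(corpus, "corpus.jsonl")
corpus_io.write_lexicon(lexicon, "lexicon.txt")

for label in ("depressed", "control"):
    users = corpus.by_label(label)
    posts = [len(u.posts) for u in users]
    signal = [len(u.metadata["signal_posts"]) for u in users]
    print(f"{label:>9}: {len(users)} users, "
          f"{np.mean(posts):.1f} posts/user, "
          f"{np.mean(signal) / np.mean(posts):.0%} signal posts")

print(f"lexicon: {len(lexicon)} signal terms, {len(background)} background words")
print("sample raw post:", corpus.users[0].posts[0].raw_text)
# Expect ~50% signal posts for the depressed cohort vs ~5% for controls, and
# fewer posts per depressed user — the contrasts every later step relies on.
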