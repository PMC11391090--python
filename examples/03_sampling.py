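"""Compare the three post-selection strategies on one user.

Retrieval sampling ranks a user's posts by how many depression-lexicon
terms they contain (ties broken by recency) and keeps the top ceil(rate*N);
random sampling keeps a uniform subset; strategy none keeps everything.
"""

import numpy as np

from deprisk import preprocess, sampling, synthetic

cfg = synthetic.preset("strong", n_users_per_class=5, seed=3)
corpus, _ = preprocess.prepare_corpus(synthetic.generate_corpus(cfg))
lexicon, _ = synthetic.make_lexicon(cfg)

user = corpus.by_label("depressed")[0]
scores = [sampling.score_post(p.tokens, lexicon) for p in user.posts]
print(f"user {user.user_id}: {len(user.posts)} posts, "
      f"lexicon scores {scores}")

retrieval = sampling.retrieval_sample(user, lexicon, rate=0.5)
random_ = sampling.random_sample(user, rate=0.5, seed=13)
print("retrieval keeps:", retrieval.selected)
print("random keeps:   ", random_.selected)

mean = lambda idx: np.mean([scores[i] for i in idx])
print(f"mean score retained — retrieval {mean(retrieval.selected):.2f}, "
      f"random {mean(random_.selected):.2f}, all {np.mean(scores):.2f}")
# Retrieval concentrates lexicon-bearing posts; random only dilutes them.
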