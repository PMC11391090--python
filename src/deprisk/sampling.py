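"""Post-selection strategies applied per user before training.

Three strategies are compared throughout the package: ``none`` (use every
post), ``random`` (uniform subset at a given rate), and ``retrieval``
(keep the posts whose tokens best match a depression lexicon).  Every
strategy selects exactly ``ceil(rate * N)`` of a user's ``N`` posts and
emits the selected indices in chronological order, so downstream encoders
always see a time-ordered subsequence.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus_io import Corpus, Lexicon, UserRecord

STRATEGIES = ("none", "random", "retrieval")


@dataclass
class SampledView:
    user_id: str
    strategy: str
    rate: float
    selected: list[int]

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.rate <= 1.0:
            raise ValueError("rate must be in (0, 1]")
        if any(b <= a for a, b in zip(self.selected, self.selected[1:])):
            raise ValueError("selected indices must be strictly increasing")


def score_post(tokens: list[str], lexicon: Lexicon) -> int:
    """Number of token occurrences that are lexicon terms (multiset count)."""
    if len(lexicon) == 0:
        raise ValueError("lexicon must be non-empty")
    return sum(1 for t in tokens if t in lexicon)


def _n_select(rate: float, n_posts: int) -> int:
    return math.ceil(rate * n_posts)


def full_view(user: UserRecord) -> SampledView:
    return SampledView(user_id=user.user_id, strategy="none", rate=1.0,
                       selected=list(range(len(user.posts))))


def retrieval_sample(user: UserRecord, lexicon: Lexicon, rate: float) -> SampledView:
    """Top-``ceil(rate*N)`` posts by lexicon match score.

    Ties are broken by recency (the later post wins), so when no post
    matches the lexicon the most recent posts are kept.  Selected indices
    are emitted in chronological order.
    """
    if not 0.0 < rate <= 1.0:
        raise ValueError("rate must be in (0, 1]")
    if not user.posts:
        raise ValueError(f"user {user.user_id!r} has no posts")
    scores = [score_post(p.tokens, lexicon) for p in user.posts]
    k = _n_select(rate, len(user.posts))
    # sort by (score desc, index desc) = score then recency
    ranked = sorted(range(len(scores)), key=lambda i: (-scores[i], -i))
    chosen = sorted(ranked[:k])
    return SampledView(user_id=user.user_id, strategy="retrieval",
                       rate=rate, selected=chosen)


def _user_seed(seed: int, user_id: str) -> int:
    """Combine the run seed with a stable per-user hash so adding users
    never perturbs the samples drawn for existing ones."""
    return (int(seed) & 0x7FFFFFFF) ^ zlib.crc32(user_id.encode("utf-8"))


def random_sample(user: UserRecord, rate: float, seed: int) -> SampledView:
    """Uniform sample without replacement of ``ceil(rate*N)`` posts,
    deterministic given ``(seed, user_id)``; chronological output order."""
    if not 0.0 < rate <= 1.0:
        raise ValueError("rate must be in (0, 1]")
    if not user.posts:
        raise ValueError(f"user {user.user_id!r} has no posts")
    n = len(user.posts)
    k = _n_select(rate, n)
    rng = np.random.default_rng(_user_seed(seed, user.user_id))
    chosen = sorted(int(i) for i in rng.choice(n, size=k, replace=False))
    return SampledView(user_id=user.user_id, strategy="random",
                       rate=rate, selected=chosen)


def sample_corpus(corpus: Corpus, strategy: str, rate: float = 1.0,
                  lexicon: Lexicon | None = None,
                  seed: int = 0) -> dict[str, SampledView]:
    """Apply one strategy to every user; returns user_id -> view."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    views: dict[str, SampledView] = {}
    for user in corpus.users:
        if strategy == "none":
            views[user.user_id] = full_view(user)
        elif strategy == "random":
            views[user.user_id] = random_sample(user, rate, seed)
        else:
            if lexicon is None:
                raise ValueError("retrieval sampling requires a lexicon")
            views[user.user_id] = retrieval_sample(user, lexicon, rate)
    return views


def write_views(views: dict[str, SampledView], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for uid in sorted(views):
            v = views[uid]
            fh.write(json.dumps({"user_id": v.user_id, "strategy": v.strategy,
                                 "rate": v.rate, "selected": v.selected}) + "\n")


def read_views(path: str | Path) -> dict[str, SampledView]:
    views: dict[str, SampledView] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                obj = json.loads(line)
                views[obj["user_id"]] = SampledView(**obj)
    return views
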