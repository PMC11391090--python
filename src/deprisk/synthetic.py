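"""Synthetic corpus, lexicon, and embedding generation.

Real user-post collections for depression screening are private, so the
package ships a generator that reproduces the *statistical* structure the
method relies on, without any claim of linguistic realism:

* two balanced cohorts (depressed / control) of users;
* per-user post sequences of overdispersed length (negative binomial),
  with the depressed cohort posting less and writing shorter posts;
* a minority of "signal" posts that draw part of their tokens from a
  depression lexicon, at much higher prevalence in the depressed cohort;
* first-person-singular pronouns, modal particles, and punctuation injected
  at class-dependent rates (more 我 / 。/ ~ / …… / 吧 for the depressed
  cohort, more 我们 / ，/ ！/ 啊 for controls);
* optional platform noise — URLs, numbers, bracketed emoticons, bot posts,
  duplicate reposts — for exercising the preprocessing rules.

Synthetic words are abstract lowercase symbols (``wab``, ``sqx``, ...), so
the pipeline stays script-agnostic; a small optional CJK term list can be
mixed into the signal lexicon to exercise Unicode paths.  The ``null``
preset removes every class contrast and is the negative control: no
classifier should beat chance on it.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import NamedTuple

import numpy as np

from .corpus_io import Corpus, EmbeddingTable, Lexicon, Post, UserRecord

_CJK_SIGNAL_TERMS = ("抑郁", "抑郁症", "失眠", "难过")

MODAL_PARTICLES = ("的", "呢", "吗", "吧", "啊")
PUNCTUATION_MARKS = ("。", "，", "！", "？", "~", "……")


class PerClass(NamedTuple):
    """A rate or mean that differs between the two cohorts."""
    depressed: float
    control: float

    def get(self, label: str) -> float:
        return self.depressed if label == "depressed" else self.control


@dataclass
class GenConfig:
    n_users_per_class: int = 200
    posts_per_user: PerClass = PerClass(24.0, 36.0)
    posts_dispersion: float = 8.0          # negative-binomial size; 0 = exact mean
    tokens_per_post: PerClass = PerClass(9.0, 13.0)
    tokens_dispersion: float = 10.0
    min_tokens_per_post: int = 3
    signal_lexicon_size: int = 30
    background_vocab_size: int = 500
    p_signal_post: PerClass = PerClass(0.5, 0.05)
    p_signal_token_in_signal_post: float = 0.4
    first_singular_per_post: PerClass = PerClass(0.8, 0.3)    # 我
    first_plural_per_post: PerClass = PerClass(0.1, 0.4)      # 我们
    particle_per_post: dict[str, PerClass] = field(default_factory=lambda: {
        "的": PerClass(0.5, 0.5), "呢": PerClass(0.05, 0.05),
        "吗": PerClass(0.1, 0.1), "吧": PerClass(0.3, 0.1),
        "啊": PerClass(0.1, 0.3)})
    punct_per_post: dict[str, PerClass] = field(default_factory=lambda: {
        "。": PerClass(1.0, 0.5), "，": PerClass(0.5, 1.0),
        "！": PerClass(0.1, 0.4), "？": PerClass(0.2, 0.2),
        "~": PerClass(0.3, 0.1), "……": PerClass(0.4, 0.1)})
    url_rate: float = 0.02
    number_rate: float = 0.02
    emoticon_rate: float = 0.03
    bot_post_rate: float = 0.01
    duplicate_rate: float = 0.01
    include_cjk_terms: bool = False
    year_start: datetime = datetime(2023, 1, 1)
    seed: int = 0

    def __post_init__(self):
        for name in ("p_signal_post",):
            pc = getattr(self, name)
            if not (0 <= pc.depressed <= 1 and 0 <= pc.control <= 1):
                raise ValueError(f"{name} must be probabilities")
        if not 0 <= self.p_signal_token_in_signal_post <= 1:
            raise ValueError("p_signal_token_in_signal_post must be in [0,1]")
        if self.p_signal_post.depressed < self.p_signal_post.control:
            raise ValueError("depressed signal-post prevalence must be >= control "
                             "(equal only in a null configuration)")
        if min(self.posts_per_user) <= 0 or min(self.tokens_per_post) <= 0:
            raise ValueError("class means must be positive")
        if self.n_users_per_class < 1:
            raise ValueError("n_users_per_class must be >= 1")


def preset(name: str, **overrides) -> GenConfig:
    """Named study conditions.

    ``strong``: the default configuration above — a clear class contrast in
    signal-post prevalence (0.5 vs 0.05) plus the behavioral contrasts.
    ``weak``: a narrowed prevalence gap (0.2 vs 0.08) and diluted signal
    tokens, for harder classification.
    ``null``: every class contrast removed (identical rates for both
    cohorts) — the negative control on which any classifier is at chance.
    """
    if name == "strong":
        cfg = GenConfig()
    elif name == "weak":
        cfg = GenConfig(p_signal_post=PerClass(0.2, 0.08),
                        p_signal_token_in_signal_post=0.25)
    elif name == "null":
        flat = {s: PerClass(0.5, 0.5) for s in MODAL_PARTICLES}
        flat_punct = {s: PerClass(0.5, 0.5) for s in PUNCTUATION_MARKS}
        cfg = GenConfig(posts_per_user=PerClass(30.0, 30.0),
                        tokens_per_post=PerClass(11.0, 11.0),
                        p_signal_post=PerClass(0.05, 0.05),
                        first_singular_per_post=PerClass(0.5, 0.5),
                        first_plural_per_post=PerClass(0.25, 0.25),
                        particle_per_post=flat, punct_per_post=flat_punct)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(cfg, **overrides) if overrides else cfg


def _symbol(prefix: str, i: int) -> str:
    letters = string.ascii_lowercase
    out = []
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out.append(letters[r])
    return prefix + "".join(reversed(out))


def make_lexicon(config: GenConfig) -> tuple[Lexicon, list[str]]:
    """Disjoint (signal lexicon, background vocabulary), deterministic.

    Signal terms are ``s``-prefixed and background words ``w``-prefixed, so
    the two namespaces cannot collide; with ``include_cjk_terms`` a handful
    of CJK words join the signal lexicon to exercise Unicode handling.
    """
    if config.signal_lexicon_size < 1 or config.background_vocab_size < 1:
        raise ValueError("vocabulary sizes must be >= 1")
    signal = [_symbol("s", i) for i in range(config.signal_lexicon_size)]
    if config.include_cjk_terms:
        signal.extend(_CJK_SIGNAL_TERMS)
    background = [_symbol("w", i) for i in range(config.background_vocab_size)]
    return Lexicon(terms=frozenset(signal)), background


def _count(rng: np.random.Generator, mean: float, dispersion: float,
           minimum: int) -> int:
    if dispersion <= 0:
        return max(minimum, int(round(mean)))
    p = dispersion / (dispersion + mean)
    return max(minimum, int(rng.negative_binomial(dispersion, p)))


def generate_corpus(config: GenConfig) -> Corpus:
    """Generate a labeled two-cohort corpus.

    Each user's signal-post ids are recorded in
    ``user.metadata['signal_posts']`` so tests can recover the generating
    process.  Raw text is the space-joined token sequence with punctuation
    attached to token ends and optional platform noise mixed in; tokens are
    left empty, as for real raw data, until preprocessing runs.
    """
    rng = np.random.default_rng(config.seed)
    lexicon, background = make_lexicon(config)
    signal_terms = sorted(lexicon.terms)
    users: list[UserRecord] = []
    year_seconds = 365 * 24 * 3600
    for label in ("depressed", "control"):
        for u in range(config.n_users_per_class):
            user_id = f"{label[:3]}{u:04d}"
            n_posts = _count(rng, config.posts_per_user.get(label),
                             config.posts_dispersion, 1)
            offsets = np.sort(rng.uniform(0, year_seconds, size=n_posts))
            posts: list[Post] = []
            signal_ids: list[str] = []
            for k, off in enumerate(offsets):
                post_id = f"{user_id}-p{k:04d}"
                is_signal = rng.random() < config.p_signal_post.get(label)
                n_tok = _count(rng, config.tokens_per_post.get(label),
                               config.tokens_dispersion,
                               config.min_tokens_per_post)
                tokens = []
                for _ in range(n_tok):
                    if is_signal and rng.random() < config.p_signal_token_in_signal_post:
                        tokens.append(signal_terms[rng.integers(len(signal_terms))])
                    else:
                        tokens.append(background[rng.integers(len(background))])
                for word, rate in (("我", config.first_singular_per_post.get(label)),
                                   ("我们", config.first_plural_per_post.get(label))):
                    for _ in range(rng.poisson(rate)):
                        tokens.insert(int(rng.integers(len(tokens) + 1)), word)
                for particle, pc in config.particle_per_post.items():
                    for _ in range(rng.poisson(pc.get(label))):
                        tokens.insert(int(rng.integers(len(tokens) + 1)), particle)
                text = _render_text(tokens, config, rng, label)
                posts.append(Post(post_id=post_id,
                                  timestamp=config.year_start + timedelta(seconds=float(off)),
                                  raw_text=text))
                if is_signal:
                    signal_ids.append(post_id)
            posts = _inject_noise_posts(posts, user_id, config, rng)
            user = UserRecord(user_id=user_id, label=label, posts=posts,
                              metadata={"signal_posts": signal_ids})
            user.sort_posts()
            users.append(user)
    return Corpus(users=users)


def _render_text(tokens: list[str], config: GenConfig,
                 rng: np.random.Generator, label: str) -> str:
    """Join tokens, attach punctuation to token ends, mix in noise."""
    parts = list(tokens)
    for mark, pc in config.punct_per_post.items():
        for _ in range(rng.poisson(pc.get(label))):
            i = int(rng.integers(len(parts)))
            parts[i] = parts[i] + mark
    if rng.random() < config.emoticon_rate:
        parts.insert(int(rng.integers(len(parts) + 1)), "[泪]")
    if rng.random() < config.url_rate:
        parts.append(f"http://t.cn/{_symbol('', int(rng.integers(17576)))}")
    if rng.random() < config.number_rate:
        parts.append(str(int(rng.integers(10, 10000))))
    return " ".join(parts)


def _inject_noise_posts(posts: list[Post], user_id: str, config: GenConfig,
                        rng: np.random.Generator) -> list[Post]:
    out = list(posts)
    for k, post in enumerate(posts):
        if rng.random() < config.duplicate_rate:
            out.append(Post(post_id=f"{user_id}-d{k:04d}",
                            timestamp=post.timestamp + timedelta(hours=1),
                            raw_text=post.raw_text))
        if rng.random() < config.bot_post_rate:
            out.append(Post(post_id=f"{user_id}-b{k:04d}",
                            timestamp=post.timestamp + timedelta(minutes=30),
                            raw_text="生日提醒 今天 是 好友 的 生日"))
    return out


def generate_embeddings(vocabulary: list[str], dimension: int, seed: int = 0,
                        cluster: set[str] | None = None) -> EmbeddingTable:
    """Unit-norm random embeddings for the given words.

    With ``cluster`` given, those words receive a shared directional bias
    (a common half-space), which makes the lexicon linearly separable from
    the background in embedding space — a controllable difficulty knob.
    """
    if dimension < 2:
        raise ValueError("dimension must be >= 2")
    rng = np.random.default_rng(seed)
    direction = np.zeros(dimension)
    direction[0] = 1.0
    vectors: dict[str, np.ndarray] = {}
    for word in vocabulary:
        v = rng.standard_normal(dimension)
        if cluster and word in cluster:
            v = v / np.linalg.norm(v) + 1.5 * direction
        vectors[word] = v / np.linalg.norm(v)
    return EmbeddingTable(dimension=dimension, vectors=vectors)


def corpus_vocabulary(config: GenConfig) -> list[str]:
    """Every token the generator can emit (for building embedding tables)."""
    lexicon, background = make_lexicon(config)
    extra = ["我", "我们", "流泪", *MODAL_PARTICLES]
    return sorted(set(background) | set(lexicon.terms) | set(extra))
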