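"""Post cleaning and filtering.

The cleaning pipeline runs in a fixed order — emoticon substitution, URL
removal, number removal, punctuation removal, word segmentation, bot-post
filtering, exact deduplication, short-post exclusion — chosen so that URL
fragments can never survive as tokens.  Punctuation is stripped only on the
classifier path; ``Post.raw_text`` is kept untouched so the linguistics
module can still profile punctuation and modal particles.

Segmentation is pluggable: any callable ``text -> list[str]`` works.  Two
segmenters ship with the package: a whitespace splitter (sufficient for the
synthetic corpora, whose words are space-delimited), and a dictionary
forward-maximum-matching segmenter for unsegmented CJK text, whose lexicon
can be extended with an external vocabulary (e.g. the vocabulary of a
pretrained embedding table).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .corpus_io import Corpus, Post, UserRecord

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_NUM_RE = re.compile(r"\d+")
_WS_RE = re.compile(r"\s+")
_EXTRA_STRIP = {"~", "～", "＋", "￥", "$", "^", "＾", "`", "｀", "|", "｜"}


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P") or ch in _EXTRA_STRIP


@dataclass
class PreprocessConfig:
    emoticon_map: dict[str, str] = field(default_factory=dict)
    bot_patterns: list[str] = field(default_factory=list)
    min_tokens: int = 3
    strip_urls: bool = True
    strip_numbers: bool = True
    strip_punct: bool = True

    def __post_init__(self):
        if self.min_tokens < 1:
            raise ValueError("min_tokens must be >= 1")
        if len(set(self.emoticon_map)) != len(self.emoticon_map):
            raise ValueError("emoticon_map keys must be unique")


def load_default_config(**overrides) -> PreprocessConfig:
    """Config with the packaged seed emoticon map and bot-pattern list."""
    data = resources.files("deprisk") / "data"
    emoticons: dict[str, str] = {}
    for line in (data / "emoticons.tsv").read_text(encoding="utf-8").splitlines():
        if line.strip() and not line.startswith("#"):
            emo, word = line.split("\t")
            emoticons[emo] = word
    patterns = [ln.strip() for ln in
                (data / "bot_patterns.txt").read_text(encoding="utf-8").splitlines()
                if ln.strip() and not ln.startswith("#")]
    return PreprocessConfig(emoticon_map=emoticons, bot_patterns=patterns, **overrides)


def read_emoticon_map(path: str | Path) -> dict[str, str]:
    """UTF-8 TSV, one ``emoticon<TAB>replacement`` per line."""
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip() and not line.startswith("#"):
            emo, word = line.split("\t")
            out[emo] = word
    return out


def clean_text(raw_text: str, config: PreprocessConfig) -> str:
    """Emoticon substitution, then URL / number / punctuation removal.

    Total on any string; the result may be empty.  Idempotent: a cleaned
    string passes through unchanged.
    """
    text = raw_text
    for emo, word in config.emoticon_map.items():
        text = text.replace(emo, f" {word} ")
    if config.strip_urls:
        text = _URL_RE.sub(" ", text)
    if config.strip_numbers:
        text = _NUM_RE.sub(" ", text)
    if config.strip_punct:
        text = "".join(" " if _is_punct(ch) else ch for ch in text)
    return _WS_RE.sub(" ", text).strip()


# -- segmenters ----------------------------------------------------------------


def whitespace_segmenter(text: str) -> list[str]:
    return text.split()


class MaxMatchSegmenter:
    """Greedy forward maximum matching against a word dictionary.

    Whitespace-delimited chunks are segmented independently; within a chunk
    the longest dictionary word starting at the cursor wins, falling back to
    a single character.  Deterministic by construction.
    """

    def __init__(self, vocab: set[str] | None = None):
        self.vocab: set[str] = set(vocab or ())
        self._max_len = max((len(w) for w in self.vocab), default=1)

    def add_words(self, words) -> None:
        for w in words:
            if w:
                self.vocab.add(w)
                self._max_len = max(self._max_len, len(w))

    def __call__(self, text: str) -> list[str]:
        tokens: list[str] = []
        for chunk in text.split():
            i = 0
            while i < len(chunk):
                for length in range(min(self._max_len, len(chunk) - i), 1, -1):
                    if chunk[i:i + length] in self.vocab:
                        tokens.append(chunk[i:i + length])
                        i += length
                        break
                else:
                    tokens.append(chunk[i])
                    i += 1
        return tokens


def segment(text: str, tokenizer, external_vocab: set[str] | None = None) -> list[str]:
    """Tokenize with a pluggable segmenter.

    When ``external_vocab`` is given and the segmenter exposes ``add_words``
    (as :class:`MaxMatchSegmenter` does), the vocabulary is injected into its
    lexicon before segmentation so multi-character terms surface as single
    tokens.
    """
    if external_vocab and hasattr(tokenizer, "add_words"):
        tokenizer.add_words(external_vocab)
    return [t for t in tokenizer(text) if t.strip()]


# -- user-level filtering ------------------------------------------------------


def _is_bot_post(post: Post, patterns: list[str]) -> bool:
    for pat in patterns:
        if pat.startswith("^") or pat.endswith("$"):
            if re.search(pat, post.raw_text):
                return True
        elif pat in post.raw_text:
            return True
    return False


def filter_user(user: UserRecord, config: PreprocessConfig) -> UserRecord:
    """Drop bot posts, exact duplicates (first kept), and short posts.

    Expects posts already cleaned and segmented.  Chronological order is
    preserved and the operation is idempotent.  A user left with zero posts
    is returned flagged in ``metadata['empty_after_filtering']`` rather than
    silently emptied; the caller decides whether to drop them.
    """
    kept: list[Post] = []
    seen: set[tuple[str, ...]] = set()
    for post in user.posts:
        if _is_bot_post(post, config.bot_patterns):
            continue
        key = tuple(post.tokens)
        if key in seen:
            continue
        if len(post.tokens) < config.min_tokens:
            continue
        seen.add(key)
        kept.append(post)
    metadata = dict(user.metadata)
    if kept:
        metadata.pop("empty_after_filtering", None)
    else:
        metadata["empty_after_filtering"] = True
    return UserRecord(user_id=user.user_id, label=user.label,
                      posts=kept, metadata=metadata)


def prepare_corpus(corpus: Corpus, config: PreprocessConfig | None = None,
                   tokenizer=whitespace_segmenter,
                   external_vocab: set[str] | None = None,
                   drop_empty_users: bool = True) -> tuple[Corpus, list[str]]:
    """Clean + segment + filter every user; returns (corpus, dropped user ids).

    ``raw_text`` is preserved on every surviving post for downstream
    punctuation/particle analysis.
    """
    if config is None:
        config = load_default_config()
    out_users: list[UserRecord] = []
    dropped: list[str] = []
    for user in corpus.users:
        cleaned_posts = []
        for post in user.posts:
            text = clean_text(post.raw_text, config)
            tokens = segment(text, tokenizer, external_vocab)
            cleaned_posts.append(replace(post, tokens=tokens))
        candidate = filter_user(
            UserRecord(user_id=user.user_id, label=user.label,
                       posts=cleaned_posts, metadata=dict(user.metadata)),
            config)
        if not candidate.posts and drop_empty_users:
            dropped.append(user.user_id)
        else:
            out_users.append(candidate)
    return Corpus(users=out_users, split_assignment=None), dropped
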