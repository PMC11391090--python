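"""Corpus data model and on-disk formats.

One *user* is the unit of classification: an anonymized id, a binary
depressed/control label, and a chronologically ordered sequence of
time-stamped posts.  Corpora are stored as newline-delimited JSON (one user
per line) so hundred-thousand-post collections stream without loading
everything eagerly elsewhere in a pipeline.

Also defined here: the plain-text depression lexicon, the LIWC-style
category dictionary (with trailing-wildcard prefixes), and the word2vec
text-format embedding table.  All text is NFC-normalized on read so that
lexicon and dictionary matching is stable for CJK input.
"""

from __future__ import annotations

import json
import unicodedata
import zlib
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

Label = Literal["depressed", "control"]
LABELS: tuple[Label, Label] = ("control", "depressed")


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass
class Post:
    post_id: str
    timestamp: datetime
    raw_text: str
    tokens: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.raw_text is None:
            raise ValueError("raw_text must not be null")
        if any(t == "" for t in self.tokens):
            raise ValueError("tokens must not contain empty strings")


@dataclass
class UserRecord:
    user_id: str
    label: Label
    posts: list[Post]
    metadata: dict = field(default_factory=dict)

    def sort_posts(self) -> None:
        """Ascending by timestamp; ties broken by post_id (stable, idempotent)."""
        self.posts.sort(key=lambda p: (p.timestamp, p.post_id))


@dataclass
class Corpus:
    users: list[UserRecord]
    split_assignment: dict[str, str] | None = None

    def __post_init__(self):
        seen: set[str] = set()
        for u in self.users:
            if u.user_id in seen:
                raise ValueError(f"duplicate user_id: {u.user_id!r}")
            seen.add(u.user_id)
        if self.split_assignment is not None:
            missing = seen - set(self.split_assignment)
            extra = set(self.split_assignment) - seen
            if missing or extra:
                raise ValueError(
                    f"split_assignment must cover every user exactly once "
                    f"(missing={sorted(missing)[:5]}, extra={sorted(extra)[:5]})")

    def by_label(self, label: Label) -> list[UserRecord]:
        return [u for u in self.users if u.label == label]

    def split(self, name: str) -> list[UserRecord]:
        if self.split_assignment is None:
            raise ValueError("corpus has no split assignment")
        return [u for u in self.users if self.split_assignment[u.user_id] == name]


@dataclass
class Lexicon:
    terms: frozenset[str]

    def __post_init__(self):
        if not self.terms:
            raise ValueError("lexicon must be non-empty")
        self.terms = frozenset(_nfc(t) for t in self.terms)

    def __contains__(self, word: str) -> bool:
        return word in self.terms

    def __len__(self) -> int:
        return len(self.terms)


class CategoryDictionary:
    """LIWC-style term -> categories map with trailing-wildcard prefixes.

    A trailing ``*`` on a pattern matches any token of which the pattern body
    is a prefix.  A token matching both a literal and a wildcard entry gets
    the union of the two category sets.
    """

    def __init__(self, categories: set[str],
                 entries: dict[str, set[str]]):
        self.categories = set(categories)
        self.literal: dict[str, set[str]] = {}
        self.prefixes: dict[str, set[str]] = {}
        seen: set[str] = set()
        for pattern, cats in entries.items():
            pattern = _nfc(pattern)
            if pattern in seen:
                raise ValueError(f"duplicate pattern: {pattern!r}")
            seen.add(pattern)
            unknown = set(cats) - self.categories
            if unknown:
                raise ValueError(
                    f"pattern {pattern!r} references undeclared categories {sorted(unknown)}")
            if not cats:
                raise ValueError(f"pattern {pattern!r} maps to no category")
            if pattern.endswith("*"):
                self.prefixes[pattern[:-1]] = set(cats)
            else:
                self.literal[pattern] = set(cats)

    def lookup(self, token: str) -> set[str]:
        token = _nfc(token)
        cats: set[str] = set()
        if token in self.literal:
            cats |= self.literal[token]
        for prefix, pcats in self.prefixes.items():
            if token.startswith(prefix):
                cats |= pcats
        return cats


class EmbeddingTable:
    """word -> dense vector, with a declared out-of-vocabulary policy.

    ``oov_policy="zero"`` returns the zero vector for unknown words;
    ``"seeded-random"`` returns a unit-scale Gaussian vector derived
    deterministically from (table seed, word).
    """

    def __init__(self, dimension: int, vectors: dict[str, np.ndarray],
                 oov_policy: str = "zero", seed: int = 0):
        if oov_policy not in ("zero", "seeded-random"):
            raise ValueError(f"unknown oov_policy {oov_policy!r}")
        self.dimension = int(dimension)
        self.vectors: dict[str, np.ndarray] = {}
        for word, vec in vectors.items():
            vec = np.asarray(vec, dtype=np.float64)
            if vec.shape != (self.dimension,):
                raise ValueError(f"vector for {word!r} has shape {vec.shape}, "
                                 f"expected ({self.dimension},)")
            self.vectors[_nfc(word)] = vec
        self.oov_policy = oov_policy
        self.seed = int(seed)

    def __contains__(self, word: str) -> bool:
        return _nfc(word) in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def lookup(self, word: str) -> np.ndarray:
        word = _nfc(word)
        if word in self.vectors:
            return self.vectors[word]
        if self.oov_policy == "zero":
            return np.zeros(self.dimension)
        # crc32 rather than hash(): stable across processes
        h = zlib.crc32(word.encode("utf-8")) ^ (self.seed & 0xFFFFFFFF)
        rng = np.random.default_rng(h)
        return rng.standard_normal(self.dimension) / np.sqrt(self.dimension)


# -- corpus JSONL --------------------------------------------------------------

_KNOWN_USER_KEYS = {"user_id", "label", "posts"}
_KNOWN_POST_KEYS = {"post_id", "ts", "text"}


def read_corpus(path: str | Path) -> Corpus:
    """Read a newline-delimited JSON corpus (one user object per line).

    Posts are re-sorted ascending by (timestamp, post_id) on read; unknown
    JSON keys are preserved in the user's ``metadata`` slot.
    """
    users: list[UserRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            try:
                posts = [
                    Post(post_id=str(p["post_id"]),
                         timestamp=datetime.fromisoformat(p["ts"]),
                         raw_text=_nfc(p["text"]),
                         tokens=[_nfc(t) for t in p.get("tokens", [])])
                    for p in obj["posts"]
                ]
                label = obj["label"]
                if label not in ("depressed", "control"):
                    raise ValueError(f"unknown label {label!r}")
                user = UserRecord(
                    user_id=str(obj["user_id"]), label=label, posts=posts,
                    metadata={k: v for k, v in obj.items() if k not in _KNOWN_USER_KEYS})
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}: invalid user record on line {lineno}: {exc}") from exc
            user.sort_posts()
            users.append(user)
    return Corpus(users=users)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u in corpus.users:
            obj = {
                "user_id": u.user_id,
                "label": u.label,
                "posts": [
                    {"post_id": p.post_id,
                     "ts": p.timestamp.isoformat(),
                     "text": p.raw_text,
                     **({"tokens": p.tokens} if p.tokens else {})}
                    for p in u.posts
                ],
                **u.metadata,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# -- lexicon -------------------------------------------------------------------

def read_lexicon(path: str | Path) -> Lexicon:
    """One term per line; ``#`` starts a comment; terms are lowercased + NFC."""
    terms: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            term = line.split("#", 1)[0].strip()
            if term:
                terms.add(_nfc(term.lower()))
    return Lexicon(terms=frozenset(terms))


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(lexicon.terms):
            fh.write(term + "\n")


# -- LIWC-style category dictionary -------------------------------------------

def read_category_dictionary(path: str | Path) -> CategoryDictionary:
    """Parse the ``.dic`` convention:

    ``%`` line, then ``id<TAB>name`` category declarations, ``%`` line, then
    ``term<TAB>id[,id...]`` (or whitespace-separated ids) entries.  ``*`` is
    only meaningful in terminal position of a term.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    # locate the two % delimiters
    marks = [i for i, ln in enumerate(lines) if ln.strip() == "%"]
    if len(marks) < 2:
        raise ValueError(f"{path}: expected a %%-delimited category header")
    id_to_name: dict[str, str] = {}
    for ln in lines[marks[0] + 1:marks[1]]:
        ln = ln.strip()
        if not ln:
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed category line {ln!r}")
        id_to_name[parts[0].strip()] = parts[1].strip()
    entries: dict[str, set[str]] = {}
    for ln in lines[marks[1] + 1:]:
        ln = ln.strip()
        if not ln:
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        term = parts[0]
        raw_ids: list[str] = []
        for chunk in parts[1:]:
            raw_ids.extend(c for c in chunk.split(",") if c)
        if not raw_ids:
            raise ValueError(f"{path}: entry {term!r} has no categories")
        cats = set()
        for cid in raw_ids:
            if cid not in id_to_name:
                raise ValueError(f"{path}: entry {term!r} references undeclared "
                                 f"category id {cid!r}")
            cats.add(id_to_name[cid])
        if term in entries:
            raise ValueError(f"{path}: duplicate pattern {term!r}")
        entries[term] = cats
    return CategoryDictionary(categories=set(id_to_name.values()), entries=entries)


def write_category_dictionary(dic: CategoryDictionary, path: str | Path) -> None:
    names = sorted(dic.categories)
    ids = {name: str(i + 1) for i, name in enumerate(names)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("%\n")
        for name in names:
            fh.write(f"{ids[name]}\t{name}\n")
        fh.write("%\n")
        for term in sorted(dic.literal):
            fh.write(f"{term}\t{','.join(sorted(ids[c] for c in dic.literal[term]))}\n")
        for prefix in sorted(dic.prefixes):
            fh.write(f"{prefix}*\t{','.join(sorted(ids[c] for c in dic.prefixes[prefix]))}\n")


# -- word2vec text embeddings --------------------------------------------------

def read_embeddings(path: str | Path, oov_policy: str = "zero",
                    seed: int = 0) -> EmbeddingTable:
    """word2vec text format: header ``V D``, then one ``word v1 ... vD`` line each."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: expected 'V D' header, got {header}")
        n_words, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            parts = [p for p in parts if p != ""]
            if not parts:
                continue
            word, vals = parts[0], parts[1:]
            if len(vals) != dim:
                raise ValueError(f"{path}: line {lineno} word {word!r} has "
                                 f"{len(vals)} values, expected {dim}")
            vectors[word] = np.array([float(v) for v in vals])
    if len(vectors) != n_words:
        raise ValueError(f"{path}: header declares {n_words} words, found {len(vectors)}")
    return EmbeddingTable(dimension=dim, vectors=vectors,
                          oov_policy=oov_policy, seed=seed)


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dimension}\n")
        for word in sorted(table.vectors):
            vals = " ".join(repr(float(v)) for v in table.vectors[word])
            fh.write(f"{word} {vals}\n")


def iter_tokens(users: Iterable[UserRecord]) -> Iterable[str]:
    for u in users:
        for p in u.posts:
            yield from p.tokens
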