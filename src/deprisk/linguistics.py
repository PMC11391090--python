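"""Group-level linguistic and behavioral profiling.

Computes, per cohort, the descriptive statistics commonly used to contrast
depressed and control users on social media: posting volume and frequency,
words per post, first-person pronoun use, depression-keyword and drug-term
mentions, modal-particle and punctuation profiles (from the raw,
pre-punctuation-strip text), and LIWC-style category relative frequencies
under a wildcard dictionary.  ``compare_groups`` turns two profiles into a
sorted difference table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .corpus_io import Corpus, CategoryDictionary, UserRecord

DEFAULT_KEYWORDS = ("抑郁症", "抑郁")
DEFAULT_DRUG_TERMS = ("舍曲林", "氟西汀", "帕罗西汀", "文拉法辛", "药物")
DEFAULT_PARTICLES = ("的", "呢", "吗", "吧", "啊")
DEFAULT_PUNCTUATION = ("。", "，", "！", "？", "~", "……")


@dataclass
class FeatureProfile:
    group: str
    features: dict[str, float] = field(default_factory=dict)
    denominators: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, value: float, denominator: str) -> None:
        if denominator in ("per-token", "per-token-pooled") and not 0 <= value <= 1:
            raise ValueError(f"relative frequency {name}={value} outside [0,1]")
        if value < 0:
            raise ValueError(f"rate {name}={value} negative")
        self.features[name] = float(value)
        self.denominators[name] = denominator


def _group_users(corpus: Corpus, group: str) -> list[UserRecord]:
    users = corpus.by_label(group)  # type: ignore[arg-type]
    if not users:
        raise ValueError(f"no users with label {group!r}")
    return users


def _user_weeks(user: UserRecord) -> int:
    """ceil(posting span in days / 7), at least 1 week."""
    if not user.posts:
        return 1
    span = (user.posts[-1].timestamp - user.posts[0].timestamp).total_seconds()
    return max(1, math.ceil(span / 86400.0 / 7.0))


def behavior_stats(corpus: Corpus,
                   keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
                   drug_terms: tuple[str, ...] = DEFAULT_DRUG_TERMS,
                   ) -> dict[str, FeatureProfile]:
    """Per-group posting-behavior averages.

    Word/Post and the per-post token counts use the segmented tokens;
    pronoun counting is token-exact, so 我 inside the token 我们 counts only
    as the plural.  All features are averaged within group.
    """
    profiles: dict[str, FeatureProfile] = {}
    for group in ("depressed", "control"):
        users = _group_users(corpus, group)
        prof = FeatureProfile(group=group)
        n_posts = sum(len(u.posts) for u in users)
        n_tokens = sum(len(p.tokens) for u in users for p in u.posts)
        sing = sum(1 for u in users for p in u.posts for t in p.tokens if t == "我")
        plur = sum(1 for u in users for p in u.posts for t in p.tokens if t == "我们")
        kw = sum(1 for u in users for p in u.posts for t in p.tokens if t in keywords)
        drugs = sum(1 for u in users for p in u.posts for t in p.tokens
                    if t in drug_terms)
        prof.add("Word/Post", n_tokens / n_posts, "per-post")
        prof.add("Post/User", n_posts / len(users), "per-user")
        prof.add("Post/User/Week",
                 sum(len(u.posts) / _user_weeks(u) for u in users) / len(users),
                 "per-user-week")
        prof.add("1stPerSing/Post", sing / n_posts, "per-post")
        prof.add("1stPerPlural/Post", plur / n_posts, "per-post")
        prof.add("Keyword/Post", kw / n_posts, "per-post")
        prof.add("Drugs/Post", drugs / n_posts, "per-post")
        profiles[group] = prof
    return profiles


def category_frequencies(corpus: Corpus, dictionary: CategoryDictionary,
                         denominator: str = "per-token-pooled",
                         ) -> dict[str, FeatureProfile]:
    """Relative frequency of each dictionary category, per group.

    ``per-token-pooled``: category token count over the group's total token
    count.  ``per-user-mean``: the same proportion computed per user, then
    averaged over the group's users.
    """
    if denominator not in ("per-token-pooled", "per-user-mean"):
        raise ValueError(f"unknown denominator {denominator!r}")
    if not dictionary.categories:
        raise ValueError("dictionary has no categories")
    cats = sorted(dictionary.categories)
    profiles: dict[str, FeatureProfile] = {}
    for group in ("depressed", "control"):
        users = _group_users(corpus, group)
        prof = FeatureProfile(group=group)
        if denominator == "per-token-pooled":
            counts = dict.fromkeys(cats, 0)
            total = 0
            for u in users:
                for p in u.posts:
                    for t in p.tokens:
                        total += 1
                        for c in dictionary.lookup(t):
                            counts[c] += 1
            for c in cats:
                prof.add(c, counts[c] / total if total else 0.0, denominator)
        else:
            sums = dict.fromkeys(cats, 0.0)
            for u in users:
                counts = dict.fromkeys(cats, 0)
                total = 0
                for p in u.posts:
                    for t in p.tokens:
                        total += 1
                        for c in dictionary.lookup(t):
                            counts[c] += 1
                for c in cats:
                    sums[c] += counts[c] / total if total else 0.0
            for c in cats:
                prof.add(c, sums[c] / len(users), denominator)
        profiles[group] = prof
    return profiles


def symbol_profile(corpus: Corpus,
                   symbol_set: tuple[str, ...] = DEFAULT_PARTICLES + DEFAULT_PUNCTUATION,
                   ) -> dict[str, FeatureProfile]:
    """Occurrences of each symbol per post, averaged within group.

    Counts run over ``raw_text`` (the pre-punctuation-strip copy), so both
    modal particles and punctuation marks are visible.  Multi-character
    symbols (……) are counted as non-overlapping substring occurrences;
    longer symbols are counted first and masked out so 。 never double-counts
    inside ……-free text and ～ sequences stay separate.
    """
    ordered = sorted(symbol_set, key=len, reverse=True)
    profiles: dict[str, FeatureProfile] = {}
    for group in ("depressed", "control"):
        users = _group_users(corpus, group)
        counts = dict.fromkeys(symbol_set, 0)
        n_posts = 0
        for u in users:
            for p in u.posts:
                n_posts += 1
                text = p.raw_text
                for sym in ordered:
                    c = text.count(sym)
                    if c:
                        counts[sym] += c
                        text = text.replace(sym, "\x00")
        prof = FeatureProfile(group=group)
        for sym in symbol_set:
            prof.add(sym, counts[sym] / n_posts if n_posts else 0.0, "per-post")
        profiles[group] = prof
    return profiles


def compare_groups(profile_depressed: FeatureProfile,
                   profile_control: FeatureProfile,
                   csv_path: str | None = None) -> pd.DataFrame:
    """Feature-by-feature difference table, sorted by |difference| desc.

    Columns: both group values, absolute difference, ratio
    (depressed/control; inf when control is 0), and a direction flag.
    """
    fd, fc = profile_depressed.features, profile_control.features
    asym = set(fd) ^ set(fc)
    if asym:
        raise ValueError(f"profiles disagree on features: {sorted(asym)}")
    rows = []
    for name in fd:
        d, c = fd[name], fc[name]
        rows.append({
            "feature": name,
            "depressed": d,
            "control": c,
            "abs_difference": abs(d - c),
            "ratio": (d / c) if c else (math.inf if d else math.nan),
            "direction": ("depressed>control" if d > c
                          else "control>depressed" if c > d else "equal"),
        })
    frame = (pd.DataFrame(rows)
             .sort_values("abs_difference", ascending=False, kind="stable")
             .reset_index(drop=True))
    if csv_path:
        frame.to_csv(csv_path, index=False)
    return frame
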