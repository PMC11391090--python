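"""Shared fixtures: tiny hand-built corpora and generated benchmarks."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from deprisk.corpus_io import Corpus, Post, UserRecord


def make_post(post_id: str, hours: int, text: str = "",
              tokens: list[str] | None = None) -> Post:
    return Post(post_id=post_id,
                timestamp=datetime(2023, 1, 1) + timedelta(hours=hours),
                raw_text=text, tokens=tokens or [])


def make_user(user_id: str, label: str, token_lists: list[list[str]],
              hours_step: int = 24) -> UserRecord:
    posts = [make_post(f"{user_id}-p{i}", i * hours_step, " ".join(toks), list(toks))
             for i, toks in enumerate(token_lists)]
    return UserRecord(user_id=user_id, label=label, posts=posts)


@pytest.fixture
def two_user_corpus() -> Corpus:
    dep = make_user("u-dep", "depressed",
                    [["想", "哭", "了"], ["失眠", "又", "来", "了"]])
    con = make_user("u-con", "control",
                    [["今天", "天气", "很", "好"], ["晚饭", "很", "好吃"]])
    return Corpus(users=[dep, con])
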