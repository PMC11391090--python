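"""Behavioral statistics, category frequencies, symbol profiles."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from deprisk import preprocess, synthetic
from deprisk.corpus_io import CategoryDictionary, Corpus, Post, UserRecord
from deprisk.linguistics import (FeatureProfile, behavior_stats,
                                 category_frequencies, compare_groups,
                                 symbol_profile)

from conftest import make_user


def user_spanning(user_id, label, n_posts, span_days, tokens=("a", "b", "c")):
    posts = [Post(post_id=f"{user_id}-p{i}",
                  timestamp=datetime(2023, 1, 1) + timedelta(
                      days=i * span_days / max(n_posts - 1, 1)),
                  raw_text=" ".join(tokens), tokens=list(tokens))
             for i in range(n_posts)]
    return UserRecord(user_id=user_id, label=label, posts=posts)


class TestBehaviorStats:
    def test_posts_per_user_week(self):
        # 10 posts over 34 days -> ceil(34/7) = 5 weeks -> 2 posts/week
        corpus = Corpus(users=[user_spanning("d", "depressed", 10, 34),
                               user_spanning("c", "control", 10, 34)])
        prof = behavior_stats(corpus)
        assert prof["depressed"].features["Post/User/Week"] == pytest.approx(2.0)

    def test_pronoun_counting_is_token_exact(self):
        dep = make_user("d", "depressed", [["我", "很", "难过"]])
        con = make_user("c", "control", [["我们", "都", "很", "好"]])
        prof = behavior_stats(Corpus(users=[dep, con]))
        assert prof["depressed"].features["1stPerSing/Post"] == 1.0
        assert prof["depressed"].features["1stPerPlural/Post"] == 0.0
        assert prof["control"].features["1stPerSing/Post"] == 0.0
        assert prof["control"].features["1stPerPlural/Post"] == 1.0

    def test_generated_corpus_reproduces_behavioral_contrasts(self):
        cfg = synthetic.preset("strong", n_users_per_class=60,
                               include_cjk_terms=True, seed=8)
        clean, _ = preprocess.prepare_corpus(synthetic.generate_corpus(cfg))
        prof = behavior_stats(clean)
        dep, con = prof["depressed"].features, prof["control"].features
        assert dep["Word/Post"] < con["Word/Post"]
        assert dep["Post/User"] < con["Post/User"]
        assert dep["1stPerSing/Post"] > con["1stPerSing/Post"]
        assert dep["1stPerPlural/Post"] < con["1stPerPlural/Post"]
        assert dep["Keyword/Post"] > con["Keyword/Post"]

    def test_missing_group_rejected(self):
        corpus = Corpus(users=[make_user("c", "control", [["a", "b", "c"]])])
        with pytest.raises(ValueError, match="depressed"):
            behavior_stats(corpus)


class TestCategoryFrequencies:
    DIC = CategoryDictionary({"NegEmo", "Any"},
                             {"难过": {"NegEmo"}, "哭*": {"NegEmo"}})

    def _corpus(self):
        dep = make_user("d", "depressed",
                        [["难过", "哭泣", "x", "y", "z"], ["p", "q", "r", "s", "t"]])
        con = make_user("c", "control", [["x"] * 10])
        return Corpus(users=[dep, con])

    def test_pooled_count_and_divide(self):
        prof = category_frequencies(self._corpus(), self.DIC)
        assert prof["depressed"].features["NegEmo"] == pytest.approx(0.2)
        assert prof["control"].features["NegEmo"] == 0.0

    def test_saturating_dictionary_gives_one(self):
        dic = CategoryDictionary({"All"}, {"*": {"All"}})
        prof = category_frequencies(self._corpus(), dic)
        assert prof["depressed"].features["All"] == 1.0

    def test_per_user_mean_denominator(self):
        corpus = Corpus(users=[
            make_user("d1", "depressed", [["难过", "x"]]),      # 0.5
            make_user("d2", "depressed", [["x", "y", "z", "w"]]),  # 0.0
            make_user("c", "control", [["x", "y"]])])
        prof = category_frequencies(corpus, self.DIC, "per-user-mean")
        assert prof["depressed"].features["NegEmo"] == pytest.approx(0.25)

    def test_agrees_with_nested_loop_counter_exactly(self):
        rng = np.random.default_rng(21)
        vocab = ["难过", "哭泣", "哭了", "x", "y", "z"]
        users = []
        for i in range(6):
            label = "depressed" if i % 2 else "control"
            token_lists = [[vocab[j] for j in rng.integers(0, 6, size=5)]
                           for _ in range(3)]
            users.append(make_user(f"u{i}", label, token_lists))
        corpus = Corpus(users=users)
        prof = category_frequencies(corpus, self.DIC)
        for group in ("depressed", "control"):
            tokens = [t for u in corpus.by_label(group)
                      for p in u.posts for t in p.tokens]
            count = sum(1 for t in tokens if self.DIC.lookup(t))
            assert prof[group].features["NegEmo"] == count / len(tokens)

    def test_disjoint_categories_sum_below_one(self):
        dic = CategoryDictionary({"A", "B"}, {"难过": {"A"}, "x": {"B"}})
        prof = category_frequencies(self._corpus(), dic)
        for group in prof:
            assert sum(prof[group].features.values()) <= 1.0


class TestSymbolProfile:
    def test_counts_particles_and_punctuation(self):
        dep = UserRecord(user_id="d", label="depressed", posts=[
            Post(post_id="p", timestamp=datetime(2023, 1, 1),
                 raw_text="好吧。", tokens=["好吧"])])
        con = make_user("c", "control", [["x", "y", "z"]])
        prof = symbol_profile(Corpus(users=[dep, con]))
        feats = prof["depressed"].features
        assert feats["吧"] == 1.0 and feats["。"] == 1.0
        assert feats["啊"] == 0.0 and feats["，"] == 0.0

    def test_absent_symbol_is_zero_for_both_groups(self):
        corpus = Corpus(users=[make_user("d", "depressed", [["a", "b", "c"]]),
                               make_user("c", "control", [["x", "y", "z"]])])
        prof = symbol_profile(corpus, symbol_set=("！",))
        assert prof["depressed"].features["！"] == 0.0
        assert prof["control"].features["！"] == 0.0

    def test_generated_corpus_reproduces_punctuation_contrasts(self):
        cfg = synthetic.preset("strong", n_users_per_class=60, seed=13)
        corpus = synthetic.generate_corpus(cfg)
        prof = symbol_profile(corpus)
        dep, con = prof["depressed"].features, prof["control"].features
        assert dep["。"] > con["。"]      # periods more frequent when depressed
        assert dep["，"] < con["，"]      # commas the other way
        assert dep["……"] > con["……"]
        assert dep["吧"] > con["吧"] and dep["啊"] < con["啊"]


class TestCompareGroups:
    def _profiles(self, d_feats, c_feats):
        d = FeatureProfile(group="depressed")
        c = FeatureProfile(group="control")
        for k, v in d_feats.items():
            d.add(k, v, "per-post")
        for k, v in c_feats.items():
            c.add(k, v, "per-post")
        return d, c

    def test_identical_profiles_have_zero_differences(self):
        d, c = self._profiles({"f": 0.3, "g": 0.1}, {"f": 0.3, "g": 0.1})
        table = compare_groups(d, c)
        assert (table["abs_difference"] == 0).all()
        assert (table["direction"] == "equal").all()

    def test_difference_ratio_direction(self):
        d, c = self._profiles({"f": 0.02}, {"f": 0.01})
        row = compare_groups(d, c).iloc[0]
        assert row["abs_difference"] == pytest.approx(0.01)
        assert row["ratio"] == pytest.approx(2.0)
        assert row["direction"] == "depressed>control"

    def test_row_count_is_shared_feature_count(self):
        d, c = self._profiles({"a": 1, "b": 2, "c": 3}, {"a": 1, "b": 1, "c": 1})
        assert len(compare_groups(d, c)) == 3

    def test_mismatched_features_error_lists_them(self):
        d, c = self._profiles({"a": 1, "weird": 2}, {"a": 1})
        with pytest.raises(ValueError, match="weird"):
            compare_groups(d, c)
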