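"""Corpus / lexicon / dictionary / embedding I-O round trips and invariants."""

from __future__ import annotations

import numpy as np
import pytest

from deprisk import corpus_io, synthetic
from deprisk.corpus_io import (CategoryDictionary, Corpus, EmbeddingTable,
                               Lexicon, read_category_dictionary, read_corpus,
                               read_embeddings, read_lexicon, write_corpus,
                               write_embeddings)

from conftest import make_post, make_user


class TestCorpusJSONL:
    def test_round_trip_is_identity(self, tmp_path):
        corpus = synthetic.generate_corpus(
            synthetic.preset("strong", n_users_per_class=5, seed=7))
        path = tmp_path / "c.jsonl"
        write_corpus(corpus, path)
        back = read_corpus(path)
        assert len(back.users) == len(corpus.users)
        for a, b in zip(corpus.users, back.users):
            assert (a.user_id, a.label) == (b.user_id, b.label)
            assert a.metadata == b.metadata
            assert [(p.post_id, p.timestamp, p.raw_text) for p in a.posts] == \
                   [(p.post_id, p.timestamp, p.raw_text) for p in b.posts]

    def test_two_wellformed_lines_give_two_users(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text(
            '{"user_id": "a", "label": "depressed", "posts": '
            '[{"post_id": "p1", "ts": "2023-01-01T00:00:00", "text": "x"}]}\n'
            '{"user_id": "b", "label": "control", "posts": '
            '[{"post_id": "p1", "ts": "2023-01-02T00:00:00", "text": "y"}]}\n',
            encoding="utf-8")
        corpus = read_corpus(path)
        assert [u.user_id for u in corpus.users] == ["a", "b"]

    def test_out_of_order_posts_are_sorted_on_read(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text(
            '{"user_id": "a", "label": "control", "posts": ['
            '{"post_id": "p2", "ts": "2023-06-01T00:00:00", "text": "later"}, '
            '{"post_id": "p1", "ts": "2023-01-01T00:00:00", "text": "earlier"}]}\n',
            encoding="utf-8")
        user = read_corpus(path).users[0]
        assert [p.post_id for p in user.posts] == ["p1", "p2"]

    def test_sorting_breaks_ties_by_post_id_and_is_idempotent(self):
        user = make_user("u", "control", [["a"], ["b"], ["c"]], hours_step=0)
        user.posts.reverse()
        user.sort_posts()
        once = [p.post_id for p in user.posts]
        user.sort_posts()
        assert once == [p.post_id for p in user.posts] == sorted(once)

    def test_duplicate_user_id_raises_naming_the_user(self, tmp_path):
        line = ('{"user_id": "dup", "label": "control", "posts": '
                '[{"post_id": "p", "ts": "2023-01-01T00:00:00", "text": "x"}]}\n')
        path = tmp_path / "c.jsonl"
        path.write_text(line + line, encoding="utf-8")
        with pytest.raises(ValueError, match="dup"):
            read_corpus(path)

    def test_malformed_line_error_names_line_number(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text('{"user_id": "a", "label": "control", "posts": []}\n'
                        "not json\n", encoding="utf-8")
        with pytest.raises(ValueError, match="line 2"):
            read_corpus(path)

    def test_unknown_keys_survive_in_metadata(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text(
            '{"user_id": "a", "label": "control", "extra": [1, 2], "posts": '
            '[{"post_id": "p", "ts": "2023-01-01T00:00:00", "text": "x"}]}\n',
            encoding="utf-8")
        assert read_corpus(path).users[0].metadata == {"extra": [1, 2]}

    def test_split_assignment_must_cover_all_users(self):
        users = [make_user("a", "control", [[["x"]][0]]),
                 make_user("b", "depressed", [[["y"]][0]])]
        with pytest.raises(ValueError, match="split_assignment"):
            Corpus(users=users, split_assignment={"a": "train"})


class TestLexicon:
    def test_read_lowercases_and_skips_comments(self, tmp_path):
        path = tmp_path / "lex.txt"
        path.write_text("# comment\n失眠\nSAD  # trailing\n\n", encoding="utf-8")
        lex = read_lexicon(path)
        assert lex.terms == frozenset({"失眠", "sad"})

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            Lexicon(terms=frozenset())


class TestCategoryDictionary:
    DIC = "%\n1\tNegEmo\n2\tAnx\n3\tSad\n%\n难过\t1\n哭*\t3\n紧张\t1,2\n"

    def test_literal_lookup(self, tmp_path):
        path = tmp_path / "d.dic"
        path.write_text(self.DIC, encoding="utf-8")
        dic = read_category_dictionary(path)
        assert dic.lookup("难过") == {"NegEmo"}
        assert dic.lookup("紧张") == {"NegEmo", "Anx"}

    def test_wildcard_matches_prefix(self, tmp_path):
        path = tmp_path / "d.dic"
        path.write_text(self.DIC, encoding="utf-8")
        dic = read_category_dictionary(path)
        assert dic.lookup("哭泣") == {"Sad"}
        assert dic.lookup("哭") == {"Sad"}
        assert dic.lookup("大哭") == set()

    def test_literal_and_wildcard_union(self):
        dic = CategoryDictionary({"A", "B"}, {"哭": {"A"}, "哭*": {"B"}})
        assert dic.lookup("哭") == {"A", "B"}
        assert dic.lookup("哭泣") == {"B"}

    def test_undeclared_category_rejected(self, tmp_path):
        path = tmp_path / "d.dic"
        path.write_text("%\n1\tNegEmo\n%\nfoo\t9\n", encoding="utf-8")
        with pytest.raises(ValueError, match="foo"):
            read_category_dictionary(path)

    def test_round_trip(self, tmp_path):
        path = tmp_path / "d.dic"
        path.write_text(self.DIC, encoding="utf-8")
        dic = read_category_dictionary(path)
        out = tmp_path / "out.dic"
        corpus_io.write_category_dictionary(dic, out)
        back = read_category_dictionary(out)
        assert back.categories == dic.categories
        assert back.literal == dic.literal
        assert back.prefixes == dic.prefixes


class TestEmbeddings:
    def test_read_header_and_rows(self, tmp_path):
        path = tmp_path / "emb.txt"
        path.write_text("3 2\na 0.5 1.0\nb -1.0 2.0\nc 0.0 0.0\n", encoding="utf-8")
        table = read_embeddings(path)
        assert table.dimension == 2 and len(table) == 3
        np.testing.assert_array_equal(table.lookup("a"), [0.5, 1.0])

    def test_oov_zero_policy(self, tmp_path):
        path = tmp_path / "emb.txt"
        path.write_text("1 3\na 1 2 3\n", encoding="utf-8")
        table = read_embeddings(path, oov_policy="zero")
        np.testing.assert_array_equal(table.lookup("missing"), np.zeros(3))

    def test_oov_seeded_random_is_deterministic(self):
        t1 = EmbeddingTable(2, {"a": np.zeros(2)}, oov_policy="seeded-random", seed=5)
        t2 = EmbeddingTable(2, {"a": np.zeros(2)}, oov_policy="seeded-random", seed=5)
        np.testing.assert_array_equal(t1.lookup("q"), t2.lookup("q"))
        assert not np.allclose(t1.lookup("q"), t1.lookup("r"))

    def test_wrong_arity_row_rejected_with_word_and_line(self, tmp_path):
        path = tmp_path / "emb.txt"
        path.write_text("2 3\na 1 2 3\nbad 1 2\n", encoding="utf-8")
        with pytest.raises(ValueError, match="bad"):
            read_embeddings(path)

    def test_write_read_round_trip_is_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        table = EmbeddingTable(4, {f"w{i}": rng.standard_normal(4) for i in range(5)})
        path = tmp_path / "emb.txt"
        write_embeddings(table, path)
        back = read_embeddings(path)
        for w in table.vectors:
            np.testing.assert_array_equal(back.vectors[w], table.vectors[w])
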