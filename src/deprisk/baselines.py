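"""Flat "concatenated long text" baseline encoders and a hierarchical CNN.

The classic alternative to hierarchical user modeling is to join all of a
user's (sampled) posts into one long document and encode it flat.  This
module implements that family — CNN, LSTM, GRU, BiLSTM, BiGRU, each with
optional additive-attention pooling — plus HCN, a hierarchical
convolutional network that mirrors the HTN hierarchy with CNN encoders at
both levels.  All models share the sigmoid classifier head and the training
loop in :mod:`deprisk.train_eval`; the encoder is the only degree of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .corpus_io import UserRecord
from .htn import Vocab
from .sampling import SampledView

FLAT_ENCODERS = ("cnn", "lstm", "gru", "bilstm", "bigru")
ALL_ENCODERS = FLAT_ENCODERS + ("hcn",)


@dataclass
class BaselineConfig:
    encoder: str = "cnn"
    attention: bool = False
    cnn_kernel_sizes: tuple[int, ...] = (2, 3, 4)
    cnn_filters: int = 100
    hidden: int = 256
    attn_size: int = 256
    max_concat_tokens: int = 1024
    max_posts_per_user: int = 128
    max_post_tokens: int = 512

    def __post_init__(self):
        if self.encoder not in ALL_ENCODERS:
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if any(k < 1 for k in self.cnn_kernel_sizes):
            raise ValueError("kernel sizes must be >= 1")
        if self.hidden < 1 or self.cnn_filters < 1:
            raise ValueError("hidden and filter sizes must be positive")


def concat_user_text(user: UserRecord, view: SampledView,
                     max_concat_tokens: int) -> list[str]:
    """Selected posts' tokens joined in chronological order, truncated."""
    if not view.selected:
        raise ValueError(f"empty view for user {user.user_id!r}")
    tokens: list[str] = []
    for i in view.selected:
        tokens.extend(user.posts[i].tokens)
        if len(tokens) >= max_concat_tokens:
            break
    return tokens[:max_concat_tokens]


class FlatBaselineModel(nn.Module):
    """Concatenated-document encoder + sigmoid head."""

    def __init__(self, config: BaselineConfig, vocab: Vocab, seed: int = 0):
        if config.encoder not in FLAT_ENCODERS:
            raise ValueError(f"{config.encoder!r} is not a flat encoder")
        rng = np.random.default_rng(seed)
        self.config = config
        self.vocab = vocab
        d = vocab.dimension
        self.embedding = nn.Tensor(vocab.matrix.copy(), requires_grad=True)
        enc = config.encoder
        if enc == "cnn":
            self.cnn = nn.TextCNN(d, config.cnn_kernel_sizes, config.cnn_filters, rng)
            out_dim = self.cnn.out_dim
        elif enc in ("lstm", "bilstm"):
            self.rnn_f = nn.LSTM(d, config.hidden, rng)
            self.rnn_b = nn.LSTM(d, config.hidden, rng) if enc == "bilstm" else None
            out_dim = config.hidden * (2 if enc == "bilstm" else 1)
        else:  # gru / bigru
            self.rnn_f = nn.GRU(d, config.hidden, rng)
            self.rnn_b = nn.GRU(d, config.hidden, rng) if enc == "bigru" else None
            out_dim = config.hidden * (2 if enc == "bigru" else 1)
        if config.attention and enc != "cnn":
            self.attn = nn.AdditiveAttention(out_dim, config.attn_size, rng)
        else:
            self.attn = None
        self.out_dim = out_dim
        self.head = nn.Linear(out_dim, 1, rng)

    def set_train(self, seed: int | None) -> None:  # interface parity with HTN
        pass

    def prepare_batch(self, pairs: list[tuple[UserRecord, SampledView]]) -> dict:
        docs = [self.vocab.ids(concat_user_text(u, v, self.config.max_concat_tokens))
                for u, v in pairs]
        if any(not d for d in docs):
            raise ValueError("a user's concatenated document is empty")
        B = len(docs)
        L = max(len(d) for d in docs)
        ids = np.zeros((B, L), dtype=np.int64)
        mask = np.zeros((B, L), dtype=np.float64)
        for b, doc in enumerate(docs):
            ids[b, :len(doc)] = doc
            mask[b, :len(doc)] = 1.0
        return {"ids": ids, "mask": mask,
                "labels": np.array([1.0 if u.label == "depressed" else 0.0
                                    for u, _ in pairs])}

    def encode_flat(self, ids: np.ndarray, mask: np.ndarray) -> nn.Tensor:
        x = nn.embedding(self.embedding, ids)  # (B, L, d)
        if self.config.encoder == "cnn":
            lengths = mask.sum(axis=1).astype(np.int64)
            return self.cnn(x, lengths)
        hs = self.rnn_f(x, mask)
        if self.rnn_b is not None:
            hs = nn.concatenate([hs, self.rnn_b(x, mask, reverse=True)], axis=-1)
        if self.attn is not None:
            return self.attn(hs, mask)
        if self.rnn_b is None:
            return hs[:, -1, :]  # masked carry-through makes this the last valid state
        fwd = hs[:, -1, :self.config.hidden]
        bwd = hs[:, 0, self.config.hidden:]
        return nn.concatenate([fwd, bwd], axis=-1)

    def forward(self, batch: dict) -> nn.Tensor:
        doc = self.encode_flat(batch["ids"], batch["mask"])
        return self.head(doc).reshape(len(batch["ids"]))

    def predict_user(self, user: UserRecord, view: SampledView,
                     threshold: float = 0.5) -> tuple[float, str]:
        batch = self.prepare_batch([(user, view)])
        with nn.no_grad():
            logit = float(self.forward(batch).data[0])
        prob = float(1.0 / (1.0 + np.exp(-logit)))
        return prob, ("depressed" if prob >= threshold else "control")


class HCNModel(nn.Module):
    """Hierarchical convolutional network: a shared per-post text CNN, then a
    CNN + max-pool over the chronological post-vector sequence."""

    def __init__(self, config: BaselineConfig, vocab: Vocab, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.vocab = vocab
        self.embedding = nn.Tensor(vocab.matrix.copy(), requires_grad=True)
        self.post_cnn = nn.TextCNN(vocab.dimension, config.cnn_kernel_sizes,
                                   config.cnn_filters, rng)
        self.user_cnn = nn.TextCNN(self.post_cnn.out_dim, config.cnn_kernel_sizes,
                                   config.cnn_filters, rng)
        self.out_dim = self.user_cnn.out_dim
        self.head = nn.Linear(self.out_dim, 1, rng)

    def set_train(self, seed: int | None) -> None:
        pass

    def prepare_batch(self, pairs: list[tuple[UserRecord, SampledView]]) -> dict:
        cfg = self.config
        seqs = []
        for user, view in pairs:
            if not view.selected:
                raise ValueError(f"empty view for user {user.user_id!r}")
            idx = view.selected[-cfg.max_posts_per_user:]
            seqs.append([self.vocab.ids(user.posts[i].tokens[:cfg.max_post_tokens])
                         for i in idx])
        B = len(seqs)
        P = max(len(s) for s in seqs)
        T = max(len(p) for s in seqs for p in s)
        ids = np.zeros((B, P, T), dtype=np.int64)
        tok_len = np.zeros((B, P), dtype=np.int64)
        post_len = np.zeros(B, dtype=np.int64)
        for b, posts in enumerate(seqs):
            post_len[b] = len(posts)
            for p, toks in enumerate(posts):
                ids[b, p, :len(toks)] = toks
                tok_len[b, p] = len(toks)
        return {"ids": ids, "tok_len": tok_len, "post_len": post_len,
                "labels": np.array([1.0 if u.label == "depressed" else 0.0
                                    for u, _ in pairs])}

    def forward(self, batch: dict) -> nn.Tensor:
        ids, tok_len = batch["ids"], batch["tok_len"]
        B, P, T = ids.shape
        x = nn.embedding(self.embedding, ids.reshape(B * P, T))
        post_vecs = self.post_cnn(x, np.maximum(tok_len.reshape(B * P), 1))
        post_vecs = post_vecs.reshape(B, P, self.post_cnn.out_dim)
        user_vec = self.user_cnn(post_vecs, batch["post_len"])
        return self.head(user_vec).reshape(B)

    def predict_user(self, user: UserRecord, view: SampledView,
                     threshold: float = 0.5) -> tuple[float, str]:
        batch = self.prepare_batch([(user, view)])
        with nn.no_grad():
            logit = float(self.forward(batch).data[0])
        prob = float(1.0 / (1.0 + np.exp(-logit)))
        return prob, ("depressed" if prob >= threshold else "control")


def build_baseline(config: BaselineConfig, vocab: Vocab, seed: int = 0):
    if config.encoder == "hcn":
        return HCNModel(config, vocab, seed)
    return FlatBaselineModel(config, vocab, seed)
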