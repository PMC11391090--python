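"""Hierarchical transformer network (HTN) for user-level classification.

Architecture, bottom to top:

1. **Word-level encoder** — a shared transformer over each post's word
   embeddings.  A learned ``[CLS]`` vector is prepended, sinusoidal
   positional encodings are added, and the final-layer ``[CLS]`` state is
   the post embedding.
2. **Post-level encoder** — a transformer over the chronological sequence
   of post embeddings (positions index posting order).
3. **Aggregation** — an LSTM over the contextualized post sequence followed
   by additive attention over its hidden states, yielding one user vector.
4. **Classifier** — an affine map + sigmoid giving the probability that the
   user belongs to the depressed cohort.

All posts of all users share the word-level encoder parameters.  Evaluation
is deterministic (dropout only active in training mode with a seeded rng).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .corpus_io import EmbeddingTable, UserRecord
from .sampling import SampledView, full_view

PAD_ID = 0
UNK_ID = 1


@dataclass
class HTNConfig:
    d_model: int = 256
    n_heads: int = 4
    n_word_layers: int = 2
    n_post_layers: int = 2
    ffn_mult: int = 4
    lstm_hidden: int = 256
    attn_size: int = 256
    max_post_tokens: int = 512
    max_posts_per_user: int = 128
    dropout: float = 0.1
    word_positional: bool = True
    post_positional: bool = True

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        for name in ("d_model", "n_heads", "n_word_layers", "n_post_layers",
                     "ffn_mult", "lstm_hidden", "attn_size",
                     "max_post_tokens", "max_posts_per_user"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class Vocab:
    """Token -> id map built from an embedding table.

    Id 0 is padding (zero vector), id 1 the unknown word (vector per the
    table's OOV policy); real words follow in sorted order so the mapping is
    deterministic.
    """

    def __init__(self, table: EmbeddingTable):
        self.words = sorted(table.vectors)
        self.index = {w: i + 2 for i, w in enumerate(self.words)}
        self.dimension = table.dimension
        unk = (np.zeros(table.dimension) if table.oov_policy == "zero"
               else table.lookup("<unk>"))
        self.matrix = np.vstack(
            [np.zeros(table.dimension), unk] + [table.vectors[w] for w in self.words])

    def __len__(self) -> int:
        return len(self.words) + 2

    def ids(self, tokens: list[str]) -> list[int]:
        return [self.index.get(t, UNK_ID) for t in tokens]


class HTNModel(nn.Module):
    def __init__(self, config: HTNConfig, vocab: Vocab, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.vocab = vocab
        d = config.d_model
        self.embedding = nn.Tensor(vocab.matrix.copy(), requires_grad=True)
        # project pretrained embeddings into the model width when they differ
        self.input_proj = (nn.Linear(vocab.dimension, d, rng)
                           if vocab.dimension != d else None)
        self.cls = nn.Tensor(rng.standard_normal(d) / np.sqrt(d), requires_grad=True)
        self.word_encoder = nn.TransformerEncoder(
            d, config.n_heads, config.n_word_layers, config.ffn_mult, rng,
            use_positions=config.word_positional)
        self.post_encoder = nn.TransformerEncoder(
            d, config.n_heads, config.n_post_layers, config.ffn_mult, rng,
            use_positions=config.post_positional)
        self.lstm = nn.LSTM(d, config.lstm_hidden, rng)
        self.attention = nn.AdditiveAttention(config.lstm_hidden, config.attn_size, rng)
        self.head = nn.Linear(config.lstm_hidden, 1, rng)
        self._drop_rng: np.random.Generator | None = None

    # -- training-mode dropout -------------------------------------------------

    def set_train(self, seed: int | None) -> None:
        """Enable dropout with a fresh seeded rng, or disable with None."""
        self._drop_rng = None if seed is None else np.random.default_rng(seed)

    @property
    def _drop(self) -> float:
        return self.config.dropout if self._drop_rng is not None else 0.0

    # -- batching ---------------------------------------------------------------

    def prepare_batch(self, pairs: list[tuple[UserRecord, SampledView]]) -> dict:
        """Pad a batch of (user, view) pairs to (B, P, T) id/mask arrays.

        Posts beyond ``max_posts_per_user`` are dropped keeping the most
        recent; tokens beyond ``max_post_tokens`` are truncated.
        """
        cfg = self.config
        seqs: list[list[list[int]]] = []
        for user, view in pairs:
            if not view.selected:
                raise ValueError(f"empty view for user {user.user_id!r}")
            idx = view.selected[-cfg.max_posts_per_user:]
            posts = []
            for i in idx:
                toks = user.posts[i].tokens[:cfg.max_post_tokens]
                if not toks:
                    raise ValueError(
                        f"user {user.user_id!r} post {user.posts[i].post_id!r} has no tokens")
                posts.append(self.vocab.ids(toks))
            seqs.append(posts)
        B = len(seqs)
        P = max(len(s) for s in seqs)
        T = max(len(p) for s in seqs for p in s)
        ids = np.zeros((B, P, T), dtype=np.int64)
        tok_mask = np.zeros((B, P, T), dtype=np.float64)
        post_mask = np.zeros((B, P), dtype=np.float64)
        for b, posts in enumerate(seqs):
            for p, toks in enumerate(posts):
                ids[b, p, :len(toks)] = toks
                tok_mask[b, p, :len(toks)] = 1.0
            post_mask[b, :len(posts)] = 1.0
        return {"ids": ids, "tok_mask": tok_mask, "post_mask": post_mask,
                "labels": np.array([1.0 if u.label == "depressed" else 0.0
                                    for u, _ in pairs])}

    # -- forward ----------------------------------------------------------------

    def _embed(self, ids: np.ndarray) -> nn.Tensor:
        emb = nn.embedding(self.embedding, ids)
        if self.input_proj is not None:
            emb = self.input_proj(emb)
        return emb

    def _encode_posts_batch(self, ids: np.ndarray, tok_mask: np.ndarray) -> nn.Tensor:
        """(B, P, T) token ids -> (B, P, d) post vectors via the shared
        word-level encoder ([CLS] state of the final layer)."""
        B, P, T = ids.shape
        d = self.config.d_model
        emb = self._embed(ids.reshape(B * P, T))          # (B*P, T, d)
        cls = self.cls.reshape(1, 1, d) * nn.Tensor(np.ones((B * P, 1, 1)))
        x = nn.concatenate([cls, emb], axis=1)            # (B*P, T+1, d)
        mask = np.concatenate(
            [np.ones((B * P, 1)), tok_mask.reshape(B * P, T)], axis=1)
        out = self.word_encoder(x, mask, self._drop, self._drop_rng)
        return out[:, 0, :].reshape(B, P, d)

    def forward(self, batch: dict) -> nn.Tensor:
        """Batch -> logits (B,)."""
        post_vecs = self._encode_posts_batch(batch["ids"], batch["tok_mask"])
        ctx = self.post_encoder(post_vecs, batch["post_mask"],
                                self._drop, self._drop_rng)
        hs = self.lstm(ctx, batch["post_mask"])
        user_vec = self.attention(hs, batch["post_mask"])
        return self.head(user_vec).reshape(len(batch["ids"]))

    # -- single-user operations --------------------------------------------------

    def encode_post(self, tokens: list[str]) -> np.ndarray:
        """One post's tokens -> its d_model-wide [CLS] embedding."""
        if not tokens:
            raise ValueError("cannot encode an empty token sequence")
        toks = tokens[:self.config.max_post_tokens]
        ids = np.array(self.vocab.ids(toks), dtype=np.int64).reshape(1, 1, -1)
        mask = np.ones_like(ids, dtype=np.float64)
        with nn.no_grad():
            return self._encode_posts_batch(ids, mask).data[0, 0]

    def encode_post_sequence(self, post_vectors: np.ndarray) -> np.ndarray:
        """Chronological (P, d) post vectors -> contextualized (P, d)."""
        post_vectors = np.asarray(post_vectors, dtype=np.float64)
        if post_vectors.ndim != 2 or post_vectors.shape[0] < 1:
            raise ValueError("expected a non-empty (P, d) array")
        pv = post_vectors[-self.config.max_posts_per_user:]
        with nn.no_grad():
            out = self.post_encoder(nn.Tensor(pv[None]),
                                    np.ones((1, pv.shape[0])))
        return out.data[0]

    def aggregate(self, context_vectors: np.ndarray) -> np.ndarray:
        """LSTM + additive attention over (P, d) vectors -> user vector."""
        cv = np.asarray(context_vectors, dtype=np.float64)
        if cv.ndim != 2 or cv.shape[0] < 1:
            raise ValueError("expected a non-empty (P, d) array")
        mask = np.ones((1, cv.shape[0]))
        with nn.no_grad():
            hs = self.lstm(nn.Tensor(cv[None]), mask)
            return self.attention(hs, mask).data[0]

    def attention_weights(self, context_vectors: np.ndarray) -> np.ndarray:
        cv = np.asarray(context_vectors, dtype=np.float64)
        mask = np.ones((1, cv.shape[0]))
        with nn.no_grad():
            hs = self.lstm(nn.Tensor(cv[None]), mask)
            return self.attention.weights(hs, mask).data[0]

    def classify(self, user_vector: np.ndarray,
                 threshold: float = 0.5) -> tuple[float, str]:
        """User vector -> (probability of depression, label at threshold)."""
        u = np.asarray(user_vector, dtype=np.float64)
        if u.shape != (self.config.lstm_hidden,):
            raise ValueError(f"expected vector of width {self.config.lstm_hidden}")
        with nn.no_grad():
            logit = self.head(nn.Tensor(u[None])).data[0, 0]
        prob = float(1.0 / (1.0 + np.exp(-logit)))
        return prob, ("depressed" if prob >= threshold else "control")

    def predict_user(self, user: UserRecord, view: SampledView | None = None,
                     threshold: float = 0.5) -> tuple[float, str]:
        """End-to-end prediction for one user under a sampled view."""
        view = view if view is not None else full_view(user)
        if not view.selected:
            raise ValueError(f"empty view for user {user.user_id!r}")
        batch = self.prepare_batch([(user, view)])
        with nn.no_grad():
            logit = float(self.forward(batch).data[0])
        prob = float(1.0 / (1.0 + np.exp(-logit)))
        return prob, ("depressed" if prob >= threshold else "control")


# -- checkpointing -------------------------------------------------------------

def save_checkpoint(model: HTNModel, path: str) -> None:
    """Single-file archive: named parameter tensors + config JSON; the
    embedding vocabulary rides along so a reload is self-contained."""
    arrays = {name: t.data for name, t in model.named_parameters()}
    arrays["__vocab_matrix__"] = model.vocab.matrix
    meta = {"config": asdict(model.config), "words": model.vocab.words,
            "dimension": model.vocab.dimension,
            "kind": type(model).__name__}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> HTNModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
        table = EmbeddingTable(
            dimension=meta["dimension"],
            vectors={w: v for w, v in
                     zip(meta["words"], archive["__vocab_matrix__"][2:])})
        model = HTNModel(HTNConfig(**meta["config"]), Vocab(table))
        named = dict(model.named_parameters())
        for name in archive.files:
            if name in named:
                named[name].data = archive[name].copy()
    return model
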