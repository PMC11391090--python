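"""Reproducible benchmark experiments on synthetic corpora.

This is the harness the examples, the test suite, and the acceptance script
share: it generates a preset corpus, preprocesses it, builds embeddings and
a model, trains under a sampling strategy, and reports test metrics.  The
model and split sizes here are deliberately small — a desk-scale twin of a
full study — chosen once so a complete strategy x rate sweep runs on one
CPU; they are documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import preprocess, sampling, synthetic, train_eval
from .baselines import ALL_ENCODERS, BaselineConfig, build_baseline
from .corpus_io import Corpus, Lexicon
from .htn import HTNConfig, HTNModel, Vocab
from .train_eval import MetricsReport, TrainConfig


@dataclass
class BenchmarkConfig:
    preset: str = "strong"
    users_per_class: int = 200
    split_per_class: tuple[int, int, int] = (120, 40, 40)
    embedding_dim: int = 16
    corpus_seed: int = 20230101


@dataclass
class ModelConfig:
    encoder: str = "htn"
    attention: bool = False
    d_model: int = 16
    n_heads: int = 2
    n_layers: int = 1
    hidden: int = 16
    ffn_mult: int = 2
    dropout: float = 0.1
    max_post_tokens: int = 20
    # the encoder ingests at most this many (most recent) posts; set well
    # below the typical timeline length so post selection actually decides
    # what the model gets to see, as in a real capacity-bounded deployment
    max_posts_per_user: int = 12
    max_concat_tokens: int = 160


#: the slightly larger network used for the separability benchmark
SEPARABILITY_MODEL = ModelConfig(d_model=32, n_heads=4, n_layers=2, hidden=32)

DEFAULT_TRAIN = TrainConfig(learning_rate=1e-3, batch_size=32,
                            max_epochs=8, patience=3)


@dataclass
class Benchmark:
    corpus: Corpus          # cleaned, tokenized, split
    lexicon: Lexicon
    vocab: Vocab
    gen_config: synthetic.GenConfig


def build_benchmark(config: BenchmarkConfig | None = None,
                    split_seed: int = 0) -> Benchmark:
    """Generate + preprocess + split a preset corpus, with embeddings."""
    cfg = config or BenchmarkConfig()
    gen = synthetic.preset(cfg.preset, n_users_per_class=cfg.users_per_class,
                           seed=cfg.corpus_seed)
    corpus = synthetic.generate_corpus(gen)
    clean, _ = preprocess.prepare_corpus(corpus)
    clean = train_eval.split_corpus(clean, cfg.split_per_class, seed=split_seed)
    lexicon, _ = synthetic.make_lexicon(gen)
    table = synthetic.generate_embeddings(
        synthetic.corpus_vocabulary(gen), cfg.embedding_dim, seed=cfg.corpus_seed)
    return Benchmark(corpus=clean, lexicon=lexicon, vocab=Vocab(table),
                     gen_config=gen)


def make_model(model_cfg: ModelConfig, vocab: Vocab, seed: int):
    if model_cfg.encoder == "htn":
        cfg = HTNConfig(d_model=model_cfg.d_model, n_heads=model_cfg.n_heads,
                        n_word_layers=model_cfg.n_layers,
                        n_post_layers=model_cfg.n_layers,
                        ffn_mult=model_cfg.ffn_mult,
                        lstm_hidden=model_cfg.hidden,
                        attn_size=model_cfg.hidden,
                        max_post_tokens=model_cfg.max_post_tokens,
                        max_posts_per_user=model_cfg.max_posts_per_user,
                        dropout=model_cfg.dropout)
        return HTNModel(cfg, vocab, seed=seed)
    if model_cfg.encoder not in ALL_ENCODERS:
        raise ValueError(f"unknown encoder {model_cfg.encoder!r}")
    bcfg = BaselineConfig(encoder=model_cfg.encoder,
                          attention=model_cfg.attention,
                          hidden=model_cfg.hidden,
                          attn_size=model_cfg.hidden,
                          max_concat_tokens=model_cfg.max_concat_tokens,
                          max_posts_per_user=model_cfg.max_posts_per_user,
                          max_post_tokens=model_cfg.max_post_tokens)
    return build_baseline(bcfg, vocab, seed=seed)


def run_one(bench: Benchmark, model_cfg: ModelConfig, strategy: str,
            rate: float, seed: int,
            train_cfg: TrainConfig | None = None) -> MetricsReport:
    """Train one model under one sampling condition; return test metrics."""
    views = sampling.sample_corpus(bench.corpus, strategy, rate=rate,
                                   lexicon=bench.lexicon, seed=seed)
    model = make_model(model_cfg, bench.vocab, seed=seed)
    cfg = replace(train_cfg or DEFAULT_TRAIN, seed=seed)
    train_eval.train(model, bench.corpus, views, cfg)
    return train_eval.evaluate(model, bench.corpus, views, "test")


def strategy_sweep(bench: Benchmark, model_cfg: ModelConfig,
                   conditions: list[tuple[str, float]],
                   seeds: list[int],
                   train_cfg: TrainConfig | None = None) -> pd.DataFrame:
    """Metrics for every (strategy, rate) x seed cell, one row each."""
    rows = []
    for strategy, rate in conditions:
        for seed in seeds:
            report = run_one(bench, model_cfg, strategy, rate, seed, train_cfg)
            rows.append({"strategy": strategy, "rate": rate, "seed": seed,
                         **report.as_dict()})
    return pd.DataFrame(rows)


def lexicon_count_classifier(corpus: Corpus, lexicon: Lexicon,
                             split: str | None = None) -> float:
    """Accuracy of the trivial per-user lexicon-count rule.

    Sums each user's lexicon matches per post (normalized by post count)
    and thresholds at the corpus median.  A sanity floor: if this rule
    cannot separate the cohorts, no encoder can be expected to.
    """
    users = corpus.split(split) if split else corpus.users
    scores = np.array([
        sum(sampling.score_post(p.tokens, lexicon) for p in u.posts) / len(u.posts)
        for u in users])
    labels = np.array([1 if u.label == "depressed" else 0 for u in users])
    threshold = float(np.median(scores))
    preds = (scores > threshold).astype(int)
    return float((preds == labels).mean())
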