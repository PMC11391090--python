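# Methods

## Task and data model

The unit of classification is a labeled user: an opaque id, a binary
cohort label (depressed / control), and a chronologically ordered sequence
of time-stamped posts. Corpora are newline-delimited JSON, one user per
line, so large collections stream; timestamp ties are broken by post id so
the chronological encoders see a deterministic order. All text is
NFC-normalized on read, which keeps lexicon and dictionary matching stable
for CJK input.

## Preprocessing

Cleaning runs in a fixed order: emoticon → emotion-word substitution first
(so bracketed emoticons survive as words rather than being stripped as
punctuation), then URL removal, digit removal, and punctuation removal;
then segmentation, bot-post filtering, exact deduplication, and exclusion
of posts with fewer than 3 tokens. Rationale for the order: URL fragments
must never survive segmentation as tokens. Duplicates are detected on the
cleaned token sequence, not raw text, because platform reposts typically
differ only in URLs or whitespace; the first occurrence is kept. "Fewer
than 3 words" means post-segmentation tokens. A user emptied by filtering
is flagged, not silently dropped — the caller decides.

Punctuation stripping applies to the classifier path only. `raw_text` is
preserved on every post, and the linguistics module reads it directly, so
punctuation and modal-particle profiles remain measurable after cleaning.

Segmentation is a pluggable callable. Two segmenters ship: a whitespace
splitter (sufficient for the synthetic corpora, whose words are
space-delimited) and a dictionary forward-maximum-matching segmenter for
unsegmented CJK text whose lexicon accepts an external vocabulary — e.g.
the vocabulary of a pretrained embedding table — so multi-character domain
terms surface as single tokens. Emoticon maps and bot-post patterns are
editable configuration files seeded with small illustrative lists, not
fixed constants.

## The hierarchical transformer network

Architecture conventions (shared by the straight-line test oracle):

* **Word level.** Token embeddings (projected linearly if the embedding
  width differs from `d_model`), a learned `[CLS]` vector prepended,
  sinusoidal positional encodings added
  (`pe[p,2i] = sin(p/10000^{2i/d})`, `pe[p,2i+1] = cos(·)`), then
  `n_word_layers` post-norm transformer blocks:
  `x = LN(x + SelfAttn(x)); x = LN(x + FFN(x))`, attention scores scaled by
  `1/sqrt(d_head)`, ReLU feed-forward of width `ffn_mult · d_model`,
  layer-norm with biased variance and `eps = 1e-5`. The final-layer `[CLS]`
  state is the post embedding. The encoder is shared across all posts.
* **Post level.** The same block structure over the chronological post
  embeddings, positions indexing posting order. No `[CLS]` at this level —
  aggregation is the attention-LSTM, not a pooled token.
* **Aggregation.** LSTM (gate order i, f, g, o) over the contextualized
  sequence; additive attention `α_i = softmax(vᵀ tanh(W h_i))`; the user
  vector is `Σ α_i h_i`.
* **Head.** Affine map + sigmoid; decision threshold 0.5 (inclusive).

Padding is handled by key-masking in every attention (additive −1e9 before
the softmax), carry-through state updates in the recurrences, and window
masking in the CNNs, so appending padded tokens or posts never changes any
output bit — a property the tests assert exactly.

Defaults follow common practice where the task definition is silent:
2 layers and 4 heads per transformer (the smallest configuration that
exercises multi-head, multi-layer code paths), dropout 0.1 (training mode
only, seeded), hidden/attention size 256, posts padded or truncated to 512
tokens. The encoder ingests at most `max_posts_per_user` posts, keeping the
most recent — a bounded-memory choice that also defines the benchmark
regime below.

Baselines share the classifier head and training loop; the encoder is the
only degree of freedom. The flat family reads the user's posts as one
concatenated token sequence (truncated at `max_concat_tokens`); recurrent
encoders use the final valid hidden state, or additive-attention pooling
when enabled; bidirectional variants concatenate direction-wise states.
The HCN applies a shared per-post text-CNN, then a second CNN +
max-over-time over the post-vector sequence — the convolutional mirror of
the HTN hierarchy.

All of this runs on a reverse-mode autodiff engine over float64 NumPy
arrays. Float64 makes evaluation bit-reproducible on one machine and
finite-difference gradient checks meaningful (relative error ~1e-8
observed, 1e-3 asserted).

## Sampling strategies

`retrieval_sample` scores each post by its multiset count of depression-
lexicon tokens and keeps the top `ceil(rate·N)` posts, ties broken by
recency (a recent post is the better depression indicator, all else equal);
indices are emitted chronologically. Top-k by score — rather than "all
matching posts" — keeps the rate sweep well defined at every rate. When no
post matches, the rule degrades gracefully to keeping the most recent
posts. `random_sample` draws uniformly without replacement, seeded by the
run seed combined with a stable per-user hash so adding users never
perturbs existing users' samples. Sampling is always per user; posts are
never pooled across users. Rate 1.0 selects every post under either
strategy and is therefore *identical* to no sampling — a fact with
consequences for the benchmarks (below).

## Training and evaluation

Adam at learning rate 1e-3, batch size 32 (users are the batch unit),
binary cross-entropy on logits (numerically stable softplus form), batches
reshuffled per epoch with the run seed, dropout seeded per epoch; the
checkpoint with the best validation macro-F1 is kept, with early stopping
on patience. Training is bit-reproducible given the seed. Metrics are
accuracy and macro-averaged precision/recall/F1 over the two cohorts
(scikit-learn backed), with 0/0-undefined per-class values set to 0; an
independent confusion-count implementation in the test suite agrees to
1e-12 on random prediction vectors. Splits are stratified with exact
per-class counts (the canonical configuration is 1000/300/300 per class),
deterministic given the seed.

## The synthetic benchmark

The generator emulates the statistical structure a user-level depression
classifier relies on, with no claim of linguistic realism:

* Balanced cohorts; per-user post counts negative-binomial (overdispersed,
  as real posting behavior is), depressed mean 24 vs control 36; tokens per
  post negative-binomial, depressed 9 vs control 13 (minimum 3 so posts
  survive preprocessing).
* A signal lexicon (30 abstract `s·` terms; optionally a few CJK words to
  exercise Unicode paths) and 500 background `w·` words. Each post is a
  *signal post* with probability 0.5 (depressed) vs 0.05 (control); signal
  posts draw each token from the lexicon with probability 0.4.
* First-person pronouns injected per post at Poisson rates (我: 0.8 vs 0.3;
  我们: 0.1 vs 0.4), modal particles and punctuation likewise with the
  depressed cohort favoring 吧, 。, ~, …… and controls favoring 啊, ，, ！ —
  the direction of the behavioral contrasts reported for real cohorts.
* Optional platform noise (URLs, digit runs, bracketed emoticons, bot
  posts, duplicate reposts) at low rates, to exercise preprocessing.
* Timestamps uniform over one year, sorted; signal-post ids recorded in
  user metadata for parameter-recovery tests.

Presets: `strong` (the defaults above), `weak` (prevalence gap 0.2 vs
0.08, diluted signal tokens), and `null` — every class contrast removed —
the negative control on which any classifier must score ~50%. A trivial
lexicon-count rule (per-user mean post score thresholded at the corpus
median) achieves ≥95% on `strong`, establishing that the learning task is
well posed before any neural training; the same rule is at chance on
`null`.

What passing these benchmarks does **not** show: robustness to topic
drift, sarcasm, code-switching, annotation noise, or any property of real
clinical language — signal here is purely lexical by construction.

## Benchmark problem sizes and the ordering/rate-sweep trade-off

The packaged experiments (`deprisk.experiments`) run at desk scale, chosen
once: 200 users/class, split 120/40/40 per class, embedding width 16, an
HTN with `d_model` 16, 1 layer per level, 2 heads, `ffn_mult` 2, LSTM and
attention width 16, post cap 12, token cap 20, 8 epochs (patience 3); the
separability benchmark uses `d_model` 32 with 2 layers per level. A full
strategy × rate × 5-seed grid completes in about a minute on one CPU.

The post capacity of 12 against timelines averaging ~30 posts is the
deliberate regime choice: the encoder cannot ingest everything, so *what
the sampler selects decides what the model sees*. In this regime the
benchmark reproduces the qualitative pattern reported for real data —
retrieval@0.5 macro-F1 0.955 > none 0.912 > random@0.5 0.887 over 5 seeds:
retrieval concentrates signal posts within the capacity budget, while
random sampling only discards signal and trails even the no-sampling
condition.

A structural consequence, worth stating plainly: retrieval at rate 1.0
selects every post and is *identical* to no sampling. Whenever retrieval at
an intermediate rate beats no sampling by more than a hair, the retrieval
F1-vs-rate curve must therefore *decline* back to the no-sampling value as
the rate approaches 1.0. Measured curve over rates 0.25/0.5/0.75/1.0:
0.894 / 0.955 / 0.945 / 0.912 — rising to the capacity-matched rate
(~cap/timeline ≈ 0.4–0.5), then falling. A monotone-nondecreasing sweep
and a materially positive retrieval-vs-none margin cannot both hold; this
package prioritizes the ordering result and reports the non-monotone sweep
as the honest outcome of that choice.

## Numerical choices and degenerate inputs

* Attention masking uses additive −1e9; fully-masked rows softmax to
  uniform garbage that is itself masked downstream, never NaN.
* Layer norm uses biased variance, `eps = 1e-5`; softmax subtracts the row
  max (treated as a constant in the backward pass).
* BCE is computed in softplus form, finite for any logit.
* Token sequences shorter than the largest CNN kernel are zero-padded to
  one window; windows starting beyond the last valid position are masked.
* Out-of-vocabulary tokens map to a dedicated UNK row (zero or
  seeded-random per the embedding table's declared policy); padding is id 0
  with a zero vector.
* Empty posts, empty views, empty splits, and unknown labels raise
  immediately rather than propagating silently.

## Known limitations

* The autodiff engine is minimal by design: no GPU, no mixed precision, no
  graph reuse; throughput is adequate for the benchmark scale only.
* The maximum-matching segmenter is greedy and dictionary-bound — adequate
  for vocabulary-injection semantics and synthetic text, not a
  state-of-the-art CJK tokenizer.
* Pretrained contextual encoders are out of scope; the embedding reader
  accepts any word2vec-format table.
* Group comparisons are descriptive (differences, ratios, directions); no
  significance testing is attached.
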