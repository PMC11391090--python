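"""Independent straight-line reference computations used only by the tests.

Everything here is written as plain NumPy loops, independently of the
package's autodiff engine and layer classes, so agreement between the two
routes is meaningful.
"""

from __future__ import annotations

import numpy as np


# -- classification metrics ----------------------------------------------------

def brute_force_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Accuracy + macro P/R/F1 from explicit confusion counts (0/0 -> 0)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    acc = float(np.mean(y_true == y_pred))
    ps, rs, fs = [], [], []
    for cls in (0, 1):
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        ps.append(p); rs.append(r); fs.append(f)
    return {"accuracy": acc, "macro_precision": float(np.mean(ps)),
            "macro_recall": float(np.mean(rs)), "macro_f1": float(np.mean(fs))}


# -- transformer forward pass --------------------------------------------------

def sinusoidal_pe(length: int, d: int) -> np.ndarray:
    pe = np.zeros((length, d))
    for pos in range(length):
        for i in range(d):
            angle = pos / 10000 ** ((2 * (i // 2)) / d)
            pe[pos, i] = np.sin(angle) if i % 2 == 0 else np.cos(angle)
    return pe


def layer_norm_ref(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                   eps: float = 1e-5) -> np.ndarray:
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def softmax_ref(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(-1, keepdims=True))
    return e / e.sum(-1, keepdims=True)


def single_head_layer_ref(x: np.ndarray, p: dict[str, np.ndarray]) -> np.ndarray:
    """One post-norm transformer layer, single head, no masking.

    ``p`` holds wq, bq, wk, bk, wv, bv, wo, bo, ln1_g, ln1_b, w1, b1, w2,
    b2, ln2_g, ln2_b.  x is (T, d).
    """
    d = x.shape[-1]
    q, k, v = x @ p["wq"] + p["bq"], x @ p["wk"] + p["bk"], x @ p["wv"] + p["bv"]
    attn = softmax_ref(q @ k.T / np.sqrt(d))
    ctx = (attn @ v) @ p["wo"] + p["bo"]
    x = layer_norm_ref(x + ctx, p["ln1_g"], p["ln1_b"])
    ff = np.maximum(x @ p["w1"] + p["b1"], 0.0) @ p["w2"] + p["b2"]
    return layer_norm_ref(x + ff, p["ln2_g"], p["ln2_b"])


def layer_params_from(layer) -> dict[str, np.ndarray]:
    """Extract one TransformerLayer's weights into plain arrays."""
    a = layer.attn
    return {"wq": a.wq.W.data, "bq": a.wq.b.data, "wk": a.wk.W.data,
            "bk": a.wk.b.data, "wv": a.wv.W.data, "bv": a.wv.b.data,
            "wo": a.wo.W.data, "bo": a.wo.b.data,
            "ln1_g": layer.ln1.gamma.data, "ln1_b": layer.ln1.beta.data,
            "w1": layer.ff1.W.data, "b1": layer.ff1.b.data,
            "w2": layer.ff2.W.data, "b2": layer.ff2.b.data,
            "ln2_g": layer.ln2.gamma.data, "ln2_b": layer.ln2.beta.data}


def lstm_trace_ref(xs: np.ndarray, wx: np.ndarray, wh: np.ndarray,
                   b: np.ndarray, hidden: int) -> np.ndarray:
    """LSTM hidden states, step by step (gate order i, f, g, o)."""
    def sig(z):
        return 1.0 / (1.0 + np.exp(-z))
    h = np.zeros(hidden)
    c = np.zeros(hidden)
    out = []
    for x in xs:
        g = x @ wx + h @ wh + b
        i, f, n, o = (sig(g[:hidden]), sig(g[hidden:2 * hidden]),
                      np.tanh(g[2 * hidden:3 * hidden]), sig(g[3 * hidden:]))
        c = f * c + i * n
        h = o * np.tanh(c)
        out.append(h.copy())
    return np.array(out)


def htn_forward_ref(model, token_ids: list[list[int]]) -> float:
    """Full hierarchical forward pass for one user, straight-line NumPy.

    Supports any single-head model whose embedding width equals d_model;
    every post must be real (no padding).  Returns the sigmoid probability.
    """
    cfg = model.config
    emb = model.embedding.data
    post_vecs = []
    for ids in token_ids:
        x = np.vstack([model.cls.data, emb[ids]])
        if cfg.word_positional:
            x = x + sinusoidal_pe(len(x), cfg.d_model)
        for layer in model.word_encoder.layers:
            x = single_head_layer_ref(x, layer_params_from(layer))
        post_vecs.append(x[0])
    x = np.array(post_vecs)
    if cfg.post_positional:
        x = x + sinusoidal_pe(len(x), cfg.d_model)
    for layer in model.post_encoder.layers:
        x = single_head_layer_ref(x, layer_params_from(layer))
    hs = lstm_trace_ref(x, model.lstm.wx.data, model.lstm.wh.data,
                        model.lstm.b.data, cfg.lstm_hidden)
    scores = np.tanh(hs @ model.attention.W.data) @ model.attention.v.data
    alpha = softmax_ref(scores.ravel())
    user_vec = alpha @ hs
    logit = float(user_vec @ model.head.W.data.ravel() + model.head.b.data[0])
    return 1.0 / (1.0 + np.exp(-logit))
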