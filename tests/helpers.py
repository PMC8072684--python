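"""Independent brute-force reference implementations used as oracles.

Everything here is written as plain scalar loops over definitions, on
purpose: these functions must not share any code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def context_encode_bruteforce(fm, codewords, smoothing=None):
    """Double loop over spatial positions and codewords."""
    h, w, c = fm.shape
    d = np.atleast_2d(np.asarray(codewords, dtype=float))
    k = d.shape[0]
    s = np.ones(k) if smoothing is None else np.asarray(smoothing, dtype=float)
    e = np.zeros(c)
    for i in range(h):
        for j in range(w):
            x = fm[i, j].astype(float)
            logits = [-s[kk] * float(((x - d[kk]) ** 2).sum()) for kk in range(k)]
            mx = max(logits)
            exps = [math.exp(l - mx) for l in logits]
            z = sum(exps)
            for kk in range(k):
                e += (exps[kk] / z) * (x - d[kk])
    return e


def channel_weights_bruteforce(e, eps=1e-8):
    total = float(np.sum(e))
    if abs(total) < eps:
        total = eps if total >= 0 else -eps
    return np.array([float(v) / total for v in e])


def bn_eval_scalar(x, gamma, beta, mean, var, eps):
    return gamma * (x - mean) / math.sqrt(var + eps) + beta


def sigmoid_scalar(x):
    return 1.0 / (1.0 + math.exp(-x))


def ceds_forward_bruteforce(fm, codeword, dw_w, dw_b, bn1, bn2, eps_bn, eps_guard=1e-8):
    """Scalar triple-loop reference of the attention forward pass.

    ``fm`` is one (H, W, C) map; ``bn1``/``bn2`` are dicts with gamma,
    beta, mean, var per channel (inference-mode statistics).  Returns
    the (H, W-2, C) output.
    """
    h, w, c = fm.shape
    k = dw_w.shape[0]
    wo = w - k + 1
    # channel weights from the ORIGINAL map
    e = context_encode_bruteforce(fm, codeword)
    wts = channel_weights_bruteforce(e, eps=eps_guard)
    out = np.zeros((h, wo, c))
    for i in range(h):
        for j in range(wo):
            for ch in range(c):
                acc = dw_b[ch]
                for u in range(k):
                    acc += fm[i, j + u, ch] * dw_w[u, ch]
                a = sigmoid_scalar(
                    bn_eval_scalar(acc, bn1["gamma"][ch], bn1["beta"][ch],
                                   bn1["mean"][ch], bn1["var"][ch], eps_bn)
                )
                a = sigmoid_scalar(
                    bn_eval_scalar(a, bn2["gamma"][ch], bn2["beta"][ch],
                                   bn2["mean"][ch], bn2["var"][ch], eps_bn)
                )
                out[i, j, ch] = a * wts[ch]
    return out


def se_forward_bruteforce(fm, w1, b1, w2, b2):
    """Scalar reference of squeeze-and-excitation on one (H, W, C) map."""
    h, w, c = fm.shape
    squeeze = [float(fm[:, :, ch].mean()) for ch in range(c)]
    hidden = []
    for m in range(w1.shape[1]):
        acc = b1[m] + sum(squeeze[ch] * w1[ch, m] for ch in range(c))
        hidden.append(max(acc, 0.0))
    scale = []
    for ch in range(c):
        acc = b2[ch] + sum(hidden[m] * w2[m, ch] for m in range(len(hidden)))
        scale.append(sigmoid_scalar(acc))
    out = np.zeros_like(fm, dtype=float)
    for i in range(h):
        for j in range(w):
            for ch in range(c):
                out[i, j, ch] = fm[i, j, ch] * scale[ch]
    return out


def macro_metrics_bruteforce(y_true, y_pred, labels):
    """Per-class recall and F1 from the confusion matrix, macro-averaged."""
    recalls, f1s = [], []
    for c in labels:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        rec = tp / (tp + fn) if tp + fn else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        recalls.append(rec)
        f1s.append(f1)
    return float(np.mean(recalls)), float(np.mean(f1s))


def auc_bruteforce(y_binary, scores):
    """Concordant-pair counting (ties count half)."""
    pos = [s for s, y in zip(scores, y_binary) if y]
    neg = [s for s, y in zip(scores, y_binary) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def count_windows_bruteforce(n_t, window_len, stride):
    """Enumerate every valid window start index."""
    count = 0
    start = 0
    while start + window_len <= n_t:
        count += 1
        start += stride
    return count
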