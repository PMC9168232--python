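"""Independent scalar-loop oracles used by the unit and acceptance tests.

Every function here recomputes an operation with explicit Python loops and
textbook formulas, deliberately sharing no code with the package internals.
"""

import math

import numpy as np


def pearson_loop(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def psg_loop(feature_mats):
    """Brute-force PSG: per-modality pair loop, min-max, +1, product."""
    p = feature_mats[0].shape[0]
    out = np.ones((p, p))
    for x in feature_mats:
        c = np.empty((p, p))
        for u in range(p):
            for v in range(p):
                c[u, v] = pearson_loop(x[u], x[v])
        lo, hi = c.min(), c.max()
        if hi == lo:
            f = np.zeros((p, p))
        else:
            f = (c - lo) / (hi - lo)
        out = out * (f + 1.0)
    return out


def duplicate_loop(subject_graph, subject_ids, scan_subjects):
    pos = {s: i for i, s in enumerate(subject_ids)}
    p = len(scan_subjects)
    out = np.empty((p, p))
    for a in range(p):
        for b in range(p):
            out[a, b] = subject_graph[pos[scan_subjects[a]], pos[scan_subjects[b]]]
    return out


def pog_loop(omics_rows, subject_ids, scan_subjects, beta):
    s = len(subject_ids)
    c = np.empty((s, s))
    for a in range(s):
        for b in range(s):
            c[a, b] = pearson_loop(omics_rows[a], omics_rows[b])
    for a in range(s):
        c[a, a] = 1.0
    w = np.abs(c) ** beta
    return duplicate_loop(w, subject_ids, scan_subjects)


def gcn_loop(h, a, w, activation):
    """Explicit D^(-1/2)(A+I)D^(-1/2) H W with loops."""
    p = a.shape[0]
    a_hat = a + np.eye(p)
    d = [sum(a_hat[u]) for u in range(p)]
    op = np.empty((p, p))
    for u in range(p):
        for v in range(p):
            op[u, v] = a_hat[u, v] / math.sqrt(d[u]) / math.sqrt(d[v])
    pre = op @ h @ w
    return np.maximum(pre, 0.0) if activation else pre


def linear_relu_loop(x, w, b):
    p, j = x.shape
    k = w.shape[1]
    out = np.empty((p, k))
    for u in range(p):
        for c in range(k):
            z = b[c] + sum(x[u, f] * w[f, c] for f in range(j))
            out[u, c] = max(z, 0.0)
    return out


def omics_head_loop(h3, w4, b4):
    p, l3 = h3.shape
    l4 = w4.shape[1]
    out = np.empty((p, l4))
    for u in range(p):
        r = [max(h3[u, i], 0.0) for i in range(l3)]
        for c in range(l4):
            z = b4[c] + sum(r[i] * w4[i, c] for i in range(l3))
            out[u, c] = max(z, 0.0)
    return out


def softmax_loop(row):
    m = max(row)
    e = [math.exp(v - m) for v in row]
    s = sum(e)
    return [v / s for v in e]


def attention_loop(h3_list, h4_list, w3c, w4c):
    """Scalar evaluation of the query/key/value fusion, sample by sample."""
    n = len(h4_list)
    p, l4 = h4_list[0].shape
    h5 = np.empty((p, l4))
    scores = np.empty((p, l4, n))
    for u in range(p):
        q = [sum(h4[u, l] for h4 in h4_list) / n for l in range(l4)]
        k = [sum(h3_list[i][u, j] * w3c[j, 0] for j in range(h3_list[i].shape[1]))
             for i in range(n)]
        v = [sum(h4_list[i][u, l] * w4c[l, 0] for l in range(l4))
             for i in range(n)]
        for l in range(l4):
            raw = [q[l] * k[i] for i in range(n)]
            s = softmax_loop(raw)
            scores[u, l] = s
            h5[u, l] = sum(s[i] * v[i] for i in range(n))
    return h5, scores


def self_attention_loop(h4_list):
    n = len(h4_list)
    p, l4 = h4_list[0].shape
    scale = 1.0 / math.sqrt(l4)
    out = np.empty((p, l4))
    for u in range(p):
        x = [[h4_list[i][u, l] for l in range(l4)] for i in range(n)]
        pooled = [0.0] * l4
        for i in range(n):
            raw = [scale * sum(x[i][l] * x[m][l] for l in range(l4))
                   for m in range(n)]
            s = softmax_loop(raw)
            for l in range(l4):
                pooled[l] += sum(s[m] * x[m][l] for m in range(n)) / n
        out[u] = pooled
    return out


def weighted_ce_loop(prob_pos, labels, weights, eps=1e-12):
    total = 0.0
    for y, yd in zip(prob_pos, labels):
        y = min(max(y, eps), 1.0 - eps)
        w = weights[yd]
        total += -w * yd * math.log(y) - (1.0 - w) * (1 - yd) * math.log(1.0 - y)
    return total / len(labels)


def mcc_covariance_form(pred, lab):
    """MCC as the Pearson correlation between prediction and label vectors."""
    pred = np.asarray(pred, float)
    lab = np.asarray(lab, float)
    num = ((pred - pred.mean()) * (lab - lab.mean())).sum()
    den = math.sqrt(((pred - pred.mean()) ** 2).sum()
                    * ((lab - lab.mean()) ** 2).sum())
    return 0.0 if den == 0 else num / den


def backward_elimination_replay(names, scores):
    """Recursive replay of the leave-one-out elimination rule on a lookup."""
    best = tuple(names)
    best_score = scores[frozenset(best)]
    while len(best) > 1:
        children = []
        for removed in sorted(best):
            child = tuple(n for n in best if n != removed)
            children.append((scores[frozenset(child)], removed, child))
        top = max(c[0] for c in children)
        score, _, child = min(
            (c for c in children if c[0] == top), key=lambda c: c[1]
        )
        if score > best_score:
            best, best_score = child, score
        else:
            break
    return best
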