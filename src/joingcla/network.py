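"""The JOIN-GCLA forward model and its gradients.

Three cascaded parts operate on a cohort of P scans at once (transductive,
full-batch):

1. **connectome encoder** — a linear layer with rectification reduces the
   concatenated connectivity features, then one spectral graph convolution
   over the fused population scan graph (PSG) smooths the representation
   across similar scans;
2. **omics networks** — one graph convolution per omics type, each over that
   type's population omics graph (POG), followed by a doubly-rectified linear
   head producing per-sample class logits;
3. **attention layer** — a query/key/value fusion where the query is the mean
   of the omics-network logits, keys and values are scalar projections of
   each network's intermediate output and logits, and the softmax runs over
   the omics axis, so each class row of the attention matrix is a probability
   distribution over omics networks (the interpretability output).

With fewer than two omics networks the attention layer is bypassed: N = 1
feeds the single head's logits straight to the softmax, N = 0 attaches a
linear head directly to the encoder output.

Everything is plain numpy.  Gradients are derived by hand, layer by layer,
and checked against central differences in the test suite.  Dropout (applied
after each graph convolution, and only there) uses inverted scaling so the
evaluation-mode forward pass is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LayerShapes",
    "ModelParameters",
    "ForwardTrace",
    "normalize_adjacency",
    "encoder_linear",
    "gcn_propagate",
    "omics_head",
    "attention_fuse",
    "self_attention_fuse",
    "output_probabilities",
    "class_weights",
    "weighted_cross_entropy",
    "model_forward",
    "loss_and_gradients",
    "AdamState",
]

_EPS = 1e-12


@dataclass(frozen=True)
class LayerShapes:
    """Layer widths: L1 encoder linear, L2 encoder GCN, L3 omics GCN, L4 classes."""

    L1: int = 16
    L2: int = 16
    L3: int = 16
    L4: int = 2

    def __post_init__(self):
        if min(self.L1, self.L2, self.L3, self.L4) < 1:
            raise ValueError("all layer widths must be >= 1")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class ModelParameters:
    """All learnable weights/biases, keyed by name.

    Encoder: W1 (J x L1), b1, W2 (L1 x L2).  Per omics network n: W3_n
    (L2 x L3), W4_n (L3 x L4), b4_n.  Attention projections (joingcla variant,
    N >= 2 only): W3c (L3 x 1), W4c (L4 x 1).  N = 0 uses a direct head
    Wh (L2 x L4), bh.
    """

    values: dict = field(default_factory=dict)
    n_omics: int = 0
    shapes: LayerShapes = field(default_factory=LayerShapes)
    variant: str = "joingcla"

    def __getitem__(self, key):
        return self.values[key]

    def __setitem__(self, key, val):
        self.values[key] = val

    def keys(self):
        return self.values.keys()

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            {k: v.copy() for k, v in self.values.items()},
            self.n_omics,
            self.shapes,
            self.variant,
        )

    def check_finite(self) -> None:
        for k, v in self.values.items():
            if not np.isfinite(v).all():
                raise FloatingPointError(f"non-finite parameter {k!r}")

    @classmethod
    def initialize(
        cls,
        n_features: int,
        n_omics: int,
        rng: np.random.Generator,
        shapes: LayerShapes | None = None,
        variant: str = "joingcla",
    ) -> "ModelParameters":
        """Glorot-uniform initialization, fully determined by ``rng``."""
        s = shapes or LayerShapes()
        if variant not in ("joingcla", "self_attention"):
            raise ValueError(f"unknown variant {variant!r}")
        vals = {
            "W1": _glorot(rng, n_features, s.L1),
            "b1": np.zeros(s.L1),
            "W2": _glorot(rng, s.L1, s.L2),
        }
        if n_omics == 0:
            vals["Wh"] = _glorot(rng, s.L2, s.L4)
            vals["bh"] = np.zeros(s.L4)
        for n in range(n_omics):
            vals[f"W3_{n}"] = _glorot(rng, s.L2, s.L3)
            vals[f"W4_{n}"] = _glorot(rng, s.L3, s.L4)
            vals[f"b4_{n}"] = np.zeros(s.L4)
        if n_omics >= 2 and variant == "joingcla":
            vals["W3c"] = _glorot(rng, s.L3, 1)
            vals["W4c"] = _glorot(rng, s.L4, 1)
        return cls(vals, n_omics, s, variant)


@dataclass
class ForwardTrace:
    """All intermediate activations of one forward pass, plus backprop caches."""

    H1: np.ndarray
    H2: np.ndarray
    H3: list
    H4: list
    attention_scores: np.ndarray | None  # (P, L4, N), rows over N sum to 1
    H5: np.ndarray
    class_probabilities: np.ndarray
    cache: dict = field(default_factory=dict, repr=False)

    @property
    def predictions(self) -> np.ndarray:
        return self.class_probabilities.argmax(axis=1)


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetric spectral normalization D^(-1/2) (A + I) D^(-1/2).

    D is the diagonal degree matrix of A + I (self-loops added), which has
    strictly positive diagonal for any nonnegative A, so the inverse square
    root always exists.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if a.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    a_hat = a + np.eye(a.shape[0])
    d = a_hat.sum(axis=1)
    assert (d > 0).all(), "zero-degree row after adding self-loops"
    inv_sqrt = 1.0 / np.sqrt(d)
    return a_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


def encoder_linear(xc: np.ndarray, w1: np.ndarray, b1: np.ndarray) -> np.ndarray:
    """H1 = ReLU(Xc W1 + b1) — dimensionality reduction of connectivity features."""
    xc = np.asarray(xc, dtype=float)
    if xc.shape[1] != w1.shape[0]:
        raise ValueError(f"feature dim {xc.shape[1]} != W1 rows {w1.shape[0]}")
    return _relu(xc @ w1 + b1)


def gcn_propagate(
    h: np.ndarray,
    a: np.ndarray,
    w: np.ndarray,
    add_self_loops: bool = True,
    activation: bool = True,
) -> np.ndarray:
    """One spectral graph-convolution layer.

    Returns act(D^(-1/2) (A + I) D^(-1/2) H W); the rectifier is used in the
    connectome encoder, the identity in the omics networks.  With
    ``add_self_loops=False`` the raw adjacency is normalized as-is (rows must
    then have positive sums).
    """
    h = np.asarray(h, dtype=float)
    a = np.asarray(a, dtype=float)
    if h.shape[0] != a.shape[0]:
        raise ValueError("H rows must match graph size")
    if h.shape[1] != w.shape[0]:
        raise ValueError("H columns must match W rows")
    if add_self_loops:
        op = normalize_adjacency(a)
    else:
        d = a.sum(axis=1)
        if (d <= 0).any():
            raise ValueError("zero-degree row without self-loops")
        inv_sqrt = 1.0 / np.sqrt(d)
        op = a * inv_sqrt[:, None] * inv_sqrt[None, :]
    out = op @ h @ w
    return _relu(out) if activation else out


def omics_head(h3: np.ndarray, w4: np.ndarray, b4: np.ndarray) -> np.ndarray:
    """H4 = ReLU(ReLU(H3) W4 + b4).

    The double rectification is part of the model definition and is kept
    as-is; the outer rectifier makes every logit nonnegative.
    """
    return _relu(_relu(np.asarray(h3, dtype=float)) @ w4 + b4)


def attention_fuse(h3_list, h4_list, w3c, w4c):
    """Fuse omics-network outputs with the bespoke query/key/value attention.

    Per sample: query = mean of logits over networks (L4); key_n and value_n
    are scalar projections of H3_n and H4_n; raw scores = query x keys
    (L4 x N) with no sqrt(d) scaling; the softmax runs over the omics axis so
    each class row is a distribution over omics networks; H5 = scores @ values.

    Returns ``(H5, scores)`` with scores shaped (P, L4, N).
    """
    n = len(h4_list)
    if n < 2:
        raise ValueError(
            "attention fusion needs >= 2 omics networks; use the reduced "
            "architecture for N <= 1"
        )
    if len(h3_list) != n:
        raise ValueError("H3 and H4 lists must have equal length")
    q = np.mean(h4_list, axis=0)  # (P, L4)
    k = np.stack([h3 @ w3c[:, 0] for h3 in h3_list], axis=1)  # (P, N)
    v = np.stack([h4 @ w4c[:, 0] for h4 in h4_list], axis=1)  # (P, N)
    raw = q[:, :, None] * k[:, None, :]  # (P, L4, N)
    scores = _softmax(raw, axis=2)
    h5 = (scores * v[:, None, :]).sum(axis=2)  # (P, L4)
    return h5, scores


def self_attention_fuse(h4_list):
    """Conventional scaled dot-product self-attention over the N logit vectors.

    Query = key = value = the stacked logits (N x L4 per sample), scaled by
    1/sqrt(L4), mean-pooled over N.  Ablation baseline only.
    """
    n = len(h4_list)
    if n < 2:
        raise ValueError("self-attention needs >= 2 omics networks")
    x = np.stack(h4_list, axis=1)  # (P, N, L4)
    scale = 1.0 / np.sqrt(x.shape[2])
    raw = np.einsum("pnl,pml->pnm", x, x) * scale  # (P, N, N)
    scores = _softmax(raw, axis=2)
    out = np.einsum("pnm,pml->pnl", scores, x)  # (P, N, L4)
    return out.mean(axis=1), scores


def output_probabilities(h5: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction; rows are probability vectors."""
    h5 = np.asarray(h5, dtype=float)
    if not np.isfinite(h5).all():
        raise ValueError("logits must be finite")
    return _softmax(h5, axis=1)


def class_weights(labels) -> np.ndarray:
    """Per-class weights w_c = 1 - P_c / P from the training labels."""
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("class weighting needs both classes present")
    n = labels.size
    n_classes = int(classes.max()) + 1
    w = np.zeros(n_classes)
    for c in range(n_classes):
        w[c] = 1.0 - (labels == c).sum() / n
    return w


def weighted_cross_entropy(prob_positive, labels, weights) -> float:
    """Class-weighted binary cross-entropy, exactly the printed form:

    mean over samples of  -w_{y_d} y_d log(y) - (1 - w_{y_d})(1 - y_d) log(1 - y)

    with y the predicted probability of the positive class, clamped to
    [eps, 1 - eps] at eps = 1e-12.  Nonnegative.
    """
    y = np.clip(np.asarray(prob_positive, dtype=float), _EPS, 1.0 - _EPS)
    yd = np.asarray(labels, dtype=int)
    w = np.asarray(weights, dtype=float)
    wy = w[yd]
    per_sample = -wy * yd * np.log(y) - (1.0 - wy) * (1 - yd) * np.log(1.0 - y)
    return float(per_sample.mean())


def _loss_coefficients(labels: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    """Per-sample coefficient multiplying the cross-entropy term.

    Binary: the printed weighted form gives w_1 on y_d=1 samples and 1 - w_0
    on y_d=0 samples.  More than two classes: weighted categorical CE with
    coefficient w_{y_d}.  Without weighting, 0.5 (half the standard CE, the
    printed form at w = 0.5).
    """
    labels = np.asarray(labels, dtype=int)
    if weights is None:
        return np.full(labels.shape, 0.5)
    w = np.asarray(weights, dtype=float)
    if w.size == 2:
        return np.where(labels == 1, w[1], 1.0 - w[0])
    return w[labels]


def model_forward(
    xc: np.ndarray,
    psg_op: np.ndarray,
    pog_ops: list,
    params: ModelParameters,
    dropout_rate: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> ForwardTrace:
    """Full forward pass; ``psg_op``/``pog_ops`` are pre-normalized operators.

    Pass the outputs of :func:`normalize_adjacency` (so graphs are normalized
    once per training run, not once per epoch).  With ``training`` off,
    dropout is the identity and the pass is deterministic.
    """
    xc = np.asarray(xc, dtype=float)
    n_omics = params.n_omics
    if len(pog_ops) != n_omics:
        raise ValueError(f"expected {n_omics} POG operators, got {len(pog_ops)}")
    p = xc.shape[0]
    if psg_op.shape != (p, p):
        raise ValueError("PSG operator size must match sample count")

    use_dropout = training and dropout_rate > 0.0
    if use_dropout and rng is None:
        raise ValueError("training-mode dropout needs an rng")
    keep = 1.0 - dropout_rate

    cache: dict = {}
    z1 = xc @ params["W1"] + params["b1"]
    h1 = _relu(z1)
    u2 = psg_op @ h1
    z2 = u2 @ params["W2"]
    h2 = _relu(z2)
    if use_dropout:
        m2 = (rng.random(h2.shape) < keep).astype(float)
        h2d = h2 * m2 / keep
        cache["m2"] = m2
    else:
        h2d = h2
    cache.update(z1=z1, u2=u2, z2=z2, h2d=h2d)

    h3_list, h4_list = [], []
    for n in range(n_omics):
        u3 = pog_ops[n] @ h2d
        h3 = u3 @ params[f"W3_{n}"]
        if use_dropout:
            m3 = (rng.random(h3.shape) < keep).astype(float)
            h3d = h3 * m3 / keep
            cache[f"m3_{n}"] = m3
        else:
            h3d = h3
        r = _relu(h3d)
        z4 = r @ params[f"W4_{n}"] + params[f"b4_{n}"]
        h4 = _relu(z4)
        cache[f"u3_{n}"] = u3
        cache[f"h3d_{n}"] = h3d
        cache[f"r_{n}"] = r
        cache[f"z4_{n}"] = z4
        h3_list.append(h3)
        h4_list.append(h4)

    scores = None
    if n_omics == 0:
        h5 = h2d @ params["Wh"] + params["bh"]
    elif n_omics == 1:
        h5 = h4_list[0]
    elif params.variant == "self_attention":
        h5, scores = self_attention_fuse(h4_list)
        cache["x_stack"] = np.stack(h4_list, axis=1)
    else:
        h3d_list = [cache[f"h3d_{n}"] for n in range(n_omics)]
        h5, scores = attention_fuse(h3d_list, h4_list, params["W3c"], params["W4c"])
        cache["att_k"] = np.stack(
            [h3d @ params["W3c"][:, 0] for h3d in h3d_list], axis=1
        )
        cache["att_v"] = np.stack(
            [h4 @ params["W4c"][:, 0] for h4 in h4_list], axis=1
        )
        cache["att_q"] = np.mean(h4_list, axis=0)
    probs = output_probabilities(h5)
    return ForwardTrace(h1, h2, h3_list, h4_list, scores, h5, probs, cache)


def loss_and_gradients(
    trace: ForwardTrace,
    xc: np.ndarray,
    psg_op: np.ndarray,
    pog_ops: list,
    params: ModelParameters,
    labels: np.ndarray,
    mask: np.ndarray,
    weights: np.ndarray | None,
    dropout_rate: float = 0.0,
    sample_multiplicity: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Loss over the masked (training) nodes and gradients for every parameter.

    The forward pass runs over all P nodes (graph propagation mixes them);
    only masked nodes contribute loss terms.  ``sample_multiplicity`` carries
    oversampling counts: a scan duplicated k times contributes k identical
    loss terms, exactly as if the duplicate rows were materialized.
    Gradients are exact for the sampled dropout masks recorded in the trace.
    """
    labels = np.asarray(labels, dtype=int)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty training mask")
    n_omics = params.n_omics
    cache = trace.cache
    probs = trace.class_probabilities
    mult = np.ones(labels.size) if sample_multiplicity is None else np.asarray(
        sample_multiplicity, dtype=float)
    mult = mult * mask
    n_train = float(mult.sum())
    coef = _loss_coefficients(labels, weights)

    p_true = np.clip(probs[np.arange(labels.size), labels], _EPS, 1.0)
    loss = float((coef * mult * -np.log(p_true)).sum() / n_train)

    # softmax + cross-entropy
    d_h5 = probs.copy()
    d_h5[np.arange(labels.size), labels] -= 1.0
    d_h5 *= (coef * mult)[:, None] / n_train

    grads = {k: np.zeros_like(v) for k, v in params.values.items()}
    keep = 1.0 - dropout_rate
    use_dropout = "m2" in cache

    d_h4 = [np.zeros_like(h4) for h4 in trace.H4]
    d_h3d = [np.zeros_like(h4) for h4 in trace.H4]  # placeholder shapes fixed below
    d_h3d = [np.zeros_like(cache[f"h3d_{n}"]) for n in range(n_omics)]
    d_h2d = np.zeros_like(cache["h2d"])

    if n_omics == 0:
        grads["Wh"] = cache["h2d"].T @ d_h5
        grads["bh"] = d_h5.sum(axis=0)
        d_h2d += d_h5 @ params["Wh"].T
    elif n_omics == 1:
        d_h4[0] = d_h5
    elif params.variant == "self_attention":
        x = cache["x_stack"]  # (P, N, L4)
        s = trace.attention_scores  # (P, N, N)
        scale = 1.0 / np.sqrt(x.shape[2])
        d_out = np.repeat(d_h5[:, None, :], n_omics, axis=1) / n_omics
        d_s = np.einsum("pnl,pml->pnm", d_out, x)
        d_x = np.einsum("pnm,pnl->pml", s, d_out)
        d_raw = s * (d_s - (d_s * s).sum(axis=2, keepdims=True))
        d_x += (
            np.einsum("pnm,pml->pnl", d_raw, x)
            + np.einsum("pnm,pnl->pml", d_raw, x)
        ) * scale
        for n in range(n_omics):
            d_h4[n] = d_x[:, n, :]
    else:
        q, k, v = cache["att_q"], cache["att_k"], cache["att_v"]
        s = trace.attention_scores  # (P, L4, N)
        d_s = d_h5[:, :, None] * v[:, None, :]
        d_v = (s * d_h5[:, :, None]).sum(axis=1)  # (P, N)
        d_raw = s * (d_s - (d_s * s).sum(axis=2, keepdims=True))
        d_q = (d_raw * k[:, None, :]).sum(axis=2)  # (P, L4)
        d_k = (d_raw * q[:, :, None]).sum(axis=1)  # (P, N)
        for n in range(n_omics):
            d_h4[n] = d_q / n_omics + d_v[:, [n]] @ params["W4c"].T
            grads["W4c"] += trace.H4[n].T @ d_v[:, [n]]
            d_h3d[n] += d_k[:, [n]] @ params["W3c"].T
            grads["W3c"] += cache[f"h3d_{n}"].T @ d_k[:, [n]]

    for n in range(n_omics):
        z4 = cache[f"z4_{n}"]
        r = cache[f"r_{n}"]
        d_z4 = d_h4[n] * (z4 > 0)
        grads[f"W4_{n}"] += r.T @ d_z4
        grads[f"b4_{n}"] += d_z4.sum(axis=0)
        d_r = d_z4 @ params[f"W4_{n}"].T
        h3d = cache[f"h3d_{n}"]
        d_h3d_n = d_h3d[n] + d_r * (h3d > 0)
        if use_dropout:
            d_h3 = d_h3d_n * cache[f"m3_{n}"] / keep
        else:
            d_h3 = d_h3d_n
        u3 = cache[f"u3_{n}"]
        grads[f"W3_{n}"] += u3.T @ d_h3
        d_u3 = d_h3 @ params[f"W3_{n}"].T
        d_h2d += pog_ops[n].T @ d_u3

    if use_dropout:
        d_h2 = d_h2d * cache["m2"] / keep
    else:
        d_h2 = d_h2d
    d_z2 = d_h2 * (cache["z2"] > 0)
    grads["W2"] += cache["u2"].T @ d_z2
    d_u2 = d_z2 @ params["W2"].T
    d_h1 = psg_op.T @ d_u2
    d_z1 = d_h1 * (cache["z1"] > 0)
    grads["W1"] += xc.T @ d_z1
    grads["b1"] += d_z1.sum(axis=0)
    return loss, grads


class AdamState:
    """Adam optimizer with conventional defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: ModelParameters, learning_rate: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.values.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.values.items()}

    def step(self, params: ModelParameters, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1**self.t)
            v_hat = self.v[key] / (1 - b2**self.t)
            params[key] = params[key] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
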