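"""Numerical core of the association model.

Pure-NumPy implementation of every trainable stage — convolutional fusion of
the PPMI channel tensor, per-head node-type transformation, graph attention
over the heterogeneous association network, the two-branch neural aggregator,
the sigmoid inner-product decoder — together with a hand-derived reverse-mode
gradient of the cross-entropy objective and an Adam optimiser.  Parameters
live in a flat ``dict[str, np.ndarray]`` so that gradient checking, hashing
and checkpointing can treat them uniformly.

All forward functions are deterministic; the only randomness in the package
enters through parameter initialisation and negative-pair sampling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "xavier_normal",
    "conv_fuse",
    "concat_structure",
    "transform_nodes",
    "attention_aggregate",
    "neural_aggregate",
    "multi_head_concat",
    "decode",
    "bce_loss",
    "forward",
    "loss_and_grads",
    "AdamOptimizer",
]

PROB_CLAMP = 1e-7


def xavier_normal(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Xavier (Glorot) normal initialisation for a (fan_in, fan_out) matrix."""
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=(fan_in, fan_out))


def _leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_relu_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


_ACTIVATIONS = {
    "elu": (_elu, _elu_grad),
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
}


def flatten_channels(channels: np.ndarray) -> np.ndarray:
    """(C, n, n) channel stack -> (n, C*n) per-node feature matrix."""
    c, n, _ = channels.shape
    return np.transpose(channels, (1, 0, 2)).reshape(n, c * n)


def conv_fuse(channels: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """High-order representation from the channel tensor.

    Each of the C_out filters spans the full feature width of every input
    channel and is summed across channels, so per node the filter is a
    learned linear functional of its complete multi-order proximity profile:
    output[v, t] = sum_c channels[c, v, :] . weight[c*n:(c+1)*n, t] + bias[t].
    """
    x = flatten_channels(np.asarray(channels, dtype=float))
    if x.shape[1] != weight.shape[0]:
        raise ValueError(
            f"channel feature width {x.shape[1]} does not match filter length {weight.shape[0]}"
        )
    return x @ weight + bias


def concat_structure(first_order: list[np.ndarray], high_order: np.ndarray | None) -> np.ndarray:
    """First-order view blocks followed by the high-order block."""
    blocks = list(first_order)
    if high_order is not None:
        blocks.append(high_order)
    n = blocks[0].shape[0]
    if any(b.shape[0] != n for b in blocks):
        raise ValueError("structure blocks disagree on node count")
    return np.hstack(blocks)


def transform_nodes(
    x_m: np.ndarray, y_d: np.ndarray, w_m: np.ndarray, w_d: np.ndarray
) -> np.ndarray:
    """Map both node types into the shared f_tran space, miRNAs stacked first."""
    return np.vstack([x_m @ w_m, y_d @ w_d])


def attention_aggregate(
    h: np.ndarray,
    adjacency: np.ndarray,
    leaky_slope: float = 0.2,
    activation: str = "elu",
    return_cache: bool = False,
):
    """Attention-weighted neighbour representation over the association graph.

    Scores e_ij = LeakyReLU(h_i . h_j) are computed only along edges of the
    heterogeneous adjacency, normalised by a per-node softmax over the
    neighbour set, and the weighted neighbour sum is passed through the
    nonlinearity.  Nodes without any neighbour receive a zero representation.
    """
    act, _ = _ACTIVATIONS[activation]
    mask = np.asarray(adjacency, dtype=bool)
    raw = h @ h.T
    scores = _leaky_relu(raw, leaky_slope)
    neg = np.where(mask, scores, -np.inf)
    row_max = np.max(neg, axis=1, keepdims=True)
    has_nbr = np.isfinite(row_max[:, 0])
    row_max = np.where(np.isfinite(row_max), row_max, 0.0)
    expw = np.where(mask, np.exp(np.where(mask, scores, 0.0) - row_max), 0.0)
    denom = expw.sum(axis=1, keepdims=True)
    coef = np.divide(expw, denom, out=np.zeros_like(expw), where=denom > 0)
    pre = coef @ h
    h_n = np.where(has_nbr[:, None], act(pre), 0.0)
    if return_cache:
        cache = {"raw": raw, "mask": mask, "coef": coef, "pre": pre, "has_nbr": has_nbr}
        return h_n, cache
    return h_n


def neural_aggregate(
    h: np.ndarray,
    h_n: np.ndarray,
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: np.ndarray,
) -> np.ndarray:
    """Two-branch combiner of a node's own and neighbour representations.

    Branch 1 is an affine map of the concatenation (h || h_N); branch 2 an
    affine map of the sum (h + h_N); their outputs are concatenated, giving
    width 2 * f_tran per head.
    """
    branch1 = np.hstack([h, h_n]) @ w1 + b1
    branch2 = (h + h_n) @ w2 + b2
    return np.hstack([branch1, branch2])


def multi_head_concat(heads: list[np.ndarray], n_mirnas: int) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate head outputs and split miRNA / disease rows."""
    z = np.hstack(heads)
    return z[:n_mirnas], z[n_mirnas:]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def decode(z_m: np.ndarray, z_d: np.ndarray) -> np.ndarray:
    """Sigmoid inner-product score for every miRNA-disease pair."""
    return _sigmoid(z_m @ z_d.T)


def bce_loss(predicted: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy with probability clamping for safety."""
    p = np.clip(np.asarray(predicted, dtype=float), PROB_CLAMP, 1.0 - PROB_CLAMP)
    y = np.asarray(labels, dtype=float)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


# ---------------------------------------------------------------------------
# Full model forward / backward
# ---------------------------------------------------------------------------


def init_params(
    rng: np.random.Generator,
    n_mirnas: int,
    n_diseases: int,
    c_in_m: int,
    c_in_d: int,
    width_fo_m: int,
    width_fo_d: int,
    c_out: int,
    f_tran: int,
    n_heads: int,
    variant: str = "full",
) -> dict[str, np.ndarray]:
    """Xavier-normal parameter dictionary for the chosen model variant."""
    params: dict[str, np.ndarray] = {}
    high_order = variant != "no_high_order"
    if high_order:
        params["conv_w_m"] = xavier_normal(rng, c_in_m * n_mirnas, c_out)
        params["conv_b_m"] = np.zeros(c_out)
        params["conv_w_d"] = xavier_normal(rng, c_in_d * n_diseases, c_out)
        params["conv_b_d"] = np.zeros(c_out)
    d_m = width_fo_m + (c_out if high_order else 0)
    d_d = width_fo_d + (c_out if high_order else 0)
    for l in range(n_heads):
        params[f"h{l}_w_m"] = xavier_normal(rng, d_m, f_tran)
        params[f"h{l}_w_d"] = xavier_normal(rng, d_d, f_tran)
        if variant == "plain_gat":
            params[f"h{l}_w1"] = xavier_normal(rng, f_tran, 2 * f_tran)
            params[f"h{l}_b1"] = np.zeros(2 * f_tran)
        else:
            params[f"h{l}_w1"] = xavier_normal(rng, 2 * f_tran, f_tran)
            params[f"h{l}_b1"] = np.zeros(f_tran)
            params[f"h{l}_w2"] = xavier_normal(rng, f_tran, f_tran)
            params[f"h{l}_b2"] = np.zeros(f_tran)
    return params


def forward(
    params: dict[str, np.ndarray],
    inputs: dict,
    n_heads: int,
    variant: str = "full",
    leaky_slope: float = 0.2,
    activation: str = "elu",
    return_cache: bool = False,
):
    """Full forward pass to the logit matrix (nm x nd).

    ``inputs`` carries the fixed (non-trainable) quantities: the first-order
    blocks ``fo_m``/``fo_d``, flattened PPMI features ``xflat_m``/``xflat_d``
    (absent for the no_high_order variant) and the boolean message-passing
    ``adjacency`` of the training fold.
    """
    nm = inputs["fo_m"].shape[0]
    high_order = variant != "no_high_order"
    if high_order:
        xhat_m = inputs["xflat_m"] @ params["conv_w_m"] + params["conv_b_m"]
        yhat_d = inputs["xflat_d"] @ params["conv_w_d"] + params["conv_b_d"]
        x_m = np.hstack([inputs["fo_m"], xhat_m])
        y_d = np.hstack([inputs["fo_d"], yhat_d])
    else:
        x_m, y_d = inputs["fo_m"], inputs["fo_d"]
    heads = []
    caches = []
    for l in range(n_heads):
        h = transform_nodes(x_m, y_d, params[f"h{l}_w_m"], params[f"h{l}_w_d"])
        h_n, att_cache = attention_aggregate(
            h, inputs["adjacency"], leaky_slope, activation, return_cache=True
        )
        if variant == "plain_gat":
            z_l = h_n @ params[f"h{l}_w1"] + params[f"h{l}_b1"]
        else:
            z_l = neural_aggregate(
                h, h_n,
                params[f"h{l}_w1"], params[f"h{l}_b1"],
                params[f"h{l}_w2"], params[f"h{l}_b2"],
            )
        heads.append(z_l)
        caches.append({"h": h, "h_n": h_n, "att": att_cache})
    z_m, z_d = multi_head_concat(heads, nm)
    logits = z_m @ z_d.T
    if not return_cache:
        return logits
    cache = {"x_m": x_m, "y_d": y_d, "z_m": z_m, "z_d": z_d, "heads": caches,
             "high_order": high_order}
    return logits, cache


def loss_and_grads(
    params: dict[str, np.ndarray],
    inputs: dict,
    pairs: tuple[np.ndarray, np.ndarray],
    labels: np.ndarray,
    n_heads: int,
    variant: str = "full",
    leaky_slope: float = 0.2,
    activation: str = "elu",
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean BCE over the training pairs and its gradient w.r.t. every parameter.

    Reverse-mode differentiation written out by hand; the attention softmax,
    LeakyReLU scoring and the activation in the neighbour aggregation are all
    differentiated along the edge mask only.
    """
    rows, cols = pairs
    y = np.asarray(labels, dtype=float)
    logits, cache = forward(params, inputs, n_heads, variant, leaky_slope, activation,
                            return_cache=True)
    probs = _sigmoid(logits[rows, cols])
    loss = bce_loss(probs, y)

    _, act_grad = _ACTIVATIONS[activation]
    nm = cache["z_m"].shape[0]
    f_tran = cache["heads"][0]["h"].shape[1]
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    # dL/dlogits is sparse over the supervised pairs
    dlogits = np.zeros_like(logits)
    np.add.at(dlogits, (rows, cols), (probs - y) / y.size)

    dz_m = dlogits @ cache["z_d"]
    dz_d = dlogits.T @ cache["z_m"]
    dz = np.vstack([dz_m, dz_d])

    dx_m = np.zeros_like(cache["x_m"])
    dy_d = np.zeros_like(cache["y_d"])
    head_width = dz.shape[1] // n_heads
    for l in range(n_heads):
        hc = cache["heads"][l]
        h, h_n, att = hc["h"], hc["h_n"], hc["att"]
        dz_l = dz[:, l * head_width : (l + 1) * head_width]
        if variant == "plain_gat":
            grads[f"h{l}_w1"] += h_n.T @ dz_l
            grads[f"h{l}_b1"] += dz_l.sum(axis=0)
            dh_n = dz_l @ params[f"h{l}_w1"].T
            dh = np.zeros_like(h)
        else:
            dc1 = dz_l[:, :f_tran]
            dc2 = dz_l[:, f_tran:]
            hn_cat = np.hstack([h, h_n])
            grads[f"h{l}_w1"] += hn_cat.T @ dc1
            grads[f"h{l}_b1"] += dc1.sum(axis=0)
            dcat = dc1 @ params[f"h{l}_w1"].T
            grads[f"h{l}_w2"] += (h + h_n).T @ dc2
            grads[f"h{l}_b2"] += dc2.sum(axis=0)
            dsum = dc2 @ params[f"h{l}_w2"].T
            dh = dcat[:, :f_tran] + dsum
            dh_n = dcat[:, f_tran:] + dsum

        # through the neighbour activation (isolated nodes contribute nothing)
        dpre = dh_n * act_grad(att["pre"])
        dpre[~att["has_nbr"]] = 0.0
        # pre = coef @ h
        dcoef = dpre @ h.T
        dh += att["coef"].T @ dpre
        # softmax over the neighbour set of each node
        s = att["coef"]
        dscores = s * (dcoef - (s * dcoef).sum(axis=1, keepdims=True))
        # leaky-relu scoring along edges of the raw inner products
        draw = np.where(att["mask"], dscores * _leaky_relu_grad(att["raw"], leaky_slope), 0.0)
        dh += draw @ h + draw.T @ h

        grads[f"h{l}_w_m"] += cache["x_m"].T @ dh[:nm]
        grads[f"h{l}_w_d"] += cache["y_d"].T @ dh[nm:]
        dx_m += dh[:nm] @ params[f"h{l}_w_m"].T
        dy_d += dh[nm:] @ params[f"h{l}_w_d"].T

    if cache["high_order"]:
        c_out = params["conv_b_m"].shape[0]
        dxhat_m = dx_m[:, -c_out:]
        dyhat_d = dy_d[:, -c_out:]
        grads["conv_w_m"] += inputs["xflat_m"].T @ dxhat_m
        grads["conv_b_m"] += dxhat_m.sum(axis=0)
        grads["conv_w_d"] += inputs["xflat_d"].T @ dyhat_d
        grads["conv_b_d"] += dyhat_d.sum(axis=0)
    return loss, grads


class AdamOptimizer:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, params: dict[str, np.ndarray], learning_rate: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
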