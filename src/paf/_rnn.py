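"""NumPy stacked-LSTM core with masked pooling and a simplex readout.

Forward pass, full backpropagation-through-time, Huber loss on the softmax
output, and a decoupled-weight-decay Adam (AdamW) optimizer.  The module is
deliberately framework-free: matrices are small (tens of hidden units over
~50 wavelength steps), so vectorised NumPy is adequate for CPU training at
the scaled problem sizes this package runs, and the gradients are verified
against central finite differences in the test suite.  Inner loops reuse
preallocated buffers; per-step temporaries dominate the runtime otherwise.

Gate layout inside the fused 4H dimension is (input, forget, cell, output).
The forget-gate bias is initialised to 1, the usual stabilisation.
"""

from __future__ import annotations

import numpy as np


def _sigmoid_inplace(x: np.ndarray) -> np.ndarray:
    np.clip(x, -60.0, 60.0, out=x)
    np.exp(-x, out=x)
    x += 1.0
    np.reciprocal(x, out=x)
    return x


def init_params(
    input_size: int,
    hidden_size: int,
    num_layers: int,
    n_outputs: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    if min(input_size, hidden_size, num_layers, n_outputs) < 1:
        raise ValueError("all model sizes must be positive integers")
    params: dict[str, np.ndarray] = {}
    H = hidden_size
    for layer in range(num_layers):
        fan_in = input_size if layer == 0 else H
        s = 1.0 / np.sqrt(H)
        params[f"W{layer}"] = rng.uniform(-s, s, size=(fan_in, 4 * H))
        params[f"U{layer}"] = rng.uniform(-s, s, size=(H, 4 * H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0
        params[f"b{layer}"] = b
    s = 1.0 / np.sqrt(H)
    params["W_out"] = rng.uniform(-s, s, size=(H, n_outputs))
    params["b_out"] = np.zeros(n_outputs)
    return params


def num_layers_of(params: dict) -> int:
    return sum(1 for k in params if k.startswith("W") and k[1:].isdigit())


def forward(
    params: dict,
    X: np.ndarray,
    mask: np.ndarray | None = None,
    pooling: str = "mean",
    want_cache: bool = True,
):
    """Run the network on a batch.

    Parameters
    ----------
    X : (B, T, F) input sequences.
    mask : (B, T) 1/0 validity mask; None means all steps valid.
    pooling : "mean" (masked mean over valid steps) or "max".

    Returns (probs, cache); probs is (B, n_outputs) on the simplex.
    """
    B, T, _ = X.shape
    H = params["W_out"].shape[0]
    L = num_layers_of(params)
    full_mask = mask is None
    if mask is None:
        mask = np.ones((B, T))
    m3 = mask[:, :, None]

    layer_caches = []
    inp = X
    for layer in range(L):
        W, U, b = params[f"W{layer}"], params[f"U{layer}"], params[f"b{layer}"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.empty((T, B, H))
        gates = np.empty((T, B, 4 * H)) if want_cache else np.empty((1, B, 4 * H))
        c_prevs = np.empty((T, B, H)) if want_cache else None
        h_prevs = np.empty((T, B, H)) if want_cache else None
        tanh_cs = np.empty((T, B, H)) if want_cache else np.empty((1, B, H))
        pre = np.einsum("btf,fg->btg", inp, W, optimize=True)
        pre += b
        for t in range(T):
            ti = t if want_cache else 0
            z = gates[ti]
            np.matmul(h, U, out=z)
            z += pre[:, t, :]
            i = _sigmoid_inplace(z[:, :H])
            f = _sigmoid_inplace(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H], out=z[:, 2 * H : 3 * H])
            o = _sigmoid_inplace(z[:, 3 * H :])
            if want_cache:
                h_prevs[t] = h
                c_prevs[t] = c
            c_new = f * c
            c_new += i * g
            tc = np.tanh(c_new, out=tanh_cs[ti])
            h_new = o * tc
            if full_mask:
                h, c = h_new, c_new
            else:
                mt = mask[:, t : t + 1]
                h = mt * h_new + (1.0 - mt) * h
                c = mt * c_new + (1.0 - mt) * c
            Hs[t] = h
        layer_caches.append(
            dict(inp=inp, Hs=Hs, gates=gates, c_prevs=c_prevs, h_prevs=h_prevs,
                 tanh_cs=tanh_cs)
        )
        inp = np.moveaxis(Hs, 0, 1)  # (B, T, H) view

    top = inp
    counts = mask.sum(axis=1, keepdims=True)
    if np.any(counts == 0):
        raise ValueError("every sequence needs at least one valid step")
    if pooling == "mean":
        if full_mask:
            pooled = top.mean(axis=1)
        else:
            pooled = (top * m3).sum(axis=1) / counts
        pool_cache = None
    elif pooling == "max":
        neg = np.where(m3 > 0, top, -np.inf)
        arg = neg.argmax(axis=1)  # (B, H)
        pooled = np.take_along_axis(top, arg[:, None, :], axis=1)[:, 0, :]
        pool_cache = arg
    else:
        raise ValueError(f"unknown pooling {pooling!r}")

    logits = pooled @ params["W_out"] + params["b_out"]
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)

    cache = None
    if want_cache:
        cache = dict(
            layers=layer_caches, mask=mask, full_mask=full_mask, counts=counts,
            pooled=pooled, probs=probs, pooling=pooling, pool_cache=pool_cache,
        )
    return probs, cache


def huber_loss(pred: np.ndarray, target: np.ndarray, delta: float = 1.0):
    """Mean smooth-L1 loss and its gradient w.r.t. pred."""
    r = pred - target
    a = np.abs(r)
    quad = a <= delta
    loss = np.where(quad, 0.5 * r**2, delta * (a - 0.5 * delta))
    grad = np.clip(r, -delta, delta) / r.size
    return float(loss.mean()), grad


def backward(params: dict, cache: dict, dprobs: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss given d(loss)/d(probs)."""
    probs = cache["probs"]
    mask = cache["mask"]
    counts = cache["counts"]
    full_mask = cache["full_mask"]
    B, T = mask.shape
    H = params["W_out"].shape[0]
    L = num_layers_of(params)

    # softmax
    dlogits = probs * (dprobs - (dprobs * probs).sum(axis=1, keepdims=True))
    grads = {
        "W_out": cache["pooled"].T @ dlogits,
        "b_out": dlogits.sum(axis=0),
    }
    dpooled = dlogits @ params["W_out"].T  # (B, H)

    if cache["pooling"] == "mean":
        dtop = np.broadcast_to((dpooled / counts)[:, None, :], (B, T, H)).copy()
        if not full_mask:
            dtop *= mask[:, :, None]
    else:
        dtop = np.zeros((B, T, H))
        arg = cache["pool_cache"]
        np.put_along_axis(dtop, arg[:, None, :], dpooled[:, None, :], axis=1)

    dz = np.empty((B, 4 * H))
    dH_ext = dtop  # (B, T, H) gradient flowing into this layer's outputs
    for layer in reversed(range(L)):
        lc = cache["layers"][layer]
        W, U = params[f"W{layer}"], params[f"U{layer}"]
        gW = np.zeros_like(W)
        gU = np.zeros_like(U)
        gb = np.zeros_like(params[f"b{layer}"])
        dInp = np.empty_like(lc["inp"])
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            gates = lc["gates"][t]
            i, f = gates[:, :H], gates[:, H : 2 * H]
            g, o = gates[:, 2 * H : 3 * H], gates[:, 3 * H :]
            tc = lc["tanh_cs"][t]
            c_prev = lc["c_prevs"][t]
            h_prev = lc["h_prevs"][t]

            dh_total = dH_ext[:, t, :] + dh_next
            if full_mask:
                dh_new, dh_carry = dh_total, 0.0
                dc_new, dc_carry = dc_next.copy(), 0.0
            else:
                mt = mask[:, t : t + 1]
                dh_new = dh_total * mt
                dh_carry = dh_total * (1.0 - mt)
                dc_new = dc_next * mt
                dc_carry = dc_next * (1.0 - mt)

            do = dh_new * tc
            dc_new += dh_new * o * (1.0 - tc**2)
            di = dc_new * g
            dg = dc_new * i
            df = dc_new * c_prev
            dc_prev = dc_new * f

            np.multiply(di * i, 1.0 - i, out=dz[:, :H])
            np.multiply(df * f, 1.0 - f, out=dz[:, H : 2 * H])
            np.multiply(dg, 1.0 - g**2, out=dz[:, 2 * H : 3 * H])
            np.multiply(do * o, 1.0 - o, out=dz[:, 3 * H :])
            x_t = lc["inp"][:, t, :]
            gW += x_t.T @ dz
            gU += h_prev.T @ dz
            gb += dz.sum(axis=0)
            np.matmul(dz, W.T, out=dInp[:, t, :])
            dh_next = dz @ U.T
            if not full_mask:
                dh_next += dh_carry
            dc_next = dc_prev
            if not full_mask:
                dc_next = dc_next + dc_carry
        grads[f"W{layer}"] = gW
        grads[f"U{layer}"] = gU
        grads[f"b{layer}"] = gb
        dH_ext = dInp
    return grads


class AdamW:
    """Adam with decoupled weight decay (biases excluded from decay)."""

    def __init__(self, params: dict, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in params.items():
            g = grads[k]
            m, v = self.m[k], self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            if self.weight_decay and not k.startswith("b"):
                p *= 1.0 - self.lr * self.weight_decay
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
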