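"""Neural building blocks: attention, multi-head projection, transformer
set encoder (no positional encodings), layer norm, linear maps and a GRU.

Parameters live in flat ``dict[str, Tensor]`` namespaces so a model can
expose a single parameter dict to the optimizer and to checkpointing.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat


def uniform_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def linear_params(rng, d_in: int, d_out: int, prefix: str) -> dict:
    return {
        f"{prefix}.W": Tensor(uniform_init(rng, d_in, (d_in, d_out)), requires_grad=True),
        f"{prefix}.b": Tensor(np.zeros(d_out), requires_grad=True),
    }


def linear(x: Tensor, params: dict, prefix: str) -> Tensor:
    return x @ params[f"{prefix}.W"] + params[f"{prefix}.b"]


def layer_norm_params(d: int, prefix: str) -> dict:
    return {
        f"{prefix}.gamma": Tensor(np.ones(d), requires_grad=True),
        f"{prefix}.beta": Tensor(np.zeros(d), requires_grad=True),
    }


def layer_norm(x: Tensor, params: dict, prefix: str, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    xn = xc / (var + eps).sqrt()
    return xn * params[f"{prefix}.gamma"] + params[f"{prefix}.beta"]


def attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """Scaled dot-product attention, softmax over the key axis.

    The scale is the square root of the feature width of ``q``.
    """
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(
            f"query width {q.shape[-1]} != key width {k.shape[-1]}"
        )
    if k.shape[0] != v.shape[0]:
        raise ValueError("key and value row counts differ")
    scores = (q @ k.T) / np.sqrt(q.shape[-1])
    return scores.softmax(axis=-1) @ v


def multi_head_params(rng, d_model: int, h: int, prefix: str) -> dict:
    if d_model % h:
        raise ValueError(f"width {d_model} not divisible by {h} heads")
    p = {}
    for name in ("Q", "K", "V"):
        p[f"{prefix}.W{name}"] = Tensor(
            uniform_init(rng, d_model, (d_model, d_model)), requires_grad=True
        )
    p[f"{prefix}.WO"] = Tensor(
        uniform_init(rng, d_model, (d_model, d_model)), requires_grad=True
    )
    return p


def multi_head(q: Tensor, k: Tensor, v: Tensor, params: dict,
               prefix: str, h: int) -> Tensor:
    """Multi-head attention: per-head projected attention, concatenated,
    then output-projected."""
    d_model = q.shape[-1]
    if d_model % h:
        raise ValueError(f"width {d_model} not divisible by {h} heads")
    dk = d_model // h
    qp = q @ params[f"{prefix}.WQ"]
    kp = k @ params[f"{prefix}.WK"]
    vp = v @ params[f"{prefix}.WV"]
    heads = [
        attention(
            qp.slice_cols(i * dk, (i + 1) * dk),
            kp.slice_cols(i * dk, (i + 1) * dk),
            vp.slice_cols(i * dk, (i + 1) * dk),
        )
        for i in range(h)
    ]
    return concat(heads, axis=-1) @ params[f"{prefix}.WO"]


def encoder_params(rng, d_model: int, h: int, ffn_size: int, prefix: str) -> dict:
    p = {}
    p.update(multi_head_params(rng, d_model, h, f"{prefix}.mh"))
    p.update(linear_params(rng, d_model, ffn_size, f"{prefix}.ffn1"))
    p.update(linear_params(rng, ffn_size, d_model, f"{prefix}.ffn2"))
    p.update(layer_norm_params(d_model, f"{prefix}.ln1"))
    p.update(layer_norm_params(d_model, f"{prefix}.ln2"))
    return p


def encoder(x: Tensor, params: dict, prefix: str, h: int) -> Tensor:
    """One transformer block over a set of rows:
    ``LayerNorm(H + FFN(H))`` with ``H = LayerNorm(X + MH(X, X, X))``.
    """
    if x.shape[0] < 1:
        raise ValueError("encoder requires at least one input row")
    hmat = layer_norm(x + multi_head(x, x, x, params, f"{prefix}.mh", h),
                      params, f"{prefix}.ln1")
    ff = linear(linear(hmat, params, f"{prefix}.ffn1").relu(), params, f"{prefix}.ffn2")
    return layer_norm(hmat + ff, params, f"{prefix}.ln2")


def pool_set(rows: Tensor) -> Tensor:
    """Mean over rows — the set-to-vector reduction used everywhere."""
    if rows.shape[0] < 1:
        raise ValueError("cannot pool zero rows")
    return rows.mean(axis=0)


def gru_params(rng, d_in: int, d_hidden: int, prefix: str) -> dict:
    """Gated recurrent unit weights (reset / update / candidate gates)."""
    p = {}
    for gate in ("r", "z", "n"):
        p[f"{prefix}.Wx{gate}"] = Tensor(
            uniform_init(rng, d_in, (d_in, d_hidden)), requires_grad=True
        )
        p[f"{prefix}.Wh{gate}"] = Tensor(
            uniform_init(rng, d_hidden, (d_hidden, d_hidden)), requires_grad=True
        )
        p[f"{prefix}.bx{gate}"] = Tensor(np.zeros(d_hidden), requires_grad=True)
        p[f"{prefix}.bh{gate}"] = Tensor(np.zeros(d_hidden), requires_grad=True)
    return p


def gru_step(x: Tensor, hprev: Tensor, params: dict, prefix: str) -> Tensor:
    r = (x @ params[f"{prefix}.Wxr"] + params[f"{prefix}.bxr"]
         + hprev @ params[f"{prefix}.Whr"] + params[f"{prefix}.bhr"]).sigmoid()
    z = (x @ params[f"{prefix}.Wxz"] + params[f"{prefix}.bxz"]
         + hprev @ params[f"{prefix}.Whz"] + params[f"{prefix}.bhz"]).sigmoid()
    n = (x @ params[f"{prefix}.Wxn"] + params[f"{prefix}.bxn"]
         + r * (hprev @ params[f"{prefix}.Whn"] + params[f"{prefix}.bhn"])).tanh()
    return (1.0 - z) * n + z * hprev


def gru_sequence(xs: list[Tensor], d_hidden: int, params: dict, prefix: str) -> Tensor:
    """Run the GRU over a chronological sequence; return the final hidden state."""
    hstate = Tensor(np.zeros(d_hidden))
    for x in xs:
        hstate = gru_step(x, hstate, params, prefix)
    return hstate
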