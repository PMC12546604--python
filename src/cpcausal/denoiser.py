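"""Conditional residual denoising network, in plain numpy.

A compact fully-connected residual network predicts the v-target from the
flattened noisy latent, a sinusoidal embedding of the diffusion step, and
the conditioning context (compound embedding + confounder embeddings).
Time and context enter as additive modulations of the first hidden layer;
two residual blocks follow, mirroring — at desk scale — the role of the
residual U-Net levels of a full latent diffusion model. Training is MSE on
v with a hand-written backward pass and AdamW updates; everything is
seeded and single-threaded-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .utils import as_rng


@dataclass
class AdamWState:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 1e-4
    step: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def update(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.step += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m.get(k, 0.0) + (1 - b1) * g
            self.v[k] = b2 * self.v.get(k, 0.0) + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.step)
            vhat = self.v[k] / (1 - b2**self.step)
            params[k] -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * params[k]
            )


class ConditionalDenoiser:
    """v-prediction network: latent + time embedding + context -> v."""

    def __init__(
        self,
        latent_dim: int,
        context_dim: int,
        time_embed_dim: int = 32,
        hidden_dim: int = 384,
        n_res_blocks: int = 2,
        seed: int | np.random.Generator = 0,
    ):
        self.latent_dim = latent_dim
        self.context_dim = context_dim
        self.time_embed_dim = time_embed_dim
        self.hidden_dim = hidden_dim
        self.n_res_blocks = n_res_blocks
        rng = as_rng(seed)
        D, H, C, T = latent_dim, hidden_dim, context_dim, time_embed_dim

        def init(shape, scale):
            return (rng.standard_normal(shape) * scale).astype(np.float64)

        p = {
            "W_in": init((D, H), np.sqrt(2.0 / D)),
            "b_in": np.zeros(H),
            "W_t": init((T, H), np.sqrt(2.0 / T)),
            # FiLM gate: the diffusion step scales the signal path
            # multiplicatively (v is a t-dependent rotation of the input)
            "W_ts": np.zeros((T, H)),
            "W_c": init((C, H), np.sqrt(2.0 / max(C, 1))) if C else np.zeros((0, H)),
            "W_out": init((H, D), np.sqrt(1.0 / H)),
            "b_out": np.zeros(D),
        }
        for i in range(n_res_blocks):
            p[f"W1_{i}"] = init((H, H), np.sqrt(2.0 / H))
            p[f"b1_{i}"] = np.zeros(H)
            # small-scale second map keeps early residual branches gentle
            p[f"W2_{i}"] = init((H, H), 0.1 * np.sqrt(2.0 / H))
            p[f"b2_{i}"] = np.zeros(H)
        self.params = p

    # -- forward / backward -------------------------------------------------

    def forward(
        self, z: np.ndarray, temb: np.ndarray, ctx: np.ndarray, cache: bool = False
    ):
        p = self.params
        pre = z @ p["W_in"]
        gate = 1.0 + temb @ p["W_ts"]
        h = pre * gate + p["b_in"] + temb @ p["W_t"]
        if self.context_dim:
            h = h + ctx @ p["W_c"]
        acts = [h]
        relus = []
        for i in range(self.n_res_blocks):
            a = h @ p[f"W1_{i}"] + p[f"b1_{i}"]
            r = np.maximum(a, 0.0)
            h = h + r @ p[f"W2_{i}"] + p[f"b2_{i}"]
            relus.append(r)
            acts.append(h)
        out = h @ p["W_out"] + p["b_out"]
        if cache:
            return out, (z, temb, ctx, acts, relus, pre, gate)
        return out

    def backward(self, dout: np.ndarray, cached) -> dict[str, np.ndarray]:
        z, temb, ctx, acts, relus, pre, gate = cached
        p = self.params
        grads: dict[str, np.ndarray] = {}
        grads["W_out"] = acts[-1].T @ dout
        grads["b_out"] = dout.sum(axis=0)
        dh = dout @ p["W_out"].T
        for i in reversed(range(self.n_res_blocks)):
            r = relus[i]
            h_prev = acts[i]
            dr = dh @ p[f"W2_{i}"].T
            grads[f"W2_{i}"] = r.T @ dh
            grads[f"b2_{i}"] = dh.sum(axis=0)
            da = dr * (r > 0)
            grads[f"W1_{i}"] = h_prev.T @ da
            grads[f"b1_{i}"] = da.sum(axis=0)
            dh = dh + da @ p[f"W1_{i}"].T
        dpre = dh * gate
        grads["W_in"] = z.T @ dpre
        grads["b_in"] = dh.sum(axis=0)
        grads["W_t"] = temb.T @ dh
        grads["W_ts"] = temb.T @ (dh * pre)
        if self.context_dim:
            grads["W_c"] = ctx.T @ dh
        return grads

    # -- training step ------------------------------------------------------

    def train_step(
        self,
        z: np.ndarray,
        temb: np.ndarray,
        ctx: np.ndarray,
        target_v: np.ndarray,
        opt: AdamWState,
    ) -> float:
        pred, cached = self.forward(z, temb, ctx, cache=True)
        diff = pred - target_v
        loss = float(np.mean(diff * diff))
        dout = 2.0 * diff / diff.size
        grads = self.backward(dout, cached)
        opt.update(self.params, grads)
        return loss

    # -- (de)serialization --------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float64)

    @property
    def meta(self) -> dict:
        return {
            "latent_dim": self.latent_dim,
            "context_dim": self.context_dim,
            "time_embed_dim": self.time_embed_dim,
            "hidden_dim": self.hidden_dim,
            "n_res_blocks": self.n_res_blocks,
        }
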