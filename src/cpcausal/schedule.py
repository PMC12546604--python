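"""Diffusion noise schedule and the angular (v) parameterization.

The schedule is scaled-linear: betas are the squares of a linear ramp
between sqrt(beta_start) and sqrt(beta_end). The denoiser is trained to
predict v = sqrt(abar_t) * eps - sqrt(1 - abar_t) * x0, the rotation-mixed
combination of signal and noise; x0 and eps are exactly recoverable from
(x_t, v) by the inverse rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiffusionConfig:
    """Hyperparameters of the miniature conditional latent diffusion model.

    Desk-scale defaults; the full-scale reference values are noted inline.
    """

    num_train_steps: int = 250          # full scale: 1000
    beta_start: float = 0.0015
    beta_end: float = 0.0205
    schedule: str = "scaled_linear"
    parameterization: str = "v"
    latent_channels: int = 8            # 2 groups x 4 channels each
    image_size: int = 64                # full scale: 384
    downsample_factor: int = 4          # full scale: 8
    hidden_dim: int = 384               # stand-in for U-Net widths (256, 512, 768)
    n_res_blocks: int = 2
    time_embed_dim: int = 32
    context_dim: int = 0                # set when the conditioning is assembled
    num_inference_steps: int = 50

    def __post_init__(self):
        if not (0 < self.beta_start < self.beta_end < 1):
            raise ValueError("need 0 < beta_start < beta_end < 1")
        if self.latent_channels % 2 != 0:
            raise ValueError("latent_channels must be 2 x per-group channels")


@dataclass
class Schedule:
    betas: np.ndarray
    alphas: np.ndarray
    alpha_bars: np.ndarray

    @property
    def num_steps(self) -> int:
        return self.betas.size


def make_schedule(config: DiffusionConfig) -> Schedule:
    """Scaled-linear schedule: betas = linspace(sqrt(b0), sqrt(b1), T) ** 2."""
    if config.schedule != "scaled_linear":
        raise ValueError(f"unsupported schedule {config.schedule!r}")
    betas = (
        np.linspace(
            np.sqrt(config.beta_start), np.sqrt(config.beta_end), config.num_train_steps
        )
        ** 2
    )
    alphas = 1.0 - betas
    return Schedule(betas, alphas, np.cumprod(alphas))


def _check_t(t: int, schedule: Schedule) -> int:
    t = int(t)
    if not 0 <= t < schedule.num_steps:
        raise ValueError(f"step {t} outside [0, {schedule.num_steps})")
    return t


def v_target(x0: np.ndarray, eps: np.ndarray, t: int, schedule: Schedule) -> np.ndarray:
    """v = sqrt(abar_t) * eps - sqrt(1 - abar_t) * x0."""
    x0 = np.asarray(x0)
    eps = np.asarray(eps)
    if x0.shape != eps.shape:
        raise ValueError("x0 and eps must share a shape")
    t = _check_t(t, schedule)
    ab = schedule.alpha_bars[t]
    return np.sqrt(ab) * eps - np.sqrt(1.0 - ab) * x0


def noisy_sample(x0: np.ndarray, eps: np.ndarray, t: int, schedule: Schedule) -> np.ndarray:
    """x_t = sqrt(abar_t) * x0 + sqrt(1 - abar_t) * eps."""
    t = _check_t(t, schedule)
    ab = schedule.alpha_bars[t]
    return np.sqrt(ab) * np.asarray(x0) + np.sqrt(1.0 - ab) * np.asarray(eps)


def recover_x0(x_t: np.ndarray, v: np.ndarray, t: int, schedule: Schedule) -> np.ndarray:
    """Inverse rotation: x0 = sqrt(abar_t) * x_t - sqrt(1 - abar_t) * v."""
    t = _check_t(t, schedule)
    ab = schedule.alpha_bars[t]
    return np.sqrt(ab) * np.asarray(x_t) - np.sqrt(1.0 - ab) * np.asarray(v)


def recover_eps(x_t: np.ndarray, v: np.ndarray, t: int, schedule: Schedule) -> np.ndarray:
    """eps = sqrt(1 - abar_t) * x_t + sqrt(abar_t) * v."""
    t = _check_t(t, schedule)
    ab = schedule.alpha_bars[t]
    return np.sqrt(1.0 - ab) * np.asarray(x_t) + np.sqrt(ab) * np.asarray(v)


def sinusoidal_time_embedding(t: np.ndarray, dim: int, num_steps: int) -> np.ndarray:
    """Standard sinusoidal embedding of (possibly batched) integer steps."""
    t = np.atleast_1d(np.asarray(t, dtype=float)) / max(num_steps - 1, 1)
    half = dim // 2
    freqs = np.exp(np.linspace(0, np.log(1000.0), half))
    angles = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(angles), np.cos(angles)], axis=1)
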