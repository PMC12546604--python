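"""Phenotype-to-image renderer (the P -> O and C -> O mechanisms).

Images are 5-channel (DNA, ER, RNA, AGP, Mito) float arrays in [0, 1].
Each cell is drawn as a bright elliptical nucleus on the DNA channel and a
larger elliptical body on the remaining channels. Designated phenotype
coordinates drive, through monotone transforms:

    p[0] -> cell count, p[1] -> nucleus radius, p[2 + ch] -> channel intensity

Confounders act on the observation only through four renderer drivers
(x/y illumination gradient slopes, background offset, blur), so that with a
zero confounder code the render depends on the phenotype alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .scm import CHANNELS, RENDER_PARAM_DIM
from .utils import as_rng


@dataclass
class RenderParams:
    height: int = 64
    width: int = 64
    base_count: float = 10.0
    max_count: int = 40
    count_log_slope: float = 0.25
    base_radius: float = 4.0
    radius_log_slope: float = 0.12
    min_radius: float = 2.0
    max_radius: float = 8.0
    base_intensity: float = 0.55
    intensity_slope: float = 0.7
    cell_scale: float = 1.9
    separation_factor: float = 2.3
    noise_sd: float = 0.02
    gradient_scale: float = 0.35
    offset_scale: float = 0.12
    blur_scale: float = 0.8


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def phenotype_to_cell_params(phenotype: np.ndarray, rp: RenderParams):
    """Monotone transforms from phenotype coordinates to renderable quantities."""
    p = np.asarray(phenotype, dtype=float)
    count = int(np.clip(round(rp.base_count * np.exp(rp.count_log_slope * p[0])),
                        1, rp.max_count))
    radius = float(np.clip(rp.base_radius * np.exp(rp.radius_log_slope * p[1]),
                           rp.min_radius, rp.max_radius))
    logit0 = np.log(rp.base_intensity / (1 - rp.base_intensity))
    intensities = np.array([
        _sigmoid(logit0 + rp.intensity_slope * p[2 + ch] if 2 + ch < p.size else logit0)
        for ch in range(len(CHANNELS))
    ])
    return count, radius, intensities


def _place_centers(count, radius, rp: RenderParams, rng) -> np.ndarray:
    """Rejection-sample centers with a soft minimum separation."""
    min_sep = rp.separation_factor * radius
    margin = radius * rp.cell_scale
    centers = []
    for _ in range(count):
        for _attempt in range(40):
            y = rng.uniform(margin, rp.height - margin)
            x = rng.uniform(margin, rp.width - margin)
            if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2 for cy, cx in centers):
                centers.append((y, x))
                break
        else:  # crowded field: accept an overlapping placement
            centers.append((rng.uniform(margin, rp.height - margin),
                            rng.uniform(margin, rp.width - margin)))
    return np.array(centers)


def _add_ellipse(channel, cy, cx, ry, rx, theta, value):
    """Additively draw a soft-edged ellipse (vectorized on the full grid)."""
    h, w = channel.shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / rx
    v = (-st * dx + ct * dy) / ry
    d2 = u * u + v * v
    # smooth falloff at the boundary keeps Otsu thresholds stable
    channel += value * np.clip(1.15 - d2, 0.0, 1.0).clip(max=1.0)


def render_image(
    phenotype: np.ndarray,
    confounder_code: np.ndarray | None = None,
    render_params: RenderParams | None = None,
    rng: int | np.random.Generator = 0,
    observation_effect: np.ndarray | None = None,
    obs_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Render a 5-channel image from a phenotype vector.

    Confounder influence on the observation enters through
    ``observation_effect`` (the 4-vector of renderer drivers), or through
    ``obs_matrix @ confounder_code`` when the C->O matrix is given. With
    neither, the observation is unconfounded.
    """
    p = np.asarray(phenotype, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("phenotype contains non-finite values")
    rp = render_params or RenderParams()
    rng = as_rng(rng)

    if observation_effect is None:
        if obs_matrix is not None and confounder_code is not None:
            observation_effect = np.asarray(obs_matrix) @ np.asarray(confounder_code, float)
        else:
            observation_effect = np.zeros(RENDER_PARAM_DIM)
    g = np.asarray(observation_effect, dtype=float)
    if g.shape != (RENDER_PARAM_DIM,):
        raise ValueError(f"observation effect must have shape ({RENDER_PARAM_DIM},)")

    count, radius, intensities = phenotype_to_cell_params(p, rp)
    centers = _place_centers(count, radius, rp, rng)

    img = np.zeros((len(CHANNELS), rp.height, rp.width), dtype=float)
    for cy, cx in centers:
        theta = rng.uniform(0, np.pi)
        ecc = rng.uniform(0.75, 1.0)
        ry_n, rx_n = radius, radius * ecc
        ry_c, rx_c = radius * rp.cell_scale, radius * rp.cell_scale * ecc
        # nucleus on DNA; cell body on the organelle channels with a dimmer
        # nuclear shadow so cytoplasm and nucleus intensities differ
        _add_ellipse(img[0], cy, cx, ry_n, rx_n, theta, intensities[0])
        for ch in range(1, len(CHANNELS)):
            _add_ellipse(img[ch], cy, cx, ry_c, rx_c, theta, 0.75 * intensities[ch])
            _add_ellipse(img[ch], cy, cx, ry_n, rx_n, theta, -0.25 * intensities[ch])

    # confounder-driven observation corruption
    yy, xx = np.mgrid[0 : rp.height, 0 : rp.width]
    yn = yy / max(rp.height - 1, 1) - 0.5
    xn = xx / max(rp.width - 1, 1) - 0.5
    gradient = 1.0 + rp.gradient_scale * (g[0] * xn + g[1] * yn)
    offset = rp.offset_scale * g[2]
    blur_sigma = rp.blur_scale * np.log1p(np.exp(g[3])) - rp.blur_scale * np.log(2.0)
    blur_sigma = max(blur_sigma, 0.0)

    for ch in range(len(CHANNELS)):
        chan = img[ch] * gradient + offset
        if blur_sigma > 1e-3:
            chan = ndimage.gaussian_filter(chan, blur_sigma)
        chan = chan + rp.noise_sd * rng.standard_normal(chan.shape)
        img[ch] = np.clip(chan, 0.0, 1.0)

    return img.astype(np.float32)
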