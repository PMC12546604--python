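"""Channel-grouped latent autoencoder for 5-channel Cell Painting stacks.

The five stains exceed a 3-channel autoencoder's input, so channels are
split into two 3-channel groups — (DNA, ER, RNA) and (AGP, Mito, DNA),
duplicating DNA to complete the second group — each group is encoded
independently to 4 latent channels, and the latents are concatenated to 8
channels. Decoding inverts the grouping and resolves the duplicated DNA
channel by averaging its two reconstructions.

Two encoder modes:

* ``pca`` (default): a linear autoencoder fit on the training images —
  space-to-depth by the downsample factor, then a per-group PCA projection
  of the resulting pixel vectors to 4 components (decode = transpose map).
* ``identity``: factor-1 zero-padded pass-through; decode(encode(x)) is
  exact. Used as the test-mode encoder.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .scm import CHANNELS

GROUP_A = (0, 1, 2)  # DNA, ER, RNA
GROUP_B = (3, 4, 0)  # AGP, Mito, DNA (duplicated)
PER_GROUP_LATENT = 4


def _space_to_depth(x: np.ndarray, f: int) -> np.ndarray:
    c, h, w = x.shape
    if h % f or w % f:
        raise ValueError(f"image size {h}x{w} not divisible by factor {f}")
    x = x.reshape(c, h // f, f, w // f, f)
    return x.transpose(0, 2, 4, 1, 3).reshape(c * f * f, h // f, w // f)


def _depth_to_space(x: np.ndarray, f: int, c: int) -> np.ndarray:
    cf, hh, ww = x.shape
    x = x.reshape(c, f, f, hh, ww).transpose(0, 3, 1, 4, 2)
    return x.reshape(c, hh * f, ww * f)


class GroupAutoencoder(BaseEstimator):
    """Linear two-group latent autoencoder (see module docstring)."""

    def __init__(self, mode: str = "pca", downsample_factor: int = 4):
        self.mode = mode
        self.downsample_factor = downsample_factor

    # -- fitting ------------------------------------------------------------

    def fit(self, images: np.ndarray):
        """Fit per-group PCA maps on a stack of (N, 5, H, W) images."""
        images = np.asarray(images, dtype=float)
        if images.ndim != 4 or images.shape[1] != len(CHANNELS):
            raise ValueError("expected images of shape (N, 5, H, W)")
        if self.mode == "identity":
            self.factor_ = 1
            self.latent_scale_ = np.ones(2 * PER_GROUP_LATENT)
            self.latent_mean_ = np.zeros(2 * PER_GROUP_LATENT)
            return self
        if self.mode != "pca":
            raise ValueError(f"unknown mode {self.mode!r}")
        self.factor_ = int(self.downsample_factor)
        self.components_ = []
        self.means_ = []
        for group in (GROUP_A, GROUP_B):
            vecs = []
            for img in images:
                std = _space_to_depth(img[list(group)], self.factor_)
                vecs.append(std.reshape(std.shape[0], -1).T)
            X = np.concatenate(vecs, axis=0)
            mean = X.mean(axis=0)
            Xc = X - mean
            # principal axes of the pixel-vector cloud
            _, _, vt = np.linalg.svd(Xc, full_matrices=False)
            self.components_.append(vt[:PER_GROUP_LATENT])
            self.means_.append(mean)
        # standardize latent channels so diffusion sees ~unit-scale inputs
        lat = np.stack([self._encode_raw(img) for img in images])
        flat = lat.reshape(lat.shape[0], lat.shape[1], -1)
        self.latent_mean_ = flat.mean(axis=(0, 2))
        sd = flat.std(axis=(0, 2))
        self.latent_scale_ = np.where(sd > 1e-8, sd, 1.0)
        return self

    # -- transforms ---------------------------------------------------------

    def _encode_raw(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.ndim != 3 or image.shape[0] != len(CHANNELS):
            raise ValueError("expected a (5, H, W) image")
        if self.mode == "identity":
            pads = []
            for group in (GROUP_A, GROUP_B):
                g = image[list(group)]
                pads.append(np.concatenate([g, np.zeros((1, *g.shape[1:]))], axis=0))
            return np.concatenate(pads, axis=0)
        parts = []
        for group, comp, mean in zip((GROUP_A, GROUP_B), self.components_, self.means_):
            std = _space_to_depth(image[list(group)], self.factor_)
            flat = std.reshape(std.shape[0], -1).T
            coords = (flat - mean) @ comp.T
            parts.append(coords.T.reshape(PER_GROUP_LATENT, *std.shape[1:]))
        return np.concatenate(parts, axis=0)

    def encode(self, image: np.ndarray) -> np.ndarray:
        z = self._encode_raw(image)
        return (z - self.latent_mean_[:, None, None]) / self.latent_scale_[:, None, None]

    def decode(self, latent: np.ndarray) -> np.ndarray:
        latent = np.asarray(latent, dtype=float)
        if latent.ndim != 3 or latent.shape[0] != 2 * PER_GROUP_LATENT:
            raise ValueError(f"expected a ({2 * PER_GROUP_LATENT}, h, w) latent")
        z = latent * self.latent_scale_[:, None, None] + self.latent_mean_[:, None, None]
        if self.mode == "identity":
            rec_a = z[:PER_GROUP_LATENT][: len(GROUP_A)]
            rec_b = z[PER_GROUP_LATENT:][: len(GROUP_B)]
        else:
            recs = []
            for k, (comp, mean, group) in enumerate(
                zip(self.components_, self.means_, (GROUP_A, GROUP_B))
            ):
                coords = z[k * PER_GROUP_LATENT : (k + 1) * PER_GROUP_LATENT]
                flat = coords.reshape(PER_GROUP_LATENT, -1).T @ comp + mean
                std = flat.T.reshape(-1, *coords.shape[1:])
                recs.append(_depth_to_space(std, self.factor_, len(group)))
            rec_a, rec_b = recs
        out = np.zeros((len(CHANNELS), *rec_a.shape[1:]))
        out[1], out[2] = rec_a[1], rec_a[2]  # ER, RNA
        out[3], out[4] = rec_b[0], rec_b[1]  # AGP, Mito
        out[0] = 0.5 * (rec_a[0] + rec_b[2])  # DNA: mean of its two copies
        return out

    def latent_shape(self, image_size: int) -> tuple[int, int, int]:
        f = getattr(self, "factor_", 1 if self.mode == "identity" else self.downsample_factor)
        return (2 * PER_GROUP_LATENT, image_size // f, image_size // f)


def channel_group_encode(image5: np.ndarray, group_encoder: GroupAutoencoder) -> np.ndarray:
    return group_encoder.encode(image5)


def channel_group_decode(latent: np.ndarray, group_decoder: GroupAutoencoder) -> np.ndarray:
    return group_decoder.decode(latent)
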