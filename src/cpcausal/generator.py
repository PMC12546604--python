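"""Conditional latent diffusion generator of 5-channel Cell Painting images.

Pipeline: images are mapped into an 8-channel latent space by the grouped
autoencoder; a conditional denoiser is trained with v-prediction on a
scaled-linear noise schedule; sampling runs a deterministic DDIM-style
reverse pass conditioned on the compound embedding and the categorical
confounder embeddings (source, plate-level batch, well position, FoV).
MoA/target labels and hidden phenotypes never enter the conditioning.

Sampling refuses confounder ids outside the training vocabulary: the
Monte-Carlo adjustment must draw its confounder combinations from the
training support.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .autoencoder import GroupAutoencoder
from .denoiser import AdamWState, ConditionalDenoiser
from .embeddings import EmbeddingTables, embed_compound, embed_confounders
from .scm import ConfounderAssignment
from .schedule import (
    DiffusionConfig,
    make_schedule,
    noisy_sample,
    recover_eps,
    recover_x0,
    sinusoidal_time_embedding,
    v_target,
)
from .utils import as_rng


class LatentDiffusionGenerator(BaseEstimator):
    """Miniature confounder-conditioned latent diffusion model.

    Parameters mirror :class:`DiffusionConfig`; ``fit`` consumes an image
    stack plus its metadata table (``Metadata_Source/Plate/Well/FoV`` and
    ``Metadata_SMILES``), ``sample`` draws images for a (compound,
    confounder assignment) pair.
    """

    def __init__(
        self,
        config: DiffusionConfig | None = None,
        autoencoder_mode: str = "pca",
        compound_dim: int = 64,
        confounder_dims: tuple[int, int, int, int] = (4, 8, 4, 2),
        epochs: int = 20,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        self.config = config
        self.autoencoder_mode = autoencoder_mode
        self.compound_dim = compound_dim
        self.confounder_dims = confounder_dims
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    # -- conditioning -------------------------------------------------------

    def _context(self, smiles: str, assignment: ConfounderAssignment) -> np.ndarray:
        vec = embed_compound(smiles, self.compound_dim)
        return embed_confounders(assignment, self.tables_, vec).context

    # -- training -----------------------------------------------------------

    def fit(self, images: np.ndarray, metadata: pd.DataFrame):
        """Train autoencoder + denoiser on (N, 5, H, W) images with metadata."""
        images = np.asarray(images, dtype=float)
        if len(images) == 0:
            raise ValueError("empty training dataset")
        if len(images) != len(metadata):
            raise ValueError("images and metadata length mismatch")
        cfg = self.config or DiffusionConfig(image_size=images.shape[-1])
        rng = as_rng(self.seed)

        self.tables_ = EmbeddingTables.build(
            sources=list(metadata["Metadata_Source"].astype(str)),
            batches=list(metadata["Metadata_Plate"].astype(str)),
            wells=list(metadata["Metadata_Well"].astype(str)),
            fovs=list(metadata["Metadata_FoV"].astype(str)),
            dims=self.confounder_dims,
            seed=rng.integers(2**31),
        )
        self.autoencoder_ = GroupAutoencoder(
            mode=self.autoencoder_mode, downsample_factor=cfg.downsample_factor
        ).fit(images)
        self.latent_shape_ = self.autoencoder_.latent_shape(images.shape[-1])
        latent_dim = int(np.prod(self.latent_shape_))

        assignments = [
            ConfounderAssignment(
                str(r["Metadata_Source"]), str(r.get("Metadata_Batch", r["Metadata_Plate"])),
                str(r["Metadata_Plate"]),
                ord(str(r["Metadata_Well"])[0]) - ord("A"),
                int(str(r["Metadata_Well"])[1:]) - 1,
                int(r["Metadata_FoV"]),
            )
            for _, r in metadata.iterrows()
        ]
        contexts = np.stack(
            [
                self._context(str(s), a)
                for s, a in zip(metadata["Metadata_SMILES"], assignments)
            ]
        )
        cfg.context_dim = contexts.shape[1]
        self.config_ = cfg
        self.schedule_ = make_schedule(cfg)

        latents = np.stack([self.autoencoder_.encode(img).ravel() for img in images])

        self.denoiser_ = ConditionalDenoiser(
            latent_dim,
            cfg.context_dim,
            cfg.time_embed_dim,
            cfg.hidden_dim,
            cfg.n_res_blocks,
            seed=rng.integers(2**31),
        )
        opt = AdamWState(lr=self.learning_rate)
        n = latents.shape[0]
        self.loss_history_ = []
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                x0 = latents[idx]
                t = int(rng.integers(cfg.num_train_steps))
                eps = rng.standard_normal(x0.shape)
                z_t = noisy_sample(x0, eps, t, self.schedule_)
                v = v_target(x0, eps, t, self.schedule_)
                temb = np.repeat(
                    sinusoidal_time_embedding(t, cfg.time_embed_dim, cfg.num_train_steps),
                    len(idx),
                    axis=0,
                )
                epoch_losses.append(
                    self.denoiser_.train_step(z_t, temb, contexts[idx], v, opt)
                )
            self.loss_history_.append(float(np.mean(epoch_losses)))
        return self

    # -- sampling -----------------------------------------------------------

    def sample(
        self,
        compound_smiles: str,
        assignment: ConfounderAssignment,
        n: int = 1,
        rng: int | np.random.Generator = 0,
        num_inference_steps: int | None = None,
    ) -> np.ndarray:
        """Draw n images from p(O | T = compound, C = assignment).

        The reverse pass is a deterministic DDIM update, so a fixed seed
        (which fixes the initial noise) yields bit-identical images.
        """
        if not hasattr(self, "denoiser_"):
            raise RuntimeError("generator is not trained")
        cfg = self.config_
        rng = as_rng(rng)
        steps = num_inference_steps or cfg.num_inference_steps
        ctx = np.repeat(self._context(compound_smiles, assignment)[None, :], n, axis=0)
        ts = np.unique(
            np.linspace(0, cfg.num_train_steps - 1, steps).round().astype(int)
        )[::-1]
        z = rng.standard_normal((n, int(np.prod(self.latent_shape_))))
        for k, t in enumerate(ts):
            temb = np.repeat(
                sinusoidal_time_embedding(t, cfg.time_embed_dim, cfg.num_train_steps),
                n,
                axis=0,
            )
            v = self.denoiser_.forward(z, temb, ctx)
            x0 = recover_x0(z, v, int(t), self.schedule_)
            eps = recover_eps(z, v, int(t), self.schedule_)
            if k + 1 < len(ts):
                ab_next = self.schedule_.alpha_bars[ts[k + 1]]
                z = np.sqrt(ab_next) * x0 + np.sqrt(1.0 - ab_next) * eps
            else:
                z = x0
        images = np.stack(
            [
                np.clip(self.autoencoder_.decode(zi.reshape(self.latent_shape_)), 0, 1)
                for zi in z
            ]
        ).astype(np.float32)
        return images

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "weights.npz",
            **{f"denoiser_{k}": v for k, v in self.denoiser_.state_dict().items()},
            latent_mean=self.autoencoder_.latent_mean_,
            latent_scale=self.autoencoder_.latent_scale_,
            **(
                {
                    f"pca_components_{i}": c
                    for i, c in enumerate(self.autoencoder_.components_)
                }
                if self.autoencoder_mode == "pca"
                else {}
            ),
            **(
                {f"pca_means_{i}": m for i, m in enumerate(self.autoencoder_.means_)}
                if self.autoencoder_mode == "pca"
                else {}
            ),
            **{f"table_source_{k}": v for k, v in self.tables_.source.items()},
            **{f"table_batch_{k}": v for k, v in self.tables_.batch.items()},
            **{f"table_well_{k}": v for k, v in self.tables_.well.items()},
            **{f"table_fov_{k}": v for k, v in self.tables_.fov.items()},
        )
        meta = {
            "config": vars(self.config_),
            "denoiser": self.denoiser_.meta,
            "latent_shape": list(self.latent_shape_),
            "autoencoder_mode": self.autoencoder_mode,
            "compound_dim": self.compound_dim,
            "confounder_dims": list(self.confounder_dims),
            "vocabularies": self.tables_.vocabularies(),
            "loss_history": self.loss_history_,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "LatentDiffusionGenerator":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        data = np.load(directory / "weights.npz")
        cfg = DiffusionConfig(**meta["config"])
        gen = cls(
            config=cfg,
            autoencoder_mode=meta["autoencoder_mode"],
            compound_dim=meta["compound_dim"],
            confounder_dims=tuple(meta["confounder_dims"]),
        )
        gen.config_ = cfg
        gen.schedule_ = make_schedule(cfg)
        gen.latent_shape_ = tuple(meta["latent_shape"])
        gen.loss_history_ = meta["loss_history"]
        ae = GroupAutoencoder(meta["autoencoder_mode"], cfg.downsample_factor)
        ae.factor_ = 1 if meta["autoencoder_mode"] == "identity" else cfg.downsample_factor
        ae.latent_mean_ = data["latent_mean"]
        ae.latent_scale_ = data["latent_scale"]
        if meta["autoencoder_mode"] == "pca":
            ae.components_ = [data["pca_components_0"], data["pca_components_1"]]
            ae.means_ = [data["pca_means_0"], data["pca_means_1"]]
        gen.autoencoder_ = ae
        vocab = meta["vocabularies"]
        gen.tables_ = EmbeddingTables(
            source={k: data[f"table_source_{k}"] for k in vocab["source"]},
            batch={k: data[f"table_batch_{k}"] for k in vocab["batch"]},
            well={k: data[f"table_well_{k}"] for k in vocab["well"]},
            fov={k: data[f"table_fov_{k}"] for k in vocab["fov"]},
        )
        dn_meta = meta["denoiser"]
        gen.denoiser_ = ConditionalDenoiser(
            dn_meta["latent_dim"],
            dn_meta["context_dim"],
            dn_meta["time_embed_dim"],
            dn_meta["hidden_dim"],
            dn_meta["n_res_blocks"],
        )
        gen.denoiser_.load_state_dict(
            {k[len("denoiser_"):]: data[k] for k in data.files if k.startswith("denoiser_")}
        )
        return gen


def train_generator(
    images: np.ndarray,
    metadata: pd.DataFrame,
    config: DiffusionConfig | None = None,
    rng: int = 0,
    **kwargs,
) -> LatentDiffusionGenerator:
    """Functional wrapper over :meth:`LatentDiffusionGenerator.fit`."""
    return LatentDiffusionGenerator(config=config, seed=int(rng), **kwargs).fit(
        images, metadata
    )


def sample_images(
    generator: LatentDiffusionGenerator,
    compound_smiles: str,
    assignment: ConfounderAssignment,
    n: int = 1,
    rng: int | np.random.Generator = 0,
    num_inference_steps: int | None = None,
) -> np.ndarray:
    return generator.sample(compound_smiles, assignment, n, rng, num_inference_steps)
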