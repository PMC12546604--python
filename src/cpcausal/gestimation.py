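"""Monte-Carlo backdoor adjustment (g-estimation) of compound effects.

The interventional distribution p(O | do(T = t)) equals the conditional
p(O | T = t, C) averaged over the confounder marginal p(C). With an
explicit conditional generator this integral is approximated by Monte
Carlo: draw N confounder combinations c_i uniformly from the training
support (enforcing C independent of T), generate images for (t, c_i),
extract image-level profiles, and average the N per-combination profiles.
The averaging happens after feature extraction, not at the pixel level.

The procedure is generic over the conditional generator: the trained
diffusion model, or the simulator's true conditional (the oracle path,
used to separate Monte-Carlo error from generative-model error).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import profiling
from .embeddings import embed_compound
from .io import feature_columns, write_profiles
from .render import RenderParams, render_image
from .scm import (
    CONTROL_COMPOUND,
    CompoundRecord,
    ConfounderAssignment,
    ExperimentDesign,
    ScmParams,
    confounder_code,
    render_params_for,
    sample_phenotype,
)
from .transform import ProfileNormalizer
from .utils import as_rng

#: generator signature: (smiles, assignment, n_images, rng) -> (n, 5, H, W) images
GeneratorFn = Callable[[str, ConfounderAssignment, int, np.random.Generator], np.ndarray]

#: profiler signature: image -> image-level profile Series (median over cells), or None on QC failure
ProfilerFn = Callable[[np.ndarray], "pd.Series | None"]


@dataclass
class ConfounderPool:
    """Uniform sampling support for confounder combinations.

    ``batches`` maps a globally unique plate-level batch id (the plate) to
    its (source, experimental batch) pair — sampling a plate implies its
    source and batch. Wells are (row, col) positions; FoV indices are
    sampled uniformly as an auxiliary condition.
    """

    batches: dict[str, tuple[str, str]]  # plate_id -> (source_id, batch_id)
    wells: list[tuple[int, int]]
    fovs: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self):
        if not self.batches or not self.wells or not self.fovs:
            raise ValueError("confounder pool components must be non-empty")

    @classmethod
    def from_design(cls, design: ExperimentDesign) -> "ConfounderPool":
        batches = {}
        for plate, (batch, _, _) in design.plates.items():
            batches[plate] = (design.batch_source[batch], batch)
        wells = sorted({w for ws in design.wells.values() for w in ws})
        return cls(batches, wells, list(range(design.fovs_per_well)))


@dataclass
class AdjustmentConfig:
    n_combinations: int = 10  # reference analysis uses N = 10 and N = 100
    images_per_combination: int = 1
    seed: int = 0
    qc_thresholds: profiling.QcThresholds | None = None


@dataclass
class DebiasedProfile:
    compound_id: str
    profile: pd.Series  # treatment-level, normalized
    raw_profile: pd.Series  # arithmetic mean over per-combination profiles
    sampled_combinations: list[ConfounderAssignment]
    n_images_used: int


def sample_confounder_combinations(
    pool: ConfounderPool, N: int, rng: int | np.random.Generator
) -> list[ConfounderAssignment]:
    """Draw N assignments, each component independently uniform over its pool."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = as_rng(rng)
    plate_ids = sorted(pool.batches)
    out = []
    for _ in range(N):
        plate = plate_ids[rng.integers(len(plate_ids))]
        source, batch = pool.batches[plate]
        r, c = pool.wells[rng.integers(len(pool.wells))]
        fov = pool.fovs[rng.integers(len(pool.fovs))]
        out.append(ConfounderAssignment(source, batch, plate, r, c, fov))
    return out


def _mean_image_profile(
    generator: GeneratorFn,
    profiler: ProfilerFn,
    smiles: str,
    combinations: Sequence[ConfounderAssignment],
    config: AdjustmentConfig,
    rng: np.random.Generator,
) -> tuple[pd.Series, int]:
    """Mean over per-combination image-level profiles; QC-failed images are
    resampled once, then the combination is dropped with a warning."""
    collected = []
    n_images = 0
    for ci in combinations:
        profile = None
        for _attempt in range(2):
            images = generator(smiles, ci, config.images_per_combination, rng)
            per_image = [profiler(img) for img in images]
            per_image = [p for p in per_image if p is not None]
            if per_image:
                profile = pd.concat(per_image, axis=1).mean(axis=1)
                n_images += len(per_image)
                break
        if profile is None:
            warnings.warn(f"combination {ci} dropped: generated images failed QC twice")
            continue
        collected.append(profile)
    if not collected:
        raise RuntimeError(
            "all generated images failed QC; no profile could be computed"
        )
    return pd.concat(collected, axis=1).mean(axis=1), n_images


def make_image_profiler(
    qc_thresholds: profiling.QcThresholds | None = None,
    illumination_radius: int = 7,
    expected_radius: float = 4.0,
) -> ProfilerFn:
    """Standard profiler: full pipeline to an image-level profile (median over cells)."""

    def profiler(image: np.ndarray):
        cells, qc = profiling.profile_image(
            image,
            illumination_radius=illumination_radius,
            qc_thresholds=qc_thresholds,
            expected_radius=expected_radius,
        )
        if not qc.passed or cells.empty:
            return None
        feats = feature_columns(cells)
        return cells[feats].median()

    return profiler


def adjust(
    generator: GeneratorFn,
    profiler: ProfilerFn,
    compound: CompoundRecord,
    pool: ConfounderPool,
    config: AdjustmentConfig,
    combinations: list[ConfounderAssignment] | None = None,
    control_smiles: str = CONTROL_COMPOUND,
) -> DebiasedProfile:
    """Debias one compound: average over N confounder combinations, then
    normalize against control profiles generated under the same combinations.

    The same combination list is reused for the control reference (and, via
    ``adjust_dataset``, for every compound of a run), enforcing exact
    independence between C and T.
    """
    rng = as_rng(config.seed)
    if combinations is None:
        combinations = sample_confounder_combinations(pool, config.n_combinations, rng)
    raw, n_images = _mean_image_profile(
        generator, profiler, compound.smiles, combinations, config, rng
    )
    ctrl_rng = as_rng(config.seed + 1)
    ctrl_raw, _ = _mean_image_profile(
        generator, profiler, control_smiles, combinations, config, ctrl_rng
    )
    table = pd.DataFrame([raw, ctrl_raw])
    table.insert(0, "Metadata_Compound", [compound.compound_id, CONTROL_COMPOUND])
    # single control profile: center on it, robust scale unavailable -> unit
    feats = feature_columns(table)
    normalized = raw[feats] - ctrl_raw[feats]
    return DebiasedProfile(
        compound.compound_id, normalized, raw, list(combinations), n_images
    )


def adjust_dataset(
    generator: GeneratorFn,
    profiler: ProfilerFn,
    compounds: Sequence[CompoundRecord],
    pool: ConfounderPool,
    config: AdjustmentConfig,
    select: bool = True,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Debias a whole compound set under one shared combination list.

    For each compound (and the DMSO control) the N-combination mean profile
    is computed; profiles are then robust-z normalized against replicated
    control profiles and (optionally) feature-selected. Returns a
    treatment-level profile table with columns ``Metadata_Compound``, ``N``,
    ``seed``, ``n_images_used`` followed by features.
    """
    rng = as_rng(config.seed)
    combinations = sample_confounder_combinations(pool, config.n_combinations, rng)

    rows = []
    meta = []
    for rec in compounds:
        if rec.is_control:
            continue
        raw, n_used = _mean_image_profile(
            generator, profiler, rec.smiles, combinations, config, rng
        )
        rows.append(raw)
        meta.append((rec.compound_id, n_used))
    # replicated control profiles define the normalization reference;
    # each replicate re-generates DMSO under the same shared combinations
    n_ctrl = max(4, min(8, len(rows)))
    for k in range(n_ctrl):
        raw, n_used = _mean_image_profile(
            generator, profiler, CONTROL_COMPOUND, combinations, config, rng
        )
        rows.append(raw)
        meta.append((CONTROL_COMPOUND, n_used))

    table = pd.DataFrame(rows).reset_index(drop=True)
    table.insert(0, "Metadata_Compound", [m[0] for m in meta])
    normalized = ProfileNormalizer(per_plate=False).fit_transform(table)
    if select:
        from .transform import FeatureSelector

        try:
            normalized = FeatureSelector().fit_transform(normalized)
        except ValueError:
            warnings.warn("feature selection dropped everything; skipped")
    normalized.insert(1, "N", config.n_combinations)
    normalized.insert(2, "seed", config.seed)
    normalized.insert(3, "n_images_used", [m[1] for m in meta])

    if out_path is not None:
        out_path = Path(out_path)
        write_profiles(normalized, out_path)
        sidecar = [
            {
                "source": ci.source_id,
                "batch": ci.batch_id,
                "plate": ci.plate_id,
                "well": ci.well_name,
                "fov": ci.fov_index,
            }
            for ci in combinations
        ]
        out_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return normalized


# ---------------------------------------------------------------------------
# oracle path: the simulator's true conditional replaces the learned model
# ---------------------------------------------------------------------------


def make_oracle_generator(
    params: ScmParams,
    design: ExperimentDesign,
    render_params: RenderParams | None = None,
    embedding_dim: int | None = None,
) -> GeneratorFn:
    """Conditional sampler p(O | T, C) straight from the simulator mechanisms."""
    rp = render_params or RenderParams()
    dim = embedding_dim or params.embedding_dim

    def generate(smiles, assignment, n, rng):
        code = confounder_code(assignment, design)
        emb = embed_compound(smiles, dim)
        out = []
        for _ in range(n):
            phenotype = sample_phenotype(emb, code, params, rng)
            out.append(
                render_image(
                    phenotype,
                    render_params=rp,
                    rng=rng,
                    observation_effect=render_params_for(code, params),
                )
            )
        return np.stack(out)

    return generate


def adjust_with_oracle(
    params: ScmParams,
    design: ExperimentDesign,
    compounds: Sequence[CompoundRecord],
    config: AdjustmentConfig,
    render_params: RenderParams | None = None,
    profiler: ProfilerFn | None = None,
    select: bool = True,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Backdoor adjustment with the true simulator conditional.

    Identical control flow to :func:`adjust_dataset`; isolates Monte-Carlo
    estimation error from diffusion-model fit error.
    """
    rp = render_params or RenderParams()
    generator = make_oracle_generator(params, design, rp)
    if profiler is None:
        profiler = make_image_profiler(
            config.qc_thresholds, expected_radius=rp.base_radius
        )
    pool = ConfounderPool.from_design(design)
    return adjust_dataset(
        generator, profiler, compounds, pool, config, select=select, out_path=out_path
    )
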