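"""Simplified CellProfiler-style morphological profiling.

The pipeline mirrors the standard high-content workflow: per-channel
illumination correction (median-filter estimate of the illumination
field), image-level quality control (blur / saturation / intensity),
Otsu-based nucleus segmentation with distance-transform declumping,
watershed expansion of cell bodies around nuclei, per-cell shape and
intensity features grouped by region (Nucleus / Cytoplasm / Cell), and
the median -> mean aggregation hierarchy:

    cells --median--> image profile --mean--> well profile --mean--> treatment profile

The reduced feature set (~84 features) keeps the region-prefixed naming
convention of CellProfiler exports so downstream code is schema-compatible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, measure, morphology, segmentation

from .io import feature_columns, metadata_columns
from .scm import CHANNELS

REGIONS = ("Nucleus", "Cytoplasm", "Cell")
SHAPE_FEATURES = ("area", "perimeter", "axis_ratio")
INTENSITY_STATS = ("mean", "median", "integrated", "sd", "texture")


# ---------------------------------------------------------------------------
# illumination correction
# ---------------------------------------------------------------------------


def correct_illumination(image: np.ndarray, filter_radius: int = 15) -> np.ndarray:
    """Divide each channel by its median-filtered illumination estimate.

    The smoothed field approximates the (slowly varying) illumination
    distribution; dividing by it and rescaling to the original channel
    mean removes gradients while preserving overall intensity.
    """
    image = np.asarray(image, dtype=float)
    if filter_radius < 1:
        raise ValueError("filter_radius must be >= 1")
    if 2 * filter_radius + 1 > min(image.shape[-2:]):
        raise ValueError("filter_radius larger than image")
    footprint = morphology.disk(filter_radius)
    out = np.empty_like(image)
    for ch in range(image.shape[0]):
        chan = image[ch]
        if np.all(chan == 0):
            warnings.warn(f"channel {ch} is identically zero; left unchanged")
            out[ch] = chan
            continue
        # the illumination field is slowly varying, so the median filter runs
        # on a 2x block-reduced copy and is upsampled back
        h, w = chan.shape
        if min(h, w) >= 32 and h % 2 == 0 and w % 2 == 0:
            small = chan.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
            r = max(filter_radius // 2, 1)
            illum = ndimage.median_filter(
                small, footprint=morphology.disk(r), mode="nearest"
            )
            illum = ndimage.gaussian_filter(illum, r / 2.0)
            illum = np.kron(illum, np.ones((2, 2)))
        else:
            illum = ndimage.median_filter(chan, footprint=footprint, mode="nearest")
            illum = ndimage.gaussian_filter(illum, filter_radius / 2.0)
        # floor clip keeps the divisor strictly positive
        floor = max(1e-6, 0.05 * float(illum.max()))
        illum = np.clip(illum, floor, None)
        corrected = chan / illum
        scale = chan.mean() / corrected.mean() if corrected.mean() > 0 else 1.0
        out[ch] = corrected * scale
    return out


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


@dataclass
class QcThresholds:
    max_saturation: float = 0.5
    min_blur: float = 1e-8
    min_intensity: float = 1e-4
    max_intensity: float = 0.98
    saturation_level: float = 0.99


@dataclass
class QcMetrics:
    blur_score: float
    saturation_fraction: float
    intensity_mean: float
    intensity_sd: float
    passed: bool


def compute_qc(image: np.ndarray, thresholds: QcThresholds | None = None) -> QcMetrics:
    """Image-level QC from blur, saturation and intensity statistics.

    ``blur_score`` is the variance of a Laplacian high-pass response of the
    mean channel (lower = blurrier); ``saturation_fraction`` the fraction of
    pixels at or above the saturation level across channels.
    """
    th = thresholds or QcThresholds()
    image = np.asarray(image, dtype=float)
    mean_chan = image.mean(axis=0)
    blur = float(ndimage.laplace(mean_chan).var())
    saturation = float((image >= th.saturation_level).mean())
    mean = float(image.mean())
    sd = float(image.std())
    passed = (
        saturation < th.max_saturation
        and blur > th.min_blur
        and th.min_intensity < mean < th.max_intensity
    )
    return QcMetrics(blur, saturation, mean, sd, passed)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_nuclei(
    dna_channel: np.ndarray,
    min_area: int = 9,
    max_area: int = 2500,
    expected_radius: float = 4.0,
) -> np.ndarray:
    """Otsu threshold + distance-transform declumping of the DNA channel."""
    chan = np.asarray(dna_channel, dtype=float)
    if chan.max() <= chan.min():
        return np.zeros(chan.shape, dtype=np.int32)
    thresh = filters.threshold_otsu(chan)
    fg = chan > thresh
    if not fg.any():
        return np.zeros(chan.shape, dtype=np.int32)
    lbl, _ = ndimage.label(fg)
    sizes = np.bincount(lbl.ravel())
    fg = (lbl > 0) & (sizes[lbl] >= min_area)
    if not fg.any():
        return np.zeros(chan.shape, dtype=np.int32)

    # split touching nuclei: seeds at distance-transform maxima
    distance = ndimage.distance_transform_edt(fg)
    peaks = feature.peak_local_max(
        distance,
        min_distance=max(int(round(expected_radius)), 1),
        labels=fg,
        exclude_border=False,
    )
    markers = np.zeros(chan.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndimage.label(fg)
    labels = segmentation.watershed(-distance, markers, mask=fg)

    # area bounds
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for prop in measure.regionprops(labels):
        if min_area <= prop.area <= max_area:
            out[labels == prop.label] = next_id
            next_id += 1
    return out


def segment_cells(nuclei_mask: np.ndarray, cell_body_channel: np.ndarray) -> np.ndarray:
    """Expand cell regions around nuclei with a seeded watershed.

    The foreground is the Otsu threshold of the cell-body channel unioned
    with the nuclei (guaranteeing nucleus ⊆ cell); watershed on the inverted
    channel assigns every foreground pixel to the nearest nucleus basin, so
    cell labels coincide with nucleus labels.
    """
    nuclei_mask = np.asarray(nuclei_mask)
    if nuclei_mask.max() == 0:
        return np.zeros_like(nuclei_mask, dtype=np.int32)
    chan = np.asarray(cell_body_channel, dtype=float)
    if chan.max() > chan.min():
        fg = chan > filters.threshold_otsu(chan)
    else:
        fg = np.zeros(chan.shape, dtype=bool)
    fg |= nuclei_mask > 0
    cells = segmentation.watershed(-chan, markers=nuclei_mask, mask=fg)
    return cells.astype(np.int32)


# ---------------------------------------------------------------------------
# per-cell features
# ---------------------------------------------------------------------------


def feature_names() -> list[str]:
    names = []
    for region in REGIONS:
        for f in SHAPE_FEATURES:
            names.append(f"{region}_{f}")
        for ch in CHANNELS:
            for stat in INTENSITY_STATS:
                names.append(f"{region}_{ch}_{stat}")
    return names


def _region_shape(mask: np.ndarray) -> tuple[float, float, float]:
    if not mask.any():
        return 0.0, 0.0, 0.0
    props = measure.regionprops(mask.astype(np.uint8))[0]
    major = props.axis_major_length
    ratio = props.axis_minor_length / major if major > 0 else 0.0
    return float(props.area), float(props.perimeter), float(ratio)


def _region_intensity(chan: np.ndarray, highpass: np.ndarray, mask: np.ndarray):
    if not mask.any():
        return 0.0, 0.0, 0.0, 0.0, 0.0
    vals = chan[mask]
    return (
        float(vals.mean()),
        float(np.median(vals)),
        float(vals.sum()),
        float(vals.std()),
        float(highpass[mask].var()),
    )


def extract_cell_features(
    image: np.ndarray, nuclei_mask: np.ndarray, cell_mask: np.ndarray
) -> pd.DataFrame:
    """Per-cell shape and intensity features for Nucleus/Cytoplasm/Cell regions.

    Per region: area, perimeter, minor/major axis ratio, and per channel
    mean / median / integrated / sd intensity plus a local-variance texture
    score — 3 x (3 + 5 x 5) = 84 features with region-prefixed names.
    """
    image = np.asarray(image, dtype=float)
    labels = sorted(set(np.unique(cell_mask)) - {0})
    names = feature_names()
    if not labels:
        return pd.DataFrame(columns=names)
    # local-variance texture source: residual after local mean removal
    highpass = np.stack(
        [chan - ndimage.uniform_filter(chan, 3) for chan in image]
    )
    rows = []
    for lab in labels:
        cell = cell_mask == lab
        nucleus = (nuclei_mask == lab) & cell
        cytoplasm = cell & ~nucleus
        row = []
        for mask in (nucleus, cytoplasm, cell):
            row.extend(_region_shape(mask))
            for ch in range(len(CHANNELS)):
                row.extend(_region_intensity(image[ch], highpass[ch], mask))
        rows.append(row)
    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "Metadata_CellLabel", labels)
    return df


def profile_image(
    image: np.ndarray,
    illumination_radius: int = 15,
    qc_thresholds: QcThresholds | None = None,
    expected_radius: float = 4.0,
    cell_body_channel: int = 3,
) -> tuple[pd.DataFrame, QcMetrics]:
    """Full single-image pipeline: correct -> QC -> segment -> features.

    Returns the per-cell feature table (empty when QC fails) and the QC
    metrics. AGP (actin/Golgi/plasma-membrane) is the default cell-body
    channel for watershed expansion.
    """
    qc = compute_qc(image, qc_thresholds)
    if not qc.passed:
        return pd.DataFrame(columns=feature_names()), qc
    corrected = correct_illumination(image, illumination_radius)
    nuclei = segment_nuclei(corrected[0], expected_radius=expected_radius)
    cells = segment_cells(nuclei, corrected[cell_body_channel])
    return extract_cell_features(corrected, nuclei, cells), qc


# ---------------------------------------------------------------------------
# aggregation hierarchy
# ---------------------------------------------------------------------------

_LEVEL_KEYS = {
    "image": ["Metadata_Plate", "Metadata_Well", "Metadata_FoV"],
    "well": ["Metadata_Plate", "Metadata_Well"],
    "treatment": ["Metadata_Compound"],
}


def aggregate(profile_table: pd.DataFrame, level: str) -> pd.DataFrame:
    """Aggregate one level up the cells -> image -> well -> treatment hierarchy.

    ``level`` names the *output* level: ``image`` takes per-cell rows and the
    per-feature median; ``well`` averages FoV image profiles; ``treatment``
    averages all wells of a compound. Metadata constant within a group is
    carried along.
    """
    if level not in _LEVEL_KEYS:
        raise ValueError(f"unknown level {level!r}")
    if profile_table.empty:
        raise ValueError(f"cannot aggregate to {level}: empty input table")
    keys = [k for k in _LEVEL_KEYS[level] if k in profile_table.columns]
    if not keys:
        raise ValueError(
            f"cannot aggregate to {level}: missing key columns {_LEVEL_KEYS[level]}"
        )
    feats = feature_columns(profile_table)
    meta = [c for c in metadata_columns(profile_table) if c not in keys]
    agg_fn = "median" if level == "image" else "mean"
    grouped = profile_table.groupby(keys, sort=True)
    out = grouped[feats].agg(agg_fn)
    # carry metadata that is constant within each group
    for col in meta:
        vals = grouped[col].agg(lambda s: s.iloc[0] if s.nunique() == 1 else np.nan)
        if not vals.isna().all():
            out[col] = vals
    out = out.reset_index()
    return out[[c for c in out.columns if c.startswith(("Metadata_", "GT_"))]
               + [c for c in out.columns if not c.startswith(("Metadata_", "GT_"))]]
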