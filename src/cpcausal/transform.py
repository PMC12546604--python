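"""Profile-table transformers: control normalization, feature selection,
baseline batch correction.

These follow the scikit-learn estimator protocol (fit / transform,
``get_params`` / ``set_params``, fitted attributes with a trailing
underscore) but operate on profile DataFrames whose ``Metadata_*`` columns
carry provenance; feature columns are everything else.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import feature_columns
from .scm import CONTROL_COMPOUND

MAD_SCALE = 1.4826  # consistency constant: MAD -> sd under normality


class ProfileNormalizer(BaseEstimator, TransformerMixin):
    """Robust z-score against same-plate negative controls.

    Each feature becomes ``(x - median_ctrl) / (MAD_SCALE * MAD_ctrl)``
    computed from the DMSO wells of the same plate (global fallback when no
    plate column is present). Features whose control MAD is zero are set to
    0 and recorded in ``degenerate_features_``.
    """

    def __init__(self, control_compound: str = CONTROL_COMPOUND, per_plate: bool = True):
        self.control_compound = control_compound
        self.per_plate = per_plate

    def fit(self, X: pd.DataFrame, y=None):
        feats = feature_columns(X)
        if not feats:
            raise ValueError("no feature columns to normalize")
        if "Metadata_Compound" not in X.columns:
            raise ValueError("normalization requires a Metadata_Compound column")
        ctrl = X[X["Metadata_Compound"] == self.control_compound]
        if len(ctrl) < 2:
            raise ValueError(
                f"need >= 2 control ({self.control_compound}) profiles, got {len(ctrl)}"
            )
        self.feature_names_ = feats
        self.stats_ = {}
        group_col = "Metadata_Plate" if self.per_plate and "Metadata_Plate" in X.columns else None
        self.group_col_ = group_col
        groups = [None] if group_col is None else list(X[group_col].unique())
        global_med = ctrl[feats].median()
        global_mad = (ctrl[feats] - global_med).abs().median()
        for g in groups:
            sub = ctrl if g is None else ctrl[ctrl[group_col] == g]
            if len(sub) >= 2:
                med = sub[feats].median()
                mad = (sub[feats] - med).abs().median()
            else:  # batch fallback: too few plate controls
                med, mad = global_med, global_mad
            self.stats_[g] = (med.to_numpy(), MAD_SCALE * mad.to_numpy())
        self.degenerate_features_ = [
            f for f in feats
            if any(scale[feats.index(f)] == 0 for _, scale in self.stats_.values())
        ]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        feats = self.feature_names_
        out = X.copy()
        groups = (
            [(None, np.ones(len(X), dtype=bool))]
            if self.group_col_ is None
            else [(g, (X[self.group_col_] == g).to_numpy()) for g in X[self.group_col_].unique()]
        )
        vals = out[feats].to_numpy(dtype=float)
        for g, mask in groups:
            med, scale = self.stats_.get(g, next(iter(self.stats_.values())))
            safe = np.where(scale == 0, 1.0, scale)
            z = (vals[mask] - med) / safe
            z[:, scale == 0] = 0.0
            vals[mask] = z
        out[feats] = vals
        if self.degenerate_features_:
            warnings.warn(
                f"{len(self.degenerate_features_)} features had zero control MAD "
                "and were set to 0"
            )
        return out


class FeatureSelector(BaseEstimator, TransformerMixin):
    """Drop non-finite, near-constant, and highly correlated features.

    A feature is removed when any value is non-finite, its variance is
    below ``variance_floor``, or its absolute Pearson correlation with an
    earlier-named retained feature exceeds ``correlation_ceiling`` (the
    first of each correlated pair, in deterministic name order, survives).
    """

    def __init__(self, variance_floor: float = 1e-6, correlation_ceiling: float = 0.95):
        self.variance_floor = variance_floor
        self.correlation_ceiling = correlation_ceiling

    def fit(self, X: pd.DataFrame, y=None):
        feats = sorted(feature_columns(X))
        vals = X[feats].to_numpy(dtype=float)
        keep = [
            f for j, f in enumerate(feats)
            if np.all(np.isfinite(vals[:, j])) and vals[:, j].var() >= self.variance_floor
        ]
        retained: list[str] = []
        if keep:
            mat = X[keep].to_numpy(dtype=float)
            corr = np.corrcoef(mat, rowvar=False)
            corr = np.atleast_2d(corr)
            for j, f in enumerate(keep):
                if all(abs(corr[j, keep.index(r)]) <= self.correlation_ceiling
                       for r in retained):
                    retained.append(f)
        if not retained:
            raise ValueError("feature selection dropped every feature")
        self.selected_features_ = retained
        self.dropped_features_ = [f for f in feats if f not in retained]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        meta = [c for c in X.columns if c.startswith(("Metadata_", "GT_"))]
        return X[meta + self.selected_features_].copy()


class BatchScaler(BaseEstimator, TransformerMixin):
    """Per-batch per-feature centering and unit scaling.

    A deliberately simple location/scale baseline for batch-effect removal
    in profile space; single-profile batches are centered only (their scale
    is undefined) with a warning.
    """

    def __init__(self, batch_column: str = "Metadata_Batch"):
        self.batch_column = batch_column

    def fit(self, X: pd.DataFrame, y=None):
        if self.batch_column not in X.columns:
            raise ValueError(f"missing batch column {self.batch_column}")
        feats = feature_columns(X)
        self.feature_names_ = feats
        self.stats_ = {}
        for g, sub in X.groupby(self.batch_column):
            vals = sub[feats].to_numpy(dtype=float)
            mean = vals.mean(axis=0)
            if len(sub) < 2:
                warnings.warn(f"batch {g!r} has a single profile; centering only")
                sd = np.ones_like(mean)
            else:
                sd = vals.std(axis=0)
                sd = np.where(sd == 0, 1.0, sd)
            self.stats_[g] = (mean, sd)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        vals = out[self.feature_names_].to_numpy(dtype=float)
        for g, (mean, sd) in self.stats_.items():
            mask = (X[self.batch_column] == g).to_numpy()
            vals[mask] = (vals[mask] - mean) / sd
        out[self.feature_names_] = vals
        return out


# thin functional wrappers ---------------------------------------------------


def normalize_profiles(
    profiles: pd.DataFrame,
    control_compound: str = CONTROL_COMPOUND,
    per_plate: bool = True,
) -> pd.DataFrame:
    return ProfileNormalizer(control_compound, per_plate).fit_transform(profiles)


def select_features(
    profiles: pd.DataFrame,
    variance_floor: float = 1e-6,
    correlation_ceiling: float = 0.95,
) -> pd.DataFrame:
    return FeatureSelector(variance_floor, correlation_ceiling).fit_transform(profiles)


def baseline_batch_correct(
    profiles: pd.DataFrame, batch_column: str = "Metadata_Batch"
) -> pd.DataFrame:
    return BatchScaler(batch_column).fit_transform(profiles)
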