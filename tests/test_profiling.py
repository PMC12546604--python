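"""Profiling pipeline: illumination, QC, segmentation, features, aggregation."""

import numpy as np
import pandas as pd
import pytest

import cpcausal as cp
from cpcausal import profiling
from cpcausal.profiling import (
    aggregate,
    compute_qc,
    correct_illumination,
    extract_cell_features,
    feature_names,
    segment_cells,
    segment_nuclei,
)


class TestIlluminationCorrection:
    def test_uniform_channel_unchanged(self):
        img = np.full((5, 64, 64), 0.4)
        out = correct_illumination(img, 7)
        np.testing.assert_allclose(out, img, atol=1e-6)

    def test_linear_gradient_flattened(self):
        xx = np.linspace(0.5, 1.5, 64)
        img = np.tile(0.4 * xx, (5, 64, 1))
        out = correct_illumination(img, 15)

        def cv(chan):
            col = chan.mean(axis=0)
            return col.std() / col.mean()

        assert cv(out[0]) < 0.3 * cv(img[0])

    def test_zero_channel_returned_unchanged_with_warning(self):
        img = np.zeros((5, 32, 32))
        img[1] = 0.5
        with pytest.warns(UserWarning, match="zero"):
            out = correct_illumination(img, 5)
        assert np.array_equal(out[0], img[0])

    def test_radius_larger_than_image_errors(self):
        with pytest.raises(ValueError, match="larger"):
            correct_illumination(np.zeros((5, 16, 16)), 20)


class TestQc:
    def test_all_saturated_image_fails(self):
        qc = compute_qc(np.ones((5, 32, 32)))
        assert qc.saturation_fraction == 1.0
        assert not qc.passed

    def test_renderer_output_passes(self, render_params):
        rng = np.random.default_rng(0)
        n_pass = 0
        for i in range(100):
            img = cp.render_image(rng.standard_normal(7) * 0.5, render_params=render_params, rng=i)
            n_pass += compute_qc(img).passed
        assert n_pass >= 99

    def test_blur_lowers_blur_score(self, example_image):
        from scipy import ndimage

        sharp = compute_qc(example_image)
        blurred = compute_qc(
            np.stack([ndimage.gaussian_filter(c, 3) for c in example_image])
        )
        assert sharp.passed
        assert blurred.blur_score < sharp.blur_score


def draw_disk(shape, cy, cx, r, value=1.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return value * ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2)


class TestSegmentation:
    def test_blank_channel_zero_objects(self):
        assert segment_nuclei(np.zeros((64, 64))).max() == 0

    def test_known_count_of_separated_blobs(self):
        chan = np.zeros((96, 96))
        centers = [(16, 16), (16, 70), (48, 40), (80, 16), (80, 70)]
        for cy, cx in centers:
            chan += draw_disk(chan.shape, cy, cx, 5, 0.8)
        labels = segment_nuclei(chan, expected_radius=5)
        assert labels.max() == len(centers)

    def test_two_overlapping_blobs_declumped(self):
        chan = np.zeros((64, 64))
        chan += draw_disk(chan.shape, 30, 26, 6, 0.8)
        chan += draw_disk(chan.shape, 30, 38, 6, 0.8)
        labels = segment_nuclei(np.clip(chan, 0, 1), expected_radius=5)
        assert labels.max() == 2

    def test_cell_count_equals_nucleus_count_and_containment(self, small_dataset):
        records, _ = small_dataset
        checked = 0
        for rec in records[:50]:
            corrected = correct_illumination(rec.image, 7)
            nuclei = segment_nuclei(corrected[0])
            cells = segment_cells(nuclei, corrected[3])
            assert set(np.unique(cells)) == set(np.unique(nuclei))
            for lab in np.unique(nuclei):
                if lab == 0:
                    continue
                assert np.all(cells[nuclei == lab] == lab)  # nucleus inside its cell
            checked += 1
        assert checked == 50

    def test_empty_nuclei_give_empty_cells(self):
        assert segment_cells(np.zeros((32, 32), dtype=np.int32), np.ones((32, 32))).max() == 0


class TestFeatures:
    def test_circle_area_close_to_analytic(self):
        r = 8
        mask = draw_disk((64, 64), 32, 32, r).astype(np.int32)
        img = np.tile(0.5 * mask, (5, 1, 1)).astype(float)
        df = extract_cell_features(img, mask, mask)
        assert len(df) == 1
        assert abs(df["Cell_area"].iloc[0] - np.pi * r**2) / (np.pi * r**2) < 0.1

    def test_uniform_intensity_cell(self):
        mask = draw_disk((32, 32), 16, 16, 6).astype(np.int32)
        img = np.tile(0.3 * mask, (5, 1, 1)).astype(float)
        df = extract_cell_features(img, mask, mask)
        assert df["Cell_DNA_sd"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert df["Cell_DNA_mean"].iloc[0] == pytest.approx(
            df["Cell_DNA_median"].iloc[0], abs=1e-12
        )

    def test_schema_stable_across_images(self, small_dataset):
        records, _ = small_dataset
        names = None
        for rec in records[:10]:
            df, qc = cp.profile_image(rec.image, illumination_radius=7)
            cols = [c for c in df.columns if not c.startswith("Metadata_")]
            if names is None:
                names = cols
            assert cols == names
        assert len(names) == 84
        assert names == feature_names()

    def test_zero_cells_empty_table(self):
        df = extract_cell_features(
            np.zeros((5, 32, 32)), np.zeros((32, 32), np.int32), np.zeros((32, 32), np.int32)
        )
        assert df.empty


class TestAggregate:
    @staticmethod
    def cells_table():
        rng = np.random.default_rng(0)
        rows = []
        for plate in ("P1", "P2"):
            for well in ("A01", "A02"):
                for fov in (0, 1):
                    for _cell in range(5):
                        rows.append(
                            {
                                "Metadata_Plate": plate,
                                "Metadata_Well": well,
                                "Metadata_FoV": fov,
                                "Metadata_Compound": "CPD" if well == "A01" else "DMSO",
                                "f1": rng.normal(),
                                "f2": rng.normal(),
                            }
                        )
        return pd.DataFrame(rows)

    def test_image_level_is_median_over_cells(self):
        cells = self.cells_table()
        img = aggregate(cells, "image")
        group = cells[
            (cells.Metadata_Plate == "P1")
            & (cells.Metadata_Well == "A01")
            & (cells.Metadata_FoV == 0)
        ]
        row = img[
            (img.Metadata_Plate == "P1")
            & (img.Metadata_Well == "A01")
            & (img.Metadata_FoV == 0)
        ]
        assert row["f1"].iloc[0] == group["f1"].median()

    def test_median_is_outlier_robust(self):
        cells = pd.DataFrame(
            {
                "Metadata_Plate": ["P"] * 3,
                "Metadata_Well": ["A01"] * 3,
                "Metadata_FoV": [0] * 3,
                "f1": [1.0, 2.0, 100.0],
            }
        )
        assert aggregate(cells, "image")["f1"].iloc[0] == 2.0

    def test_treatment_equals_brute_force_mean_of_wells(self):
        cells = self.cells_table()
        wells = aggregate(aggregate(cells, "image"), "well")
        treatment = aggregate(wells, "treatment")
        brute = wells.groupby("Metadata_Compound")["f1"].mean()
        for _, row in treatment.iterrows():
            assert np.isclose(row["f1"], brute[row["Metadata_Compound"]])

    def test_permutation_invariance(self):
        cells = self.cells_table()
        shuffled = cells.sample(frac=1.0, random_state=1)
        a = aggregate(cells, "image").reset_index(drop=True)
        b = aggregate(shuffled, "image").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_image_values_bounded_by_cell_extremes(self):
        cells = self.cells_table()
        img = aggregate(cells, "image")
        assert img["f1"].max() <= cells["f1"].max()
        assert img["f1"].min() >= cells["f1"].min()

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate(pd.DataFrame(), "image")


def test_pipeline_is_deterministic(small_dataset):
    records, _ = small_dataset
    a, _ = cp.profile_image(records[0].image, illumination_radius=7)
    b, _ = cp.profile_image(records[0].image, illumination_radius=7)
    pd.testing.assert_frame_equal(a, b)


def test_different_moa_compounds_more_distant_than_replicates():
    """With the T->P edge only, treatment profiles separate by MoA."""
    lib = cp.make_compound_library(20, 4, 8, seed=3)
    design = cp.make_design(1, 1, 1, 6, 8, 2, lib, allocation_bias=0.0, seed=3)
    params = cp.ScmParams.random(
        7,
        64,
        cp.confounder_code_dim(design),
        seed=3,
        confounder_phenotype_scale=0.0,
        confounder_observation_scale=0.0,
        phenotype_noise_sd=0.15,
    )
    _, table = cp.generate_dataset(design, params, lib, rng=3)
    gt = [c for c in table.columns if c.startswith("GT_P_")]
    wells = table.groupby(["Metadata_Compound", "Metadata_Well"])[gt].mean()
    treatment = wells.groupby(level=0).mean()
    moa = {c.compound_id: c.moa_label for c in lib}
    within, between, replicate_dist = [], [], []
    ids = [i for i in treatment.index if i != "DMSO"]
    for i, a in enumerate(ids):
        reps = wells.loc[a]
        if len(reps) >= 2:
            replicate_dist.append(
                np.linalg.norm(reps.iloc[0] - reps.iloc[1])
            )
        for b in ids[i + 1 :]:
            d = np.linalg.norm(treatment.loc[a] - treatment.loc[b])
            (within if moa[a] == moa[b] else between).append(d)
    assert np.mean(between) > np.mean(replicate_dist)
    assert np.mean(between) > np.mean(within)
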