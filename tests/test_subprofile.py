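"""Reference subprofiles, Biosimilarity, folds, and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cpcausal as cp
from cpcausal.subprofile import (
    FoldSplit,
    SubprofileClassifier,
    biosimilarity,
    build_subprofile,
    classify_dataset,
    make_folds,
    score_compound,
)


class TestBiosimilarity:
    def test_identical_profiles_score_one(self):
        u = np.array([1.0, 2.0, 5.0, -1.0])
        assert biosimilarity(u, u) == pytest.approx(1.0)

    def test_negated_centered_profile_scores_minus_one(self):
        u = np.array([1.0, 2.0, 5.0, -1.0])
        v = -(u - u.mean())
        assert biosimilarity(u, v) == pytest.approx(-1.0)

    def test_matches_pearson_correlation_to_1e12(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            u = rng.standard_normal(20)
            v = rng.standard_normal(20)
            # independent textbook formula for Pearson's r
            r = stats.pearsonr(u, v).statistic
            assert abs(biosimilarity(u, v) - r) < 1e-12

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            biosimilarity(np.ones(5), np.arange(5.0))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=12),
        st.floats(0.1, 10),
        st.floats(-50, 50),
    )
    def test_symmetry_and_positive_affine_invariance(self, vals, a, b):
        u = np.array(vals)
        v = np.sin(u) + np.linspace(0, 1, len(u))  # deterministic partner
        if np.allclose(u, u.mean()) or np.allclose(v, v.mean()):
            return
        s = biosimilarity(u, v)
        assert biosimilarity(v, u) == pytest.approx(s, abs=1e-9)
        assert biosimilarity(a * u + b, v) == pytest.approx(s, abs=1e-9)


def profiles_with_sign_pattern(n_profiles, n_pos, feature="f0", seed=0):
    """n_profiles profiles where `feature` is positive in exactly n_pos of
    them and negative elsewhere; a second feature is always positive."""
    rng = np.random.default_rng(seed)
    vals = np.where(np.arange(n_profiles) < n_pos, 1.0, -1.0) * rng.uniform(
        0.5, 2.0, n_profiles
    )
    return pd.DataFrame(
        {feature: vals, "f_keep": rng.uniform(0.5, 1.5, n_profiles)}
    )


class TestSubprofileRetention:
    def test_90_percent_consistency_retained(self):
        sp = build_subprofile(profiles_with_sign_pattern(10, 9), threshold=0.85)
        assert "f0" in sp.feature_subset

    def test_80_percent_consistency_dropped(self):
        sp = build_subprofile(profiles_with_sign_pattern(10, 8), threshold=0.85)
        assert "f0" not in sp.feature_subset

    def test_exactly_85_percent_dropped_by_strict_inequality(self):
        sp = build_subprofile(profiles_with_sign_pattern(20, 17), threshold=0.85)
        assert "f0" not in sp.feature_subset

    def test_zeros_count_toward_neither_sign(self):
        df = profiles_with_sign_pattern(10, 9)
        df.loc[0, "f0"] = 0.0  # 8/10 positive now
        sp = build_subprofile(df, threshold=0.85)
        assert "f0" not in sp.feature_subset

    def test_values_are_medians(self):
        df = profiles_with_sign_pattern(10, 10)
        sp = build_subprofile(df, threshold=0.85)
        idx = sp.feature_subset.index("f0")
        assert sp.median_values[idx] == df["f0"].median()

    def test_raising_threshold_never_adds_features(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((12, 30)), columns=[f"f{i}" for i in range(30)])
        df += 0.8  # bias toward positive so some features pass
        sets = []
        for th in (0.0, 0.5, 0.8, 0.9):
            sp = build_subprofile(df, threshold=th)
            sets.append(set(sp.feature_subset))
        for lo, hi in zip(sets, sets[1:]):
            assert hi <= lo

    def test_empty_subset_errors(self):
        df = profiles_with_sign_pattern(10, 5)
        df["f_keep"] = np.where(np.arange(10) < 5, 1.0, -1.0)
        with pytest.raises(ValueError, match="threshold"):
            build_subprofile(df, threshold=0.85)


class TestScoring:
    def test_query_equal_to_median_scores_one(self):
        df = profiles_with_sign_pattern(10, 10)
        sp = build_subprofile(df, threshold=0.85, class_label="A")
        query = pd.Series(sp.median_values, index=sp.feature_subset)
        assert score_compound(query, [sp])["A"] == pytest.approx(1.0)

    def test_scores_within_unit_interval(self):
        rng = np.random.default_rng(5)
        refs = pd.DataFrame(
            rng.standard_normal((8, 20)) + 0.5, columns=[f"f{i}" for i in range(20)]
        )
        clf = SubprofileClassifier(threshold=0.6).fit(refs, ["A"] * 4 + ["B"] * 4)
        queries = pd.DataFrame(
            rng.standard_normal((10, 20)), columns=[f"f{i}" for i in range(20)]
        )
        s = clf.decision_function(queries).to_numpy()
        assert np.nanmax(s) <= 1.0 and np.nanmin(s) >= -1.0

    def test_threshold_zero_reduces_to_pearson_against_class_median(self):
        rng = np.random.default_rng(6)
        refs = pd.DataFrame(
            rng.standard_normal((5, 15)) + 1.0, columns=[f"f{i}" for i in range(15)]
        )
        # all features same-sign-consistent enough for threshold 0 retention
        refs = refs.abs()
        sp = build_subprofile(refs, threshold=0.0, class_label="A")
        assert len(sp.feature_subset) == 15
        q = rng.standard_normal(15)
        expected = stats.pearsonr(q, refs.median().to_numpy()).statistic
        got = score_compound(pd.Series(q, index=refs.columns), [sp])["A"]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_noise_free_phenotypes_recover_generating_moa(self):
        lib = cp.make_compound_library(40, 4, 8, seed=9)
        params = cp.ScmParams.random(7, 64, 10, seed=9)
        rows, labels = [], {}
        for c in lib:
            if c.is_control:
                continue
            p = params.compound_effect @ cp.embed_compound(c.smiles, 64)
            rows.append({"Metadata_Compound": c.compound_id, **{f"P{i}": v for i, v in enumerate(p)}})
            labels[c.compound_id] = c.moa_label
        prof = pd.DataFrame(rows).set_index("Metadata_Compound")
        # the classifier contract assumes control-centered (normalized) profiles
        prof = (prof - prof.mean()) / prof.std()
        by_class = pd.Series(labels)
        clf = SubprofileClassifier(threshold=0.5).fit(prof, by_class[prof.index].to_list())
        pred = clf.predict(prof)
        acc = (pred == by_class[prof.index].to_numpy()).mean()
        assert acc > 0.8


class TestFolds:
    def test_class_of_ten_gives_five_references_five_queries(self):
        lib = cp.make_compound_library(20, 2, 4, seed=1)
        folds = make_folds(lib, "moa", n_ref_per_class=5, n_folds=3, min_class_size=10, rng=1)
        for f in folds:
            for cls, refs in f.reference_ids.items():
                assert len(refs) == 5
            assert len(f.query_seen_ids) == 20 - 2 * 5

    def test_reference_sets_vary_across_folds(self):
        lib = cp.make_compound_library(30, 2, 4, seed=2)
        folds = make_folds(lib, "moa", 5, 10, min_class_size=10, rng=2)
        ref_sets = [tuple(sorted(f.reference_ids["MoA_01"])) for f in folds]
        assert len(set(ref_sets)) > 1

    def test_unseen_ids_only_in_unseen_queries(self):
        lib = cp.make_compound_library(24, 2, 4, seed=3)
        unseen = {c.compound_id for c in lib[:4]}
        folds = make_folds(lib, "moa", 4, 3, unseen_ids=unseen, min_class_size=8, rng=3)
        for f in folds:
            for refs in f.reference_ids.values():
                assert not (set(refs) & unseen)
            assert set(f.query_unseen_ids) <= unseen

    def test_small_class_dropped_with_warning(self):
        lib = cp.make_compound_library(10, 3, 4, seed=4)  # classes of size 3-4
        with pytest.warns(UserWarning, match="dropped"):
            make_folds(lib, "moa", 2, 2, min_class_size=4, rng=4)

    def test_leakage_impossible_by_construction(self):
        with pytest.raises(ValueError, match="both"):
            FoldSplit(0, "moa", {"A": ["c1", "c2"]}, ["c1"], [])

    def test_target_task_allows_multi_class_references(self):
        lib = cp.make_compound_library(40, 2, 4, seed=5)
        folds = make_folds(lib, "target", 3, 2, min_class_size=8, rng=5)
        for f in folds:
            assert len(f.reference_ids) >= 1


class TestClassifyDataset:
    @staticmethod
    def small_setup(seed=0):
        lib = cp.make_compound_library(20, 2, 4, seed=seed)
        rng = np.random.default_rng(seed)
        rows = []
        for c in lib:
            if c.is_control:
                continue
            center = 1.5 if c.moa_label == "MoA_01" else -1.5
            rows.append(
                {
                    "Metadata_Compound": c.compound_id,
                    **{f"f{i}": center + rng.normal(0, 0.5) for i in range(12)},
                }
            )
        profiles = pd.DataFrame(rows)
        folds = make_folds(lib, "moa", 5, 2, min_class_size=10, rng=seed)
        return lib, profiles, folds

    def test_moa_relevance_rows_sum_to_one(self):
        lib, profiles, folds = self.small_setup()
        results = classify_dataset(profiles, lib, folds, threshold=0.6)
        for res in results:
            assert (res.relevance.sum(axis=1) == 1).all()

    def test_matrix_shapes_consistent_with_folds(self):
        lib, profiles, folds = self.small_setup()
        results = classify_dataset(profiles, lib, folds, threshold=0.6)
        by_fold = {(r.fold_id, r.split): r for r in results}
        for f in folds:
            r = by_fold[(f.fold_id, "seen")]
            assert r.scores.shape == (len(f.query_seen_ids), len(f.reference_ids))
            assert list(r.scores.columns) == sorted(f.reference_ids)
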