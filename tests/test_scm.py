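"""Simulator: design allocation, mechanisms, and the interventional oracle."""

import numpy as np
import pytest
from scipy import stats

import cpcausal as cp
from cpcausal.embeddings import embed_compound
from cpcausal.scm import (
    CONTROL_COMPOUND,
    confounder_code,
    enumerate_confounder_codes,
)


def count_by_batch(design, compound_id):
    counts = {}
    for assignment, cid in design.iter_assignments():
        if cid == compound_id:
            counts[assignment.batch_id] = counts.get(assignment.batch_id, 0) + 1
    return counts


class TestMakeDesign:
    def test_zero_bias_allocation_is_uniform(self):
        lib = cp.make_compound_library(2, 1, 2, seed=0)
        design = cp.make_design(
            1, 1, 2, 8, 12, 1, lib, allocation_bias=0.0, seed=0
        )
        counts = [
            sum(count_by_batch(design, c.compound_id).values())
            for c in lib
            if not c.is_control
        ]
        # two compounds over ~176 treatment wells: binomial balance
        total = sum(counts)
        assert stats.binomtest(counts[0], total, 0.5).pvalue > 1e-4

    def test_bias_makes_compound_batch_contingency_nonuniform(self):
        lib = cp.make_compound_library(6, 2, 4, seed=1)
        design = cp.make_design(
            2, 2, 4, 16, 16, 1, lib, allocation_bias=5.0, seed=1
        )
        treatments = [c.compound_id for c in lib if not c.is_control]
        batches = [b for _, b in design.batches]
        table = np.zeros((len(treatments), len(batches)))
        for assignment, cid in design.iter_assignments():
            if cid in treatments:
                table[treatments.index(cid), batches.index(assignment.batch_id)] += 1
        chi2 = stats.chi2_contingency(table + 1e-9)
        assert chi2.pvalue < 1e-6

    def test_fixed_seed_is_byte_identical(self, library):
        d1 = cp.make_design(2, 2, 1, 4, 6, 1, library, 2.0, seed=11)
        d2 = cp.make_design(2, 2, 1, 4, 6, 1, library, 2.0, seed=11)
        assert d1.allocation == d2.allocation
        assert d1.plates == d2.plates

    def test_every_plate_has_a_control_and_every_compound_a_well(self, design, library):
        for plate in design.plates:
            labels = {design.allocation[(plate, w)] for w in design.wells[plate]}
            assert CONTROL_COMPOUND in labels
        allocated = set(design.allocation.values())
        for rec in library:
            if not rec.is_control:
                assert rec.compound_id in allocated

    def test_too_many_compounds_without_replication_errors(self):
        lib = cp.make_compound_library(30, 3, 6, seed=0)
        with pytest.raises(ValueError, match="exceed"):
            cp.make_design(1, 1, 1, 4, 6, 1, lib, 0.0, seed=0, replicate=False)


class TestSamplePhenotype:
    def test_deterministic_limit(self, params):
        e = np.ones(params.embedding_dim) / np.sqrt(params.embedding_dim)
        c = np.zeros(params.confounder_code_dim)
        c[0] = 1.0
        tiny = cp.ScmParams(
            params.compound_effect,
            params.confounder_effect_phenotype,
            params.confounder_effect_observation,
            phenotype_noise_sd=1e-12,
        )
        p = cp.sample_phenotype(e, c, tiny, rng=0)
        expected = params.compound_effect @ e + params.confounder_effect_phenotype @ c
        np.testing.assert_allclose(p, expected, atol=1e-9)

    def test_monte_carlo_mean_matches_closed_form(self, params):
        rng = np.random.default_rng(3)
        e = np.ones(params.embedding_dim) / np.sqrt(params.embedding_dim)
        c = np.zeros(params.confounder_code_dim)
        draws = np.stack(
            [cp.sample_phenotype(e, c, params, rng) for _ in range(10_000)]
        )
        expected = params.compound_effect @ e
        tol = 4 * params.phenotype_noise_sd / np.sqrt(10_000)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < tol)

    def test_dimension_mismatch_errors(self, params):
        with pytest.raises(ValueError, match="dim"):
            cp.sample_phenotype(np.ones(3), np.zeros(params.confounder_code_dim), params, 0)


class TestInterventionalMean:
    def test_zero_confounder_effect_reduces_to_compound_effect(self, params):
        zero = cp.ScmParams(
            params.compound_effect,
            np.zeros_like(params.confounder_effect_phenotype),
            params.confounder_effect_observation,
        )
        e = embed_compound("C1CCCCC1", params.embedding_dim)
        np.testing.assert_allclose(
            cp.interventional_mean(zero, e, np.zeros(params.confounder_code_dim)),
            params.compound_effect @ e,
        )

    def test_symmetric_two_point_distribution_cancels(self, params):
        e = embed_compound("c1ccccc1N(C)C", params.embedding_dim)
        c = np.random.default_rng(0).standard_normal(params.confounder_code_dim)
        out = cp.interventional_mean(params, e, np.stack([c, -c]))
        np.testing.assert_allclose(out, params.compound_effect @ e, atol=1e-12)

    def test_matches_exhaustive_enumeration_in_noise_free_limit(self, design, params):
        """Brute-force average of sample_phenotype over all codes, noise -> 0."""
        codes = enumerate_confounder_codes(design)
        e = embed_compound("OCCN1CCOCC1", params.embedding_dim)
        tiny = cp.ScmParams(
            params.compound_effect,
            params.confounder_effect_phenotype,
            params.confounder_effect_observation,
            phenotype_noise_sd=1e-15,
        )
        brute = np.mean(
            [cp.sample_phenotype(e, c, tiny, rng=i) for i, c in enumerate(codes)],
            axis=0,
        )
        closed = cp.interventional_mean(params, e, codes)
        np.testing.assert_allclose(brute, closed, atol=1e-9)


class TestCompoundLibrary:
    def test_single_class_library(self):
        lib = cp.make_compound_library(5, 1, 3, seed=0)
        moas = {c.moa_label for c in lib if not c.is_control}
        assert moas == {"MoA_01"}

    def test_within_class_embeddings_more_similar_than_between(self):
        lib = [
            c
            for c in cp.make_compound_library(100, 5, 10, seed=4)
            if not c.is_control
        ]
        E = np.stack([embed_compound(c.smiles, 64) for c in lib])
        moa = np.array([c.moa_label for c in lib])
        cos = E @ E.T
        same = moa[:, None] == moa[None, :]
        off = ~np.eye(len(lib), dtype=bool)
        assert cos[same & off].mean() > cos[~same].mean() + 0.1

    def test_fixed_seed_identical_library(self):
        a = cp.make_compound_library(10, 2, 4, seed=9)
        b = cp.make_compound_library(10, 2, 4, seed=9)
        assert a == b

    def test_control_record_and_target_counts(self, library):
        controls = [c for c in library if c.is_control]
        assert len(controls) == 1 and controls[0].smiles == CONTROL_COMPOUND
        for c in library:
            if not c.is_control:
                assert 1 <= len(c.target_labels) <= 3
                assert c.moa_label is not None


def test_confounding_is_real_on_two_compound_design():
    """With biased allocation and nonzero C->P, naive per-compound means of
    hidden P deviate from the interventional mean by exactly the amount the
    realized allocation frequencies predict."""
    lib = cp.make_compound_library(2, 1, 2, seed=5)
    design = cp.make_design(1, 2, 1, 8, 12, 1, lib, allocation_bias=5.0, seed=5)
    params = cp.ScmParams.random(
        7,
        64,
        cp.confounder_code_dim(design),
        seed=5,
        confounder_phenotype_scale=1.5,
        phenotype_noise_sd=0.05,
    )
    embeddings = {c.compound_id: embed_compound(c.smiles, 64) for c in lib}
    rng = np.random.default_rng(5)
    draws = {}
    codes = {}
    for assignment, cid in design.iter_assignments():
        if cid == CONTROL_COMPOUND:
            continue
        code = confounder_code(assignment, design)
        p = cp.sample_phenotype(embeddings[cid], code, params, rng)
        draws.setdefault(cid, []).append(p)
        codes.setdefault(cid, []).append(code)
    pool_mean_code = enumerate_confounder_codes(design).mean(axis=0)
    biased_compound = max(draws, key=lambda k: len(draws[k]))
    naive = np.mean(draws[biased_compound], axis=0)
    # predicted naive mean from realized allocation frequencies
    predicted = cp.interventional_mean(
        params, embeddings[biased_compound], np.stack(codes[biased_compound])
    )
    oracle = cp.interventional_mean(params, embeddings[biased_compound], pool_mean_code)
    mc_tol = 4 * params.phenotype_noise_sd / np.sqrt(len(draws[biased_compound]))
    assert np.abs(naive - predicted).max() < mc_tol + 1e-6
    # and the bias is material: naive sits away from the interventional mean
    assert np.abs(predicted - oracle).max() > 10 * mc_tol


def test_generate_dataset_counts_and_ground_truth(small_dataset, design):
    records, table = small_dataset
    assert len(records) == design.n_observations() == len(table)
    assert {r.image.shape for r in records} == {(5, 64, 64)}
    gt_cols = [c for c in table.columns if c.startswith("GT_P_")]
    assert len(gt_cols) == 7
    # every record's hidden phenotype matches its table row
    np.testing.assert_allclose(
        records[0].phenotype, table.iloc[0][gt_cols].to_numpy(dtype=float)
    )
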