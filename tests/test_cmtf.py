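"""Factorization engine: CP-ALS, coupled sparse fits, alignment, variation."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import assert_monotone_trace, truth_model
from sparsecmtf import generate_cohort, prepare
from sparsecmtf.cmtf import (
    CMTFModel,
    align_components,
    cmtf_fit,
    component_patterns,
    cp_als,
    explained_variation,
    select_lambda,
)
from sparsecmtf.cmtf import DimensionError
from sparsecmtf.validation import match_components


class TestCpAls:
    def test_rank1_noiseless_exact(self):
        rng = np.random.default_rng(0)
        a, b, c = rng.standard_normal(12), rng.standard_normal(7), rng.standard_normal(4)
        X = np.einsum("i,j,k->ijk", a, b, c)
        m = cp_als(X, rank=1, n_starts=3, seed=1)
        assert explained_variation(m, X) == pytest.approx(100.0, abs=1e-6)
        est = m.B[:, 0]
        cong = abs(est @ b / (np.linalg.norm(est) * np.linalg.norm(b)))
        assert cong >= 0.999
        assert_monotone_trace(m)

    def test_rank2_noiseless_masked_recovery(self):
        ds, truth = generate_cohort(
            subjects=20, biomarkers=10, timepoints=4, baseline_vars=5, snps=8,
            noise_sd=(0, 0, 0), missing_rate=0.1, seed=7, discretize_genes=False,
        )
        m = cp_als(ds.tensor, ds.tensor_mask, rank=2, n_starts=5, seed=3)
        assert explained_variation(m, (ds.tensor, ds.tensor_mask)) == pytest.approx(
            100.0, abs=1e-6
        )
        tm = CMTFModel(A=truth.subject_scores, B=truth.biomarker_loadings,
                       C=truth.time_loadings)
        mm = match_components(align_components(m), tm)
        assert mm.overall.min() >= 0.999
        assert_monotone_trace(m)

    def test_reference_oracle_equivalence_including_noise(self):
        from _reference import cp_fit_reference

        rng = np.random.default_rng(42)
        for trial in range(5):
            A = rng.standard_normal((15, 2))
            B = rng.standard_normal((8, 2))
            C = rng.standard_normal((4, 2))
            X = np.einsum("ir,jr,kr->ijk", A, B, C)
            if trial >= 2:
                X = X + 0.3 * rng.standard_normal(X.shape)
            tot = (X**2).sum()
            m = cp_als(X, rank=2, n_starts=5, seed=trial, tol=1e-12, max_iter=800)
            res_als = ((X - m.tensor_hat()) ** 2).sum()
            *_, res_ref = cp_fit_reference(X, 2, n_starts=3, seed=trial)
            assert abs(res_als - res_ref) / tot <= 1e-4

    def test_rank_exceeding_dimension_rejected(self):
        X = np.zeros((5, 3, 4))
        with pytest.raises(DimensionError):
            cp_als(X, rank=4)

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(1).standard_normal((10, 6, 4))
        m1 = cp_als(X, rank=2, n_starts=2, seed=5, max_iter=50)
        m2 = cp_als(X, rank=2, n_starts=2, seed=5, max_iter=50)
        np.testing.assert_array_equal(m1.A, m2.A)
        np.testing.assert_array_equal(m1.loss_trace, m2.loss_trace)


class TestCmtfFit:
    def test_negligible_matrix_weight_matches_cp_als(self, prepared_small):
        ds, _ = prepared_small
        # noise-only matrix blocks with (near) zero weight: the coupled fit
        # should reduce to plain CP on the tensor
        rng = np.random.default_rng(0)
        ds2 = replace(
            ds,
            baseline=rng.standard_normal(ds.baseline.shape),
            gene=rng.standard_normal(ds.gene.shape),
            block_weights=np.array([ds.block_weights[0], 1e-12, 1e-12]),
        )
        mc = cmtf_fit(ds2, rank=2, lam=0.0, n_starts=4, seed=2)
        mp = cp_als(ds.tensor, ds.tensor_mask, rank=2, n_starts=4, seed=2)
        mm = match_components(
            align_components(replace(mc, D=None, E=None, baseline_gains=None,
                                     gene_gains=None)),
            align_components(mp),
        )
        assert mm.overall.min() >= 0.99

    def test_noiseless_coupled_recovery_with_exact_zero_supports(self):
        # noiseless blocks are fitted raw (weighted only): with zero noise
        # the per-column sds are purely signal-driven, so column
        # standardization would deform the planted multilinear structure
        from sparsecmtf.preprocess import weight_blocks

        ds, truth = generate_cohort(
            subjects=25, biomarkers=10, timepoints=4, baseline_vars=6, snps=12,
            noise_sd=(0, 0, 0), missing_rate=0.05, seed=4, discretize_genes=False,
            sparsity=(0.4, 0.3, 0.6),
        )
        dsp = weight_blocks(ds)
        m = align_components(cmtf_fit(dsp, rank=2, lam=3e-3, n_starts=5, seed=1), dsp)
        mm = match_components(m, truth_model(truth))
        assert min(np.abs(v).min() for v in mm.mode_congruence.values()) >= 0.95
        # true-zero gene loadings estimated exactly zero
        for r in range(2):
            tz = truth.gene_loadings[:, mm.permutation[r]] == 0
            assert np.all(m.E[tz, r] == 0.0)
        assert_monotone_trace(m)

    def test_overshrinkage_zeroes_penalized_modes(self, prepared_small):
        ds, _ = prepared_small
        m = cmtf_fit(ds, rank=2, lam=1e3, n_starts=2, seed=0, max_iter=50)
        assert np.all(m.B == 0) and np.all(m.D == 0) and np.all(m.E == 0)
        assert np.allclose(m.tensor_hat(), 0.0)
        assert_monotone_trace(m)

    def test_negative_penalty_rejected(self, prepared_small):
        ds, _ = prepared_small
        with pytest.raises(ValueError):
            cmtf_fit(ds, rank=2, lam=-0.1)

    def test_rank_exceeding_mode_rejected(self, prepared_small):
        ds, _ = prepared_small
        with pytest.raises(DimensionError):
            cmtf_fit(ds, rank=5)


class TestExplainedVariation:
    def test_perfect_reconstruction_is_100(self, small_fit):
        model, ds, _ = small_fit
        perfect = replace(
            model,
            A=model.A, B=model.B, C=model.C,
        )
        ds_perfect = replace(
            ds,
            tensor=model.tensor_hat(),
            baseline=model.baseline_hat(),
            gene=np.where(ds.gene_mask, model.gene_hat(), 0.0),
        )
        for block in ("tensor", "baseline", "gene", "total"):
            assert explained_variation(perfect, ds_perfect, block) == pytest.approx(
                100.0, abs=1e-9
            )

    def test_zero_factors_explain_nothing(self, prepared_small):
        ds, _ = prepared_small
        z = CMTFModel(
            A=np.zeros((ds.n_subjects, 2)),
            B=np.zeros((ds.tensor.shape[1], 2)),
            C=np.zeros((ds.tensor.shape[2], 2)),
            D=np.zeros((ds.baseline.shape[1], 2)),
            E=np.zeros((ds.gene.shape[1], 2)),
        )
        assert explained_variation(z, ds, "tensor") == pytest.approx(0.0)
        assert explained_variation(z, ds, "total") == pytest.approx(0.0)

    def test_rank2_model_on_rank2_noiseless_data(self):
        ds, _ = generate_cohort(
            subjects=16, biomarkers=7, timepoints=4, baseline_vars=4, snps=5,
            noise_sd=(0, 0, 0), missing_rate=0.0, seed=12,
        )
        m = cp_als(ds.tensor, rank=2, n_starts=4, seed=0)
        assert explained_variation(m, ds.tensor) == pytest.approx(100.0, abs=1e-6)

    def test_dimension_mismatch_rejected(self, small_fit):
        model, ds, _ = small_fit
        with pytest.raises(ValueError):
            explained_variation(model, np.zeros((3, 3, 3)), "tensor")


class TestAlignComponents:
    def test_idempotent(self, small_fit):
        model, ds, _ = small_fit
        twice = align_components(model, ds)
        np.testing.assert_allclose(twice.A, model.A, atol=1e-12)
        np.testing.assert_allclose(twice.B, model.B, atol=1e-12)
        np.testing.assert_allclose(
            twice.baseline_gains, model.baseline_gains, atol=1e-12
        )

    def test_reconstruction_invariant(self, prepared_small):
        ds, _ = prepared_small
        m = cmtf_fit(ds, rank=2, lam=1e-4, n_starts=2, seed=3, max_iter=100)
        a = align_components(m, ds)
        np.testing.assert_allclose(a.tensor_hat(), m.tensor_hat(), atol=1e-10)
        np.testing.assert_allclose(a.baseline_hat(), m.baseline_hat(), atol=1e-10)
        np.testing.assert_allclose(a.gene_hat(), m.gene_hat(), atol=1e-10)

    def test_column_rescaling_yields_same_aligned_model(self, small_fit):
        model, ds, _ = small_fit
        scaled = replace(
            model,
            A=model.A / -3.0 * np.array([1.0, 1.0]),
            B=model.B * -3.0,
        )
        re_aligned = align_components(scaled, ds)
        np.testing.assert_allclose(re_aligned.B, model.B, atol=1e-9)
        np.testing.assert_allclose(re_aligned.A, model.A, atol=1e-9)

    def test_unit_norms_sign_convention_and_order(self, small_fit):
        model, ds, _ = small_fit
        for mat in (model.B, model.C, model.D, model.E):
            nrm = np.linalg.norm(mat, axis=0)
            assert np.all((np.abs(nrm - 1) < 1e-9) | (nrm == 0))
        for r in range(model.rank):
            assert model.B[np.argmax(np.abs(model.B[:, r])), r] > 0
        ev = [p.explained_variation for p in component_patterns(model, ds)]
        assert ev == sorted(ev, reverse=True)


class TestSelectLambda:
    def test_returns_grid_member_and_table(self, prepared_small):
        ds, _ = prepared_small
        grid = (1e-3, 1e-2)
        lam, tab = select_lambda(ds, rank=2, grid=grid, n_splits=2, seed=0,
                                 n_starts=1, max_iter=60, tol=1e-5)
        assert lam in grid
        assert set(tab["lam"]) == set(grid)
        assert tab["stability"].between(-1, 1).all()
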