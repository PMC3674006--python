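"""Permutation association, component matching, split-half consistency."""

from dataclasses import replace

import numpy as np
import pytest

from sparsecmtf import generate_cohort, prepare
from sparsecmtf.cmtf import CMTFModel, align_components, cmtf_fit
from sparsecmtf.validation import (
    block_scores,
    congruence_coefficient,
    gene_selection_homogeneity,
    match_components,
    permutation_association_test,
    split_half_consistency,
    split_half_once,
)


class TestCongruence:
    def test_identical_opposite_orthogonal(self):
        v = np.array([1.0, 2.0, -3.0])
        assert congruence_coefficient(v, v) == pytest.approx(1.0)
        assert congruence_coefficient(v, -v) == pytest.approx(-1.0)
        assert congruence_coefficient([1, 0], [0, 5]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            congruence_coefficient([0, 0], [1, 2])

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        u, v = rng.standard_normal(9), rng.standard_normal(9)
        assert congruence_coefficient(3 * u, 0.1 * v) == pytest.approx(
            congruence_coefficient(u, v)
        )


def _random_model(rng, n=15, J=8, K=4, M=5, P=7, R=2):
    return CMTFModel(
        A=rng.standard_normal((n, R)), B=rng.standard_normal((J, R)),
        C=rng.standard_normal((K, R)), D=rng.standard_normal((M, R)),
        E=rng.standard_normal((P, R)),
    )


class TestMatchComponents:
    def test_recovers_permutation_and_signs(self):
        rng = np.random.default_rng(0)
        m1 = _random_model(rng)
        m2 = replace(
            m1,
            A=m1.A[:, ::-1].copy(), B=-m1.B[:, ::-1].copy(),
            C=m1.C[:, ::-1].copy(), D=-m1.D[:, ::-1].copy(),
            E=-m1.E[:, ::-1].copy(),
        )
        mm = match_components(m1, m2)
        np.testing.assert_array_equal(mm.permutation, [1, 0])
        np.testing.assert_allclose(mm.overall, 1.0, atol=1e-12)
        np.testing.assert_allclose(np.abs(mm.mode_congruence["gene"]), 1.0)

    def test_invariant_to_gauge_of_either_input(self):
        rng = np.random.default_rng(5)
        m1, m2 = _random_model(rng), _random_model(rng)
        base = match_components(m1, m2)
        flipped = replace(m2, B=-m2.B, A=-m2.A)  # a legal CP gauge change
        again = match_components(m1, flipped)
        np.testing.assert_array_equal(base.permutation, again.permutation)
        np.testing.assert_allclose(base.overall, again.overall, atol=1e-12)

    def test_independent_models_have_low_congruence(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(40):
            mm = match_components(_random_model(rng), _random_model(rng))
            vals.append(mm.overall.mean())
        # mean |cosine| of independent directions in dims 8/4/5/7 is well
        # below 0.8; matching optimism raises it above the raw null mean
        assert 0.1 < np.mean(vals) < 0.65

    def test_rank_one_forced_pair(self):
        rng = np.random.default_rng(1)
        m1 = _random_model(rng, R=1)
        m2 = _random_model(rng, R=1)
        mm = match_components(m1, m2)
        assert mm.permutation.tolist() == [0]

    def test_rank_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            match_components(_random_model(rng, R=1), _random_model(rng, R=2))


class TestBlockScores:
    def test_exact_matrix_projection_returns_scores(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((20, 2))
        D = rng.standard_normal((6, 2))
        ds, _ = generate_cohort(subjects=20, biomarkers=5, timepoints=4,
                                baseline_vars=6, snps=5, seed=0)
        ds = replace(ds, baseline=A @ D.T)
        model = CMTFModel(A=A, B=rng.standard_normal((5, 2)),
                          C=rng.standard_normal((4, 2)), D=D,
                          E=rng.standard_normal((5, 2)))
        s = block_scores(model, ds, "baseline")
        np.testing.assert_allclose(s, A, atol=1e-9)

    def test_noiseless_tensor_scores_match_subject_scores(self):
        ds, truth = generate_cohort(
            subjects=18, biomarkers=8, timepoints=4, baseline_vars=4, snps=5,
            noise_sd=(0, 0, 0), missing_rate=0.1, seed=6, discretize_genes=False,
        )
        model = CMTFModel(A=truth.subject_scores, B=truth.biomarker_loadings,
                          C=truth.time_loadings)
        s = block_scores(model, ds, "tensor")
        for r in range(2):
            assert abs(congruence_coefficient(s[:, r], truth.subject_scores[:, r])) >= 1 - 1e-9

    def test_zero_loading_component_yields_zero_scores(self):
        rng = np.random.default_rng(9)
        ds, _ = generate_cohort(subjects=12, biomarkers=4, timepoints=4,
                                baseline_vars=4, snps=4, seed=3)
        D = rng.standard_normal((4, 2))
        D[:, 1] = 0.0
        model = CMTFModel(A=rng.standard_normal((12, 2)),
                          B=rng.standard_normal((4, 2)),
                          C=rng.standard_normal((4, 2)), D=D,
                          E=rng.standard_normal((4, 2)))
        s = block_scores(model, ds, "baseline")
        np.testing.assert_allclose(s[:, 1], 0.0, atol=1e-9)


@pytest.fixture(scope="module")
def shared_factor_fit():
    ds, truth = generate_cohort(
        subjects=40, biomarkers=8, timepoints=4, baseline_vars=6, snps=10,
        noise_sd=(0.2, 0.2, 0.2), missing_rate=0.05, seed=21,
    )
    dsp = prepare(ds)
    model = align_components(
        cmtf_fit(dsp, rank=2, lam=0.0, n_starts=3, seed=2, max_iter=200, tol=1e-7),
        dsp,
    )
    return dsp, model


class TestPermutationAssociation:
    def test_p_value_bounds_and_determinism(self, shared_factor_fit):
        ds, model = shared_factor_fit
        r1 = permutation_association_test(ds, model, ("tensor", "baseline"),
                                          component=0, n_perm=99, seed=5)
        r2 = permutation_association_test(ds, model, ("tensor", "baseline"),
                                          component=0, n_perm=99, seed=5)
        assert 1 / 100 <= r1.p_value <= 1.0
        assert len(r1.null_stats) == 99
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null_stats, r2.null_stats)

    def test_shared_factors_detected(self, shared_factor_fit):
        ds, model = shared_factor_fit
        res = permutation_association_test(ds, model, ("tensor", "baseline"),
                                           component=0, n_perm=199, seed=1)
        assert res.p_value <= 0.05

    def test_identical_scores_attain_minimum_p(self):
        # second block constructed as an exact copy of the first block's
        # score structure -> observed |corr| = 1 beats every null draw
        rng = np.random.default_rng(8)
        ds, truth = generate_cohort(subjects=30, biomarkers=6, timepoints=4,
                                    baseline_vars=4, snps=5, seed=14,
                                    noise_sd=(0, 0, 0), missing_rate=0.0,
                                    discretize_genes=False)
        model = CMTFModel(A=truth.subject_scores, B=truth.biomarker_loadings,
                          C=truth.time_loadings, D=truth.baseline_loadings,
                          E=truth.gene_loadings)
        res = permutation_association_test(
            ds, model, ("tensor", "baseline"), component=0, n_perm=999,
            seed=3, method="model",
        )
        assert res.statistic == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_small_n_perm_rejected(self, shared_factor_fit):
        ds, model = shared_factor_fit
        with pytest.raises(ValueError):
            permutation_association_test(ds, model, n_perm=50)


class TestSplitHalf:
    def test_identical_halves_fully_congruent(self):
        ds, _ = generate_cohort(subjects=24, biomarkers=6, timepoints=4,
                                baseline_vars=4, snps=6, seed=17,
                                noise_sd=(0.1, 0.1, 0.1))
        idx = np.arange(24)
        rec = split_half_once(ds, idx, idx, rank=2, lam=0.0, seed=5, n_null=0,
                              n_starts=2, max_iter=120, tol=1e-7)
        for mode, vals in rec["congruence"].items():
            np.testing.assert_allclose(np.abs(vals), 1.0, atol=1e-6)

    def test_deterministic_given_seed(self):
        ds, _ = generate_cohort(subjects=20, biomarkers=5, timepoints=4,
                                baseline_vars=4, snps=6, seed=19)
        kw = dict(rank=2, lam=0.0, n_splits=2, seed=11, n_null=3,
                  n_starts=1, max_iter=60, tol=1e-5)
        r1 = split_half_consistency(ds, **kw)
        r2 = split_half_consistency(ds, **kw)
        assert r1.median_congruence.equals(r2.median_congruence)
        assert r1.worst_p.equals(r2.worst_p)

    def test_strong_signal_beats_noise(self):
        strong, _ = generate_cohort(subjects=40, biomarkers=8, timepoints=4,
                                    baseline_vars=5, snps=8, seed=23,
                                    noise_sd=(0.1, 0.1, 0.1))
        noise, _ = generate_cohort(subjects=40, biomarkers=8, timepoints=4,
                                   baseline_vars=5, snps=8, seed=29,
                                   signal_strength=0.0)
        kw = dict(rank=2, lam=0.0, n_splits=3, seed=2, n_null=0,
                  n_starts=1, max_iter=80, tol=1e-6)
        rs = split_half_consistency(strong, **kw)
        rn = split_half_consistency(noise, **kw)
        assert (
            rs.median_congruence["biomarker"].abs().min()
            > rn.median_congruence["biomarker"].abs().max()
        )

    def test_too_few_subjects_rejected(self):
        ds, _ = generate_cohort(subjects=6, biomarkers=4, timepoints=4,
                                baseline_vars=3, snps=4, seed=31)
        with pytest.raises(ValueError):
            split_half_consistency(ds, n_splits=1)


class TestGeneHomogeneity:
    @pytest.mark.parametrize("size", [5, 15, 25])
    def test_identical_subsets_significant(self, size):
        universe = [f"rs{i}" for i in range(51)]
        sel = set(universe[:size])
        _, p = gene_selection_homogeneity(sel, sel, universe)
        assert p < 0.05

    def test_all_selected_degenerate_p_one(self):
        universe = [f"rs{i}" for i in range(51)]
        _, p = gene_selection_homogeneity(universe, universe, universe)
        assert p == pytest.approx(1.0)

    def test_independent_selections_approximately_uniform(self):
        rng = np.random.default_rng(0)
        universe = [f"rs{i}" for i in range(51)]
        ps = []
        for _ in range(200):
            s1 = rng.choice(universe, size=15, replace=False)
            s2 = rng.choice(universe, size=15, replace=False)
            ps.append(gene_selection_homogeneity(s1, s2, universe)[1])
        ps = np.array(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps <= 0.05).mean() <= 0.10

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_selection_homogeneity(set(), set(), set())

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_selection_homogeneity({"rsX"}, set(), {"rs1"})
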