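"""Randomized moment accumulation, normal equations and summaries."""

import numpy as np
import pytest

from randhe import annotations as A
from randhe import estimator as E
from randhe import oracle, simulate
from randhe.estimator import (
    MomSystem,
    accumulate,
    assemble_system,
    iter_matrix_blocks,
    make_sketch,
    project_covariates,
    solve_system,
    summarize,
)
from randhe.fitting import fit_variance_components


class TestSketch:
    def test_reproducible_and_default_size(self):
        s1 = make_sketch(30, seed=7)
        s2 = make_sketch(30, seed=7)
        np.testing.assert_array_equal(s1.vectors, s2.vectors)
        assert s1.n_vectors == 10  # default number of probe vectors

    def test_moments_match_standard_normal(self):
        s = make_sketch(100_000, 10, seed=1)
        z = s.vectors
        assert np.abs(z.mean(axis=0)).max() < 0.05
        cov = z.T @ z / z.shape[0]
        assert np.abs(cov - np.eye(10)).max() < 0.05


class TestAccumulate:
    def test_single_component_matches_dense_product(self, rng):
        x = simulate.standardized_dataset(50, 30, seed=8)[0].values
        annot = A.single_component(30)
        sketch = make_sketch(50, 1, seed=3)
        y = rng.standard_normal(50)
        y -= y.mean()
        acc = accumulate(iter_matrix_blocks(x, 30), annot, sketch, y, 2)
        image = acc.sketch_images.sum(axis=0)[0]
        expected = x @ (x.T @ sketch.vectors)
        np.testing.assert_allclose(image, expected, atol=1e-9)
        assert acc.quad_partials.sum() == pytest.approx(
            float(((x.T @ y) ** 2).sum()), rel=1e-10
        )

    def test_block_size_invariance(self, small_dataset, annot8, rng):
        x = small_dataset[0].values
        sketch = make_sketch(200, 4, seed=9)
        y = rng.standard_normal(200)
        y -= y.mean()
        acc_a = accumulate(iter_matrix_blocks(x, 1000), annot8, sketch, y, 5)
        acc_b = accumulate(iter_matrix_blocks(x, 37), annot8, sketch, y, 5)
        np.testing.assert_allclose(acc_a.sketch_images, acc_b.sketch_images, atol=1e-8)
        np.testing.assert_allclose(acc_a.quad_partials, acc_b.quad_partials, atol=1e-8)
        np.testing.assert_array_equal(acc_a.snp_counts, acc_b.snp_counts)

    def test_null_phenotype(self, small_dataset, annot8):
        x = small_dataset[0].values
        acc = accumulate(
            iter_matrix_blocks(x, 100), annot8, make_sketch(200, 2, seed=0),
            np.zeros(200), 4,
        )
        assert acc.yty == 0.0
        assert np.all(acc.quad_partials == 0.0)


class TestAssemble:
    def test_duplicate_components_identical_entries(self, small_dataset, rng):
        x = small_dataset[0].values[:, :50]
        idx = np.arange(50)
        annot = A.AnnotationSet(
            "overlapping", [idx, idx.copy()], [np.ones(50), np.ones(50)],
            ["a", "b"], 50,
        )
        y = rng.standard_normal(200)
        y -= y.mean()
        acc = accumulate(iter_matrix_blocks(x, 20), annot, make_sketch(200, 3, seed=2), y, 2)
        system = assemble_system(acc)
        assert system.t_hat[0, 0] == pytest.approx(system.t_hat[0, 1], rel=1e-12)
        assert system.t_hat[0, 0] == pytest.approx(system.t_hat[1, 1], rel=1e-12)

    def test_trace_estimate_converges_to_oracle(self, rng):
        x = simulate.standardized_dataset(50, 30, seed=4)[0].values
        annot = A.single_component(30)
        y = np.zeros(50)
        acc = accumulate(
            iter_matrix_blocks(x, 30), annot, make_sketch(50, 1000, seed=6), y, 2
        )
        t_hat = assemble_system(acc).t_hat[0, 0]
        grm = oracle.exact_grm(x).matrix
        t_exact = float(np.sum(grm * grm))
        # Monte-Carlo SE of a B-probe Hutchinson estimate of tr(K^2)
        k2 = grm @ grm
        mc_se = np.sqrt(2.0 * float(np.sum(k2 * k2)) / 1000)
        assert abs(t_hat - t_exact) < 3.0 * mc_se

    def test_quadratic_form_matches_dense(self, small_dataset, annot8, rng):
        x = small_dataset[0].values
        y = rng.standard_normal(200)
        y -= y.mean()
        acc = accumulate(iter_matrix_blocks(x, 64), annot8, make_sketch(200, 2, seed=1), y, 3)
        c = assemble_system(acc).c_vec
        for k, idx in enumerate(annot8.snp_indices):
            grm = oracle.exact_grm(x[:, idx]).matrix
            assert c[k] == pytest.approx(float(y @ grm @ y), rel=1e-9)


class TestSolve:
    def test_two_by_two(self):
        system = MomSystem(
            t_hat=np.array([[3.0]]), b_vec=np.array([1.0]), c_vec=np.array([5.0]),
            yty=3.0, n_eff=2,
        )
        np.testing.assert_allclose(solve_system(system), [1.4, 0.8])

    def test_duplicated_rows_fall_back_to_lstsq(self):
        system = MomSystem(
            t_hat=np.array([[2.0, 2.0], [2.0, 2.0]]),
            b_vec=np.array([1.0, 1.0]),
            c_vec=np.array([3.0, 3.0]),
            yty=2.0,
            n_eff=1,
        )
        with pytest.warns(UserWarning, match="ill-conditioned"):
            sol = solve_system(system)
        assert np.all(np.isfinite(sol))

    def test_null_heritability_recovered(self):
        rng = np.random.default_rng(0)
        x = simulate.standardized_dataset(300, 200, seed=13)[0].values
        grms = [oracle.exact_grm(x)]
        ests = []
        for _ in range(200):
            y = rng.standard_normal(300)
            y -= y.mean()
            ests.append(oracle.exact_mom_fit(grms, y, n_eff=299)[0])
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean()) < 2 * se + 1e-3


class TestSummaries:
    def test_single_component_arithmetic(self):
        annot = A.single_component(10)
        s = summarize(np.array([1.0, 1.0]), annot)
        assert s.h2_total == pytest.approx(0.5)
        assert s.enrichment[0] == pytest.approx(1.0)

    def test_disjoint_enrichment_arithmetic(self):
        labels = np.repeat([0, 1], [10, 90])
        annot = A.from_labels(labels)
        s = summarize(np.array([0.3, 0.2, 0.5]), annot)
        assert s.h2_total == pytest.approx(0.5)
        np.testing.assert_allclose(s.h2_per_component, [0.3, 0.2])
        assert s.enrichment[0] == pytest.approx(6.0)  # (0.3/0.5)/(10/100)

    def test_overlapping_shared_snp_set(self):
        idx = np.arange(3)
        annot = A.AnnotationSet(
            "overlapping", [idx, idx.copy()], [np.ones(3), np.ones(3)],
            ["a", "b"], 3,
        )
        # both annotations cover the same 3 SNPs: per-SNP density is
        # 0.1/3 + 0.1/3, summed over 3 SNPs -> 0.2 in the numerator
        s = summarize(np.array([0.1, 0.1, 0.8]), annot)
        assert s.h2_per_component[0] == pytest.approx(0.2 / 1.0)
        assert s.h2_per_component[1] == pytest.approx(0.2 / 1.0)

    def test_zero_h2_enrichment_undefined(self):
        annot = A.single_component(5)
        s = summarize(np.array([0.0, 1.0]), annot)
        assert np.isnan(s.enrichment[0])

    def test_disjoint_enrichment_conservation(self, rng):
        labels = rng.integers(0, 4, 200)
        annot = A.from_labels(labels)
        sigma2 = np.append(rng.uniform(-0.1, 0.5, 4), 0.4)
        s = summarize(sigma2, annot)
        m_k = annot.component_sizes / annot.n_snps
        assert float(m_k @ s.enrichment) == pytest.approx(1.0, rel=1e-10)


class TestCovariates:
    def test_intercept_only_centers(self, rng):
        y = rng.standard_normal(40) + 3.0
        y_res, n_eff, proj = project_covariates(y)
        assert n_eff == 39
        np.testing.assert_allclose(y_res, y - y.mean(), atol=1e-10)

    def test_phenotype_as_covariate_absorbs_signal(self, small_dataset, annot8):
        x = small_dataset[0].values
        rng = np.random.default_rng(5)
        y = rng.standard_normal(200)
        fit = fit_variance_components(
            x, y, annot8, n_vectors=4, n_jackknife_blocks=4, seed=1,
            covariates=y[:, None],
        )
        assert np.abs(fit.sigma2).max() < 1e-8

    def test_rank_deficient_covariates_dropped(self, rng):
        y = rng.standard_normal(30)
        w = np.ones((30, 2))  # duplicates the intercept
        with pytest.warns(UserWarning, match="dependent"):
            _, n_eff, _ = project_covariates(y, w)
        assert n_eff == 29

    def test_independent_covariates_leave_h2_unchanged(self, small_dataset, annot8):
        x, freqs, _ = small_dataset
        x = x.values
        rng = np.random.default_rng(17)
        diffs = []
        for rep in range(30):
            spec = simulate.ArchitectureSpec(h2=0.5, seed=1000 + rep)
            y, _ = simulate.simulate_phenotype(x, freqs, spec)
            w = rng.standard_normal((200, 5))
            f0 = fit_variance_components(x, y, annot8, n_vectors=6, n_jackknife_blocks=4, seed=rep)
            f1 = fit_variance_components(
                x, y, annot8, n_vectors=6, n_jackknife_blocks=4, seed=rep, covariates=w
            )
            diffs.append(f1.h2_total - f0.h2_total)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 2 * se + 0.01

    def test_scale_invariance(self, small_dataset, annot8):
        x, freqs, _ = small_dataset
        x = x.values
        y, _ = simulate.simulate_phenotype(
            x, freqs, simulate.ArchitectureSpec(h2=0.4, seed=3)
        )
        f1 = fit_variance_components(x, y, annot8, n_vectors=4, n_jackknife_blocks=4, seed=2)
        f2 = fit_variance_components(x, 7.3 * y, annot8, n_vectors=4, n_jackknife_blocks=4, seed=2)
        assert f2.h2_total == pytest.approx(f1.h2_total, rel=1e-9)
        np.testing.assert_allclose(f2.enrichment, f1.enrichment, rtol=1e-9)
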