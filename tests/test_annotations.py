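"""Annotation maps, MAF/LD partitions and in-sample LD scores."""

import numpy as np
import pytest

from randhe import annotations as A
from randhe import plink, simulate
from randhe.estimator import accumulate, iter_matrix_blocks, make_sketch


def _block(values, positions, chrom="1"):
    recs = [
        plink.SnpRecord(id=f"s{j}", chromosome=chrom, position_bp=int(p))
        for j, p in enumerate(positions)
    ]
    return plink.StandardizedBlock(values=values, snps=recs)


class TestLdScores:
    def test_duplicated_snps_score_two(self, rng):
        x = plink.standardize(
            rng.choice([0, 1, 2], size=(50, 1)).astype(np.int8)
        ).values
        blk = _block(np.hstack([x, x]), [1000, 1100])
        scores = A.compute_ld_scores(blk, window_bp=1_000_000).scores
        np.testing.assert_allclose(scores, [2.0, 2.0], atol=1e-10)

    def test_lone_chromosome_scores_one(self, rng):
        counts = rng.choice([0, 1, 2], size=(60, 2)).astype(np.int8)
        x = plink.standardize(counts).values
        blk1 = _block(x[:, :1], [1000], chrom="1")
        blk2 = _block(x[:, 1:], [1000], chrom="2")
        scores = A.compute_ld_scores([blk1, blk2], window_bp=1_000_000).scores
        np.testing.assert_allclose(scores, [1.0, 1.0], atol=1e-12)

    def test_matches_dense_all_pairs_oracle(self):
        block, _, positions = simulate.standardized_dataset(300, 200, seed=3)
        window = 40_000
        scores = A.compute_ld_scores(block, window_bp=window).scores
        x = block.values
        corr = (x.T @ x) / x.shape[0]
        within = np.abs(positions[:, None] - positions[None, :]) <= window
        expected = (corr**2 * within).sum(axis=1)
        np.testing.assert_allclose(scores, expected, atol=1e-10)
        assert scores.min() >= 1.0

    def test_window_excludes_distant_pairs(self, rng):
        x = plink.standardize(
            rng.choice([0, 1, 2], size=(50, 1)).astype(np.int8)
        ).values
        blk = _block(np.hstack([x, x]), [1000, 500_000])
        scores = A.compute_ld_scores(blk, window_bp=10_000).scores
        np.testing.assert_allclose(scores, [1.0, 1.0], atol=1e-12)

    def test_unsorted_positions_rejected(self, rng):
        x = plink.standardize(
            rng.choice([0, 1, 2], size=(30, 2)).astype(np.int8)
        ).values
        blk = _block(x, [5000, 1000])
        with pytest.raises(ValueError, match="sorted"):
            A.compute_ld_scores(blk, window_bp=10_000)


class TestMafLdPartition:
    def test_eight_bin_scheme(self, small_dataset, annot8):
        assert annot8.mode == "disjoint"
        assert annot8.n_components == 8
        assert annot8.component_sizes.sum() == 300

    def test_quantiles_on_distinct_scores(self):
        freqs = np.array([0.2, 0.25, 0.3, 0.35])
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        annot = A.make_maf_ld_partition(freqs, scores, maf_breaks=(0.5,), n_score_quantiles=4)
        assert annot.n_components == 4
        np.testing.assert_array_equal(annot.component_sizes, [1, 1, 1, 1])

    def test_empty_maf_bin_dropped(self):
        freqs = np.full(100, 0.3)  # nothing below the 5% break
        scores = np.arange(100.0)
        annot = A.make_maf_ld_partition(freqs, scores, (0.05,), 4)
        assert annot.n_components == 4  # the four low-MAF bins vanish
        assert annot.component_sizes.sum() == 100

    def test_partition_conservation_24_bins(self):
        rng = np.random.default_rng(0)
        freqs = rng.uniform(0.005, 0.5, 2000)
        scores = rng.gamma(2.0, 1.0, 2000) + 1
        annot = A.make_maf_ld_partition(
            freqs, scores, (0.01, 0.02, 0.03, 0.04, 0.05), 4
        )
        assert annot.component_sizes.sum() == 2000
        flat = np.concatenate(annot.snp_indices)
        assert len(np.unique(flat)) == 2000


class TestAnnotationFile:
    def test_binary_overlapping_28_columns(self, tmp_path, rng):
        m, k = 60, 28
        values = rng.integers(0, 2, size=(m, k))
        values[:, 0] = 1  # guarantee coverage
        path = tmp_path / "annot.txt"
        np.savetxt(path, values, fmt="%d")
        annot = A.load_annotation_file(path, "binary", n_snps=m)
        assert annot.mode == "overlapping"
        assert annot.n_components == k
        np.testing.assert_array_equal(
            annot.component_sizes, values.sum(axis=0)
        )

    def test_all_ones_single_column(self, tmp_path):
        path = tmp_path / "a.txt"
        np.savetxt(path, np.ones((10, 1)), fmt="%d")
        annot = A.load_annotation_file(path, "binary", n_snps=10)
        assert annot.n_components == 1
        assert annot.component_sizes[0] == 10

    def test_negative_continuous_rejected(self, tmp_path):
        path = tmp_path / "a.txt"
        np.savetxt(path, np.array([[1.0], [-0.5], [2.0]]))
        with pytest.raises(ValueError, match="negative"):
            A.load_annotation_file(path, "continuous")

    def test_row_count_mismatch(self, tmp_path):
        path = tmp_path / "a.txt"
        np.savetxt(path, np.ones((5, 2)), fmt="%d")
        with pytest.raises(ValueError, match="rows"):
            A.load_annotation_file(path, "binary", n_snps=7)

    def test_uncovered_snp_needs_rest(self, tmp_path):
        values = np.array([[1], [0], [1]])
        path = tmp_path / "a.txt"
        np.savetxt(path, values, fmt="%d")
        with pytest.raises(ValueError, match="no annotation"):
            A.load_annotation_file(path, "binary")
        annot = A.load_annotation_file(path, "binary", add_rest=True)
        assert annot.names[-1] == "rest"
        assert annot.component_sizes[-1] == 1


class TestContinuousWeights:
    def test_identity_and_scalar_weights(self, small_dataset):
        block, _, _ = small_dataset
        x = block.values[:, :4]
        weights = np.array([1.0, 1.0, 4.0, 1.0])
        annot = A.AnnotationSet(
            mode="continuous",
            snp_indices=[np.arange(4)],
            weights=[weights],
            names=["w"],
            n_snps=4,
        )
        sub = plink.StandardizedBlock(values=x, snps=block.snps[:4])
        out = A.apply_continuous_weights(sub, annot, 0)
        np.testing.assert_allclose(out[:, [0, 1, 3]], x[:, [0, 1, 3]])
        np.testing.assert_allclose(out[:, 2], 2.0 * x[:, 2])

    def test_unit_weights_match_binary_moments(self, small_dataset):
        block, _, _ = small_dataset
        x = block.values[:, :40]
        n = x.shape[0]
        idx = [np.arange(20), np.arange(20, 40)]
        binary = A.AnnotationSet(
            "overlapping", idx, [np.ones(20), np.ones(20)], ["a", "b"], 40
        )
        contin = A.AnnotationSet(
            "continuous", idx, [np.ones(20), np.ones(20)], ["a", "b"], 40
        )
        sketch = make_sketch(n, 4, seed=5)
        y = np.random.default_rng(1).standard_normal(n)
        y -= y.mean()
        acc_b = accumulate(iter_matrix_blocks(x, 16), binary, sketch, y, 2)
        acc_c = accumulate(iter_matrix_blocks(x, 16), contin, sketch, y, 2)
        np.testing.assert_allclose(
            acc_b.sketch_images, acc_c.sketch_images, atol=1e-10
        )
        np.testing.assert_allclose(acc_b.quad_partials, acc_c.quad_partials, atol=1e-10)

    def test_weighted_grm_matches_dense_oracle(self, small_dataset, rng):
        from randhe.oracle import exact_grm

        block, _, _ = small_dataset
        x = block.values[:, :10]
        w = rng.uniform(0.1, 3.0, 10)
        grm = exact_grm(x, weights=w)
        expected = (x * w) @ x.T / 10
        np.testing.assert_allclose(grm.matrix, expected, atol=1e-10)
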