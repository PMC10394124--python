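import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats

from scasim.exceptions import ParameterError, ValidationError
from scasim.effects import HubSpec
from scasim.evaluation import (
    batch_separation_test,
    clustering_scores,
    f1_score_sets,
    interaction_f1,
    lsi_embedding,
    milisi,
    peak_pair_correlation,
    quantile_compare,
)
from scasim.io_formats import CountMatrix, default_cell_table, default_peak_table


def _cm(array):
    a = np.asarray(array, dtype=np.int64)
    return CountMatrix(
        sp.csr_matrix(a), default_peak_table(a.shape[0]), default_cell_table(a.shape[1])
    )


class TestQuantileCompare:
    def test_identical_samples_score_zero_everywhere(self, rng):
        x = rng.gamma(2.0, 10.0, size=500)
        qc = quantile_compare(x, x.copy(), "peak_mean", 100)
        for name, value in qc.metrics.items():
            assert value == pytest.approx(0.0, abs=1e-12), name

    def test_constant_log_shift_appears_in_all_error_metrics(self, rng):
        real = rng.lognormal(7.0, 0.5, size=2000)
        synth = real * np.exp(0.3)
        qc = quantile_compare(real, synth, "library_size", 100)
        for name in ("MAD", "MAE", "RMSE"):
            assert qc.metrics[name] == pytest.approx(0.3, abs=1e-9), name
        assert qc.metrics["one_minus_PCC"] == pytest.approx(0.0, abs=1e-9)

    def test_shifted_uniforms_reach_ks_half(self, rng):
        real = rng.uniform(0, 1, size=20000)
        synth = rng.uniform(0.5, 1.5, size=20000)
        qc = quantile_compare(real, synth, "generic", 100)
        assert qc.metrics["KSS"] == pytest.approx(0.5, abs=0.02)

    def test_too_few_quantiles_rejected(self, rng):
        with pytest.raises(ParameterError):
            quantile_compare(rng.random(10), rng.random(10), n_quantiles=1)

    def test_empty_sample_rejected(self, rng):
        with pytest.raises(ValidationError):
            quantile_compare(np.array([]), rng.random(10))


class TestPeakPairCorrelation:
    def test_identical_matrices_identical_correlations(self, small_reference):
        real_c, synth_c = peak_pair_correlation(
            small_reference, small_reference, top_k=50
        )
        np.testing.assert_array_equal(real_c, synth_c)

    def test_toy_hand_computed_spearman(self):
        real = _cm([[10, 20, 30, 40], [40, 30, 20, 10], [10, 30, 20, 40]])
        synth = _cm([[1, 2, 3, 4], [1, 2, 3, 4], [1, 2, 3, 4]])
        real_c, synth_c = peak_pair_correlation(real, synth, top_k=3)
        # pairs in row order: (0,1), (0,2), (1,2)
        np.testing.assert_allclose(np.sort(real_c), [-1.0, -0.8, 0.8], atol=1e-12)
        np.testing.assert_allclose(synth_c, [1.0, 1.0, 1.0], atol=1e-12)

    def test_top_k_clamped_with_warning(self, small_reference):
        with pytest.warns(UserWarning, match="clamped"):
            real_c, _ = peak_pair_correlation(
                small_reference, small_reference, top_k=10**6
            )
        npeak = small_reference.npeak
        assert real_c.size == npeak * (npeak - 1) // 2

    def test_pair_subsampling_is_seeded(self, small_reference):
        a = peak_pair_correlation(
            small_reference, small_reference, top_k=200,
            max_pairs=1000, rng=np.random.default_rng(3),
        )
        b = peak_pair_correlation(
            small_reference, small_reference, top_k=200,
            max_pairs=1000, rng=np.random.default_rng(3),
        )
        np.testing.assert_array_equal(a[0], b[0])


class TestMilisi:
    def test_label_shuffle_of_one_dataset_mixes_fully(self, small_reference):
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_reference.ncell)
        half = small_reference.ncell // 2
        a = small_reference.subset(cell_idx=perm[:half])
        b = small_reference.subset(cell_idx=perm[half:])
        assert milisi(a, b) > 1.9

    def test_disjoint_peak_support_separates(self, small_reference):
        cm = small_reference
        npeak, ncell = cm.npeak, cm.ncell
        zeros = sp.csr_matrix((npeak, ncell), dtype=np.int64)
        top = CountMatrix(
            sp.vstack([cm.counts, zeros]).tocsr(),
            default_peak_table(2 * npeak), cm.cells.copy(),
        )
        bottom = CountMatrix(
            sp.vstack([zeros, cm.counts]).tocsr(),
            default_peak_table(2 * npeak), cm.cells.copy(),
        )
        assert milisi(top, bottom) < 1.1

    def test_invariant_to_swapping_real_and_synthetic(self, small_reference):
        # near-invariance: the joint SVD is refit after the swap, so the
        # embedding (and the score) can move by numerical noise only
        rng = np.random.default_rng(1)
        perm = rng.permutation(small_reference.ncell)
        half = small_reference.ncell // 2
        a = small_reference.subset(cell_idx=perm[:half])
        b = small_reference.subset(cell_idx=perm[half:])
        assert milisi(a, b) == pytest.approx(milisi(b, a), abs=0.05)

    def test_too_few_cells_rejected(self, small_reference):
        tiny = small_reference.subset(cell_idx=np.arange(20))
        with pytest.raises(ParameterError):
            milisi(tiny, tiny, perplexity=30)


class TestClusteringScores:
    def test_identical_partitions_score_one(self):
        scores = clustering_scores([0, 0, 1, 1], [0, 0, 1, 1])
        assert all(v == pytest.approx(1.0) for v in scores.values())

    def test_permutation_invariance(self):
        scores = clustering_scores([0, 0, 1, 1], [1, 1, 0, 0])
        assert all(v == pytest.approx(1.0) for v in scores.values())

    def test_crossed_partition_hand_ari(self):
        scores = clustering_scores([0, 0, 1, 1], [0, 1, 0, 1])
        assert scores["ARI"] == pytest.approx(-0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            clustering_scores([0, 1], [0, 1, 2])


class TestInteractionF1:
    def _hub(self):
        return HubSpec("h", np.arange(0, 66), np.arange(0, 40))

    def test_exact_prediction_scores_one(self):
        out = interaction_f1([self._hub()], [list(range(40))])
        assert out["h"] == pytest.approx(1.0)

    def test_whole_hub_prediction_closed_form(self):
        out = interaction_f1([self._hub()], [list(range(66))])
        precision = 40 / 66
        expected = 2 * precision / (1 + precision)
        assert out["h"] == pytest.approx(expected, abs=1e-12)

    def test_disjoint_prediction_scores_zero(self):
        out = interaction_f1([self._hub()], [list(range(40, 66))])
        assert out["h"] == 0.0

    def test_best_of_multiple_predictions(self):
        preds = [list(range(40, 66)), list(range(0, 40)), list(range(0, 66))]
        assert interaction_f1([self._hub()], preds)["h"] == pytest.approx(1.0)

    def test_empty_prediction_list_warns(self):
        with pytest.warns(UserWarning):
            out = interaction_f1([self._hub()], [])
        assert out["h"] == 0.0

    def test_prediction_outside_hub_is_ignored(self):
        out = interaction_f1([self._hub()], [list(range(0, 40)) + [100, 200]])
        assert out["h"] == pytest.approx(1.0)

    def test_f1_of_empty_prediction_is_zero(self):
        assert f1_score_sets({1, 2}, set()) == 0.0


class TestKssOracle:
    def test_kss_matches_brute_force_ecdf_sweep(self, rng):
        for _ in range(5):
            a = rng.normal(size=40)
            b = rng.normal(0.5, 1.2, size=25)
            kss = quantile_compare(a, b, "generic", 10).metrics["KSS"]
            grid = np.sort(np.concatenate([a, b]))
            ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
            ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
            assert kss == pytest.approx(np.abs(ecdf_a - ecdf_b).max(), abs=1e-12)


class TestLsiAndBatchTest:
    def test_lsi_shape(self, small_reference):
        emb = lsi_embedding(small_reference.counts, n_dims=10)
        assert emb.shape == (small_reference.ncell, 10)

    def test_batch_test_requires_two_batches(self, small_reference):
        with pytest.raises(ParameterError):
            batch_separation_test(
                small_reference, np.repeat("only", small_reference.ncell)
            )

    def test_random_split_is_null(self, small_reference):
        rng = np.random.default_rng(2)
        labels = np.where(rng.random(small_reference.ncell) < 0.5, "a", "b")
        out = batch_separation_test(
            small_reference, labels, n_permutations=99, rng=rng
        )
        assert out["p_value"] > 0.01
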