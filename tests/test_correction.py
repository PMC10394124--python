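import numpy as np
import pytest
import scipy.stats

from scasim.exceptions import ParameterError, ValidationError
from scasim.correction import (
    ParamMatrix,
    activate,
    correct_cellwise,
    correct_joint,
    correct_peakwise,
    raw_param_matrix,
    sample_counts_bernoulli,
    sample_counts_poisson,
)


def _activated(values):
    return ParamMatrix(np.asarray(values, dtype=float), "activated")


def _peak_corrected(values):
    return ParamMatrix(np.asarray(values, dtype=float), "peak_corrected")


class TestRawParamMatrix:
    def test_hand_product(self):
        P = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        C = np.ones((2, 2))
        out = raw_param_matrix(P, C)
        np.testing.assert_allclose(out.values, [[1, 1], [1, 1], [2, 2]])
        assert out.stage == "raw"

    def test_zero_cem_gives_zero_matrix(self, rng):
        out = raw_param_matrix(rng.normal(size=(5, 3)), np.zeros((3, 4)))
        assert not out.values.any()

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            raw_param_matrix(rng.normal(size=(5, 3)), rng.normal(size=(4, 2)))


class TestActivate:
    def test_softplus_closed_form_at_zero(self):
        out = activate(ParamMatrix(np.zeros((1, 1)), "raw"), "softplus")
        assert out.values[0, 0] == pytest.approx(np.log(2.0))

    def test_exponential_closed_form_at_zero(self):
        out = activate(ParamMatrix(np.zeros((1, 1)), "raw"), "exponential")
        assert out.values[0, 0] == pytest.approx(1.0)

    def test_monotone_on_random_pairs(self, rng):
        x = np.sort(rng.normal(scale=3.0, size=(1, 100)))
        for kind in ("softplus", "exponential"):
            y = activate(ParamMatrix(x, "raw"), kind).values.ravel()
            assert (np.diff(y) > 0).all()

    def test_exponential_clips_large_arguments(self):
        out = activate(ParamMatrix(np.array([[100.0]]), "raw"), "exponential")
        assert out.values[0, 0] == pytest.approx(np.exp(30.0))


class TestCorrectPeakwise:
    def test_targets_equal_to_row_sums_is_identity(self, rng):
        m = _activated(rng.random((6, 4)) + 0.1)
        out = correct_peakwise(m, m.values.sum(axis=1))
        np.testing.assert_allclose(out.values, m.values)

    def test_hand_rank_matched_example(self):
        m = _activated([[1.0, 1.0], [3.0, 1.0]])
        out = correct_peakwise(m, np.array([8.0, 2.0]))
        np.testing.assert_allclose(out.values.sum(axis=1), [2.0, 8.0])
        # within-row proportions unchanged
        np.testing.assert_allclose(out.values[1] / out.values[1].sum(), [0.75, 0.25])

    def test_rank_preservation_is_exact(self, rng):
        m = _activated(rng.random((50, 10)) + 0.01)
        targets = rng.gamma(1.0, 100.0, size=50)
        out = correct_peakwise(m, targets)
        rho = scipy.stats.spearmanr(
            m.values.sum(axis=1), out.values.sum(axis=1)
        ).statistic
        assert rho == pytest.approx(1.0)

    def test_negative_targets_rejected(self, rng):
        with pytest.raises(ValidationError):
            correct_peakwise(_activated(rng.random((3, 2))), np.array([1.0, -1.0, 2.0]))


class TestCorrectCellwise:
    def test_fixed_point_when_targets_match_current_state(self, rng):
        values = rng.random((100, 5)) + 0.2
        m = _peak_corrected(values)
        lib = values.sum(axis=0)
        spars = (-np.expm1(-values)).mean(axis=0)
        cev = np.argsort(np.argsort(lib)).astype(float)  # comonotone scores
        out, report = correct_cellwise(m, lib, spars, cev)
        np.testing.assert_allclose(out.values, values, rtol=0.05)
        assert not report.clamped.any()

    def test_single_column_closed_form(self):
        # lambda = [1, 1] rescaled to library 2 stays [1, 1] for every
        # exponent (the power transform cannot reshape a constant column),
        # and the expected non-zero proportion is exactly 1 - e^-1
        m = _peak_corrected(np.array([[1.0], [1.0]]))
        target_prop = 1.0 - np.exp(-1.0)
        out, report = correct_cellwise(
            m, np.array([2.0]), np.array([target_prop]), np.array([0.0])
        )
        np.testing.assert_allclose(out.values[:, 0], [1.0, 1.0], rtol=1e-6)
        assert report.achieved_prop[0] == pytest.approx(target_prop, abs=1e-9)
        assert not report.clamped[0]

    def test_library_sums_exact_and_cev_monotone(self, rng):
        values = rng.random((200, 30)) + 0.05
        lib = rng.gamma(3.0, 200.0, size=30) + 1.0
        spars = rng.uniform(0.1, 0.5, size=30)
        cev = rng.normal(size=30)
        out, _ = correct_cellwise(_peak_corrected(values), lib, spars, cev)
        np.testing.assert_allclose(
            np.sort(out.values.sum(axis=0)), np.sort(lib), rtol=1e-9
        )
        # larger cev score -> larger assigned library target
        order = np.argsort(cev)
        sums = out.values.sum(axis=0)[order]
        assert (np.diff(sums) >= -1e-9).all()

    def test_total_mass_conserved(self, rng):
        values = rng.random((50, 8)) + 0.1
        lib = rng.uniform(5.0, 50.0, size=8)
        spars = rng.uniform(0.2, 0.6, size=8)
        out, _ = correct_cellwise(
            _peak_corrected(values), lib, spars, rng.normal(size=8)
        )
        assert out.values.sum() == pytest.approx(lib.sum(), rel=1e-9)

    def test_unattainable_target_clamped_and_flagged(self, rng):
        values = rng.random((20, 1)) + 0.5
        out, report = correct_cellwise(
            _peak_corrected(values),
            np.array([0.5]),  # tiny library
            np.array([0.99]),  # near-saturated proportion: unattainable
            np.array([0.0]),
        )
        assert report.clamped[0]
        assert out.values[:, 0].sum() == pytest.approx(0.5, rel=1e-9)


class TestCorrectJoint:
    def test_margins_and_sparsity_after_convergence(self, rng):
        values = np.log1p(np.exp(rng.normal(size=(300, 40))))
        act = ParamMatrix(values, "activated")
        peak_targets = rng.gamma(0.8, 50.0, size=300) + 0.5
        lib = rng.gamma(4.0, 100.0, size=40) + 10.0
        peak_targets *= lib.sum() / peak_targets.sum()
        spars = np.clip(rng.uniform(0.2, 0.4, size=40), 0, 1)
        cev = rng.normal(size=40)
        final, report, spars_used = correct_joint(
            act, peak_targets, lib, np.sort(spars)[np.argsort(np.argsort(cev))], cev
        )
        np.testing.assert_allclose(
            np.sort(final.values.sum(axis=0)), np.sort(lib), rtol=1e-9
        )
        achieved = (-np.expm1(-final.values)).mean(axis=0)
        ok = ~report.clamped
        assert np.abs(achieved[ok] - np.sort(spars_used)[np.argsort(np.argsort(cev))][ok]).max() < 5e-3

    def test_requires_activated_stage(self, rng):
        m = ParamMatrix(rng.random((4, 3)), "final")
        with pytest.raises(ParameterError):
            correct_joint(m, np.ones(4), np.ones(3), np.full(3, 0.5), np.zeros(3))


class TestSampling:
    def test_zero_mean_matrix_gives_zero_counts(self, rng):
        cm = sample_counts_poisson(ParamMatrix(np.zeros((5, 4)), "final"), rng)
        assert cm.counts.nnz == 0

    def test_poisson_moments(self, rng):
        cm = sample_counts_poisson(ParamMatrix(np.full((500, 200), 4.0), "final"), rng)
        data = np.asarray(cm.counts.todense(), dtype=float)
        assert data.mean() == pytest.approx(4.0, abs=0.05)
        assert data.var() == pytest.approx(4.0, abs=0.1)

    def test_column_sums_concentrate_on_targets(self, rng):
        lam = rng.random((1000, 20)) + 0.5
        lam *= 1000.0 / lam.sum(axis=0, keepdims=True)
        cm = sample_counts_poisson(ParamMatrix(lam, "final"), rng)
        sums = np.asarray(cm.counts.sum(axis=0)).ravel()
        assert np.abs(sums - 1000.0).max() < 3 * np.sqrt(1000.0)

    def test_bernoulli_closed_form_probability(self, rng):
        lam = np.full((1000, 100), np.log(2.0))
        cm = sample_counts_bernoulli(ParamMatrix(lam, "final"), rng)
        assert cm.binarized
        freq = cm.counts.nnz / (1000 * 100)
        assert freq == pytest.approx(0.5, abs=0.01)

    def test_bernoulli_limits(self, rng):
        lam = np.array([[0.0, 40.0]])
        cm = sample_counts_bernoulli(ParamMatrix(lam, "final"), rng)
        dense = np.asarray(cm.counts.todense())
        assert dense[0, 0] == 0 and dense[0, 1] == 1

    def test_identical_rng_states_reproduce_counts(self):
        lam = np.random.default_rng(1).random((30, 20)) * 3
        a = sample_counts_poisson(ParamMatrix(lam, "final"), np.random.default_rng(5))
        b = sample_counts_poisson(ParamMatrix(lam, "final"), np.random.default_rng(5))
        assert (a.counts != b.counts).nnz == 0
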