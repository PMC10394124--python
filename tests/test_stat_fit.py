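import numpy as np
import pytest
import scipy.sparse as sp
import scipy.special
import scipy.stats

from scasim.exceptions import FitError, ParameterError
from scasim.io_formats import CountMatrix, default_cell_table, default_peak_table
from scasim.stat_fit import (
    DISCRETE_FAMILIES,
    build_stat_models,
    compute_statistics,
    fit_discrete,
    fit_gmm2,
    fit_kde,
    select_best_discrete,
)


def _cm(array):
    a = np.asarray(array, dtype=np.int64)
    return CountMatrix(
        sp.csr_matrix(a), default_peak_table(a.shape[0]), default_cell_table(a.shape[1])
    )


class TestComputeStatistics:
    def test_hand_computed_example(self):
        st = compute_statistics(_cm([[1, 0], [2, 3]]))
        assert st.lib_size.tolist() == [3, 3]
        assert st.nonzero_prop.tolist() == [1.0, 0.5]
        assert st.peak_sum.tolist() == [1, 5]

    def test_all_zero_matrix(self):
        st = compute_statistics(_cm(np.zeros((4, 3))))
        assert not st.lib_size.any() and not st.peak_sum.any()
        assert not st.nonzero_prop.any()

    def test_mass_conservation_on_random_fixture(self, rng):
        st = compute_statistics(_cm(rng.poisson(2.0, size=(30, 20))))
        assert st.lib_size.sum() == st.peak_sum.sum()

    def test_binarized_lib_size_counts_nonzeros(self, small_reference):
        cm = small_reference
        binar = CountMatrix(
            (cm.counts > 0).astype(np.int64), cm.peaks.copy(), cm.cells.copy(),
            binarized=True,
        )
        st = compute_statistics(binar)
        nnz = np.asarray((cm.counts > 0).sum(axis=0)).ravel()
        assert st.lib_size.tolist() == nnz.tolist()


class TestGmm2:
    def test_two_component_parameter_recovery(self, rng):
        comp = rng.random(5000) < 0.5
        data = np.where(comp, rng.normal(0, 1, 5000), rng.normal(6, 1, 5000))
        model = fit_gmm2(data)
        assert model.means[0] == pytest.approx(0.0, abs=0.15)
        assert model.means[1] == pytest.approx(6.0, abs=0.15)
        assert model.weights[0] == pytest.approx(0.5, abs=0.05)

    def test_single_cluster_means_stay_in_data_range(self, rng):
        data = rng.normal(3.0, 0.1, 200)
        model = fit_gmm2(data)
        assert data.min() <= model.means[0] <= model.means[1] <= data.max()

    def test_deterministic_for_fixed_inputs(self, rng):
        data = rng.normal(size=100)
        a, b = fit_gmm2(data), fit_gmm2(data)
        np.testing.assert_array_equal(a.means, b.means)

    def test_degenerate_data_rejected(self):
        with pytest.raises(FitError):
            fit_gmm2(np.full(50, 2.0))

    def test_sampler_matches_fitted_mixture(self, rng):
        comp = rng.random(4000) < 0.3
        data = np.where(comp, rng.normal(-2, 0.5, 4000), rng.normal(2, 0.5, 4000))
        model = fit_gmm2(data)
        samples = model.sample(10000, rng)
        assert scipy.stats.ks_2samp(samples, data).statistic < 0.03


class TestDiscreteFits:
    def test_logvariant_parameter_recovery(self):
        data = scipy.stats.logser.rvs(0.8, size=10000, random_state=1) - 1
        fit = fit_discrete(data, "logvariant")
        assert fit.params["p"] == pytest.approx(0.8, rel=0.02)

    def test_poisson_mle_is_sample_mean(self, rng):
        data = rng.poisson(4.0, size=500)
        fit = fit_discrete(data, "poisson")
        assert fit.params["lam"] == pytest.approx(data.mean())

    @pytest.mark.parametrize(
        "family", ["logvariant", "poisson", "negative_binomial", "geometric", "zipf"]
    )
    def test_pmf_normalizes_over_truncated_support(self, rng, family):
        data = rng.poisson(3.0, size=200) if family != "zipf" else rng.poisson(1.0, 200)
        fit = fit_discrete(data, family)
        support_cap = 20_000
        total = fit.pmf(np.arange(0, support_cap + 1)).sum()
        if family == "zipf":
            # power-law tail needs an analytic bound: sum_{k>K} k^-a / zeta(a)
            # <= K^(1-a) / ((a-1) zeta(a))
            a = fit.params["a"]
            tail = support_cap ** (1 - a) / ((a - 1) * scipy.special.zeta(a))
        else:
            tail = 0.0
        assert total <= 1 + 1e-9
        assert total + tail >= 1 - 1e-6

    def test_logvariant_mle_matches_grid_search(self):
        data = scipy.stats.logser.rvs(0.6, size=500, random_state=3) - 1
        fit = fit_discrete(data, "logvariant")
        grid = np.linspace(0.3, 0.9, 601)
        nll = [
            -scipy.stats.logser.logpmf(data + 1, p).sum() for p in grid
        ]
        assert fit.params["p"] == pytest.approx(grid[int(np.argmin(nll))], abs=1e-3)

    def test_unknown_family_rejected(self, rng):
        with pytest.raises(ParameterError):
            fit_discrete(rng.poisson(1.0, 100), "binomial")

    def test_logarithmic_requires_positive_support(self, rng):
        data = rng.poisson(2.0, size=100)
        data[0] = 0
        with pytest.raises(FitError):
            fit_discrete(data, "logarithmic")

    def test_sampling_follows_fitted_distribution(self, rng):
        data = scipy.stats.logser.rvs(0.7, size=2000, random_state=5) - 1
        fit = fit_discrete(data, "logvariant")
        draws = fit.sample(10000, rng)
        ecdf_grid = np.arange(0, draws.max() + 1)
        ecdf = np.searchsorted(np.sort(draws), ecdf_grid, side="right") / draws.size
        assert np.abs(ecdf - fit.cdf(ecdf_grid)).max() < 0.02


class TestSelectBestDiscrete:
    def test_poisson_data_selects_poisson(self, rng):
        data = rng.poisson(4.0, size=2000)
        best = select_best_discrete(data, ["poisson", "geometric"])
        assert best.family == "poisson"

    def test_single_candidate_returned(self, rng):
        best = select_best_discrete(rng.poisson(2.0, 100), ["poisson"])
        assert best.family == "poisson"

    def test_log_series_tail_beats_poisson(self):
        data = scipy.stats.logser.rvs(0.95, size=3000, random_state=2) - 1
        best = select_best_discrete(data, ["logvariant", "poisson"])
        assert best.family == "logvariant"

    def test_all_failures_aggregate(self, rng):
        data = rng.poisson(2.0, 100)
        data[0] = 0
        with pytest.raises(FitError, match="logarithmic"):
            select_best_discrete(data, ["logarithmic"])


class TestKde:
    def test_point_mass_data_warns_and_returns_constant(self, rng):
        with pytest.warns(UserWarning):
            sampler = fit_kde(np.full(20, 3.0))
        assert (sampler.sample(100, rng) == 3.0).all()

    def test_standard_normal_recovery(self, rng):
        sampler = fit_kde(rng.normal(size=5000))
        draws = sampler.sample(10000, rng)
        assert scipy.stats.kstest(draws, "norm").statistic < 0.03

    def test_domain_clamp_never_violated(self, rng):
        sampler = fit_kde(rng.uniform(0.9, 1.0, size=200), domain=(-np.inf, 0.0))
        assert sampler.sample(5000, rng).max() <= 0.0


class TestBuildStatModels:
    def test_pseudo_mode_one_entry_per_type(self, small_reference):
        models = build_stat_models(small_reference, "pseudo_cell_type")
        assert sorted(models.cell_types) == ["type0", "type1"]
        assert all(t.backend == "gmm2+discrete" for t in models.models.values())

    def test_global_mode_ignores_labels(self, small_reference):
        models = build_stat_models(
            small_reference, "discrete", labels=small_reference.cells["cell_type"]
        )
        assert list(models.models) == [models.GLOBAL]
        assert models.get().backend == "kde"

    def test_tiny_cell_type_raises_with_its_name(self, small_reference):
        labels = np.array(
            ["rare"] * 5 + ["common"] * (small_reference.ncell - 5)
        )
        with pytest.raises(FitError, match="rare"):
            build_stat_models(small_reference, "pseudo_cell_type", labels=labels)

    def test_library_model_round_trip(self, small_reference):
        models = build_stat_models(small_reference, "pseudo_cell_type")
        st = compute_statistics(small_reference)
        labels = small_reference.cells["cell_type"].to_numpy()
        for t in models.cell_types:
            draws = models.get(t).sample_lib(5000, np.random.default_rng(0))
            ref = st.lib_size[labels == t]
            assert scipy.stats.ks_2samp(np.log(draws), np.log(ref)).statistic < 0.08

    def test_proportion_sampler_respects_domain(self, small_reference):
        models = build_stat_models(small_reference, "discrete")
        draws = models.get().sample_prop(5000, np.random.default_rng(3))
        assert draws.max() <= 1.0 and draws.min() > 0.0

    def test_all_six_families_are_exposed(self):
        assert set(DISCRETE_FAMILIES) == {
            "logvariant", "poisson", "negative_binomial",
            "geometric", "zipf", "logarithmic",
        }
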