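import numpy as np
import pytest

from thznitro.chemometrics import cross_validate, feasible_components, loo_coefficient_matrix
from thznitro.synthetic import SimulationConfig, generate_spectra, true_informative_indices
from thznitro.variable_selection import (
    edf_schedule,
    ipls_interval_search,
    ipls_select,
    scars_select,
    uve_select,
)


def _planted_instance(seed, n=40, p_noise=45, p_signal=5):
    """p_signal columns collinear with y plus pure-noise columns."""
    rng = np.random.default_rng(seed)
    y = rng.normal(size=n)
    signal = y[:, None] * rng.uniform(0.5, 2.0, size=p_signal) + 0.05 * rng.normal(
        size=(n, p_signal)
    )
    noise = rng.normal(size=(n, p_noise))
    return np.hstack([signal, noise]), y


class TestUve:
    def test_planted_columns_recovered(self):
        X, y = _planted_instance(seed=0)
        res = uve_select(X, y, seed=0)
        assert set(range(5)) <= set(res.selected.tolist())
        assert np.sum(res.selected >= 5) <= 5

    def test_pure_noise_selects_almost_nothing(self):
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 40))
            y = rng.normal(size=30)
            res = uve_select(X, y, seed=seed)
            rates.append(res.selected.size / 40)
        assert np.mean(rates) <= 0.05

    def test_huge_threshold_factor_selects_nothing(self):
        X, y = _planted_instance(seed=1)
        res = uve_select(X, y, threshold_factor=1e12, seed=1)
        assert res.selected.size == 0

    def test_stability_matches_two_pass_oracle(self):
        X, y = _planted_instance(seed=2, n=12, p_noise=6, p_signal=2)
        res = uve_select(X, y, n_components=2, seed=2)
        rng = np.random.default_rng(2)
        noise = 1e-10 * rng.random(X.shape)
        L = loo_coefficient_matrix(np.hstack([X, noise]), y, 2)
        means, stds = L.mean(axis=0), L.std(axis=0)
        S = np.where(stds > 0, means / np.where(stds > 0, stds, 1.0), 0.0)
        np.testing.assert_allclose(res.stability, S[: X.shape[1]], rtol=1e-10)
        np.testing.assert_allclose(res.noise_stability, S[X.shape[1] :], rtol=1e-10)
        assert res.threshold == pytest.approx(np.max(np.abs(S[X.shape[1] :])))

    def test_selected_respect_threshold_invariant(self):
        X, y = _planted_instance(seed=3)
        res = uve_select(X, y, seed=3)
        assert np.all(np.abs(res.stability[res.selected]) > res.threshold)


class TestEdfSchedule:
    def test_endpoints(self):
        p, runs = 682, 50
        r = edf_schedule(p, runs)
        assert r[0] == pytest.approx((p - 1) / p)
        assert r[-1] == pytest.approx(2 / p)

    def test_monotone_decreasing(self):
        r = edf_schedule(100, 30)
        assert np.all(np.diff(r) < 0)

    def test_two_runs_endpoint_arithmetic(self):
        # with n_runs=2 the second (final) quota is the EDF endpoint ~2 variables
        r = edf_schedule(50, 2)
        assert round(r[-1] * 50) == 2


class TestScars:
    def test_planted_band_groups_recovered(self):
        # band-level recovery: the winning subset hits >=4 of the 5 planted
        # bands in >=80% of seeds (each band counted if any of its window
        # indices survives)
        cfg = SimulationConfig()
        f = cfg.frequency_grid()
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            data = generate_spectra(cfg, seed=seed)
            res = scars_select(data.power, data.nitrogen_pct, seed=seed)
            groups = sum(
                any(abs(f[i] - b) <= cfg.band_width_thz for i in res.selected)
                for b in cfg.informative_bands_thz
            )
            hits += groups >= 4
        assert hits >= 0.8 * n_seeds

    def test_subset_sizes_track_edf_schedule(self, small_world):
        cfg, data = small_world
        res = scars_select(data.power, data.nitrogen_pct, n_runs=20, seed=0)
        sizes = np.array([s.size for s in res.per_run_subsets])
        assert np.all(np.diff(sizes) <= 0)
        quotas = np.maximum(2, np.round(edf_schedule(data.n_frequencies, 20) * data.n_frequencies))
        np.testing.assert_array_equal(sizes, np.minimum(quotas, sizes[0]))

    def test_best_run_is_argmin_and_selected_matches(self, small_world):
        cfg, data = small_world
        res = scars_select(data.power, data.nitrogen_pct, n_runs=15, seed=1)
        assert res.best_run == int(np.argmin(res.per_run_rmsecv))
        np.testing.assert_array_equal(res.selected, res.per_run_subsets[res.best_run])

    def test_seed_determinism(self, small_world):
        cfg, data = small_world
        a = scars_select(data.power, data.nitrogen_pct, n_runs=10, seed=4)
        b = scars_select(data.power, data.nitrogen_pct, n_runs=10, seed=4)
        np.testing.assert_array_equal(a.selected, b.selected)
        np.testing.assert_allclose(a.per_run_rmsecv, b.per_run_rmsecv)

    def test_bad_mc_fraction_rejected(self, small_world):
        cfg, data = small_world
        with pytest.raises(ValueError):
            scars_select(data.power, data.nitrogen_pct, mc_fraction=1.5)


class TestIpls:
    def test_default_grid_interval_arithmetic(self, default_world):
        res = ipls_select(default_world.power, default_world.nitrogen_pct,
                          default_world.frequencies_thz, 22)
        assert all(b.size == 31 for b in res.interval_indices)
        assert res.interval_bounds_thz[11] == (0.6996, 0.7632)
        assert res.interval_bounds_thz[-1][1] == pytest.approx(1.4)

    def test_planted_interval_attains_minimum(self):
        # signal confined to one interval of an otherwise pure-noise grid
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 60))
        y = 2.0 + X[:, 24:30] @ np.full(6, 0.5) + 0.05 * rng.normal(size=40)
        freqs = np.linspace(0.01, 1.39, 60)
        res = ipls_select(X, y, freqs, 10, n_components=3)
        assert res.best_interval == 4  # indices 24..29 live in block 4

    def test_shuffled_response_gives_no_sharp_minimum(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 60))
        y = rng.permutation(np.linspace(1, 4, 40))
        res = ipls_select(X, y, np.linspace(0.01, 1.39, 60), 10, n_components=3)
        spread = res.per_interval_rmsecv.max() - res.per_interval_rmsecv.min()
        assert spread < 0.5 * res.per_interval_rmsecv.min()

    def test_invalid_interval_counts_rejected(self, small_world):
        cfg, data = small_world
        with pytest.raises(ValueError):
            ipls_select(data.power, data.nitrogen_pct, data.frequencies_thz, 1)
        with pytest.raises(ValueError):
            ipls_select(data.power, data.nitrogen_pct, data.frequencies_thz, 999)


class TestIplsIntervalSearch:
    def test_single_candidate_returned(self, small_world):
        cfg, data = small_world
        best, trace = ipls_interval_search(
            data.power, data.nitrogen_pct, data.frequencies_thz, (8, 8)
        )
        assert best == 8
        assert trace.shape == (1,)

    def test_trace_matches_independent_recomputation(self, small_world):
        cfg, data = small_world
        best, trace = ipls_interval_search(
            data.power, data.nitrogen_pct, data.frequencies_thz, (6, 10)
        )
        for k, n_int in enumerate(range(6, 11)):
            res = ipls_select(data.power, data.nitrogen_pct, data.frequencies_thz, n_int)
            assert trace[k] == pytest.approx(res.per_interval_rmsecv[res.best_interval])
        assert best == 6 + int(np.argmin(trace))

    def test_empty_range_rejected(self, small_world):
        cfg, data = small_world
        with pytest.raises(ValueError):
            ipls_interval_search(data.power, data.nitrogen_pct, data.frequencies_thz, (9, 5))
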