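"""Simulator contracts: determinism, refractoriness, count statistics, I/O."""

import math

import numpy as np
import pytest
from scipy import stats

from avacrit.models import (
    BrunelParams,
    SpikeRaster,
    SurrogateParams,
    ou_rate_path,
    read_raster,
    simulate_brunel,
    simulate_surrogate,
    write_raster,
)

from conftest import make_raster


class TestBrunel:
    def test_zero_drive_gives_empty_raster(self):
        params = BrunelParams(J=0.0, nu_ext_ratio=0.0)
        raster = simulate_brunel(params, 500.0, seed=3, v_init=params.v_reset)
        assert raster.n_events == 0

    def test_same_seed_is_bit_identical(self):
        a = simulate_brunel(BrunelParams(), 1000.0, seed=7)
        b = simulate_brunel(BrunelParams(), 1000.0, seed=7)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.units, b.units)

    def test_different_seeds_differ(self):
        a = simulate_brunel(BrunelParams(), 1000.0, seed=7)
        b = simulate_brunel(BrunelParams(), 1000.0, seed=8)
        assert a.n_events > 0 and b.n_events > 0
        assert a.n_events != b.n_events or not np.array_equal(a.times, b.times)

    def test_dt_larger_than_delay_rejected(self):
        with pytest.raises(ValueError, match="delay"):
            simulate_brunel(BrunelParams(delay=1.5), 100.0, dt=2.0, seed=0)

    def test_nonfinite_parameter_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            BrunelParams(J=float("nan"))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            BrunelParams(theta=5.0, v_reset=10.0)
        with pytest.raises(ValueError):
            BrunelParams(conn_prob=0.0)

    def test_refractory_period_respected(self):
        params = BrunelParams()
        raster = simulate_brunel(params, 5000.0, seed=11)
        assert raster.n_events > 100
        for unit in np.unique(raster.units)[:50]:
            t = raster.times[raster.units == unit]
            if t.size > 1:
                assert np.min(np.diff(t)) >= params.t_ref - 1e-9

    def test_step_halving_changes_rate_by_less_than_ten_percent(self):
        # self-consistency of the Euler integration: halving dt must not move
        # the population mean rate appreciably in the default regime
        params = BrunelParams()
        coarse = simulate_brunel(params, 20_000.0, dt=0.1, seed=5)
        fine = simulate_brunel(params, 20_000.0, dt=0.05, seed=5)
        assert coarse.mean_rate() > 0.1
        assert abs(fine.mean_rate() - coarse.mean_rate()) / coarse.mean_rate() < 0.10


class TestSurrogate:
    def test_constant_rate_total_count_is_poisson_mean(self):
        # ou_noise = 0 degenerates to a homogeneous Poisson population
        lam0, n_units, dur = 5.0, 20, 1000.0
        params = SurrogateParams(n_units=n_units, ou_mean=lam0, ou_noise=0.0)
        counts = [
            simulate_surrogate(params, dur, seed=s).n_events for s in range(100)
        ]
        expected = n_units * lam0 * dur * 1e-3
        se_of_mean = math.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se_of_mean

    def test_per_unit_counts_pass_poisson_gof(self):
        # chi-square goodness of fit at alpha=0.01 in >= 95 of 100 seeded runs
        lam0, n_units, dur = 5.0, 200, 5000.0
        params = SurrogateParams(n_units=n_units, ou_mean=lam0, ou_noise=0.0)
        mean_count = lam0 * dur * 1e-3
        passed = 0
        for seed in range(100):
            raster = simulate_surrogate(params, dur, seed=seed)
            counts = np.bincount(raster.units, minlength=n_units)
            kmax = int(stats.poisson.isf(1e-6, mean_count))
            edges = np.arange(kmax + 2)
            probs = stats.poisson.pmf(edges[:-1], mean_count)
            probs[-1] += stats.poisson.sf(kmax, mean_count)
            observed = np.bincount(np.clip(counts, 0, kmax), minlength=kmax + 1)
            expected = probs * n_units
            # merge low-expectation cells from both tails
            keep = expected >= 5
            obs = np.array([observed[~keep].sum(), *observed[keep]], dtype=float)
            exp = np.array([expected[~keep].sum(), *expected[keep]])
            p = stats.chisquare(obs, exp * obs.sum() / exp.sum()).pvalue
            passed += p > 0.01
        assert passed >= 95

    def test_ou_stationary_variance_matches_closed_form(self):
        noise, timescale = 0.3, 200.0
        rng = np.random.default_rng(1)
        path = ou_rate_path(5.0, timescale, noise, 2_000_000.0, 1.0, rng)
        target = noise**2 * timescale / 2.0
        assert abs(np.var(path) - target) / target < 0.10

    def test_rectification_keeps_rate_nonnegative(self):
        # an unrectified negative rate would make Poisson sampling blow up;
        # with ou_mean = 0 the latent path is negative half the time
        params = SurrogateParams(n_units=50, ou_mean=0.0, ou_timescale=100.0, ou_noise=2.0)
        raster = simulate_surrogate(params, 5000.0, seed=2)
        assert raster.n_events > 0
        assert np.all(raster.times >= 0)

    def test_randomized_coefficients_recorded_and_within_ranges(self):
        params = SurrogateParams()
        raster = simulate_surrogate(params, 1000.0, seed=9, randomize_coeffs=True)
        lo, hi = params.coeff_ranges["ou_mean"]
        assert lo <= raster.metadata["ou_mean"] <= hi
        lo, hi = params.coeff_ranges["ou_timescale"]
        assert lo <= raster.metadata["ou_timescale"] <= hi

    def test_empty_coeff_ranges_rejected(self):
        params = SurrogateParams(coeff_ranges={})
        with pytest.raises(ValueError, match="coeff_ranges"):
            simulate_surrogate(params, 1000.0, seed=0, randomize_coeffs=True)

    def test_deterministic_under_seed(self):
        a = simulate_surrogate(SurrogateParams(), 2000.0, seed=4, randomize_coeffs=True)
        b = simulate_surrogate(SurrogateParams(), 2000.0, seed=4, randomize_coeffs=True)
        assert np.array_equal(a.times, b.times)
        assert a.metadata == b.metadata


class TestRasterIO:
    def test_empty_raster_roundtrip(self, tmp_path):
        raster = make_raster([], [], n_units=5, t_end=100.0)
        path = tmp_path / "empty.csv"
        write_raster(raster, path)
        text = path.read_text()
        assert all(line.startswith("#") for line in text.splitlines())
        back = read_raster(path)
        assert back.n_events == 0
        assert back.n_units == 5
        assert back.t_end == 100.0

    def test_handwritten_three_event_file(self, tmp_path):
        path = tmp_path / "events.csv"
        path.write_text("# comment\n#n_units=2\n#t_end=10\n1.5,0\n2.0 1\n7.25,0\n")
        raster = read_raster(path)
        assert raster.events == [(1.5, 0), (2.0, 1), (7.25, 0)]

    def test_simulated_raster_roundtrip_exact(self, tmp_path, surrogate_raster):
        path = tmp_path / "r.csv"
        write_raster(surrogate_raster, path)
        back = read_raster(path)
        assert np.array_equal(back.times, surrogate_raster.times)
        assert np.array_equal(back.units, surrogate_raster.units)
        assert back.seed == surrogate_raster.seed

    def test_brunel_roundtrip_exact(self, tmp_path):
        raster = simulate_brunel(BrunelParams(), 2000.0, seed=1)
        path = tmp_path / "b.csv"
        write_raster(raster, path)
        back = read_raster(path)
        assert np.array_equal(back.times, raster.times)
        assert np.array_equal(back.units, raster.units)

    def test_malformed_line_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("1.0,0\noops\n")
        with pytest.raises(ValueError, match=":2"):
            read_raster(path)

    def test_negative_unit_rejected(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text("1.0,-3\n")
        with pytest.raises(ValueError, match="negative unit"):
            read_raster(path)


class TestSpikeRaster:
    def test_invariants(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            make_raster([2.0, 1.0], [0, 0], n_units=1, t_end=10.0)
        with pytest.raises(ValueError, match="unit ids"):
            make_raster([1.0], [5], n_units=2, t_end=10.0)
        with pytest.raises(ValueError):
            make_raster([11.0], [0], n_units=1, t_end=10.0)

    def test_subsample_remaps_and_preserves_counts(self, surrogate_raster):
        sub = surrogate_raster.subsample(10, seed=1)
        assert sub.n_units == 10
        assert sub.n_events <= surrogate_raster.n_events
        assert sub.units.max() < 10
        again = surrogate_raster.subsample(10, seed=1)
        assert np.array_equal(sub.times, again.times)
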