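"""Umbrella sampling: schedules, decorrelation, WHAM and bootstrap."""

import numpy as np
import pytest

from flexfes.constants import kt
from flexfes.toysim import (
    LangevinParams,
    PotentialSpec,
    RestraintSpec,
    basin_free_energy_difference,
    run_langevin,
    sample_harmonic_window,
)
from flexfes.umbrella import (
    AggregationError,
    BootstrapError,
    ConnectivityError,
    CVSeries,
    DegenerateSeriesError,
    ScheduleError,
    UmbrellaWindow,
    WHAM,
    aggregate_conformers,
    bootstrap_pmf,
    make_staged_equilibration,
    make_window_schedule,
    statistical_inefficiency,
    subsample,
    wham_from_histograms,
    wham_solve,
)

KT310 = kt(310.0)


def ar1(rho, n, seed):
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = 0.0
    eps = rng.standard_normal(n) * np.sqrt(1 - rho ** 2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return x


def harmonic_window_dataset(kappa, k, interval, n_windows, n, seed0):
    base = PotentialSpec.harmonic(kappa)
    windows = make_window_schedule(interval, n_windows, k)
    data = [
        sample_harmonic_window(base, RestraintSpec(w.center, k), n, seed=seed0 + i)
        for i, w in enumerate(windows)
    ]
    return windows, data


class TestWindowSchedule:
    def test_31_window_schedule(self):
        ws = make_window_schedule([2, 8], 31, 500.0)
        centers = np.array([w.center for w in ws])
        assert centers[0] == 2.0 and centers[-1] == 8.0
        assert np.allclose(np.diff(centers), 0.2)

    def test_two_windows_endpoints(self):
        ws = make_window_schedule([0, 1], 2, 1000.0)
        assert [w.center for w in ws] == [0.0, 1.0]

    def test_61_windows_spacing(self):
        ws = make_window_schedule([1, 7], 61, 1000.0)
        assert np.allclose(np.diff([w.center for w in ws]), 0.1)

    def test_too_few_windows(self):
        with pytest.raises(ScheduleError):
            make_window_schedule([0, 1], 1, 1000.0)


class TestStagedEquilibration:
    def test_default_total_duration(self):
        w = UmbrellaWindow(5.0, 1000.0)
        stages = make_staged_equilibration(w, start_center=2.0)
        assert len(stages) == 20
        assert sum(d for _, d in stages) == pytest.approx(50.0)
        assert stages[-1][0] == pytest.approx(5.0)

    def test_start_equals_target(self):
        w = UmbrellaWindow(3.0, 1000.0)
        stages = make_staged_equilibration(w, start_center=3.0, n_stages=5)
        assert all(c == pytest.approx(3.0) for c, _ in stages)

    def test_linear_interpolation_convention(self):
        w = UmbrellaWindow(3.0, 1000.0)
        stages = make_staged_equilibration(w, start_center=0.0, n_stages=4)
        assert [c for c, _ in stages] == pytest.approx([0.75, 1.5, 2.25, 3.0])


class TestStatisticalInefficiency:
    def test_iid_series(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        assert 0.9 <= statistical_inefficiency(x) <= 1.2

    @pytest.mark.parametrize("rho,target", [(0.9, 19.0), (0.5, 3.0)])
    def test_ar1_closed_form(self, rho, target):
        g = statistical_inefficiency(ar1(rho, 100_000, seed=1))
        assert g == pytest.approx(target, rel=0.15)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            statistical_inefficiency(np.ones(100))

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            statistical_inefficiency(np.arange(5.0))


class TestSubsample:
    def _series(self, values):
        return CVSeries(times=np.arange(len(values), dtype=float), values=values)

    def test_identity_at_g_one(self):
        s = self._series(np.arange(10.0))
        out = subsample(s, 1.0)
        assert np.array_equal(out.values, s.values)

    def test_stride_arithmetic(self):
        s = self._series(np.arange(10.0))
        out = subsample(s, 3.2)  # ceil -> 4
        assert np.array_equal(out.values, [0.0, 4.0, 8.0])

    def test_decorrelates_ar1(self):
        x = ar1(0.9, 100_000, seed=2)
        g = statistical_inefficiency(x)
        sub = subsample(self._series(x), g)
        assert 0.8 <= statistical_inefficiency(sub.values) <= 1.5


class TestAggregateConformers:
    def _window_series(self, windows, n, tag):
        return [
            CVSeries(
                times=np.arange(n, dtype=float),
                values=np.full(n, w.center),
                window=w,
                source=tag,
            )
            for w in windows
        ]

    def test_single_source_identity(self):
        ws = make_window_schedule([0, 1], 3, 100.0)
        pooled = aggregate_conformers([self._window_series(ws, 5, "a")])
        assert [len(p) for p in pooled] == [5, 5, 5]

    def test_27_sources_pool_counts(self):
        ws = make_window_schedule([0, 1], 4, 100.0)
        sources = [self._window_series(ws, 100, f"c{i}") for i in range(27)]
        pooled = aggregate_conformers(sources)
        assert all(len(p) == 2700 for p in pooled)

    def test_tags_are_union(self):
        ws = make_window_schedule([0, 1], 2, 100.0)
        pooled = aggregate_conformers(
            [self._window_series(ws, 3, "a"), self._window_series(ws, 3, "b")]
        )
        assert pooled[0].source == "a+b"

    def test_mismatched_schedules_rejected(self):
        ws1 = make_window_schedule([0, 1], 3, 100.0)
        ws2 = make_window_schedule([0, 1.1], 3, 100.0)
        with pytest.raises(AggregationError):
            aggregate_conformers(
                [self._window_series(ws1, 3, "a"), self._window_series(ws2, 3, "b")]
            )


class TestWHAM:
    def test_flat_potential_single_unbiased_window(self):
        rng = np.random.default_rng(3)
        n = 40_000
        s = CVSeries(
            times=np.arange(n, dtype=float),
            values=rng.uniform(0, 1, n),
            window=UmbrellaWindow(0.5, 0.0),
        )
        res = wham_solve([s.window], [s], [0, 1], n_bins=20)
        # binomial histogram noise on F: kT * sigma_n / n per bin
        noise = KT310 / 4.184 * np.sqrt(20 / n)
        assert res.free_energy.max() <= 3 * noise * 2 + 1e-9

    def test_harmonic_oracle_rms(self):
        # overlapping windows; exact Gaussian samples; analytic PMF 1/2 kappa x^2
        kappa, k = 10.0, 100.0
        windows, data = harmonic_window_dataset(kappa, k, [-2, 2], 15, 5000, seed0=10)
        res = wham_solve(windows, data, [-2, 2], n_bins=40)
        c, fe = res.bin_centers[4:36], res.free_energy[4:36]
        an = 0.5 * kappa * c ** 2 / 4.184
        rms = np.sqrt(np.mean((fe - fe.min() - (an - an.min())) ** 2))
        assert rms <= 0.1

    def test_minimum_is_exactly_zero_and_grid_arithmetic(self):
        windows, data = harmonic_window_dataset(10.0, 100.0, [-1, 1], 9, 2000, seed0=20)
        res = wham_solve(windows, data, [-1, 1], n_bins=20)
        assert res.free_energy.min() == 0.0
        assert np.allclose(np.diff(res.bin_centers), 0.1)
        assert res.bin_centers[0] == pytest.approx(-0.95)

    def test_invariant_to_additive_bias_constant(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 50, size=(4, 12)).astype(float)
        bias = rng.uniform(0, 5, size=(4, 12))
        fe1, _, _, _, _ = wham_from_histograms(counts, bias, 310.0)
        bias2 = bias.copy()
        bias2[2] += 7.3  # constant offset on one window's bias
        fe2, _, _, _, _ = wham_from_histograms(counts, bias2, 310.0)
        assert np.allclose(fe1, fe2, atol=1e-6)

    def test_invariant_to_window_relabeling(self):
        windows, data = harmonic_window_dataset(10.0, 100.0, [-1, 1], 7, 2000, seed0=30)
        res = wham_solve(windows, data, [-1, 1], n_bins=20)
        order = [3, 0, 6, 1, 5, 2, 4]
        res_shuf = wham_solve(
            [windows[i] for i in order], [data[i] for i in order], [-1, 1], n_bins=20
        )
        assert np.allclose(res.free_energy, res_shuf.free_energy, atol=1e-9)

    def test_halving_tolerance_does_not_worsen_fit(self):
        kappa, k = 10.0, 100.0
        windows, data = harmonic_window_dataset(kappa, k, [-2, 2], 15, 3000, seed0=40)

        def rms(tol):
            res = wham_solve(windows, data, [-2, 2], n_bins=40, tolerance=tol)
            c, fe = res.bin_centers[4:36], res.free_energy[4:36]
            an = 0.5 * kappa * c ** 2 / 4.184
            return np.sqrt(np.mean((fe - fe.min() - (an - an.min())) ** 2))

        tol = 1e-4
        assert rms(tol / 2) <= rms(tol) + tol

    def test_langevin_double_well_barrier(self):
        h = 4 * KT310
        pot = PotentialSpec.double_well(h, 0.4)
        windows = make_window_schedule([-0.7, 0.7], 25, 1000.0)
        data = []
        for i, w in enumerate(windows):
            s = run_langevin(
                pot,
                restraints=[RestraintSpec(w.center, w.force_constant)],
                params=LangevinParams(timestep=1e-5, n_steps=50_000, seed=100 + i),
                x0=w.center,
                save_every=10,
            )
            s.window = w
            data.append(subsample(s, statistical_inefficiency(s)))
        res = wham_solve(windows, data, [-0.7, 0.7], n_bins=40)
        c, fe = res.bin_centers, res.free_energy
        barrier = fe[np.abs(c) < 0.2].max() - fe.min()
        assert barrier == pytest.approx(h / 4.184, rel=0.10)

    def test_gap_raises_connectivity_error(self):
        base = PotentialSpec.harmonic(10.0)
        w1 = UmbrellaWindow(-1.5, 1000.0)
        w2 = UmbrellaWindow(1.5, 1000.0)  # far apart, no overlap
        data = [
            sample_harmonic_window(base, RestraintSpec(w.center, 1000.0), 500, seed=i)
            for i, w in enumerate([w1, w2])
        ]
        with pytest.raises(ConnectivityError, match="gap"):
            wham_solve([w1, w2], data, [-2, 2], n_bins=20)

    def test_window_without_samples_in_range(self):
        base = PotentialSpec.harmonic(10.0)
        w = UmbrellaWindow(5.0, 1000.0)
        data = [sample_harmonic_window(base, RestraintSpec(5.0, 1000.0), 100, seed=0)]
        with pytest.raises(ConnectivityError, match="no.*samples"):
            wham_solve([w], data, [-1, 1], n_bins=10)

    def test_unconverged_flagged_not_silent(self):
        windows, data = harmonic_window_dataset(10.0, 100.0, [-1, 1], 5, 500, seed0=50)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            est = WHAM(cv_range=[-1, 1], n_bins=10, tolerance=1e-13,
                       max_iterations=2).fit(data, windows=windows)
        assert est.converged_ is False

    def test_out_of_range_samples_dropped_and_counted(self):
        # sampling range wider than the analysis range: edge-window tails
        # fall outside and are dropped, not silently binned
        windows, data = harmonic_window_dataset(10.0, 100.0, [-2, 2], 9, 2000, seed0=60)
        est = WHAM(cv_range=[-1.8, 1.8], n_bins=20).fit(data, windows=windows)
        assert est.n_dropped_ > 0
        assert est.counts_.sum() + est.n_dropped_ == 9 * 2000


class TestBootstrap:
    def test_single_trial_degenerate_ci(self):
        windows, data = harmonic_window_dataset(10.0, 100.0, [-1, 1], 7, 2000, seed0=70)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = bootstrap_pmf(windows, data, [-1, 1], n_bins=20, n_trials=1, seed=0)
        finite = np.isfinite(res.free_energy)
        width = res.ci_high[finite] - res.ci_low[finite]
        assert np.all(width <= 1e-12)

    def test_ci_brackets_point_estimate(self):
        windows, data = harmonic_window_dataset(10.0, 100.0, [-1, 1], 7, 2000, seed0=80)
        res = bootstrap_pmf(windows, data, [-1, 1], n_bins=20, n_trials=30, seed=1)
        finite = np.isfinite(res.free_energy)
        assert np.all(res.ci_low[finite] <= res.free_energy[finite] + 1e-12)
        assert np.all(res.ci_high[finite] >= res.free_energy[finite] - 1e-12)

    def test_coverage_of_analytic_pmf(self):
        # study-density windows (spacing ~2.6 window widths); per-bin
        # coverage fluctuates dataset to dataset, so assert the median over
        # independent datasets
        kappa, k = 10.0, 1000.0
        covs = []
        for s in range(4):
            windows, data = harmonic_window_dataset(
                kappa, k, [-2, 2], 31, 2000, seed0=500 * s + 7
            )
            res = bootstrap_pmf(windows, data, [-2, 2], n_bins=40, n_trials=60, seed=2)
            sl = slice(4, 36)
            an = 0.5 * kappa * res.bin_centers[sl] ** 2 / 4.184
            an = an - an.min()
            inside = (res.ci_low[sl] - 1e-9 <= an) & (an <= res.ci_high[sl] + 1e-9)
            covs.append(inside.mean())
        assert np.median(covs) >= 0.90

    def test_more_data_shrinks_ci(self):
        kappa, k = 10.0, 100.0
        med = {}
        for n in (400, 1600):
            widths = []
            for seed in range(5):
                windows, data = harmonic_window_dataset(
                    kappa, k, [-1, 1], 9, n, seed0=1000 * seed
                )
                res = bootstrap_pmf(
                    windows, data, [-1, 1], n_bins=20, n_trials=40, seed=seed
                )
                finite = np.isfinite(res.free_energy)
                widths.append(np.median(res.ci_high[finite] - res.ci_low[finite]))
            med[n] = np.median(widths)
        assert med[1600] < med[400]

    def test_determinism_under_seed(self):
        windows, data = harmonic_window_dataset(10.0, 100.0, [-1, 1], 7, 1000, seed0=95)
        a = bootstrap_pmf(windows, data, [-1, 1], n_bins=20, n_trials=20, seed=5)
        b = bootstrap_pmf(windows, data, [-1, 1], n_bins=20, n_trials=20, seed=5)
        assert np.array_equal(a.ci_low, b.ci_low)
        assert np.array_equal(a.ci_high, b.ci_high)


class TestFullPipelineRecovery:
    def test_tilted_double_well_free_energy_difference(self):
        """Schedule -> staged equilibration -> sampling -> subsample ->
        aggregate over 3 synthetic conformers -> WHAM, recovering the basin
        free-energy difference of a tilted double well."""
        h = 4 * KT310
        pot = PotentialSpec.tilted_double_well(h, 0.4, 5.0)
        windows = make_window_schedule([-0.7, 0.7], 25, 1000.0)
        per_source = []
        for c in range(3):
            series = []
            for i, w in enumerate(windows):
                stages = make_staged_equilibration(w, -0.4, n_stages=5)
                x = -0.4
                for j, (center, _) in enumerate(stages):
                    s = run_langevin(
                        pot,
                        restraints=[RestraintSpec(center, w.force_constant)],
                        params=LangevinParams(
                            timestep=1e-5, n_steps=500, seed=90_000 + 100 * c + 10 * i + j
                        ),
                        x0=x,
                        save_every=500,
                    )
                    x = float(s.values[-1])
                prod = run_langevin(
                    pot,
                    restraints=[RestraintSpec(w.center, w.force_constant)],
                    params=LangevinParams(
                        timestep=1e-5, n_steps=40_000, seed=80_000 + 100 * c + i
                    ),
                    x0=x,
                    save_every=10,
                )
                prod.window = w
                prod.source = f"conf{c}"
                series.append(subsample(prod, statistical_inefficiency(prod)))
            per_source.append(series)
        pooled = aggregate_conformers(per_source)
        res = wham_solve(windows, pooled, [-0.7, 0.7], n_bins=40)
        c_, fe = res.bin_centers, res.free_energy
        xs = np.linspace(-0.2, 0.2, 2001)
        split = xs[np.argmax(pot.energy(xs))]
        p = np.exp(-fe * 4.184 / KT310)
        dF = -KT310 * np.log(p[c_ > split].sum() / p[c_ < split].sum()) / 4.184
        dF_an = basin_free_energy_difference(pot) / 4.184
        assert dF == pytest.approx(dF_an, abs=0.5)  # kcal/mol
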