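"""Tribology pipeline: signal preprocessing, friction and lubrication
numbers, regressions, Stribeck surfaces and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cartifls as cf
from cartifls.friction import (
    GROUPS,
    FrictionSeries,
    LiftoffOptions,
    RecordRejected,
    TribologyRecord,
    _merge_intervals,
    build_stribeck_surface,
    compute_cof,
    group_stats,
    kinematics,
    linear_regression,
    mu_ifls_analysis,
    preprocess_signals,
)


def make_record(duration=600.0, fs=10.0, force=30.0, torque=0.007,
                dips=(), group="healthy-saline", noise=0.0, seed=0):
    t = np.arange(0.0, duration, 1.0 / fs)
    rng = np.random.default_rng(seed)
    f = np.full_like(t, force) + noise * rng.standard_normal(len(t))
    tau = np.full_like(t, torque) + noise * 1e-4 * rng.standard_normal(len(t))
    for a, b in dips:
        w = (t >= a) & (t < b)
        f[w] = 0.5
    return TribologyRecord(
        time=t, axial_force=f, axial_displacement=np.zeros_like(t),
        torque=tau, plug_radius=3.5, pair_thicknesses=(1.7, 1.7),
        angular_velocity=36.0, lubricant_name="saline",
        lubricant_viscosity=0.9, group=group)


class TestPreprocess:
    def test_ten_second_dips_each_excluded_once(self):
        rec = make_record(dips=[(100.0, 110.0), (300.0, 310.0)])
        _, intervals = preprocess_signals(rec, window_s=10.0)
        assert len(intervals) == 2
        (a1, b1), (a2, b2) = intervals
        # dip +- guard band
        assert a1 == pytest.approx(98.0, abs=0.21)
        assert b1 == pytest.approx(112.0, abs=0.21)

    def test_constant_torque_preserved_by_filter(self):
        rec = make_record(torque=0.005)
        tau_f, _ = preprocess_signals(rec)
        assert np.allclose(tau_f, 0.005)

    def test_single_spike_attenuated_by_window(self):
        rec = make_record(torque=0.005)
        rec.torque[3000] += 0.1   # single-sample spike
        tau_f, _ = preprocess_signals(rec, window_s=10.0)
        # centered moving average spreads the spike over window_s * rate
        bound = 0.1 / (10.0 * rec.sampling_rate) + 1e-12
        assert np.nanmax(np.abs(tau_f - 0.005)) <= bound

    def test_short_dips_not_excluded(self):
        rec = make_record(dips=[(100.0, 102.0)])   # 2 s < min_duration
        _, intervals = preprocess_signals(rec)
        assert intervals == []

    def test_mostly_unloaded_record_rejected(self):
        rec = make_record(duration=100.0, dips=[(10.0, 95.0)])
        with pytest.raises(RecordRejected):
            preprocess_signals(rec)

    def test_exclusion_bookkeeping_no_overlap_and_complete(self):
        rec = make_record(dips=[(100.0, 110.0), (108.0, 120.0)])
        tau_f, intervals = preprocess_signals(rec)
        for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
            assert b1 < a2
        mask = np.zeros(len(rec.time), dtype=bool)
        for a, b in intervals:
            mask |= (rec.time >= a) & (rec.time <= b)
        # retained + excluded = total
        assert mask.sum() + np.isfinite(tau_f).sum() == len(rec.time)

    def test_merge_intervals(self):
        assert _merge_intervals([(3, 5), (1, 2), (4, 7)]) == [(1, 2), (3, 7)]


class TestComputeCof:
    def test_zero_torque_gives_zero(self):
        assert compute_cof(0.0, 30.0, 0.0035) == 0.0

    def test_printed_arithmetic(self):
        # mu = 1.5 * 0.007 / (30 * 0.0035) = 0.10
        assert compute_cof(0.007, 30.0, 0.0035) == pytest.approx(0.10)

    def test_linear_in_torque(self):
        assert compute_cof(0.014, 30.0, 0.0035) == pytest.approx(
            2.0 * compute_cof(0.007, 30.0, 0.0035))

    def test_unit_system_invariance(self):
        # N*m with r in m equals N*mm with r in mm
        mu_si = compute_cof(0.007, 30.0, 0.0035)
        mu_mm = compute_cof(0.007 * 1e3, 30.0, 3.5)
        assert mu_si == pytest.approx(mu_mm, rel=1e-12)

    def test_nonpositive_load_detected(self):
        with pytest.raises(ValueError):
            compute_cof(np.array([0.005, 0.005]), np.array([30.0, -1.0]),
                        0.0035)


class TestKinematics:
    @pytest.mark.parametrize("omega,v_expected", [
        (36.0, 1.5), (108.0, 4.4), (360.0, 15.0), (1080.0, 44.0)])
    def test_effective_velocities(self, omega, v_expected):
        v, _ = kinematics(omega, 3.5, 3.5, 0.78)
        assert v == pytest.approx(v_expected, rel=0.03)

    @pytest.mark.parametrize("v_nominal,H_expected", [
        (1.5, 8.1e-10), (4.4, 2.4e-9), (15.0, 8.1e-9), (44.0, 2.4e-8)])
    def test_hersey_numbers_reproduce_study_values(self, v_nominal,
                                                   H_expected):
        # same convention must reproduce all four printed values; the
        # nominal velocities imply omega = v / r_eff
        omega = np.rad2deg(v_nominal / ((2 / 3) * 3.5))
        _, H = kinematics(omega, 3.5, 3.5, 0.78)
        assert H == pytest.approx(H_expected, rel=0.02)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            kinematics(36.0, 3.5, 3.5, 0.78, convention="bogus")

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            kinematics(-36.0, 3.5, 3.5, 0.78)


class TestIflsSeries:
    def test_limits_and_clipping(self, healthy_solution):
        ifls, strain = cf.compute_ifls_series(healthy_solution, 0.78)
        assert np.all((0.0 <= ifls) & (ifls <= 1.0))
        assert len(strain) == len(healthy_solution.times)
        # POR = 0 at t = 0 -> IFLS = 0
        assert ifls[0] == 0.0

    def test_interpolation_grid(self, healthy_solution):
        tt = np.array([1.0, 10.0, 100.0])
        ifls, strain = cf.compute_ifls_series(healthy_solution, 0.78,
                                              at_times=tt)
        assert len(ifls) == 3 and len(strain) == 3

    def test_extrapolation_rejected(self, healthy_solution):
        with pytest.raises(ValueError):
            cf.compute_ifls_series(healthy_solution, 0.78,
                                   at_times=np.array([1e9]))


class TestLinearRegression:
    def test_exact_line_recovered(self):
        x = np.linspace(0.0, 1.0, 50)
        y = -0.15 * x + 0.11
        reg = linear_regression(x, y)
        assert reg.slope == pytest.approx(-0.15, abs=1e-12)
        assert reg.intercept == pytest.approx(0.11, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_y_convention(self):
        reg = linear_regression(np.linspace(0, 1, 20), np.full(20, 0.06))
        assert reg.slope == 0.0
        assert reg.intercept == 0.06
        assert reg.r_squared == 0.0

    def test_constant_x_degenerate(self):
        with pytest.raises(ValueError):
            linear_regression(np.ones(10), np.arange(10.0))

    def test_two_sigma_coverage_monte_carlo(self):
        """Slope lies within 2 standard errors of truth at close to the
        nominal 95.4% rate (500 seeded replicates; the asserted band is
        the nominal rate +- 2.6 binomial standard deviations)."""
        rng = np.random.default_rng(0)
        cover = 0
        for _ in range(500):
            x = rng.uniform(0, 1, 200)
            y = -0.15 * x + 0.11 + 0.02 * rng.standard_normal(200)
            reg = linear_regression(x, y)
            if abs(reg.slope + 0.15) <= 2.0 * reg.slope_sd:
                cover += 1
        assert 0.93 <= cover / 500 <= 0.98


class TestMuIflsAnalysis:
    def _series(self, mu, t=None):
        t = np.arange(len(mu)) * 0.1 if t is None else t
        return FrictionSeries(time=t, mu=mu, excluded_intervals=[],
                              v_eff=1.5, hersey=8.1e-10)

    def test_constant_mu_gives_zero_slope(self):
        n = 500
        ifls = np.linspace(0.9, 0.0, n)
        fs = self._series(np.full(n, 0.06))
        reg, _, _ = mu_ifls_analysis(fs, ifls, np.linspace(0.1, 0.35, n))
        assert reg.slope == 0.0
        assert reg.intercept == pytest.approx(0.06)

    def test_synthetic_law_recovered_within_three_se(self):
        rng = np.random.default_rng(5)
        n = 3000
        ifls = np.linspace(0.7, 0.0, n)
        mu = -0.15 * ifls + 0.11 + 0.003 * rng.standard_normal(n)
        fs = self._series(mu)
        reg, _, _ = mu_ifls_analysis(fs, ifls, 0.33 - 0.29 * ifls)
        assert abs(reg.slope + 0.15) <= 3.0 * reg.slope_sd
        assert abs(reg.intercept - 0.11) <= 3.0 * reg.intercept_sd

    def test_quadratic_term_reduces_linear_fit_quality(self):
        rng = np.random.default_rng(6)
        n = 3000
        ifls = np.linspace(0.7, 0.0, n)
        noise = 0.001 * rng.standard_normal(n)
        healthy = -0.15 * ifls + 0.11 + noise
        degraded = -0.15 * ifls + 0.11 + 0.03 * ifls**2 + noise
        r_h, _, _ = mu_ifls_analysis(self._series(healthy), ifls, ifls)
        r_d, _, _ = mu_ifls_analysis(self._series(degraded), ifls, ifls)
        assert r_h.r_squared > r_d.r_squared

    def test_slope_sign_matches_spearman_sign(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = 400
            ifls = np.sort(rng.uniform(0, 1, n))[::-1]
            mu = np.sort(rng.uniform(0.02, 0.1, n))  # monotone increasing
            fs = self._series(mu)
            reg, _, _ = mu_ifls_analysis(fs, ifls, ifls)
            rho = stats.spearmanr(ifls, mu).statistic
            assert np.sign(reg.slope) == np.sign(rho)

    def test_mismatched_lengths_rejected(self):
        fs = self._series(np.full(10, 0.05))
        with pytest.raises(ValueError):
            mu_ifls_analysis(fs, np.zeros(5), np.zeros(10))


class TestStribeck:
    def _regs(self):
        table = [(8.1e-10, (-0.15, 0.11)), (2.4e-9, (-0.14, 0.10)),
                 (8.1e-9, (-0.08, 0.06)), (2.4e-8, (-0.07, 0.06))]
        return [(h, cf.RegressionResult(s, i, 0.999, 0.01, 0.01, 100,
                                        "mu_vs_ifls"))
                for h, (s, i) in table]

    def test_surface_reproduces_source_regression_at_knot(self):
        surf = build_stribeck_surface(self._regs())
        for h, reg in surf.sources:
            mu = surf.evaluate(surf.ifls_grid, np.full_like(surf.ifls_grid,
                                                            h))
            assert np.allclose(mu, reg.predict(surf.ifls_grid), atol=1e-12)

    def test_identical_regressions_give_constant_surface(self):
        reg = cf.RegressionResult(-0.1, 0.08, 1.0, 0.0, 0.0, 10, "")
        surf = build_stribeck_surface([(1e-9, reg), (1e-8, reg)])
        assert np.allclose(surf.mu[:, 0], surf.mu[:, 1])

    def test_negative_ifls_gradient_everywhere(self):
        surf = build_stribeck_surface(self._regs())
        dmu = np.diff(surf.mu, axis=0)
        assert np.all(dmu < 0)

    def test_duplicate_hersey_collapsed_with_warning(self):
        regs = self._regs()
        regs.append(regs[0])
        with pytest.warns(UserWarning):
            surf = build_stribeck_surface(regs)
        assert len(surf.sources) == 4

    def test_fewer_than_two_velocities_rejected(self):
        with pytest.raises(ValueError):
            build_stribeck_surface(self._regs()[:1])


class TestGroupStats:
    def _table(self, n_pairs=5, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in GROUPS:
            shift = effect if g.startswith("degraded") else 0.0
            for p in range(n_pairs):
                E_nf = 0.3 * np.exp(0.1 * rng.standard_normal()) - shift * 0.1
                for v in (1.5, 4.4, 15.0, 44.0):
                    rows.append({
                        "sample_id": f"{g}_{p}", "group": g, "v_eff": v,
                        "mu_0": 0.08 + shift + 0.01 * rng.standard_normal(),
                        "mu_ifls": -0.1 + shift
                        + 0.01 * rng.standard_normal(),
                        "eps0": 0.34 + shift + 0.02 * rng.standard_normal(),
                        "E_nf": E_nf,
                    })
        return pd.DataFrame(rows)

    def test_slowest_velocity_excluded_from_group_comparison(self):
        rep = group_stats(self._table(), ["mu_0"])
        assert rep.excluded_conditions[0]["condition"] == "v_eff == 1.5"
        assert rep.kruskal_wallis["mu_0"]["n_per_group"] == [15, 15, 15, 15]

    def test_perfect_correlation_detected(self):
        df = self._table()
        df["mu_0"] = 2.0 * df["E_nf"] + 1.0
        rep = group_stats(df, ["mu_0"])
        assert rep.pearson["E_nf_vs_mu_0"]["r"] == pytest.approx(1.0)

    def test_identical_velocity_blocks_give_zero_friedman(self):
        df = self._table()
        df["mu_0"] = df.groupby("sample_id")["mu_0"].transform("first")
        rep = group_stats(df, ["mu_0"])
        assert rep.friedman["mu_0"]["statistic"] == 0.0

    def test_group_effect_detected_at_large_n(self):
        rep = group_stats(self._table(n_pairs=20, effect=0.05), ["mu_0"])
        assert rep.kruskal_wallis["mu_0"]["p_value"] < 0.05

    def test_small_groups_skipped(self):
        df = self._table(n_pairs=1)
        df = df[df["group"] == "healthy-saline"]
        rep = group_stats(df, ["mu_0"])
        assert any(s["test"] == "kruskal_wallis" for s in rep.skipped)

    def test_report_round_trips_to_json(self, tmp_path):
        rep = group_stats(self._table(), ["mu_0", "mu_ifls"])
        path = tmp_path / "stats.json"
        rep.to_json(path)
        import json
        loaded = json.loads(path.read_text())
        assert "kruskal_wallis" in loaded

    def test_kruskal_wallis_type_one_error_calibrated(self):
        """Null simulations: two groups from one distribution, n = 20,
        1000 replicates -> rejection rate 5% +- 1.5%."""
        rng = np.random.default_rng(0)
        rej = 0
        for _ in range(1000):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            if stats.kruskal(a, b).pvalue < 0.05:
                rej += 1
        assert 0.035 <= rej / 1000 <= 0.065


class TestRecordValidation:
    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 0.1, 0.3])
        with pytest.raises(ValueError):
            TribologyRecord(time=t, axial_force=np.ones(3),
                            axial_displacement=np.zeros(3),
                            torque=np.zeros(3), plug_radius=3.5,
                            pair_thicknesses=(1.7, 1.7),
                            angular_velocity=36.0, lubricant_name="saline",
                            lubricant_viscosity=0.9,
                            group="healthy-saline")

    def test_unknown_group_rejected(self):
        rec = make_record()
        with pytest.raises(ValueError):
            TribologyRecord(
                time=rec.time, axial_force=rec.axial_force,
                axial_displacement=rec.axial_displacement,
                torque=rec.torque, plug_radius=3.5,
                pair_thicknesses=(1.7, 1.7), angular_velocity=36.0,
                lubricant_name="saline", lubricant_viscosity=0.9,
                group="mystery")

    def test_csv_round_trip(self, tmp_path):
        rec = make_record(duration=10.0)
        path = tmp_path / "rec.csv"
        cf.write_record(rec, path)
        back = cf.read_record(path)
        assert np.allclose(back.torque, rec.torque)
        assert back.group == rec.group
        assert back.pair_thicknesses == rec.pair_thicknesses


class TestDeterminism:
    def test_identical_record_gives_identical_report(self):
        rec = make_record(dips=[(100.0, 110.0)], noise=0.05, seed=3)
        out = []
        for _ in range(2):
            tau_f, intervals = preprocess_signals(rec)
            load = rec.axial_force.copy()
            load[~np.isfinite(tau_f)] = np.nan
            mu = compute_cof(tau_f, load, rec.plug_radius * 1e-3)
            out.append((tau_f, intervals, mu))
        assert np.array_equal(out[0][0], out[1][0], equal_nan=True)
        assert out[0][1] == out[1][1]
        assert np.array_equal(out[0][2], out[1][2], equal_nan=True)
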