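"""Simulator: closed-form growth model, noise models, feature tables."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import fermprof as fp
from fermprof.gas import compute_cer
from fermprof.simulate import (
    M_CO2,
    cer_g_per_l_h,
    recovery_config,
    simulate_stage_series,
    _Trajectory,
)

#: standard atomic masses for the independent formula-mass oracle
ATOMIC = {"C": 12.0, "H": 1.00782503207, "O": 15.99491461956, "Cl": 34.96885268}


class TestGrowthModel:
    def test_dryweight_ratio_forced_by_exponential_model(self, make_noise_free_config):
        cfg = make_noise_free_config(
            mu_max=0.2, lag_h=15.0, dw_times_h=(20.0, 25.0), duration_h=30.0
        )
        run, _ = fp.simulate_run(cfg, 0)
        ratio = run.samples.dw_g_l[1] / run.samples.dw_g_l[0]
        assert ratio == pytest.approx(math.exp(0.2 * 5), rel=1e-12)

    def test_exhaustion_time_closed_form_and_ode_oracle(self, make_noise_free_config):
        cfg = make_noise_free_config(mu_max=0.2, x0=0.01, s0=15.0, y_sx=0.5)
        _, truth = fp.simulate_run(cfg, 0)
        closed = cfg.lag_h + math.log(1 + cfg.y_sx * cfg.s0 / cfg.x0) / cfg.mu_max
        assert truth.t_exhaust_h == pytest.approx(closed, rel=1e-12)

        # independent fine-step ODE integration of dX/dt = mu X until S = 0
        def rhs(t, y):
            return [cfg.mu_max * y[0] if t >= cfg.lag_h else 0.0]

        def exhausted(t, y):
            return cfg.s0 - (y[0] - cfg.x0) / cfg.y_sx

        exhausted.terminal = True
        exhausted.direction = -1
        sol = solve_ivp(
            rhs, (0, 200), [cfg.x0], events=exhausted, rtol=1e-10, atol=1e-12,
            max_step=0.1,
        )
        assert sol.t_events[0][0] == pytest.approx(closed, rel=1e-6)
        assert truth.t_exhaust_h == pytest.approx(sol.t_events[0][0], rel=1e-6)

    def test_mass_balance_during_growth(self, make_noise_free_config):
        cfg = make_noise_free_config()
        run, truth = fp.simulate_run(cfg, 0)
        t = run.samples.dw_time_h
        grow = (t > truth.lag_h) & (t < truth.t_exhaust_h)
        gained = run.samples.dw_g_l[grow] - cfg.x0
        consumed = cfg.s0 - run.samples.glucose_g_l[grow]
        assert np.allclose(gained / consumed, cfg.y_sx, rtol=1e-6)

    def test_monotonicity(self, make_noise_free_config):
        run, _ = fp.simulate_run(make_noise_free_config(t_pellet_h=30.0), 0)
        assert np.all(np.diff(run.samples.dw_g_l) >= 0)
        assert np.all(np.diff(run.samples.glucose_g_l) <= 0)

    def test_no_transition_means_no_nonexponential_phase(self, noise_free_run):
        _, truth = noise_free_run
        assert truth.t_pellet_h is None
        assert truth.nonexp_duration_h == 0.0

    def test_transition_before_lag_rejected(self):
        with pytest.raises(ValueError):
            fp.SimulationConfig(t_pellet_h=3.0, lag_h=8.0)

    def test_invalid_yield_rejected(self):
        with pytest.raises(ValueError):
            fp.SimulationConfig(y_sx=2.0)


class TestGasReconstruction:
    def test_cer_round_trip_within_one_percent(self, make_noise_free_config):
        cfg = make_noise_free_config()
        run, truth = fp.simulate_run(cfg, 0)
        cer = compute_cer(run.offgas, inlet_co2_pct=cfg.inlet_co2_pct)
        traj = _Trajectory.solve(cfg, truth.mu_per_h, truth.lag_h)
        configured = cer_g_per_l_h(traj, run.offgas.time_h, cfg) / M_CO2 * 1e3
        sel = configured > 0.05 * configured.max()
        assert np.allclose(cer.cer[sel], configured[sel], rtol=1e-6)

    def test_accumulated_co2_closure(self, make_noise_free_config):
        # gas-balance closure: integral of recovered CER vs configured CER
        cfg = make_noise_free_config()
        run, truth = fp.simulate_run(cfg, 0)
        cer = compute_cer(run.offgas, inlet_co2_pct=cfg.inlet_co2_pct)
        traj = _Trajectory.solve(cfg, truth.mu_per_h, truth.lag_h)
        t_fine = np.linspace(0, run.offgas.time_h[-1], 200_001)
        ref = np.trapezoid(cer_g_per_l_h(traj, t_fine, cfg) / M_CO2 * 1e3, t_fine)
        assert cer.acc_co2[-1] == pytest.approx(ref, rel=0.01)


class TestReplication:
    def test_deterministic_byte_identical(self, make_noise_free_config):
        cfg = dataclasses.replace(fp.SimulationConfig(), seed=5)
        r1, t1 = fp.simulate_run(cfg, 1)
        r2, t2 = fp.simulate_run(cfg, 1)
        assert r1.offgas.co2_pct.tobytes() == r2.offgas.co2_pct.tobytes()
        assert r1.samples.dw_g_l.tobytes() == r2.samples.dw_g_l.tobytes()
        assert t1 == t2

    def test_zero_replicate_cv_identical_truth(self, make_noise_free_config):
        cfg = make_noise_free_config(replicate_cv=0.0)
        truths = [t for _, t in fp.simulate_triplicate(cfg)]
        assert (
            truths[0].mu_per_h == truths[1].mu_per_h == truths[2].mu_per_h
        )
        assert truths[0].t_exhaust_h == truths[2].t_exhaust_h

    def test_shared_sampling_grids(self):
        cfg = fp.SimulationConfig(seed=9)
        runs = [r for r, _ in fp.simulate_triplicate(cfg)]
        for r in runs[1:]:
            assert np.array_equal(r.offgas.time_h, runs[0].offgas.time_h)
            assert np.array_equal(r.samples.dw_time_h, runs[0].samples.dw_time_h)

    def test_replicate_cv_monte_carlo(self):
        # sample CV of realized mu over 200 triplicates within 20% of 0.05
        mus = []
        for s in range(200):
            cfg = fp.SimulationConfig(seed=s, replicate_cv=0.05, duration_h=50.0)
            mus.extend(t.mu_per_h for _, t in fp.simulate_triplicate(cfg))
        cv = np.std(mus, ddof=1) / np.mean(mus)
        assert 0.04 <= cv <= 0.06


class TestScenarios:
    def test_recovery_template_scales_transition_biomass(self):
        for mu in (0.15, 0.2, 0.3):
            cfg = recovery_config(mu)
            xp = cfg.x0 * math.exp(mu * (cfg.t_pellet_h - cfg.lag_h))
            assert xp == pytest.approx(1.35, rel=1e-9)

    def test_unknown_scenario_lists_available(self):
        with pytest.raises(KeyError, match="vulpinum-like"):
            fp.scenario_config("no-such-scenario")

    def test_vulpinum_calibration_hits_observable_targets(self):
        cfg = fp.vulpinum_like_config(seed=0)
        clean = dataclasses.replace(
            cfg, offgas_cv=0.0, dw_sd=0.0, glucose_sd=0.0, replicate_cv=0.0
        )
        _, truth = fp.simulate_run(clean, 0, detection=fp.SCENARIO_SEGMENTATION)
        assert truth.exp_end_h == pytest.approx(36.0, abs=1e-9)
        assert truth.t_co2max_h == pytest.approx(110.0, abs=1e-9)
        assert truth.t_pellet_h < 36.0  # latent transition precedes the fit end

    def test_vulpinum_noisy_median_near_noise_free_value(self):
        # the CO2 trace approaches its maximum along a flat maintenance
        # plateau, so the detected peak time scatters by hours under 2%
        # sensor noise; the median must still track the noise-free value
        cfg = fp.vulpinum_like_config(seed=0)
        vals = []
        for s in range(5):
            c = dataclasses.replace(cfg, seed=100 + s)
            for run, _ in fp.simulate_triplicate(c):
                seg = fp.segment_run(run, fp.SCENARIO_SEGMENTATION)
                vals.append(seg.nonexp_duration_h)
        assert abs(np.median(vals) - 74.0) <= 5.0


class TestFeatureTables:
    def test_planted_only_tables(self, library):
        planted = [(n, 1e6, 5e4) for n in library.entries["name"][:5]]
        tables, truth = fp.simulate_feature_table(
            library, planted, n_noise=0, replicate_dropout=0.0, seed=1
        )
        assert len(tables) == 3
        assert all(len(t) == 5 for t in tables)
        assert truth["present"].all()

    def test_full_dropout_removes_planted(self, library):
        planted = [("griseofulvin", 1e6, 5e4)]
        tables, truth = fp.simulate_feature_table(
            library, planted, n_noise=4, replicate_dropout=1.0, seed=1
        )
        assert all(len(t) == 4 for t in tables)
        assert not truth["present"].any()

    def test_proton_adduct_mass_against_atomic_oracle(self, library):
        # griseofulvin C17H17ClO6, computed from standard atomic masses
        mono = 17 * ATOMIC["C"] + 17 * ATOMIC["H"] + ATOMIC["Cl"] + 6 * ATOMIC["O"]
        assert library.mass_of("griseofulvin") == pytest.approx(mono, abs=1e-4)
        tables, truth = fp.simulate_feature_table(
            library, [("griseofulvin", 1e6, 5e4)], n_noise=0, seed=2,
            mz_jitter_ppm=0.0,
        )
        mz = tables[0].features["mz"].iloc[0]
        assert mz == pytest.approx(mono + 1.007276, abs=2e-4)

    def test_noise_masses_respect_exclusion(self, library):
        tables, _ = fp.simulate_feature_table(
            library, [], n_noise=50, seed=3, noise_exclusion_ppm=30.0
        )
        adduct_mz = np.array(
            [
                m + s
                for m in library.entries["monoisotopic_mass"]
                for s in fp.ADDUCTS_ESI_POS.values()
            ]
        )
        for t in tables:
            for mz in t.features["mz"]:
                assert np.min(np.abs(mz - adduct_mz) / adduct_mz * 1e6) > 30.0

    def test_unknown_planted_compound_rejected(self, library):
        with pytest.raises(KeyError):
            fp.simulate_feature_table(library, [("unobtainium", 1e6, 1e4)])


class TestStageSeries:
    def test_rising_count_constructed_exactly(self):
        per_stage, rising = simulate_stage_series(20, 17, seed=4)
        assert len(per_stage) == 20 and len(rising) == 17
        report = fp.stage_profile(per_stage)
        assert report.n_rising == 17
        flagged = {p.condition for p in report.profiles if p.rising_final}
        assert flagged == set(rising)
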