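"""Phase segmentation: lag rule, exponential window, CO2 maximum."""

import dataclasses

import numpy as np
import pytest

import fermprof as fp
from fermprof import (
    CerSeries,
    ExponentialWindowError,
    LagNotDetectedError,
    OffGasSeries,
    SegmentationError,
    detect_lag_end,
    find_co2_max,
    fit_exponential_window,
    segment_run,
)
from fermprof.gas import accumulate_co2


def gas_from(co2, t=None):
    co2 = np.asarray(co2, float)
    t = np.arange(len(co2), dtype=float) if t is None else np.asarray(t, float)
    return OffGasSeries(
        time_h=t, co2_pct=co2, airflow_vvm=np.full(len(co2), 0.9), volume_l=0.9
    )


# ---------------------------------------------------------------- lag rule


class TestDetectLagEnd:
    def test_first_sample_of_first_qualifying_run(self):
        gas = gas_from([1, 2, 7, 8, 9])
        assert detect_lag_end(gas, threshold_pct=6, k_consecutive=2) == 2.0

    def test_interrupted_runs_not_found(self):
        gas = gas_from([7, 1, 7, 1, 7])
        with pytest.raises(LagNotDetectedError):
            detect_lag_end(gas, threshold_pct=6, k_consecutive=2)

    def test_threshold_is_strict(self):
        gas = gas_from([6.0, 6.0, 6.0])
        with pytest.raises(LagNotDetectedError):
            detect_lag_end(gas, threshold_pct=6, k_consecutive=1)

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_matches_brute_force_scan(self, k):
        # exhaustive scan over all runs of consecutive above-threshold samples
        rng = np.random.default_rng(42 + k)
        for _ in range(60):
            co2 = rng.choice([0.0, 10.0], size=rng.integers(2, 25))
            gas = gas_from(co2)
            above = co2 > 6.0
            expected = None
            for i in range(len(co2) - k + 1):
                if above[i : i + k].all():
                    expected = float(i)
                    break
            if expected is None:
                with pytest.raises(LagNotDetectedError):
                    detect_lag_end(gas, 6.0, k)
            else:
                assert detect_lag_end(gas, 6.0, k) == expected


# ------------------------------------------------- exponential window fit


def brute_force_window(cer, after_h, r2_min, min_points, fixed_start=False):
    """Independent oracle: enumerate every contiguous window with np.polyfit."""
    t, acc = cer.time_h, cer.acc_co2
    n = len(t)
    anchor = int(np.searchsorted(t, after_h, side="left"))
    valid = (acc > 0) & (np.arange(n) >= anchor)
    first_valid = int(np.argmax(valid)) if valid.any() else None
    best = None
    for s in range(anchor, n):
        if not valid[s]:
            continue
        if fixed_start and s != first_valid:
            continue
        for e in range(s + min_points - 1, n):
            if not valid[s : e + 1].all():
                break
            x, y = t[s : e + 1], np.log(acc[s : e + 1])
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            sst = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 if sst <= 0 else 1.0 - float(resid @ resid) / sst
            if r2 >= r2_min and (best is None or e - s + 1 > best[0]):
                best = (e - s + 1, s, e)
    return best


def random_cer(rng):
    n = int(rng.integers(4, 21))
    t = np.cumsum(rng.uniform(0.2, 1.0, n))
    style = rng.integers(0, 3)
    if style == 0:
        cer = rng.uniform(0, 3, n)
    elif style == 1:
        cer = np.exp(rng.uniform(0.05, 0.4) * t) * rng.lognormal(0, 0.05, n)
    else:
        cer = np.concatenate([np.zeros(n // 2), rng.uniform(0.5, 2, n - n // 2)])
    return accumulate_co2(CerSeries(time_h=t, cer=cer))


class TestFitExponentialWindow:
    def test_pure_exponential_full_range(self):
        t = np.arange(0.0, 10.01, 0.25)
        acc = np.exp(0.25 * t)
        acc[0] = 0.0  # integral starts at zero; first sample unusable for ln
        cer = CerSeries(time_h=t, cer=np.zeros_like(t), acc_co2=acc)
        fit = fit_exponential_window(cer, after_h=0.0, r2_min=0.99, min_points=3)
        assert fit.start_idx == 1 and fit.end_idx == len(t) - 1
        assert fit.slope_per_h == pytest.approx(0.25, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("fixed_start", [False, True])
    def test_matches_exhaustive_enumeration(self, fixed_start):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(150):
            cer = random_cer(rng)
            after = float(rng.choice([0.0, cer.time_h[len(cer) // 3]]))
            expected = brute_force_window(cer, after, 0.99, 3, fixed_start)
            if expected is None:
                with pytest.raises((ExponentialWindowError, ValueError)):
                    fit_exponential_window(cer, after, 0.99, 3, fixed_start)
            else:
                fit = fit_exponential_window(cer, after, 0.99, 3, fixed_start)
                assert (fit.n_points, fit.start_idx, fit.end_idx) == expected
                checked += 1
        assert checked > 30  # the sweep must actually exercise accepted fits

    def test_failure_reports_best_achieved(self):
        t = np.arange(6.0)
        acc = np.array([0.0, 1.0, 1.1, 5.0, 5.1, 20.0])
        cer = CerSeries(time_h=t, cer=np.zeros(6), acc_co2=acc)
        with pytest.raises(ExponentialWindowError) as exc:
            fit_exponential_window(cer, 0.0, r2_min=0.9999, min_points=4)
        assert exc.value.best_n >= 4
        assert exc.value.best_r2 < 0.9999


# ------------------------------------------------------------ CO2 maximum


class TestFindCo2Max:
    def test_unimodal_peak(self):
        t = np.linspace(0, 10, 101)
        gas = gas_from(10 * np.exp(-((t - 6.2) ** 2)), t=t)
        assert find_co2_max(gas, smooth_window_h=0.0) == pytest.approx(6.2, abs=0.06)

    def test_tie_broken_earliest(self):
        gas = gas_from([1, 5, 2, 5, 1])
        assert find_co2_max(gas, smooth_window_h=0.0) == 1.0

    def test_smoothing_recovers_noisefree_peak(self, make_noise_free_config):
        clean_cfg = make_noise_free_config()
        noisy_cfg = dataclasses.replace(clean_cfg, offgas_cv=0.02)
        run_c, _ = fp.simulate_run(clean_cfg, 0)
        run_n, _ = fp.simulate_run(noisy_cfg, 0)
        t_clean = find_co2_max(run_c.offgas, 1.0)
        t_noisy = find_co2_max(run_n.offgas, 1.0)
        dt = clean_cfg.offgas_interval_min / 60
        assert abs(t_noisy - t_clean) <= 2 * dt


# ------------------------------------------------------------- composition


class TestSegmentRun:
    def test_no_transition_no_nonexponential_phase(self, noise_free_run, scenario_detection):
        run, truth = noise_free_run
        seg = segment_run(run, scenario_detection)
        assert seg.nonexp_duration_h == 0.0
        assert seg.lag_end_h <= seg.exp_start_h <= seg.exp_end_h <= seg.t_co2max_h

    def test_long_nonexponential_scenario(self, scenario_detection):
        cfg = fp.vulpinum_like_config(seed=3)
        clean = dataclasses.replace(
            cfg, offgas_cv=0.0, dw_sd=0.0, glucose_sd=0.0, replicate_cv=0.0
        )
        run, _ = fp.simulate_run(clean, 0)
        seg = segment_run(run, scenario_detection)
        assert seg.exp_end_h == pytest.approx(36.0, abs=1e-9)
        assert seg.t_co2max_h == pytest.approx(110.0, abs=1e-9)
        assert seg.nonexp_duration_h == pytest.approx(74.0, abs=1e-9)

    def test_threshold_never_crossed_fails_at_lag_stage(self, noise_free_run):
        run, _ = noise_free_run
        with pytest.raises(SegmentationError) as exc:
            segment_run(run, fp.SegmentationParams(lag_threshold_pct=50.0))
        assert exc.value.stage == "lag"

    def test_idempotent_under_truncation(self, scenario_detection, make_noise_free_config):
        cfg = make_noise_free_config(seed=21)
        run, _ = fp.simulate_run(cfg, 0)
        seg_full = segment_run(run, scenario_detection)
        keep = run.offgas.time_h <= seg_full.fit.end_h + 4.0
        gas = OffGasSeries(
            time_h=run.offgas.time_h[keep],
            co2_pct=run.offgas.co2_pct[keep],
            airflow_vvm=run.offgas.airflow_vvm[keep],
            volume_l=run.offgas.volume_l,
        )
        run2 = dataclasses.replace(run, offgas=gas)
        seg_trunc = segment_run(run2, scenario_detection)
        assert seg_trunc.lag_end_h == seg_full.lag_end_h
        assert seg_trunc.exp_start_h == seg_full.exp_start_h
        assert seg_trunc.fit.end_h == seg_full.fit.end_h
        assert seg_trunc.t_co2max_h == seg_full.t_co2max_h

    def test_noisy_recovery_against_noise_free_truth(self, scenario_detection):
        # pelleted template: median errors over noisy replicates stay within
        # a couple of off-gas samples of the noise-free detection values
        from fermprof.simulate import recovery_config

        dt = 5 / 60
        err_end, err_lag, err_nonexp = [], [], []
        for trip in range(12):
            cfg = dataclasses.replace(recovery_config(0.2), seed=300 + trip)
            for run, truth in fp.simulate_triplicate(cfg, detection=scenario_detection):
                seg = segment_run(run, scenario_detection)
                err_lag.append(abs(seg.lag_end_h - truth.lag_detect_h))
                err_end.append(abs(seg.exp_end_h - truth.exp_end_h))
                err_nonexp.append(abs(seg.nonexp_duration_h - truth.nonexp_duration_h))
        assert np.median(err_lag) <= dt
        assert np.median(err_end) <= 2 * dt
        assert np.median(err_nonexp) <= 2 * dt
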