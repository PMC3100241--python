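"""Synthetic culture generator: spike trains, calibration, voltage, spines."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from burstnet import (
    BurstParams,
    CalibrationError,
    RecordingConfig,
    SimulationParams,
    SpikeTrain,
    SpineSimParams,
    builtin_fixtures,
    calibrate_burst_duration_dist,
    detect_bursts,
    generate_spike_trains,
    generate_spine_population,
    make_default_template,
    spine_fixtures,
    synthesize_voltage,
)

MAX_ISI_S = 0.020


def small_params(**kw):
    defaults = dict(
        condition_label="test",
        duration_s=120.0,
        n_electrodes=6,
        long_ibi_median_s=10.0,
        long_ibi_log_sd=0.5,
        seed=0,
    )
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestGenerateSpikeTrains:
    def test_infinite_silence_means_no_activity(self):
        trains, gt = generate_spike_trains(
            small_params(long_ibi_median_s=math.inf)
        )
        assert all(len(t) == 0 for t in trains)
        assert gt.bursts == []

    def test_same_seed_bitwise_identical(self):
        p = small_params(seed=42)
        t1, g1 = generate_spike_trains(p)
        t2, g2 = generate_spike_trains(p)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.times_s, b.times_s)
        assert g1.bursts == g2.bursts

    def test_event_rate_matches_silence_median(self):
        # deterministic 20 s silences in a 600 s window: ~30 events per
        # electrode; pooled mean over electrodes and seeds within +-5
        counts = []
        for seed in range(20):
            p = SimulationParams(
                condition_label="rate",
                duration_s=600.0,
                n_electrodes=3,
                long_ibi_median_s=20.0,
                long_ibi_log_sd=0.0,
                motif_prob_doublet=0.0,
                motif_prob_triplet=0.0,
                seed=seed,
            )
            _, gt = generate_spike_trains(p)
            per_el = len(gt.bursts) / p.n_electrodes
            counts.append(per_el)
        assert abs(np.mean(counts) - 30.0) <= 5.0

    def test_ground_truth_isi_and_gap_invariants(self):
        p = small_params(motif_prob_doublet=0.3, motif_prob_triplet=0.2, seed=3)
        trains, gt = generate_spike_trains(p)
        by_el = gt.bursts_by_electrode()
        for train in trains:
            spikes = train.times_s
            bursts = by_el.get(train.electrode_id, [])
            for b in bursts:
                inside = spikes[(spikes >= b.t_start_s) & (spikes <= b.t_end_s)]
                assert inside.size == b.n_spikes
                assert np.all(np.diff(inside) <= MAX_ISI_S + 1e-12)
            for b1, b2 in zip(bursts, bursts[1:]):
                assert b2.t_start_s - b1.t_end_s > MAX_ISI_S

    def test_detector_recovers_ground_truth_exactly(self):
        for seed in [0, 1, 2]:
            p = small_params(motif_prob_doublet=0.25, motif_prob_triplet=0.1, seed=seed)
            trains, gt = generate_spike_trains(p)
            by_el = gt.bursts_by_electrode()
            for train in trains:
                detected = detect_bursts(train, BurstParams()).bursts
                truth = by_el.get(train.electrode_id, [])
                assert len(detected) == len(truth)
                for d, t in zip(detected, truth):
                    assert d.t_start_s == pytest.approx(t.t_start_s, abs=1e-12)
                    assert d.t_end_s == pytest.approx(t.t_end_s, abs=1e-12)
                    assert d.n_spikes == t.n_spikes

    def test_burst_stat_means_match_configuration(self):
        p = small_params(duration_s=600.0, n_electrodes=30, seed=9)
        _, gt = generate_spike_trains(p)
        durs = np.array([(b.t_end_s - b.t_start_s) * 1000 for b in gt.bursts])
        spks = np.array([b.n_spikes for b in gt.bursts])
        assert durs.size >= 1000
        for sample, target in [(durs, gt.mean_duration_ms), (spks, gt.mean_spikes_per_burst)]:
            se = sample.std(ddof=1) / np.sqrt(sample.size)
            assert abs(sample.mean() - target) <= 3 * se

    def test_unsynchronized_mode(self):
        p = small_params(synchronize=False, seed=5)
        trains, gt = generate_spike_trains(p)
        assert sum(len(t) for t in trains) > 0
        detected = [detect_bursts(t).bursts for t in trains]
        by_el = gt.bursts_by_electrode()
        assert [len(d) for d in detected] == [
            len(by_el.get(t.electrode_id, [])) for t in trains
        ]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            small_params(motif_prob_doublet=0.8, motif_prob_triplet=0.5)
        with pytest.raises(ValueError):
            small_params(motif_gap_ms_range=(15.0, 50.0))
        with pytest.raises(ValueError):
            small_params(
                spikes_per_burst_dist={"name": "fixed", "value": 20},
                burst_duration_dist={"name": "fixed", "value_ms": 500.0},
            )


class TestCalibration:
    def test_joint_mean_and_quantile_constraints(self):
        d = calibrate_burst_duration_dist(182.5, 0.65, 200.0)
        k, scale = d["shape"], d["scale_ms"]
        assert k * scale == pytest.approx(182.5, abs=1e-6)
        assert stats.gamma.cdf(200.0, k, scale=scale) == pytest.approx(0.65, abs=1e-6)

    def test_skew_preference_selects_root(self):
        lo = calibrate_burst_duration_dist(182.5, 0.65, 200.0, prefer="most_skewed")
        hi = calibrate_burst_duration_dist(182.5, 0.65, 200.0, prefer="most_symmetric")
        assert lo["shape"] < hi["shape"]
        for d in (lo, hi):
            assert stats.gamma.cdf(
                200.0, d["shape"], scale=d["scale_ms"]
            ) == pytest.approx(0.65, abs=1e-6)

    def test_gamma_median_approaches_mean_in_shape_limit(self):
        # right-skew vanishes as shape grows: CDF at the mean tends to 1/2,
        # so mean == cutoff forces the achievable fraction toward 0.5
        gaps = [
            abs(stats.gamma.cdf(200.0, k, scale=200.0 / k) - 0.5)
            for k in [1e2, 1e3, 1e4]
        ]
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] < 2e-3

    def test_infeasible_constraints_raise(self):
        with pytest.raises(CalibrationError):
            calibrate_burst_duration_dist(100.0, 0.99, 100.0)
        with pytest.raises(CalibrationError):
            calibrate_burst_duration_dist(200.0, 0.5, 200.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            calibrate_burst_duration_dist(100.0, 0.0, 100.0)
        with pytest.raises(ValueError):
            calibrate_burst_duration_dist(-1.0, 0.5, 100.0)


class TestSynthesizeVoltage:
    def test_no_spikes_no_noise_all_zero(self):
        cfg = RecordingConfig(n_electrodes=2, duration_s=0.5)
        tmpl = make_default_template(cfg.sampling_rate_hz)
        rec = synthesize_voltage([], tmpl, 0.0, cfg)
        assert np.all(rec.voltage_uv == 0.0)

    def test_template_placed_at_spike_time(self):
        cfg = RecordingConfig(n_electrodes=1, duration_s=1.0)
        tmpl = make_default_template(cfg.sampling_rate_hz, peak_uv=-60.0)
        rec = synthesize_voltage(
            [SpikeTrain(0, np.array([0.5]))], tmpl, 0.0, cfg
        )
        trace = rec.voltage_uv[0]
        center = int(round(0.5 * cfg.sampling_rate_hz))
        assert trace[center] == pytest.approx(-60.0)
        assert int(np.argmin(trace)) == center
        start = center - tmpl.peak_index
        assert np.all(trace[: start]) == 0
        assert np.allclose(
            trace[start : start + tmpl.waveform_uv.size], tmpl.waveform_uv
        )

    def test_noise_sd_calibrated(self):
        cfg = RecordingConfig(n_electrodes=2, duration_s=10.0)
        tmpl = make_default_template(cfg.sampling_rate_hz)
        rec = synthesize_voltage([], tmpl, 10.0, cfg, seed=1)
        sds = rec.voltage_uv.std(axis=1)
        assert np.all(np.abs(sds - 10.0) / 10.0 < 0.02)

    def test_overlapping_templates_sum(self):
        cfg = RecordingConfig(n_electrodes=1, duration_s=1.0)
        tmpl = make_default_template(cfg.sampling_rate_hz, peak_uv=-60.0)
        rec = synthesize_voltage(
            [SpikeTrain(0, np.array([0.5, 0.50004]))], tmpl, 0.0, cfg
        )
        assert rec.voltage_uv[0].min() < -60.0

    def test_spike_beyond_end_rejected(self):
        cfg = RecordingConfig(n_electrodes=1, duration_s=1.0)
        tmpl = make_default_template(cfg.sampling_rate_hz)
        with pytest.raises(ValueError, match="beyond"):
            synthesize_voltage([SpikeTrain(0, np.array([2.0]))], tmpl, 0.0, cfg)

    def test_sampling_rate_mismatch_rejected(self):
        cfg = RecordingConfig(n_electrodes=1, duration_s=1.0)
        tmpl = make_default_template(20_000.0)
        with pytest.raises(ValueError, match="sampling rate"):
            synthesize_voltage([], tmpl, 0.0, cfg)


class TestSpinePopulation:
    def test_one_hot_class_six_all_mature(self):
        probs = tuple(1.0 if i == 5 else 0.0 for i in range(8))
        df = generate_spine_population(
            SpineSimParams(n_cells=10, shape_probs=probs, seed=0)
        )
        assert set(df["shape_class"]) == {6}

    def test_same_seed_identical(self):
        p = SpineSimParams(n_cells=20, seed=9)
        a = generate_spine_population(p)
        b = generate_spine_population(p)
        assert a.equals(b)

    def test_every_cell_has_at_least_one_spine(self):
        df = generate_spine_population(
            SpineSimParams(n_cells=200, mean_spines_per_cell=1.0, seed=2)
        )
        assert df.groupby("cell_id").size().min() >= 1
        assert df["cell_id"].nunique() == 200

    def test_epha4_class6_fraction_matches_parameter(self):
        p = spine_fixtures(seed=4, n_cells=800)["epha4"]  # ~10,400 spines
        df = generate_spine_population(p)
        frac = (df["shape_class"] == 6).mean()
        n = len(df)
        assert n >= 10_000
        sd = math.sqrt(0.22 * 0.78 / n)
        assert abs(frac - 0.22) <= 3 * sd

    def test_missing_psd95_supported(self):
        df = generate_spine_population(
            SpineSimParams(n_cells=5, psd95_prob=None, seed=0)
        )
        assert df["psd95"].isna().all()

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            SpineSimParams(shape_probs=(0.5, 0.5, 0, 0, 0, 0, 0, 0.1))


def test_builtin_fixtures_cover_four_conditions():
    fx = builtin_fixtures()
    assert set(fx) == {
        "control_7div",
        "epha4_7div",
        "control_14div",
        "epha4_14div",
    }
    assert fx["control_7div"].div == 7 and fx["epha4_14div"].div == 14
    # calibrated control 7 DIV duration distribution carries its constraints
    d = fx["control_7div"].burst_duration_dist
    assert stats.gamma.cdf(200.0, d["shape"], scale=d["mean_ms"] / d["shape"]) == (
        pytest.approx(0.65, abs=1e-6)
    )
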