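"""Parameter extraction: artifact onset, cursor measurements, recruitment."""

import math

import numpy as np
import pytest

from cmapkit import (
    ConfigError,
    DetectionError,
    RecordingMeta,
    Sweep,
    SweepSet,
    analyze_recruitment,
    detect_artifact_onset,
    measure_cmap,
    measure_sweepset,
    simulate_sweep,
    subtract_baseline,
)


def piecewise_linear_sweep(meta):
    """0 until 2.0 ms, linear to +5 mV at 2.5 ms, to -1 mV at 3.5 ms, to 0 at 4.5 ms.

    All corners are exact sample times at 40 kHz, so linear interpolation of
    the crossings is exact: rising crossing at 2.0 ms, peak 5 mV at 2.5 ms,
    falling crossing where the segment (+5 at 2.5, -1 at 3.5) hits zero at
    2.5 + 5/6 ms.
    """
    t = meta.times_ms()
    y = np.interp(t, [0.0, 2.0, 2.5, 3.5, 4.5, meta.sweep_duration], [0, 0, 5.0, -1.0, 0, 0])
    return Sweep(y, meta)


class TestArtifactOnset:
    def test_configured_returns_meta_value(self, meta):
        sw = Sweep(np.zeros(meta.n_samples), meta)
        assert detect_artifact_onset(sw, mode="configured") == 1.0

    def test_flat_trace_auto_fails(self, meta):
        sw = Sweep(np.zeros(meta.n_samples), meta)
        with pytest.raises(DetectionError):
            detect_artifact_onset(sw, mode="auto")

    def test_injected_rectangle_found_within_one_sample(self, meta, rng):
        t = meta.times_ms()
        y = 0.005 * rng.normal(size=meta.n_samples)
        y[(t >= 1.0) & (t < 1.1)] += 5.0
        found = detect_artifact_onset(Sweep(y, meta), mode="auto")
        assert found == pytest.approx(1.0, abs=meta.dt_ms)


class TestMeasureCmap:
    def test_all_zero_flags_no_response(self, meta):
        m = measure_cmap(Sweep(np.zeros(meta.n_samples), meta))
        assert m.flags == {"no_response"}
        assert m.amplitude == 0.0
        assert math.isnan(m.latency) and math.isnan(m.duration)

    def test_piecewise_linear_closed_form(self, meta):
        m = measure_cmap(piecewise_linear_sweep(meta))
        assert m.amplitude == pytest.approx(5.0, abs=1e-12)
        assert m.latency == pytest.approx(1.0, abs=1e-12)  # crossing 2.0 - onset 1.0
        assert m.duration == pytest.approx(5.0 / 6.0 + 0.5, abs=1e-9)
        assert m.peak_time == pytest.approx(2.5, abs=1e-12)
        assert m.flags == frozenset()

    def test_scale_equivariance(self, meta):
        sw = piecewise_linear_sweep(meta)
        base = measure_cmap(sw)
        for c in (0.5, 3.0):
            m = measure_cmap(sw.with_samples(c * sw.samples))
            assert m.amplitude == pytest.approx(c * base.amplitude, rel=1e-12)
            assert m.latency == pytest.approx(base.latency, abs=1e-12)
            assert m.duration == pytest.approx(base.duration, abs=1e-9)

    def test_time_shift_equivariance(self, quiet_config):
        dt = quiet_config.meta.dt_ms
        sw0, tr0 = simulate_sweep(quiet_config, 0)
        m0 = measure_cmap(subtract_baseline(sw0))
        for delta in (0.5, 1.0):
            cfg = quiet_config.replace(latency=quiet_config.latency + delta)
            sw, _ = simulate_sweep(cfg, 0)
            m = measure_cmap(subtract_baseline(sw))
            assert m.latency - m0.latency == pytest.approx(delta, abs=2 * dt)
            assert m.duration == pytest.approx(m0.duration, abs=2 * dt)

    def test_noise_threshold_blocks_small_peaks(self, meta):
        sw = piecewise_linear_sweep(meta)
        m = measure_cmap(sw, noise_threshold=6.0)
        assert "no_response" in m.flags
        m2 = measure_cmap(sw, noise_threshold=1.0)
        assert m2.is_response

    def test_window_outside_sweep_rejected(self, meta):
        sw = piecewise_linear_sweep(meta)
        with pytest.raises(ConfigError):
            measure_cmap(sw, search_window=(21.0, 25.0))
        with pytest.raises(ConfigError):
            measure_cmap(sw, search_window=(0.2, 20.0))  # starts before onset

    def test_dense_resampling_converges_to_truth(self, quiet_config):
        """Cursor errors shrink with the sample period (oracle equivalence)."""
        errs = {}
        for fs in (40_000.0, 400_000.0):
            cfg = quiet_config.replace(
                latency=1.5037, duration=1.2093,
                meta=quiet_config.meta.replace(sampling_rate=fs),
            )
            sw, tr = simulate_sweep(cfg, 0)
            m = measure_cmap(subtract_baseline(sw))
            errs[fs] = (
                abs(m.amplitude - tr.amplitude),
                abs(m.latency - tr.latency),
                abs(m.duration - tr.duration),
            )
            dt = 1000.0 / fs
            assert errs[fs][1] <= dt
            assert errs[fs][2] <= 2 * dt
        assert all(e4 <= e1 + 1e-12 for e4, e1 in zip(errs[400_000.0], errs[40_000.0]))

    def test_offgrid_truths_recovered_to_crossing_precision(self, quiet_config, rng):
        """Each zero crossing is sub-sample accurate; duration, being the
        difference of two crossings, is accurate to two sample periods."""
        dt = quiet_config.meta.dt_ms
        for _ in range(40):
            cfg = quiet_config.replace(
                amplitude=float(rng.uniform(0.5, 10)),
                latency=float(rng.uniform(0.5, 3)),
                duration=float(rng.uniform(0.5, 2)),
            )
            sw, tr = simulate_sweep(cfg, 0)
            m = measure_cmap(subtract_baseline(sw))
            t_on = sw.meta.artifact_onset + tr.latency
            assert m.amplitude == pytest.approx(tr.amplitude, rel=0.02)
            assert abs(m.onset_crossing_time - t_on) <= dt
            assert abs(m.offset_crossing_time - (t_on + tr.duration)) <= dt
            assert abs(m.latency - tr.latency) <= dt
            assert abs(m.duration - tr.duration) <= 2 * dt


class TestRecruitment:
    def test_plateau_rule_hand_evaluated(self):
        """First negligible increment (0.1 on a 4.0 running max) arrives at
        1.0 mA and everything after stays negligible -> supramaximal 1.0."""
        rc = analyze_recruitment(
            list(zip([0.1, 0.5, 1.0, 1.5, 2.0], [0.5, 3.9, 4.0, 4.02, 4.05]))
        )
        assert rc.supramaximal_intensity == 1.0

    def test_proportional_growth_never_plateaus(self):
        rc = analyze_recruitment(list(zip([0.5, 1.0, 1.5, 2.0], [1.0, 2.0, 3.0, 4.0])))
        assert rc.supramaximal_intensity is None

    def test_unordered_intensities_rejected(self):
        with pytest.raises(ValueError):
            analyze_recruitment([(0.5, 1.0), (0.4, 2.0), (1.0, 3.0)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            analyze_recruitment([(0.5, 1.0), (1.0, 2.0)])


class TestMeasureSweepset:
    def test_identical_sweeps_equal_single_measure(self, quiet_config):
        sw, _ = simulate_sweep(quiet_config, 0)
        single = measure_cmap(subtract_baseline(sw))
        ss = SweepSet([sw.with_samples(sw.samples.copy()) for _ in range(10)])
        combined = measure_sweepset(ss)
        assert combined.amplitude == pytest.approx(single.amplitude, abs=1e-12)
        assert combined.latency == pytest.approx(single.latency, abs=1e-12)
        assert combined.duration == pytest.approx(single.duration, abs=1e-12)

    def test_white_noise_amplitude_within_tolerance(self, quiet_config):
        from cmapkit import NoiseSpec, simulate_recording

        sigma = 0.2
        cfg = quiet_config.replace(
            amplitude=5.02, noise=NoiseSpec(white_sd=sigma, line_amplitude=0.0), seed=42
        )
        ss, truth = simulate_recording(cfg)
        m = measure_sweepset(ss)
        assert abs(m.amplitude - truth.mean_amplitude) < 3 * sigma / math.sqrt(10)

    def test_sweep_selection_drops_contaminated_trials(self, quiet_config):
        sw, _ = simulate_sweep(quiet_config, 0)
        pulse = np.where((sw.times_ms() >= 6.0) & (sw.times_ms() < 7.0), 50.0, 0.0)
        bad = sw.with_samples(sw.samples + pulse)  # e.g. a pulse-noise trial
        ss = SweepSet([sw, bad, sw])
        clean = measure_sweepset(ss, selection=[0, 2])
        all_in = measure_sweepset(ss)
        ref = measure_cmap(subtract_baseline(sw))
        assert clean.amplitude == pytest.approx(ref.amplitude, abs=1e-9)
        assert all_in.amplitude != pytest.approx(ref.amplitude, abs=1e-3)
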