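"""Activity series and wavelet periodograms."""

import numpy as np
import pandas as pd
import pytest

from cyclenet import (ActivitySeries, ColonyConfig, OscillatorConfig,
                      TemporalNetwork, TrajectoryTable, contact_rate,
                      cycle_rate, day_night_summary, generate_contact_sequence,
                      movement_activity, wavelet_periodogram)
from tests.conftest import toy_network

FLAT = dict(diurnal_day_level=1.0, diurnal_night_level=1.0,
            night_period_factor=1.0, night_amplitude_factor=1.0)


def sinusoid_series(period_s=960.0, duration_s=259200.0, bin_s=60.0,
                    amplitude=0.5, offset=1.0):
    t = (np.arange(int(duration_s / bin_s)) + 0.5) * bin_s
    return ActivitySeries(bin_s=bin_s, t0_s=0.0,
                          values=offset + amplitude * np.sin(2 * np.pi * t / period_s))


class TestMovementActivity:
    def test_constant_velocity_gives_expected_speed(self):
        # One ant moving 1 mm per frame at 2 Hz -> 2 mm/s.
        rows = [(k * 0.5, 0, float(k), 0.0, 0.0) for k in range(240)]
        trajs = TrajectoryTable(pd.DataFrame(rows, columns=[
            "time_s", "ant_id", "x_mm", "y_mm", "orientation_deg"]),
            frame_rate_hz=2.0)
        act = movement_activity(trajs, bin_s=60.0)
        assert np.allclose(act.values, 2.0)

    def test_single_frame_rejected(self):
        trajs = TrajectoryTable(pd.DataFrame(
            [(0.0, 0, 1.0, 1.0, 0.0)],
            columns=["time_s", "ant_id", "x_mm", "y_mm", "orientation_deg"]),
            frame_rate_hz=2.0)
        with pytest.raises(ValueError, match="two frames"):
            movement_activity(trajs)

    def test_missing_bins_flagged(self):
        rows = [(k * 0.5, 0, float(k), 0.0, 0.0) for k in range(360)
                if not 120 <= k < 240]  # a full bin with no detections
        trajs = TrajectoryTable(pd.DataFrame(rows, columns=[
            "time_s", "ant_id", "x_mm", "y_mm", "orientation_deg"]),
            frame_rate_hz=2.0)
        act = movement_activity(trajs, bin_s=60.0)
        assert act.missing.any()
        assert (act.values[act.missing] == 0).all()


class TestContactRate:
    def test_empty_network_gives_zero_series(self):
        net = TemporalNetwork.from_events(
            pd.DataFrame(columns=["ant_i", "ant_j", "t_start_s", "t_end_s"]),
            duration_s=600.0, ants=[0, 1])
        assert (contact_rate(net, 60.0).values == 0).all()

    def test_contact_counts_start_and_stop(self):
        net = toy_network([(0, 1, 70.0, 100.0)], duration_s=300.0)
        values = contact_rate(net, 60.0).values
        assert values[1] == 2  # both endpoints inside bin 1
        assert values.sum() == 2

    def test_starts_and_stops_in_different_bins(self):
        net = toy_network([(0, 1, 10.0, 130.0), (0, 2, 20.0, 140.0),
                           (1, 2, 30.0, 45.0)], duration_s=300.0)
        values = contact_rate(net, 60.0).values
        assert values[0] == 4  # three starts + one stop
        assert values[2] == 2  # two stops


class TestWaveletPeriodogram:
    def test_pure_sinusoid_dominant_period(self):
        pg = wavelet_periodogram(sinusoid_series(960.0))
        step = pg.periods_s[1] / pg.periods_s[0]
        assert 960.0 / step <= pg.lambda_s <= 960.0 * step

    def test_fft_oracle_agrees(self):
        s = sinusoid_series(1800.0, duration_s=86400.0)
        freqs = np.fft.rfftfreq(len(s.values), s.bin_s)
        spec = np.abs(np.fft.rfft(s.values - s.values.mean())) ** 2
        fft_period = 1.0 / freqs[np.argmax(spec)]
        pg = wavelet_periodogram(s)
        assert pg.lambda_s == pytest.approx(fft_period, rel=0.06)

    def test_larger_amplitude_component_dominates(self):
        t = (np.arange(1440) + 0.5) * 60.0
        x = 3.0 + 2.0 * np.sin(2 * np.pi * t / 1800.0) \
            + 1.0 * np.sin(2 * np.pi * t / 600.0)
        pg = wavelet_periodogram(ActivitySeries(bin_s=60.0, t0_s=0.0, values=x))
        assert pg.lambda_s == pytest.approx(1800.0, rel=0.06)

    def test_doubling_amplitude_quadruples_raw_power(self):
        pg1 = wavelet_periodogram(sinusoid_series(amplitude=0.25))
        pg2 = wavelet_periodogram(sinusoid_series(amplitude=0.5))
        k = np.argmax(pg1.power_raw)
        assert pg2.power_raw[k] / pg1.power_raw[k] == pytest.approx(4.0, rel=1e-6)

    def test_power_nonnegative_and_normalised(self):
        pg = wavelet_periodogram(sinusoid_series())
        assert (pg.power >= 0).all()
        assert pg.power.sum() == pytest.approx(1.0)
        assert pg.lambda_power == pg.power.max()

    def test_out_of_band_period_range_rejected(self):
        s = sinusoid_series(duration_s=86400.0)
        with pytest.raises(ValueError, match="resolvable"):
            wavelet_periodogram(s, (30.0, 7200.0))  # below 2 * bin
        with pytest.raises(ValueError, match="resolvable"):
            wavelet_periodogram(s, (240.0, 86400.0))  # beyond half duration

    def test_period_recovery_from_generated_contact_sequences(self):
        # Generator-driven sequences at amplitudes 0.5 and 1.0: recovered
        # lambda within one scale step of the generator period in >= 95% of
        # seeded replicates.
        hits, total = 0, 0
        for amp in (0.5, 1.0):
            for seed in range(10):
                colony = ColonyConfig(n_ants=20, duration_s=43200.0)
                osc = OscillatorConfig(stac_period_s=960.0,
                                       stac_amplitude=amp, **FLAT)
                net = generate_contact_sequence(colony, osc, 0.3, rng=seed)
                pg = wavelet_periodogram(contact_rate(net, 60.0))
                step = pg.periods_s[1] / pg.periods_s[0]
                total += 1
                if 960.0 / step <= pg.lambda_s <= 960.0 * step:
                    hits += 1
        assert hits >= 0.95 * total

    def test_aperiodic_sequence_has_no_outstanding_peak(self):
        colony = ColonyConfig(n_ants=20, duration_s=43200.0)
        osc = OscillatorConfig(stac_amplitude=0.0, **FLAT)
        net = generate_contact_sequence(colony, osc, 0.3, rng=5)
        pg = wavelet_periodogram(contact_rate(net, 60.0))
        assert pg.lambda_power < 3 * np.median(pg.power)

    def test_movement_and_contact_spectra_share_dominant_period(self):
        from cyclenet import generate_trajectories
        colony = ColonyConfig(n_ants=12, duration_s=14400.0, frame_rate_hz=2.0)
        osc = OscillatorConfig(stac_period_s=960.0, stac_amplitude=1.0, **FLAT)
        trajs = generate_trajectories(colony, osc, 2.0, rng=3)
        net = generate_contact_sequence(colony, osc, 0.4, rng=3)
        rng_band = (240.0, 3600.0)
        pg_move = wavelet_periodogram(movement_activity(trajs, 60.0), rng_band)
        pg_contact = wavelet_periodogram(contact_rate(net, 60.0), rng_band)
        step = pg_move.periods_s[1] / pg_move.periods_s[0]
        assert pg_move.lambda_s / pg_contact.lambda_s == pytest.approx(1.0, abs=step - 1)


class TestCycleRate:
    def test_mean_colony_period_scale_value(self):
        # 19-minute period -> 0.00088 /s, i.e. 0.0008 to the leading
        # significant digit (truncated, as conventionally quoted).
        gamma = cycle_rate(19 * 60.0)
        assert gamma == pytest.approx(0.00088, abs=5e-6)
        assert np.floor(gamma * 1e4) / 1e4 == 0.0008

    def test_reciprocal_scaling(self):
        assert cycle_rate(960.0) == pytest.approx(1 / 960.0)
        assert cycle_rate(2 * 960.0) == pytest.approx(cycle_rate(960.0) / 2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cycle_rate(0.0)


class TestDayNightSummary:
    def test_constant_series_has_equal_means(self):
        s = ActivitySeries(bin_s=60.0, t0_s=0.0, values=np.ones(1440))
        summ = day_night_summary(s)
        assert summ.day_mean == pytest.approx(summ.night_mean)

    def test_diurnal_generator_ratio_recovered(self):
        colony = ColonyConfig(n_ants=20, duration_s=86400.0)
        osc = OscillatorConfig(stac_amplitude=0.0, diurnal_day_level=2.0,
                               diurnal_night_level=1.0,
                               night_period_factor=1.0,
                               night_amplitude_factor=1.0)
        net = generate_contact_sequence(colony, osc, 0.3, rng=8)
        summ = day_night_summary(contact_rate(net, 60.0))
        assert summ.day_mean / summ.night_mean == pytest.approx(2.0, rel=0.15)

    def test_exclusion_windows_remove_eight_hours_per_day(self):
        s = ActivitySeries(bin_s=60.0, t0_s=0.0, values=np.ones(1440))
        windows = [(17 * 3600.0, 21 * 3600.0), (5 * 3600.0, 9 * 3600.0)]
        summ = day_night_summary(s, exclude_windows=windows)
        assert summ.n_day + summ.n_night == 1440 - 8 * 60

    def test_short_series_rejected(self):
        s = ActivitySeries(bin_s=60.0, t0_s=0.0, values=np.ones(600))
        with pytest.raises(ValueError, match="24"):
            day_night_summary(s)
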