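import numpy as np
import pytest

import thermomaze as tm
from thermomaze.behavior import Trajectory
from thermomaze.ripples import ripple_bandpass
from thermomaze.synthetic import (SyntheticGroundTruth, UnitTuning,
                                  generate_within_ripple_spikes, make_ground_truth,
                                  tuning_rate)


def uniform_truth(n_units=1, participation=0.25, **unit_kwargs):
    defaults = dict(center=(10.0, 10.0), width_cm=np.inf, peak_rate_hz=2.0,
                    baseline_rate_hz=2.0, cell_type="pyramidal", tuned=False)
    defaults.update(unit_kwargs)
    units = [UnitTuning(uid, **defaults) for uid in range(n_units)]
    return SyntheticGroundTruth(units, np.full((n_units, 4), participation))


class TestDeterminism:
    def test_identical_seed_bitwise_identical_outputs(self, short_config):
        a = tm.simulate_session(short_config, n_units=5, with_lfp=False,
                                n_ripples=50)
        b = tm.simulate_session(short_config, n_units=5, with_lfp=False,
                                n_ripples=50)
        assert np.array_equal(a.trajectory.x, b.trajectory.x)
        assert np.array_equal(a.trajectory.likelihood, b.trajectory.likelihood)
        for sa, sb in zip(a.spikes, b.spikes):
            assert np.array_equal(sa.times, sb.times)
        assert np.array_equal(a.true_ripples["time"], b.true_ripples["time"])

    def test_different_seed_differs(self, short_config, short_session):
        other = tm.simulate_session(short_config, seed=999, n_units=12,
                                    with_lfp=False, n_ripples=150)
        assert not np.array_equal(other.trajectory.x,
                                  short_session.trajectory.x)


class TestUnitGeneration:
    def test_constant_rate_poisson_count(self):
        # width -> inf, baseline == peak == r: homogeneous Poisson oracle
        r, T, fs = 5.0, 200.0, 25.0
        t = np.arange(int(T * fs)) / fs
        traj = Trajectory(t, np.full(len(t), 10.0), np.full(len(t), 10.0),
                          np.ones(len(t)))
        truth = uniform_truth(peak_rate_hz=r, baseline_rate_hz=r)
        cfg = tm.SessionConfig(rng_seed=0)
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trains = tm.synthetic.generate_units(cfg, truth, traj, rng)
            counts.append(len(trains[0].times))
        mean = r * T
        assert abs(np.mean(counts) - mean) < 4 * np.sqrt(mean)

    def test_silent_unit_empty_train(self):
        t = np.arange(100) / 25.0
        traj = Trajectory(t, np.full(100, 5.0), np.full(100, 5.0), np.ones(100))
        truth = uniform_truth(peak_rate_hz=0.0, baseline_rate_hz=0.0)
        trains = tm.synthetic.generate_units(tm.SessionConfig(), truth, traj,
                                             np.random.default_rng(0))
        assert len(trains[0].times) == 0

    def test_spike_times_strictly_increasing(self, short_session):
        for st in short_session.spikes:
            if len(st.times) > 1:
                assert np.all(np.diff(st.times) > 0)

    def test_tuned_unit_rate_map_argmax_recovers_center(self, short_config):
        hits = 0
        for seed in range(10):
            cfg = tm.SessionConfig(
                sub_sessions=short_config.sub_sessions,
                warm_spot_schedule=list(short_config.warm_spot_schedule),
                rng_seed=1000 + seed)
            truth = SyntheticGroundTruth(
                [UnitTuning(0, (8.0, 16.0), 3.0, 25.0, 0.1, "pyramidal", True)],
                np.full((1, 4), 0.25))
            s = tm.simulate_session(cfg, with_lfp=False, n_ripples=0,
                                    truth=truth)
            traj = s.clean_trajectory
            v = tm.compute_speed(traj)
            seg = tm.segment_states(traj, v)
            occ_m = tm.occupancy_map(traj, seg, "movement", cfg)
            occ_i = tm.occupancy_map(traj, seg, "immobility", cfg)
            occ_all = occ_m.grid + occ_i.grid
            idx = traj.nearest_index(s.spikes[0].times)
            row, col = cfg.bin_of(traj.x[idx], traj.y[idx])
            counts = np.zeros_like(occ_all)
            np.add.at(counts, (row, col), 1.0)
            rate = np.where(occ_all > 0.5, counts / np.maximum(occ_all, 1e-9), 0)
            r, c = np.unravel_index(np.argmax(rate), rate.shape)
            if np.hypot(c + 0.5 - 8.0, r + 0.5 - 16.0) <= 3.0:
                hits += 1
        assert hits >= 8

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            uniform_truth(peak_rate_hz=1.0, baseline_rate_hz=2.0)

    def test_tuning_rate_profile(self):
        u = UnitTuning(0, (10.0, 10.0), 2.0, 11.0, 1.0, "pyramidal", True)
        assert tuning_rate(u, 10.0, 10.0) == pytest.approx(11.0)
        assert tuning_rate(u, 10.0 + 2.0, 10.0) == pytest.approx(
            1.0 + 10.0 * np.exp(-0.5))


class TestRipplesAndLFP:
    def test_requested_count_bookkeeping(self, short_config):
        s = tm.simulate_session(short_config, n_units=0, with_lfp=False,
                                n_ripples=200)
        assert len(s.true_ripples) == 200
        assert np.array_equal(s.truth.ripple_times,
                              s.true_ripples["time"].to_numpy())

    def test_ripples_lie_in_cooling_immobility(self, short_session,
                                               short_config):
        traj = short_session.clean_trajectory
        v = tm.compute_speed(traj)
        seg = tm.segment_states(traj, v)
        span = short_config.sub_session("Cooling")
        t = short_session.true_ripples["time"].to_numpy()
        assert np.all((t >= span[0]) & (t <= span[1]))
        assert np.mean(seg.state_at(t) == "immobility") > 0.95

    def test_band_power_concentrated_in_ripple_windows(self, short_config):
        ratios = []
        for seed in range(5):
            s = tm.simulate_session(short_config, seed=3000 + seed, n_units=0,
                                    with_lfp=True, n_ripples=60)
            filt = ripple_bandpass(s.lfp.channel("pyramidal_layer"),
                                   s.lfp.rate)
            power = filt ** 2
            t = np.arange(len(power)) / s.lfp.rate + short_config.session_span[0]
            in_win = np.zeros(len(power), dtype=bool)
            for tc, d in zip(s.true_ripples["time"], s.true_ripples["duration"]):
                a = int((tc - d / 2 - t[0]) * s.lfp.rate)
                b = int((tc + d / 2 - t[0]) * s.lfp.rate)
                in_win[max(a, 0):b] = True
            ratios.append(np.median(power[in_win]) / np.median(power[~in_win]))
        assert np.median(ratios) > 2.0

    def test_noise_channel_nearly_ripple_free(self, short_config):
        s = tm.simulate_session(short_config, seed=77, n_units=0,
                                with_lfp=True, n_ripples=200)
        ev = tm.detect_ripples(s.lfp)
        nev = tm.detect_ripples(s.lfp, channel_role="noise")
        assert len(nev) < 0.05 * len(ev)

    def test_nonpositive_amplitude_rejected(self, short_config):
        truth = uniform_truth()
        truth.ripple_amplitude_sd = 0.0
        with pytest.raises(ValueError):
            tm.synthetic.generate_ripples_and_lfp(
                short_config, truth,
                tm.simulate_session(short_config, n_units=0, with_lfp=False,
                                    n_ripples=0).clean_trajectory,
                np.random.default_rng(0))


class TestWithinRippleSpikes:
    def test_forced_single_quadrant_gives_sts_one(self):
        from conftest import make_events
        truth = SyntheticGroundTruth(
            [UnitTuning(0, (5, 5), np.inf, 1.0, 1.0)],
            np.array([[1.0, 0.0, 0.0, 0.0]]))
        rng = np.random.default_rng(0)
        times = np.arange(100) * 2.0
        quads = np.tile([0, 1, 2, 3], 25)
        trains = generate_within_ripple_spikes(
            truth, times, np.full(100, 0.08), rng, quadrants=quads)
        prof = tm.within_ripple_rates(trains[0], make_events(times, quads))
        assert tm.compute_sts(prof).sts == 1.0

    def test_uniform_participation_binomial_oracle(self):
        truth = SyntheticGroundTruth(
            [UnitTuning(0, (5, 5), np.inf, 1.0, 1.0)],
            np.full((1, 4), 0.4))
        rng = np.random.default_rng(1)
        n = 500
        times = np.arange(n) * 2.0
        quads = rng.integers(0, 4, size=n)
        trains = generate_within_ripple_spikes(
            truth, times, np.full(n, 0.08), rng, quadrants=quads)
        participated = 0
        for tc in times:
            k = np.count_nonzero(np.abs(trains[0].times - tc) <= 0.04)
            participated += k > 0
        assert abs(participated / n - 0.4) <= 0.05

    def test_zero_participation_absent_everywhere(self):
        truth = SyntheticGroundTruth(
            [UnitTuning(0, (5, 5), np.inf, 1.0, 1.0)],
            np.zeros((1, 4)))
        trains = generate_within_ripple_spikes(
            truth, np.arange(50) * 2.0, np.full(50, 0.08),
            np.random.default_rng(0), quadrants=np.zeros(50, dtype=int))
        assert len(trains[0].times) == 0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SyntheticGroundTruth([UnitTuning(0, (5, 5), np.inf, 1, 1)],
                                 np.full((1, 4), 1.2))


def test_occupancy_conservation_full_session(short_session, short_config):
    traj = short_session.clean_trajectory
    seg = tm.segment_states(traj, tm.compute_speed(traj))
    occ_m = tm.occupancy_map(traj, seg, "movement", short_config)
    occ_i = tm.occupancy_map(traj, seg, "immobility", short_config)
    lo, hi = short_config.session_span
    frame = 1.0 / short_config.frame_rate
    assert occ_m.total() + occ_i.total() == pytest.approx(hi - lo, abs=2 * frame)


def test_state_bouts_partition_session(short_config):
    cfg = tm.two_spot_config(rng_seed=2)
    truth = make_ground_truth(cfg, np.random.default_rng(0), n_units=1)
    bouts = tm.synthetic.generate_state_bouts(cfg, truth)
    lo, hi = cfg.session_span
    assert bouts["start"].iloc[0] == lo and bouts["end"].iloc[-1] == hi
    assert np.allclose(bouts["start"].iloc[1:].to_numpy(),
                       bouts["end"].iloc[:-1].to_numpy())
    assert (bouts["state"] == "NREM").any()
    # 5-min schedule: never NREM
    bouts5 = tm.synthetic.generate_state_bouts(
        short_config, make_ground_truth(short_config,
                                        np.random.default_rng(0), n_units=1))
    assert list(bouts5["state"]) == ["WAKE"]
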