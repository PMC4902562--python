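import numpy as np
import pandas as pd
import pytest

from antkin import geometry as geo, synth
from antkin.circstats import circ_mean_sd


class TestMakeBeeProfile:
    def test_defaults(self):
        p = synth.make_bee_profile(seed=1)
        assert p.baseline_iaa == 96.0
        assert p.sigmoid_amplitude == 35.0
        assert p.of_threshold == 10.0
        assert p.noise_sd == 0.8

    def test_determinism(self):
        assert synth.make_bee_profile({"of_gain": 2.0}, seed=3) == synth.make_bee_profile(
            {"of_gain": 2.0}, seed=3
        )

    def test_zero_amplitude_flat_airflow_response(self):
        p = synth.make_bee_profile({"sigmoid_amplitude": 0.0})
        v = np.linspace(0, 5.5, 12)
        assert np.allclose(p.airflow_term(v), 0.0)

    def test_invalid_noise_named_in_error(self):
        with pytest.raises(synth.ProfileValidationError, match="noise_sd"):
            synth.make_bee_profile({"noise_sd": -1.0})

    def test_unknown_key_rejected(self):
        with pytest.raises(synth.ProfileValidationError):
            synth.make_bee_profile({"wingbeat_hz": 200.0})


class TestBuildProtocol:
    def test_linear_of_ramp_structure(self):
        p = synth.build_protocol("linear_ramp_of")
        assert len(p.epochs) == 26
        assert p.total_duration_s == 26.0
        assert [e.tf_cps for e in p.epochs] == list(map(float, range(26)))

    def test_low_range_total_duration(self):
        p = synth.build_protocol("low_range_of")
        assert p.total_duration_s == 54.0
        moving = [e for e in p.epochs if e.tf_cps != 0]
        static = [e for e in p.epochs if e.tf_cps == 0]
        assert all(e.duration_s == 6.0 for e in moving)
        assert all(e.duration_s == 3.0 for e in static)

    def test_random_of_deterministic_permutation(self):
        p1 = synth.build_protocol("random_of", {"seed": 7})
        p2 = synth.build_protocol("random_of", {"seed": 7})
        seq1 = [e.tf_cps for e in p1.epochs]
        assert seq1 == [e.tf_cps for e in p2.epochs]
        assert sorted(seq1) == list(map(float, range(1, 26)))

    def test_air_ramp_levels(self):
        p = synth.build_protocol("linear_ramp_air")
        assert [e.windspeed_mps for e in p.epochs] == pytest.approx(np.arange(0, 5.51, 0.5))

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            synth.build_protocol("staircase")

    def test_nonpositive_step(self):
        with pytest.raises(ValueError):
            synth.build_protocol("linear_ramp_of", {"step_cps": 0.0})

    def test_regime_conditions(self):
        p = synth.build_protocol("regime", {"transition": "BC", "condition": "air"})
        assert p.epochs[0].windspeed_mps == 2.5 and p.epochs[0].tf_cps == 0.9
        assert p.epochs[1].windspeed_mps == 4.0 and p.epochs[1].tf_cps == 0.9


class TestSimulateTrace:
    def test_constant_airflow_statistics(self, default_bee):
        proto = synth.StimulusProtocol((synth.Epoch(1.0, 0.5, 0.0),), fps=250.0)
        tr = synth.simulate_iaa_trace(default_bee, proto, seed=6)
        assert len(tr.frames) == 250
        m = circ_mean_sd(tr.frames["iaa_deg"])
        assert m.mean_deg == pytest.approx(96.0, abs=0.3)
        assert m.sd_deg == pytest.approx(0.8, abs=0.15)

    def test_time_axis(self, quiet_bee):
        proto = synth.build_protocol("linear_ramp_air", {"fps": 500.0})
        tr = synth.simulate_iaa_trace(quiet_bee, proto, seed=0)
        t = tr.frames["time_s"].to_numpy()
        assert np.allclose(np.diff(t), 1.0 / 500.0)

    def test_determinism(self, default_bee):
        proto = synth.build_protocol("random_of", {"seed": 2})
        a = synth.simulate_iaa_trace(default_bee, proto, seed=9)
        b = synth.simulate_iaa_trace(default_bee, proto, seed=9)
        pd.testing.assert_frame_equal(a.frames, b.frames)

    def test_of_step_impulse_decay_closed_form(self):
        # closed-form oracle: step 0 -> 5 cps gives G(t) = 5 exp(-t/tau)
        bee = synth.make_bee_profile({"noise_sd": 0.0, "onset_jump": 0.0})
        proto = synth.StimulusProtocol(
            (synth.Epoch(2.0, 0.0, 0.0), synth.Epoch(4.0, 0.0, 5.0)), fps=250.0
        )
        tr = synth.simulate_iaa_trace(bee, proto, seed=0)
        df = tr.frames
        t0 = df.loc[df.tf_cps == 5.0, "time_s"].iloc[0]
        seg = df[df.tf_cps == 5.0]
        expected = 96.0 + 5.0 * np.exp(-(seg["time_s"] - t0) / bee.adaptation_tau)
        assert np.allclose(seg["iaa_deg"], expected, atol=1e-9)

    def test_step_above_threshold_no_response(self):
        bee = synth.make_bee_profile({"noise_sd": 0.0, "onset_jump": 0.0})
        proto = synth.StimulusProtocol(
            (synth.Epoch(1.0, 0.0, 15.0), synth.Epoch(1.0, 0.0, 20.0)), fps=250.0
        )
        tr = synth.simulate_iaa_trace(bee, proto, seed=0)
        # both levels clip to theta=10: the transition adds no jump, only the
        # ongoing exponential relaxation continues across the boundary
        before = tr.frames[tr.frames.tf_cps == 15.0]["iaa_deg"].iloc[-1]
        after = tr.frames[tr.frames.tf_cps == 20.0]["iaa_deg"].iloc[0]
        one_frame_decay = (before - 96.0) * (1 - np.exp(-1 / (250.0 * bee.adaptation_tau)))
        assert abs(after - before) <= abs(one_frame_decay) + 1e-6

    def test_antagonism_directions(self, quiet_bee):
        # airspeed raises -> antennae forward (IAA down); optic flow below
        # threshold raises -> antennae backward (IAA up)
        slow = synth.StimulusProtocol((synth.Epoch(1.0, 0.5, 0.0),), fps=250.0)
        fast = synth.StimulusProtocol((synth.Epoch(1.0, 5.0, 0.0),), fps=250.0)
        iaa_slow = synth.simulate_iaa_trace(quiet_bee, slow, seed=0).frames["iaa_deg"].iloc[-1]
        iaa_fast = synth.simulate_iaa_trace(quiet_bee, fast, seed=0).frames["iaa_deg"].iloc[-1]
        assert iaa_fast < iaa_slow - 30

        of = synth.StimulusProtocol(
            (synth.Epoch(0.5, 0.0, 0.0), synth.Epoch(0.5, 0.0, 5.0)), fps=250.0
        )
        tr = synth.simulate_iaa_trace(quiet_bee, of, seed=0).frames
        assert tr["iaa_deg"].iloc[-1] > tr["iaa_deg"].iloc[0] + 3

    def test_matched_mode_regime_covariation_cancels(self):
        bee = synth.make_bee_profile(
            {"noise_sd": 0.0, "onset_jump": 0.0, "of_mode": "matched"}
        )
        proto = synth.build_protocol("regime", {"transition": "BC", "condition": "both"})
        tr = synth.simulate_iaa_trace(bee, proto, seed=0).frames
        before = tr[tr.epoch == 0]["iaa_deg"].iloc[-1]
        after = tr[tr.epoch == 1]["iaa_deg"].iloc[-1]
        assert abs(after - before) < 0.8  # |delta S| < sigma

    def test_saturation_in_plateaus(self, quiet_bee):
        lo = synth.StimulusProtocol((synth.Epoch(0.5, 0.5, 0.0),), fps=250.0)
        lo2 = synth.StimulusProtocol((synth.Epoch(0.5, 1.4, 0.0),), fps=250.0)
        a = synth.simulate_iaa_trace(quiet_bee, lo, seed=0).frames["iaa_deg"].iloc[-1]
        b = synth.simulate_iaa_trace(quiet_bee, lo2, seed=0).frames["iaa_deg"].iloc[-1]
        assert abs(a - b) < 0.5


class TestSimulateBinMeans:
    def test_air_plateau_difference(self, default_bee):
        levels = np.arange(0, 5.51, 0.5)
        bins = synth.simulate_bin_means(default_bee, levels, 200, "air", seed=0)
        slow = np.mean([b.circ_mean_deg for b in bins if b.level <= 1.5])
        fast = np.mean([b.circ_mean_deg for b in bins if b.level >= 3.0])
        assert slow - fast == pytest.approx(35.0, abs=0.5)

    def test_of_ramp_saturation(self, default_bee):
        bins = synth.simulate_bin_means(
            synth.make_bee_profile({"noise_sd": 0.0}), [10.0, 15.0], 5, "of_ramp", seed=0
        )
        assert bins[0].circ_mean_deg == pytest.approx(bins[1].circ_mean_deg, abs=1e-9)

    def test_noise_free_exact(self, quiet_bee):
        bins = synth.simulate_bin_means(quiet_bee, [2.25], 5, "air", seed=0)
        assert np.allclose(bins[0].angles_deg, 96.0 - 17.5)

    def test_empty_levels(self, default_bee):
        with pytest.raises(ValueError):
            synth.simulate_bin_means(default_bee, [], 5, "air", seed=0)


class TestSimulateGeometry:
    @pytest.fixture
    def short_trace(self, default_bee):
        proto = synth.StimulusProtocol((synth.Epoch(0.4, 0.5, 0.0),), fps=250.0)
        return synth.simulate_iaa_trace(default_bee, proto, seed=1)

    def _reconstruct_frames(self, pixels, cams):
        frames = []
        for _, g in pixels.groupby("frame"):
            pts = {}
            for name in ("LB", "LT", "RB", "RT"):
                sub = g[g.landmark == name].sort_values("camera")
                pts[name] = geo.dlt_reconstruct(cams, sub[["x_px", "y_px"]].to_numpy())
            frames.append(geo.AntennaFrame(pts["LB"], pts["LT"], pts["RB"], pts["RT"]))
        return frames

    def test_zero_noise_round_trip(self, short_trace):
        pixels, truth = synth.simulate_geometry(short_trace, pixel_noise=0.0)
        cams = synth.default_camera_rig()
        frames = self._reconstruct_frames(pixels, cams)
        iaa = np.array([geo.compute_iaa(f) for f in frames])
        assert np.allclose(iaa, short_trace.frames["iaa_deg"], atol=1e-6)
        err = geo.digitization_error(frames)
        assert err["left_cv_pct"] < 1e-6 and err["right_cv_pct"] < 1e-6

    def test_tethered_noise_length_variation(self, short_trace):
        # pixel noise tuned to the tethered digitization-error range
        pixels, _ = synth.simulate_geometry(short_trace, pixel_noise=0.2, seed=5)
        frames = self._reconstruct_frames(pixels, synth.default_camera_rig())
        err = geo.digitization_error(frames)
        assert 0.5 <= err["left_cv_pct"] <= 1.5
        assert 0.5 <= err["right_cv_pct"] <= 1.5

    def test_free_flight_noise_length_variation(self, short_trace):
        pixels, _ = synth.simulate_geometry(short_trace, pixel_noise=0.85, seed=5)
        frames = self._reconstruct_frames(pixels, synth.default_camera_rig())
        err = geo.digitization_error(frames)
        assert 3.0 <= err["left_cv_pct"] <= 5.0
        assert 3.0 <= err["right_cv_pct"] <= 5.0

    def test_degenerate_camera_pair_rejected(self, short_trace):
        cam = geo.pinhole_dlt((0.0, 0.0, 200.0), up=(0.0, 1.0, 0.0))
        cam2 = geo.pinhole_dlt((0.0, 0.0, 300.0), up=(0.0, 1.0, 0.0))
        with pytest.raises(geo.CalibrationError):
            synth.simulate_geometry(short_trace, cameras=(cam, cam2))


class TestFreeFlight:
    def test_groundspeed_held_across_winds(self):
        table = synth.simulate_free_flight(np.arange(0, 3.51, 0.5), seed=7)
        for w, g in table.groupby("windspeed_mps"):
            pos = g[["x_mm", "y_mm", "z_mm"]].to_numpy()
            ground, _ = geo.flight_speeds(pos, fps=500.0, windspeed_vector_mps=(-w, 0, 0))
            assert np.mean(np.linalg.norm(ground, axis=1)) == pytest.approx(0.43, abs=0.02)

    def test_collinear_airspeed(self):
        table = synth.simulate_free_flight(
            [2.0], groundspeed_target=0.4, speed_noise_sd=0.0, position_noise_mm=0.0, seed=0
        )
        pos = table[["x_mm", "y_mm", "z_mm"]].to_numpy()
        ground, air = geo.flight_speeds(pos, fps=500.0, windspeed_vector_mps=(-2.0, 0, 0))
        interior = slice(5, -5)
        assert np.allclose(np.linalg.norm(air[interior], axis=1), 2.4, atol=1e-9)

    def test_zero_noise_exact_target(self):
        table = synth.simulate_free_flight(
            [1.0], speed_noise_sd=0.0, position_noise_mm=0.0, seed=0
        )
        pos = table[["x_mm", "y_mm", "z_mm"]].to_numpy()
        ground, _ = geo.flight_speeds(pos, fps=500.0)
        assert np.allclose(np.linalg.norm(ground[5:-5], axis=1), 0.43, atol=1e-12)

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            synth.simulate_free_flight([1.0], groundspeed_target=0.0)


def test_generator_determinism_end_to_end(default_bee):
    proto = synth.build_protocol("linear_ramp_air")
    t1 = synth.simulate_iaa_trace(default_bee, proto, seed=5).frames
    t2 = synth.simulate_iaa_trace(default_bee, proto, seed=5).frames
    assert t1.equals(t2)
    b1 = synth.simulate_bin_means(default_bee, [1.0, 2.0], 10, "air", seed=4)
    b2 = synth.simulate_bin_means(default_bee, [1.0, 2.0], 10, "air", seed=4)
    assert all(np.array_equal(x.angles_deg, y.angles_deg) for x, y in zip(b1, b2))
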