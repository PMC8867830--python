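import numpy as np
import pytest

from tumortrack.motion import (
    ExtrapolationError,
    InsufficientHistoryError,
    IRMarkerTrace,
    LogfileSchemaError,
    LogfileValidationError,
    TargetTrace,
    TrackingLogfile,
    ir_position_at,
    ir_velocity_at,
    make_sample_pairs,
    read_logfile,
    split_logfile,
    write_logfile,
)

from conftest import grid, make_logfile


class TestTraceInvariants:
    def test_marker_trace_rejects_irregular_spacing(self):
        t = grid(1.0)
        t[10] += 0.002
        with pytest.raises(LogfileValidationError):
            IRMarkerTrace(1, t, np.zeros_like(t))

    def test_marker_trace_rejects_nonfinite(self):
        t = grid(1.0)
        p = np.zeros_like(t)
        p[3] = np.nan
        with pytest.raises(LogfileValidationError):
            IRMarkerTrace(1, t, p)

    def test_target_trace_rejects_gap_outside_bounds(self):
        with pytest.raises(LogfileValidationError, match="gap"):
            TargetTrace(np.array([0.0, 0.2, 0.9]), np.zeros((3, 3)))
        with pytest.raises(LogfileValidationError, match="gap"):
            TargetTrace(np.array([0.0, 0.05]), np.zeros((2, 3)))

    def test_logfile_requires_four_markers(self):
        lf = make_logfile()
        with pytest.raises(LogfileValidationError, match="4"):
            TrackingLogfile("x", lf.markers[:3], lf.target)

    def test_fixture_counts(self):
        lf = make_logfile(duration=30.0, det_gap=0.2)
        assert len(lf.markers) == 4
        assert lf.markers[0].timestamps.size == 1800
        assert lf.clinically_shaped


class TestRoundTrip:
    def test_lossless_round_trip(self, tmp_path, sim_logfile):
        path = write_logfile(sim_logfile, tmp_path / "f.h5")
        back = read_logfile(path)
        assert back.session_id == sim_logfile.session_id
        for a, b in zip(sim_logfile.markers, back.markers):
            assert a.marker_id == b.marker_id
            np.testing.assert_allclose(a.positions, b.positions, atol=1e-9)
            np.testing.assert_allclose(a.timestamps, b.timestamps, atol=1e-12)
        np.testing.assert_allclose(
            sim_logfile.target.positions3d, back.target.positions3d, atol=1e-9
        )

    def test_unicode_session_id_preserved(self, tmp_path):
        lf = make_logfile(session_id="séance-Δ-呼吸")
        back = read_logfile(write_logfile(lf, tmp_path / "u.h5"))
        assert back.session_id == "séance-Δ-呼吸"

    def test_schema_error_names_missing_field(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.attrs["session_id"] = "x"
            f.attrs["schema_version"] = "1"
            f.create_group("markers")
        with pytest.raises(LogfileSchemaError, match="target"):
            read_logfile(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_logfile(tmp_path / "nope.h5")


class TestSplit:
    def test_three_quarter_split_window(self):
        lf = make_logfile(duration=40.0)
        sp = split_logfile(lf, 0.75)
        t_split = lf.window[0] + 0.75 * lf.duration
        assert sp.train.window[1] <= t_split + 1e-9
        assert sp.test.window[0] > t_split
        assert t_split == pytest.approx(30.0, abs=2 / 60)

    @pytest.mark.parametrize("fraction", [0.5, 0.75])
    def test_split_conserves_counts(self, fraction):
        lf = make_logfile(duration=20.0)
        sp = split_logfile(lf, fraction)
        assert len(sp.train.target) + len(sp.test.target) == len(lf.target)
        n = sp.train.markers[0].timestamps.size + sp.test.markers[0].timestamps.size
        assert n == lf.markers[0].timestamps.size

    def test_boundary_sample_goes_to_train(self):
        # marker window exactly [0, 20] s so the half split lands on the
        # detection at t = 10.0 s
        t = np.arange(1201) / 60.0
        markers = [IRMarkerTrace(i + 1, t, np.sin(t)) for i in range(4)]
        det_t = np.arange(0.25, 19.8, 0.25)
        lf = TrackingLogfile(
            "b", markers, TargetTrace(det_t, np.zeros((det_t.size, 3)))
        )
        sp = split_logfile(lf, 0.5)
        assert 10.0 in sp.train.target.timestamps
        assert 10.0 not in sp.test.target.timestamps

    def test_empty_test_period_errors(self):
        t = grid(40.0)
        markers = [IRMarkerTrace(i + 1, t, np.sin(t)) for i in range(4)]
        det_t = np.arange(0.2, 5.0, 0.2)
        target = TargetTrace(det_t, np.zeros((det_t.size, 3)))
        lf = TrackingLogfile("early", markers, target)
        with pytest.raises(LogfileValidationError, match="test"):
            split_logfile(lf, 0.75)

    def test_bad_fraction(self, sine_logfile):
        with pytest.raises(ValueError):
            split_logfile(sine_logfile, 1.2)


class TestAlignment:
    def test_position_interpolates_ramp_exactly(self):
        t = grid(2.0)
        tr = IRMarkerTrace(1, t, t.copy())  # mm == s
        assert ir_position_at(tr, 1.2345) == pytest.approx(1.2345, abs=1e-12)

    def test_position_exact_at_stored_timestamps(self, sim_logfile):
        m = sim_logfile.markers[0]
        for i in (0, 17, 500, m.timestamps.size - 1):
            assert ir_position_at(m, m.timestamps[i]) == m.positions[i]

    def test_position_outside_span_errors(self, sine_logfile):
        with pytest.raises(ExtrapolationError):
            ir_position_at(sine_logfile.markers[0], -1.0)

    def test_sinusoid_interpolation_error_bound(self):
        A, T = 5.0, 4.0
        t = grid(8.0)
        tr = IRMarkerTrace(1, t, A * np.sin(2 * np.pi * t / T))
        dt = 1 / 60
        bound = A * (2 * np.pi / T) ** 2 * dt**2 / 8
        q = np.linspace(0.01, 7.9, 500)
        err = [
            abs(ir_position_at(tr, x) - A * np.sin(2 * np.pi * x / T)) for x in q
        ]
        assert max(err) <= bound * 1.01

    def test_velocity_exact_on_ramp(self):
        t = grid(2.0)
        tr = IRMarkerTrace(1, t, 3.0 * t)
        for q in (0.5, 1.0, 1.99):
            assert ir_velocity_at(tr, q) == pytest.approx(3.0, abs=1e-9)

    def test_velocity_zero_on_constant(self):
        t = grid(2.0)
        tr = IRMarkerTrace(1, t, np.full_like(t, 7.0))
        assert ir_velocity_at(tr, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_velocity_matches_analytic_derivative(self):
        A, T = 5.0, 4.0
        t = grid(8.0)
        tr = IRMarkerTrace(1, t, A * np.sin(2 * np.pi * t / T))
        # at t = T/2 and t = T the acceleration vanishes, so the causal
        # window's half-window lag introduces no bias there
        for q in (T / 2, T, 1.5 * T):
            v = ir_velocity_at(tr, q)
            truth = A * (2 * np.pi / T) * np.cos(2 * np.pi * q / T)
            assert v == pytest.approx(truth, rel=0.02)

    def test_velocity_insufficient_history(self, sine_logfile):
        with pytest.raises(InsufficientHistoryError):
            ir_velocity_at(sine_logfile.markers[0], 0.02)


class TestSamplePairs:
    def test_pair_count_matches_detections(self):
        lf = make_logfile(duration=40.0, det_gap=0.2)
        sp = split_logfile(lf, 0.75)
        pairs = make_sample_pairs(sp, "train")
        assert len(pairs) == len(sp.train.target)
        pairs_test = make_sample_pairs(sp, "test")
        assert len(pairs) + len(pairs_test) == len(lf.target)

    def test_identical_markers_average_to_each(self, sine_logfile):
        sp = split_logfile(sine_logfile, 0.75)
        pairs = make_sample_pairs(sp, "train")
        m = sine_logfile.markers[0]
        expected = [ir_position_at(m, t) for t in pairs["t"]]
        np.testing.assert_allclose(pairs["p_ir"], expected, atol=1e-12)

    def test_antisymmetric_markers_average_to_zero(self):
        f = lambda t: np.sin(t)
        lf = make_logfile(
            marker_fn=f,
        )
        # replace two markers with x and -x
        lf.markers[1] = IRMarkerTrace(
            2, lf.markers[0].timestamps, -lf.markers[0].positions
        )
        lf.markers[3] = IRMarkerTrace(
            4, lf.markers[2].timestamps, -lf.markers[2].positions
        )
        sp = split_logfile(lf, 0.75)
        pairs = make_sample_pairs(sp, "train")
        np.testing.assert_allclose(pairs["p_ir"], 0.0, atol=1e-12)

    def test_velocity_modes_agree_for_synchronized_traces(self, sim_split):
        a = make_sample_pairs(sim_split, "train", velocity_mode="per-marker")
        b = make_sample_pairs(sim_split, "train", velocity_mode="averaged-trace")
        np.testing.assert_allclose(a["v_ir"], b["v_ir"], atol=1e-9)
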