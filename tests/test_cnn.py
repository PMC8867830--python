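import numpy as np
import pytest

from tumortrack.cnn import (
    ArchitectureError,
    CnnArchitectureSpec,
    CnnReference,
    CnnReferenceResults,
    TrainingSchedule,
    assemble_batch,
    build_network,
    make_cnn_example,
)
from tumortrack.motion import TrackingLogfile, split_logfile
from tumortrack.simulate import CohortSpec, SimulatorConfig, simulate_cohort, simulate_logfile

from conftest import make_logfile

FAST = TrainingSchedule(reference_epochs=3, reference_lr=0.001)


@pytest.fixture(scope="module")
def tiny_cohort():
    return simulate_cohort(CohortSpec(3, master_seed=50, duration_range=(24.0, 30.0)))


@pytest.fixture(scope="module")
def tiny_reference(tiny_cohort):
    return CnnReference(tiny_cohort, schedule=FAST, seed=7).fit()


class TestArchitecture:
    def test_layer_census(self):
        net = build_network(CnnArchitectureSpec(), seed=0)
        assert net.census() == {
            "conv": 8, "batchnorm": 5, "dropout": 3, "flatten": 1, "dense": 2,
        }

    def test_census_violation_rejected(self):
        with pytest.raises(ArchitectureError):
            CnnArchitectureSpec(conv_channels=(8, 8), conv_kernels=(7, 5),
                                conv_strides=(2, 1))
        with pytest.raises(ArchitectureError):
            CnnArchitectureSpec(dropout_after_conv=(3, 5))
        with pytest.raises(ArchitectureError):
            CnnArchitectureSpec(output_dim=1)

    def test_forward_pass_shape_and_finiteness(self):
        net = build_network(CnnArchitectureSpec(), seed=1)
        x = np.random.default_rng(0).normal(size=(4, 5, 720))
        y = net.forward(x, training=False)
        assert y.shape == (4, 3)
        assert np.all(np.isfinite(y))

    def test_initialization_deterministic(self):
        a = build_network(CnnArchitectureSpec(), seed=3)
        b = build_network(CnnArchitectureSpec(), seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)


class TestSchedule:
    def test_fine_tune_rates_linear(self):
        r = TrainingSchedule().fine_tune_rates()
        assert r[0] == 5e-4 and r[-1] == 1e-4
        np.testing.assert_allclose(np.diff(r), np.diff(r)[0], atol=1e-12)

    def test_increasing_fine_tune_rate_rejected(self):
        with pytest.raises(ValueError):
            TrainingSchedule(fine_tune_lr=(1e-4, 5e-4))


class TestExampleExtraction:
    def test_stream_lengths(self, sim_logfile):
        sp = split_logfile(sim_logfile, 0.75)
        t = sp.test.target.timestamps[0]
        ex = make_cnn_example(sim_logfile, 1, t, sp.split_time, require_label=False)
        assert ex.context_ir.shape == (720,)
        assert ex.context_targets.shape == (25, 3)
        assert ex.recent_ir.shape == (50,)

    def test_constant_logfile_constant_streams(self):
        lf = make_logfile(marker_fn=lambda t: np.full_like(t, 2.0),
                          target_fn=lambda t: np.tile([1.0, 2.0, 3.0], (t.size, 1)))
        t = lf.target.timestamps[-1]
        ex = make_cnn_example(lf, 1, t, context_end=20.0)
        np.testing.assert_allclose(ex.context_ir, 2.0)
        np.testing.assert_allclose(ex.recent_ir, 2.0)
        np.testing.assert_allclose(ex.context_targets, np.tile([1, 2, 3], (25, 1)))
        np.testing.assert_allclose(ex.label, [1, 2, 3])

    def test_recent_window_index_arithmetic(self):
        lf = make_logfile(marker_fn=lambda t: t.copy())  # position == time
        t = 25.0
        ex = make_cnn_example(lf, 1, t, context_end=20.0, require_label=False)
        ts = lf.markers[0].timestamps
        n = int(np.searchsorted(ts, t + 1e-9))
        np.testing.assert_array_equal(ex.recent_ir, ts[n - 50 : n])
        assert ex.recent_ir[-1] <= t

    def test_window_too_short_errors(self, sim_logfile):
        with pytest.raises(ValueError, match="12 s"):
            make_cnn_example(sim_logfile, 1, 11.0, context_end=10.0,
                             require_label=False)

    def test_label_required(self, sim_logfile):
        with pytest.raises(ValueError, match="detection"):
            make_cnn_example(sim_logfile, 1, 12.34567, context_end=12.3)


class TestTraining:
    def test_descent_on_learnable_cohort(self, tiny_reference):
        h = tiny_reference.loss_history
        assert h[-1] < h[0]

    def test_deterministic_loss_trajectory(self, tiny_cohort):
        h1 = CnnReference(tiny_cohort, schedule=FAST, seed=9).fit().loss_history
        h2 = CnnReference(tiny_cohort, schedule=FAST, seed=9).fit().loss_history
        assert h1 == h2

    def test_constant_target_cohort_learned(self):
        lf = make_logfile(
            duration=28.0,
            marker_fn=lambda t: 5 * np.sin(2 * np.pi * t / 4),
            target_fn=lambda t: np.tile([0.5, 4.0, -1.0], (t.size, 1)),
        )
        ref = CnnReference([lf], schedule=FAST, seed=2).fit()
        assert ref.loss_history[-1] < 0.05

    def test_fine_tune_rates_and_stability(self, tiny_cohort, tiny_reference):
        sp = split_logfile(tiny_cohort[0], 0.75)
        tuned = tiny_reference.fine_tune(sp, seed=4)
        assert tuned.learning_rates[0] == 5e-4
        assert tuned.learning_rates[-1] == 1e-4
        # tuning on a file the reference already saw must not blow up
        assert tuned.loss_history[-1] < 1.1 * tuned.loss_history[0] + 0.05

    def test_fine_tune_adapts_to_shifted_coupling(self, tiny_reference):
        from tumortrack.simulate import DirectionalCoupling

        cfg = SimulatorConfig(
            target_coupling={
                "rl": DirectionalCoupling(gain=0.6, lag=0.25),
                "si": DirectionalCoupling(gain=3.1, lag=0.28, quadratic_coeff=-0.05),
                "ap": DirectionalCoupling(gain=0.8, lag=0.22),
            },
        )
        lf = simulate_logfile(cfg, seed=33)
        sp = split_logfile(lf, 0.75)
        times = sp.test.target.timestamps
        detect = sp.test.target.positions3d
        untuned = tiny_reference.predict_split(sp, times)
        tuned = tiny_reference.fine_tune(sp, seed=5).predict(times=times)
        err_untuned = np.linalg.norm(untuned - detect, axis=1).mean()
        err_tuned = np.linalg.norm(tuned - detect, axis=1).mean()
        assert err_tuned < err_untuned


class TestPrediction:
    def test_identical_markers_mean_idempotent(self, tiny_reference):
        lf = make_logfile()
        sp = split_logfile(lf, 0.75)
        times = sp.test.target.timestamps[:4]
        pred = tiny_reference.predict_split(sp, times)
        # manual single-marker forward must equal the 4-marker average
        ex = [
            make_cnn_example(lf, 1, t, sp.split_time, require_label=False)
            for t in times
        ]
        X, _, off, sc = assemble_batch(ex)
        single = tiny_reference.network.forward(X, training=False) * sc + off
        np.testing.assert_allclose(pred, single, atol=1e-9)

    def test_prediction_is_arithmetic_marker_mean(self, sim_logfile, tiny_reference):
        sp = split_logfile(sim_logfile, 0.75)
        times = sp.test.target.timestamps[:4]
        pred = tiny_reference.predict_split(sp, times)
        per_marker = []
        for m in sim_logfile.markers:
            ex = [
                make_cnn_example(sim_logfile, m.marker_id, t, sp.split_time,
                                 require_label=False)
                for t in times
            ]
            X, _, off, sc = assemble_batch(ex)
            per_marker.append(
                tiny_reference.network.forward(X, training=False) * sc + off
            )
        np.testing.assert_allclose(pred, np.mean(per_marker, axis=0), atol=1e-9)

    def test_marker_permutation_invariance(self, sim_logfile, tiny_reference):
        sp = split_logfile(sim_logfile, 0.75)
        times = sp.test.target.timestamps[:4]
        base = tiny_reference.predict_split(sp, times)
        permuted = TrackingLogfile(
            sim_logfile.session_id, sim_logfile.markers[::-1], sim_logfile.target
        )
        sp2 = split_logfile(permuted, 0.75)
        np.testing.assert_allclose(
            tiny_reference.predict_split(sp2, times), base, atol=1e-12
        )

    def test_checkpoint_round_trip(self, tmp_path, sim_logfile, tiny_reference):
        path = tmp_path / "ref.npz"
        tiny_reference.save(path)
        back = CnnReferenceResults.load(path)
        sp = split_logfile(sim_logfile, 0.75)
        times = sp.test.target.timestamps[:4]
        np.testing.assert_allclose(
            back.predict_split(sp, times),
            tiny_reference.predict_split(sp, times),
            atol=1e-12,
        )
        assert back.loss_history == tiny_reference.loss_history
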