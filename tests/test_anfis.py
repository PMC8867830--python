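import itertools

import numpy as np
import pytest

from tumortrack.anfis import (
    AnfisModel,
    AnfisResults,
    AnfisTrainConfig,
    candidate_lags,
    forward_select_inputs,
    generate_fis,
    hybrid_train,
    subtractive_clustering,
)
from tumortrack.motion import IRMarkerTrace, TrackingLogfile, split_logfile
from tumortrack.simulate import simulate_logfile


class TestCandidateLags:
    def test_fixed_set(self):
        lags = candidate_lags()
        assert lags.tolist() == list(range(11)) + [15, 20, 25, 30, 35, 40, 45, 50]
        assert lags.size == 19
        assert np.all(np.diff(lags) > 0)
        # deepest lag reaches ~0.83 s of 60 Hz history
        assert lags.max() / 60.0 == pytest.approx(0.833, abs=0.001)


class TestClusteringAndFis:
    def test_single_tight_cluster_one_rule(self):
        # one dense blob (tight relative to the normalized data span, which
        # a lone distant point defines); the outlier's potential falls
        # below the rejection threshold, leaving a single rule
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0.5, 0.01, 29), [1.5]]).reshape(-1, 1)
        y = np.concatenate([rng.normal(0.5, 0.01, 29), [1.5]])
        fis = generate_fis(X, y, cluster_radius=0.5)
        assert fis.n_rules == 1

    def test_two_separated_clusters_two_rules(self):
        # hand-placed blobs far apart relative to the radius
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0.0, 0.01, 20), rng.normal(1.0, 0.01, 20)])
        y = np.concatenate([np.zeros(20), np.ones(20)]) + rng.normal(0, 0.01, 40)
        fis = generate_fis(X.reshape(-1, 1), y, cluster_radius=0.3)
        assert fis.n_rules == 2
        # direct check against the clustering primitive on the unit square
        Z = np.column_stack(
            [(X - X.min()) / np.ptp(X), (y - y.min()) / np.ptp(y)]
        )
        centers = subtractive_clustering(Z, radius=0.3)
        assert centers.shape[0] == 2

    def test_firing_strengths_normalized(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-3, 3, (50, 2))
        y = X @ [1.0, -2.0] + 0.5
        fis = generate_fis(X, y)
        # inside and far outside the training hull
        queries = np.vstack([X, X + 50.0])
        w = fis.firing_strengths(queries)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_degenerate_rows_single_rule_warning(self):
        X = np.ones((10, 2))
        y = np.ones(10)
        with pytest.warns(UserWarning, match="degenerate"):
            fis = generate_fis(X, y)
        assert fis.n_rules == 1


class TestHybridTraining:
    def test_lse_step_exact_on_linear_target(self):
        x = np.linspace(0, 1, 40).reshape(-1, 1)
        y = 2.0 * x.ravel() + 1.0
        fis = generate_fis(x, y, cluster_radius=1.0, max_rules=1)
        assert fis.n_rules == 1
        fis, hist = hybrid_train(fis, x, y, AnfisTrainConfig(), epochs=1)
        assert hist[0] < 1e-8

    def test_constant_target(self):
        x = np.linspace(0, 1, 30).reshape(-1, 1)
        y = np.full(30, 4.2)
        fis = generate_fis(x, y)
        fis, hist = hybrid_train(fis, x, y, AnfisTrainConfig())
        assert hist[-1] < 1e-8
        np.testing.assert_allclose(fis.evaluate(x), 4.2, atol=1e-6)

    def test_error_trajectory_non_increasing(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-2, 2, (60, 2))
        y = np.sin(x[:, 0]) + 0.3 * x[:, 1] ** 2 + rng.normal(0, 0.05, 60)
        fis = generate_fis(x, y)
        fis, hist = hybrid_train(fis, x, y, AnfisTrainConfig(epochs=4))
        diffs = np.diff(hist)
        assert np.all(diffs <= 1e-9)

    def test_lse_matches_dense_normal_equations(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, (50, 2))
        y = x[:, 0] ** 2 - x[:, 1] + rng.normal(0, 0.1, 50)
        fis = generate_fis(x, y)
        # with memberships frozen, consequents are the global LSE optimum
        from tumortrack.anfis import _lse_design

        wn = fis.firing_strengths(x)
        Phi = _lse_design(wn, x)
        oracle, *_ = np.linalg.lstsq(Phi, y, rcond=None)
        resid_fis = fis.evaluate(x) - y
        resid_oracle = Phi @ oracle - y
        assert resid_fis @ resid_fis <= resid_oracle @ resid_oracle + 1e-6


def smooth_signal(n, seed, dt=1 / 60):
    """Band-limited random trace so different lags are distinguishable."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    sig = sum(
        a * np.sin(2 * np.pi * f * t + ph)
        for a, f, ph in zip(
            rng.uniform(1, 3, 6), rng.uniform(0.1, 1.2, 6), rng.uniform(0, 6.28, 6)
        )
    )
    return sig


class TestForwardSelection:
    def test_recovers_generating_lag_pair_vs_exhaustive(self):
        lags = candidate_lags()
        pos = smooth_signal(4000, seed=5)
        base = np.arange(60, 4000, 25)
        lagmat = pos[base[:, None] - lags[None, :]]
        y = 1.5 * lagmat[:, 0] - 0.8 * lagmat[:, list(lags).index(20)]
        cfg = AnfisTrainConfig(selection_size=2)
        chosen = forward_select_inputs(lagmat, y, cfg)
        assert set(chosen) == {0, 20}
        # exhaustive oracle over all C(19, 2) pairs
        best_err, best_pair = np.inf, None
        for i, j in itertools.combinations(range(19), 2):
            fis = generate_fis(lagmat[:, [i, j]], y, cfg.cluster_radius)
            _, hist = hybrid_train(fis, lagmat[:, [i, j]], y, cfg, epochs=1)
            if hist[-1] < best_err:
                best_err, best_pair = hist[-1], (lags[i], lags[j])
        assert set(best_pair) == {0, 20}

    def test_constant_target_tie_break_smallest_lags(self):
        pos = smooth_signal(2000, seed=6)
        base = np.arange(60, 2000, 30)
        lagmat = pos[base[:, None] - candidate_lags()[None, :]]
        y = np.full(base.size, 2.5)
        chosen = forward_select_inputs(lagmat, y, AnfisTrainConfig())
        assert chosen == [0, 1, 2, 3, 4]

    def test_returns_five_distinct_lags(self):
        pos = smooth_signal(3000, seed=7)
        base = np.arange(60, 3000, 40)
        lagmat = pos[base[:, None] - candidate_lags()[None, :]]
        y = lagmat[:, 3] ** 2 + lagmat[:, 12]
        chosen = forward_select_inputs(lagmat, y, AnfisTrainConfig())
        assert len(chosen) == 5
        assert len(set(chosen)) == 5
        assert set(chosen) <= set(candidate_lags().tolist())

    def test_greedy_matches_exhaustive_on_reduced_candidates(self):
        # <= 6 candidates: greedy must reach the best same-size subset when
        # the dependence is on a candidate subset
        reduced = [0, 5, 10, 20, 35, 50]
        pos = smooth_signal(3000, seed=8)
        base = np.arange(60, 3000, 25)
        lagmat = pos[base[:, None] - np.asarray(reduced)[None, :]]
        y = 2.0 * lagmat[:, 2] + 0.5 * lagmat[:, 5]  # lags 10 and 50
        cfg = AnfisTrainConfig(selection_size=2)
        chosen = forward_select_inputs(lagmat, y, cfg, lags=reduced)
        errs = {}
        for i, j in itertools.combinations(range(6), 2):
            fis = generate_fis(lagmat[:, [i, j]], y, cfg.cluster_radius)
            _, hist = hybrid_train(fis, lagmat[:, [i, j]], y, cfg, epochs=1)
            errs[frozenset((reduced[i], reduced[j]))] = hist[-1]
        best_set = min(errs, key=errs.get)
        assert frozenset(chosen) == best_set == frozenset({10, 50})
        cols = [reduced.index(l) for l in chosen]
        fis = generate_fis(lagmat[:, cols], y, cfg.cluster_radius)
        _, hist = hybrid_train(fis, lagmat[:, cols], y, cfg, epochs=1)
        assert hist[-1] <= errs[best_set] + 1e-9

    def test_too_few_rows(self):
        lagmat = np.zeros((10, 19))
        with pytest.raises(ValueError):
            forward_select_inputs(lagmat, np.zeros(10), AnfisTrainConfig())


@pytest.fixture(scope="module")
def fitted(noiseless_linear_config):
    lf = simulate_logfile(noiseless_linear_config, seed=21)
    sp = split_logfile(lf, 0.75)
    return lf, sp, AnfisModel(sp).fit()


class TestAnfisModel:

    def test_unit_cardinality(self, fitted):
        lf, sp, res = fitted
        assert len(res.units) == 4 * 3
        for (mid, d), u in res.units.items():
            assert len(u.lags) == 5

    def test_noiseless_linear_coupling_near_exact(self, fitted):
        lf, sp, res = fitted
        times = sp.test.target.timestamps
        err = np.linalg.norm(res.predict(times=times) - sp.test.target.positions3d, axis=1)
        assert err.mean() < 0.1

    def test_marker_permutation_invariance(self, fitted):
        lf, sp, res = fitted
        times = sp.test.target.timestamps[:10]
        base = res.predict(lf, times)
        permuted = TrackingLogfile(lf.session_id, lf.markers[::-1], lf.target)
        np.testing.assert_allclose(res.predict(permuted, times), base, atol=1e-12)

    def test_prediction_is_marker_mean(self, fitted):
        lf, sp, res = fitted
        times = sp.test.target.timestamps[:5]
        from tumortrack.anfis import _lag_features

        per_marker = []
        for m in lf.markers:
            cols = np.empty((times.size, 3))
            for i, d in enumerate(("rl", "si", "ap")):
                u = res.units[(m.marker_id, d)]
                cols[:, i] = u.fis.evaluate(
                    _lag_features(m.timestamps, m.positions, times, u.lags)
                )
            per_marker.append(cols)
        np.testing.assert_allclose(
            res.predict(lf, times), np.mean(per_marker, axis=0), atol=1e-12
        )

    def test_determinism(self, noiseless_linear_config):
        lf = simulate_logfile(noiseless_linear_config, seed=22)
        sp = split_logfile(lf, 0.75)
        r1 = AnfisModel(sp).fit()
        r2 = AnfisModel(sp).fit()
        t = sp.test.target.timestamps[:5]
        np.testing.assert_array_equal(r1.predict(times=t), r2.predict(times=t))

    def test_serialization_round_trip(self, fitted):
        lf, sp, res = fitted
        times = sp.test.target.timestamps[:8]
        back = AnfisResults.from_dict(res.to_dict())
        np.testing.assert_allclose(
            back.predict(lf, times), res.predict(lf, times), atol=1e-12
        )
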