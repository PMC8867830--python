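"""Sugeno ANFIS target-position predictor with lagged-input pattern search.

Per marker and per anatomical direction, a first-order Sugeno fuzzy
inference system maps a handful of lagged 60 Hz marker positions to the
internal target coordinate.  The candidate inputs are the 19 array lags
{0..10, 15, 20, 25, 30, 35, 40, 45, 50} behind the detection time (up to
0.83 s of history); a greedy sequential forward search keeps the 5 lags
that minimize the training total squared error.  Rule antecedents use
Gaussian membership functions seeded by subtractive clustering of the
joint input-output space; training is the classic hybrid scheme: the
linear rule consequents are solved exactly by least squares at each epoch
while the membership centers/widths take one normalized gradient step.
Cross-marker predictions are averaged arithmetically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .motion import SplitLogfile, TrackingLogfile

DIRECTIONS = ("rl", "si", "ap")

#: array lags (60 Hz sample offsets) of the 19 candidate inputs
CANDIDATE_LAGS = tuple(range(11)) + tuple(range(15, 51, 5))


def candidate_lags() -> np.ndarray:
    """The fixed 19-lag candidate set (sample offsets, strictly increasing)."""
    return np.asarray(CANDIDATE_LAGS, dtype=int)


@dataclass(frozen=True)
class AnfisTrainConfig:
    """Hybrid-learning and pattern-search hyperparameters."""

    epochs: int = 4
    selection_size: int = 5
    cluster_radius: float = 0.5
    selection_epochs: int = 1  # training budget per candidate during search
    step_size: float = 0.01  # normalized membership gradient step

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.selection_epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 1 <= self.selection_size <= len(CANDIDATE_LAGS):
            raise ValueError("selection_size must be in [1, 19]")
        if not 0.0 < self.cluster_radius <= 1.0:
            raise ValueError("cluster_radius must be in (0, 1]")


def subtractive_clustering(
    Z: np.ndarray,
    radius: float = 0.5,
    squash: float = 1.25,
    accept_ratio: float = 0.5,
    reject_ratio: float = 0.15,
    max_centers: Optional[int] = None,
) -> np.ndarray:
    """Chiu's subtractive clustering on data normalized to the unit box.

    Returns the selected cluster centers (rows of ``Z``).  Potentials use
    alpha = 4 / radius**2; after each selection the winner's potential
    field, widened by the squash factor, is subtracted.  Candidates between
    the accept and reject thresholds are kept only when distance-to-
    existing-centers plus relative potential reaches 1.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n == 0:
        raise ValueError("no data to cluster")
    alpha = 4.0 / radius**2
    beta = 4.0 / (squash * radius) ** 2
    d2 = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=2)
    P = np.exp(-alpha * d2).sum(axis=1)
    centers: list[int] = []
    p_ref = None
    while max_centers is None or len(centers) < max_centers:
        i = int(np.argmax(P))
        p = float(P[i])
        if p_ref is None:
            p_ref = p
            take = True
        elif p > accept_ratio * p_ref:
            take = True
        elif p < reject_ratio * p_ref:
            break
        else:
            dmin = np.sqrt(min(d2[i, c] for c in centers))
            if dmin / radius + p / p_ref >= 1.0:
                take = True
            else:
                P[i] = 0.0
                if np.all(P <= 0.0):
                    break
                continue
        if take:
            centers.append(i)
            P = P - p * np.exp(-beta * d2[:, i])
            P[i] = -np.inf
            if np.all(~np.isfinite(P) | (P <= 0.0)):
                break
    return Z[centers]


@dataclass
class SugenoFis:
    """First-order Sugeno system with Gaussian antecedent memberships.

    ``centers``/``sigmas`` are (rules, d) in raw input units; each rule's
    consequent is the linear form ``p . x + q`` stored as the (d+1)-row of
    ``consequents``.  The output is the firing-strength-normalized weighted
    sum of rule consequents.
    """

    centers: np.ndarray
    sigmas: np.ndarray
    consequents: np.ndarray  # (rules, d + 1)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.sigmas = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
        self.consequents = np.atleast_2d(np.asarray(self.consequents, dtype=float))
        if np.any(self.sigmas <= 0):
            raise ValueError("membership widths must be > 0")

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[1]

    def firing_strengths(self, X: np.ndarray) -> np.ndarray:
        """Normalized rule firing strengths, rows summing to 1.

        Computed in log space (softmax style), so far-from-hull queries
        degrade to the nearest rule instead of 0/0.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = (X[:, None, :] - self.centers[None, :, :]) / self.sigmas[None, :, :]
        logw = -0.5 * np.sum(z**2, axis=2)  # (n, rules)
        logw = logw - logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        return w / w.sum(axis=1, keepdims=True)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        wn = self.firing_strengths(X)
        f = X @ self.consequents[:, :-1].T + self.consequents[:, -1]  # (n, rules)
        return np.sum(wn * f, axis=1)


def _lse_design(wn: np.ndarray, X: np.ndarray) -> np.ndarray:
    n, r = wn.shape
    Xa = np.column_stack([X, np.ones(len(X))])  # (n, d+1)
    return (wn[:, :, None] * Xa[:, None, :]).reshape(n, r * Xa.shape[1])


def _solve_consequents(fis: SugenoFis, X: np.ndarray, y: np.ndarray) -> None:
    """Globally optimal consequents for the current memberships (LSE)."""
    wn = fis.firing_strengths(X)
    Phi = _lse_design(wn, X)
    # tiny always-on Tikhonov term for conditioning; escalated when the
    # system is genuinely singular
    gram = Phi.T @ Phi
    scale = max(1.0, float(np.trace(gram)) / Phi.shape[1])
    rank = np.linalg.matrix_rank(Phi)
    lam = 1e-10 * scale
    if rank < Phi.shape[1]:
        warnings.warn("singular consequent system; ridge-regularized solve", stacklevel=2)
        lam = 1e-8 * scale
    sol = np.linalg.solve(gram + lam * np.eye(Phi.shape[1]), Phi.T @ y)
    fis.consequents = sol.reshape(fis.n_rules, fis.n_inputs + 1)


def generate_fis(
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    cluster_radius: float = 0.5,
    max_rules: Optional[int] = None,
) -> SugenoFis:
    """Seed a Sugeno FIS by subtractive clustering of the joint space.

    One rule per cluster; Gaussian centers are the cluster centers
    projected on the inputs, widths ``radius * span / sqrt(8)`` per input;
    consequents initialized by global least squares.  ``max_rules`` caps
    the rule count on top of the data-support cap.
    """
    X = np.atleast_2d(np.asarray(train_inputs, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and np.ndim(train_inputs) == 1:
        X = X.T
    y = np.asarray(train_targets, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("inputs/targets length mismatch")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    joint = np.column_stack([X, y])
    lo = joint.min(axis=0)
    span = joint.max(axis=0) - lo
    span_safe = np.where(span > 0, span, 1.0)
    Z = (joint - lo) / span_safe
    if np.allclose(Z, Z[0]):
        warnings.warn("degenerate (identical) training rows; single-rule FIS", stacklevel=2)
        centers_z = Z[:1]
    else:
        # cap rules by data support: each first-order consequent carries
        # d+1 parameters, and fewer than ~3 rows per parameter puts the
        # consequent solve in the interpolation regime, where coefficients
        # explode and testing-period extrapolation diverges
        cap = max(1, X.shape[0] // (3 * (X.shape[1] + 1)))
        if max_rules is not None:
            cap = min(cap, max_rules)
        centers_z = subtractive_clustering(Z, radius=cluster_radius, max_centers=cap)
    centers = centers_z[:, :-1] * span_safe[:-1] + lo[:-1]
    x_span = span_safe[:-1]
    sigmas = np.tile(
        np.maximum(cluster_radius * x_span / np.sqrt(8.0), 1e-6), (centers.shape[0], 1)
    )
    fis = SugenoFis(
        centers=centers,
        sigmas=sigmas,
        consequents=np.zeros((centers.shape[0], X.shape[1] + 1)),
    )
    _solve_consequents(fis, X, y)
    return fis


def _sse(fis: SugenoFis, X: np.ndarray, y: np.ndarray) -> float:
    r = fis.evaluate(X) - y
    return float(r @ r)


def _membership_gradients(fis, X, y):
    """d(total squared error)/d(centers, sigmas)."""
    wn = fis.firing_strengths(X)  # (n, r)
    f = X @ fis.consequents[:, :-1].T + fis.consequents[:, -1]
    yhat = np.sum(wn * f, axis=1)
    e = yhat - y  # (n,)
    # dyhat/d(log w_r) = wn_r (f_r - yhat)
    dlogw = wn * (f - yhat[:, None]) * (2.0 * e)[:, None]  # (n, r)
    z = (X[:, None, :] - fis.centers[None, :, :]) / fis.sigmas[None, :, :]
    dc = np.einsum("nr,nrd->rd", dlogw, z / fis.sigmas[None, :, :])
    ds = np.einsum("nr,nrd->rd", dlogw, z**2 / fis.sigmas[None, :, :])
    return dc, ds


def hybrid_train(
    fis: SugenoFis,
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    config: AnfisTrainConfig = AnfisTrainConfig(),
    epochs: Optional[int] = None,
) -> tuple[SugenoFis, list[float]]:
    """Hybrid-optimize a FIS: exact consequent LSE + membership gradient.

    Per epoch the consequents are re-solved exactly for the current
    memberships, the total squared error logged, and one normalized
    gradient step (adaptive length, rejected and halved on error increase)
    applied to the Gaussian centers and widths.  The logged trajectory is
    therefore non-increasing.  Returns ``(fis, error_history)``.
    """
    X = np.atleast_2d(np.asarray(train_inputs, dtype=float))
    if np.ndim(train_inputs) == 1:
        X = np.asarray(train_inputs, dtype=float).reshape(-1, 1)
    y = np.asarray(train_targets, dtype=float).ravel()
    n_epochs = config.epochs if epochs is None else epochs
    step = config.step_size * float(np.mean(np.ptp(X, axis=0)) or 1.0)
    history: list[float] = []
    for _ in range(n_epochs):
        _solve_consequents(fis, X, y)
        err = _sse(fis, X, y)
        history.append(err)
        dc, ds = _membership_gradients(fis, X, y)
        norm = float(np.sqrt(np.sum(dc**2) + np.sum(ds**2)))
        if norm <= 1e-300:
            continue
        c_old, s_old = fis.centers.copy(), fis.sigmas.copy()
        fis.centers = fis.centers - step * dc / norm
        fis.sigmas = np.maximum(fis.sigmas - step * ds / norm, 1e-6)
        _solve_consequents(fis, X, y)
        if _sse(fis, X, y) > err:
            fis.centers, fis.sigmas = c_old, s_old
            _solve_consequents(fis, X, y)
            step *= 0.5
        else:
            step *= 1.1
    _solve_consequents(fis, X, y)
    history.append(_sse(fis, X, y))
    return fis, history


def forward_select_inputs(
    lag_matrix: np.ndarray,
    targets: np.ndarray,
    config: AnfisTrainConfig = AnfisTrainConfig(),
    lags: Sequence[int] = CANDIDATE_LAGS,
) -> list[int]:
    """Greedy sequential forward selection of lags.

    ``lag_matrix`` has one column per candidate lag (same order as
    ``lags``).  At each round every unselected lag is tentatively appended,
    a fresh FIS is generated and briefly hybrid-trained
    (``selection_epochs``), and the lag with minimum training total squared
    error is kept; exact ties go to the smaller lag.  Returns
    ``selection_size`` lags in selection order.
    """
    X = np.asarray(lag_matrix, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    lags = list(lags)
    if X.shape[1] != len(lags):
        raise ValueError("lag_matrix columns must match the candidate lags")
    if X.shape[0] < len(lags) + config.selection_size:
        raise ValueError(
            f"need >= {len(lags) + config.selection_size} training rows, have {X.shape[0]}"
        )
    selected: list[int] = []
    sel_cols: list[int] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(config.selection_size):
            best_err, best_j = np.inf, None
            for j in np.argsort(lags):  # ascending lag => ties to smaller lag
                if j in sel_cols:
                    continue
                cols = sel_cols + [j]
                fis = generate_fis(X[:, cols], y, config.cluster_radius)
                _, hist = hybrid_train(fis, X[:, cols], y, config,
                                       epochs=config.selection_epochs)
                err = hist[-1]
                if not np.isfinite(err):
                    continue
                if best_j is None or err < best_err - 1e-12 * max(1.0, best_err):
                    best_err, best_j = err, int(j)
            if best_j is None:
                raise RuntimeError("no candidate produced a finite training error")
            sel_cols.append(best_j)
            selected.append(int(lags[best_j]))
    return selected


def _lag_features(
    marker_ts: np.ndarray, marker_pos: np.ndarray, times: np.ndarray,
    lags: Sequence[int],
) -> np.ndarray:
    """Lagged marker positions at each detection time.

    The base index is the last 60 Hz sample at or before t; lags index
    backwards into the marker array.
    """
    idx = np.searchsorted(marker_ts, np.asarray(times) + 1e-9) - 1
    if np.any(idx < max(lags)):
        raise ValueError("insufficient marker history for the requested lags")
    return marker_pos[idx[:, None] - np.asarray(lags)[None, :]]


@dataclass
class _FisUnit:
    lags: list[int]
    fis: SugenoFis
    error_history: list[float]


class AnfisModel:
    """Per-session ANFIS predictor (one FIS per marker and direction)."""

    def __init__(
        self,
        split: SplitLogfile,
        config: AnfisTrainConfig = AnfisTrainConfig(),
    ) -> None:
        self.split = split
        self.config = config

    @classmethod
    def from_logfile(cls, logfile: TrackingLogfile, fraction: float = 0.75,
                     config: AnfisTrainConfig = AnfisTrainConfig()) -> "AnfisModel":
        from .motion import split_logfile

        return cls(split_logfile(logfile, fraction), config=config)

    def fit(self) -> "AnfisResults":
        lf = self.split.original
        all_lags = candidate_lags()
        train_t = self.split.train.target.timestamps
        usable = []
        for t in train_t:
            i = np.searchsorted(lf.markers[0].timestamps, t + 1e-9) - 1
            if i >= max(CANDIDATE_LAGS):
                usable.append(t)
        usable = np.asarray(usable)
        labels = {
            d: self.split.train.target.positions3d[np.isin(train_t, usable), i]
            for i, d in enumerate(DIRECTIONS)
        }
        units: dict[tuple[int, str], _FisUnit] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for m in lf.markers:
                lagmat = _lag_features(m.timestamps, m.positions, usable, all_lags)
                for d in DIRECTIONS:
                    y = labels[d]
                    lags = forward_select_inputs(lagmat, y, self.config, all_lags)
                    cols = [list(all_lags).index(l) for l in lags]
                    fis = generate_fis(lagmat[:, cols], y, self.config.cluster_radius)
                    fis, hist = hybrid_train(fis, lagmat[:, cols], y, self.config)
                    units[(m.marker_id, d)] = _FisUnit(lags, fis, hist)
        return AnfisResults(model=self, units=units)


@dataclass
class AnfisResults:
    """Fitted per-(marker, direction) FIS units with their selected lags."""

    model: Optional[AnfisModel]
    units: dict[tuple[int, str], _FisUnit]

    def predict(self, logfile: TrackingLogfile | None = None, times=None) -> np.ndarray:
        """(n, 3) marker-averaged predictions at ``times``."""
        if times is None:
            raise ValueError("times is required")
        if logfile is None and self.model is None:
            raise ValueError("logfile is required for a deserialized model")
        lf = logfile if logfile is not None else self.model.split.original
        times = np.atleast_1d(np.asarray(times, dtype=float))
        per_marker = []
        for m in lf.markers:
            cols = np.empty((times.size, 3))
            for i, d in enumerate(DIRECTIONS):
                unit = self.units[(m.marker_id, d)]
                feats = _lag_features(m.timestamps, m.positions, times, unit.lags)
                cols[:, i] = unit.fis.evaluate(feats)
            per_marker.append(cols)
        return np.mean(per_marker, axis=0)

    def selected_lags(self) -> dict[tuple[int, str], list[int]]:
        return {k: list(u.lags) for k, u in self.units.items()}

    def to_dict(self) -> dict:
        """Human-inspectable serialization (centers, widths, consequents)."""
        out = {}
        for (mid, d), u in self.units.items():
            out[f"marker{mid}_{d}"] = {
                "lags": [int(l) for l in u.lags],
                "centers": u.fis.centers.tolist(),
                "sigmas": u.fis.sigmas.tolist(),
                "consequents": u.fis.consequents.tolist(),
                "final_sse": u.error_history[-1],
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "AnfisResults":
        units: dict[tuple[int, str], _FisUnit] = {}
        for key, u in d.items():
            mid_s, direction = key.removeprefix("marker").rsplit("_", 1)
            fis = SugenoFis(
                centers=np.asarray(u["centers"], dtype=float),
                sigmas=np.asarray(u["sigmas"], dtype=float),
                consequents=np.asarray(u["consequents"], dtype=float),
            )
            units[(int(mid_s), direction)] = _FisUnit(
                lags=[int(l) for l in u["lags"]], fis=fis,
                error_history=[float(u["final_sse"])],
            )
        return cls(model=None, units=units)

    def summary(self) -> str:
        lines = ["Sugeno ANFIS predictor (per marker x direction)", "-" * 56]
        for (mid, d), u in sorted(self.units.items()):
            lines.append(
                f"marker {mid} {d}: lags {u.lags}, rules {u.fis.n_rules}, "
                f"SSE {u.error_history[0]:.4g} -> {u.error_history[-1]:.4g} mm^2"
            )
        return "\n".join(lines)


def fit_anfis(
    split: SplitLogfile, config: AnfisTrainConfig = AnfisTrainConfig()
) -> AnfisResults:
    """Functional wrapper: lag selection + 4-epoch hybrid training."""
    return AnfisModel(split, config=config).fit()


def predict_anfis(results: AnfisResults, logfile: TrackingLogfile, t) -> np.ndarray:
    """Functional wrapper: marker-averaged prediction at time(s) ``t``."""
    out = results.predict(logfile, np.atleast_1d(t))
    return out[0] if np.ndim(t) == 0 else out
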