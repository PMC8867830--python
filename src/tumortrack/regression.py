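"""Clinical baseline predictor: quadratic position/velocity regression.

The gimbal-head tracking system builds, per session, the model

    f(P_IR, v_IR) = a * P_IR**2 + b * P_IR + c + d * v_IR**2 + e * v_IR,

where ``P_IR`` is the cross-marker averaged 1-D IR-marker position and
``v_IR`` its averaged vertical velocity, and applies it per anatomical
direction (RL, SI, AP; 15 coefficients in total).  Marker positions are
extrapolated 25 ms forward from their causal velocity to compensate for
the system latency.  Coefficients are fitted by ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motion import (
    DEFAULT_VELOCITY_WINDOW,
    IRMarkerTrace,
    SplitLogfile,
    TrackingLogfile,
    ir_position_at,
    ir_velocity_at,
    split_logfile,
)

DIRECTIONS = ("rl", "si", "ap")
FEATURE_NAMES = ("p_ir^2", "p_ir", "const", "v_ir^2", "v_ir")


class RankDeficientDesignError(ValueError):
    """The quadratic feature matrix is collinear."""


@dataclass(frozen=True)
class LatencyPolicy:
    """Forward extrapolation of marker positions to offset system delay."""

    compensation: float = 0.025  # s

    def __post_init__(self) -> None:
        if self.compensation < 0:
            raise ValueError("latency compensation must be >= 0")


@dataclass
class RegressionCoefficients:
    """(a, b, c, d, e) per direction; rows ordered RL, SI, AP."""

    values: np.ndarray  # (3, 5)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3, 5):
            raise ValueError("coefficients must have shape (3, 5)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficients must be finite")

    def for_direction(self, direction: str) -> np.ndarray:
        return self.values[DIRECTIONS.index(direction)]

    def to_dict(self) -> dict:
        return {
            d: dict(zip("abcde", map(float, self.values[i])))
            for i, d in enumerate(DIRECTIONS)
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionCoefficients":
        vals = [[d[dir_][k] for k in "abcde"] for dir_ in DIRECTIONS]
        return cls(np.asarray(vals, dtype=float))


def compensate_latency(
    trace: IRMarkerTrace,
    policy: LatencyPolicy = LatencyPolicy(),
    window: int = DEFAULT_VELOCITY_WINDOW,
) -> IRMarkerTrace:
    """Replace each position by its linear extrapolation ``compensation``
    seconds forward using the causal least-squares velocity.

    Timestamps are unchanged.  The leading ``window - 1`` samples lack the
    velocity history and pass through unmodified (a warning is emitted once
    per call when that happens and compensation is non-zero).
    """
    if policy.compensation == 0.0:
        return IRMarkerTrace(trace.marker_id, trace.timestamps.copy(), trace.positions.copy())
    n = trace.positions.size
    out = trace.positions.copy()
    start = min(window - 1, n)
    if start > 0:
        warnings.warn(
            f"marker {trace.marker_id}: first {start} samples lack velocity "
            "history and were not latency-compensated",
            stacklevel=2,
        )
    ts = trace.timestamps
    pos = trace.positions
    for i in range(start, n):
        tw = ts[i - window + 1 : i + 1]
        pw = pos[i - window + 1 : i + 1]
        tc = tw - tw.mean()
        v = float(np.dot(tc, pw - pw.mean()) / np.dot(tc, tc))
        out[i] = pos[i] + v * policy.compensation
    return IRMarkerTrace(trace.marker_id, ts.copy(), out)


def _design_matrix(p_ir: np.ndarray, v_ir: np.ndarray) -> np.ndarray:
    return np.column_stack([p_ir**2, p_ir, np.ones_like(p_ir), v_ir**2, v_ir])


def _check_rank(X: np.ndarray) -> None:
    # pivoted-QR style diagnostic: report which feature columns collapse
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps * 1e3 if s[0] > 0 else 1.0
    if s[-1] > tol:
        return
    null = vt[s <= tol]
    involved = sorted(
        {FEATURE_NAMES[j] for row in null for j in np.nonzero(np.abs(row) > 0.1)[0]}
    )
    raise RankDeficientDesignError(
        f"collinear regression features: {', '.join(involved)}"
    )


def fit_regression(pairs: pd.DataFrame) -> RegressionCoefficients:
    """Ordinary-least-squares fit of the quadratic model per direction.

    ``pairs`` is the aligned sample table from
    :func:`tumortrack.motion.make_sample_pairs` (columns ``t, p_ir, v_ir,
    rl, si, ap``); at least 5 rows with a full-rank feature matrix are
    required.
    """
    if len(pairs) < 5:
        raise ValueError("need at least 5 training pairs")
    X = _design_matrix(pairs["p_ir"].to_numpy(), pairs["v_ir"].to_numpy())
    _check_rank(X)
    coef = np.empty((3, 5))
    for i, d in enumerate(DIRECTIONS):
        coef[i], *_ = np.linalg.lstsq(X, pairs[d].to_numpy(), rcond=None)
    return RegressionCoefficients(coef)


def predict_regression(
    coeffs: RegressionCoefficients, p_ir: float, v_ir: float
) -> np.ndarray:
    """Evaluate the quadratic model; returns the (RL, SI, AP) triple in mm."""
    p = np.atleast_1d(np.asarray(p_ir, dtype=float))
    v = np.atleast_1d(np.asarray(v_ir, dtype=float))
    X = _design_matrix(p, v)
    out = X @ coeffs.values.T
    return out[0] if np.isscalar(p_ir) or np.ndim(p_ir) == 0 else out


def predict_with_coefficients(
    coeffs: RegressionCoefficients,
    logfile: TrackingLogfile,
    times,
    latency: LatencyPolicy = LatencyPolicy(),
    apply_latency: str = "both",
    velocity_window: int = DEFAULT_VELOCITY_WINDOW,
) -> np.ndarray:
    """Evaluate fitted coefficients on a session's marker traces."""
    markers = logfile.markers
    if apply_latency in ("both", "predict"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            markers = [compensate_latency(m, latency, velocity_window) for m in markers]
    times = np.atleast_1d(np.asarray(times, dtype=float))
    p = np.array([np.mean([ir_position_at(m, t) for m in markers]) for t in times])
    v = np.array(
        [np.mean([ir_velocity_at(m, t, velocity_window) for m in markers]) for t in times]
    )
    return predict_regression(coeffs, p, v)


class QuadraticRegression:
    """Quadratic position/velocity model for one session's training period.

    Parameters
    ----------
    train : TrackingLogfile
        Training period (markers + target detections).
    full_session : TrackingLogfile, optional
        The unsplit session, used so early test detections keep their
        marker history; defaults to ``train``.
    latency : LatencyPolicy
        25-ms forward extrapolation of marker positions; applied during
        both fitting and prediction by default (``apply_latency``).
    """

    def __init__(
        self,
        train: TrackingLogfile,
        full_session: TrackingLogfile | None = None,
        latency: LatencyPolicy = LatencyPolicy(),
        apply_latency: str = "both",  # 'both', 'fit', 'predict', 'none'
        velocity_window: int = DEFAULT_VELOCITY_WINDOW,
    ) -> None:
        if apply_latency not in ("both", "fit", "predict", "none"):
            raise ValueError("apply_latency must be both/fit/predict/none")
        self.train = train
        self.full_session = full_session if full_session is not None else train
        self.latency = latency
        self.apply_latency = apply_latency
        self.velocity_window = velocity_window

    @classmethod
    def from_split(cls, split: SplitLogfile, **kw) -> "QuadraticRegression":
        return cls(split.train, full_session=split.original, **kw)

    @classmethod
    def from_logfile(
        cls, logfile: TrackingLogfile, fraction: float = 0.75, **kw
    ) -> "QuadraticRegression":
        return cls.from_split(split_logfile(logfile, fraction), **kw)

    # -- internals ----------------------------------------------------

    def _markers(self, stage: str) -> list[IRMarkerTrace]:
        markers = self.full_session.markers
        if self.apply_latency in ("both", stage):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                markers = [
                    compensate_latency(m, self.latency, self.velocity_window)
                    for m in markers
                ]
        return markers

    def _features_at(self, markers, times) -> tuple[np.ndarray, np.ndarray]:
        p = np.array(
            [np.mean([ir_position_at(m, t) for m in markers]) for t in times]
        )
        v = np.array(
            [
                np.mean([ir_velocity_at(m, t, self.velocity_window) for m in markers])
                for t in times
            ]
        )
        return p, v

    def fit(self) -> "QuadraticRegressionResults":
        markers = self._markers("fit")
        times = self.train.target.timestamps
        p, v = self._features_at(markers, times)
        pairs = pd.DataFrame(
            {
                "t": times,
                "p_ir": p,
                "v_ir": v,
                "rl": self.train.target.positions3d[:, 0],
                "si": self.train.target.positions3d[:, 1],
                "ap": self.train.target.positions3d[:, 2],
            }
        )
        coeffs = fit_regression(pairs)
        fitted = predict_regression(coeffs, p, v)
        resid = self.train.target.positions3d - fitted
        X = _design_matrix(p, v)
        # per-direction OLS standard errors
        xtx_inv = np.linalg.pinv(X.T @ X)
        dof = max(len(pairs) - 5, 1)
        bse = np.sqrt(
            np.outer(np.sum(resid**2, axis=0) / dof, np.diag(xtx_inv))
        )
        return QuadraticRegressionResults(
            model=self, coefficients=coeffs, pairs=pairs, resid=resid, bse=bse
        )


@dataclass
class QuadraticRegressionResults:
    """Fitted coefficients plus training diagnostics."""

    model: QuadraticRegression
    coefficients: RegressionCoefficients
    pairs: pd.DataFrame
    resid: np.ndarray  # (n, 3) training residuals, mm
    bse: np.ndarray  # (3, 5) coefficient standard errors

    @property
    def params(self) -> np.ndarray:
        return self.coefficients.values

    @property
    def train_mae_3d(self) -> float:
        return float(np.mean(np.linalg.norm(self.resid, axis=1)))

    def predict(self, logfile: TrackingLogfile, times) -> np.ndarray:
        """Predicted (n, 3) target positions at ``times`` using the marker
        traces of ``logfile`` (latency-compensated per policy)."""
        return predict_with_coefficients(
            self.coefficients,
            logfile,
            times,
            latency=self.model.latency,
            apply_latency=self.model.apply_latency,
            velocity_window=self.model.velocity_window,
        )

    def summary(self) -> str:
        lines = [
            "Quadratic position/velocity regression",
            "f(P_IR, v_IR) = a P^2 + b P + c + d v^2 + e v   (per direction)",
            "-" * 64,
            f"{'dir':<5}" + "".join(f"{k:>11}" for k in "abcde"),
        ]
        for i, d in enumerate(DIRECTIONS):
            lines.append(
                f"{d:<5}" + "".join(f"{x:>11.4g}" for x in self.coefficients.values[i])
            )
            lines.append(
                f"{'(se)':<5}" + "".join(f"{x:>11.2g}" for x in self.bse[i])
            )
        lines.append(f"n = {len(self.pairs)}, training 3-D MAE = {self.train_mae_3d:.4f} mm")
        return "\n".join(lines)
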