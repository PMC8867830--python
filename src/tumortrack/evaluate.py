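"""Tracking-accuracy and respiratory-change statistics.

Prediction accuracy follows the ISO 5725-1 framing: trueness is the mean
absolute 3-D positional error (MAE), precision its sample standard
deviation (SD), and models are ranked per session by MAE + 2 SD and by the
percentage of predictions within 2 mm of the detected target.  Breathing
traces are summarized by the peak-to-peak range R, the period T and the
90th-percentile speed v90; their relative change between training and
testing periods is delta = |value_test / value_train - 1|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from scipy.ndimage import uniform_filter1d

from .motion import IRMarkerTrace, SplitLogfile, TrackingLogfile

TWO_MM = 2.0
SIGNIFICANCE_LEVEL = 0.05

#: moving-average width used to locate breathing extrema (s)
_SMOOTH_S = 0.5
#: half-width of the raw-trace refinement window around each extremum (s)
_REFINE_S = 0.25
#: Savitzky-Golay derivative window for the speed percentile (s)
_DERIV_S = 0.25


def positional_error_3d(pred, detect) -> float:
    """Euclidean 3-D distance between predicted and detected positions (mm)."""
    p = np.asarray(pred, dtype=float)
    d = np.asarray(detect, dtype=float)
    return float(np.linalg.norm(p - d))


def positional_errors_3d(pred, detect) -> np.ndarray:
    """Row-wise 3-D error norms for (n, 3) prediction/detection arrays."""
    p = np.asarray(pred, dtype=float).reshape(-1, 3)
    d = np.asarray(detect, dtype=float).reshape(-1, 3)
    return np.linalg.norm(p - d, axis=1)


def pct_within(errors, threshold: float) -> float:
    """Percentage of errors at or below ``threshold`` mm."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error sequence")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return 100.0 * float(np.count_nonzero(e <= threshold)) / e.size


def cumulative_curve(errors, grid) -> np.ndarray:
    """Cumulative percentage of errors within each grid threshold (mm)."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error sequence")
    g = np.asarray(grid, dtype=float)
    return 100.0 * np.searchsorted(np.sort(e), g, side="right") / e.size


def mae_sd(errors) -> tuple[float, float, float]:
    """(MAE, SD, MAE + 2 SD) of an error sequence (mm).

    Errors are non-negative 3-D norms, so the MAE is their plain mean; SD
    uses the n-1 sample convention.
    """
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 errors")
    mae = float(np.mean(e))
    sd = float(np.std(e, ddof=1))
    return mae, sd, mae + 2.0 * sd


@dataclass(frozen=True)
class BreathingMetrics:
    """Peak-to-peak range R (mm), period T (s), 90th-percentile speed v90 (mm/s)."""

    R: float
    T: float
    v90: float


def breathing_metrics(trace: IRMarkerTrace) -> BreathingMetrics:
    """Cycle statistics of a 60 Hz breathing trace.

    Extrema are located on a 0.5-s moving-average copy with a prominence
    floor of 20 % of the trace span, then each extremum value is refined on
    the raw trace within +/- 0.25 s so smoothing does not bias the range.
    R averages peak-minus-following-trough over cycles; T averages the
    peak-to-peak intervals; v90 is the 90th percentile of the absolute
    Savitzky-Golay (0.25 s, quadratic) derivative of the raw trace.
    """
    t = trace.timestamps
    p = trace.positions
    dt = float(np.median(np.diff(t)))
    w = max(3, int(round(_SMOOTH_S / dt)))
    smooth = uniform_filter1d(p, size=w, mode="nearest")
    prom = 0.2 * (smooth.max() - smooth.min())
    peaks, _ = sp_signal.find_peaks(smooth, prominence=prom)
    troughs, _ = sp_signal.find_peaks(-smooth, prominence=prom)
    # short windows may expose only one interior peak; the sharp troughs
    # carry the same cycle information, so use whichever family is richer
    family = peaks if peaks.size >= troughs.size else troughs
    if family.size < 2:
        raise ValueError("fewer than 2 breathing cycles detected")
    T = float(np.mean(np.diff(t[family])))

    half = max(1, int(round(_REFINE_S / dt)))

    def refine(idx: int, kind: str) -> float:
        lo, hi = max(0, idx - half), min(p.size, idx + half + 1)
        seg = p[lo:hi]
        return float(seg.max() if kind == "peak" else seg.min())

    merged = sorted(
        [(i, "peak") for i in peaks] + [(i, "trough") for i in troughs]
    )
    ranges = [
        abs(refine(a_i, a_k) - refine(b_i, b_k))
        for (a_i, a_k), (b_i, b_k) in zip(merged, merged[1:])
        if a_k != b_k
    ]
    if not ranges:
        raise ValueError("no complete peak-to-trough half-cycle detected")
    R = float(np.mean(ranges))

    wd = max(5, int(round(_DERIV_S / dt)) | 1)  # odd window
    v = sp_signal.savgol_filter(p, wd, polyorder=2, deriv=1, delta=dt)
    v90 = float(np.percentile(np.abs(v), 90))
    return BreathingMetrics(R=R, T=T, v90=v90)


def delta(value_train: float, value_test: float) -> float:
    """Relative change |value_test / value_train - 1| (unitless)."""
    if value_train == 0:
        raise ValueError("training-period value must be non-zero")
    return abs(value_test / value_train - 1.0)


@dataclass(frozen=True)
class DeltaMetrics:
    """Relative training-to-testing change of the breathing statistics."""

    delta_r: float
    delta_p: float
    delta_v: float


def delta_metrics(split: SplitLogfile) -> DeltaMetrics:
    """Breathing-pattern change between the training and testing periods.

    Computed on the cross-marker averaged trace of each period.  Short
    testing periods occasionally contain fewer than two detectable cycles;
    the affected deltas are returned as NaN rather than raising.
    """

    def averaged(lf: TrackingLogfile) -> IRMarkerTrace:
        return IRMarkerTrace(
            0, lf.markers[0].timestamps, np.mean([m.positions for m in lf.markers], axis=0)
        )

    try:
        m_train = breathing_metrics(averaged(split.train))
        m_test = breathing_metrics(averaged(split.test))
    except ValueError:
        return DeltaMetrics(float("nan"), float("nan"), float("nan"))
    return DeltaMetrics(
        delta_r=delta(m_train.R, m_test.R),
        delta_p=delta(m_train.T, m_test.T),
        delta_v=delta(m_train.v90, m_test.v90),
    )


DEFAULT_CURVE_GRID = np.round(np.arange(0.0, 10.01, 0.25), 2)


@dataclass
class EvaluationReport:
    """Accuracy of one model on one session's testing period."""

    session_id: str
    model: str
    errors: np.ndarray  # per-detection 3-D error norms, mm
    mae: float
    sd: float
    mae_plus_2sd: float
    pct_within_2mm: float
    curve_grid: np.ndarray
    curve: np.ndarray
    per_axis_mae: tuple[float, float, float]  # RL, SI, AP
    deltas: Optional[DeltaMetrics] = None

    def to_dict(self) -> dict:
        d = {
            "session_id": self.session_id,
            "model": self.model,
            "n": int(self.errors.size),
            "mae": self.mae,
            "sd": self.sd,
            "mae_plus_2sd": self.mae_plus_2sd,
            "pct_within_2mm": self.pct_within_2mm,
            "per_axis_mae": list(self.per_axis_mae),
        }
        if self.deltas is not None:
            d["delta_r"] = self.deltas.delta_r
            d["delta_p"] = self.deltas.delta_p
            d["delta_v"] = self.deltas.delta_v
        return d


def evaluate_predictions(
    session_id: str,
    model: str,
    pred: np.ndarray,
    detect: np.ndarray,
    deltas: Optional[DeltaMetrics] = None,
    curve_grid: np.ndarray = DEFAULT_CURVE_GRID,
) -> EvaluationReport:
    """Score (n, 3) predictions against detections for one session."""
    pred = np.asarray(pred, dtype=float).reshape(-1, 3)
    detect = np.asarray(detect, dtype=float).reshape(-1, 3)
    errors = positional_errors_3d(pred, detect)
    mae, sd, m2 = mae_sd(errors)
    axis_mae = tuple(float(x) for x in np.mean(np.abs(pred - detect), axis=0))
    return EvaluationReport(
        session_id=session_id,
        model=model,
        errors=errors,
        mae=mae,
        sd=sd,
        mae_plus_2sd=m2,
        pct_within_2mm=pct_within(errors, TWO_MM),
        curve_grid=np.asarray(curve_grid, dtype=float),
        curve=cumulative_curve(errors, curve_grid),
        per_axis_mae=axis_mae,
        deltas=deltas,
    )


@dataclass
class ModelComparison:
    """Cross-session comparison of several fitted predictors."""

    reports: list[EvaluationReport]
    model_names: list[str]
    best_model: dict[str, str]  # session_id -> winning model (min MAE + 2 SD)
    win_counts: dict[str, int]
    ttests: dict[str, dict]  # model -> {p_value, t, mean_diff, degenerate}
    tie_sessions: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.reports])

    def pooled_pct_within_2mm(self, model: str) -> float:
        errs = np.concatenate([r.errors for r in self.reports if r.model == model])
        return pct_within(errs, TWO_MM)

    def median_mae(self, model: str) -> float:
        return float(np.median([r.mae for r in self.reports if r.model == model]))

    def pooled_curve(self, model: str) -> tuple[np.ndarray, np.ndarray]:
        errs = np.concatenate([r.errors for r in self.reports if r.model == model])
        return DEFAULT_CURVE_GRID, cumulative_curve(errs, DEFAULT_CURVE_GRID)

    def summary(self) -> str:
        lines = ["Model comparison (testing periods)", "=" * 56]
        lines.append(
            f"{'model':<12}{'median MAE':>12}{'% <=2 mm':>12}{'wins':>8}"
        )
        for m in self.model_names:
            lines.append(
                f"{m:<12}{self.median_mae(m):>12.3f}"
                f"{self.pooled_pct_within_2mm(m):>12.1f}{self.win_counts[m]:>8d}"
            )
        for m, tt in self.ttests.items():
            note = " (degenerate)" if tt["degenerate"] else ""
            lines.append(
                f"paired t-test {m} vs baseline: p = {tt['p_value']:.4g}{note}"
            )
        return "\n".join(lines)


def compare_models(
    session_reports: dict[str, dict[str, EvaluationReport]],
    model_names: Sequence[str],
    baseline: str = "regression",
) -> ModelComparison:
    """Rank models per session and test AI-vs-baseline MAE differences.

    ``session_reports`` maps session_id -> model name -> report.  The best
    model per session minimizes MAE + 2 SD (ties go to the earlier-listed
    model and are recorded).  Each non-baseline model is compared to the
    baseline with a two-sided paired t-test on per-session MAE; an all-zero
    difference vector is degenerate and reported as p = 1.0 with a flag.
    """
    model_names = list(model_names)
    reports: list[EvaluationReport] = []
    best: dict[str, str] = {}
    ties: list[str] = []
    wins = {m: 0 for m in model_names}
    for sid, per_model in session_reports.items():
        if set(per_model) != set(model_names):
            raise ValueError(f"session {sid} missing some models")
        for m in model_names:
            reports.append(per_model[m])
        scores = [per_model[m].mae_plus_2sd for m in model_names]
        order = int(np.argmin(scores))
        if sum(abs(s - scores[order]) < 1e-12 for s in scores) > 1:
            ties.append(sid)
        best[sid] = model_names[order]
        wins[model_names[order]] += 1

    ttests = {}
    if baseline in model_names:
        base_mae = np.array(
            [session_reports[s][baseline].mae for s in session_reports]
        )
        for m in model_names:
            if m == baseline:
                continue
            mae = np.array([session_reports[s][m].mae for s in session_reports])
            diff = mae - base_mae
            if np.allclose(diff, 0.0):
                ttests[m] = {
                    "p_value": 1.0, "t": 0.0, "mean_diff": 0.0, "degenerate": True,
                }
            else:
                t, p = sp_stats.ttest_rel(mae, base_mae)
                ttests[m] = {
                    "p_value": float(p),
                    "t": float(t),
                    "mean_diff": float(diff.mean()),
                    "degenerate": False,
                }
    return ModelComparison(
        reports=reports,
        model_names=model_names,
        best_model=best,
        win_counts=wins,
        ttests=ttests,
        tie_sessions=ties,
    )
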