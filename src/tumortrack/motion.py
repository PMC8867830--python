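"""Domain model and I/O for hybrid real-time tumor-tracking session logfiles.

A tracking session records two asynchronous streams over a 20-40 s window:

* several infrared-reflective (IR) skin markers, each a 1-D vertical
  displacement trace sampled at 60 Hz (``P_IR``), and
* the internal target position in 3-D (right-left, superior-inferior,
  anterior-posterior; mm), imaged at irregular 80-640 ms intervals
  (``P_detect``).

Prediction models are fitted on the first part of the window (by default
the first three quarters) and scored on the remainder, so this module also
provides the time alignment between the two streams (interpolation of the
60 Hz traces at detection times, causal velocity estimation) and the
train/test split.

The native vendor logfile format is proprietary; files are exchanged in a
simple versioned HDF5 schema (see :func:`write_logfile`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd

IR_RATE_HZ = 60.0
IR_DT = 1.0 / IR_RATE_HZ
DETECTION_GAP_MIN = 0.08
DETECTION_GAP_MAX = 0.64
#: trailing 60 Hz samples used for the causal least-squares velocity fit
DEFAULT_VELOCITY_WINDOW = 5

SCHEMA_VERSION = "1"


class LogfileValidationError(ValueError):
    """A trace or logfile violates a structural invariant."""


class LogfileSchemaError(ValueError):
    """An interchange file does not conform to the HDF5 schema."""


class ExtrapolationError(ValueError):
    """A query time falls outside the recorded span of a trace."""


class InsufficientHistoryError(ValueError):
    """Not enough trailing samples before the query time."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise LogfileValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class IRMarkerTrace:
    """One external IR marker: 1-D vertical displacement at nominally 60 Hz."""

    marker_id: int
    timestamps: np.ndarray  # s, strictly increasing
    positions: np.ndarray  # mm

    def __post_init__(self) -> None:
        self.timestamps = _as_float_array(self.timestamps, "timestamps")
        self.positions = _as_float_array(self.positions, "positions")
        if self.timestamps.ndim != 1 or self.positions.shape != self.timestamps.shape:
            raise LogfileValidationError("timestamps/positions must be 1-D and equal length")
        if self.timestamps.size < 2:
            raise LogfileValidationError("marker trace needs at least 2 samples")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            raise LogfileValidationError("marker timestamps must be strictly increasing")
        if np.any(np.abs(dt - IR_DT) > 1e-6):
            raise LogfileValidationError(
                f"marker {self.marker_id}: sample spacing deviates from 1/60 s"
            )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.timestamps[0]), float(self.timestamps[-1])

    def position_at(self, t: float) -> float:
        """Linear interpolation of the trace at time ``t`` (mm)."""
        return ir_position_at(self, t)

    def velocity_at(self, t: float, window: int = DEFAULT_VELOCITY_WINDOW) -> float:
        return ir_velocity_at(self, t, window)


@dataclass
class TargetTrace:
    """Irregularly imaged 3-D internal target positions (RL, SI, AP; mm)."""

    timestamps: np.ndarray
    positions3d: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.timestamps = _as_float_array(self.timestamps, "target timestamps")
        self.positions3d = _as_float_array(self.positions3d, "target positions")
        if self.positions3d.ndim != 2 or self.positions3d.shape[1] != 3:
            raise LogfileValidationError("target positions must have shape (n, 3)")
        if self.positions3d.shape[0] != self.timestamps.size:
            raise LogfileValidationError("target timestamps/positions length mismatch")
        if self.timestamps.size < 1:
            raise LogfileValidationError("target trace is empty")
        gaps = np.diff(self.timestamps)
        if np.any(gaps <= 0):
            raise LogfileValidationError("target timestamps must be strictly increasing")
        bad = (gaps < DETECTION_GAP_MIN - 1e-6) | (gaps > DETECTION_GAP_MAX + 1e-6)
        if np.any(bad):
            g = float(gaps[np.argmax(bad)])
            raise LogfileValidationError(
                f"target detection gap {g:.3f} s outside [{DETECTION_GAP_MIN}, {DETECTION_GAP_MAX}] s"
            )

    def __len__(self) -> int:
        return int(self.timestamps.size)


@dataclass
class TrackingLogfile:
    """One tracking session: >= 4 IR marker traces plus the 3-D target trace."""

    session_id: str
    markers: list[IRMarkerTrace]
    target: TargetTrace

    def __post_init__(self) -> None:
        self.markers = list(self.markers)
        self.validate()

    def validate(self) -> None:
        if len(self.markers) < 4:
            raise LogfileValidationError(
                f"logfile requires >= 4 IR markers, got {len(self.markers)}"
            )
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise LogfileValidationError("duplicate marker ids")
        starts = [m.span[0] for m in self.markers]
        ends = [m.span[1] for m in self.markers]
        if max(starts) - min(starts) > 1e-6 or max(ends) - min(ends) > 1e-6:
            raise LogfileValidationError("marker traces do not cover a common window")
        t0, t1 = self.window
        # detections are asynchronous to the 60 Hz clock; allow one tick of
        # slack at the edges (relevant for split sub-logfiles)
        tol = IR_DT + 1e-9
        if self.target.timestamps[0] < t0 - tol or self.target.timestamps[-1] > t1 + tol:
            raise LogfileValidationError("target detections outside the marker window")

    @property
    def window(self) -> tuple[float, float]:
        return self.markers[0].span

    @property
    def duration(self) -> float:
        t0, t1 = self.window
        return t1 - t0

    @property
    def clinically_shaped(self) -> bool:
        """True when the duration matches the clinical 20-40 s protocol."""
        return 20.0 - 1e-9 <= self.duration <= 40.0 + 1e-9


@dataclass
class SplitLogfile:
    """A logfile partitioned in time into a training and a testing period."""

    train: TrackingLogfile
    test: TrackingLogfile
    fraction: float
    original: TrackingLogfile = field(repr=False, default=None)

    @property
    def split_time(self) -> float:
        return float(self.test.window[0])


def split_logfile(logfile: TrackingLogfile, fraction: float = 0.75) -> SplitLogfile:
    """Split a session at ``t0 + fraction * duration``.

    Samples are assigned by timestamp; a sample lying exactly on the split
    instant goes to the training period.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    t0, t1 = logfile.window
    t_split = t0 + fraction * (t1 - t0)

    def cut_marker(m: IRMarkerTrace, lo: bool) -> IRMarkerTrace:
        sel = m.timestamps <= t_split + 1e-12 if lo else m.timestamps > t_split + 1e-12
        if np.count_nonzero(sel) < 2:
            raise LogfileValidationError("split leaves a marker trace with < 2 samples")
        return IRMarkerTrace(m.marker_id, m.timestamps[sel], m.positions[sel])

    def cut_target(lo: bool) -> TargetTrace:
        tt = logfile.target
        sel = tt.timestamps <= t_split + 1e-12 if lo else tt.timestamps > t_split + 1e-12
        if np.count_nonzero(sel) == 0:
            side = "training" if lo else "testing"
            raise LogfileValidationError(f"{side} period contains no target detections")
        return TargetTrace(tt.timestamps[sel], tt.positions3d[sel])

    train = TrackingLogfile(
        logfile.session_id, [cut_marker(m, True) for m in logfile.markers], cut_target(True)
    )
    test = TrackingLogfile(
        logfile.session_id, [cut_marker(m, False) for m in logfile.markers], cut_target(False)
    )
    return SplitLogfile(train=train, test=test, fraction=fraction, original=logfile)


def ir_position_at(trace: IRMarkerTrace, t: float) -> float:
    """Marker position at ``t`` by linear interpolation between 60 Hz samples."""
    ts = trace.timestamps
    if t < ts[0] - 1e-12 or t > ts[-1] + 1e-12:
        raise ExtrapolationError(f"t={t:.4f} s outside trace span {trace.span}")
    return float(np.interp(t, ts, trace.positions))


def ir_velocity_at(
    trace: IRMarkerTrace, t: float, window: int = DEFAULT_VELOCITY_WINDOW
) -> float:
    """Causal marker velocity at ``t`` (mm/s).

    Least-squares slope of the ``window`` samples at or before ``t``; exact
    for linear motion and noise-suppressing on quantized 60 Hz traces.
    """
    if window < 2:
        raise ValueError("velocity window must be >= 2 samples")
    ts = trace.timestamps
    n = int(np.searchsorted(ts, t + 1e-9))
    if n < window:
        raise InsufficientHistoryError(
            f"need {window} samples at or before t={t:.4f} s, have {n}"
        )
    tw = ts[n - window : n]
    pw = trace.positions[n - window : n]
    tc = tw - tw.mean()
    return float(np.dot(tc, pw - pw.mean()) / np.dot(tc, tc))


def make_sample_pairs(
    split: SplitLogfile,
    which: Literal["train", "test"],
    velocity_window: int = DEFAULT_VELOCITY_WINDOW,
    velocity_mode: Literal["per-marker", "averaged-trace"] = "per-marker",
) -> pd.DataFrame:
    """Aligned (t, P_IR, v_IR, P_detect) rows for the chosen period.

    One row per target detection in the period.  ``P_IR`` is the marker
    positions interpolated at the detection time and averaged across
    markers; ``v_IR`` the cross-marker mean causal velocity (or the
    velocity of the pre-averaged trace; identical for synchronized traces).
    Interpolation and velocity use the full-session traces so detections
    early in the testing period keep their history.

    Returns a DataFrame with columns ``t, p_ir, v_ir, rl, si, ap``.
    """
    if which not in ("train", "test"):
        raise ValueError("which must be 'train' or 'test'")
    part = split.train if which == "train" else split.test
    source = split.original if split.original is not None else part
    markers = source.markers
    rows = []
    for t, xyz in zip(part.target.timestamps, part.target.positions3d):
        p = float(np.mean([ir_position_at(m, t) for m in markers]))
        if velocity_mode == "per-marker":
            v = float(np.mean([ir_velocity_at(m, t, velocity_window) for m in markers]))
        else:
            mean_trace = IRMarkerTrace(
                -1, markers[0].timestamps, np.mean([m.positions for m in markers], axis=0)
            )
            v = ir_velocity_at(mean_trace, t, velocity_window)
        rows.append((t, p, v, xyz[0], xyz[1], xyz[2]))
    return pd.DataFrame(rows, columns=["t", "p_ir", "v_ir", "rl", "si", "ap"])


# ---------------------------------------------------------------------------
# interchange I/O
# ---------------------------------------------------------------------------


def write_logfile(logfile: TrackingLogfile, path) -> Path:
    """Write a session to the versioned HDF5 interchange layout.

    Layout: ``/markers/<id>/{t,pos}``, ``/target/{t,rl,si,ap}`` (float64,
    lossless round-trip) with root attributes ``session_id`` and
    ``schema_version``.
    """
    logfile.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["session_id"] = logfile.session_id
        f.attrs["schema_version"] = SCHEMA_VERSION
        g = f.create_group("markers")
        for m in logfile.markers:
            mg = g.create_group(str(m.marker_id))
            mg.create_dataset("t", data=m.timestamps, dtype="f8")
            mg.create_dataset("pos", data=m.positions, dtype="f8")
        tg = f.create_group("target")
        tg.create_dataset("t", data=logfile.target.timestamps, dtype="f8")
        for j, name in enumerate(("rl", "si", "ap")):
            tg.create_dataset(name, data=logfile.target.positions3d[:, j], dtype="f8")
    return path


def read_logfile(path) -> TrackingLogfile:
    """Read and validate a session from the HDF5 interchange layout."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for key in ("session_id", "schema_version"):
            if key not in f.attrs:
                raise LogfileSchemaError(f"missing root attribute '{key}'")
        session_id = str(f.attrs["session_id"])
        if "markers" not in f:
            raise LogfileSchemaError("missing group '/markers'")
        if "target" not in f:
            raise LogfileSchemaError("missing group '/target'")
        markers = []
        for mid in sorted(f["markers"], key=lambda s: (len(s), s)):
            mg = f["markers"][mid]
            for ds in ("t", "pos"):
                if ds not in mg:
                    raise LogfileSchemaError(f"missing dataset '/markers/{mid}/{ds}'")
            markers.append(
                IRMarkerTrace(int(mid), np.asarray(mg["t"]), np.asarray(mg["pos"]))
            )
        tg = f["target"]
        for ds in ("t", "rl", "si", "ap"):
            if ds not in tg:
                raise LogfileSchemaError(f"missing dataset '/target/{ds}'")
        target = TargetTrace(
            np.asarray(tg["t"]),
            np.column_stack([np.asarray(tg["rl"]), np.asarray(tg["si"]), np.asarray(tg["ap"])]),
        )
    return TrackingLogfile(session_id=session_id, markers=markers, target=target)
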