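"""Synthetic respiratory tracking-session generator.

Clinical tracking logfiles (external IR-marker traces plus kV-imaged
internal target positions) are generally not shareable, so this module
generates surrogate sessions whose statistics are calibrated to reported
clinical cohort summaries: external peak-to-peak range R = 7.2 +/- 2.9 mm,
breathing period T = 4.2 +/- 1.5 s, 90th-percentile speed v90 = 7.3 +/- 2.0
mm/s, and internal target ranges of 2.1 / 16.4 / 3.0 mm (RL / SI / AP).

The latent breathing signal is a Lujan-type power-of-sine waveform,

    b(t) = -A_k * sin(pi (t - t_k) / T_k) ** m      on cycle k,

with per-cycle amplitude A_k and period T_k jitter.  The even exponent m
(default 4) reproduces the dwell near end-exhale seen in real abdominal
traces; the sine phase places cycle boundaries at the b = 0 dwell so the
concatenated signal is continuous despite amplitude jitter.  Markers are
per-marker gain-scaled noisy copies of the latent signal; the internal
target couples through a per-direction gain, a pure time lag and a
quadratic distortion,

    target_d(t) = g_d * b(t - lag_d) + q_d * b(t - lag_d)^2 + noise.

The lag and quadratic term are deliberate model mismatch for the clinical
quadratic position/velocity regression: an instantaneous linear coupling
would make that baseline exact and hide any benefit of the learned models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .motion import (
    DETECTION_GAP_MAX,
    DETECTION_GAP_MIN,
    IR_RATE_HZ,
    IRMarkerTrace,
    TargetTrace,
    TrackingLogfile,
)

#: latent signal generated this long before t = 0 so lagged target coupling
#: and causal velocity estimates never run out of history
_PAD_S = 2.0
#: first detection is offset from the window start so every detection has
#: enough 60 Hz history for the causal velocity fit
_FIRST_DETECTION_S = 0.3

# Table-calibrated cohort statistics (mean, sd, min, max)
EXTERNAL_RANGE_MM = (7.2, 2.9, 2.9, 15.5)
PERIOD_S = (4.2, 1.5, 2.5, 8.2)
TARGET_RANGE_MM = {
    "rl": (2.1, 1.7, 0.5, 9.1),
    "si": (16.4, 8.1, 7.6, 37.1),
    "ap": (3.0, 1.3, 0.8, 6.4),
}
#: per-direction quadratic distortion of the external->internal coupling
#: (1/mm); negative sign deepens the inhale excursion
DEFAULT_QUADRATIC = {"rl": -0.005, "si": -0.04, "ap": -0.008}
#: per-direction physiological lag sampling range (s); well inside the
#: 50-sample (0.83 s) history the predictors can see
DEFAULT_LAG_RANGE = (0.08, 0.32)


@dataclass(frozen=True)
class DeepInhaleEvent:
    """Irregular deep-inhale late in the recording (the 'logfile No. 44'
    scenario): breathing amplitude ramps to ``amplitude_multiplier`` times
    its baseline starting at ``onset_fraction`` of the duration."""

    onset_fraction: float = 0.75
    amplitude_multiplier: float = 2.5
    ramp: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.onset_fraction < 1.0:
            raise ValueError("onset_fraction must be in (0, 1)")
        if self.amplitude_multiplier <= 1.0:
            raise ValueError("amplitude_multiplier must exceed 1")
        if self.ramp < 0:
            raise ValueError("ramp must be >= 0")


@dataclass(frozen=True)
class DirectionalCoupling:
    """External-to-internal coupling for one anatomical direction."""

    gain: float  # unitless
    lag: float  # s, >= 0
    quadratic_coeff: float = 0.0  # 1/mm

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("coupling lag must be >= 0")


def _default_coupling() -> dict[str, DirectionalCoupling]:
    # gains chosen so that gain*A + |q|*A^2 matches the reported mean
    # target ranges at the mean external amplitude A = 7.2 mm
    out = {}
    for d in ("rl", "si", "ap"):
        r, q = TARGET_RANGE_MM[d][0], DEFAULT_QUADRATIC[d]
        a = EXTERNAL_RANGE_MM[0]
        out[d] = DirectionalCoupling(
            gain=(r - abs(q) * a * a) / a,
            lag={"rl": 0.12, "si": 0.20, "ap": 0.16}[d],
            quadratic_coeff=q,
        )
    return out


@dataclass
class SimulatorConfig:
    """Parameters of one synthetic tracking session."""

    amplitude_mean: float = EXTERNAL_RANGE_MM[0]  # mm, peak-to-peak of b(t)
    amplitude_sd: float = 0.36  # mm, per-cycle jitter (5 % of the mean)
    period_mean: float = PERIOD_S[0]  # s
    period_sd: float = 0.21  # s, per-cycle jitter
    n_markers: int = 4
    marker_gain_range: tuple[float, float] = (0.8, 1.2)
    target_coupling: dict[str, DirectionalCoupling] = field(default_factory=_default_coupling)
    noise_sd_marker: float = 0.1  # mm
    noise_sd_target: float = 0.2  # mm
    detection_interval_range: tuple[float, float] = (DETECTION_GAP_MIN, DETECTION_GAP_MAX)
    duration: float = 30.0  # s
    drift_rate: float = 0.0  # mm/s baseline drift
    irregularity: Optional[DeepInhaleEvent] = None
    shape_exponent: int = 4  # even exponent m of the sin**m waveform

    def __post_init__(self) -> None:
        if self.amplitude_sd < 0 or self.period_sd < 0:
            raise ValueError("jitter standard deviations must be >= 0")
        if self.noise_sd_marker < 0 or self.noise_sd_target < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_markers < 4:
            raise ValueError("n_markers must be >= 4")
        lo, hi = self.detection_interval_range
        if lo < DETECTION_GAP_MIN - 1e-12 or hi > DETECTION_GAP_MAX + 1e-12 or lo > hi:
            raise ValueError(
                f"detection_interval_range must lie within "
                f"[{DETECTION_GAP_MIN}, {DETECTION_GAP_MAX}] s"
            )
        if self.shape_exponent < 2 or self.shape_exponent % 2:
            raise ValueError("shape_exponent must be a positive even integer")
        if set(self.target_coupling) != {"rl", "si", "ap"}:
            raise ValueError("target_coupling must define 'rl', 'si', 'ap'")

    def expected_v90(self) -> float:
        """90th-percentile speed of the noiseless mean-parameter waveform,
        by dense numerical differentiation (mm/s)."""
        t = np.linspace(0.0, self.period_mean, 20001)
        b = -self.amplitude_mean * np.sin(np.pi * t / self.period_mean) ** self.shape_exponent
        return float(np.percentile(np.abs(np.gradient(b, t)), 90))


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size)
    return np.clip(x, lo, hi)


def _latent_extended(config: SimulatorConfig, rng: np.random.Generator):
    """Latent breathing signal on a 60 Hz grid covering [-_PAD_S, duration).

    Cycle boundaries sit at b = 0; one backward cycle chain covers the
    padding so lagged coupling and early-history queries are defined.
    """
    m = config.shape_exponent

    def draw_cycle():
        a = float(
            _truncated_normal(
                rng, config.amplitude_mean, config.amplitude_sd,
                0.2 * config.amplitude_mean, 3.0 * config.amplitude_mean,
            )
        )
        t = float(
            _truncated_normal(
                rng, config.period_mean, config.period_sd,
                max(0.3 * config.period_mean, 0.5), 3.0 * config.period_mean,
            )
        )
        return a, t

    cycles = []  # (t_start, A, T)
    t_edge = 0.0
    while t_edge > -_PAD_S:  # backward chain
        a, tt = draw_cycle()
        t_edge -= tt
        cycles.insert(0, (t_edge, a, tt))
    t_edge = 0.0
    while t_edge < config.duration:  # forward chain
        a, tt = draw_cycle()
        cycles.append((t_edge, a, tt))
        t_edge += tt

    n_pad = int(round(_PAD_S * IR_RATE_HZ))
    n = int(round(config.duration * IR_RATE_HZ))
    t_grid = np.arange(-n_pad, n) / IR_RATE_HZ
    b = np.zeros_like(t_grid)
    for t0, a, tt in cycles:
        sel = (t_grid >= t0 - 1e-12) & (t_grid < t0 + tt - 1e-12)
        b[sel] = -a * np.sin(np.pi * (t_grid[sel] - t0) / tt) ** m

    if config.irregularity is not None:
        ev = config.irregularity
        t_on = ev.onset_fraction * config.duration
        if ev.ramp > 0:
            s = np.clip((t_grid - t_on) / ev.ramp, 0.0, 1.0)
        else:
            s = (t_grid >= t_on).astype(float)
        b = b * (1.0 + (ev.amplitude_multiplier - 1.0) * s)

    b = b + config.drift_rate * t_grid
    return t_grid, b


def simulate_breathing_signal(config: SimulatorConfig, seed: int):
    """Latent breathing displacement on the session's 60 Hz grid.

    Returns ``(timestamps, b)`` for t in [0, duration); deterministic in
    ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    t_ext, b_ext = _latent_extended(config, rng)
    sel = t_ext >= -1e-12
    return t_ext[sel], b_ext[sel]


def simulate_logfile(config: SimulatorConfig, seed: int) -> TrackingLogfile:
    """Generate one synthetic tracking session.

    Markers are gain-scaled noisy copies of the latent signal at 60 Hz;
    the 3-D target is the lagged gain/quadratic coupling sampled at random
    detection intervals.  Deterministic in ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    t_ext, b_ext = _latent_extended(config, rng)
    sel = t_ext >= -1e-12
    t_grid, b = t_ext[sel], b_ext[sel]

    gains = rng.uniform(*config.marker_gain_range, config.n_markers)
    markers = [
        IRMarkerTrace(
            marker_id=i + 1,
            timestamps=t_grid,
            positions=g * b + rng.normal(0.0, config.noise_sd_marker, t_grid.size),
        )
        for i, g in enumerate(gains)
    ]

    lo, hi = config.detection_interval_range
    t_det = []
    t = _FIRST_DETECTION_S + rng.uniform(lo, hi)
    while t <= t_grid[-1]:
        t_det.append(t)
        t += rng.uniform(lo, hi)
    t_det = np.asarray(t_det)

    cols = []
    for d in ("rl", "si", "ap"):
        c = config.target_coupling[d]
        bl = np.interp(t_det - c.lag, t_ext, b_ext)
        cols.append(
            c.gain * bl
            + c.quadratic_coeff * bl**2
            + rng.normal(0.0, config.noise_sd_target, t_det.size)
        )
    target = TargetTrace(t_det, np.column_stack(cols))
    return TrackingLogfile(session_id=f"sim-{seed:010d}", markers=markers, target=target)


@dataclass
class CohortSpec:
    """A population of sessions with per-file parameters drawn from the
    reported clinical cohort distributions (truncated normals for amplitude, period
    and per-direction target range; uniform lags and durations)."""

    n_logfiles: int
    master_seed: int = 0
    duration_range: tuple[float, float] = (24.0, 40.0)
    amplitude: tuple[float, float, float, float] = EXTERNAL_RANGE_MM
    period: tuple[float, float, float, float] = PERIOD_S
    target_range: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(TARGET_RANGE_MM)
    )
    lag_range: tuple[float, float] = DEFAULT_LAG_RANGE
    quadratic: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_QUADRATIC))
    cycle_jitter_frac: float = 0.05  # within-file A_k / T_k jitter
    n_markers: int = 4
    noise_sd_marker: float = 0.1
    noise_sd_target: float = 0.2
    shape_exponent: int = 4
    irregular_fraction: float = 0.0  # fraction of files given a DeepInhaleEvent

    def __post_init__(self) -> None:
        if self.n_logfiles < 1:
            raise ValueError("n_logfiles must be >= 1")
        if not 0.0 <= self.irregular_fraction <= 1.0:
            raise ValueError("irregular_fraction must be in [0, 1]")

    def sample_config(self, rng: np.random.Generator) -> SimulatorConfig:
        a = float(_truncated_normal(rng, *self.amplitude))
        t = float(_truncated_normal(rng, *self.period))
        coupling = {}
        for d in ("rl", "si", "ap"):
            r = float(_truncated_normal(rng, *self.target_range[d]))
            q = self.quadratic[d]
            gain = max(r - abs(q) * a * a, 0.1 * r) / a
            coupling[d] = DirectionalCoupling(
                gain=gain, lag=float(rng.uniform(*self.lag_range)), quadratic_coeff=q
            )
        irregular = rng.uniform() < self.irregular_fraction
        return SimulatorConfig(
            amplitude_mean=a,
            amplitude_sd=self.cycle_jitter_frac * a,
            period_mean=t,
            period_sd=self.cycle_jitter_frac * t,
            n_markers=self.n_markers,
            target_coupling=coupling,
            noise_sd_marker=self.noise_sd_marker,
            noise_sd_target=self.noise_sd_target,
            duration=float(rng.uniform(*self.duration_range)),
            irregularity=DeepInhaleEvent() if irregular else None,
            shape_exponent=self.shape_exponent,
        )


def simulate_cohort(spec: CohortSpec) -> list[TrackingLogfile]:
    """Generate ``spec.n_logfiles`` sessions, reproducibly.

    Per-file configs and seeds derive from ``master_seed`` through a
    ``numpy.random.SeedSequence``, so the cohort is identical across runs
    and unaffected by consumption order elsewhere.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    children = ss.spawn(spec.n_logfiles + 1)
    rng_cfg = np.random.default_rng(children[0])
    out = []
    for i in range(spec.n_logfiles):
        config = spec.sample_config(rng_cfg)
        seed = int(children[i + 1].generate_state(1)[0] & 0x7FFFFFFF)
        lf = simulate_logfile(config, seed)
        lf.session_id = f"sim-{spec.master_seed}-{i:04d}"
        out.append(lf)
    return out


def cohort_configs(spec: CohortSpec) -> list[SimulatorConfig]:
    """The per-file configs :func:`simulate_cohort` would use (same draws)."""
    ss = np.random.SeedSequence(spec.master_seed)
    rng_cfg = np.random.default_rng(ss.spawn(spec.n_logfiles + 1)[0])
    return [spec.sample_config(rng_cfg) for _ in range(spec.n_logfiles)]
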