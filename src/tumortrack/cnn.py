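"""CNN target-position predictor with cohort pre-training and per-session
fine-tuning.

One shared reference network is trained on a historical cohort of tracking
sessions, then adapted to each new session with a few low-rate epochs on
its training period (transfer learning).  Per prediction time ``t`` the
network sees, per marker, three streams:

* ``context_ir`` — 12 s of the marker trace (720 samples at 60 Hz) from
  the tail of the training period,
* ``context_targets`` — 25 detected 3-D target positions sampled at equal
  time intervals over that same 12 s window (nearest detection to each
  grid time), and
* ``recent_ir`` — the 50 marker samples immediately before ``t``;

and emits the 3-D target estimate.  Per-marker outputs are averaged
arithmetically to give the final prediction.  The context pair tells the
network what the external-internal coupling looks like for this patient;
the recent stream carries the current breathing phase.

Architecture: nineteen layers — eight 1-D convolutions, five batch
normalizations, three dropouts, one flatten and two dense layers.  The
three streams are fused as channels of one 720-tick stack (the 25 context
targets are linearly resampled to 720 per axis; the 50 recent samples are
right-aligned and zero-padded), so the network stays purely convolutional
until the head.  Training uses Adam with a mean-absolute-error loss;
inputs and labels are mean-centered per example and the offset is restored
at the output, making the predictor invariant to couch translations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .motion import SplitLogfile, TrackingLogfile, split_logfile

CONTEXT_SECONDS = 12.0
CONTEXT_IR_LEN = 720
CONTEXT_TARGET_LEN = 25
RECENT_IR_LEN = 50
N_INPUT_CHANNELS = 5  # context_ir, 3x context_targets, recent_ir

REQUIRED_CENSUS = {"conv": 8, "batchnorm": 5, "dropout": 3, "flatten": 1, "dense": 2}

# Example-mining and ensembling choices (motivated in the methods note):
# each historical session contributes examples under two frozen contexts,
# fine-tuning sees several shifted context windows of its own session, and
# the deployed predictor averages a small ensemble of independently tuned
# copies over the newest few contexts.
REFERENCE_CONTEXT_OFFSETS = (0.0, 2.5)  # s before the training-period tail
FINE_TUNE_CONTEXTS = 5
FINE_TUNE_CONTEXT_SPACING = 1.0  # s
PREDICT_CONTEXTS = 3
FINE_TUNE_ENSEMBLE = 2


class ArchitectureError(ValueError):
    """The layer plan violates the 8/5/3/1/2 layer-census contract."""


@dataclass(frozen=True)
class CnnArchitectureSpec:
    """Hyperparameters of the 19-layer stack.

    The layer-type census (8 conv, 5 batch-norm, 3 dropout, 1 flatten,
    2 dense) is the normative contract; kernel widths, channel counts,
    strides and dropout rates are free hyperparameters.
    """

    conv_channels: tuple[int, ...] = (16, 16, 32, 32, 32, 32, 32, 32)
    conv_kernels: tuple[int, ...] = (7, 5, 7, 5, 7, 5, 7, 5)
    conv_strides: tuple[int, ...] = (4, 1, 2, 1, 2, 1, 2, 1)
    batchnorm_after_conv: tuple[int, ...] = (1, 3, 5, 7)  # conv indices (0-based)
    dropout_after_conv: tuple[int, ...] = (3, 5, 7)
    dropout_rate: float = 0.25
    dense_units: int = 96
    output_dim: int = 3

    def __post_init__(self) -> None:
        n = len(self.conv_channels)
        if not (n == len(self.conv_kernels) == len(self.conv_strides)):
            raise ArchitectureError("conv channel/kernel/stride lists disagree")
        census = {
            "conv": n,
            "batchnorm": len(self.batchnorm_after_conv) + 1,  # +1 after first dense
            "dropout": len(self.dropout_after_conv),
            "flatten": 1,
            "dense": 2,
        }
        if census != REQUIRED_CENSUS:
            raise ArchitectureError(
                f"layer census {census} != required {REQUIRED_CENSUS}"
            )
        if self.output_dim != 3:
            raise ArchitectureError("output dimension must be 3 (RL, SI, AP)")


@dataclass(frozen=True)
class TrainingSchedule:
    """Reference pre-training and per-session fine-tuning hyperparameters."""

    reference_epochs: int = 20
    reference_lr: float = 0.001
    #: when set, the reference rate anneals geometrically to this value
    #: (used e.g. by long capacity probes); None keeps the rate constant
    reference_lr_final: Optional[float] = None
    fine_tune_epochs: int = 5
    fine_tune_lr: tuple[float, float] = (0.0005, 0.0001)  # linear start -> end
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.reference_epochs < 1 or self.fine_tune_epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.fine_tune_lr[1] >= self.fine_tune_lr[0]:
            raise ValueError("fine-tune learning rate must strictly decrease")

    def reference_rates(self) -> np.ndarray:
        if self.reference_lr_final is None:
            return np.full(self.reference_epochs, self.reference_lr)
        return np.geomspace(
            self.reference_lr, self.reference_lr_final, self.reference_epochs
        )

    def fine_tune_rates(self) -> np.ndarray:
        return np.linspace(*self.fine_tune_lr, self.fine_tune_epochs)


@dataclass
class CnnInputExample:
    """One (context, recent, label) training or prediction example."""

    context_ir: np.ndarray  # (720,) mm
    context_targets: np.ndarray  # (25, 3) mm
    recent_ir: np.ndarray  # (50,) mm
    t: float
    label: Optional[np.ndarray] = None  # (3,) mm

    def __post_init__(self) -> None:
        if self.context_ir.shape != (CONTEXT_IR_LEN,):
            raise ValueError(f"context_ir must have length {CONTEXT_IR_LEN}")
        if self.context_targets.shape != (CONTEXT_TARGET_LEN, 3):
            raise ValueError(f"context_targets must have shape ({CONTEXT_TARGET_LEN}, 3)")
        if self.recent_ir.shape != (RECENT_IR_LEN,):
            raise ValueError(f"recent_ir must have length {RECENT_IR_LEN}")


def make_cnn_example(
    logfile: TrackingLogfile,
    marker_id: int,
    t: float,
    context_end: float,
    require_label: bool = True,
) -> CnnInputExample:
    """Assemble the three input streams for one marker at time ``t``.

    ``context_end`` is the right edge of the 12 s context window (the tail
    of the training period during deployment).  ``recent_ir`` is the 50
    marker samples at or before ``t``; the label is the detection at ``t``
    when one exists.
    """
    marker = next((m for m in logfile.markers if m.marker_id == marker_id), None)
    if marker is None:
        raise ValueError(f"no marker with id {marker_id}")
    ts, pos = marker.timestamps, marker.positions

    n_ctx = int(np.searchsorted(ts, context_end + 1e-9))
    if n_ctx < CONTEXT_IR_LEN:
        raise ValueError(
            f"need {CONTEXT_IR_LEN} marker samples (12 s) before context_end, have {n_ctx}"
        )
    context_ir = pos[n_ctx - CONTEXT_IR_LEN : n_ctx]
    ctx_t0 = ts[n_ctx - CONTEXT_IR_LEN]
    ctx_t1 = ts[n_ctx - 1]

    # 25 equal-interval grid times over the window, nearest detection each
    grid = np.linspace(ctx_t0, ctx_t1, CONTEXT_TARGET_LEN)
    det_t = logfile.target.timestamps
    nearest = np.clip(np.searchsorted(det_t, grid), 1, det_t.size - 1)
    left = nearest - 1
    pick = np.where(
        np.abs(det_t[left] - grid) <= np.abs(det_t[nearest] - grid), left, nearest
    ) if det_t.size > 1 else np.zeros(CONTEXT_TARGET_LEN, dtype=int)
    context_targets = logfile.target.positions3d[pick]

    n_rec = int(np.searchsorted(ts, t + 1e-9))
    if n_rec < RECENT_IR_LEN:
        raise ValueError(
            f"need {RECENT_IR_LEN} marker samples at or before t={t:.3f}, have {n_rec}"
        )
    recent_ir = pos[n_rec - RECENT_IR_LEN : n_rec]

    label = None
    hit = np.nonzero(np.abs(det_t - t) < 1e-9)[0]
    if hit.size:
        label = logfile.target.positions3d[hit[0]].copy()
    elif require_label:
        raise ValueError(f"no target detection at t={t:.4f}")
    return CnnInputExample(
        context_ir=context_ir.copy(),
        context_targets=context_targets.copy(),
        recent_ir=recent_ir.copy(),
        t=float(t),
        label=label,
    )


def assemble_batch(
    examples: Sequence[CnnInputExample],
) -> tuple[np.ndarray, Optional[np.ndarray], np.ndarray, np.ndarray]:
    """Stack examples into the (n, 5, 720) channel tensor.

    Channels are standardized per example: marker channels by the
    context-IR mean/std, target channels per axis by the context-target
    mean/std.  The per-axis affine transform is returned so predictions
    (and the training loss) live in absolute mm; factoring the
    patient-specific amplitude and coupling gain out of the network input
    makes the cross-patient task approximately scale-invariant, which is
    what lets one reference network serve every session.  Returns
    ``(X, labels_mm_or_None, offsets, scales)`` with ``offsets``/``scales``
    of shape (n, 3): prediction_mm = net_output * scale + offset.
    """
    n = len(examples)
    X = np.zeros((n, N_INPUT_CHANNELS, CONTEXT_IR_LEN))
    offsets = np.zeros((n, 3))
    scales = np.zeros((n, 3))
    have_labels = all(e.label is not None for e in examples)
    y = np.zeros((n, 3)) if have_labels else None
    src = np.arange(CONTEXT_TARGET_LEN) * (CONTEXT_IR_LEN - 1) / (CONTEXT_TARGET_LEN - 1)
    dst = np.arange(CONTEXT_IR_LEN)
    for i, e in enumerate(examples):
        m_ir = e.context_ir.mean()
        s_ir = max(e.context_ir.std(), 1e-6)
        c = e.context_targets.mean(axis=0)
        s = np.maximum(e.context_targets.std(axis=0), 1e-6)
        X[i, 0] = (e.context_ir - m_ir) / s_ir
        for ax in range(3):
            X[i, 1 + ax] = np.interp(dst, src, (e.context_targets[:, ax] - c[ax]) / s[ax])
        X[i, 4, -RECENT_IR_LEN:] = (e.recent_ir - m_ir) / s_ir
        offsets[i] = c
        scales[i] = s
        if have_labels:
            y[i] = e.label
    return X, y, offsets, scales


def build_network(spec: CnnArchitectureSpec, seed: int) -> nn.Sequential:
    """Instantiate the 19-layer stack with seed-deterministic weights."""
    ss = np.random.SeedSequence(seed)
    init_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    layers: list[nn.Layer] = []
    c_in = N_INPUT_CHANNELS
    length = CONTEXT_IR_LEN
    for i, (c_out, k, s) in enumerate(
        zip(spec.conv_channels, spec.conv_kernels, spec.conv_strides)
    ):
        layers.append(nn.Conv1D(c_in, c_out, k, stride=s, activation="relu", rng=init_rng))
        length = -(-length // s)
        c_in = c_out
        if i in spec.batchnorm_after_conv:
            layers.append(nn.BatchNorm(c_out))
        if i in spec.dropout_after_conv:
            layers.append(nn.Dropout(spec.dropout_rate, rng=drop_rng))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(c_in * length, spec.dense_units, activation="relu", rng=init_rng))
    layers.append(nn.BatchNorm(spec.dense_units))
    layers.append(nn.Dense(spec.dense_units, spec.output_dim, rng=init_rng))
    net = nn.Sequential(layers)
    if net.census() != REQUIRED_CENSUS:
        raise ArchitectureError(f"built census {net.census()} != {REQUIRED_CENSUS}")
    return net


build_reference_model = build_network


def _admissible_times(split: SplitLogfile, period: str) -> np.ndarray:
    """Detection times in the chosen period with full recent-IR history."""
    lf = split.original
    part = split.train if period == "train" else split.test
    ts = lf.markers[0].timestamps
    ok = []
    for t in part.target.timestamps:
        if np.searchsorted(ts, t + 1e-9) >= RECENT_IR_LEN:
            ok.append(t)
    return np.asarray(ok)


def _fine_tune_context_end(split: SplitLogfile) -> float:
    """Frozen-context right edge used for fine-tuning (and kept for the
    tuned network's predictions): leaves a causal gap the size of the
    testing horizon between the context and the label times."""
    t0, t1 = split.original.window
    return max(t0 + CONTEXT_SECONDS, 2.0 * split.split_time - t1)


def _fine_tune_contexts(split: SplitLogfile) -> list[float]:
    """Shifted frozen-context right edges used during fine-tuning, newest
    first; all leave at least 12 s of history."""
    t0, _ = split.original.window
    ce1 = _fine_tune_context_end(split)
    ctxs = {
        max(t0 + CONTEXT_SECONDS, ce1 - k * FINE_TUNE_CONTEXT_SPACING)
        for k in range(FINE_TUNE_CONTEXTS)
    }
    return sorted(ctxs, reverse=True)


def _session_examples(
    split: SplitLogfile, period: str
) -> list[CnnInputExample]:
    """Labelled examples for every admissible (marker, t) of the period.

    For testing-period examples (reference training) the 12 s context is
    frozen near the tail of the training period — the deployed
    configuration — under two slightly shifted windows so each historical
    session contributes more than one conditioning view.  For
    training-period examples (fine-tuning) the contexts are frozen earlier,
    leaving a causal gap the size of the testing horizon, so no label time
    falls inside its own context window; a context that covers t would let
    the network read the label off the context-target channel and learn to
    copy instead of predict.
    """
    lf = split.original
    t0, t1 = lf.window
    if period == "test":
        context_ends = sorted(
            {
                max(t0 + CONTEXT_SECONDS, split.split_time - off)
                for off in REFERENCE_CONTEXT_OFFSETS
            },
            reverse=True,
        )
    else:
        context_ends = _fine_tune_contexts(split)
    out = []
    times = _admissible_times(split, period)
    for context_end in context_ends:
        tt = times[times > context_end + 1e-9]
        for m in lf.markers:
            for t in tt:
                out.append(make_cnn_example(lf, m.marker_id, t, context_end))
    return out


def _train_epochs(
    net: nn.Sequential,
    X: np.ndarray,
    y: np.ndarray,
    offsets: np.ndarray,
    scales: np.ndarray,
    rates: Sequence[float],
    batch_size: int,
    shuffle_rng: np.random.Generator,
) -> list[float]:
    """Adam/MAE training loop; the loss is the mean absolute difference
    between predicted and detected positions in mm (network outputs are
    mapped back through the per-example affine transform first)."""
    opt = nn.Adam(net.parameters())
    history = []
    n = X.shape[0]
    for lr in rates:
        order = shuffle_rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            sel = order[lo : lo + batch_size]
            out = net.forward(X[sel], training=True)
            pred = out * scales[sel] + offsets[sel]
            loss, grad = nn.mae_loss(pred, y[sel])
            net.backward(grad * scales[sel])
            opt.step(net.gradients(), lr)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


class CnnReference:
    """Reference-model builder over a historical session cohort.

    Enumerates every admissible (session, marker, detection time in the
    testing quarter) example once per epoch, shuffled per epoch, and trains
    the stack for ``reference_epochs`` at the reference learning rate.
    """

    def __init__(
        self,
        cohort: Sequence[TrackingLogfile],
        spec: CnnArchitectureSpec | None = None,
        schedule: TrainingSchedule | None = None,
        seed: int = 0,
        split_fraction: float = 0.75,
    ) -> None:
        if len(cohort) == 0:
            raise ValueError("historical cohort is empty")
        self.cohort = list(cohort)
        self.spec = spec or CnnArchitectureSpec()
        self.schedule = schedule or TrainingSchedule()
        self.seed = int(seed)
        self.split_fraction = split_fraction

    def fit(self) -> "CnnReferenceResults":
        net = build_network(self.spec, self.seed)
        examples: list[CnnInputExample] = []
        for lf in self.cohort:
            split = split_logfile(lf, self.split_fraction)
            examples.extend(_session_examples(split, "test"))
        if not examples:
            raise ValueError("cohort admits no training examples")
        X, y, offsets, scales = assemble_batch(examples)
        shuffle_rng = np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(3)[2]
        )
        history = _train_epochs(
            net,
            X,
            y,
            offsets,
            scales,
            self.schedule.reference_rates(),
            self.schedule.batch_size,
            shuffle_rng,
        )
        return CnnReferenceResults(
            spec=self.spec,
            schedule=self.schedule,
            network=net,
            loss_history=history,
            n_examples=len(examples),
            seed=self.seed,
            n_cohort=len(self.cohort),
        )


def _marker_batches(split: SplitLogfile, times, context_end: float):
    """Assembled per-marker input batches at ``times`` for one context."""
    lf = split.original
    out = []
    for m in lf.markers:
        ex = [
            make_cnn_example(lf, m.marker_id, t, context_end, require_label=False)
            for t in times
        ]
        out.append(assemble_batch(ex))
    return out


class _FittedCnn:
    """Shared prediction machinery for reference and fine-tuned networks."""

    network: nn.Sequential
    spec: CnnArchitectureSpec

    def _predict_split(
        self, split: SplitLogfile, times, context_end: float | None = None
    ) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if context_end is None:
            context_end = split.split_time
        per_marker = [
            self.network.forward(X, training=False) * scales + offsets
            for X, _, offsets, scales in _marker_batches(split, times, context_end)
        ]
        return np.mean(per_marker, axis=0)

    def predict_split(self, split: SplitLogfile, times) -> np.ndarray:
        """(n, 3) predictions at ``times`` for the session of ``split``,
        context frozen at the training-period tail, averaged over markers."""
        return self._predict_split(split, times)


@dataclass
class CnnReferenceResults(_FittedCnn):
    """Trained reference network plus its loss trajectory."""

    spec: CnnArchitectureSpec
    schedule: TrainingSchedule
    network: nn.Sequential
    loss_history: list[float]
    n_examples: int
    seed: int = 0
    n_cohort: int = 0

    def fine_tune(
        self,
        split: SplitLogfile,
        schedule: TrainingSchedule | None = None,
        seed: int = 0,
        ensemble: int = FINE_TUNE_ENSEMBLE,
    ) -> "CnnResults":
        """Adapt copies of the reference to one session's training period.

        Each ensemble member runs five epochs with the learning rate
        annealed linearly from 5e-4 to 1e-4 over every admissible
        (marker, detection time) of the training period, per the
        transfer-learning protocol; members differ only in their shuffle
        and dropout streams.  Batch-norm statistics stay frozen so the
        small correlated batches cannot corrupt them.
        """
        schedule = schedule or self.schedule
        examples = _session_examples(split, "train")
        if not examples:
            raise ValueError("training period admits no fine-tuning examples")
        X, y, offsets, scales = assemble_batch(examples)
        member_seeds = np.random.SeedSequence(seed).spawn(max(1, ensemble))
        networks, histories = [], []
        for ms in member_seeds:
            net = self.network.copy()
            for layer in net.layers:
                if isinstance(layer, nn.BatchNorm):
                    layer.frozen = True
            history = _train_epochs(
                net, X, y, offsets, scales, schedule.fine_tune_rates(),
                schedule.batch_size, np.random.default_rng(ms),
            )
            networks.append(net)
            histories.append(history)
        return CnnResults(
            reference=self,
            networks=networks,
            split=split,
            member_histories=histories,
            learning_rates=list(schedule.fine_tune_rates()),
        )

    def summary(self) -> str:
        return (
            "CNN reference model\n"
            f"  cohort: {self.n_cohort} sessions, {self.n_examples} examples\n"
            f"  epochs: {len(self.loss_history)} @ lr {self.schedule.reference_lr}\n"
            f"  training MAE: {self.loss_history[0]:.3f} -> {self.loss_history[-1]:.3f} mm"
        )

    def save(self, path) -> None:
        """Single-file checkpoint: architecture spec + schedule + seed +
        all network state (weights and batch-norm running statistics)."""
        import json

        meta = json.dumps(
            {
                "spec": {
                    k: list(v) if isinstance(v, tuple) else v
                    for k, v in self.spec.__dict__.items()
                },
                "schedule": {
                    k: list(v) if isinstance(v, tuple) else v
                    for k, v in self.schedule.__dict__.items()
                },
                "seed": self.seed,
                "n_examples": self.n_examples,
                "n_cohort": self.n_cohort,
                "loss_history": self.loss_history,
            }
        )
        arrays = {f"arr{i}": a for i, a in enumerate(self.network.state_arrays())}
        np.savez(path, meta=np.bytes_(meta.encode()), **arrays)

    @classmethod
    def load(cls, path) -> "CnnReferenceResults":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            arrays = [data[f"arr{i}"] for i in range(len(data.files) - 1)]
        sp = meta["spec"]
        spec = CnnArchitectureSpec(
            conv_channels=tuple(sp["conv_channels"]),
            conv_kernels=tuple(sp["conv_kernels"]),
            conv_strides=tuple(sp["conv_strides"]),
            batchnorm_after_conv=tuple(sp["batchnorm_after_conv"]),
            dropout_after_conv=tuple(sp["dropout_after_conv"]),
            dropout_rate=sp["dropout_rate"],
            dense_units=sp["dense_units"],
            output_dim=sp["output_dim"],
        )
        sc = meta["schedule"]
        schedule = TrainingSchedule(
            reference_epochs=sc["reference_epochs"],
            reference_lr=sc["reference_lr"],
            reference_lr_final=sc.get("reference_lr_final"),
            fine_tune_epochs=sc["fine_tune_epochs"],
            fine_tune_lr=tuple(sc["fine_tune_lr"]),
            batch_size=sc["batch_size"],
        )
        net = build_network(spec, meta["seed"])
        net.set_state(arrays)
        return cls(
            spec=spec,
            schedule=schedule,
            network=net,
            loss_history=list(meta["loss_history"]),
            n_examples=meta["n_examples"],
            seed=meta["seed"],
            n_cohort=meta["n_cohort"],
        )


@dataclass
class CnnResults(_FittedCnn):
    """Per-session fine-tuned ensemble; the deployable predictor."""

    reference: CnnReferenceResults
    networks: list[nn.Sequential]
    split: SplitLogfile
    member_histories: list[list[float]]
    learning_rates: list[float]

    @property
    def spec(self) -> CnnArchitectureSpec:
        return self.reference.spec

    @property
    def network(self) -> nn.Sequential:
        return self.networks[0]

    @property
    def loss_history(self) -> list[float]:
        """First ensemble member's per-epoch training MAE (mm)."""
        return self.member_histories[0]

    def predict(self, logfile: TrackingLogfile | None = None, times=None) -> np.ndarray:
        """(n, 3) predictions at ``times``; ``logfile`` defaults to the
        fine-tuning session (pass it explicitly to e.g. permute markers).

        The frozen contexts are the ones the ensemble was fine-tuned with,
        so tuning and deployment condition on identical patient
        descriptors; the output averages ensemble members, the newest few
        contexts, and the markers.
        """
        if times is None:
            raise ValueError("times is required")
        if logfile is None:
            split = self.split
        else:
            split = SplitLogfile(
                train=self.split.train,
                test=self.split.test,
                fraction=self.split.fraction,
                original=logfile,
            )
        times = np.atleast_1d(np.asarray(times, dtype=float))
        ctxs = _fine_tune_contexts(self.split)[:PREDICT_CONTEXTS]
        preds = []
        for ce in ctxs:
            batches = _marker_batches(split, times, ce)
            for net in self.networks:
                per_marker = [
                    net.forward(X, training=False) * scales + offsets
                    for X, _, offsets, scales in batches
                ]
                preds.append(np.mean(per_marker, axis=0))
        return np.mean(preds, axis=0)

    def summary(self) -> str:
        rates = ", ".join(f"{r:.2g}" for r in self.learning_rates)
        return (
            "Fine-tuned CNN predictor\n"
            f"  session: {self.split.train.session_id}\n"
            f"  ensemble: {len(self.networks)} members\n"
            f"  fine-tune epochs: {len(self.loss_history)} @ lr [{rates}]\n"
            f"  training MAE: {self.loss_history[0]:.3f} -> {self.loss_history[-1]:.3f} mm"
        )


def train_reference(
    cohort: Sequence[TrackingLogfile],
    spec: CnnArchitectureSpec | None = None,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
) -> CnnReferenceResults:
    """Functional wrapper: build and train the reference model."""
    return CnnReference(cohort, spec=spec, schedule=schedule, seed=seed).fit()


def fine_tune(
    reference: CnnReferenceResults,
    split: SplitLogfile,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
) -> CnnResults:
    """Functional wrapper: per-session transfer learning."""
    return reference.fine_tune(split, schedule=schedule, seed=seed)


def predict_cnn(results: _FittedCnn, split: SplitLogfile, t) -> np.ndarray:
    """Functional wrapper: marker-averaged prediction at time(s) ``t``."""
    out = results.predict_split(split, np.atleast_1d(t))
    return out[0] if np.ndim(t) == 0 else out
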