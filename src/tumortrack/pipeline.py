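"""End-to-end benchmark: simulate cohorts, train all three predictors,
score them on each evaluation session's testing period.

Reproduces the clinical-evaluation workflow at desk scale: a historical cohort
pre-trains the CNN reference; each evaluation session is split 3/4 - 1/4,
the quadratic regression and the ANFIS are fitted on its training period,
the CNN reference is fine-tuned on it, and all three predict the detected
target positions of the testing period.  Sessions are then ranked by
MAE + 2 SD and the AI models compared to the regression baseline with
paired t-tests.  Every stochastic stage is seeded from one master seed, so
a run directory can be reproduced bit-for-bit from its stored config.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .anfis import AnfisModel, AnfisTrainConfig
from .cnn import CnnArchitectureSpec, CnnReference, CnnReferenceResults, TrainingSchedule
from .evaluate import (
    EvaluationReport,
    ModelComparison,
    compare_models,
    delta_metrics,
    evaluate_predictions,
)
from .motion import TrackingLogfile, split_logfile, write_logfile
from .regression import QuadraticRegression
from .simulate import CohortSpec, simulate_cohort

log = logging.getLogger("tumortrack")

MODEL_NAMES = ("cnn", "anfis", "regression")


@dataclass
class RunConfig:
    """Configuration of one benchmark run.

    Desk-scale defaults are 30 historical and 10 evaluation sessions;
    clinical-scale cohorts (on the order of 1000 historical / 76
    evaluation) are reachable through this config.
    """

    n_historical: int = 30
    n_evaluation: int = 10
    split_fraction: float = 0.75
    master_seed: int = 0
    output_dir: Optional[str] = None
    cohort_kwargs: dict = field(default_factory=dict)
    cnn_spec: CnnArchitectureSpec = field(default_factory=CnnArchitectureSpec)
    cnn_schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    anfis_config: AnfisTrainConfig = field(default_factory=AnfisTrainConfig)
    save_logfiles: bool = False

    def __post_init__(self) -> None:
        if self.n_historical < 1 or self.n_evaluation < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must be in (0, 1)")


@dataclass
class BenchmarkResult:
    comparison: ModelComparison
    reference: CnnReferenceResults
    config: RunConfig
    evaluation_cohort: list[TrackingLogfile]
    timings: dict[str, float]


def _derived_seeds(master_seed: int, n_eval: int) -> dict:
    ss = np.random.SeedSequence(master_seed)
    kids = ss.spawn(3 + n_eval)
    as_int = lambda s: int(s.generate_state(1)[0] & 0x7FFFFFFF)
    return {
        "historical": as_int(kids[0]),
        "evaluation": as_int(kids[1]),
        "reference": as_int(kids[2]),
        "fine_tune": [as_int(k) for k in kids[3:]],
    }


def run_benchmark(config: RunConfig) -> BenchmarkResult:
    """Execute the full simulate -> train -> evaluate workflow."""
    seeds = _derived_seeds(config.master_seed, config.n_evaluation)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    historical = simulate_cohort(
        CohortSpec(config.n_historical, master_seed=seeds["historical"], **config.cohort_kwargs)
    )
    evaluation = simulate_cohort(
        CohortSpec(config.n_evaluation, master_seed=seeds["evaluation"], **config.cohort_kwargs)
    )
    timings["simulate"] = time.perf_counter() - t0
    log.info("simulated %d historical + %d evaluation sessions (%.1f s)",
             len(historical), len(evaluation), timings["simulate"])

    t0 = time.perf_counter()
    reference = CnnReference(
        historical,
        spec=config.cnn_spec,
        schedule=config.cnn_schedule,
        seed=seeds["reference"],
        split_fraction=config.split_fraction,
    ).fit()
    timings["train_reference"] = time.perf_counter() - t0
    log.info("reference CNN trained: MAE %.3f -> %.3f mm (%.1f s)",
             reference.loss_history[0], reference.loss_history[-1],
             timings["train_reference"])

    session_reports: dict[str, dict[str, EvaluationReport]] = {}
    per_stage = {"regression": 0.0, "cnn": 0.0, "anfis": 0.0}
    for i, lf in enumerate(evaluation):
        split = split_logfile(lf, config.split_fraction)
        times = split.test.target.timestamps
        detect = split.test.target.positions3d
        deltas = delta_metrics(split)

        t0 = time.perf_counter()
        reg = QuadraticRegression.from_split(split).fit()
        pred_reg = reg.predict(lf, times)
        per_stage["regression"] += time.perf_counter() - t0

        t0 = time.perf_counter()
        tuned = reference.fine_tune(split, config.cnn_schedule, seed=seeds["fine_tune"][i])
        pred_cnn = tuned.predict(times=times)
        per_stage["cnn"] += time.perf_counter() - t0

        t0 = time.perf_counter()
        anfis = AnfisModel(split, config=config.anfis_config).fit()
        pred_anfis = anfis.predict(times=times)
        per_stage["anfis"] += time.perf_counter() - t0

        session_reports[lf.session_id] = {
            "cnn": evaluate_predictions(lf.session_id, "cnn", pred_cnn, detect, deltas),
            "anfis": evaluate_predictions(lf.session_id, "anfis", pred_anfis, detect, deltas),
            "regression": evaluate_predictions(
                lf.session_id, "regression", pred_reg, detect, deltas
            ),
        }
        log.info(
            "session %s: MAE cnn %.3f / anfis %.3f / regression %.3f mm",
            lf.session_id,
            session_reports[lf.session_id]["cnn"].mae,
            session_reports[lf.session_id]["anfis"].mae,
            session_reports[lf.session_id]["regression"].mae,
        )
    timings.update(per_stage)

    comparison = compare_models(session_reports, MODEL_NAMES, baseline="regression")
    result = BenchmarkResult(
        comparison=comparison,
        reference=reference,
        config=config,
        evaluation_cohort=evaluation,
        timings=timings,
    )
    if config.output_dir is not None:
        _write_outputs(result, seeds)
    return result


def _write_outputs(result: BenchmarkResult, seeds: dict) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    comp = result.comparison
    comp.table().to_csv(out / "comparison.csv", index=False)
    (out / "summary.txt").write_text(comp.summary() + "\n")
    per_session = {}
    for r in comp.reports:
        per_session.setdefault(r.session_id, {})[r.model] = r.to_dict()
    (out / "reports.json").write_text(json.dumps(per_session, indent=2))
    curves = {m: list(comp.pooled_curve(m)[1]) for m in comp.model_names}
    curves["grid_mm"] = list(comp.pooled_curve(comp.model_names[0])[0])
    (out / "cumulative_curves.json").write_text(json.dumps(curves, indent=2))

    cfg = asdict(result.config)
    provenance = {
        "config": cfg,
        "seeds": seeds,
        "versions": {
            "tumortrack": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "timings_s": {k: round(v, 2) for k, v in result.timings.items()},
        "win_counts": comp.win_counts,
        "ttests": comp.ttests,
    }
    (out / "provenance.yaml").write_text(yaml.safe_dump(provenance, sort_keys=False))
    if result.config.save_logfiles:
        lf_dir = out / "logfiles"
        lf_dir.mkdir(exist_ok=True)
        for lf in result.evaluation_cohort:
            write_logfile(lf, lf_dir / f"{lf.session_id}.h5")
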