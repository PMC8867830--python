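# tumortrack

Surrogate-based 3-D tumor-motion prediction for infrared-marker hybrid
real-time tumor tracking (RTTT) in radiotherapy.

During beam delivery the tumor moves with respiration, but it can only be
imaged every 80–640 ms, while reflective markers on the abdominal wall
are tracked continuously at 60 Hz.  A per-patient prediction model maps
the external marker signal `P_IR` (mm) to the internal 3-D target
position `P_detect` (right–left, superior–inferior, anterior–posterior;
mm) so the beam can follow the tumor between detections.  Each tracking
session records 20–40 s of both streams; models are fitted on the first
three quarters and scored on the last quarter.

The package implements three predictors and the statistics to compare
them:

* **Quadratic regression** — the baseline used clinically in gimbal-head
  systems: `f(P_IR, v_IR) = a·P_IR² + b·P_IR + c + d·v_IR² + e·v_IR`,
  fitted per direction by ordinary least squares, with 25-ms
  velocity-based latency compensation.
* **CNN with transfer learning** — a 19-layer 1-D convolutional network
  (8 conv / 5 batch-norm / 3 dropout / flatten / 2 dense; Adam, MAE loss
  in mm) pre-trained on a historical cohort of sessions and fine-tuned on
  each new session's training period (5 epochs, lr 5e-4 → 1e-4).
* **Sugeno ANFIS with pattern search** — per marker and direction, a
  greedy forward search picks 5 of 19 lagged marker positions
  ({0…10, 15…50} samples back), then a first-order Sugeno fuzzy system
  seeded by subtractive clustering is hybrid-trained (exact least-squares
  consequents + gradient membership updates) for 4 epochs.

Because the clinical logfiles cannot be shared, the package ships a
respiratory simulator whose external-marker statistics (peak-to-peak
range 7.2 ± 2.9 mm, period 4.2 ± 1.5 s, 90th-percentile speed ≈ 7 mm/s)
and per-direction target ranges (SI-dominant, 16.4 ± 8.1 mm) are
calibrated to reported clinical cohort summaries, including lagged quadratic
external↔internal coupling and optional deep-inhale irregularity.
Accuracy is reported in the ISO trueness/precision framing: per-session
MAE and SD of the 3-D error, MAE + 2 SD for ranking, percentage of
predictions within 2 mm, cumulative error curves, and the respiratory
change metrics δ = |value_test/value_train − 1| for range, period and
speed.  See `docs/methods.md` for the full model description.

## Worked example

Fit all three models on one simulated session and score its testing
period:

```python
import numpy as np
from tumortrack import (
    AnfisModel, CnnReference, CohortSpec, QuadraticRegression,
    SimulatorConfig, simulate_cohort, simulate_logfile, split_logfile,
)

session = simulate_logfile(SimulatorConfig(), seed=42)
split = split_logfile(session, 0.75)          # 3/4 train, 1/4 test
times = split.test.target.timestamps
truth = split.test.target.positions3d

reg = QuadraticRegression.from_split(split).fit()
print(reg.summary())

reference = CnnReference(simulate_cohort(CohortSpec(30, master_seed=7))).fit()
cnn = reference.fine_tune(split, seed=0)
anfis = AnfisModel(split).fit()

for name, pred in [("regression", reg.predict(session, times)),
                   ("cnn", cnn.predict(times=times)),
                   ("anfis", anfis.predict(times=times))]:
    err = np.linalg.norm(pred - truth, axis=1)
    print(f"{name:<11} MAE {err.mean():.3f} mm   {100*(err<=2).mean():.1f} % within 2 mm")
```

The regression summary prints the fitted (a…e) quintuple per direction
with standard errors; the per-model lines report the 3-D testing-period
error.  On a stable-breathing session the ANFIS typically sits near the
0.2-mm detection-noise floor, the fine-tuned CNN close behind, and the
regression baseline behind both whenever the coupling is lagged or
curved.

The full cohort comparison is one command:

```bash
tumortrack benchmark --historical 30 --evaluation 10 --seed 1 --out runs/demo
```

which simulates both cohorts, trains the reference CNN, fits and scores
all three models per evaluation session, and prints (actual output):

```
Model comparison (testing periods)
========================================================
model         median MAE    % <=2 mm    wins
cnn                0.513       100.0       1
anfis              0.408       100.0       9
regression         0.691        92.9       0
paired t-test cnn vs baseline: p = 0.02265
paired t-test anfis vs baseline: p = 0.003938
```

`median MAE` is the per-session median of the mean absolute 3-D error
(mm), `% <= 2 mm` pools all testing-period predictions, `wins` counts the
sessions where each model minimizes MAE + 2 SD, and the paired t-tests
compare per-session MAE against the regression baseline.  The run
directory contains the per-session reports (JSON/CSV), pooled cumulative
error curves, and a provenance file (config, seeds, versions) from which
the run reproduces bit-for-bit.

Other subcommands: `tumortrack simulate`, `train-reference`,
`fit-regression`, `fit-anfis`, `predict`, `evaluate` (see `--help`).

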