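# swimclass

High-throughput behavioral pharmacology from larval-zebrafish swim tracks.
Instead of reducing a locomotor recording to summary statistics (mean speed,
pause rate), `swimclass` renders each 30-second window of a fish's 2-D track
as a small image whose strokes are colored by relative speed, and trains a
convolutional classifier to predict which exposure condition (e.g. an
ethanol concentration) produced it. The classifier's mistakes are as
informative as its successes:

* **Drug-similarity networks.** Aggregated confusion counts between classes
  are symmetrized into a weighted graph; Louvain communities of that graph
  are clusters of conditions with similar behavioral effects. A rival
  network built from pairwise Cohen's *d* of average speeds
  (edge weight `max(0, 0.5 − d)`) shows what speed statistics alone can
  resolve; comparing modularities quantifies the difference.
* **Time-resolved effects ("sobering").** Predictions are binned into
  10-minute windows; per-bin predicted-class fractions are gated by
  permutation-test baselines, and the per-bin mean predicted concentration
  is tested for monotone decline (exact Spearman) and abrupt change
  (exact piecewise-constant breakpoint search).
* **Embedding analysis.** PCA of the penultimate-layer activations, with
  rank correlations of each component against average speed and
  concentration (the "speed gradient").

The classifier is trained with the focal loss

```
FL(p_t) = −(1 − p_t)^γ · log(p_t),        γ ≥ 0
```

(`p_t` = predicted probability of the true class; γ defaults to 2; γ = 0
recovers cross-entropy), optimized with Adam (lr 0.001, β₁ = 0.9), which
down-weights easy examples when the merged control class dominates.
Validation is grouped K-fold **by fish** (default K = 5), so the model can
never score by recognizing an individual animal.

Because in vivo recordings are rarely shareable, the package includes a
correlated-random-walk simulator with per-condition kinematic regimes
(speed, directional persistence, pausing, circular swimming, immobility),
time-varying schedules (step or linear return toward control kinematics),
reflective circular-well boundaries, and fully deterministic seeding — so
every analysis here can be exercised end to end in silico.

## Worked example

```python
import numpy as np
from swimclass import (RenderConfig, SegmentImageClassifier, TrainConfig,
                       accuracy, confusion_matrix)
from swimclass.insilico import regime_recovery_study

study = regime_recovery_study(seed=11)
print(f"accuracy          {study['accuracy']:.3f}")
print(f"Q confusion graph {study['q_confusion']:.3f}")
print(f"Q speed graph     {study['q_speed']:.3f}")
print("confusion clusters", [sorted(c) for c in study['communities_confusion']])
print("speed clusters    ", [sorted(c) for c in study['communities_speed']])
```

prints (seed 11):

```
accuracy          0.503
Q confusion graph 0.549
Q speed graph     0.178
confusion clusters [['control', 'ethanol_0.5'], ['ethanol_1.5', 'ethanol_2'], ['ethanol_2.5', 'ethanol_3']]
speed clusters     [['control', 'ethanol_0.5'], ['ethanol_1.5', 'ethanol_2', 'ethanol_2.5', 'ethanol_3']]
```

The simulated cohort contains three kinematic regime groups — a slow pair
(control and 0.5%), a fast straight-swimming pair (1.5/2.0%), and a fast
circling pair (2.5/3.0%) — where all four fast conditions share the same
step-speed distribution. Raw accuracy is only ~0.5 because conditions within
a pair are intentionally near-identical, yet the *pattern* of confusions
recovers all three regime groups (three clusters, Q = 0.55), while the
speed-based network cannot tell straight from circling swimming and merges
the four fast conditions into one cluster (two clusters, Q = 0.18). That
contrast — track-shape classification resolving structure invisible to
speed statistics — is the package's central result.

The command line mirrors the library:

```
swimclass run-all --config my_config.json   # simulate → ... → embed
swimclass simulate --out sim/               # write trajectory CSVs + manifest
swimclass segment --manifest sim/manifest.csv --out segments.csv
swimclass dilution --stock-pct 95 --v-stock 2 --v-neutral 45.5   # -> 4.0
```

Stages consume the previous stage's manifest, so `segment` and everything
after it run equally on real tracking output (per-fish CSV of
`frame,x,y`, NaN for lost frames).

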