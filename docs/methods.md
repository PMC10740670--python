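# Methods

## Overview

`swimclass` treats short windows of an animal's 2-D locomotor track as
images and poses condition identification as image classification. The
pipeline is: trajectory → gap filling → 30-s segmentation → speed-colored
rasterization → CNN with focal loss → grouped K-fold predictions → (a)
confusion-based drug-similarity networks, (b) time-binned prediction
fractions with permutation gating and trend/breakpoint analysis, (c) PCA of
model embeddings. A locomotion simulator supplies reproducible cohorts with
known kinematic structure.

## Trajectories and segmentation

Coordinates are pixels in the camera frame (origin top-left, y downward),
one row per frame, time = frame / fps. Tracking dropouts appear as NaN.
Runs of at most `max_gap` missing frames (default 12 ≈ 0.5 s at 25 fps) are
linearly interpolated; longer runs — and any missing frames at the very
start or end — are left missing, and any window still containing a gap is
dropped from analysis. The gap policy is this package's choice; trackers
differ in dropout behavior, and 0.5 s is the scale below which linear
interpolation cannot invent meaningful structure.

Windows are half-open `[t, t + w)` from time 0 with `w = 30 s` by default;
the final partial window is discarded, so a gap-free recording of duration
`T` yields `floor(T / w)` segments (a 90-min, 25-fps recording yields 180
segments of 750 points each). Segments of immobile or dead fish are retained:
immobility is informative high-dose behavior, not missing data.

Step speed is the Euclidean distance between consecutive points times fps;
a segment's average speed is the mean of its step speeds (0 when
stationary). Step speeds are translation-invariant and scale linearly with
spatial rescaling.

## Rendering

A segment is drawn on a square canvas (default 224 px; the desk-scale
studies use 64 px): the arena's circumscribing square maps affinely onto
the image minus a 5% margin, consecutive points are joined by 1-px strokes,
and each stroke's color is its step's *relative* speed through the viridis
map. With the default `segment_minmax` normalization speeds are rescaled to
[0, 1] within each segment (a constant-speed segment maps to mid-colormap);
a `global_fixed` mode with an explicit speed range is available when colors
must be comparable across segments. Anti-aliasing is off, so a given
segment renders to identical bytes on any platform — the classifier's input
is a pure function of the data and the render configuration. A stationary
segment renders as a single dot.

## Classifier

The classifier is a compact convolutional network written directly in NumPy
(3×3 same-padding convolutions via im2col, 2×2 max-pooling, global average
pooling, a dense embedding layer, and a dense decision layer), with two
backbones: `small_cnn` (four conv blocks, the default; trains on a few
hundred 64×64 images in well under a minute per fold on one CPU) and
`resnet_small` (a residual variant with projected skips). Weights use He
initialization from a counter-based seeded generator, so two builds with
the same seed are bit-identical, and training is deterministic on one
device.

The loss is the focal loss `FL(p_t) = −(1 − p_t)^γ log(p_t)` with `p_t`
clipped to `[1e−7, 1]`; its gradient with respect to the logits is
implemented analytically (`dFL/dz = dFL/dp_t · p_t (δ_tj − p_j)`), reducing
exactly to softmax cross-entropy at γ = 0. γ defaults to 2, the canonical
focusing setting; it down-weights easy (well-classified) examples, which
matters when merged controls outnumber each drug class. The optimizer is
Adam with learning rate 0.001 and first-moment decay β₁ = 0.9 (β₂ = 0.999);
β₁ is the natural reading of "momentum" for Adam, which has no classical
momentum term. Batch size 16 and 10 epochs are the defaults: small batches
give enough optimizer steps for the few-hundred-image datasets these
desk-scale studies use. Inputs are scaled per channel to [0, 1]; no
pretrained weights are used anywhere (reproducibility over raw accuracy).

The "embedding" of an image is the ReLU output of the dense layer directly
under the decision layer (default width 64).

## Validation protocol

K-fold splits are **by fish**, stratified by condition (shuffle within
condition, deal round-robin; per-condition fold sizes differ by at most
one). Splitting by segment would leak individual identity: a model can
recognize a particular fish's idiosyncrasies rather than the treatment.
Confusion matrices aggregate raw out-of-fold counts; rates (row
normalization) are computed only for display and network construction.
Chance levels come from permutation tests: true labels are shuffled across
records (default 1000 times), the statistic — overall accuracy, or the
fraction of a given predicted class among records of one true class — is
recomputed each time, and the threshold is the empirical (1 − α) quantile
(α = 0.05).

## Similarity networks

Row-normalized confusion rates `R` define an undirected graph on the
classes with edge weight `(R[i,j] + R[j,i]) / 2` (self-loops dropped); the
arithmetic-mean symmetrization is the package's choice. Communities are
found by Louvain at resolution 1.0 with several seeded restarts, keeping
the highest-modularity partition — on graphs of ≤ 9 nodes (one per class)
this reliably equals the exhaustive-search optimum, which the test suite
verifies by enumerating all set partitions. Modularity is standard weighted
Newman modularity; a graph with zero total weight has Q defined as 0.

The rival speed network uses the absolute Cohen's *d* between per-segment
average speeds of each class pair (pooled-SD form, segments pooled over
fish): classes with `d < 0.5` — the conventional small/medium boundary —
are connected with weight `0.5 − d`. Equal constant samples give d = 0;
unequal constant samples are flagged infinite.

## Time-resolved analysis

A prediction belongs to the 10-min bin of its segment's start time (30 s
divides 600 s, so segments never straddle bins). Per true class and bin,
the fractions of predicted classes form a simplex; each fraction is
compared with its per-bin permutation baseline and masked when not
significant (masked fractions are retained for display, mirroring hatched
timeline bars). The per-bin *mean predicted concentration* (control → 0)
gives a one-number effect trajectory per true class:

* **Trend.** Spearman's ρ between bin index and the series; for ≤ 9 bins
  the two-sided p-value is exact (all rank permutations enumerated), longer
  series use the asymptotic approximation. A declining series (ρ < 0) is
  the sobering signature. Constant series are flagged degenerate with ρ = 0.
* **Breakpoints.** Exact piecewise-constant least-squares segmentation by
  exhaustive enumeration of split placements (series have ≤ 9 points, so
  this is the exact optimum, not a heuristic); an extra split is kept only
  if it reduces the residual sum of squares by more than a penalty
  (default 0, i.e. the best split for a fixed budget). A breakpoint index
  is the first bin of the new piece.

## Embedding analysis

PCA (full SVD, mean-centered) of the embedding matrix, with a deterministic
sign convention (each component's largest-magnitude loading is positive).
Rank (Spearman) correlation — not Pearson — relates each component to
per-segment average speed and to concentration, because the speed relation
is a gradient rather than a line; control segments carry NaN concentration
and are excluded from the concentration correlation only.

## Locomotion simulator

Each fish is a correlated random walk in a circular well. Per frame:
heading gains a wrapped-Gaussian increment with variance
`1 / (turn_concentration · fps)` — `turn_concentration` is directional
persistence *per second*, so trajectories are frame-rate invariant — plus a
constant drift `circling_bias / fps` (rad/frame) that produces circular
swimming with loop radius ≈ speed / bias; step length is
`max(0, Normal(speed_mean, speed_sd)) / fps`; pauses begin with probability
`pause_prob / fps` per frame and last Exponential(`pause_duration_mean`)
seconds; an `immobile` regime emits a constant position (death). A point
landing outside the well is mirrored back across the wall along the radius
and the heading is reflected about the local tangent — this preserves path
length and hence speed statistics near walls. Schedules interpolate all
regime parameters over the recording (`none`, `linear`, or `step` at a
given time), which is how sobering — drugged kinematics returning toward
control-like — is emulated. All randomness flows from one master seed
through counter-based per-fish derivations (Philox); identical designs
reproduce bit-identical cohorts.

The preset library (`ETHANOL_PRESETS`) maps a dose series to regimes: a
mild speed increase at low doses, marked hyperactivity at 1.5%, circular
swimming emerging at 2.0–2.5%, an unstable heavy-pausing regime at 3.0%,
near-immobility at 3.5% and immobility at 4.0%. These numbers (pixel units,
radius-100 wells, 25 fps) are this package's own choices, made once for
qualitative plausibility of that biphasic structure; no quantitative
kinematics per dose were available to copy. The simulator aims at
segment-level statistical realism only — it has no burst-glide
microstructure, tail kinematics, thigmotaxis preference, or inter-fish
interaction — so passing in-silico tests demonstrates that the analysis
machinery recovers structure that is present, not that real fish produce
that structure.

## Reference in-silico studies

`swimclass.insilico` fixes two canonical experiments.

*Regime recovery* (`regime_recovery_study`): six conditions in three
near-identical pairs — slow (control, 0.5%), fast straight (1.5%, 2.0%),
fast circling (2.5%, 3.0%) — six fish per condition, 15-min recordings,
`small_cnn` at 64×64, grouped 3-fold validation. All four fast conditions
share one step-speed distribution (identical means; the small residual
differences come from boundary contact and are well below d = 0.5), so the
speed network merges them into a single cluster while the confusion network
separates straight from circling swimming: three clusters versus two, with
higher modularity. Pairs rather than singletons are used deliberately:
modularity of a community without internal edge weight is not positive, so
a lone control node attaches to whichever cluster it shares a single stray
misclassification with — pair structure makes the community assignment
stable and the modularity contrast structural rather than accidental.

*Sobering* (`sobering_study`): a classifier trained on static control / 1% /
2% regimes (15 min per fish) scores 90-min six-fish cohorts whose schedule
either steps back to control kinematics at minute 30, declines linearly
over the full recording, or stays control throughout. Expected outcomes,
checked over 10 seeded replicates: the step cohort's breakpoint lands in
bin 3 (the first post-switch bin), the linear cohort's trend is
significantly negative (exact p < 0.05), and the static cohort shows no
significant negative trend.

*Calibration* (`calibration_study`): uniform-random predictions pushed
through the per-bin permutation gate are masked in ≥ 95% of (bin, class)
cells at α = 0.05 (the empirical-quantile threshold plus count discreteness
makes the gate slightly conservative).

Problem sizes in these studies (6 fish, 15-min training recordings, 64-px
images, 10–12 epochs, 1000 permutations) are the package's desk-scale
defaults: large enough for every qualitative effect to be stable across
seeds, small enough to run on a single CPU in minutes.

## Numerical and degenerate-input choices

* Focal-loss `p_t` clipped to `[1e−7, 1]`; the γ < 1 gradient singularity at
  `p_t = 1` is handled explicitly (the loss term still → 0).
* Per-segment min-max speed normalization treats a spread below
  `1e−9 · max(|v|)` as constant (mid-colormap) to avoid amplifying float
  noise into full-range color.
* Trajectory CSVs are written with `%.17g` and read with pandas'
  `round_trip` parser, so simulate → write → load is bit-exact.
* Louvain ties and restart selection are deterministic given the seed;
  empty graphs partition into singletons with Q = 0.
* Cohen's d with zero pooled SD: 0 if means agree, infinity flag otherwise.
* Exhaustive breakpoint search breaks cost ties toward the earliest split.

## Known limitations

* The CNN is deliberately small; it is sized for desk-scale in-silico
  studies, not for maximizing accuracy on large video corpora. No data
  augmentation or pretrained weights are used.
* The simulator's realism is statistical, not biomechanical (see above);
  conclusions about real recordings require real recordings.
* Modularity comparisons are reported without significance tests on the
  modularity difference itself.
* Exact Spearman p-values are enumerated only up to 9 bins; longer series
  fall back to the asymptotic approximation.
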