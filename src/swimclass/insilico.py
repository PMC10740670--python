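"""Reference in-silico experiments.

Two ready-made desk-scale studies exercise the full method end to end on
simulated cohorts:

* :func:`regime_recovery_study` — three kinematic regime groups (slow pair,
  fast straight pair, fast circling pair; all fast conditions speed-matched)
  are classified from rendered tracks with grouped 3-fold cross-validation.
  The confusion-matrix similarity network should resolve all three groups
  while the Cohen's-d speed network collapses the speed-matched ones, and
  the confusion network should carry higher modularity.

* :func:`sobering_study` — a classifier trained on static control/1%/2%
  regimes scores 90-min cohorts whose kinematics return to control-like
  either abruptly (step at 30 min), gradually (linear), or not at all;
  per-bin mean predicted concentration is then tested for breakpoints and
  monotone trends.

* :func:`calibration_study` — uniform-random predictions pushed through the
  per-bin permutation gate; almost all class fractions should be masked.
"""

from __future__ import annotations

import numpy as np

from .classifier import PredictionRecord, SegmentImageClassifier, TrainConfig, predict
from .config import stage_seed
from .embeddings import pca, speed_gradient, variance_explained
from .evaluate import accuracy, confusion_matrix
from .networks import (compare_networks, confusion_to_graph, effectsize_to_graph,
                       pairwise_effect_sizes)
from .presets import (DEFAULT_ARENA, ETHANOL_PRESETS, ethanol_cohort_design,
                      ethanol_label, sobering_linear_schedule,
                      sobering_step_schedule, speed_circling_design)
from .render import RenderConfig
from .simulate import CohortDesign, RegimeSchedule
from .timecourse import (bin_permutation_nulls, bin_predictions, concentration_series,
                         detect_breakpoints, gate_significance, sobering_trend)
from .trajectory import average_speed
from .workflow import (cohort_segments, crossval_predictions, segment_dataset,
                       speeds_by_class)

__all__ = ["regime_recovery_study", "sobering_study", "calibration_study"]

REGIME_GROUPS = (
    frozenset({"control", "ethanol_0.5"}),
    frozenset({"ethanol_1.5", "ethanol_2"}),
    frozenset({"ethanol_2.5", "ethanol_3"}),
)


def regime_recovery_study(seed: int = 0, n_fish: int = 6, duration: float = 900.0,
                          epochs: int = 12, k: int = 3,
                          image_size: int = 64) -> dict:
    """Run the regime-group recovery experiment; returns all summary numbers."""
    design = speed_circling_design(n_fish_per_condition=n_fish, duration=duration,
                                  seed=stage_seed(seed, "cohort"))
    segments = cohort_segments(design, 30.0)
    render_cfg = RenderConfig(image_size=image_size)
    train_cfg = TrainConfig(epochs=epochs, batch_size=16,
                            seed=stage_seed(seed, "train"))
    records, models = crossval_predictions(segments, train_cfg, render_cfg, k=k,
                                           seed=stage_seed(seed, "folds"))
    classes = sorted({r.true_label for r in records})
    cm = confusion_matrix(records, classes, classes)
    fold_acc = {}
    for r in records:
        fold_acc.setdefault(r.fold_id, []).append(r.true_label == r.predicted_label)
    fold_accuracies = [float(np.mean(v)) for _, v in sorted(fold_acc.items())]

    g_confusion = confusion_to_graph(cm)
    effect_sizes = pairwise_effect_sizes(speeds_by_class(segments))
    g_speed = effectsize_to_graph(effect_sizes, similarity_threshold=0.5)
    comparison = compare_networks(g_confusion, g_speed,
                                  seed=stage_seed(seed, "louvain"))

    # embedding-space structure from the first fold's model
    images, labels, _, _, refs = segment_dataset(segments, render_cfg)
    emb = models[0].transform(images)
    from .classifier import EmbeddingMatrix

    result = pca(EmbeddingMatrix(rows=emb, segment_refs=refs), n_components=3)
    speeds = np.array([average_speed(s) for s in segments])
    conc = np.array([s.label.concentration if s.label.kind == "drug" else np.nan
                     for s in segments])
    gradient = speed_gradient(result, speeds, conc)

    group_of = {name: gi for gi, grp in enumerate(REGIME_GROUPS) for name in grp}
    groups = np.array([group_of[l.name] for l in labels])
    proj = result.projections
    rng = np.random.default_rng(stage_seed(seed, "dist"))
    idx = rng.choice(len(proj), size=min(len(proj), 600), replace=False)
    d = np.linalg.norm(proj[idx, None, :] - proj[None, idx, :], axis=-1)
    same = groups[idx, None] == groups[None, idx]
    triu = np.triu_indices(len(idx), 1)
    within = float(d[triu][same[triu]].mean())
    between = float(d[triu][~same[triu]].mean())

    return {
        "accuracy": accuracy(cm),
        "fold_accuracies": fold_accuracies,
        "fold_spread": float(max(fold_accuracies) - min(fold_accuracies)),
        "confusion_matrix": cm,
        "q_confusion": comparison["q_confusion"],
        "q_speed": comparison["q_speed"],
        "communities_confusion": comparison["partition_confusion"].as_sets(),
        "communities_speed": comparison["partition_speed"].as_sets(),
        "n_communities_confusion": comparison["partition_confusion"].n_communities,
        "n_communities_speed": comparison["partition_speed"].n_communities,
        "max_fast_pair_speed_d": float(effect_sizes.d[2:, 2:].max()),
        "variance_explained_3": variance_explained(result, 3),
        "max_speed_gradient_rho": float(np.nanmax(np.abs(gradient.spearman_with_speed))),
        "embedding_within_group_distance": within,
        "embedding_between_group_distance": between,
    }


def _predict_cohort(model, schedule, label, seed, render_cfg, n_fish=6,
                    duration=5400.0):
    design = CohortDesign(conditions=((label, schedule),),
                          n_fish_per_condition=n_fish, duration=duration, fps=25.0,
                          arena=DEFAULT_ARENA, seed=seed)
    segments = cohort_segments(design, 30.0)
    images, labels, _, starts, refs = segment_dataset(segments, render_cfg)
    return predict(model, images, true_labels=labels, refs=refs, start_times=starts)


def sobering_study(seed: int = 0, n_replicates: int = 10, n_fish: int = 6,
                   epochs: int = 12, image_size: int = 64) -> dict:
    """Run the time-resolved drug-effect experiment over seeded replicates."""
    render_cfg = RenderConfig(image_size=image_size)
    train_design = ethanol_cohort_design(
        concentrations=(0.0, 1.0, 2.0), n_fish_per_condition=n_fish,
        duration=900.0, seed=stage_seed(seed, "train_cohort"))
    segments = cohort_segments(train_design, 30.0)
    images, labels, *_ = segment_dataset(segments, render_cfg)
    model = SegmentImageClassifier(epochs=epochs, batch_size=16,
                                   seed=stage_seed(seed, "train"))
    model.fit(images, labels)

    drugged = ethanol_label(2.0)
    control = ethanol_label(0.0)
    switch_bin = 3  # regime switch at minute 30 -> first bin of the new regime
    step_hits = 0
    linear_significant = 0
    static_significant = 0
    details = []
    for rep in range(n_replicates):
        rec = _predict_cohort(model, sobering_step_schedule(2.0, 1800.0, 5400.0),
                              drugged, stage_seed(seed, f"step{rep}"), render_cfg,
                              n_fish)
        series = concentration_series(rec, drugged, 10.0, 90.0)
        bp = detect_breakpoints(series, max_breakpoints=1)
        step_hits += bp.breakpoint_bins == [switch_bin]

        rec = _predict_cohort(model, sobering_linear_schedule(2.0, 5400.0), drugged,
                              stage_seed(seed, f"linear{rep}"), render_cfg, n_fish)
        lin = sobering_trend(concentration_series(rec, drugged, 10.0, 90.0))
        linear_significant += (lin.rho < 0) and (lin.p_value < 0.05)

        rec = _predict_cohort(
            model, RegimeSchedule.constant(ETHANOL_PRESETS[0.0], 5400.0), control,
            stage_seed(seed, f"static{rep}"), render_cfg, n_fish)
        stat = sobering_trend(concentration_series(rec, control, 10.0, 90.0))
        static_significant += (stat.rho < 0) and (stat.p_value < 0.05)
        details.append({"breakpoints": bp.breakpoint_bins, "linear_rho": lin.rho,
                        "linear_p": lin.p_value, "static_rho": stat.rho,
                        "static_p": stat.p_value})

    return {
        "n_replicates": n_replicates,
        "step_breakpoint_hits": step_hits,
        "linear_trend_significant": linear_significant,
        "static_trend_significant": static_significant,
        "details": details,
    }


def calibration_study(seed: int = 0, n_true_classes: int = 3,
                      n_per_class_bin: int = 24, n_permutations: int = 1000,
                      alpha: float = 0.05) -> dict:
    """Mask rate of the per-bin permutation gate on uniform-random predictions."""
    rng = np.random.default_rng(stage_seed(seed, "calibration"))
    classes = [ethanol_label(c) for c in sorted(ETHANOL_PRESETS)]
    records = []
    for t in classes:
        for b in range(9):
            for i in range(n_per_class_bin):
                records.append(PredictionRecord(
                    segment_ref=(t.name, b * 100 + i), true_label=t,
                    predicted_label=classes[rng.integers(len(classes))],
                    probabilities=np.ones(len(classes)) / len(classes),
                    start_time=b * 600.0 + 30.0 * (i % 20)))
    masked = total = 0
    for t in classes[:n_true_classes]:
        profile = bin_predictions(records, t, classes, 10.0, 90.0)
        nulls = bin_permutation_nulls(records, t, classes, 10.0, n_permutations,
                                      alpha, seed=stage_seed(seed, f"null_{t.name}"))
        gate_significance(profile, nulls)
        for tb in profile.bins:
            for c in classes:
                total += 1
                masked += not tb.significant[c]
    return {"masked_fraction": masked / total, "n_cells": total, "alpha": alpha}
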