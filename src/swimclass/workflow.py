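"""End-to-end building blocks: cohort → segments → images → predictions.

These helpers glue the stage modules together for the common study designs
(grouped cross-validation within one experiment, or train on one experiment
and test on an independent one) without hiding any stage: each returns the
plain objects of the underlying modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import (PredictionRecord, SegmentImageClassifier, TrainConfig,
                         predict)
from .evaluate import kfold_split
from .render import RenderConfig, render_array
from .simulate import CohortDesign, simulate_cohort
from .trajectory import TrackSegment, segment_trajectory

__all__ = [
    "cohort_segments",
    "segment_dataset",
    "crossval_predictions",
    "cross_experiment_predictions",
    "speeds_by_class",
]


def cohort_segments(design: CohortDesign,
                    window_seconds: float = 30.0) -> list[TrackSegment]:
    """Simulate a cohort and clip every trajectory into segments."""
    trajectories, _ = simulate_cohort(design)
    segments: list[TrackSegment] = []
    for traj in trajectories:
        segments.extend(segment_trajectory(traj, window_seconds))
    return segments


def segment_dataset(segments: list[TrackSegment], render_config: RenderConfig):
    """Render segments and collect aligned metadata arrays.

    Returns ``(images, labels, fish_ids, start_times, refs)`` where images
    is a (n, size, size, 3) uint8 array.
    """
    images = render_array(segments, render_config)
    labels = np.array([s.label for s in segments], dtype=object)
    fish_ids = np.array([s.fish_id for s in segments])
    start_times = np.array([s.start_time for s in segments])
    refs = [s.ref for s in segments]
    return images, labels, fish_ids, start_times, refs


def _fish_manifest(segments: list[TrackSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fish_id": [s.fish_id for s in segments],
            "label": [s.label.name for s in segments],
        }
    ).drop_duplicates("fish_id")


def crossval_predictions(
    segments: list[TrackSegment],
    train_config: TrainConfig,
    render_config: RenderConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[list[PredictionRecord], list[SegmentImageClassifier]]:
    """Grouped K-fold: hold out whole fish, train on the rest, predict.

    Returns the pooled out-of-fold prediction records and the per-fold
    fitted models (for embedding extraction).
    """
    if render_config is None:
        render_config = RenderConfig(image_size=64)
    images, labels, fish_ids, start_times, refs = segment_dataset(segments, render_config)
    folds = kfold_split(_fish_manifest(segments), k=k, seed=seed)
    fold_idx = np.array([folds.fold_of_fish[f] for f in fish_ids])
    records: list[PredictionRecord] = []
    models = []
    for fold in range(k):
        test = fold_idx == fold
        model = SegmentImageClassifier(
            backbone=train_config.backbone, learning_rate=train_config.learning_rate,
            beta1=train_config.beta1, beta2=train_config.beta2,
            gamma=train_config.gamma, epochs=train_config.epochs,
            batch_size=train_config.batch_size, seed=train_config.seed + fold,
        )
        model.fit(images[~test], labels[~test])
        records.extend(
            predict(
                model,
                images[test],
                true_labels=labels[test],
                refs=[r for r, m in zip(refs, test) if m],
                start_times=start_times[test],
                fold_id=fold,
            )
        )
        models.append(model)
    return records, models


def cross_experiment_predictions(
    train_segments: list[TrackSegment],
    test_segments: list[TrackSegment],
    train_config: TrainConfig,
    render_config: RenderConfig | None = None,
) -> tuple[list[PredictionRecord], SegmentImageClassifier]:
    """Train on one experiment, predict an independent one."""
    if render_config is None:
        render_config = RenderConfig(image_size=64)
    tr_images, tr_labels, *_ = segment_dataset(train_segments, render_config)
    te_images, te_labels, _, te_starts, te_refs = segment_dataset(test_segments, render_config)
    model = SegmentImageClassifier(
        backbone=train_config.backbone, learning_rate=train_config.learning_rate,
        beta1=train_config.beta1, beta2=train_config.beta2,
        gamma=train_config.gamma, epochs=train_config.epochs,
        batch_size=train_config.batch_size, seed=train_config.seed,
    )
    model.fit(tr_images, tr_labels)
    records = predict(model, te_images, true_labels=te_labels, refs=te_refs,
                      start_times=te_starts)
    return records, model


def speeds_by_class(segments: list[TrackSegment]) -> dict:
    """Per-segment average speeds grouped by class name (for effect sizes)."""
    from .trajectory import average_speed

    out: dict[str, list] = {}
    for s in segments:
        out.setdefault(s.label.name, []).append(average_speed(s))
    return {k: np.asarray(v) for k, v in out.items()}
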