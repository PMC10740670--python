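"""Reproducible end-to-end run: one config in, one report out.

Stages execute in order (simulate, segment, render+train+evaluate, cluster,
timeline, embed, speedstats); every artifact is stamped with the config
hash, all randomness flows from the master seed via per-stage derived
seeds, and a failed stage aborts the run leaving a FAILED marker naming the
stage.  Rerunning with an identical config reproduces every output.
"""

from __future__ import annotations

import json
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import TrainConfig, extract_embeddings
from .config import PipelineConfig, stage_seed
from .embeddings import pca, speed_gradient, variance_explained
from .evaluate import accuracy, confusion_matrix, permutation_threshold
from .networks import (compare_networks, confusion_to_graph, effectsize_to_graph,
                       pairwise_effect_sizes)
from .presets import ETHANOL_PRESETS, ethanol_label
from .render import RenderConfig, render_dataset
from .simulate import CohortDesign, RegimeSchedule, simulate_cohort
from .trajectory import ArenaGeometry, average_speed, segment_index, segment_trajectory
from .timecourse import (bin_permutation_nulls, bin_predictions, concentration_series,
                         detect_breakpoints, gate_significance, sobering_trend)
from .workflow import crossval_predictions, segment_dataset, speeds_by_class

__all__ = ["run_pipeline", "design_from_config", "render_config_from"]


def design_from_config(cfg: PipelineConfig) -> CohortDesign:
    arena = ArenaGeometry(
        center=(cfg.design.arena.center_x, cfg.design.arena.center_y),
        radius=cfg.design.arena.radius,
    )
    conditions = tuple(
        (ethanol_label(c),
         RegimeSchedule.constant(ETHANOL_PRESETS[c], cfg.design.duration_seconds))
        for c in cfg.design.concentrations
    )
    return CohortDesign(
        conditions=conditions,
        n_fish_per_condition=cfg.design.n_fish_per_condition,
        duration=cfg.design.duration_seconds,
        fps=cfg.design.fps,
        arena=arena,
        seed=stage_seed(cfg.seed, "simulate"),
    )


def render_config_from(cfg: PipelineConfig) -> RenderConfig:
    return RenderConfig(
        image_size=cfg.render.image_size,
        line_width=cfg.render.line_width,
        colormap=cfg.render.colormap,
        speed_norm=cfg.render.speed_norm,
        margin=cfg.render.margin,
    )


def _graph_to_csv(g, path) -> None:
    rows = [{"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.model_dump(), "config_hash": cfg.config_hash,
                    "stages": {}}
    state: dict = {}

    def simulate():
        design = design_from_config(cfg)
        trajectories, manifest = simulate_cohort(design)
        manifest["config_hash"] = cfg.config_hash
        manifest.to_csv(out / "manifest.csv", index=False)
        state["trajectories"] = trajectories
        return {"n_fish": len(trajectories)}

    def segment():
        segments = []
        for traj in state["trajectories"]:
            segments.extend(segment_trajectory(traj, cfg.window_seconds))
        idx = segment_index(segments)
        idx["config_hash"] = cfg.config_hash
        idx.to_csv(out / "segments.csv", index=False)
        state["segments"] = segments
        return {"n_segments": len(segments)}

    def render():
        rc = render_config_from(cfg)
        state["render_config"] = rc
        if cfg.save_images:
            manifest = render_dataset(state["segments"], rc, out / "images")
            return {"n_images": len(manifest), "written": True}
        return {"n_images": len(state["segments"]), "written": False}

    def evaluate():
        tc = TrainConfig(
            backbone=cfg.train.backbone, learning_rate=cfg.train.learning_rate,
            beta1=cfg.train.beta1, gamma=cfg.train.gamma, epochs=cfg.train.epochs,
            batch_size=cfg.train.batch_size, seed=stage_seed(cfg.seed, "train"),
        )
        records, models = crossval_predictions(
            state["segments"], tc, state["render_config"], k=cfg.k_folds,
            seed=stage_seed(cfg.seed, "folds"),
        )
        state["records"], state["models"] = records, models
        classes = sorted({r.true_label for r in records})
        state["classes"] = classes
        cm = confusion_matrix(records, classes, classes)
        state["cm"] = cm
        cm.to_frame().to_csv(out / "confusion_matrix.csv")
        null = permutation_threshold(
            records, "accuracy", n_permutations=cfg.n_permutations,
            alpha=cfg.alpha, seed=stage_seed(cfg.seed, "perm"),
        )
        rows = [{"segment": f"{r.segment_ref[0]}:{r.segment_ref[1]}",
                 "true": r.true_label.name, "predicted": r.predicted_label.name,
                 "start_time": r.start_time, "fold": r.fold_id,
                 **{f"p_{c.name}": r.probabilities[i]
                    for i, c in enumerate(classes)}}
                for r in records]
        pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False)
        return {"accuracy": accuracy(cm), "chance_threshold": null.threshold,
                "above_chance": accuracy(cm) > null.threshold}

    def cluster():
        g_conf = confusion_to_graph(state["cm"])
        speeds = speeds_by_class(state["segments"])
        esm = pairwise_effect_sizes(speeds)
        g_speed = effectsize_to_graph(esm, cfg.similarity_threshold)
        comparison = compare_networks(g_conf, g_speed,
                                      seed=stage_seed(cfg.seed, "louvain"))
        _graph_to_csv(g_conf, out / "confusion_graph.csv")
        _graph_to_csv(g_speed, out / "speed_graph.csv")
        import networkx as nx
        nx.write_graphml(g_conf, out / "confusion_graph.graphml")
        nx.write_graphml(g_speed, out / "speed_graph.graphml")
        part = comparison["partition_confusion"].community_of_node
        pd.DataFrame(sorted(part.items()), columns=["node", "community"]).to_csv(
            out / "communities.csv", index=False)
        return {
            "q_confusion": comparison["q_confusion"],
            "q_speed": comparison["q_speed"],
            "delta_q": comparison["delta_q"],
            "communities_confusion": comparison["partition_confusion"].n_communities,
            "communities_speed": comparison["partition_speed"].n_communities,
        }

    def timeline():
        records = state["records"]
        classes = state["classes"]
        recording_minutes = cfg.design.duration_seconds / 60.0
        results = {}
        long_rows = []
        for cls in classes:
            profile = bin_predictions(records, cls, classes, cfg.bin_minutes,
                                      recording_minutes)
            nulls = bin_permutation_nulls(
                records, cls, classes, cfg.bin_minutes,
                n_permutations=cfg.n_permutations, alpha=cfg.alpha,
                seed=stage_seed(cfg.seed, f"binperm_{cls.name}"),
            )
            gate_significance(profile, nulls)
            for tb in profile.bins:
                for c in classes:
                    long_rows.append({
                        "true_class": cls.name, "bin": tb.bin_index,
                        "predicted_class": c.name, "fraction": tb.fractions[c],
                        "n": tb.n_records, "significant": tb.significant.get(c, False),
                    })
            series = concentration_series(records, cls, cfg.bin_minutes,
                                          recording_minutes)
            trend = sobering_trend(series)
            bp = detect_breakpoints(series, max_breakpoints=2)
            results[cls.name] = {
                "spearman_rho": trend.rho, "p_value": trend.p_value,
                "degenerate": trend.degenerate,
                "breakpoints": bp.breakpoint_bins,
                "piece_means": bp.segment_means,
                "series": [None if np.isnan(v) else float(v) for v in series],
            }
        pd.DataFrame(long_rows).to_csv(out / "timeline.csv", index=False)
        with open(out / "trends.json", "w") as fh:
            json.dump(results, fh, indent=2)
        return {"classes_analyzed": len(results)}

    def embed():
        rc = state["render_config"]
        images, labels, _, _, refs = segment_dataset(state["segments"], rc)
        emb = extract_embeddings(state["models"][0], images, refs)
        n_comp = min(3, min(emb.rows.shape))
        result = pca(emb, n_components=n_comp)
        speeds = np.array([average_speed(s) for s in state["segments"]])
        conc = np.array([s.label.concentration if s.label.kind == "drug" else np.nan
                         for s in state["segments"]])
        grad = speed_gradient(result, speeds, conc)
        payload = {
            "explained_variance_ratio": result.explained_variance_ratio.tolist(),
            "variance_explained_3": variance_explained(result, n_comp),
            "spearman_with_speed": grad.spearman_with_speed.tolist(),
            "spearman_with_concentration": grad.spearman_with_concentration.tolist(),
        }
        with open(out / "embedding_pca.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload

    def speedstats():
        speeds = speeds_by_class(state["segments"])
        esm = pairwise_effect_sizes(speeds)
        pd.DataFrame(esm.d, index=esm.classes, columns=esm.classes).to_csv(
            out / "effect_sizes.csv")
        return {"n_classes": len(esm.classes)}

    stages = [("simulate", simulate), ("segment", segment), ("render", render),
              ("evaluate", evaluate), ("cluster", cluster), ("timeline", timeline),
              ("embed", embed), ("speedstats", speedstats)]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            summary = fn()
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {name}: {exc}\n{traceback.format_exc()}")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["stages"][name] = {
            "summary": summary,
            "seconds": round(time.perf_counter() - t0, 3),
            "seed": stage_seed(cfg.seed, name),
        }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
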