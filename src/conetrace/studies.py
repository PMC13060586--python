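"""Benchmark and calibration studies built from the pipeline primitives.

These are the package's self-validation workflows: scoring the vision
stage against simulator ground truth over a batch of seeded videos, and
null-simulation calibration of the test procedures (type-I error of
Levene's test and of the factorial ANOVA under the null).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import PRESETS, RenderParams, default_geometry, run_assay, vision_scores
from .stats import levene_test, two_way_anova

__all__ = ["vision_benchmark", "levene_null_calibration", "anova_null_calibration"]


def vision_benchmark(
    n_videos: int = 10,
    base_seed: int = 0,
    noise_sd: float = 4.0,
    min_area: int = 8,
) -> dict[str, float]:
    """Pooled detection recall/precision over seeded synthetic videos.

    Alternates control and high-irritancy cohorts so the benchmark covers
    both sparse and dense movement regimes.  Scores are pooled over all
    detections and truth movers of all videos.
    """
    geometry = default_geometry()
    render = RenderParams(blob_radius=3.0, noise_sd=noise_sd)
    presets = ["control", "treated_high_irritancy"]
    tp_truth = n_truth = tp_det = n_det = 0
    per_video = []
    for i in range(n_videos):
        params = PRESETS[presets[i % len(presets)]]
        run = run_assay(
            params,
            geometry,
            seed=(base_seed + 7907 * i + 1) % (2**31),
            render=render,
        )
        sc = vision_scores(run.truth, run.series, match_radius=render.blob_radius)
        per_video.append(sc)
        tp_truth += sc["recall"] * sc["n_truth"]
        n_truth += sc["n_truth"]
        tp_det += sc["precision"] * sc["n_detections"]
        n_det += sc["n_detections"]
    return {
        "recall": tp_truth / n_truth,
        "precision": tp_det / n_det,
        "min_video_recall": min(s["recall"] for s in per_video),
        "min_video_precision": min(s["precision"] for s in per_video),
        "n_truth": n_truth,
        "n_detections": n_det,
        "n_videos": n_videos,
    }


def levene_null_calibration(
    n_reps: int = 1000,
    n_groups: int = 6,
    n_per_group: int = 40,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of Levene's test under equal-variance normal data."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        groups = [rng.normal(0.0, 1.0, n_per_group) for _ in range(n_groups)]
        if levene_test(groups).p < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def anova_null_calibration(
    n_reps: int = 1000,
    reps_per_cell: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the 2x3 factorial ANOVA under a zero-effect null."""
    rng = np.random.default_rng(seed)
    strains = ["s1", "s2"]
    nets = ["n1", "n2", "n3"]
    base = pd.DataFrame(
        [
            {"strain": s, "net": n}
            for s in strains
            for n in nets
            for _ in range(reps_per_cell)
        ]
    )
    hits = {"strain": 0, "net": 0, "strain:net": 0}
    for _ in range(n_reps):
        df = base.assign(y=rng.normal(0.0, 1.0, len(base)))
        rep = two_way_anova(df, "y", "strain", "net")
        for _, row in rep.effects.iterrows():
            if row["p"] < alpha:
                hits[row["effect"]] += 1
    return {
        "strain_rate": hits["strain"] / n_reps,
        "net_rate": hits["net"] / n_reps,
        "interaction_rate": hits["strain:net"] / n_reps,
        "n_reps": n_reps,
    }
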