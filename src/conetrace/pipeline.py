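"""End-to-end assay pipelines: simulate → render → detect → aggregate.

Bundles the per-module operations into the workflows a study actually
runs: a single simulated video cone test scored against its own truth log,
replicate batches, and the two-arm discrimination study that mirrors a
susceptible-vs-resistant or net-vs-net contrast in total movement.

The behavioural presets encode the qualitative response structure of the
assay: a control cohort with stable low activity, and treated cohorts
whose activation rates ramp with accumulated net contact (irritancy) and
which accumulate knockdown through contact-dependent toxicity.  The rate
constants are package defaults chosen to produce realistic activity
magnitudes and profile shapes; they are not estimates of any real strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import ActivityProfile, aggregate_bins
from .geometry import ConeGeometry
from .simulate import BehaviorParams, TruthLog, render_video, simulate_cohort
from .stats import GroupSummary, welch_t, cohens_d
from .vision import DetectionSeries, MogParams, analyze_recording

__all__ = [
    "PRESETS",
    "RenderParams",
    "default_geometry",
    "fast_geometry",
    "run_assay",
    "run_replicates",
    "vision_scores",
    "discrimination_study",
]

PRESETS: dict[str, BehaviorParams] = {
    # stable low activity, resting predominates, no irritancy or toxicity
    "control": BehaviorParams(
        rate_C_to_F=0.05,
        rate_F_to_C=0.25,
        rate_F_to_N=0.15,
        rate_N_to_F=0.08,
        irritancy_gain=0.0,
        toxicity_hazard=0.0,
    ),
    # strongly irritant net: activity ramps with contact, knockdown follows
    "treated_high_irritancy": BehaviorParams(
        rate_C_to_F=0.05,
        rate_F_to_C=0.25,
        rate_F_to_N=0.15,
        rate_N_to_F=0.08,
        irritancy_gain=0.65,
        toxicity_hazard=0.0003,
    ),
    # weakly irritant net: attenuated activation, little knockdown
    "treated_low_irritancy": BehaviorParams(
        rate_C_to_F=0.05,
        rate_F_to_C=0.25,
        rate_F_to_N=0.15,
        rate_N_to_F=0.08,
        irritancy_gain=0.06,
        toxicity_hazard=0.0001,
    ),
    # strongly toxic net: pronounced knockdown accumulation over the assay
    "knockdown_prone": BehaviorParams(
        rate_C_to_F=0.05,
        rate_F_to_C=0.25,
        rate_F_to_N=0.15,
        rate_N_to_F=0.08,
        irritancy_gain=0.30,
        toxicity_hazard=0.0015,
    ),
}


@dataclass(frozen=True)
class RenderParams:
    blob_radius: float = 3.0
    agent_intensity: float = 200.0
    noise_sd: float = 4.0


def default_geometry() -> ConeGeometry:
    """Standard study geometry (160 × 192 px)."""
    return ConeGeometry.default(160, 192)


def fast_geometry() -> ConeGeometry:
    """Reduced geometry for large repetition studies (64 × 80 px)."""
    return ConeGeometry.default(64, 80)


@dataclass
class AssayRun:
    truth: TruthLog
    series: DetectionSeries
    profile: ActivityProfile


def run_assay(
    params: BehaviorParams,
    geometry: ConeGeometry | None = None,
    seed: int = 0,
    render: RenderParams | None = None,
    mog: MogParams | None = None,
    n_agents: int = 5,
    duration: float = 180.0,
    assay_id: str = "assay",
    strain: str = "",
    net: str = "",
) -> AssayRun:
    """Simulate, render and analyse one cone assay.

    The simulation and rendering seeds are derived from ``seed`` so that a
    single integer reproduces the whole run.
    """
    geometry = geometry or default_geometry()
    render = render or RenderParams()
    truth = simulate_cohort(
        params.with_seed(seed), geometry, n_agents=n_agents, duration=duration
    )
    frames = render_video(
        truth,
        geometry,
        blob_radius=render.blob_radius,
        agent_intensity=render.agent_intensity,
        noise_sd=render.noise_sd,
        seed=(seed * 7919 + 17) % (2**31),
    )
    min_area = max(2, int(0.3 * np.pi * render.blob_radius**2))
    series = analyze_recording(
        frames, fps=round(1.0 / truth.dt), mog_params=mog, min_area=min_area
    )
    profile = aggregate_bins(
        series,
        geometry,
        assay_id=assay_id,
        strain=strain,
        net=net,
        expected_duration=duration,
    )
    return AssayRun(truth=truth, series=series, profile=profile)


def run_replicates(
    params: BehaviorParams,
    n_replicates: int,
    geometry: ConeGeometry | None = None,
    base_seed: int = 0,
    label: str = "arm",
    **kwargs,
) -> list[AssayRun]:
    return [
        run_assay(
            params,
            geometry,
            seed=(base_seed + 1000003 * i) % (2**31),
            assay_id=f"{label}-{i}",
            **kwargs,
        )
        for i in range(n_replicates)
    ]


def vision_scores(
    truth: TruthLog,
    series: DetectionSeries,
    match_radius: float = 3.0,
    motion_window_s: float = 0.3,
) -> dict[str, float]:
    """Score a detection series against the simulator truth log.

    Ground-truth movers at an analysed frame are agents that displaced by
    more than half a pixel within the trailing ``motion_window_s`` — the
    detector's temporal resolution, since the background model needs a few
    frames to re-absorb a mosquito that stops.  A truth mover is recalled
    if a detection centroid lies within ``match_radius``; a detection is a
    true positive if a truth mover lies within ``match_radius``.  Also
    reports the fraction of frames whose count is within ±1 of truth.
    """
    win = max(1, int(round(motion_window_s / truth.dt)))
    disp = np.zeros(truth.states.shape, dtype=bool)
    pos = truth.positions
    for lag in range(1, win + 1):
        d = np.linalg.norm(pos[lag:] - pos[:-lag], axis=2) > 0.5
        disp[lag:] |= d
    tp_truth = n_truth = tp_det = n_det = 0
    ok_frames = n_frames = 0
    for k in range(len(series)):
        if series.burnin[k]:
            continue
        frame = int(series.frame_index[k] * series.analysis_interval / truth.dt)
        truth_pos = truth.positions[frame][disp[frame]]
        det = series.centroids[k]
        n_frames += 1
        if abs(len(det) - len(truth_pos)) <= 1:
            ok_frames += 1
        n_truth += len(truth_pos)
        n_det += len(det)
        if len(truth_pos) and len(det):
            dist = np.linalg.norm(
                truth_pos[:, None, :] - det[None, :, :], axis=2
            )
            tp_truth += int((dist.min(axis=1) <= match_radius).sum())
            tp_det += int((dist.min(axis=0) <= match_radius).sum())
    return {
        "recall": tp_truth / n_truth if n_truth else float("nan"),
        "precision": tp_det / n_det if n_det else float("nan"),
        "count_within_1": ok_frames / n_frames if n_frames else float("nan"),
        "n_truth": n_truth,
        "n_detections": n_det,
    }


def discrimination_study(
    params_a: BehaviorParams | None = None,
    params_b: BehaviorParams | None = None,
    n_per_arm: int = 10,
    repetitions: int = 20,
    base_seed: int = 0,
    geometry: ConeGeometry | None = None,
    alpha: float = 0.01,
) -> dict:
    """Repeatedly test whether the full chain separates two irritancy arms.

    Each repetition simulates ``n_per_arm`` video assays per arm, runs the
    detect → activity chain, and applies Welch's t test to the total
    activities.  Returns per-repetition p-values, effect sizes, and the
    fraction of repetitions flagged at ``alpha``.
    """
    params_a = params_a or PRESETS["treated_high_irritancy"]
    params_b = params_b or PRESETS["treated_low_irritancy"]
    geometry = geometry or fast_geometry()
    render = RenderParams(blob_radius=2.0)
    pvals, dvals = [], []
    for rep in range(repetitions):
        totals = {}
        for arm, params in (("a", params_a), ("b", params_b)):
            runs = run_replicates(
                params,
                n_per_arm,
                geometry,
                base_seed=(base_seed + 104729 * rep + (0 if arm == "a" else 499979))
                % (2**31),
                label=arm,
                render=render,
            )
            totals[arm] = [r.profile.total_activity for r in runs]
        ga = GroupSummary.from_values("a", totals["a"])
        gb = GroupSummary.from_values("b", totals["b"])
        res = welch_t(ga, gb)
        pvals.append(res.p)
        dvals.append(cohens_d(ga, gb).d)
    pvals = np.asarray(pvals)
    return {
        "p_values": pvals,
        "effect_sizes": np.asarray(dvals),
        "detection_rate": float((pvals < alpha).mean()),
        "mean_effect_size": float(np.mean(dvals)),
        "repetitions": repetitions,
        "n_per_arm": n_per_arm,
    }
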