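"""Automated movement detection for cone-assay recordings.

Replicates the machine-vision stage of a video cone test: adaptive
per-pixel Gaussian-mixture background subtraction, connected-component blob
extraction, and per-frame moving-mosquito counts and centroids at 0.1-s
analysis intervals.  A mosquito that stops moving is absorbed into the
background within a few frames and no longer counted — the reported
quantity is *movement*, not presence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ._mog import mog_update

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity

__all__ = [
    "MogParams",
    "BackgroundModel",
    "Blob",
    "DetectionSeries",
    "segment_foreground",
    "detect_blobs",
    "analyze_recording",
]


@dataclass(frozen=True)
class MogParams:
    """Stauffer–Grimson-style mixture-of-Gaussians parameters.

    ``n_components`` mixture components per pixel, learning rate ``alpha``,
    background cumulative-weight threshold ``T``, match threshold ``lam``
    (standard deviations), a positive variance floor, and the weight /
    variance given to a freshly created component.
    """

    n_components: int = 3
    alpha: float = 0.02
    T: float = 0.9
    lam: float = 2.5
    var_floor: float = 4.0
    new_weight: float = 0.05
    init_var: float = 225.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.T < 1.0):
            raise ValueError("T must be in (0, 1)")
        if self.n_components < 1 or self.var_floor <= 0:
            raise ValueError("need n_components >= 1 and var_floor > 0")


class BackgroundModel:
    """Per-pixel adaptive MOG background model.

    Lazily initialised from the first frame: component 0 takes the frame as
    its mean with full weight; spare components start empty (zero weight,
    off-range mean) and are recruited when unexplained pixel values appear.
    """

    def __init__(self, params: MogParams | None = None):
        self.params = params or MogParams()
        self.w: np.ndarray | None = None
        self.mu: np.ndarray | None = None
        self.var: np.ndarray | None = None

    @property
    def initialized(self) -> bool:
        return self.w is not None

    def _initialize(self, frame: np.ndarray) -> None:
        h, wdt = frame.shape
        k = self.params.n_components
        self.w = np.zeros((h, wdt, k))
        self.mu = np.full((h, wdt, k), -1e4)
        self.var = np.full((h, wdt, k), self.params.init_var)
        self.w[:, :, 0] = 1.0
        self.mu[:, :, 0] = frame

    def weight_sums(self) -> np.ndarray:
        if not self.initialized:
            raise ValueError("model not initialised")
        return self.w.sum(axis=2)

    def dominant_mean(self) -> np.ndarray:
        """Per-pixel mean of the highest-weight component."""
        if not self.initialized:
            raise ValueError("model not initialised")
        idx = self.w.argmax(axis=2)[..., None]
        return np.take_along_axis(self.mu, idx, axis=2)[..., 0]


def segment_foreground(
    frame: np.ndarray, model: BackgroundModel
) -> tuple[np.ndarray, BackgroundModel]:
    """Classify one grayscale frame and update the model in place.

    Returns the boolean foreground mask and the (mutated) model.  The mask
    reflects the model state *before* this frame's update.  The first frame
    initialises the model and yields an all-background mask.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D grayscale image")
    if not model.initialized:
        model._initialize(frame)
        return np.zeros(frame.shape, dtype=bool), model
    if model.w.shape[:2] != frame.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match model {model.w.shape[:2]}"
        )
    mask = np.empty(frame.shape, dtype=np.uint8)
    p = model.params
    mog_update(
        frame,
        model.w,
        model.mu,
        model.var,
        p.alpha,
        p.T,
        p.lam,
        p.var_floor,
        p.new_weight,
        p.init_var,
        mask,
    )
    return mask.astype(bool), model


@dataclass(frozen=True)
class Blob:
    centroid: tuple[float, float]  # (x, y), unweighted pixel mean
    area: int


def detect_blobs(mask: np.ndarray, min_area: int = 3, max_area: int = 500) -> list[Blob]:
    """8-connected components of a binary mask, filtered by area."""
    if min_area <= 0 or max_area <= 0 or min_area >= max_area:
        raise ValueError("need 0 < min_area < max_area")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    lab, n = ndi.label(mask, structure=_STRUCT8)
    ys, xs = np.nonzero(mask)
    labs = lab[ys, xs]
    areas = np.bincount(labs, minlength=n + 1)
    sx = np.bincount(labs, weights=xs, minlength=n + 1)
    sy = np.bincount(labs, weights=ys, minlength=n + 1)
    blobs = []
    for i in range(1, n + 1):
        a = int(areas[i])
        if min_area <= a <= max_area:
            blobs.append(Blob(centroid=(sx[i] / a, sy[i] / a), area=a))
    return blobs


@dataclass
class DetectionSeries:
    """Per-analyzed-frame moving-mosquito counts and centroids.

    A standard 180-s assay analyzed at 0.1-s intervals has exactly 1800
    frames.  Burn-in frames are processed for model adaptation but reported
    with count 0 and flagged.
    """

    frame_index: np.ndarray
    time_s: np.ndarray
    counts: np.ndarray
    centroids: list[np.ndarray]  # per frame, (m, 2) arrays of (x, y)
    areas: list[np.ndarray] = field(default_factory=list)
    burnin: np.ndarray | None = None
    analysis_interval: float = 0.1

    def __post_init__(self) -> None:
        if self.burnin is None:
            self.burnin = np.zeros(len(self.counts), dtype=bool)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def total_count(self) -> int:
        """Total movements over non-burn-in frames."""
        return int(self.counts[~self.burnin].sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": self.frame_index,
                "time_s": self.time_s,
                "count": self.counts,
                "burnin": self.burnin.astype(int),
                "centroids": [
                    json.dumps(np.round(c, 3).tolist()) for c in self.centroids
                ],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "DetectionSeries":
        df = pd.read_csv(path)
        cents = [
            np.array(json.loads(s), dtype=float).reshape(-1, 2)
            for s in df["centroids"]
        ]
        times = df["time_s"].to_numpy(dtype=float)
        interval = float(times[1] - times[0]) if len(times) > 1 else 0.1
        return cls(
            frame_index=df["frame_index"].to_numpy(),
            time_s=times,
            counts=df["count"].to_numpy(),
            centroids=cents,
            burnin=df["burnin"].to_numpy(dtype=bool),
            analysis_interval=interval,
        )


def analyze_recording(
    frames: np.ndarray,
    fps: float = 10.0,
    mog_params: MogParams | None = None,
    min_area: int = 6,
    max_area: int = 500,
    analysis_interval: float = 0.1,
    burnin_s: float = 1.0,
    polarity: str = "bright",
) -> DetectionSeries:
    """Run the full detection stage over a recording.

    ``frames`` are samples at t = k / fps, spanning [0, (len-1)/fps]; the
    stream is subsampled to the analysis interval *before* segmentation, so
    the background model only ever sees analyzed frames.  A 180-s recording
    (1801 samples at 10 fps) yields exactly 1800 analyzed frames at
    t = 0.0 … 179.9.  Frames with t < ``burnin_s`` adapt the model but are
    reported with count 0 and flagged.

    ``polarity`` restricts foreground to one contrast phase against the
    dominant background mean: ``"bright"`` (light mosquitoes on a dark
    scene, the rendering convention here), ``"dark"``, or ``"both"``.  A
    single-phase filter suppresses revealed-background ghosts at positions
    a resting mosquito has just vacated.
    """
    if polarity not in ("bright", "dark", "both"):
        raise ValueError("polarity must be 'bright', 'dark' or 'both'")
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a (T, H, W) stack")
    if fps is None or fps <= 0:
        raise ValueError("fps must be supplied and positive")
    stride_f = fps * analysis_interval
    stride = int(round(stride_f))
    if stride < 1 or abs(stride_f - stride) > 1e-9:
        raise ValueError(
            f"fps * analysis_interval = {stride_f} is not an integer stride"
        )
    n_analyzed = (len(frames) - 1) // stride
    if n_analyzed < 1:
        raise ValueError("recording too short for one analysis interval")

    model = BackgroundModel(mog_params)
    counts = np.zeros(n_analyzed, dtype=int)
    cents: list[np.ndarray] = []
    areas: list[np.ndarray] = []
    burnin = np.zeros(n_analyzed, dtype=bool)
    times = np.arange(n_analyzed) * analysis_interval

    for k in range(n_analyzed):
        frame = frames[k * stride]
        mask, model = segment_foreground(frame, model)
        if polarity != "both" and mask.any():
            # dominant background mean evaluated only at masked pixels
            ys, xs = np.nonzero(mask)
            comp = model.w[ys, xs].argmax(axis=1)
            dom = model.mu[ys, xs, comp]
            vals = frame[ys, xs]
            keep = vals > dom if polarity == "bright" else vals < dom
            mask[ys[~keep], xs[~keep]] = False
        if times[k] < burnin_s:
            burnin[k] = True
            cents.append(np.empty((0, 2)))
            areas.append(np.empty(0, dtype=int))
            continue
        blobs = detect_blobs(mask, min_area=min_area, max_area=max_area)
        counts[k] = len(blobs)
        cents.append(np.array([b.centroid for b in blobs], dtype=float).reshape(-1, 2))
        areas.append(np.array([b.area for b in blobs], dtype=int))

    return DetectionSeries(
        frame_index=np.arange(n_analyzed),
        time_s=times,
        counts=counts,
        centroids=cents,
        areas=areas,
        burnin=burnin,
        analysis_interval=analysis_interval,
    )
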