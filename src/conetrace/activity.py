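"""Behavioural activity quantities derived from detection series.

Converts per-frame movement detections into the assay-level summaries used
for comparison between net types and strains: total activity (number of
detected movements over the assay), assignment of each detection to the
upper or lower half region of the cone, 5-s binned activity time series,
and cross-replicate mean profiles with confidence intervals.

Coordinate convention (declared once, used everywhere): image coordinates,
``y`` grows downward, so the *top* of the cone is the smaller ``y``.  A
centroid exactly on the midline counts as *bottom* (net-proximal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ConeGeometry
from .vision import DetectionSeries

__all__ = [
    "ActivityProfile",
    "assign_region",
    "aggregate_bins",
    "mean_profile",
    "summary_table",
]


@dataclass(frozen=True)
class ActivityProfile:
    """5-s binned activity of one assay, split by cone region.

    ``bins`` is a DataFrame with columns (bin_start_s, count_top,
    count_bottom); ``total_activity`` counts every detection on non-burn-in
    frames, and ``burnin_excluded`` the detections discarded during model
    burn-in (zero by construction since burn-in frames report count 0).
    """

    assay_id: str
    total_activity: int
    bins: pd.DataFrame
    strain: str = ""
    net: str = ""
    burnin_excluded: int = 0

    @property
    def bin_width(self) -> float:
        starts = self.bins["bin_start_s"].to_numpy()
        return float(starts[1] - starts[0]) if len(starts) > 1 else np.nan

    def to_csv(self, path) -> None:
        df = self.bins.copy()
        df.insert(0, "assay_id", self.assay_id)
        df["strain"] = self.strain
        df["net"] = self.net
        df["total_activity"] = self.total_activity
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ActivityProfile":
        df = pd.read_csv(path, keep_default_na=False)
        return cls(
            assay_id=str(df["assay_id"].iloc[0]),
            total_activity=int(df["total_activity"].iloc[0]),
            bins=df[["bin_start_s", "count_top", "count_bottom"]].reset_index(drop=True),
            strain=str(df["strain"].iloc[0]),
            net=str(df["net"].iloc[0]),
        )


def assign_region(centroid, geometry: ConeGeometry) -> str:
    """Assign a detection centroid to the top or bottom half of the cone.

    Top iff the centroid lies strictly above the midline (smaller ``y``);
    the midline itself belongs to the bottom (net-proximal) region.
    """
    x, y = float(centroid[0]), float(centroid[1])
    if not (0 <= x <= geometry.frame_width and 0 <= y <= geometry.frame_height):
        raise ValueError(f"centroid {centroid} outside frame")
    return "top" if y < geometry.midline_y else "bottom"


def aggregate_bins(
    series: DetectionSeries,
    geometry: ConeGeometry,
    bin_width: float = 5.0,
    assay_id: str = "assay",
    strain: str = "",
    net: str = "",
    expected_duration: float = 180.0,
) -> ActivityProfile:
    """Aggregate a detection series into half-open [t, t+bin_width) bins.

    Requires a complete series covering the full assay at the analysis
    interval (1800 frames for the standard 180-s assay).
    """
    n_expected = int(round(expected_duration / series.analysis_interval))
    if len(series) != n_expected:
        raise ValueError(
            f"incomplete series: {len(series)} frames, expected {n_expected} "
            f"({expected_duration} s at {series.analysis_interval} s intervals)"
        )
    n_bins = int(round(expected_duration / bin_width))
    top = np.zeros(n_bins, dtype=int)
    bottom = np.zeros(n_bins, dtype=int)
    total = 0
    for t, cents, is_burn in zip(series.time_s, series.centroids, series.burnin):
        if is_burn:
            continue
        b = int(t // bin_width)
        for c in cents:
            if assign_region(c, geometry) == "top":
                top[b] += 1
            else:
                bottom[b] += 1
            total += 1
    bins = pd.DataFrame(
        {
            "bin_start_s": np.arange(n_bins) * bin_width,
            "count_top": top,
            "count_bottom": bottom,
        }
    )
    return ActivityProfile(
        assay_id=assay_id,
        total_activity=total,
        bins=bins,
        strain=strain,
        net=net,
    )


def summary_table(profiles: list[ActivityProfile]) -> pd.DataFrame:
    """One row per cone test: the layout the statistics stage consumes.

    Columns (assay_id, strain, net, total_activity) — the per-assay totals
    that feed group comparisons and the factorial model.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    return pd.DataFrame(
        {
            "assay_id": [p.assay_id for p in profiles],
            "strain": [p.strain for p in profiles],
            "net": [p.net for p in profiles],
            "total_activity": [p.total_activity for p in profiles],
        }
    )


def mean_profile(profiles: list[ActivityProfile], level: float = 0.95) -> pd.DataFrame:
    """Per-bin mean and t-based CI of activity across replicate assays.

    Returns one row per bin with mean and CI for each region (the quantity
    plotted as a mean activity-over-time profile).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 replicate profiles")
    ref = profiles[0].bins["bin_start_s"].to_numpy()
    for p in profiles[1:]:
        if not np.array_equal(p.bins["bin_start_s"].to_numpy(), ref):
            raise ValueError("heterogeneous binning across profiles")
    n = len(profiles)
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    out = {"bin_start_s": ref}
    for region in ("top", "bottom"):
        mat = np.stack([p.bins[f"count_{region}"].to_numpy() for p in profiles])
        m = mat.mean(axis=0)
        se = mat.std(axis=0, ddof=1) / np.sqrt(n)
        out[f"mean_{region}"] = m
        out[f"ci_lo_{region}"] = m - tcrit * se
        out[f"ci_hi_{region}"] = m + tcrit * se
    return pd.DataFrame(out)
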