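"""Scan-sampling behavioural-state analysis.

Scan sampling records the instantaneous behavioural state of every
mosquito — contacting the net (N), flying (F), resting on the cone (C) or
knocked down (K) — at fixed 5-s intervals.  A 3-min assay scanned at 5-s
intervals yields 37 time points (t = 0 through t = 180 inclusive).  In the
field this coding is done manually from paused video; here it can also be
read exactly off a simulator truth log, which makes the simulator the
oracle for the summary statistics.

Manual annotations are imported from a tidy CSV with columns
(assay_id, time_point_s, state, count); see :func:`read_scans_csv` for the
expected layout when converting exports from ethology-coding software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import STATE_LETTERS, TruthLog

STATES = ("N", "F", "C", "K")

__all__ = [
    "ScanRecord",
    "scan_sample",
    "summarize_states",
    "scans_to_dataframe",
    "read_scans_csv",
    "write_scans_csv",
]


@dataclass(frozen=True)
class ScanRecord:
    """State counts of the cohort at one scan instant."""

    time_point_s: float
    n_N: int
    n_F: int
    n_C: int
    n_K: int

    @property
    def cohort_size(self) -> int:
        return self.n_N + self.n_F + self.n_C + self.n_K

    def count(self, state: str) -> int:
        return getattr(self, f"n_{state}")


def scan_sample(truth: TruthLog, interval: float = 5.0) -> list[ScanRecord]:
    """Scan-sample a truth log at fixed intervals (t = 0 included).

    For the standard 180-s assay at 5-s intervals this yields 37 records.
    The truth grid must contain every scan instant exactly.
    """
    step_f = interval / truth.dt
    step = int(round(step_f))
    if step < 1 or abs(step_f - step) > 1e-9:
        raise ValueError(
            f"truth grid (dt={truth.dt}) does not contain {interval}-s scan instants"
        )
    n_points = (truth.n_frames - 1) // step + 1
    records = []
    for k in range(n_points):
        frame = k * step
        st = truth.states[frame]
        counts = {s: int((STATE_LETTERS[st] == s).sum()) for s in STATES}
        records.append(
            ScanRecord(
                time_point_s=k * interval,
                n_N=counts["N"],
                n_F=counts["F"],
                n_C=counts["C"],
                n_K=counts["K"],
            )
        )
    return records


def summarize_states(
    replicates: list[list[ScanRecord]], level: float = 0.95
) -> pd.DataFrame:
    """Mean state counts and t-based CIs across replicate assays.

    Returns a tidy frame (time_point_s, state, mean, ci_lo, ci_hi); at every
    time point the four state means sum to the cohort size.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    times = [r.time_point_s for r in replicates[0]]
    for rep in replicates[1:]:
        if [r.time_point_s for r in rep] != times:
            raise ValueError("misaligned scan time grids across replicates")
    n = len(replicates)
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    rows = []
    for i, t in enumerate(times):
        for s in STATES:
            vals = np.array([rep[i].count(s) for rep in replicates], dtype=float)
            m = vals.mean()
            se = vals.std(ddof=1) / np.sqrt(n)
            rows.append(
                {
                    "time_point_s": t,
                    "state": s,
                    "mean": m,
                    "ci_lo": m - tcrit * se,
                    "ci_hi": m + tcrit * se,
                }
            )
    return pd.DataFrame(rows)


def scans_to_dataframe(scans: list[ScanRecord], assay_id: str = "assay") -> pd.DataFrame:
    rows = []
    for r in scans:
        for s in STATES:
            rows.append(
                {
                    "assay_id": assay_id,
                    "time_point_s": r.time_point_s,
                    "state": s,
                    "count": r.count(s),
                }
            )
    return pd.DataFrame(rows)


def write_scans_csv(scans: list[ScanRecord], path, assay_id: str = "assay") -> None:
    scans_to_dataframe(scans, assay_id).to_csv(path, index=False)


def read_scans_csv(path) -> dict[str, list[ScanRecord]]:
    """Read tidy scan tables: columns (assay_id, time_point_s, state, count).

    Converter stub for external ethology-software exports: reshape the
    export so each row carries one (assay, time point, state) count; states
    must be the letters N/F/C/K.  Returns records grouped per assay.
    """
    df = pd.read_csv(path)
    required = {"assay_id", "time_point_s", "state", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"scan CSV must have columns {sorted(required)}")
    out: dict[str, list[ScanRecord]] = {}
    for assay_id, grp in df.groupby("assay_id", sort=False):
        wide = grp.pivot_table(
            index="time_point_s", columns="state", values="count", aggfunc="sum"
        ).fillna(0)
        records = []
        for t, row in wide.sort_index().iterrows():
            records.append(
                ScanRecord(
                    time_point_s=float(t),
                    **{f"n_{s}": int(row.get(s, 0)) for s in STATES},
                )
            )
        out[str(assay_id)] = records
    return out
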