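"""Chemical-QC computations for insecticide-treated nets.

Two strands:

* **HPLC quantification** of deltamethrin over up to four sequential
  extraction rounds: per-round content ``I = (x/a) × (0.001/m) × C × f`` in
  g/kg, round totals with a first-round-fraction QC flag, conversion to
  areal dose (mg/m²) and relative-SD variability.

  Unit convention: ``x/a`` yields the concentration (µg/ml) of the final
  1-ml acetonitrile resuspension, so ``x/a`` is micrograms of analyte; the
  0.001 factor converts µg to mg against the net mass ``m`` in grams,
  giving mg/g = g/kg.  ``C`` is the dimensionless internal-standard
  correction (accepted as input) and ``f`` the dilution factor.

* **Raman preprocessing** of spectra: Savitzky–Golay smoothing (window 5,
  first order), asymmetric-least-squares baseline subtraction and L2
  (vector) normalisation, plus a crystallinity heuristic that scores the
  1000 cm⁻¹ marker band (with 942/479 cm⁻¹ secondary bands) against local
  noise to separate crystalline-like from amorphous-like particulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

__all__ = [
    "ExtractionRound",
    "SpectrumTrace",
    "ContentTotal",
    "MarkerCall",
    "content_per_round",
    "total_content",
    "convert_to_areal",
    "rsd",
    "als_baseline",
    "preprocess_spectrum",
    "crystalline_marker",
]


# ---------------------------------------------------------------------------
# HPLC


@dataclass(frozen=True)
class ExtractionRound:
    """One HPLC extraction round of a net sample."""

    round_index: int  # 1..4
    x: float  # sample peak area (detector units)
    a: float  # calibration slope (area per concentration unit)
    C: float = 1.0  # internal-standard correction factor
    f: float = 1.0  # dilution factor
    m: float = 0.15  # net sample mass, g

    def __post_init__(self) -> None:
        if not 1 <= self.round_index <= 4:
            raise ValueError("round_index must be in 1..4")
        if self.a <= 0:
            raise ValueError("calibration slope a must be > 0")
        if self.m <= 0:
            raise ValueError("sample mass m must be > 0")
        if self.f < 1:
            raise ValueError("dilution factor f must be >= 1")


def content_per_round(r: ExtractionRound) -> float:
    """Insecticide content of one extraction round, g/kg."""
    return (r.x / r.a) * (0.001 / r.m) * r.C * r.f


@dataclass(frozen=True)
class ContentTotal:
    total_g_per_kg: float
    per_round_g_per_kg: tuple[float, ...]
    first_round_fraction: float
    incomplete_first_extraction: bool  # flag: first round yielded < 97%


def total_content(rounds: list[ExtractionRound], qc_fraction: float = 0.97) -> ContentTotal:
    """Combine 1–4 extraction rounds into a total content with a QC flag.

    An efficient extraction recovers more than ``qc_fraction`` of the
    analyte in the first round; anything less raises the flag.
    """
    if not 1 <= len(rounds) <= 4:
        raise ValueError("expected 1 to 4 extraction rounds")
    ordered = sorted(rounds, key=lambda r: r.round_index)
    per = tuple(content_per_round(r) for r in ordered)
    total = float(sum(per))
    frac = per[0] / total if total > 0 else 1.0
    return ContentTotal(
        total_g_per_kg=total,
        per_round_g_per_kg=per,
        first_round_fraction=frac,
        incomplete_first_extraction=frac < qc_fraction,
    )


def convert_to_areal(i_g_per_kg: float, sample_mass_g: float, sample_area_cm2: float) -> float:
    """Convert mass content (g/kg) to areal dose (mg/m²).

    g/kg = mg/g, so dose = I × (mass / area) × 10⁴ cm²/m².
    """
    if sample_mass_g <= 0 or sample_area_cm2 <= 0:
        raise ValueError("mass and area must be positive")
    return i_g_per_kg * sample_mass_g / sample_area_cm2 * 1.0e4


def rsd(values) -> float:
    """Percent relative standard deviation, 100 × sample SD / mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    m = v.mean()
    if m <= 0:
        raise ValueError("RSD requires a positive mean")
    return 100.0 * v.std(ddof=1) / m


# ---------------------------------------------------------------------------
# Raman


@dataclass(frozen=True)
class SpectrumTrace:
    """A Raman spectrum with processing-state flags."""

    wavenumber: np.ndarray  # cm^-1, strictly monotone
    intensity: np.ndarray
    smoothed: bool = False
    baseline_corrected: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumber, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if wn.shape != it.shape or wn.ndim != 1:
            raise ValueError("wavenumber and intensity must be equal-length 1-D")
        d = np.diff(wn)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber axis must be strictly monotone")
        object.__setattr__(self, "wavenumber", wn)
        object.__setattr__(self, "intensity", it)

    @classmethod
    def read_text(cls, path) -> "SpectrumTrace":
        """Two-column whitespace/comma text: wavenumber, intensity."""
        arr = np.loadtxt(path, delimiter=None, ndmin=2)
        if arr.shape[1] == 1:
            arr = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(wavenumber=arr[:, 0], intensity=arr[:, 1])

    def write_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.wavenumber, self.intensity]), fmt="%.6f")


def als_baseline(
    y: np.ndarray, lam: float = 1.0e5, p: float = 0.01, niter: int = 10
) -> np.ndarray:
    """Asymmetric-least-squares baseline (penalized least squares).

    Minimises ``Σ w_i (y_i − z_i)² + λ Σ (Δ²z)²`` where points above the
    running baseline get asymmetry weight ``p`` and points below ``1 − p``,
    re-weighting for a fixed number of iterations.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("spectrum too short for baseline estimation")
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n)).tocsc()
    penalty = lam * (d2.T @ d2)
    w = np.ones(n)
    z = y.copy()
    for _ in range(niter):
        W = sparse.diags(w)
        z = spsolve((W + penalty).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def preprocess_spectrum(
    s: SpectrumTrace,
    sg_window: int = 5,
    sg_order: int = 1,
    als_lambda: float = 1.0e5,
    als_p: float = 0.01,
    als_iters: int = 10,
    baseline: bool = True,
) -> SpectrumTrace:
    """Standard chain: SG smoothing → ALS baseline subtraction → L2 norm.

    ``baseline=False`` skips the baseline step (smooth + normalise only),
    e.g. for spectra already baseline-corrected upstream.
    """
    if sg_window % 2 == 0:
        raise ValueError("sg_window must be odd")
    if sg_order >= sg_window:
        raise ValueError("sg_order must be < sg_window")
    if len(s.intensity) < sg_window:
        raise ValueError("spectrum shorter than the smoothing window")
    y = savgol_filter(s.intensity, window_length=sg_window, polyorder=sg_order)
    if baseline:
        y = y - als_baseline(y, lam=als_lambda, p=als_p, niter=als_iters)
    norm = np.linalg.norm(y)
    if norm == 0:
        raise ValueError("zero spectrum cannot be normalized")
    y = y / norm
    return replace(
        s, intensity=y, smoothed=True, baseline_corrected=baseline, normalized=True
    )


@dataclass(frozen=True)
class MarkerCall:
    classification: str  # "crystalline-like" | "amorphous-like"
    score: float  # marker prominence / local noise
    secondary_scores: dict[str, float]


def _band_score(wn: np.ndarray, y: np.ndarray, center: float, window: float) -> float:
    """Peak prominence inside ``center ± window`` over flanking noise.

    A straight line fitted through the two flanking regions
    (``center ± (window, 4·window)``) serves as the local baseline; the
    score is the maximum in-band residual over the robust (MAD-based) SD
    of the flank residuals.
    """
    in_band = (wn >= center - window) & (wn <= center + window)
    flank = ((wn >= center - 4 * window) & (wn < center - window)) | (
        (wn > center + window) & (wn <= center + 4 * window)
    )
    if not in_band.any() or flank.sum() < 4:
        raise ValueError(f"spectrum does not cover the {center} cm^-1 band")
    coef = np.polynomial.polynomial.polyfit(wn[flank] - center, y[flank], 1)
    fit_flank = np.polynomial.polynomial.polyval(wn[flank] - center, coef)
    fit_band = np.polynomial.polynomial.polyval(wn[in_band] - center, coef)
    prominence = float((y[in_band] - fit_band).max())
    mad = np.median(np.abs(y[flank] - fit_flank))
    noise = 1.4826 * float(mad)
    if noise <= 0:
        return 0.0 if prominence <= 0 else math.inf
    return max(prominence, 0.0) / noise


def crystalline_marker(
    s: SpectrumTrace,
    marker: float = 1000.0,
    secondary: tuple[float, ...] = (942.0, 479.0),
    window: float = 5.0,
    snr_threshold: float = 5.0,
) -> MarkerCall:
    """Score the crystalline-deltamethrin marker band of a spectrum.

    Classifies as crystalline-like iff the prominence of the marker band
    (default 1000 cm⁻¹) exceeds ``snr_threshold`` times the local noise;
    secondary bands are scored but do not drive the call (they flag the
    particulate signature seen alongside amorphous-like spectra).
    """
    wn, y = s.wavenumber, s.intensity
    score = _band_score(wn, y, marker, window)
    sec = {f"{int(c)}": _band_score(wn, y, c, window) for c in secondary}
    cls = "crystalline-like" if score >= snr_threshold else "amorphous-like"
    return MarkerCall(classification=cls, score=score, secondary_scores=sec)
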