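"""Perfusion-CT kinetic analysis.

Given a dynamic contrast-enhanced CT series, a tumor VOI and an aortic
candidate region, this module estimates the three perfusion outputs:

* **BF** (blood flow, mL/100 mL/min) by the maximum slope method:
  the peak rate of tissue enhancement divided by the peak arterial
  enhancement,

      BF = max_t dC_t/dt / max_t C_a(t) * 6000,

  valid while contrast is still in first pass (no venous outflow);

* **BV** (blood volume, mL/100 mL) and **PS** (permeability-surface
  product, mL/100 mL/min) by Patlak graphical analysis: ordinary least
  squares of y = C_t/C_a on x = (int_0^t C_a)/C_a over a late window in
  which the arterial input has equilibrated; PS = slope * 6000 and
  BV = intercept * 100.

Analysis is curve-first: the VOI-mean enhancement curve is computed
once and both estimators run on it (whole-tumor averages).  A
voxel-wise map mode is available through :func:`parameter_maps`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DynamicSeries, KineticParams, TimeCurve, ValidationError

__all__ = [
    "SegmentationSettings",
    "PatlakResult",
    "VoiKinetics",
    "baseline_correct",
    "extract_aif",
    "segment_voi",
    "max_slope_bf",
    "patlak_fit",
    "voi_summary",
    "parameter_maps",
]

#: Patlak window start (s) used by the VOI pipeline: well into the
#: final, 6-second-interval phase of the acquisition, where the
#: arterial plateau and the long vascular transit of these
#: hypervascular tumors have both equilibrated.
DEFAULT_PATLAK_WINDOW_START = 78.0


@dataclass(frozen=True)
class SegmentationSettings:
    """HU windows used for VOI refinement and arterial voxel selection.

    Tissue voxels are kept when their baseline HU lies within the
    closed interval [lower, upper]; arterial candidates are kept when
    their peak raw HU lies within the window given by center +- width/2.
    ``relative_threshold_inside``/``outside`` are vendor segmentation
    percentages retained for interface parity; they are inert here.
    """

    tissue_hu_lower: float = -50.0
    tissue_hu_upper: float = 150.0
    vessel_window_width: float = 300.0
    vessel_window_center: float = 150.0
    relative_threshold_inside: float = 50.0
    relative_threshold_outside: float = 50.0

    def __post_init__(self) -> None:
        if self.tissue_hu_lower >= self.tissue_hu_upper:
            raise ValidationError("tissue_hu_lower must be < tissue_hu_upper")
        if self.vessel_window_width <= 0:
            raise ValidationError("vessel window width must be positive")

    @property
    def vessel_window(self) -> tuple[float, float]:
        half = self.vessel_window_width / 2.0
        return (
            self.vessel_window_center - half,
            self.vessel_window_center + half,
        )


def baseline_correct(curve: TimeCurve, n_baseline_frames: int) -> TimeCurve:
    """Subtract the mean of the first ``n_baseline_frames`` samples,
    converting a raw HU curve into an enhancement curve."""
    n = int(n_baseline_frames)
    if n < 1:
        raise ValidationError("n_baseline_frames must be >= 1")
    if n >= len(curve):
        raise ValidationError("n_baseline_frames must be smaller than the curve")
    baseline = float(curve.values[:n].mean())
    return TimeCurve(curve.times, curve.values - baseline, kind="enhancement")


def extract_aif(
    series: DynamicSeries,
    candidate_mask: np.ndarray,
    settings: SegmentationSettings = SegmentationSettings(),
    n_baseline_frames: int = 3,
) -> TimeCurve:
    """Arterial input function from an aortic candidate region.

    Candidate voxels whose peak raw HU falls inside the vessel window
    are retained; the AIF is their per-frame mean, baseline-corrected.
    """
    mask = np.asarray(candidate_mask, dtype=bool)
    if not mask.any():
        raise ValidationError("candidate mask is empty")
    courses = series.data[:, mask]  # (t, n)
    lo, hi = settings.vessel_window
    peaks = courses.max(axis=0)
    keep = (peaks >= lo) & (peaks <= hi)
    if not keep.any():
        raise ValidationError(
            f"no valid AIF: no candidate voxel peaks inside [{lo}, {hi}] HU"
        )
    raw = TimeCurve(series.frame_times, courses[:, keep].mean(axis=1), kind="raw")
    return baseline_correct(raw, n_baseline_frames)


def segment_voi(
    baseline_volume: np.ndarray,
    drawn_mask: np.ndarray,
    settings: SegmentationSettings = SegmentationSettings(),
) -> np.ndarray:
    """Refine a hand-drawn tumor mask by the tissue HU limits (closed
    interval on the pre-contrast baseline volume)."""
    drawn = np.asarray(drawn_mask, dtype=bool)
    if not drawn.any():
        raise ValidationError("drawn mask is empty")
    vol = np.asarray(baseline_volume, dtype=float)
    refined = drawn & (vol >= settings.tissue_hu_lower) & (vol <= settings.tissue_hu_upper)
    if not refined.any():
        raise ValidationError(
            "empty VOI: no drawn voxel lies within the tissue HU limits"
        )
    return refined


def _sliding_slopes(times: np.ndarray, values: np.ndarray, window: int) -> np.ndarray:
    """Least-squares slope of each run of ``window`` consecutive samples
    (handles non-uniform sampling)."""
    n = times.size
    if window < 2:
        raise ValidationError("slope window must span at least 2 frames")
    if n < window:
        raise ValidationError("curve shorter than the slope window")
    slopes = np.empty(n - window + 1)
    for i in range(slopes.size):
        t = times[i : i + window]
        v = values[i : i + window]
        tc = t - t.mean()
        slopes[i] = np.dot(tc, v - v.mean()) / np.dot(tc, tc)
    return slopes


def max_slope_bf(
    tissue: TimeCurve, aif: TimeCurve, slope_window: int = 3
) -> float:
    """Blood flow (mL/100 mL/min) by the maximum slope method.

    The tissue slope (HU/s) is the maximum of sliding ``slope_window``-
    frame regression slopes; dividing by the arterial peak (HU) gives a
    fractional flow per second, converted to per 100 mL per minute.
    """
    if not np.array_equal(tissue.times, aif.times):
        aif = aif.sample_at(tissue.times)
    peak = aif.peak
    if peak <= 0:
        raise ValidationError("AIF peak must be positive")
    max_slope = float(_sliding_slopes(tissue.times, tissue.values, slope_window).max())
    return max(max_slope, 0.0) / peak * 6000.0


@dataclass(frozen=True)
class PatlakResult:
    """Patlak fit output: estimates, diagnostics and clamp flags."""

    bv: float
    ps: float
    r_squared: float
    n_points: int
    slope: float
    intercept: float
    clamped: bool


def patlak_fit(
    tissue: TimeCurve,
    aif: TimeCurve,
    window_start: float | str = "peak",
    min_points: int = 4,
) -> PatlakResult:
    """Patlak graphical analysis of a tissue curve against the AIF.

    Frames at ``t >= window_start`` (``"peak"``: the AIF peak time)
    enter an ordinary least squares fit of ``y = C_t/C_a`` on
    ``x = int_0^t C_a / C_a`` with the arterial integral taken by
    trapezoid on the frame grid.  Negative estimates are clamped to
    zero and flagged.
    """
    if not np.array_equal(tissue.times, aif.times):
        aif = aif.sample_at(tissue.times)
    t = tissue.times
    start = aif.peak_time if window_start == "peak" else float(window_start)
    window = t >= start
    ca = aif.values
    if np.any(ca[window] <= 0):
        raise ValidationError("AIF must be positive throughout the Patlak window")
    if int(window.sum()) < min_points:
        raise ValidationError(
            f"Patlak window holds {int(window.sum())} frames; need >= {min_points}"
        )
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (ca[1:] + ca[:-1]) * np.diff(t))]
    )
    x = integral[window] / ca[window]
    y = tissue.values[window] / ca[window]
    fit = stats.linregress(x, y)
    ps = fit.slope * 6000.0
    bv = fit.intercept * 100.0
    clamped = bool(ps < 0 or bv < 0)
    return PatlakResult(
        bv=max(bv, 0.0),
        ps=max(ps, 0.0),
        r_squared=float(fit.rvalue**2),
        n_points=int(window.sum()),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        clamped=clamped,
    )


@dataclass(frozen=True)
class VoiKinetics:
    """Whole-VOI perfusion estimates plus the Patlak diagnostics."""

    params: KineticParams
    patlak: PatlakResult


def voi_summary(
    series: DynamicSeries,
    refined_mask: np.ndarray,
    aif: TimeCurve,
    n_baseline_frames: int = 3,
    slope_window: int = 3,
    patlak_window_start: float | str = DEFAULT_PATLAK_WINDOW_START,
) -> VoiKinetics:
    """Curve-first whole-tumor kinetics: average the VOI enhancement
    curve, then run both estimators on it."""
    tissue = baseline_correct(series.voi_curve(refined_mask), n_baseline_frames)
    bf = max_slope_bf(tissue, aif, slope_window)
    pat = patlak_fit(tissue, aif, window_start=patlak_window_start)
    params = KineticParams(bf=bf, bv=pat.bv, ps=pat.ps)
    return VoiKinetics(params=params, patlak=pat)


def parameter_maps(
    series: DynamicSeries,
    mask: np.ndarray,
    aif: TimeCurve,
    n_baseline_frames: int = 3,
    slope_window: int = 3,
    patlak_window_start: float | str = DEFAULT_PATLAK_WINDOW_START,
):
    """Voxel-wise BF/BV/PS maps over the mask (non-default mode; the
    VOI pipeline averages the curve first).  Returns a dict of 3D
    arrays, NaN outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    out = {k: np.full(mask.shape, np.nan) for k in ("bf", "bv", "ps")}
    for idx in np.argwhere(mask):
        raw = TimeCurve(
            series.frame_times, series.data[:, idx[0], idx[1], idx[2]], kind="raw"
        )
        tissue = baseline_correct(raw, n_baseline_frames)
        out["bf"][tuple(idx)] = max_slope_bf(tissue, aif, slope_window)
        pat = patlak_fit(tissue, aif, window_start=patlak_window_start)
        out["bv"][tuple(idx)] = pat.bv
        out["ps"][tuple(idx)] = pat.ps
    return out
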