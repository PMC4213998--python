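"""Synthetic phantoms with known ground truth.

Every downstream stage (perfusion kinetics, SUV metrics, texture,
microvessel counting, cohort statistics) is validated by parameter
recovery on data produced here.  The generator emulates a two-arm
longitudinal animal study: per-tumor dynamic contrast-enhanced CT
series on a 40-frame, 120-second schedule, static PET SUV volumes with
controllable heterogeneity, and CD31-stained histology sections with
planted vessel counts.

The forward tissue model is chosen so that both perfusion estimators
are exact in their validity regimes:

    C_t(t) = f * int_{t-MTT}^{t} C_a  +  k * int_0^t C_a

with ``f = BF/6000`` and ``k = PS/6000`` (per-second fractional rates).
The first term is intravascular transit with a boxcar residue (plateau
``BV/100 * C_a`` once the arterial input has equilibrated), the second
is unidirectional leakage with no backflux.  Hence the Patlak plot of
the late, equilibrated window is exactly linear with slope ``PS/6000``
and intercept ``BV/100``, and for ``PS = 0`` the maximum early slope is
exactly ``f * max(C_a)``.

The arterial input is a normalized gamma-variate bolus (peak = A) plus
an optional recirculation/equilibrium component that rises smoothly to
a steady-state plateau of ``recirculation_fraction * A`` — the regime
the Patlak intercept identity requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core import DynamicSeries, KineticParams, TimeCurve, ValidationError

__all__ = [
    "ScanSchedule",
    "InjectionProtocol",
    "AIFParams",
    "PhantomSpec",
    "PetPhantomSpec",
    "HistologySectionSpec",
    "CohortScan",
    "make_scan_schedule",
    "default_scan_schedule",
    "default_injection_protocol",
    "simulate_aif",
    "simulate_tissue_curve",
    "simulate_dynamic_series",
    "simulate_pet_volume",
    "draw_cohort_truth",
    "simulate_histology_section",
    "reference_param_table",
    "simulate_cohort",
    "ellipsoid_mask",
]


# --------------------------------------------------------------------
# acquisition protocol
# --------------------------------------------------------------------

@dataclass(frozen=True)
class ScanSchedule:
    """Dynamic-CT frame schedule built from (frame_count, interval) phases.

    The first frame is acquired AT ``start_offset`` (the delay between
    contrast injection and the first scan); within a phase consecutive
    frames are separated by that phase's interval.  ``total_duration``
    is defined as ``sum(count * interval)`` over phases, which is the
    conventional way such protocols are quoted.
    """

    frame_times: np.ndarray
    start_offset: float
    phases: tuple[tuple[int, float], ...]

    @property
    def n_frames(self) -> int:
        return self.frame_times.size

    @property
    def total_duration(self) -> float:
        return float(sum(count * interval for count, interval in self.phases))


def make_scan_schedule(
    phases: Sequence[tuple[int, float]], start_offset: float = 0.0
) -> ScanSchedule:
    """Build a frame schedule from acquisition phases.

    Parameters
    ----------
    phases
        Sequence of ``(frame_count, interval_s)`` pairs.
    start_offset
        Time of the first frame (s), i.e. scan delay after injection.
    """
    if start_offset < 0:
        raise ValidationError("start_offset must be nonnegative")
    norm: list[tuple[int, float]] = []
    for count, interval in phases:
        count = int(count)
        interval = float(interval)
        if count < 1:
            raise ValidationError("phase frame count must be >= 1")
        if interval <= 0:
            raise ValidationError("phase interval must be positive")
        norm.append((count, interval))
    if not norm:
        raise ValidationError("at least one phase is required")
    times = [float(start_offset)]
    for count, interval in norm:
        start = len(times) - 1
        # the first frame of the first phase is already placed
        needed = count if start > 0 else count - 1
        for _ in range(needed):
            times.append(times[-1] + interval)
    return ScanSchedule(np.asarray(times), float(start_offset), tuple(norm))


def default_scan_schedule() -> ScanSchedule:
    """The study protocol: 40 frames — 20 at 1.5 s, 10 at 3 s, 10 at
    6 s — starting 2 s after injection (total duration 120 s)."""
    return make_scan_schedule([(20, 1.5), (10, 3.0), (10, 6.0)], start_offset=2.0)


@dataclass(frozen=True)
class InjectionProtocol:
    """Contrast injection phases plus a saline flush (volumes mL, rates mL/s)."""

    contrast_phases: tuple[tuple[float, float], ...]
    flush: tuple[float, float]

    def __post_init__(self) -> None:
        for volume, rate in (*self.contrast_phases, self.flush):
            if volume <= 0 or rate <= 0:
                raise ValidationError("injection volumes and rates must be positive")

    @property
    def total_contrast_volume(self) -> float:
        """Total contrast medium (mL); the flush is excluded."""
        return float(sum(v for v, _ in self.contrast_phases))


def default_injection_protocol() -> InjectionProtocol:
    """Dual-phase protocol: 3 mL at 0.5 mL/s then 3.5 mL at 0.1 mL/s,
    followed by a 1.5 mL saline flush at 0.1 mL/s."""
    return InjectionProtocol(
        contrast_phases=((3.0, 0.5), (3.5, 0.1)), flush=(1.5, 0.1)
    )


# --------------------------------------------------------------------
# arterial input function
# --------------------------------------------------------------------

@dataclass(frozen=True)
class AIFParams:
    """Gamma-variate arterial input with an equilibrium plateau.

    ``amplitude`` is the bolus peak enhancement (HU); ``onset`` the
    contrast arrival time (s); ``shape``/``scale`` the gamma-variate
    parameters (dimensionless / s); ``recirculation_fraction`` the
    steady-state plateau level as a fraction of the peak.
    """

    amplitude: float = 200.0
    onset: float = 6.0
    shape: float = 3.0
    scale: float = 2.5
    recirculation_fraction: float = 0.35

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValidationError("amplitude must be positive")
        if self.shape <= 0 or self.scale <= 0:
            raise ValidationError("shape and scale must be positive")
        if not 0 <= self.recirculation_fraction < 1:
            raise ValidationError("recirculation_fraction must lie in [0, 1)")
        if self.onset < 0:
            raise ValidationError("onset must be nonnegative")


def simulate_aif(times, params: AIFParams = AIFParams()) -> TimeCurve:
    """Evaluate the arterial enhancement curve on a time grid.

    ``times`` may be a :class:`ScanSchedule` (evaluated at its frame
    times) or any increasing array of nonnegative times.  The curve is
    zero up to the onset; with zero recirculation its peak equals the
    amplitude exactly (in continuous time).
    """
    if isinstance(times, ScanSchedule):
        t = times.frame_times
    else:
        t = np.asarray(times, dtype=float)
    u = np.maximum((t - params.onset) / params.scale, 0.0)
    # normalized gamma variate: peak value A at u == shape
    bolus = params.amplitude * np.power(u / params.shape, params.shape) * np.exp(
        params.shape - u
    )
    if params.recirculation_fraction > 0:
        tau = params.shape * params.scale  # rise on the bolus timescale
        dt = np.maximum(t - params.onset, 0.0)
        plateau = (
            params.recirculation_fraction
            * params.amplitude
            * (1.0 - np.exp(-dt / tau))
        )
        bolus = bolus + plateau
    return TimeCurve(t, bolus, kind="enhancement")


def dense_times(end: float, dt: float = 0.02) -> np.ndarray:
    """A dense sampling grid from 0 to at least ``end`` (step ``dt``)."""
    n = int(math.ceil(end / dt)) + 1
    return np.arange(n) * dt


# --------------------------------------------------------------------
# tissue forward model
# --------------------------------------------------------------------

def simulate_tissue_curve(
    aif_dense: TimeCurve, kinetics: KineticParams
) -> TimeCurve:
    """Tissue enhancement curve for the boxcar-residue + Patlak-leakage
    forward model (see module docstring).

    ``aif_dense`` must be densely sampled (max step 0.1 s) — the
    integrals are computed by cumulative trapezoid on its grid.  Sample
    the result at a :class:`ScanSchedule` with ``curve.sample_at``.
    """
    t = aif_dense.times
    steps = np.diff(t)
    if steps.max() > 0.1 + 1e-12:
        raise ValidationError(
            "AIF must be densely sampled (interval <= 0.1 s) for the forward model"
        )
    f = kinetics.flow_per_second
    k = kinetics.leak_per_second
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (aif_dense.values[1:] + aif_dense.values[:-1]) * steps)]
    )
    # I(t - MTT), with I == 0 for arguments <= t[0]
    lagged = np.interp(t - kinetics.mtt, t, integral, left=0.0)
    values = f * (integral - lagged) + k * integral
    return TimeCurve(t, values, kind="enhancement")


# --------------------------------------------------------------------
# dynamic CT series phantom
# --------------------------------------------------------------------

def ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: tuple[float, float, float],
    semiaxes_mm: tuple[float, float, float],
) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipsoid given in mm coordinates
    (voxel centers at ``index * spacing``)."""
    if any(a <= 0 for a in semiaxes_mm):
        raise ValidationError("ellipsoid semi-axes must be positive")
    coords = [
        (np.arange(n) * s - c) / a
        for n, s, c, a in zip(grid_shape, spacing, center_mm, semiaxes_mm)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    return zz**2 + yy**2 + xx**2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and composition of one dynamic-CT tumor phantom.

    ``kinetics`` may be a single :class:`KineticParams` (uniform tumor)
    or a sequence of them, in which case the tumor is split into
    equal-volume slabs along the x axis, one kinetic set per slab.
    An aorta-like column at the grid corner carries the pure arterial
    curve for AIF extraction.
    """

    grid_shape: tuple[int, int, int] = (12, 20, 20)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_center_mm: tuple[float, float, float] = (11.0, 22.0, 22.0)
    tumor_semiaxes_mm: tuple[float, float, float] = (7.0, 7.0, 7.0)
    background_hu: float = 40.0
    blood_baseline_hu: float = 40.0
    kinetics: KineticParams | Sequence[KineticParams] = field(
        default_factory=lambda: KineticParams(bf=36.16, bv=25.36, ps=9.47)
    )
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValidationError("noise sigma must be nonnegative")
        extent = [n * s for n, s in zip(self.grid_shape, self.spacing)]
        for c, a, e in zip(self.tumor_center_mm, self.tumor_semiaxes_mm, extent):
            if c - a < 0 or c + a > e:
                raise ValidationError("tumor ellipsoid must lie fully inside the grid")

    @property
    def kinetics_list(self) -> list[KineticParams]:
        if isinstance(self.kinetics, KineticParams):
            return [self.kinetics]
        return list(self.kinetics)


def _aorta_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """A 2x2 voxel column along z in the (y, x) corner of the grid."""
    mask = np.zeros(grid_shape, dtype=bool)
    mask[:, 0:2, 0:2] = True
    return mask


def simulate_dynamic_series(
    spec: PhantomSpec,
    schedule: ScanSchedule | None = None,
    aif_params: AIFParams = AIFParams(),
    dense_dt: float = 0.02,
):
    """Simulate a 4D dynamic CT series with known kinetics.

    Returns ``(series, tumor_mask, aorta_mask, truth)`` where ``truth``
    is the list of per-slab :class:`KineticParams` actually used.
    Voxel time courses are baseline HU plus the forward-model tissue
    curve plus seeded Gaussian noise; the aorta column carries the raw
    (baseline + arterial) curve.
    """
    if schedule is None:
        schedule = default_scan_schedule()
    tumor = ellipsoid_mask(
        spec.grid_shape, spec.spacing, spec.tumor_center_mm, spec.tumor_semiaxes_mm
    )
    aorta = _aorta_mask(spec.grid_shape)
    if (tumor & aorta).any():
        raise ValidationError("tumor ellipsoid overlaps the aorta region")

    t_dense = dense_times(schedule.frame_times[-1], dense_dt)
    aif_dense = simulate_aif(t_dense, aif_params)
    aif_frames = aif_dense.sample_at(schedule.frame_times)

    kin_list = spec.kinetics_list
    data = np.full(
        (schedule.n_frames, *spec.grid_shape), float(spec.background_hu)
    )
    # split the tumor into equal-volume slabs along x (sorted flat order)
    voxels = np.argwhere(tumor)
    order = np.lexsort((voxels[:, 0], voxels[:, 1], voxels[:, 2]))  # by x, then y, z
    voxels = voxels[order]
    chunks = np.array_split(voxels, len(kin_list))
    for kin, chunk in zip(kin_list, chunks):
        curve = simulate_tissue_curve(aif_dense, kin).sample_at(schedule.frame_times)
        data[:, chunk[:, 0], chunk[:, 1], chunk[:, 2]] = (
            spec.background_hu + curve.values[:, None]
        )
    data[:, aorta] = spec.blood_baseline_hu + aif_frames.values[:, None]

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)

    series = DynamicSeries(data, schedule.frame_times, spec.spacing)
    return series, tumor, aorta, kin_list


# --------------------------------------------------------------------
# PET SUV phantom
# --------------------------------------------------------------------

@dataclass(frozen=True)
class PetPhantomSpec:
    """One static PET tumor phantom with exact SUV targets.

    Within the tumor mask the volume is a smooth radial profile plus
    seeded heterogeneity noise, affinely rescaled so the masked maximum
    and mean hit ``suv_max`` / ``suv_mean`` exactly.
    """

    grid_shape: tuple[int, int, int] = (12, 20, 20)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_center_mm: tuple[float, float, float] = (11.0, 22.0, 22.0)
    tumor_semiaxes_mm: tuple[float, float, float] = (7.0, 7.0, 7.0)
    suv_max: float = 3.73
    suv_mean: float = 2.10
    heterogeneity: float = 0.15
    background_suv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.suv_max >= self.suv_mean > 0:
            raise ValidationError("targets must satisfy SUVmax >= SUVmean > 0")
        if self.heterogeneity < 0:
            raise ValidationError("heterogeneity amplitude must be nonnegative")


def simulate_pet_volume(spec: PetPhantomSpec):
    """Simulate an SUV volume; returns ``(volume, tumor_mask)``.

    The masked max equals ``suv_max`` and the masked mean equals
    ``suv_mean`` to float precision (affine rescaling); the background
    sits near ``background_suv``.
    """
    mask = ellipsoid_mask(
        spec.grid_shape, spec.spacing, spec.tumor_center_mm, spec.tumor_semiaxes_mm
    )
    if not mask.any():
        raise ValidationError("tumor mask is empty")
    rng = np.random.default_rng(spec.seed)

    coords = [
        (np.arange(n) * s - c) / a
        for n, s, c, a in zip(
            spec.grid_shape, spec.spacing, spec.tumor_center_mm, spec.tumor_semiaxes_mm
        )
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    r2 = zz**2 + yy**2 + xx**2
    profile = np.clip(1.0 - r2, 0.0, None)  # smooth, peaked at the center

    volume = np.clip(
        spec.background_suv + rng.normal(0.0, 0.03, size=spec.grid_shape), 0.05, None
    )
    raw = profile[mask]
    if spec.heterogeneity > 0:
        raw = raw + spec.heterogeneity * rng.standard_normal(raw.size)
    vmax, vmean = raw.max(), raw.mean()
    if spec.suv_max == spec.suv_mean:
        volume[mask] = spec.suv_mean
    else:
        if vmax - vmean <= 1e-12:
            raise ValidationError(
                "degenerate tumor profile: cannot hit distinct SUVmax/SUVmean targets"
            )
        gain = (spec.suv_max - spec.suv_mean) / (vmax - vmean)
        volume[mask] = spec.suv_mean + gain * (raw - vmean)
    return volume, mask


# --------------------------------------------------------------------
# histology phantom
# --------------------------------------------------------------------

@dataclass(frozen=True)
class HistologySectionSpec:
    """A synthetic CD31-stained section tiled into high-power fields.

    ``counts`` is a 2D grid (rows x cols) of planted vessel counts, one
    per field; the ``n_hot_spots`` fields with the highest counts are
    the designated hot spots and must end up with a strictly higher
    stained-area fraction than every other field.
    """

    counts: tuple[tuple[int, ...], ...]
    field_shape: tuple[int, int] = (96, 96)
    radius_range: tuple[float, float] = (3.0, 5.0)
    min_separation: float = 2.0
    n_hot_spots: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        counts = tuple(tuple(int(c) for c in row) for row in self.counts)
        if any(c < 0 for row in counts for c in row):
            raise ValidationError("vessel counts must be nonnegative")
        if len({len(row) for row in counts}) != 1:
            raise ValidationError("counts grid must be rectangular")
        object.__setattr__(self, "counts", counts)
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValidationError("invalid radius range")

    @property
    def grid(self) -> tuple[int, int]:
        return len(self.counts), len(self.counts[0])


def _place_disks(
    field: np.ndarray, count: int, spec: HistologySectionSpec, rng
) -> None:
    """Draw ``count`` disjoint disks into one field, in place."""
    from skimage.draw import disk as draw_disk

    h, w = field.shape
    placed: list[tuple[float, float, float]] = []
    for _ in range(count):
        for attempt in range(4000):
            r = rng.uniform(*spec.radius_range)
            # keep a 1-px clearance from the field border so components
            # never bridge adjacent fields
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            ok = all(
                math.hypot(cy - py, cx - px) >= r + pr + spec.min_separation
                for py, px, pr in placed
            )
            if ok:
                placed.append((cy, cx, r))
                rr, cc = draw_disk((cy, cx), r, shape=field.shape)
                field[rr, cc] = 1
                break
        else:
            raise ValidationError(
                f"could not place {count} disjoint vessels in a "
                f"{h}x{w} field; reduce counts or radii"
            )


def simulate_histology_section(spec: HistologySectionSpec):
    """Simulate a binary CD31 section; returns ``(image, counts, hot_spots)``.

    ``image`` is uint8 {0,1}; ``counts`` the planted per-field counts as
    an array; ``hot_spots`` the (row, col) field coordinates of the
    designated hot spots.  Raises if the stained-area ordering between
    hot spots and background fields fails (choose more separated counts).
    """
    rng = np.random.default_rng(spec.seed)
    n_rows, n_cols = spec.grid
    fh, fw = spec.field_shape
    counts = np.asarray(spec.counts, dtype=int)
    image = np.zeros((n_rows * fh, n_cols * fw), dtype=np.uint8)
    for i in range(n_rows):
        for j in range(n_cols):
            fld = image[i * fh : (i + 1) * fh, j * fw : (j + 1) * fw]
            _place_disks(fld, counts[i, j], spec, rng)

    order = np.argsort(counts.ravel(), kind="stable")[::-1][: spec.n_hot_spots]
    hot = [(int(k // n_cols), int(k % n_cols)) for k in sorted(order)]
    fractions = np.array(
        [
            [
                image[i * fh : (i + 1) * fh, j * fw : (j + 1) * fw].mean()
                for j in range(n_cols)
            ]
            for i in range(n_rows)
        ]
    )
    hot_set = set(hot)
    hot_fracs = [fractions[i, j] for (i, j) in hot_set]
    bg_fracs = [
        fractions[i, j]
        for i in range(n_rows)
        for j in range(n_cols)
        if (i, j) not in hot_set
    ]
    if bg_fracs and hot_fracs and min(hot_fracs) <= max(bg_fracs):
        raise ValidationError(
            "hot-spot fields are not strictly denser than background fields; "
            "increase the count separation"
        )
    return image, counts, hot


# --------------------------------------------------------------------
# longitudinal cohort
# --------------------------------------------------------------------

#: Group/day reference values (mean, SD) for the six simulated
#: parameters; days are measured from the start of therapy.
_REFERENCE_CELLS: dict[str, dict[int, dict[str, tuple[float, float]]]] = {
    "treatment": {
        0: dict(tv=(0.18, 0.08), bf=(36.16, 11.15), bv=(25.36, 5.62),
                ps=(9.47, 3.09), suv_max=(1.45, 0.26), suv_mean=(0.96, 0.18)),
        3: dict(tv=(0.53, 0.32), bf=(35.82, 25.93), bv=(16.71, 4.91),
                ps=(10.18, 5.81), suv_max=(2.23, 0.65), suv_mean=(1.30, 0.33)),
        7: dict(tv=(0.79, 0.47), bf=(30.05, 14.87), bv=(19.99, 5.30),
                ps=(7.246, 1.97), suv_max=(2.42, 0.92), suv_mean=(1.33, 0.40)),
        14: dict(tv=(1.53, 1.11), bf=(34.34, 17.10), bv=(18.35, 7.48),
                 ps=(7.36, 2.48), suv_max=(3.03, 1.36), suv_mean=(1.77, 0.66)),
    },
    "control": {
        0: dict(tv=(0.18, 0.10), bf=(28.64, 13.78), bv=(22.56, 5.56),
                ps=(11.18, 2.24), suv_max=(1.31, 0.43), suv_mean=(0.84, 0.29)),
        3: dict(tv=(0.43, 0.23), bf=(36.44, 9.22), bv=(22.81, 5.95),
                ps=(9.39, 1.58), suv_max=(2.21, 0.60), suv_mean=(1.33, 0.29)),
        7: dict(tv=(0.76, 0.57), bf=(54.13, 30.11), bv=(23.54, 9.04),
                ps=(12.06, 7.25), suv_max=(2.13, 0.89), suv_mean=(1.27, 0.45)),
        14: dict(tv=(1.88, 1.32), bf=(70.75, 50.65), bv=(32.20, 9.76),
                 ps=(9.91, 3.59), suv_max=(3.73, 1.22), suv_mean=(2.10, 0.54)),
    },
}

#: physical truncation bounds for stochastic draws (lower, upper)
_DRAW_BOUNDS = {
    "tv": (0.05, 3.0),  # cm^3; upper bound keeps the tumor inside the grid
    "bf": (1.0, np.inf),
    "bv": (1.0, np.inf),
    "ps": (0.0, np.inf),
    "suv_max": (0.1, np.inf),
    "suv_mean": (0.1, np.inf),
}


def reference_param_table() -> pd.DataFrame:
    """The default cohort parameterization as a tidy table with columns
    ``group, day, parameter, mean, sd``."""
    rows = []
    for group, by_day in _REFERENCE_CELLS.items():
        for day, params in by_day.items():
            for name, (mean, sd) in params.items():
                rows.append(
                    dict(group=group, day=day, parameter=name, mean=mean, sd=sd)
                )
    return pd.DataFrame(rows)


@dataclass
class CohortScan:
    """All simulated inputs and ground truth for one tumor at one day."""

    rabbit_id: str
    tumor_id: str
    group: str
    day: int
    truth: dict
    series: DynamicSeries
    tumor_mask: np.ndarray
    aorta_mask: np.ndarray
    suv_volume: np.ndarray


def _draw(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _cell_lookup(table: pd.DataFrame, group: str, day: int) -> dict:
    cell = table[(table["group"] == group) & (table["day"] == day)]
    out = {}
    for name in _DRAW_BOUNDS:
        row = cell[cell["parameter"] == name]
        if len(row) != 1:
            raise ValidationError(
                f"param_table is missing entry ({group!r}, day {day}, {name!r})"
            )
        out[name] = (float(row["mean"].iloc[0]), float(row["sd"].iloc[0]))
    return out


def draw_cohort_truth(
    param_table: pd.DataFrame | None = None,
    n_rabbits_per_group: int = 6,
    tumors_per_rabbit: int = 2,
    days: Sequence[int] = (0, 3, 7, 14),
    groups: Sequence[str] = ("treatment", "control"),
    seed: int = 0,
    mode: str = "stochastic",
) -> pd.DataFrame:
    """Draw per-tumor per-day ground-truth parameters for a cohort.

    Values come from the group/day cells of ``param_table`` (normal
    distributions truncated at physical bounds; the default table holds
    the study's reference values).  ``mode="fixed"`` pins every tumor
    exactly at its cell mean.  SUVmax is nudged above SUVmean when a
    draw inverts them.  Returns one row per tumor-day with columns
    ``rabbit_id, tumor_id, group, day, tv, bf, bv, ps, suv_max,
    suv_mean``.
    """
    if mode not in ("stochastic", "fixed"):
        raise ValidationError("mode must be 'stochastic' or 'fixed'")
    if param_table is None:
        param_table = reference_param_table()
    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        for r in range(1, n_rabbits_per_group + 1):
            rabbit_id = f"{group[0].upper()}{r}"
            sides = (
                "LR"[:tumors_per_rabbit]
                if tumors_per_rabbit <= 2
                else [str(i) for i in range(tumors_per_rabbit)]
            )
            for side in sides:
                for day in days:
                    cell = _cell_lookup(param_table, group, int(day))
                    if mode == "fixed":
                        drawn = {k: float(np.clip(m, *_DRAW_BOUNDS[k]))
                                 for k, (m, _) in cell.items()}
                    else:
                        drawn = {
                            k: _draw(rng, m, sd, *_DRAW_BOUNDS[k])
                            for k, (m, sd) in cell.items()
                        }
                    if drawn["suv_max"] < drawn["suv_mean"]:
                        drawn["suv_max"] = drawn["suv_mean"] * 1.05
                    rows.append(
                        dict(rabbit_id=rabbit_id, tumor_id=f"{rabbit_id}-{side}",
                             group=group, day=int(day), **drawn)
                    )
    return pd.DataFrame(rows)


def simulate_cohort(
    param_table: pd.DataFrame | None = None,
    n_rabbits_per_group: int = 6,
    tumors_per_rabbit: int = 2,
    days: Sequence[int] = (0, 3, 7, 14),
    groups: Sequence[str] = ("treatment", "control"),
    seed: int = 0,
    mode: str = "stochastic",
    grid_shape: tuple[int, int, int] = (12, 20, 20),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    noise_sigma: float = 0.0,
    schedule: ScanSchedule | None = None,
    aif_params: AIFParams = AIFParams(),
    pet_heterogeneity: float = 0.15,
) -> list[CohortScan]:
    """Simulate a two-arm longitudinal cohort of tumor scans.

    Ground truth is drawn by :func:`draw_cohort_truth`; per tumor-day a
    dynamic CT series and an SUV volume are synthesized on one shared
    grid.  The tumor ellipsoid (a sphere here) is sized so its analytic
    volume equals the drawn tumor volume.
    """
    if schedule is None:
        schedule = default_scan_schedule()
    truth_table = draw_cohort_truth(
        param_table, n_rabbits_per_group, tumors_per_rabbit, days, groups,
        seed=seed, mode=mode,
    )
    rng = np.random.default_rng(seed + 1)  # sub-seeds for noise fields
    extent_mm = tuple(n * s for n, s in zip(grid_shape, spacing))
    center = tuple(e / 2 for e in extent_mm)

    scans: list[CohortScan] = []
    for row in truth_table.itertuples():
        radius = (3.0 * row.tv * 1000.0 / (4.0 * math.pi)) ** (1 / 3)
        kin = KineticParams(bf=row.bf, bv=row.bv, ps=row.ps)
        spec = PhantomSpec(
            grid_shape=grid_shape,
            spacing=spacing,
            tumor_center_mm=center,
            tumor_semiaxes_mm=(radius, radius, radius),
            kinetics=kin,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        series, tumor_mask, aorta_mask, _ = simulate_dynamic_series(
            spec, schedule, aif_params
        )
        pet_spec = PetPhantomSpec(
            grid_shape=grid_shape,
            spacing=spacing,
            tumor_center_mm=center,
            tumor_semiaxes_mm=(radius, radius, radius),
            suv_max=row.suv_max,
            suv_mean=row.suv_mean,
            heterogeneity=pet_heterogeneity,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        suv_volume, _ = simulate_pet_volume(pet_spec)
        truth = dict(
            bf=kin.bf, bv=kin.bv, ps=kin.ps, mtt=kin.mtt,
            tv_cm3=row.tv, suv_max=row.suv_max, suv_mean=row.suv_mean,
        )
        scans.append(
            CohortScan(
                rabbit_id=row.rabbit_id,
                tumor_id=row.tumor_id,
                group=row.group,
                day=row.day,
                truth=truth,
                series=series,
                tumor_mask=tumor_mask,
                aorta_mask=aorta_mask,
                suv_volume=suv_volume,
            )
        )
    return scans
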