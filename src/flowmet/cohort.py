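"""Per-tumor analysis orchestration and cohort-level statistics.

``run_timepoint`` composes the full measurement chain for one tumor at
one imaging day: VOI refinement -> AIF extraction -> perfusion
kinetics -> SUV statistics -> GLCM texture -> flow-metabolic ratio.
``summarize`` aggregates the per-tumor records into a group x day
table of mean +- SD, ``correlate`` provides Pearson/Spearman
coefficients, and ``group_compare`` contrasts the two arms at one day
with a rabbit-level permutation test (both tumors of a rabbit move
together, respecting within-animal correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core import DynamicSeries, ValidationError
from .metabolism import fmr, suv_stats
from .perfusion import (
    DEFAULT_PATLAK_WINDOW_START,
    SegmentationSettings,
    extract_aif,
    segment_voi,
    voi_summary,
)
from .phantom import CohortScan
from .texture import texture_indices

__all__ = [
    "AnalysisConfig",
    "CohortRecord",
    "run_timepoint",
    "analyze_cohort",
    "summarize",
    "correlate",
    "group_compare",
    "REPORT_PARAMETERS",
]

#: record fields reported in the cohort summary table, in layout order
REPORT_PARAMETERS = (
    "tv_cm3",
    "bf",
    "bv",
    "ps",
    "suv_max",
    "suv_mean",
    "tlg",
    "entropy",
    "homogeneity",
    "fmr",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunables of the per-tumor measurement chain."""

    settings: SegmentationSettings = field(default_factory=SegmentationSettings)
    n_baseline_frames: int = 3
    slope_window: int = 3
    patlak_window_start: float | str = DEFAULT_PATLAK_WINDOW_START
    n_levels: int = 128
    glcm_distance: int = 1
    glcm_mode: str = "accumulate"


@dataclass(frozen=True)
class CohortRecord:
    """All measured parameters for one tumor at one time point."""

    rabbit_id: str
    tumor_id: str
    group: str
    day: int
    tv_cm3: float
    bf: float
    bv: float
    ps: float
    suv_max: float
    suv_mean: float
    tlg: float
    entropy: float
    homogeneity: float
    fmr: float
    mvd: float | None = None
    patlak_r_squared: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def run_timepoint(
    series: DynamicSeries,
    suv_volume: np.ndarray,
    tumor_mask: np.ndarray,
    aorta_mask: np.ndarray,
    config: AnalysisConfig = AnalysisConfig(),
    rabbit_id: str = "",
    tumor_id: str = "",
    group: str = "",
    day: int = 0,
    mvd_value: float | None = None,
) -> CohortRecord:
    """Run the full measurement chain for one tumor scan pair.

    All volumes must share one grid.  Any stage failure propagates as a
    :class:`~flowmet.core.ValidationError` naming the stage.
    """
    baseline = series.baseline_volume(config.n_baseline_frames)
    refined = segment_voi(baseline, tumor_mask, config.settings)
    aif = extract_aif(
        series, aorta_mask, config.settings, config.n_baseline_frames
    )
    kinetics = voi_summary(
        series,
        refined,
        aif,
        n_baseline_frames=config.n_baseline_frames,
        slope_window=config.slope_window,
        patlak_window_start=config.patlak_window_start,
    )
    pet = suv_stats(suv_volume, tumor_mask, series.spacing)
    tex = texture_indices(
        suv_volume,
        tumor_mask,
        n_levels=config.n_levels,
        distance=config.glcm_distance,
        mode=config.glcm_mode,
    )
    return CohortRecord(
        rabbit_id=rabbit_id,
        tumor_id=tumor_id,
        group=group,
        day=int(day),
        tv_cm3=pet.tv_cm3,
        bf=kinetics.params.bf,
        bv=kinetics.params.bv,
        ps=kinetics.params.ps,
        suv_max=pet.suv_max,
        suv_mean=pet.suv_mean,
        tlg=pet.tlg,
        entropy=tex.entropy,
        homogeneity=tex.homogeneity,
        fmr=fmr(kinetics.params.bf, pet.suv_max),
        mvd=mvd_value,
        patlak_r_squared=kinetics.patlak.r_squared,
    )


def analyze_cohort(
    scans: list[CohortScan], config: AnalysisConfig = AnalysisConfig()
) -> list[CohortRecord]:
    """Apply :func:`run_timepoint` to every simulated cohort scan."""
    return [
        run_timepoint(
            s.series,
            s.suv_volume,
            s.tumor_mask,
            s.aorta_mask,
            config,
            rabbit_id=s.rabbit_id,
            tumor_id=s.tumor_id,
            group=s.group,
            day=s.day,
        )
        for s in scans
    ]


def records_frame(records: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def summarize(records: list[CohortRecord]) -> pd.DataFrame:
    """Group x day summary table: mean, sample SD (n-1) and n per cell.

    Layout mirrors the study report: one row per parameter, one column
    block per day with treatment and control side by side.  Cells with
    no records are reported as missing (NaN, n = 0), not as errors.
    Single-record cells report SD = 0 with n = 1.
    """
    if not records:
        raise ValidationError("no records to summarize")
    df = records_frame(records)
    rows = []
    days = sorted(df["day"].unique())
    groups = sorted(df["group"].unique())
    for parameter in REPORT_PARAMETERS:
        for day in days:
            for group in groups:
                cell = df[(df["day"] == day) & (df["group"] == group)][parameter]
                cell = cell.dropna()
                n = int(len(cell))
                rows.append(
                    dict(
                        parameter=parameter,
                        day=int(day),
                        group=group,
                        mean=float(cell.mean()) if n else float("nan"),
                        sd=(float(cell.std(ddof=1)) if n > 1 else (0.0 if n else float("nan"))),
                        n=n,
                    )
                )
    return pd.DataFrame(rows)


def correlate(x, y, method: str = "pearson") -> float:
    """Pearson product-moment or Spearman rank correlation coefficient
    (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValidationError("method must be 'pearson' or 'spearman'")


def group_compare(
    records: list[CohortRecord],
    parameter: str,
    day: int,
    n_permutations: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided rabbit-level permutation test at one day.

    The statistic is the treatment-minus-control difference of group
    means of ``parameter``.  Group labels are permuted over RABBITS so
    both tumors of an animal always travel together; with few rabbits
    the full label assignment space is enumerated exactly, otherwise
    ``n_permutations`` random reassignments are drawn (seeded).
    Returns ``(mean_difference, p_value)``.
    """
    df = records_frame(records)
    df = df[df["day"] == int(day)].dropna(subset=[parameter])
    by_rabbit = df.groupby("rabbit_id").agg(
        group=("group", "first"), value=(parameter, "mean"),
        values_sum=(parameter, "sum"), n_tumors=(parameter, "size"),
    )
    treat_ids = by_rabbit.index[by_rabbit["group"] == "treatment"]
    control_ids = by_rabbit.index[by_rabbit["group"] == "control"]
    n_t, n_c = len(treat_ids), len(control_ids)
    if n_t < 2 or n_c < 2:
        raise ValidationError(
            "group comparison needs at least 2 rabbits per group "
            f"(found {n_t} treatment, {n_c} control at day {day})"
        )

    # tumor-level group means, permuting whole rabbits
    sums = by_rabbit["values_sum"].to_numpy()
    sizes = by_rabbit["n_tumors"].to_numpy()
    is_treat = (by_rabbit["group"] == "treatment").to_numpy()

    def statistic(assign: np.ndarray) -> float:
        st, ct = sums[assign].sum(), sums[~assign].sum()
        nt, nc = sizes[assign].sum(), sizes[~assign].sum()
        return st / nt - ct / nc

    observed = statistic(is_treat)
    n_rabbits = len(by_rabbit)
    exact_count = comb(n_rabbits, n_t)
    hits = 0
    total = 0
    if exact_count <= n_permutations:
        for chosen in combinations(range(n_rabbits), n_t):
            assign = np.zeros(n_rabbits, dtype=bool)
            assign[list(chosen)] = True
            if abs(statistic(assign)) >= abs(observed) - 1e-12:
                hits += 1
            total += 1
        p = hits / total
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            perm = rng.permutation(n_rabbits)
            assign = np.zeros(n_rabbits, dtype=bool)
            assign[perm[:n_t]] = True
            if abs(statistic(assign)) >= abs(observed) - 1e-12:
                hits += 1
            total += 1
        p = (hits + 1) / (total + 1)
    return float(observed), float(p)
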