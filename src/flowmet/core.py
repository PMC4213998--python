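"""Shared containers for the multiparametric imaging pipeline.

The pipeline couples three measurement channels on the same tumor:
dynamic contrast-enhanced CT (perfusion kinetics), static FDG-PET
(metabolic burden and texture), and CD31 histology (microvessel
density).  These dataclasses are the common currency passed between
modules: sampled time-enhancement curves, perfusion kinetic parameter
sets, 4D dynamic series, and SUV summary statistics.

Unit conventions (used consistently everywhere):

* time in seconds, CT attenuation in Hounsfield units (HU)
* blood flow BF in mL/100 mL/min, blood volume BV in mL/100 mL,
  permeability-surface product PS in mL/100 mL/min, mean transit
  time MTT in seconds; the three are tied by ``BV = BF * MTT / 60``
* voxel spacing in mm; volumes reported in cm^3
* SUV is dimensionless (g/mL under unit tissue density)
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "ValidationError",
    "TimeCurve",
    "KineticParams",
    "DynamicSeries",
    "SUVStats",
]


class ValidationError(ValueError):
    """An input violated a documented precondition."""


def _as_float_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class TimeCurve:
    """A sampled concentration/attenuation curve over time.

    ``kind`` distinguishes raw attenuation (HU, baseline included) from
    enhancement (HU above the pre-contrast baseline).  Arterial input
    functions and tissue curves are both represented this way.
    """

    times: np.ndarray
    values: np.ndarray
    kind: Literal["raw", "enhancement"] = "raw"

    def __post_init__(self) -> None:
        times = _as_float_1d(self.times, "times")
        values = _as_float_1d(self.values, "values")
        if times.size != values.size:
            raise ValidationError(
                f"times ({times.size}) and values ({values.size}) differ in length"
            )
        if times.size == 0:
            raise ValidationError("curve must contain at least one sample")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(times < 0):
            raise ValidationError("times must be nonnegative")
        if self.kind not in ("raw", "enhancement"):
            raise ValidationError(f"unknown curve kind {self.kind!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size

    @property
    def peak(self) -> float:
        return float(self.values.max())

    @property
    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.values))])

    def sample_at(self, times) -> "TimeCurve":
        """Linear interpolation onto a new time grid (no extrapolation
        beyond the end points: values are clamped)."""
        t = _as_float_1d(times, "times")
        return TimeCurve(t, np.interp(t, self.times, self.values), kind=self.kind)

    def scaled(self, factor: float) -> "TimeCurve":
        return replace(self, values=self.values * float(factor))


@dataclass(frozen=True)
class KineticParams:
    """Perfusion kinetics of a voxel or VOI.

    ``bf`` (mL/100 mL/min), ``bv`` (mL/100 mL) and ``ps``
    (mL/100 mL/min) are the three perfusion-CT outputs; ``mtt`` (s) is
    the vascular mean transit time tying flow to volume through
    ``BV = BF * MTT / 60``.  Exactly this consistency is enforced: give
    any two of (bf, bv, mtt) and the third is derived; giving all three
    inconsistently is an error.  ``mtt`` defaults to 8 s when only
    ``bf`` is supplied.
    """

    bf: float
    bv: float | None = None
    ps: float = 0.0
    mtt: float | None = None

    #: fallback transit time (s) when neither bv nor mtt is given
    DEFAULT_MTT = 8.0

    def __post_init__(self) -> None:
        bf = float(self.bf)
        ps = float(self.ps)
        if bf < 0 or ps < 0:
            raise ValidationError("bf and ps must be nonnegative")
        bv = None if self.bv is None else float(self.bv)
        mtt = None if self.mtt is None else float(self.mtt)
        if bv is not None and bv < 0:
            raise ValidationError("bv must be nonnegative")
        if mtt is not None and mtt <= 0:
            raise ValidationError("mtt must be positive")

        if bv is None and mtt is None:
            mtt = self.DEFAULT_MTT
        if bv is None:
            bv = bf * mtt / 60.0
        elif mtt is None:
            if bf > 0:
                mtt = 60.0 * bv / bf
            else:
                # stagnant limit: zero flow with pooled volume
                mtt = float("inf") if bv > 0 else self.DEFAULT_MTT
        elif bf > 0 or bv > 0:
            implied = bf * mtt / 60.0
            if abs(implied - bv) > 1e-6 * max(1.0, abs(bv)):
                raise ValidationError(
                    f"inconsistent kinetics: bf*mtt/60 = {implied:.6g} but bv = {bv:.6g}"
                )
        object.__setattr__(self, "bf", bf)
        object.__setattr__(self, "bv", bv)
        object.__setattr__(self, "ps", ps)
        object.__setattr__(self, "mtt", mtt)

    @property
    def flow_per_second(self) -> float:
        """BF expressed as a fractional flow per second (1/s)."""
        return self.bf / 6000.0

    @property
    def leak_per_second(self) -> float:
        """PS expressed as a fractional transfer per second (1/s)."""
        return self.ps / 6000.0


@dataclass(frozen=True)
class DynamicSeries:
    """A 4D dynamic CT acquisition: ``data[t, z, y, x]`` in HU."""

    data: np.ndarray
    frame_times: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        times = _as_float_1d(self.frame_times, "frame_times")
        if data.ndim != 4:
            raise ValidationError(f"data must be 4D (t,z,y,x), got shape {data.shape}")
        if data.shape[0] != times.size:
            raise ValidationError(
                f"{data.shape[0]} frames but {times.size} frame times"
            )
        if np.any(np.diff(times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError("spacing must be three positive lengths (mm)")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "frame_times", times)
        object.__setattr__(self, "spacing", spacing)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voi_curve(self, mask: np.ndarray) -> TimeCurve:
        """Mean raw HU over the mask, per frame."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid_shape:
            raise ValidationError("mask shape does not match the series grid")
        if not mask.any():
            raise ValidationError("mask is empty")
        return TimeCurve(self.frame_times, self.data[:, mask].mean(axis=1), kind="raw")

    def baseline_volume(self, n_baseline_frames: int) -> np.ndarray:
        """Mean of the first ``n_baseline_frames`` frames (pre-contrast HU)."""
        n = int(n_baseline_frames)
        if not 1 <= n <= self.n_frames:
            raise ValidationError("n_baseline_frames out of range")
        return self.data[:n].mean(axis=0)


@dataclass(frozen=True)
class SUVStats:
    """VOI summary of an SUV volume.

    TLG (total lesion glycolysis) is by definition ``TV * SUVmean`` and
    is stored as a derived property so the identity holds exactly.
    """

    suv_max: float
    suv_mean: float
    tv_cm3: float

    def __post_init__(self) -> None:
        if self.suv_mean < 0:
            raise ValidationError("SUVmean must be nonnegative")
        if self.suv_max < self.suv_mean:
            raise ValidationError("SUVmax must be >= SUVmean")
        if self.tv_cm3 < 0:
            raise ValidationError("tumor volume must be nonnegative")

    @property
    def tlg(self) -> float:
        return self.tv_cm3 * self.suv_mean
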