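"""PET metabolic metrics: SUV statistics, TLG and the flow-metabolic ratio.

SUV normalizes tissue tracer activity by injected dose per body weight
(unit tissue density assumed), so a uniform distribution of the whole
dose over the body would read SUV = 1 everywhere.  TLG (total lesion
glycolysis) is tumor volume times SUVmean, a volume-weighted metabolic
burden.  The flow-metabolic ratio FMR = BF / SUVmax couples the
perfusion and metabolism channels of the same tumor; a falling FMR
flags flow-metabolism mismatch (falling perfusion with preserved or
rising glucose uptake) as seen early under antiangiogenic therapy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import SUVStats, ValidationError

__all__ = [
    "DoseRecord",
    "activity_to_suv",
    "suv_stats",
    "fmr",
    "resample_to_grid",
]


@dataclass(frozen=True)
class DoseRecord:
    """Injected FDG activity (MBq), subject weight (kg) and uptake time
    (min; recorded for provenance, not used in the SUV formula)."""

    injected_activity_mbq: float = 37.0
    weight_kg: float = 3.2
    uptake_time_min: float = 45.0

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise ValidationError("injected activity must be positive")
        if self.weight_kg <= 0:
            raise ValidationError("subject weight must be positive")


def activity_to_suv(activity_kbq_ml: np.ndarray, dose: DoseRecord) -> np.ndarray:
    """Convert an activity-concentration volume (kBq/mL) to SUV.

    SUV(x) = activity(x) * weight_g / injected_activity_kBq, with
    tissue density taken as 1 g/mL (body-weight normalization).
    """
    activity = np.asarray(activity_kbq_ml, dtype=float)
    if np.any(activity < 0):
        raise ValidationError("activity must be nonnegative")
    weight_g = dose.weight_kg * 1000.0
    dose_kbq = dose.injected_activity_mbq * 1000.0
    return activity * (weight_g / dose_kbq)


def suv_stats(
    suv_volume: np.ndarray,
    mask: np.ndarray,
    voxel_spacing_mm: tuple[float, float, float],
) -> SUVStats:
    """SUVmax, SUVmean and tumor volume over a mask.

    TV is the masked voxel count times the voxel volume, in cm^3; TLG
    follows from the :class:`~flowmet.core.SUVStats` identity
    TLG = TV * SUVmean.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    vol = np.asarray(suv_volume, dtype=float)
    if vol.shape != mask.shape:
        raise ValidationError("volume and mask shapes differ")
    voxel_cm3 = float(np.prod(voxel_spacing_mm)) / 1000.0
    inside = vol[mask]
    return SUVStats(
        suv_max=float(inside.max()),
        suv_mean=float(inside.mean()),
        tv_cm3=float(mask.sum()) * voxel_cm3,
    )


def fmr(bf: float, suv_max: float) -> float:
    """Flow-metabolic ratio: blood flow (mL/100 mL/min) over SUVmax."""
    if suv_max <= 0:
        raise ValidationError("SUVmax must be positive")
    if bf < 0:
        raise ValidationError("BF must be nonnegative")
    return bf / suv_max


def _check_rigid(matrix: np.ndarray, atol: float = 1e-6) -> None:
    r = matrix[:3, :3]
    if not np.allclose(r @ r.T, np.eye(3), atol=atol) or not np.isclose(
        np.linalg.det(r), 1.0, atol=atol
    ):
        raise ValidationError("transform must be rigid (pure rotation + translation)")


def resample_to_grid(
    volume: np.ndarray,
    transform: np.ndarray,
    target_shape: tuple[int, int, int] | None = None,
    interpolation: str = "trilinear",
) -> np.ndarray:
    """Apply a KNOWN rigid transform, resampling onto a target grid.

    ``transform`` is a 4x4 homogeneous matrix mapping target voxel
    coordinates to source voxel coordinates.  Use ``"nearest"`` for
    masks and ``"trilinear"`` for intensity volumes.  The identity
    transform returns the input unchanged (up to dtype).
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4):
        raise ValidationError("transform must be a 4x4 homogeneous matrix")
    _check_rigid(transform)
    if interpolation not in ("trilinear", "nearest"):
        raise ValidationError("interpolation must be 'trilinear' or 'nearest'")
    vol = np.asarray(volume, dtype=float)
    order = 1 if interpolation == "trilinear" else 0
    out = ndimage.affine_transform(
        vol,
        transform[:3, :3],
        offset=transform[:3, 3],
        output_shape=target_shape or vol.shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    return out
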