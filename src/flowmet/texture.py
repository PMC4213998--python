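"""Local texture heterogeneity of the tumor SUV distribution.

The masked SUV volume is first quantized to at most 128 discrete gray
levels by min-max resampling,

    R(x) = n_levels * ((I(x) - SUVmin) / (SUVmax - SUVmin) + 1),

which maps the VOI onto the closed band [n_levels, 2*n_levels];
discrete levels are floor(R) with the top value clipped, so exactly
the integers {n_levels, ..., 2*n_levels - 1} are achievable.  (The
constant offset of the band is immaterial: both texture indices depend
only on level differences and pair probabilities.)

A gray-level cooccurrence matrix (GLCM) then counts, over the 13
unique 3D neighbor directions at a given voxel distance, how often the
ordered level pair (i, j) occurs between two in-mask voxels; it is
symmetrized and normalized to a joint probability table p(i, j).  Two
Haralick indices summarize it:

* entropy  = -sum p(i,j) * log2 p(i,j)   (bits; randomness of pairs)
* homogeneity = sum p(i,j) / (1 + |i-j|) (inverse difference; 1 for a
  perfectly uniform VOI)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError

__all__ = [
    "LevelVolume",
    "GLCM",
    "TextureIndices",
    "resample_levels",
    "glcm",
    "glcm_entropy",
    "glcm_homogeneity",
    "texture_indices",
    "DIRECTIONS_3D",
]

#: the 13 unique 3D nearest-neighbor offsets (one per +/- direction pair)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)


@dataclass(frozen=True)
class LevelVolume:
    """Quantized gray levels over a mask.

    ``levels`` holds integers in {n_levels, ..., 2*n_levels - 1} inside
    the mask and -1 outside; ``suv_min``/``suv_max`` record the VOI
    range used for the mapping.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    suv_min: float
    suv_max: float

    @property
    def level_offset(self) -> int:
        """The lowest achievable level (== n_levels for this mapping)."""
        return self.n_levels


def resample_levels(
    suv_volume: np.ndarray, mask: np.ndarray, n_levels: int = 128
) -> LevelVolume:
    """Quantize the masked SUV range onto ``n_levels`` discrete values.

    A flat VOI (SUVmax == SUVmin) maps every voxel to the single lowest
    level; downstream entropy is 0 and homogeneity 1.
    """
    if n_levels < 2:
        raise ValidationError("n_levels must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    vol = np.asarray(suv_volume, dtype=float)
    inside = vol[mask]
    suv_min, suv_max = float(inside.min()), float(inside.max())
    levels = np.full(vol.shape, -1, dtype=np.int32)
    if suv_max == suv_min:
        levels[mask] = n_levels
    else:
        r = n_levels * ((inside - suv_min) / (suv_max - suv_min) + 1.0)
        q = np.floor(r).astype(np.int32)
        levels[mask] = np.minimum(q, 2 * n_levels - 1)
    return LevelVolume(
        levels=levels, mask=mask, n_levels=int(n_levels),
        suv_min=suv_min, suv_max=suv_max,
    )


@dataclass(frozen=True)
class GLCM:
    """Normalized, symmetric cooccurrence probability table.

    ``p[i, j]`` is the probability of the level pair
    ``(level_offset + i, level_offset + j)``; indices run over the
    achievable band so |i - j| equals the gray-level difference.
    """

    p: np.ndarray
    level_offset: int
    distance: int
    mode: str

    def __post_init__(self) -> None:
        if not np.isclose(self.p.sum(), 1.0, atol=1e-8):
            raise ValidationError("GLCM must be normalized to sum 1")


def glcm(
    levels: LevelVolume,
    distance: int = 1,
    mode: str = "accumulate",
) -> GLCM:
    """Cooccurrence matrix over the 13 unique 3D directions.

    Each direction contributes the ordered pairs of in-mask voxels
    separated by ``distance * direction`` (in voxel units); pairs are
    counted in both orders (symmetrization).  ``mode="accumulate"``
    pools all direction counts into one matrix before normalizing;
    ``mode="average"`` normalizes per direction and averages the
    resulting probability tables.
    """
    if mode not in ("accumulate", "average"):
        raise ValidationError("mode must be 'accumulate' or 'average'")
    if distance < 1:
        raise ValidationError("distance must be >= 1")
    n = levels.n_levels
    offset = levels.level_offset
    lv = levels.levels
    mask = levels.mask
    matrices = []
    total = np.zeros((n, n), dtype=float)
    any_pairs = False
    for direction in DIRECTIONS_3D:
        shift = tuple(d * distance for d in direction)
        src = tuple(
            slice(max(-s, 0), lv.shape[ax] - max(s, 0)) for ax, s in enumerate(shift)
        )
        dst = tuple(
            slice(max(s, 0), lv.shape[ax] + min(s, 0)) for ax, s in enumerate(shift)
        )
        valid = mask[src] & mask[dst]
        if not valid.any():
            if mode == "average":
                continue
            continue
        any_pairs = True
        i = lv[src][valid] - offset
        j = lv[dst][valid] - offset
        counts = np.zeros((n, n), dtype=float)
        np.add.at(counts, (i, j), 1.0)
        counts = counts + counts.T  # count (i, j) and (j, i)
        if mode == "average":
            matrices.append(counts / counts.sum())
        else:
            total += counts
    if mode == "average":
        if not matrices:
            raise ValidationError("no valid voxel pairs for the GLCM")
        p = np.mean(matrices, axis=0)
    else:
        if not any_pairs:
            raise ValidationError("no valid voxel pairs for the GLCM")
        p = total / total.sum()
    return GLCM(p=p, level_offset=offset, distance=int(distance), mode=mode)


def glcm_entropy(matrix: GLCM) -> float:
    """Pair entropy in bits: -sum p log2 p with 0 log 0 = 0."""
    p = matrix.p[matrix.p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_homogeneity(matrix: GLCM) -> float:
    """Inverse-difference homogeneity: sum p(i,j) / (1 + |i - j|)."""
    n = matrix.p.shape[0]
    i, j = np.indices((n, n))
    return float((matrix.p / (1.0 + np.abs(i - j))).sum())


@dataclass(frozen=True)
class TextureIndices:
    """The two reported local heterogeneity indices."""

    entropy: float
    homogeneity: float
    n_levels_observed: int


def texture_indices(
    suv_volume: np.ndarray,
    mask: np.ndarray,
    n_levels: int = 128,
    distance: int = 1,
    mode: str = "accumulate",
) -> TextureIndices:
    """Quantize, build the GLCM, and return entropy and homogeneity."""
    levels = resample_levels(suv_volume, mask, n_levels)
    matrix = glcm(levels, distance=distance, mode=mode)
    observed = int(np.unique(levels.levels[levels.mask]).size)
    return TextureIndices(
        entropy=glcm_entropy(matrix),
        homogeneity=glcm_homogeneity(matrix),
        n_levels_observed=observed,
    )
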