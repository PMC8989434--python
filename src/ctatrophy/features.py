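"""Shared per-subject image preparation for the trainable modules.

All three image modules (key-slice detector, measurement regressor, sulci
classifier) consume windowed, tilt-corrected slices standardized to the
224 x 224 model input and then downsampled to their working resolution.
This module performs that preparation once per subject and caches only the
small downsampled stacks, so desk-scale experiments stay within memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .phantom import CTVolume, GroundTruthAnnotation, KeySliceSet, MeasurementSet
from .preprocess import (
    WindowConfig,
    correct_midline_rotation,
    estimate_head_tilt,
    standardize_for_model,
    window_normalize,
)

__all__ = ["SubjectData", "prepare_subject", "prepare_volume", "slice_stacks"]

DETECT_SIZE = 32  # key-slice scorer input (downsampled from the 224 standard)
MEASURE_SIZE = 56  # measurement / sulci input per fused channel


def prepare_volume(
    volume: CTVolume, *, window: WindowConfig | None = None, correct_tilt: bool = True
) -> tuple[CTVolume, float]:
    """Tilt-correct (on HU) and window a raw volume; returns (volume, angle)."""
    angle = 0.0
    if correct_tilt:
        volume, angle = correct_midline_rotation(volume)
    return window_normalize(volume, window), angle


def slice_stacks(
    volume: CTVolume,
    sizes: tuple[int, ...] = (DETECT_SIZE, MEASURE_SIZE),
    *,
    rotate_deg: float = 0.0,
) -> dict[int, np.ndarray]:
    """Standardize every slice to 224 x 224, then downsample to each size.

    Returns ``{size: (n_slices, size, size) float32 in [0, 1]}``.  The
    volume must already be windowed (0-255 intensities).  ``rotate_deg``
    applies the tilt correction at the 224 x 224 stage, which is equivalent
    to rotating the full-resolution volume up to interpolation error but an
    order of magnitude cheaper.
    """
    out = {s: np.empty((volume.n_slices, s, s), dtype=np.float32) for s in sizes}
    for z in range(volume.n_slices):
        std = standardize_for_model(volume.voxels[z], volume.pixel_spacing[1])
        img = std.image
        if abs(rotate_deg) > 1e-9:
            img = ndimage.rotate(img, -rotate_deg, reshape=False, order=1, mode="nearest")
        img = img / 255.0
        for s in sizes:
            # anti-aliased decimation turns sub-pixel CSF widths into a
            # graded intensity signal instead of aliasing them away
            out[s][z] = resize(img, (s, s), order=1, anti_aliasing=True, preserve_range=True)
    return out


@dataclass
class SubjectData:
    """Downsampled slice stacks plus annotations for one training subject."""

    subject_id: str
    stacks: dict[int, np.ndarray]
    fov_mm: float  # in-plane field of view; mm targets are normalized by it
    key_slices: KeySliceSet | None = None
    measurements: MeasurementSet | None = None
    sulci_enlarged: bool | None = None
    atrophy_class: str | None = None
    age: float | None = None
    gender_code: int | None = None
    estimated_tilt_deg: float = 0.0
    extras: dict = field(default_factory=dict)

    @property
    def n_slices(self) -> int:
        return next(iter(self.stacks.values())).shape[0]


def prepare_subject(
    subject_id: str,
    volume: CTVolume,
    annotation: GroundTruthAnnotation | None = None,
    *,
    age: float | None = None,
    gender_code: int | None = None,
    sizes: tuple[int, ...] = (DETECT_SIZE, MEASURE_SIZE),
    correct_tilt: bool = True,
    window: WindowConfig | None = None,
) -> SubjectData:
    """Run the standard pre-processing chain and package the result.

    Tilt is estimated on the raw volume; the rotation itself is applied at
    the standardized 224 x 224 stage (see :func:`slice_stacks`).
    """
    angle = estimate_head_tilt(volume) if correct_tilt else 0.0
    windowed = window_normalize(volume, window)
    stacks = slice_stacks(windowed, sizes, rotate_deg=angle)
    data = SubjectData(
        subject_id=subject_id,
        stacks=stacks,
        fov_mm=volume.pixel_spacing[1] * volume.voxels.shape[2],
        age=age,
        gender_code=gender_code,
        estimated_tilt_deg=angle,
    )
    if annotation is not None:
        data.key_slices = annotation.key_slices
        data.measurements = annotation.measurements
        data.sulci_enlarged = annotation.sulci_enlarged
        data.atrophy_class = annotation.atrophy_class
    return data


def fused_channels(stack: np.ndarray, slice_index: int) -> np.ndarray:
    """Three-channel fusion (z-1, z, z+1) with edge-slice duplication."""
    n = stack.shape[0]
    if not 0 <= slice_index < n:
        raise IndexError(f"slice index {slice_index} outside volume of {n} slices")
    idx = [max(0, slice_index - 1), slice_index, min(n - 1, slice_index + 1)]
    return stack[idx]
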