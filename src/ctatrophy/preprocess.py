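"""Image normalization and geometry correction for head CT.

Implements the pipeline's pre-processing: HU windowing to 0-255 (default
brain window WW = 80 HU, WL = 40 HU), estimation and correction of in-plane
head tilt so the brain midline is vertical, resampling of slices to the
224 x 224 model input size, and the training-time augmentations (small
rotation, shift, zoom, left-right flip, Gaussian noise).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .phantom import CTVolume

__all__ = [
    "WindowConfig",
    "AugmentConfig",
    "StandardizedSlice",
    "window_normalize",
    "estimate_head_tilt",
    "correct_midline_rotation",
    "standardize_for_model",
    "augment",
]

MODEL_SIZE = 224
BONE_HU = 300.0


@dataclass(frozen=True)
class WindowConfig:
    """CT display window: level (center) and width, in HU."""

    window_width_WW: float = 80.0
    window_level_WL: float = 40.0

    def __post_init__(self) -> None:
        if self.window_width_WW <= 0:
            raise ValueError("window width WW must be > 0")


@dataclass(frozen=True)
class AugmentConfig:
    max_rotation_deg: float = 5.0
    max_shift_frac: float = 0.05
    zoom_range: tuple[float, float] = (0.95, 1.05)
    allow_lr_flip: bool = True
    gaussian_noise_sd: float = 5.0  # on the 0-255 intensity scale
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.zoom_range[0] <= 1.0 <= self.zoom_range[1]):
            raise ValueError("zoom_range must bracket 1.0")


def window_normalize(volume: CTVolume, cfg: WindowConfig | None = None) -> CTVolume:
    """Map HU linearly from [WL - WW/2, WL + WW/2] onto integers 0-255.

    Values outside the window are clamped; rounding is half-up, so the
    window center WL maps to 128.  Spacing metadata is preserved.
    """
    cfg = cfg or WindowConfig()
    hu = np.asarray(volume.voxels, dtype=np.float32)
    if not np.all(np.isfinite(hu)):
        raise ValueError("volume contains non-finite HU values")
    lo = np.float32(cfg.window_level_WL - cfg.window_width_WW / 2.0)
    frac = (hu - lo) * np.float32(255.0 / cfg.window_width_WW)
    np.clip(frac, 0.0, 255.0, out=frac)
    frac += np.float32(0.5)
    out = np.floor(frac, out=frac)  # round half-up
    return replace(volume, voxels=out.astype(np.uint8))


# ------------------------------------------------------------- tilt estimation
def estimate_head_tilt(
    volume: CTVolume,
    *,
    refine: bool = True,
    bone_hu: float = BONE_HU,
) -> float:
    """Estimate the in-plane head tilt (degrees) from the skull ring.

    The principal axis of the bone mask on the mid-stack slice gives the
    anteroposterior head axis; its deviation from vertical is the tilt.  The
    estimate is optionally refined by maximizing left-right overlap of the
    mirrored head mask over a fine angular grid.
    """
    mid = volume.voxels[volume.n_slices // 2]
    mask = np.asarray(mid, dtype=np.float64) >= bone_hu
    if not mask.any():
        raise ValueError("no skull voxels above the bone threshold: not a head image")
    r, c = np.nonzero(mask)
    x = c - c.mean()
    y = -(r - r.mean())  # y grows toward the anterior (up)
    cov = np.cov(np.stack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]  # major (anteroposterior) axis
    if v[1] < 0:
        v = -v
    angle = float(np.degrees(np.arctan2(-v[0], v[1])))

    if refine:
        angle = _refine_by_mirror_symmetry(volume, angle)
    return angle


def _refine_by_mirror_symmetry(volume: CTVolume, angle: float) -> float:
    """Refine a tilt estimate by maximizing left-right overlap of the
    mirrored ventricular CSF mask on the slice where CSF is most abundant.

    The thin, midline-symmetric ventricles give a much sharper angular
    optimum than the nearly elliptical head outline.  Falls back to the
    input estimate if no CSF-attenuation voxels are found.
    """
    hu = np.asarray(volume.voxels)
    csf = (hu > -100.0) & (hu < 21.5)
    per_slice = csf.reshape(csf.shape[0], -1).sum(axis=1)
    if per_slice.max() < 20:
        return angle
    sl = csf[int(np.argmax(per_slice))].astype(np.float32)
    # crop to a centered window covering the ventricular system
    n = sl.shape[0]
    lo, hi = max(0, n // 2 - 128), min(n, n // 2 + 128)
    sl = sl[lo:hi, lo:hi]
    best, best_score = angle, -np.inf
    for cand in np.arange(angle - 0.5, angle + 0.5 + 1e-9, 0.05):
        rot = ndimage.rotate(sl, -cand, reshape=False, order=1, mode="constant")
        score = float((rot * rot[:, ::-1]).sum())
        if score > best_score + 1e-9:
            best, best_score = float(cand), score
    return best


def correct_midline_rotation(
    volume: CTVolume, *, refine: bool = True
) -> tuple[CTVolume, float]:
    """Rotate all slices so the brain midline is vertical.

    Returns the corrected volume and the estimated tilt in degrees (the
    rigid rotation applied is the negative of the estimate).
    """
    angle = estimate_head_tilt(volume, refine=refine)
    if abs(angle) < 1e-6:
        return volume, angle
    fill = float(np.min(volume.voxels))
    rotated = ndimage.rotate(
        np.asarray(volume.voxels, dtype=np.float32),
        -angle,
        axes=(1, 2),
        reshape=False,
        order=1,
        mode="constant",
        cval=fill,
    )
    return replace(volume, voxels=rotated), angle


# --------------------------------------------------------------- model input
@dataclass(frozen=True)
class StandardizedSlice:
    """A model-input slice with its effective mm-per-pixel scale."""

    image: np.ndarray  # (224, 224) float32
    mm_per_px: float


def standardize_for_model(
    slice_image: np.ndarray,
    mm_per_px_in: float = 1.0,
    *,
    size: int = MODEL_SIZE,
    anti_aliasing: bool = True,
) -> StandardizedSlice:
    """Resample a 2-D slice to the model input size (default 224 x 224).

    Records the effective mm-per-pixel after resampling so pixel-unit model
    outputs can be converted back to millimetres.
    """
    img = np.asarray(slice_image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D slice image, got shape {img.shape}")
    if min(img.shape) < 2:
        raise ValueError("slice image sides must be >= 2")
    out = resize(
        img.astype(np.float32),
        (size, size),
        order=1,
        anti_aliasing=anti_aliasing,
        preserve_range=True,
    ).astype(np.float32)
    scale = float(mm_per_px_in) * img.shape[1] / size
    return StandardizedSlice(image=out, mm_per_px=scale)


# ---------------------------------------------------------------- augmentation
def augment(
    slice_image: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator | None = None,
    *,
    force_flip: bool | None = None,
) -> np.ndarray:
    """Apply the training-time augmentations with independent random draws.

    Rotation within +-max_rotation_deg, shift within +-max_shift_frac of the
    image size, zoom within zoom_range, left-right flip with probability 0.5
    (if allowed), then additive Gaussian noise.  A degenerate config (all
    magnitudes zero, flip off) is the identity.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    img = np.asarray(slice_image, dtype=np.float32)

    if cfg.max_rotation_deg > 0:
        ang = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
        img = ndimage.rotate(img, ang, reshape=False, order=1, mode="nearest")
    if cfg.max_shift_frac > 0:
        dy = rng.uniform(-cfg.max_shift_frac, cfg.max_shift_frac) * img.shape[0]
        dx = rng.uniform(-cfg.max_shift_frac, cfg.max_shift_frac) * img.shape[1]
        img = ndimage.shift(img, (dy, dx), order=1, mode="nearest")
    if cfg.zoom_range != (1.0, 1.0):
        z = rng.uniform(*cfg.zoom_range)
        center = (np.array(img.shape) - 1) / 2.0
        matrix = np.eye(2) / z
        offset = center - matrix @ center
        img = ndimage.affine_transform(img, matrix, offset=offset, order=1, mode="nearest")
    if cfg.allow_lr_flip:
        do_flip = force_flip if force_flip is not None else bool(rng.uniform() < 0.5)
        if do_flip:
            img = img[:, ::-1].copy()
    if cfg.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.gaussian_noise_sd, size=img.shape).astype(np.float32)
    return img
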