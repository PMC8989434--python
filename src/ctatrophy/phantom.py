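"""Synthetic head-CT phantoms with analytically known atrophy geometry.

The generator emulates the anatomy that the linear-measurement pipeline
quantifies on axial non-contrast CT: a high-attenuation skull ring, brain
parenchyma, CSF-attenuation lateral and third ventricles, Sylvian fissures,
choroid-plexus calcifications and parietal sulci.  Every structure's width
along its measurement line is set directly from a :class:`PhantomSpec`, so
rendered volumes come with exact ground truth for the nine linear
measurements (A, B, C, D, E, F, G, HL, HR), the four key slices and the
ordinal atrophy class.

Atrophy classes follow the clinical label rules: *severe* atrophy requires a
markedly widened third ventricle and Sylvian fissures together with at least
two parietal sulci wider than 5 mm; *no atrophy* requires all of these in
the normal range; everything in between is *mild*.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CLASSES",
    "PhantomSpec",
    "CTVolume",
    "KeySliceSet",
    "MeasurementSet",
    "GroundTruthAnnotation",
    "sample_phantom_spec",
    "classify_spec",
    "render_volume",
    "generate_dataset",
    "load_volume",
    "load_annotation",
    "pixel_count_measurements",
]

CLASSES = ("no_atrophy", "mild", "severe")

# Attenuation (HU) of the rendered tissues
HU_AIR = -1000.0
HU_CSF = 8.0
HU_PARENCHYMA = 35.0
HU_SKULL = 1000.0
HU_CHOROID = 150.0  # calcified choroid plexus

# Default acquisition geometry: 512 x 512 matrix, 5 mm reconstruction
N_SLICES = 40
MATRIX = 512
PIXEL_SPACING = 0.45  # mm
SLICE_THICKNESS = 5.0  # mm
HEAD_ELONGATION = 1.25  # anteroposterior / transverse semi-axis ratio

# Sulci-enlargement label rule: at least 2 parietal sulci wider than 5 mm
SULCUS_WIDTH_MM = 5.0
SULCUS_MIN_COUNT = 2
# Decision boundaries separating the class-conditional sampling ranges
_C_NORMAL_MAX = 6.25
_C_SEVERE_MIN = 8.75
_SYLVIAN_NORMAL_MAX = 5.15
_SYLVIAN_SEVERE_MIN = 6.85


# --------------------------------------------------------------------- types
@dataclass
class KeySliceSet:
    """Indices (0-based, inferior-to-superior) of the four key slices."""

    key1: int  # basal ganglia: caudate heads, third ventricle
    key2: int  # body of the lateral ventricles
    key3: int  # clearest Sylvian fissures
    key4: int  # third slice above the top of the lateral ventricles

    def validate(self, n_slices: int | None = None) -> None:
        if not (0 <= self.key1 <= self.key2 < self.key4):
            raise ValueError(f"key-slice ordering violated: {self}")
        if self.key3 < 0:
            raise ValueError(f"negative key slice index: {self}")
        if n_slices is not None:
            for v in (self.key1, self.key2, self.key3, self.key4):
                if v >= n_slices:
                    raise ValueError(f"key slice {v} outside volume of {n_slices} slices")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.key1, self.key2, self.key3, self.key4)


@dataclass
class MeasurementSet:
    """The nine linear measurements, in millimetres."""

    A: float  # maximal frontal horn width          (key slice 1)
    B: float  # minimal intercaudate distance       (key slice 1)
    C: float  # maximal third-ventricle width       (key slice 1)
    D: float  # choroid-plexus distance             (key slice 1)
    E: float  # minimal ventricular body width      (key slice 2)
    F: float  # maximal transverse intracranial width  (key slice 2)
    G: float  # maximal transverse extracranial width  (key slice 2)
    HL: float  # maximal left Sylvian fissure width  (key slice 3)
    HR: float  # maximal right Sylvian fissure width (key slice 3)

    NAMES = ("A", "B", "C", "D", "E", "F", "G", "HL", "HR")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.NAMES], dtype=float)

    def validate(self) -> None:
        for n in self.NAMES:
            if not getattr(self, n) > 0:
                raise ValueError(f"measurement {n} must be positive")
        if not self.F > self.E:
            raise ValueError("intracranial width F must exceed ventricular width E")


@dataclass
class PhantomSpec:
    """Ground-truth geometry, demographics and label for one synthetic subject."""

    atrophy_class: str
    frontal_horn_width_A: float
    intercaudate_distance_B: float
    third_ventricle_width_C: float
    choroid_plexus_distance_D: float
    ventricular_body_width_E: float
    intracranial_width_F: float
    extracranial_width_G: float
    sylvian_width_left_HL: float
    sylvian_width_right_HR: float
    parietal_sulci_widths: list[float]
    head_tilt_deg: float
    age: float
    gender_code: int  # 0 = female, 1 = male
    seed: int

    def validate(self) -> None:
        if self.atrophy_class not in CLASSES:
            raise ValueError(
                f"unknown atrophy class {self.atrophy_class!r}; allowed: {CLASSES}"
            )
        m = self.measurements()
        m.validate()
        if not self.choroid_plexus_distance_D > self.intercaudate_distance_B:
            raise ValueError("choroid-plexus distance D must exceed intercaudate B")
        if len(self.parietal_sulci_widths) < 3:
            raise ValueError("at least 3 parietal sulci are required")
        if any(w <= 0 for w in self.parietal_sulci_widths):
            raise ValueError("sulci widths must be positive")
        if abs(self.head_tilt_deg) > 10:
            raise ValueError("|head tilt| must be <= 10 degrees")
        if classify_spec(self) != self.atrophy_class:
            raise ValueError("geometry inconsistent with stored atrophy class")

    def measurements(self) -> MeasurementSet:
        return MeasurementSet(
            A=self.frontal_horn_width_A,
            B=self.intercaudate_distance_B,
            C=self.third_ventricle_width_C,
            D=self.choroid_plexus_distance_D,
            E=self.ventricular_body_width_E,
            F=self.intracranial_width_F,
            G=self.extracranial_width_G,
            HL=self.sylvian_width_left_HL,
            HR=self.sylvian_width_right_HR,
        )


@dataclass
class CTVolume:
    """Axial voxel grid in Hounsfield units with spacing metadata.

    ``voxels`` is ordered (slices, rows, cols); slice 0 is the most inferior.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]  # (row, col) mm/pixel
    slice_thickness: float  # mm

    def validate(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array (slices, rows, cols)")
        vmin, vmax = float(self.voxels.min()), float(self.voxels.max())
        if vmin < -1024 or vmax > 3071:
            raise ValueError(f"HU values outside [-1024, 3071]: [{vmin}, {vmax}]")
        if min(self.pixel_spacing) <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacing must be strictly positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class GroundTruthAnnotation:
    key_slices: KeySliceSet
    measurements: MeasurementSet
    sulci_enlarged: bool
    atrophy_class: str
    top_ventricle_slice: int
    parietal_sulci_widths: list[float] = field(default_factory=list)
    head_tilt_deg: float = 0.0

    def to_dict(self) -> dict:
        return {
            "key_slices": asdict(self.key_slices),
            "measurements": asdict(self.measurements),
            "sulci_enlarged": bool(self.sulci_enlarged),
            "atrophy_class": self.atrophy_class,
            "top_ventricle_slice": int(self.top_ventricle_slice),
            "parietal_sulci_widths": [float(w) for w in self.parietal_sulci_widths],
            "head_tilt_deg": float(self.head_tilt_deg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthAnnotation":
        return cls(
            key_slices=KeySliceSet(**d["key_slices"]),
            measurements=MeasurementSet(**d["measurements"]),
            sulci_enlarged=bool(d["sulci_enlarged"]),
            atrophy_class=d["atrophy_class"],
            top_ventricle_slice=int(d["top_ventricle_slice"]),
            parietal_sulci_widths=list(d.get("parietal_sulci_widths", [])),
            head_tilt_deg=float(d.get("head_tilt_deg", 0.0)),
        )


# ----------------------------------------------------------------- label rule
def sulci_count_enlarged(widths) -> int:
    return int(sum(1 for w in widths if w > SULCUS_WIDTH_MM))


def classify_spec(spec: PhantomSpec) -> str:
    """Apply the atrophy label rules to a spec's geometry.

    Severe atrophy = enlarged ventricular system (third ventricle) together
    with widened Sylvian fissures and at least two parietal sulci > 5 mm.
    No atrophy = all three in the normal range.  Everything else is mild.
    """
    c = spec.third_ventricle_width_C
    syl_min = min(spec.sylvian_width_left_HL, spec.sylvian_width_right_HR)
    syl_max = max(spec.sylvian_width_left_HL, spec.sylvian_width_right_HR)
    enlarged = sulci_count_enlarged(spec.parietal_sulci_widths) >= SULCUS_MIN_COUNT
    if enlarged and c > _C_SEVERE_MIN and syl_min > _SYLVIAN_SEVERE_MIN:
        return "severe"
    if (
        c <= _C_NORMAL_MAX
        and syl_max <= _SYLVIAN_NORMAL_MAX
        and all(w <= SULCUS_WIDTH_MM for w in spec.parietal_sulci_widths)
    ):
        return "no_atrophy"
    return "mild"


# ------------------------------------------------------------------ sampling
_N_SULCI = 4
_AGE = {  # (mean, sd, low, high) per class, ordered young -> old
    "no_atrophy": (53.0, 8.0, 40.0, 67.0),
    "mild": (72.0, 10.0, 44.0, 94.0),
    "severe": (80.0, 8.0, 60.0, 99.0),
}
_MALE_FRACTION = {"no_atrophy": 0.449, "mild": 0.519, "severe": 0.415}


def sample_phantom_spec(atrophy_class: str, rng_seed: int) -> PhantomSpec:
    """Draw a spec from the class-conditional geometry distribution.

    Identical ``(atrophy_class, rng_seed)`` pairs return identical specs.
    """
    if atrophy_class not in CLASSES:
        raise ValueError(
            f"unknown atrophy class {atrophy_class!r}; allowed: {CLASSES}"
        )
    rng = np.random.default_rng(rng_seed)
    # skull geometry is class-independent
    f_width = rng.uniform(118.0, 132.0)
    g_width = f_width + 2.0 * rng.uniform(7.0, 10.0)

    base_a = rng.uniform(32.0, 40.0)
    base_b = rng.uniform(15.0, 21.0)
    base_d = rng.uniform(46.0, 58.0)
    base_e = rng.uniform(28.0, 36.0)

    if atrophy_class == "no_atrophy":
        vent_scale, d_scale = 1.0, 1.0
        c = rng.uniform(2.0, 6.0)
        hl, hr = rng.uniform(2.0, 5.0, size=2)
        sulci = list(rng.uniform(1.0, 4.0, size=_N_SULCI))
    elif atrophy_class == "mild":
        vent_scale = rng.uniform(1.1, 1.3)
        d_scale = rng.uniform(1.0, 1.15)
        c = rng.uniform(6.5, 8.5)
        hl, hr = rng.uniform(5.3, 6.7, size=2)
        sulci = list(rng.uniform(2.0, 5.0, size=_N_SULCI))
        if rng.uniform() < 0.25:  # at most one widened sulcus: still not "enlarged"
            sulci[int(rng.integers(_N_SULCI))] = rng.uniform(5.05, 6.0)
    else:  # severe
        vent_scale = rng.uniform(1.3, 1.6)
        d_scale = rng.uniform(1.1, 1.25)
        c = rng.uniform(9.0, 14.0)
        hl, hr = rng.uniform(7.0, 12.0, size=2)
        sulci = list(rng.uniform(2.0, 5.0, size=_N_SULCI))
        n_wide = int(rng.integers(SULCUS_MIN_COUNT, _N_SULCI + 1))
        for i in rng.choice(_N_SULCI, size=n_wide, replace=False):
            sulci[int(i)] = rng.uniform(5.5, 9.0)

    mean, sd, lo, hi = _AGE[atrophy_class]
    spec = PhantomSpec(
        atrophy_class=atrophy_class,
        frontal_horn_width_A=base_a * vent_scale,
        intercaudate_distance_B=base_b * vent_scale,
        third_ventricle_width_C=c,
        choroid_plexus_distance_D=base_d * d_scale,
        ventricular_body_width_E=base_e * vent_scale,
        intracranial_width_F=f_width,
        extracranial_width_G=g_width,
        sylvian_width_left_HL=hl,
        sylvian_width_right_HR=hr,
        parietal_sulci_widths=[float(w) for w in sulci],
        head_tilt_deg=float(rng.uniform(-8.0, 8.0)),
        age=float(np.clip(rng.normal(mean, sd), lo, hi)),
        gender_code=int(rng.uniform() < _MALE_FRACTION[atrophy_class]),
        seed=int(rng_seed),
    )
    spec.validate()
    return spec


# ----------------------------------------------------------------- rendering
def _key_slice_layout(rng: np.random.Generator) -> tuple[KeySliceSet, int]:
    """Jittered axial placement of the key levels within a 40-slice stack."""
    key1 = 12 + int(rng.integers(0, 4))
    key3 = key1 - 2 - int(rng.integers(0, 2))
    key2 = key1 + int(rng.integers(3, 6))
    z_top = key2 + int(rng.integers(2, 5))
    key4 = z_top + 3  # third slice above the lateral-ventricle top
    return KeySliceSet(key1=key1, key2=key2, key3=key3, key4=key4), z_top


def render_volume(
    spec: PhantomSpec,
    *,
    n_slices: int = N_SLICES,
    matrix: int = MATRIX,
    pixel_spacing: float = PIXEL_SPACING,
    slice_thickness: float = SLICE_THICKNESS,
    noise_sd: float = 2.0,
) -> tuple[CTVolume, GroundTruthAnnotation]:
    """Render a spec into a HU volume plus its exact annotation.

    All in-plane structures are drawn in head coordinates that are rotated by
    ``spec.head_tilt_deg``, so widths along the (tilted) measurement lines
    equal the spec values to within one pixel spacing.
    """
    spec.validate()
    fov = matrix * pixel_spacing
    if spec.extracranial_width_G * HEAD_ELONGATION >= fov - 10.0:
        raise ValueError(
            f"head size {spec.extracranial_width_G:.1f} mm exceeds the "
            f"{fov:.1f} mm field of view"
        )
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 0x5EED])
    key_slices, z_top = _key_slice_layout(rng)

    half = (matrix - 1) / 2.0
    cols = (np.arange(matrix) - half) * pixel_spacing
    rows = (half - np.arange(matrix)) * pixel_spacing
    x_img, y_img = np.meshgrid(cols, rows)  # x right, y anterior (up)
    th = np.deg2rad(spec.head_tilt_deg)
    # head-frame coordinates of every pixel
    xh = np.cos(th) * x_img + np.sin(th) * y_img
    yh = -np.sin(th) * x_img + np.cos(th) * y_img

    rx_out, ry_out = spec.extracranial_width_G / 2.0, spec.extracranial_width_G * HEAD_ELONGATION / 2.0
    rx_in, ry_in = spec.intracranial_width_F / 2.0, spec.intracranial_width_F * HEAD_ELONGATION / 2.0
    outer = (xh / rx_out) ** 2 + (yh / ry_out) ** 2 <= 1.0
    inner = (xh / rx_in) ** 2 + (yh / ry_in) ** 2 <= 1.0

    def rect(x_lo, x_hi, y_lo, y_hi):
        return (xh >= x_lo) & (xh <= x_hi) & (yh >= y_lo) & (yh <= y_hi)

    def disc(cx, cy, r):
        return (xh - cx) ** 2 + (yh - cy) ** 2 <= r**2

    m = spec.measurements()
    z_brain_lo, z_brain_hi = 3, min(36, n_slices - 1)
    vol = np.full((n_slices, matrix, matrix), HU_AIR, dtype=np.float32)
    k1, k2, k3, k4 = key_slices.as_tuple()

    base = np.full((matrix, matrix), HU_AIR, dtype=np.float32)
    base[outer] = HU_SKULL
    base[inner] = HU_PARENCHYMA

    for z in range(z_brain_lo, z_brain_hi + 1):
        has_structure = (
            abs(z - k1) <= 1
            or k1 < z <= z_top
            or abs(z - k3) <= 1
            or z_top < z <= min(k4 + 2, z_brain_hi)
        )
        if not has_structure:
            vol[z] = base
            continue
        sl = base.copy()
        csf = np.zeros((matrix, matrix), dtype=bool)

        # -- basal-ganglia level: frontal horns, third ventricle, choroid
        if abs(z - k1) <= 1:
            s = 1.0 if z == k1 else 0.65
            h_fh = 14.0 * s
            csf |= rect(m.B / 2.0, m.A / 2.0, 16.0, 16.0 + h_fh)
            csf |= rect(-m.A / 2.0, -m.B / 2.0, 16.0, 16.0 + h_fh)
            csf |= rect(-m.C / 2.0, m.C / 2.0, -2.0 - 14.0 * s, -2.0)
        # -- lateral-ventricle bodies between the basal ganglia and the top
        if k1 < z <= z_top:
            if z == k2:
                w = 1.0
            elif z < k2:
                w = 0.85
            else:
                w = 1.0 - 0.55 * (z - k2) / max(1, z_top - k2)
            sy = 1.0 if z == k2 else 0.85
            x_out = m.E / 2.0 * w
            x_in = max(2.0, x_out - max(5.0, 0.18 * m.E))
            csf |= rect(x_in, x_out, -22.0 * sy, 12.0 * sy)
            csf |= rect(-x_out, -x_in, -22.0 * sy, 12.0 * sy)
        # -- Sylvian-fissure level
        if abs(z - k3) <= 1:
            length = 22.0 if z == k3 else 12.0
            x_edge = spec.intracranial_width_F / 2.0 - 4.0
            csf |= rect(-x_edge, -x_edge + length, 6.0 - m.HL / 2.0, 6.0 + m.HL / 2.0)
            csf |= rect(x_edge - length, x_edge, 6.0 - m.HR / 2.0, 6.0 + m.HR / 2.0)
        # -- supraventricular parietal sulci
        if z_top < z <= min(k4 + 2, z_brain_hi):
            s4 = 1.0 if z == k4 else 0.7
            centers = (-33.0, -11.0, 11.0, 33.0)
            for cx, w_s in zip(centers, spec.parietal_sulci_widths):
                csf |= rect(cx - w_s / 2.0, cx + w_s / 2.0, -28.0 - 22.0 * s4, -28.0)

        sl[csf & inner] = HU_CSF
        if abs(z - k1) <= 1:
            r_marker = 2.5 if z == k1 else 1.8
            marker = disc(-m.D / 2.0, -26.0, r_marker) | disc(m.D / 2.0, -26.0, r_marker)
            sl[marker & inner] = HU_CHOROID
        vol[z] = sl

    if noise_sd > 0:
        vol += noise_sd * rng.standard_normal(size=vol.shape, dtype=np.float32)
    np.clip(vol, -1024.0, 3071.0, out=vol)

    volume = CTVolume(
        voxels=vol,
        pixel_spacing=(pixel_spacing, pixel_spacing),
        slice_thickness=slice_thickness,
    )
    annotation = GroundTruthAnnotation(
        key_slices=key_slices,
        measurements=m,
        sulci_enlarged=sulci_count_enlarged(spec.parietal_sulci_widths) >= SULCUS_MIN_COUNT,
        atrophy_class=spec.atrophy_class,
        top_ventricle_slice=z_top,
        parietal_sulci_widths=list(spec.parietal_sulci_widths),
        head_tilt_deg=spec.head_tilt_deg,
    )
    return volume, annotation


# ------------------------------------------------- pixel-count oracle measure
def pixel_count_measurements(
    volume: CTVolume, annotation: GroundTruthAnnotation
) -> MeasurementSet:
    """Measure a rendered, untilted phantom by thresholding and pixel counting.

    Independent of both the renderer's stored ground truth and the learned
    regressors: CSF, bone and calcification are segmented by HU thresholds
    and widths are read off along the defined measurement lines.  Accurate to
    about one pixel spacing; requires ``head_tilt_deg`` close to 0.
    """
    sp = volume.pixel_spacing[1]
    matrix = volume.voxels.shape[1]
    half = (matrix - 1) / 2.0

    def row_of(y_mm: float) -> int:
        return int(round(half - y_mm / sp))

    def col_x(c: np.ndarray) -> np.ndarray:
        return (c - half) * sp

    def rows_between(y_lo, y_hi):
        return slice(row_of(y_hi), row_of(y_lo) + 1)  # row index grows downward

    def extent(mask) -> float:
        cidx = np.where(mask.any(axis=0))[0]
        return (cidx[-1] - cidx[0]) * sp + sp

    def gap(mask) -> float:
        cidx = np.where(mask.any(axis=0))[0]
        x = col_x(cidx)
        return float(x[x > 0].min() - x[x < 0].max() - sp)

    ks = annotation.key_slices
    csf1 = _csf_mask(volume.voxels[ks.key1])
    csf2 = _csf_mask(volume.voxels[ks.key2])
    csf3 = _csf_mask(volume.voxels[ks.key3])

    # key slice 1: frontal horns (A, B), third ventricle (C), choroid (D)
    horns = np.zeros_like(csf1)
    horns[rows_between(18.0, 26.0)] = csf1[rows_between(18.0, 26.0)]
    a = extent(horns)
    b = gap(horns)
    row = volume.voxels[ks.key1][row_of(-8.0)]
    cols = np.abs(col_x(np.arange(matrix))) <= 15.0
    c = float(np.count_nonzero(_csf_mask(row[None, :])[0] & cols)) * sp
    markers = volume.voxels[ks.key1] > 100.0
    lab, n_lab = ndimage.label(markers)
    if n_lab < 2:
        raise ValueError("choroid-plexus markers not found")
    coms = ndimage.center_of_mass(markers, lab, range(1, n_lab + 1))
    xs = sorted(col_x(np.array([cm[1] for cm in coms])))
    d = float(xs[-1] - xs[0])

    # key slice 2: ventricular bodies (E), skull widths (F, G)
    body = np.zeros_like(csf2)
    body[rows_between(-18.0, 8.0)] = csf2[rows_between(-18.0, 8.0)]
    e = extent(body)
    mid_row = volume.voxels[ks.key2][row_of(0.0)][None, :]
    skull = mid_row >= 500.0
    g = extent(skull)
    f = gap(skull)

    # key slice 3: Sylvian fissure widths as vertical CSF extent laterally
    def sylvian(side: int) -> float:
        xs_cols = col_x(np.arange(matrix))
        sel = (xs_cols * side >= 36.0) if side > 0 else (xs_cols <= -36.0)
        region = csf3[rows_between(-4.0, 16.0)][:, sel]
        ridx = np.where(region.any(axis=1))[0]
        return (ridx[-1] - ridx[0]) * sp + sp

    return MeasurementSet(A=a, B=b, C=c, D=d, E=e, F=f, G=g, HL=sylvian(-1), HR=sylvian(+1))


def pixel_count_sulci_widths(volume: CTVolume, annotation: GroundTruthAnnotation) -> list[float]:
    """Widths of the parietal sulci on key slice 4, by blob extent."""
    sp = volume.pixel_spacing[1]
    matrix = volume.voxels.shape[1]
    half = (matrix - 1) / 2.0
    csf4 = _csf_mask(volume.voxels[annotation.key_slices.key4])
    r_lo = int(round(half + 24.0 / sp))
    r_hi = int(round(half + 54.0 / sp))
    region = np.zeros_like(csf4)
    region[r_lo : r_hi + 1] = csf4[r_lo : r_hi + 1]
    lab, n_lab = ndimage.label(region)
    widths = []
    for i in range(1, n_lab + 1):
        cidx = np.where((lab == i).any(axis=0))[0]
        widths.append(float((cidx[-1] - cidx[0]) * sp + sp))
    return sorted(widths)


def _csf_mask(hu: np.ndarray) -> np.ndarray:
    return (hu > -100.0) & (hu < 21.5)  # CSF ~8 HU vs parenchyma ~35 HU


# -------------------------------------------------------------------- dataset
def dataset_specs(n_per_class: int, rng_seed: int) -> list[tuple[str, PhantomSpec]]:
    """The (subject_id, spec) sequence underlying :func:`generate_dataset`.

    Exposed so that desk-scale experiments can work with in-memory phantoms
    while remaining byte-for-byte consistent with the on-disk dataset writer.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out = []
    idx = 0
    for cls in CLASSES:
        for _ in range(n_per_class):
            seed = (int(rng_seed) * 1_000_003 + idx) % (2**31)
            out.append((f"phantom_{idx:04d}", sample_phantom_spec(cls, seed)))
            idx += 1
    return out


def generate_dataset(
    n_per_class: int,
    rng_seed: int,
    out_dir: str | Path,
    *,
    noise_sd: float = 2.0,
) -> pd.DataFrame:
    """Write a labeled phantom dataset (NIfTI volumes + JSON annotations).

    Returns the manifest, also written to ``out_dir/manifest.csv`` with
    columns subject_id, age, gender_code, atrophy_class, volume_path,
    annotation_path.  Fully reproducible given the seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}") from exc

    rows = []
    for sid, spec in dataset_specs(n_per_class, rng_seed):
        volume, annotation = render_volume(spec, noise_sd=noise_sd)
        vol_path = out_dir / f"{sid}.nii.gz"
        ann_path = out_dir / f"{sid}.json"
        save_volume(volume, vol_path)
        ann_path.write_text(
            json.dumps({"spec": asdict(spec), **annotation.to_dict()}, indent=1, sort_keys=True)
        )
        rows.append(
            {
                "subject_id": sid,
                "age": round(spec.age, 2),
                "gender_code": spec.gender_code,
                "atrophy_class": spec.atrophy_class,
                "volume_path": str(vol_path),
                "annotation_path": str(ann_path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def save_volume(volume: CTVolume, path: str | Path) -> None:
    affine = np.diag(
        [volume.slice_thickness, volume.pixel_spacing[0], volume.pixel_spacing[1], 1.0]
    )
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.int16), affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return CTVolume(
        voxels=np.asanyarray(img.dataobj).astype(np.float32),
        pixel_spacing=(float(zooms[1]), float(zooms[2])),
        slice_thickness=float(zooms[0]),
    )


def load_annotation(path: str | Path) -> GroundTruthAnnotation:
    return GroundTruthAnnotation.from_dict(json.loads(Path(path).read_text()))
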