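"""Voxel-based bone microanatomy: VOI placement, bone volume fraction
(BV/TV), model-independent mean trabecular thickness (Tb.Th), and
whole-diaphysis global compactness.

Thickness follows the sphere-fitting definition of Hildebrand &
Ruegsegger: the local thickness at a bone voxel is the diameter of the
largest sphere that fits entirely inside bone and contains the voxel.  It
is computed from the Euclidean distance transform through a sequence of
morphological openings with balls of decreasing radius, which realizes the
same definition without an explicit medial-axis step.

Coordinate convention: voxel indices are 0-based; VOI bounds are half-open.
Axis 0 is the stack (slice) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volumes import VoxelVolume

__all__ = [
    "VOISpec",
    "CapitulumLandmarks",
    "MicroanatomyRecord",
    "DiaphysisProfile",
    "binarize",
    "capitulum_voi_center",
    "bone_volume_fraction",
    "local_thickness_map",
    "mean_trabecular_thickness",
    "diaphysis_profile",
    "ExcludedSpecimenError",
    "UndefinedThicknessError",
]


class ExcludedSpecimenError(ValueError):
    """The VOI intersects the epiphyseal line; the specimen is excluded."""


class UndefinedThicknessError(ValueError):
    """No bone voxels in the VOI; thickness is undefined."""


@dataclass
class VOISpec:
    """Volume of interest: cube or sphere, extent in mm, fully inside the
    volume.  ``epiphyseal_line_present`` is a manual exclusion flag."""

    center: tuple[int, int, int]
    shape: str = "cube"
    extent: float = 1.0  # edge length (cube) or diameter (sphere), mm
    epiphyseal_line_present: bool = False

    def __post_init__(self):
        if self.shape not in ("cube", "sphere"):
            raise ValueError("VOI shape must be 'cube' or 'sphere'")
        if self.extent <= 0:
            raise ValueError("VOI extent must be positive")

    def mask(self, volume: VoxelVolume) -> np.ndarray:
        """Boolean VOI mask on the volume grid (raises if out of bounds)."""
        extent_vox = self.extent / volume.voxel_size
        dims = np.array(volume.grid.shape)
        c = np.asarray(self.center)
        if self.shape == "cube":
            e = int(round(extent_vox))
            lo = c - e // 2
            hi = lo + e
            if (lo < 0).any() or (hi > dims).any():
                raise IndexError("VOI extends outside the volume")
            m = np.zeros(volume.grid.shape, dtype=bool)
            m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
            return m
        r = extent_vox / 2.0
        if (c - r < -0.5).any() or (c + r > dims - 0.5).any():
            raise IndexError("VOI extends outside the volume")
        grids = np.ogrid[: dims[0], : dims[1], : dims[2]]
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        return d2 <= r * r


@dataclass
class CapitulumLandmarks:
    """Landmarks bounding the capitulum VOI-center construction.

    The proximodistal axis is z; x is mediolateral, y is anteroposterior.
    The rectangle is bounded laterally/medially in x (capitulum edge vs
    the maximal concavity of the anterior articular surface at the
    capitulum/trochlea junction) and anteriorly/posteriorly in y (capitulum
    edge vs the posterior maximal extension at the mediolateral middle).
    """

    proximal_z: float
    distal_z: float
    lateral_x: float
    medial_x: float
    anterior_y: float
    posterior_y: float


@dataclass
class MicroanatomyRecord:
    """Per-specimen quantitative summary."""

    bvtv: float | None = None
    mean_tbth: float | None = None  # mm
    mean_global_compactness: float | None = None
    mean_cross_sectional_area: float | None = None  # mm^2
    specimen: str = ""


@dataclass
class DiaphysisProfile:
    """Per-slice compactness / total cross-sectional area plus means."""

    slice_index: np.ndarray
    compactness: np.ndarray
    total_area: np.ndarray  # mm^2
    empty_slices: np.ndarray  # indices flagged (no bone), excluded from means
    mean_global_compactness: float = field(default=np.nan)
    mean_total_area: float = field(default=np.nan)


def binarize(volume: VoxelVolume, threshold: float | str = "otsu") -> VoxelVolume:
    """Threshold a grayscale volume; voxels >= threshold are bone.

    ``threshold="otsu"`` maximizes the between-class variance of the
    grayscale histogram; a numeric threshold must lie within the observed
    grayscale range.
    """
    if volume.binary:
        raise ValueError("volume is already binary")
    grid = np.asarray(volume.grid)
    lo, hi = float(grid.min()), float(grid.max())
    if threshold == "otsu":
        if lo == hi:
            raise ValueError("constant volume: histogram carries no contrast")
        thr = float(threshold_otsu(grid))
    else:
        thr = float(threshold)
        if not lo <= thr <= hi:
            raise ValueError(
                f"threshold {thr} outside grayscale range [{lo}, {hi}]"
            )
    return VoxelVolume((grid >= thr).astype(np.uint8), volume.voxel_size, binary=True)


def capitulum_voi_center(landmarks: CapitulumLandmarks) -> tuple[float, float, float]:
    """Center of the capitulum VOI from articular landmarks.

    z is the midpoint of the proximodistal extremes; (x, y) is the center of
    the rectangle bounded laterally/anteriorly by the capitulum edges,
    medially by the articular concavity, and posteriorly by the maximal
    posterior extension at the mediolateral middle — evaluated in that
    order.
    """
    lm = landmarks
    if lm.lateral_x == lm.medial_x or lm.anterior_y == lm.posterior_y:
        raise ValueError("degenerate capitulum rectangle (zero width)")
    z = 0.5 * (lm.proximal_z + lm.distal_z)
    x = 0.5 * (lm.lateral_x + lm.medial_x)
    y = 0.5 * (lm.anterior_y + lm.posterior_y)
    return (x, y, z)


def bone_volume_fraction(volume: VoxelVolume, voi: VOISpec) -> float:
    """BV/TV: bone voxels in the VOI divided by total VOI voxels."""
    if voi.epiphyseal_line_present:
        raise ExcludedSpecimenError(
            "VOI comprises the epiphyseal line; specimen excluded"
        )
    mask = voi.mask(volume)
    bone = volume.bone_mask()
    total = int(mask.sum())
    if total == 0:
        raise ValueError("empty VOI")
    return float(bone[mask].sum() / total)


def local_thickness_map(mask: np.ndarray, max_radii: int = 48) -> np.ndarray:
    """Sphere-fitting local thickness (in voxels) for a binary mask.

    For each candidate radius r (descending), the morphological opening of
    the mask with a ball of radius r marks every voxel contained in some
    fully-inscribed ball of that radius; such voxels have local thickness
    at least 2r.  Radii are the distinct distance-transform values (capped
    at ``max_radii`` levels for large volumes).
    """
    mask = np.asarray(mask, dtype=bool)
    lt = np.zeros(mask.shape, dtype=float)
    if not mask.any():
        return lt
    edt = ndimage.distance_transform_edt(mask)
    radii = np.unique(edt[mask])
    if len(radii) > max_radii:
        qs = np.linspace(0.0, 1.0, max_radii)
        radii = np.unique(np.quantile(radii, qs))
    for r in radii[::-1]:
        seeds = edt >= r
        covered = ndimage.distance_transform_edt(~seeds) <= r
        update = mask & covered & (lt == 0.0)
        lt[update] = 2.0 * r
    return lt


def mean_trabecular_thickness(
    volume: VoxelVolume, voi: VOISpec | None = None
) -> float:
    """Mean Tb.Th in mm: mean of the local-thickness map over bone voxels
    (restricted to the VOI when one is given)."""
    bone = volume.bone_mask()
    if voi is not None:
        if voi.epiphyseal_line_present:
            raise ExcludedSpecimenError(
                "VOI comprises the epiphyseal line; specimen excluded"
            )
        region = voi.mask(volume)
        sub = bone & region
    else:
        sub = bone
    if not sub.any():
        raise UndefinedThicknessError("no bone voxels in the VOI")
    # thickness is computed on the full bone mask so struts crossing the
    # VOI boundary are not artificially truncated, then averaged inside it
    lt = local_thickness_map(bone)
    return float(lt[sub].mean() * volume.voxel_size)


def diaphysis_profile(
    volume: VoxelVolume,
    axis_slices: slice | None = None,
    closing_radius: int = 3,
) -> DiaphysisProfile:
    """Per-slice diaphyseal compactness and total cross-sectional area.

    For each transverse slice (axis 0), the total area is the area enclosed
    by the periosteal contour, recovered by a morphological closing (disk
    of ``closing_radius`` voxels, bridging nutrient foramina) followed by
    hole filling; compactness is bone area over total area.  Slices with no
    bone are flagged and excluded from the means.
    """
    bone = volume.bone_mask()
    n = bone.shape[0]
    sl = axis_slices if axis_slices is not None else slice(0, n)
    idx = np.arange(n)[sl]
    r = int(closing_radius)
    if r > 0:
        yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
        disk = xx * xx + yy * yy <= r * r
    else:
        disk = None

    comp, area, empty = [], [], []
    vs2 = volume.voxel_size**2
    for i in idx:
        plane = bone[i]
        nbone = int(plane.sum())
        if nbone == 0:
            empty.append(i)
            comp.append(np.nan)
            area.append(np.nan)
            continue
        if disk is not None:
            # pad so structures touching the image border survive the
            # erosion half of the closing
            padded = np.pad(plane, r)
            closed = ndimage.binary_closing(padded, structure=disk)[r:-r, r:-r]
        else:
            closed = plane
        filled = ndimage.binary_fill_holes(closed) | plane
        total = int(filled.sum())
        comp.append(nbone / total)
        area.append(total * vs2)

    comp_arr = np.asarray(comp)
    area_arr = np.asarray(area)
    ok = ~np.isnan(comp_arr)
    return DiaphysisProfile(
        slice_index=idx,
        compactness=comp_arr,
        total_area=area_arr,
        empty_slices=np.asarray(empty, dtype=int),
        mean_global_compactness=float(comp_arr[ok].mean()) if ok.any() else np.nan,
        mean_total_area=float(area_arr[ok].mean()) if ok.any() else np.nan,
    )
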