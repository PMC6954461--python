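"""Per-organ activity quantification from voxelized PET images.

Operates purely in voxel-index space on congruent grids: images and masks
must share one shape and spacing, as in a single-session study where all
volumes of interest are drawn on co-registered CT.  Activities come out in
MBq by mean-concentration x volume, with two study-specific estimators on
top: the kidney-spillover correction for the pancreas (the left-kidney mask
is dilated by a physical margin and the overlapped pancreatic voxels are
re-imputed from the clean remainder of the organ) and the homogeneous
remainder-of-body activity extrapolated from the scanned region to the
whole-body volume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .nucdata_phantoms import REMAINDER, TOTAL_BODY, RadionuclideData, canonical_organ

log = logging.getLogger(__name__)

SOFT_TISSUE_DENSITY_G_PER_ML = 1.05


@dataclass
class VoxelImage:
    """Activity-concentration grid in Bq/mL on an anisotropic voxel lattice."""

    grid: np.ndarray                      # Bq/mL, 3-D
    spacing_mm: tuple[float, float, float]
    acquisition_time_min: float
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("image grid must be 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive in every axis")
        negatives = int(np.count_nonzero(self.grid < 0))
        if negatives:
            log.warning("clipping %d negative voxels to 0 (reconstruction artifacts)", negatives)
            self.grid = np.clip(self.grid, 0.0, None)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass
class VOI:
    """Boolean organ mask congruent with a :class:`VoxelImage` grid."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"VOI {self.label!r} is empty")
        if canonical_organ(self.label) in (TOTAL_BODY, REMAINDER):
            raise ValueError(f"{self.label!r} is a reserved pseudo-organ id, not a VOI label")

    def volume_ml(self, image: VoxelImage) -> float:
        self._check(image)
        return float(self.mask.sum()) * image.voxel_volume_ml

    def _check(self, image: VoxelImage) -> None:
        if self.mask.shape != image.grid.shape:
            raise ValueError(f"VOI {self.label!r} shape {self.mask.shape} != image {image.grid.shape}")


@dataclass(frozen=True)
class ActivityMeasurement:
    organ: str
    t_min: float
    activity_mbq: float
    decay_corrected: bool


def organ_activity(image: VoxelImage, voi: VOI) -> ActivityMeasurement:
    """Mean concentration over the mask times the VOI volume, Bq -> MBq."""
    voi._check(image)
    mean_bq_per_ml = float(image.grid[voi.mask].mean())
    activity = mean_bq_per_ml * voi.volume_ml(image) / 1e6
    return ActivityMeasurement(voi.label, image.acquisition_time_min, activity, image.decay_corrected)


def _spherical_element(dilation_mm: float, spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """Ellipsoidal structuring element: a physical sphere in voxel units.

    Per-axis radii are the physical radius divided by the spacing, rounded to
    the nearest voxel (so anisotropic voxels keep the margin isotropic in mm).
    """
    radii = [int(round(dilation_mm / s)) for s in spacing_mm]
    if all(r == 0 for r in radii):
        return np.ones((1, 1, 1), dtype=bool)
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii)]
    norm = sum((g / max(r, 1)) ** 2 for g, r in zip(grids, radii))
    return norm <= 1.0 + 1e-9


def spillover_correct_pancreas(image: VoxelImage, pancreas: VOI, left_kidney: VOI,
                               dilation_mm: float = 9.0) -> ActivityMeasurement:
    """Pancreas activity with the kidney partial-volume spillover removed.

    The left-kidney mask is dilated by ``dilation_mm``; pancreatic voxels
    inside the dilated kidney are assumed contaminated and their uptake is
    replaced by the mean of the remaining pancreas, so the corrected activity
    is that clean mean times the *full* pancreas volume.
    """
    pancreas._check(image)
    left_kidney._check(image)
    if dilation_mm < 0:
        raise ValueError("dilation must be non-negative")
    element = _spherical_element(dilation_mm, image.spacing_mm)
    dilated = ndimage.binary_dilation(left_kidney.mask, structure=element)
    clean = pancreas.mask & ~dilated
    if not clean.any():
        raise ValueError("pancreas lies entirely inside the dilated kidney margin; "
                         "manual review of the VOIs is required")
    clean_mean_bq_per_ml = float(image.grid[clean].mean())
    activity = clean_mean_bq_per_ml * pancreas.volume_ml(image) / 1e6
    return ActivityMeasurement(pancreas.label, image.acquisition_time_min, activity,
                               image.decay_corrected)


def body_volume_ml(weight_kg: float, height_cm: float | None = None) -> float:
    """Total-body volume from body weight at soft-tissue density (1.05 g/mL).

    Height is accepted for provenance and logged but does not enter the
    default density rule.
    """
    if weight_kg <= 0:
        raise ValueError("body weight must be positive")
    if height_cm is not None:
        log.info("body_volume: height %.1f cm recorded (unused by the density rule)", height_cm)
    return weight_kg * 1000.0 / SOFT_TISSUE_DENSITY_G_PER_ML


def remainder_activity(image: VoxelImage, scanned_region: VOI, source_vois: list[VOI],
                       body_volume: float, injected_activity_mbq: float | None = None,
                       nuclide: RadionuclideData | None = None) -> ActivityMeasurement:
    """Remainder-of-body activity assuming a homogeneous distribution.

    Mean concentration over (scanned region minus all source organs) is
    extrapolated to the non-source body volume.  If the injected activity and
    nuclide are supplied, the implied total-body activity is capped at the
    physically decayed injected activity.
    """
    scanned_region._check(image)
    union_sources = np.zeros(image.grid.shape, dtype=bool)
    source_volume_ml = 0.0
    source_activity_mbq = 0.0
    for voi in source_vois:
        voi._check(image)
        union_sources |= voi.mask
        source_volume_ml += voi.volume_ml(image)
        source_activity_mbq += organ_activity(image, voi).activity_mbq
    background = scanned_region.mask & ~union_sources
    if not background.any():
        raise ValueError("scanned region minus source organs is empty")
    if body_volume < scanned_region.volume_ml(image):
        log.info("body volume (%.0f mL) smaller than scanned region (%.0f mL)",
                 body_volume, scanned_region.volume_ml(image))
    mean_bq_per_ml = float(image.grid[background].mean())
    activity = mean_bq_per_ml * max(body_volume - source_volume_ml, 0.0) / 1e6
    if injected_activity_mbq is not None:
        available = injected_activity_mbq
        if not image.decay_corrected:
            if nuclide is None:
                raise ValueError("nuclide required to decay the injected activity")
            available *= np.exp(-nuclide.decay_constant_per_min * image.acquisition_time_min)
        cap = max(available - source_activity_mbq, 0.0)
        if activity > cap:
            log.warning("remainder activity %.3f MBq exceeds available %.3f MBq; capping",
                        activity, cap)
            activity = cap
    return ActivityMeasurement("remainder", image.acquisition_time_min, activity,
                               image.decay_corrected)


# ---------------------------------------------------------------------------
# NIfTI / manifest I/O

def save_image_nifti(image: VoxelImage, path: str | Path) -> None:
    affine = np.diag([*image.spacing_mm, 1.0])
    img = nib.Nifti1Image(image.grid.astype(np.float32), affine)
    img.header["descrip"] = f"t={image.acquisition_time_min}min dc={int(image.decay_corrected)}".encode()
    nib.save(img, str(path))


def load_image_nifti(path: str | Path, acquisition_time_min: float,
                     decay_corrected: bool = True) -> VoxelImage:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelImage(np.asarray(img.dataobj, dtype=np.float64), spacing,
                      acquisition_time_min, decay_corrected)


def save_voi_nifti(voi: VOI, spacing_mm: tuple[float, float, float], path: str | Path) -> None:
    affine = np.diag([*spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(voi.mask.astype(np.uint8), affine), str(path))


def load_voi_nifti(path: str | Path, label: str) -> VOI:
    img = nib.load(str(path))
    return VOI(label, np.asarray(img.dataobj) > 0)


def save_voi_manifest(vois: dict[str, str | Path], path: str | Path) -> None:
    """Write a JSON manifest mapping organ label -> mask file name."""
    Path(path).write_text(json.dumps({k: str(v) for k, v in vois.items()},
                                     indent=2, sort_keys=True) + "\n")


def load_voi_set(manifest_path: str | Path) -> dict[str, VOI]:
    manifest_path = Path(manifest_path)
    mapping = json.loads(manifest_path.read_text())
    vois: dict[str, VOI] = {}
    for label, fname in mapping.items():
        if label in vois:
            raise ValueError(f"duplicate VOI label {label!r}")
        vois[label] = load_voi_nifti(manifest_path.parent / fname, label)
    return vois
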