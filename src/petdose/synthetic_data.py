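"""Synthetic voxel phantoms and cohorts with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: a small
abdominal field of view imaged at four time points (~30/60/120/240 min after
injection), organs with mono-exponential kinetics

    A_organ(t) = A0 * f * exp(-(lambda_phys + lambda_bio) t)

spread uniformly over ellipsoidal masks on the scanner's 3.18 x 3.18 x 3 mm
grid, a Gaussian point-spread function that blurs the hot left kidney into
the adjacent pancreatic tail, count-scale Poisson noise, and a homogeneous
background representing the remainder of the body.  Because the kinetics are
closed-form, every study carries its exact ground-truth TACs and TIACs
(TIAC = f / (lambda_phys + lambda_bio)), which serve as recovery oracles.

Default organ fractions are illustrative, tuned only qualitatively to the
tracer's biodistribution (renal clearance with high retention; small
pancreas/duodenum fractions with slow washout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .kinetics import TIACSet, TimeActivityCurve
from .nucdata_phantoms import RadionuclideData, load_nuclide
from .voi_quant import VOI, VoxelImage, body_volume_ml

log = logging.getLogger(__name__)

DEFAULT_SPACING_MM = (3.18, 3.18, 3.0)
#: two-bed-position abdominal field of view (~41 x 25 x 38 cm, ~18 L body
#: region) so the homogeneous-remainder extrapolation has the geometry it
#: assumes: source organs occupy a small fraction of the scanned volume
DEFAULT_SHAPE = (128, 80, 128)
DEFAULT_SCAN_TIMES_MIN = (30.0, 60.0, 120.0, 240.0)

SOURCE_ORGANS = ("kidneys", "pancreas", "duodenum")


@dataclass(frozen=True)
class OrganKinetics:
    uptake_fraction: float          # fraction of injected dose taken up at t=0
    lambda_bio_per_min: float       # biological clearance rate

    def __post_init__(self) -> None:
        if not 0.0 <= self.uptake_fraction <= 1.0:
            raise ValueError("uptake fraction must be in [0, 1]")
        if self.lambda_bio_per_min < 0:
            raise ValueError("biological clearance must be non-negative")


@dataclass(frozen=True)
class KineticsModel:
    """Organ kinetics + imaging corruption parameters for the generator."""

    organs: dict[str, OrganKinetics]
    background: OrganKinetics
    psf_fwhm_mm: float = 6.0
    noise_counts_per_bq: float = 0.05   # 0 disables Poisson noise
    jitter_sigma: float = 0.10          # per-patient log-normal jitter on f, lambda_bio

    def __post_init__(self) -> None:
        total = sum(o.uptake_fraction for o in self.organs.values()) + self.background.uptake_fraction
        if total > 1.0:
            raise ValueError(f"uptake fractions sum to {total:.3f} > 1")
        if self.psf_fwhm_mm < 0 or self.noise_counts_per_bq < 0 or self.jitter_sigma < 0:
            raise ValueError("corruption parameters must be non-negative")


def default_model(psf_fwhm_mm: float = 6.0, noise_counts_per_bq: float = 0.05,
                  jitter_sigma: float = 0.10) -> KineticsModel:
    """Illustrative default: kidney-dominated uptake with slow washout."""
    return KineticsModel(
        organs={
            "kidneys": OrganKinetics(0.30, 0.0005),
            "pancreas": OrganKinetics(0.0025, 0.0003),
            "duodenum": OrganKinetics(0.002, 0.0008),
        },
        background=OrganKinetics(0.55, 0.001),
        psf_fwhm_mm=psf_fwhm_mm,
        noise_counts_per_bq=noise_counts_per_bq,
        jitter_sigma=jitter_sigma,
    )


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str                         # 'M' or 'F'
    age_y: float
    weight_kg: float
    injected_activity_mbq: float
    scan_times_min: tuple[float, ...] = DEFAULT_SCAN_TIMES_MIN
    height_cm: float | None = None


def load_reference_patients() -> list[PatientRecord]:
    """The packaged six-patient study table (sex, age, weight, A0, scan times)."""
    path = Path(str(resources.files("petdose").joinpath("data", "reference_patients.csv")))
    frame = pd.read_csv(path)
    records = []
    for _, row in frame.iterrows():
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            sex=str(row["sex"]),
            age_y=float(row["age_y"]),
            weight_kg=float(row["weight_kg"]),
            injected_activity_mbq=float(row["injected_activity_mbq"]),
            scan_times_min=tuple(float(row[f"scan{i}_min"]) for i in range(1, 5)),
        ))
    return records


@dataclass
class SyntheticStudy:
    """One simulated patient: record, jittered kinetics, and exact truth."""

    patient: PatientRecord
    model: KineticsModel              # per-patient (jittered) kinetics
    nuclide: RadionuclideData
    seed: int
    truth_tiacs: TIACSet = field(init=False)
    truth_tacs: dict[str, TimeActivityCurve] = field(init=False)

    def __post_init__(self) -> None:
        self.truth_tiacs = ground_truth_tiacs(self.model, self.nuclide)
        lam = self.nuclide.decay_constant_per_min
        a0 = self.patient.injected_activity_mbq
        times = self.patient.scan_times_min
        tacs = {}
        for organ, kin in {**self.model.organs, "remainder": self.model.background}.items():
            rate = lam + kin.lambda_bio_per_min
            acts = tuple(a0 * kin.uptake_fraction * float(np.exp(-rate * t)) for t in times)
            tacs[organ] = TimeActivityCurve(organ, times, acts, a0, decay_corrected=False)
        self.truth_tacs = tacs

    def truth_activity_mbq(self, organ: str, t_min: float) -> float:
        kin = self.model.background if organ == "remainder" else self.model.organs[organ]
        rate = self.nuclide.decay_constant_per_min + kin.lambda_bio_per_min
        return self.patient.injected_activity_mbq * kin.uptake_fraction * float(np.exp(-rate * t_min))


def ground_truth_tiacs(model: KineticsModel, nuclide: RadionuclideData) -> TIACSet:
    """Closed-form TIACs: f / (lambda_phys + lambda_bio), in hours."""
    lam = nuclide.decay_constant_per_min
    organ_tiacs = {organ: kin.uptake_fraction / (lam + kin.lambda_bio_per_min) / 60.0
                   for organ, kin in model.organs.items()}
    remainder = model.background.uptake_fraction / (lam + model.background.lambda_bio_per_min) / 60.0
    return TIACSet(organ_tiacs, remainder, nuclide)


def _jitter_model(model: KineticsModel, rng: np.random.Generator) -> KineticsModel:
    if model.jitter_sigma == 0:
        return model
    def jit(kin: OrganKinetics) -> OrganKinetics:
        return OrganKinetics(
            min(kin.uptake_fraction * float(rng.lognormal(0.0, model.jitter_sigma)), 1.0),
            kin.lambda_bio_per_min * float(rng.lognormal(0.0, model.jitter_sigma)),
        )
    organs = {name: jit(kin) for name, kin in model.organs.items()}
    background = jit(model.background)
    total = sum(o.uptake_fraction for o in organs.values()) + background.uptake_fraction
    if total > 0.98:
        # keep the study physical: rescale all fractions below unity
        factor = 0.98 / total
        organs = {n: OrganKinetics(o.uptake_fraction * factor, o.lambda_bio_per_min)
                  for n, o in organs.items()}
        background = OrganKinetics(background.uptake_fraction * factor, background.lambda_bio_per_min)
    return replace(model, organs=organs, background=background)


def generate_cohort(n: int = 6, model: KineticsModel | None = None, seed: int = 0,
                    nuclide: RadionuclideData | None = None,
                    use_reference_patients: bool = True) -> list[SyntheticStudy]:
    """Reproducible cohort; patient records verbatim from the packaged table
    when available, synthesized from realistic ranges beyond it."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    model = model if model is not None else default_model()
    nuclide = nuclide or load_nuclide()
    reference = load_reference_patients() if use_reference_patients else []
    seeds = np.random.SeedSequence(seed).spawn(n)
    studies = []
    for i in range(n):
        rng = np.random.default_rng(seeds[i])
        if i < len(reference):
            patient = reference[i]
        else:
            patient = PatientRecord(
                patient_id=f"synthetic_{i + 1}",
                sex="F" if rng.random() < 0.5 else "M",
                age_y=float(rng.uniform(20, 70)),
                weight_kg=float(rng.normal(77.0, 11.0)),
                injected_activity_mbq=float(rng.normal(105.6, 2.3)),
            )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        studies.append(SyntheticStudy(patient, _jitter_model(model, rng), nuclide, sub_seed))
    return studies


# ---------------------------------------------------------------------------
# Voxel geometry

def _ellipsoid(shape: tuple[int, int, int], spacing: tuple[float, float, float],
               center_mm: tuple[float, float, float],
               radii_mm: tuple[float, float, float]) -> np.ndarray:
    axes = [ (np.arange(shape[i]) + 0.5) * spacing[i] for i in range(3) ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return ((xx - center_mm[0]) / radii_mm[0]) ** 2 + \
           ((yy - center_mm[1]) / radii_mm[1]) ** 2 + \
           ((zz - center_mm[2]) / radii_mm[2]) ** 2 <= 1.0


def organ_geometry(shape: tuple[int, int, int] = DEFAULT_SHAPE,
                   spacing: tuple[float, float, float] = DEFAULT_SPACING_MM) -> dict[str, np.ndarray]:
    """Deterministic abdominal layout; the pancreatic tail abuts the left kidney."""
    extent = tuple(shape[i] * spacing[i] for i in range(3))
    cx, cy, cz = extent[0] / 2, extent[1] / 2, extent[2] / 2
    body = _ellipsoid(shape, spacing, (cx, cy, cz),
                      (cx - 13.0, cy - 7.0, cz - 6.0))
    right_kidney = _ellipsoid(shape, spacing, (cx - 55.0, cy + 40.0, cz), (22.0, 28.0, 42.0))
    left_kidney = _ellipsoid(shape, spacing, (cx + 55.0, cy + 40.0, cz), (22.0, 28.0, 42.0))
    kidneys = right_kidney | left_kidney
    pancreas = _ellipsoid(shape, spacing, (cx, cy + 8.0, cz + 5.0), (60.0, 16.0, 14.0)) & ~kidneys
    duodenum = _ellipsoid(shape, spacing, (cx - 40.0, cy, cz - 25.0),
                          (18.0, 14.0, 25.0)) & ~kidneys & ~pancreas
    for name, mask in [("body", body), ("kidneys", kidneys), ("pancreas", pancreas),
                       ("duodenum", duodenum)]:
        if not mask.any():
            raise ValueError(f"organ {name} does not fit on the grid")
    return {"body": body, "kidneys": kidneys, "left_kidney": left_kidney,
            "pancreas": pancreas, "duodenum": duodenum}


def generate_phantom_image(study: SyntheticStudy, t_min: float,
                           shape: tuple[int, int, int] = DEFAULT_SHAPE,
                           spacing: tuple[float, float, float] = DEFAULT_SPACING_MM,
                           ) -> tuple[VoxelImage, dict[str, VOI], dict[str, float]]:
    """Simulate one scan: truth activities placed uniformly per organ,
    Gaussian PSF blur, then count-scale Poisson noise.

    Returns the (physical-activity) image, the truth VOIs (plus the
    ``scanned_region`` body VOI and the ``left_kidney`` helper mask), and the
    truth activity per organ in MBq at this time point.
    """
    if t_min < 0:
        raise ValueError("time must be non-negative")
    masks = organ_geometry(shape, spacing)
    voxel_volume_ml = float(np.prod(spacing)) / 1000.0
    grid = np.zeros(shape, dtype=np.float64)

    truth: dict[str, float] = {}
    for organ in SOURCE_ORGANS:
        activity_mbq = study.truth_activity_mbq(organ, t_min)
        volume_ml = float(masks[organ].sum()) * voxel_volume_ml
        grid[masks[organ]] = activity_mbq * 1e6 / volume_ml       # Bq/mL
        truth[organ] = activity_mbq

    # homogeneous background at the whole-body concentration
    background_mbq = study.truth_activity_mbq("remainder", t_min)
    body_ml = body_volume_ml(study.patient.weight_kg)
    organ_union = masks["kidneys"] | masks["pancreas"] | masks["duodenum"]
    grid[masks["body"] & ~organ_union] = background_mbq * 1e6 / body_ml
    truth["remainder"] = background_mbq

    model = study.model
    if model.psf_fwhm_mm > 0:
        sigma_vox = [model.psf_fwhm_mm / 2.3548200450309493 / s for s in spacing]
        grid = ndimage.gaussian_filter(grid, sigma=sigma_vox)
    if model.noise_counts_per_bq > 0:
        rng = np.random.default_rng([study.seed, int(round(t_min * 1000))])
        counts = grid * voxel_volume_ml * model.noise_counts_per_bq
        grid = rng.poisson(counts).astype(np.float64) / (voxel_volume_ml * model.noise_counts_per_bq)

    image = VoxelImage(grid, spacing, acquisition_time_min=t_min, decay_corrected=False)
    vois = {
        "kidneys": VOI("kidneys", masks["kidneys"]),
        "left_kidney": VOI("left_kidney", masks["left_kidney"]),
        "pancreas": VOI("pancreas", masks["pancreas"]),
        "duodenum": VOI("duodenum", masks["duodenum"]),
        "scanned_region": VOI("scanned_region", masks["body"]),
    }
    return image, vois, truth
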