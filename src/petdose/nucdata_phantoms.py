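"""Physical decay data, reference phantoms and S-value (dose-factor) algebra.

The MIRD schema expresses the absorbed dose to a target region T as

    D(T) = sum_s  A-tilde(s) * S(T <- s)

where ``A-tilde`` is the cumulated activity in source region s (MBq h) and
``S(T <- s)`` the dose factor in mGy per MBq h.  This module holds everything
on the right-hand side that is *not* patient-specific: the radionuclide decay
data, the reference-phantom organ masses, the tabulated S factors, and the
mass-corrected remainder-of-body S value

    S(T <- ROB) = [S(T <- TB) m_TB - sum_s S(T <- s) m_s] / (m_TB - sum_s m_s)

used when the activity not assigned to any explicit source organ is assumed
uniformly distributed over the rest of the body.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

log = logging.getLogger(__name__)

LN2 = math.log(2.0)

#: J per MeV
MEV_TO_J = 1.602176634e-13
#: decays per MBq h
DECAYS_PER_MBQ_H = 3.6e9
#: mGy kg per (MeV deposited per decay * MBq h):  MeV->J, /kg, decays/MBq h, Gy->mGy
S_UNIT = MEV_TO_J * DECAYS_PER_MBQ_H * 1e3

TOTAL_BODY = "total_body"
REMAINDER = "remainder"

PHANTOM_MODELS = ("adult_male", "adult_female", "newborn", "one_year", "five_year")
PEDIATRIC_MODELS = ("newborn", "one_year", "five_year")

# Single canonicalization point for organ vocabulary.  VOI labels that have no
# counterpart in the reference-phantom source list map onto the region whose
# dose factors they share; notably the duodenum is booked as small intestine.
ORGAN_ALIASES: dict[str, str] = {
    "duodenum": "small_intestine",
    "left_kidney": "kidneys",
    "right_kidney": "kidneys",
    "kidney": "kidneys",
    "small_intestine_wall": "small_intestine",
    "urinary_bladder": "urinary_bladder_wall",
    "bladder_wall": "urinary_bladder_wall",
    "gallbladder": "gallbladder_wall",
    "stomach": "stomach_wall",
    "heart": "heart_wall",
    "bone_surface": "osteogenic_cells",
    "whole_body": TOTAL_BODY,
}


def canonical_organ(name: str) -> str:
    """Map an organ label to its canonical lower-snake-case id."""
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    return ORGAN_ALIASES.get(key, key)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("petdose").joinpath("data", name)))


@dataclass(frozen=True)
class RadionuclideData:
    """Decay properties of the positron-emitting label.

    ``delta_np_mev`` is the mean non-penetrating (electron/positron) energy
    emitted per decay; ``photon_emissions`` lists (energy MeV, yield/decay)
    for the penetrating component (annihilation quanta and gammas).
    """

    name: str
    half_life_min: float
    delta_np_mev: float
    photon_emissions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")
        if self.delta_np_mev < 0:
            raise ValueError("delta_np must be non-negative")
        for energy, yld in self.photon_emissions:
            if energy < 0 or not (0.0 <= yld <= 2.0):
                raise ValueError(f"bad photon emission ({energy}, {yld})")

    @property
    def decay_constant_per_min(self) -> float:
        return LN2 / self.half_life_min

    @property
    def mean_lifetime_min(self) -> float:
        return self.half_life_min / LN2

    @property
    def mean_lifetime_h(self) -> float:
        """Upper bound on any time-integrated activity coefficient (h)."""
        return self.mean_lifetime_min / 60.0

    @property
    def delta_photon_mev(self) -> float:
        return sum(e * y for e, y in self.photon_emissions)


def load_nuclide(path: str | Path | None = None) -> RadionuclideData:
    """Load radionuclide data from YAML; defaults to the packaged Ga-68 file."""
    p = Path(path) if path is not None else _data_path("ga68.yaml")
    raw = yaml.safe_load(p.read_text())
    return RadionuclideData(
        name=raw["name"],
        half_life_min=float(raw["half_life_min"]),
        delta_np_mev=float(raw["delta_np_mev"]),
        photon_emissions=tuple((float(e), float(y)) for e, y in raw.get("photon_emissions", [])),
    )


class SMatrix:
    """Sparse (target, source) -> S table in mGy per MBq h.

    Missing pairs read back as 0 with a one-shot logged warning, so an
    incomplete table degrades to under- rather than mis-counting.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float], matrix_id: str = "unnamed"):
        self.matrix_id = matrix_id
        self.entries: dict[tuple[str, str], float] = {}
        for (target, source), value in entries.items():
            if value < 0:
                raise ValueError(f"negative S value for ({target} <- {source}): {value}")
            self.entries[(canonical_organ(target), canonical_organ(source))] = float(value)
        self._warned: set[tuple[str, str]] = set()

    @property
    def targets(self) -> set[str]:
        return {t for t, _ in self.entries}

    @property
    def sources(self) -> set[str]:
        return {s for _, s in self.entries}

    def get(self, target: str, source: str) -> float:
        key = (canonical_organ(target), canonical_organ(source))
        if key not in self.entries:
            if key not in self._warned:
                log.warning("S-matrix %s: missing pair %s <- %s, using 0", self.matrix_id, *key)
                self._warned.add(key)
            return 0.0
        return self.entries[key]

    def __len__(self) -> int:
        return len(self.entries)


def load_smatrix(path: str | Path, matrix_id: str | None = None) -> SMatrix:
    """Read an S-value table from CSV with header ``target,source,s_mGy_per_MBq_h``."""
    path = Path(path)
    entries: dict[tuple[str, str], float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(row for row in fh if not row.startswith("#"))
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["target", "source", "s_mGy_per_MBq_h"]:
            raise ValueError(f"{path}: expected header target,source,s_mGy_per_MBq_h, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}")
            try:
                value = float(row[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric S value {row[2]!r}") from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative S value {value}")
            entries[(row[0], row[1])] = value
    if not entries:
        log.warning("S-matrix %s is empty; all lookups will return 0", path)
    return SMatrix(entries, matrix_id=matrix_id or path.stem)


@dataclass
class Phantom:
    """Reference anatomical model: organ masses (g) plus its S-value table."""

    model_id: str
    organ_masses_g: dict[str, float]
    total_body_mass_g: float
    s_matrix: SMatrix | None = None
    sex: str = "both"

    def __post_init__(self) -> None:
        self.organ_masses_g = {canonical_organ(k): float(v) for k, v in self.organ_masses_g.items()}
        for organ, mass in self.organ_masses_g.items():
            if mass <= 0:
                raise ValueError(f"{self.model_id}: non-positive mass for {organ}")
        if sum(self.organ_masses_g.values()) >= self.total_body_mass_g:
            raise ValueError(f"{self.model_id}: organ masses sum to >= total-body mass")
        if self.s_matrix is not None:
            known = set(self.organ_masses_g) | {TOTAL_BODY}
            unknown = (self.s_matrix.targets | self.s_matrix.sources) - known
            if unknown:
                raise ValueError(f"{self.model_id}: S-matrix organs not in phantom: {sorted(unknown)}")

    @property
    def is_pediatric(self) -> bool:
        return self.model_id in PEDIATRIC_MODELS

    def mass(self, organ: str) -> float:
        organ = canonical_organ(organ)
        if organ == TOTAL_BODY:
            return self.total_body_mass_g
        return self.organ_masses_g[organ]


def load_phantom(model_id: str, smatrix_path: str | Path | None = None,
                 np_only: bool = False, nuclide: RadionuclideData | None = None) -> Phantom:
    """Load a packaged reference phantom.

    By default the packaged approximate S-value CSV for the model is attached;
    ``np_only=True`` instead computes a self-dose-only (non-penetrating) table
    from the organ masses, which is fully self-contained but ignores photon
    cross-fire.
    """
    if model_id not in PHANTOM_MODELS:
        raise ValueError(f"unknown phantom model {model_id!r}; choose from {PHANTOM_MODELS}")
    raw = yaml.safe_load(_data_path(f"phantom_{model_id}.yaml").read_text())
    phantom = Phantom(
        model_id=raw["model_id"],
        organ_masses_g={k: float(v) for k, v in raw["organ_masses_g"].items()},
        total_body_mass_g=float(raw["total_body_mass_g"]),
        sex=raw.get("sex", "both"),
    )
    if np_only:
        nuclide = nuclide or load_nuclide()
        phantom.s_matrix = np_only_smatrix(phantom, nuclide)
    else:
        path = Path(smatrix_path) if smatrix_path is not None else _data_path(raw["smatrix"])
        phantom.s_matrix = load_smatrix(path)
    return phantom


def approximate_self_s(organ_mass_g: float, nuclide: RadionuclideData) -> float:
    """Non-penetrating self-dose S value, mGy/(MBq h): S = delta_np / m.

    Assumes all electron/positron energy is absorbed locally and ignores the
    photon component entirely; reports built in this mode must flag that
    photon cross-fire is not included.
    """
    if organ_mass_g <= 0:
        raise ValueError("organ mass must be positive")
    return nuclide.delta_np_mev * S_UNIT / (organ_mass_g / 1000.0)


def np_only_smatrix(phantom: Phantom, nuclide: RadionuclideData) -> SMatrix:
    """Self-dose-only S table: S(T<-T) = delta_np/m_T, S(T<-TB) = delta_np/m_TB.

    The total-body row follows from a uniform distribution: every gram holds
    1/m_TB of the activity, so every target absorbs delta_np/m_TB per decay.
    """
    entries: dict[tuple[str, str], float] = {}
    for organ, mass in phantom.organ_masses_g.items():
        entries[(organ, organ)] = approximate_self_s(mass, nuclide)
        entries[(organ, TOTAL_BODY)] = approximate_self_s(phantom.total_body_mass_g, nuclide)
    entries[(TOTAL_BODY, TOTAL_BODY)] = approximate_self_s(phantom.total_body_mass_g, nuclide)
    return SMatrix(entries, matrix_id=f"np_only_{phantom.model_id}")


def rob_s(target: str, phantom: Phantom, source_organs: Iterable[str]) -> float:
    """Mass-corrected remainder-of-body S value for one target.

    S(T<-ROB) = [S(T<-TB) m_TB - sum_s S(T<-s) m_s] / m_ROB with
    m_ROB = m_TB - sum_s m_s.  Negative algebra (possible with approximate
    tables) is clamped to 0 with a logged warning.
    """
    if phantom.s_matrix is None:
        raise ValueError("phantom has no S-matrix attached")
    target = canonical_organ(target)
    sources = sorted({canonical_organ(s) for s in source_organs})
    for s in sources:
        if s not in phantom.organ_masses_g:
            raise ValueError(f"source organ {s!r} not in phantom {phantom.model_id}")
    m_sources = sum(phantom.organ_masses_g[s] for s in sources)
    m_rob = phantom.total_body_mass_g - m_sources
    if m_rob <= 0:
        raise ValueError("source organ masses meet or exceed total-body mass")
    numerator = phantom.s_matrix.get(target, TOTAL_BODY) * phantom.total_body_mass_g
    for s in sources:
        numerator -= phantom.s_matrix.get(target, s) * phantom.organ_masses_g[s]
    value = numerator / m_rob
    if value < 0:
        log.warning("remainder S for %s in %s came out negative (%.3g); clamping to 0",
                    target, phantom.model_id, value)
        return 0.0
    return value
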