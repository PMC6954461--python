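"""MIRD-schema absorbed doses, effective dose and per-administration scaling.

Given a set of time-integrated activity coefficients and a reference phantom
with its S-value table, the absorbed dose coefficient of every target is

    d(T) = sum_s tau(s) S(T <- s)  +  tau_ROB S(T <- ROB)        [mGy/MBq]

with the remainder-of-body S value obtained by mass-correcting the
total-body row.  The effective dose applies ICRP tissue weighting factors
(radiation weighting factor 1 for photons and electrons/positrons, so organ
equivalent dose in mSv is numerically the absorbed dose in mGy).  Pediatric
extrapolation re-runs the same schema with the adult TIACs on a child
phantom, the standard assumption of a comparable biodistribution across
ages.  Per-administration doses, annual examination budgets and cohort
mean +/- SD summaries are simple arithmetic on top.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import TIACSet
from .nucdata_phantoms import (PEDIATRIC_MODELS, REMAINDER, TOTAL_BODY, Phantom,
                               canonical_organ, rob_s)

log = logging.getLogger(__name__)

EFFECTIVE_DOSE_ROW = "effective_dose"

#: adult reporting order for cohort tables
TABLE_ORDER = [
    "adrenals", "brain", "breasts", "gallbladder_wall", "stomach_wall", "heart_wall",
    "kidneys", "lower_large_intestine_wall", "upper_large_intestine_wall",
    "small_intestine", "liver", "lungs", "muscle", "ovaries", "pancreas",
    "red_marrow", "osteogenic_cells", "skin", "spleen", "testes", "thymus",
    "thyroid", "urinary_bladder_wall", "uterus", "total_body", EFFECTIVE_DOSE_ROW,
]


@dataclass
class TissueWeights:
    """ICRP tissue weighting factors plus the organ-resolution rules."""

    scheme: str
    weights: dict[str, float]
    composite: dict[str, list[str]] = field(default_factory=dict)
    surrogate: dict[str, str] = field(default_factory=dict)
    gonad_organs: tuple[str, ...] = ("ovaries", "testes")
    remainder_tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"tissue weights must sum to 1 (got {total!r})")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("tissue weights must be non-negative")


def load_tissue_weights(path: str | Path | None = None) -> TissueWeights:
    """Load a weighting scheme from YAML; defaults to the packaged ICRP-60 file."""
    p = Path(path) if path is not None else Path(
        str(resources.files("petdose").joinpath("data", "icrp60_weights.yaml")))
    raw = yaml.safe_load(p.read_text())
    return TissueWeights(
        scheme=raw["scheme"],
        weights={k: float(v) for k, v in raw["weights"].items()},
        composite={k: list(v) for k, v in raw.get("composite", {}).items()},
        surrogate=dict(raw.get("surrogate", {})),
        gonad_organs=tuple(raw.get("gonads", ["ovaries", "testes"])),
        remainder_tissues=tuple(raw.get("remainder_tissues", [])),
    )


def absorbed_doses(tiacs: TIACSet, phantom: Phantom) -> dict[str, float]:
    """Dose coefficient (mGy/MBq) for every target in the phantom S-matrix."""
    if phantom.s_matrix is None:
        raise ValueError("phantom has no S-matrix attached")
    sources = {canonical_organ(k): v for k, v in tiacs.organ_tiacs_h.items()}
    smatrix = phantom.s_matrix
    for s in sources:
        if s not in smatrix.sources:
            raise ValueError(f"source organ {s!r} has no S-matrix column in {phantom.model_id}")
        if (s, s) not in smatrix.entries:
            raise ValueError(f"S-matrix for {phantom.model_id} lacks the self-dose entry of {s!r}")
    targets = sorted(smatrix.targets)
    doses: dict[str, float] = {}
    for target in targets:
        dose = sum(tau * smatrix.get(target, s) for s, tau in sources.items())
        if tiacs.remainder_tiac_h > 0:
            dose += tiacs.remainder_tiac_h * rob_s(target, phantom, sources)
        doses[target] = dose
    return doses


def _mass_weighted_mean(doses: dict[str, float], organs: list[str], phantom: Phantom) -> float:
    present = [o for o in organs if o in doses and o in phantom.organ_masses_g]
    if not present:
        raise ValueError(f"none of {organs} resolvable to a dose in {phantom.model_id}")
    masses = np.array([phantom.organ_masses_g[o] for o in present])
    values = np.array([doses[o] for o in present])
    return float(np.average(values, weights=masses))


def _resolve_tissue_dose(tissue: str, doses: dict[str, float], weights: TissueWeights,
                         phantom: Phantom) -> float:
    if tissue == "gonads":
        present = [g for g in weights.gonad_organs if g in doses and g in phantom.organ_masses_g]
        if not present:
            raise ValueError(f"no gonad organ available in phantom {phantom.model_id}")
        if phantom.sex == "male" and "testes" in present:
            return doses["testes"]
        # female and two-sex (pediatric) models use the ovaries
        return doses[present[0]] if "ovaries" not in present else doses["ovaries"]
    if tissue in weights.composite:
        return _mass_weighted_mean(doses, weights.composite[tissue], phantom)
    if tissue in weights.surrogate:
        tissue = weights.surrogate[tissue]
    if tissue == REMAINDER:
        return _mass_weighted_mean(doses, list(weights.remainder_tissues), phantom)
    organ = canonical_organ(tissue)
    if organ in doses:
        return doses[organ]
    raise ValueError(f"weighted tissue {tissue!r} has no dose and is not in the remainder list")


def effective_dose(doses: dict[str, float], weights: TissueWeights, phantom: Phantom) -> float:
    """E = sum_T w_T H_T in mSv/MBq (w_R = 1 for this emission spectrum)."""
    doses = {canonical_organ(k): v for k, v in doses.items()}
    total = 0.0
    for tissue, w in weights.weights.items():
        total += w * _resolve_tissue_dose(tissue, doses, weights, phantom)
    return total


@dataclass
class DoseReport:
    """Per-target dose coefficients for one patient on one phantom."""

    model_id: str
    organ_doses_mgy_per_mbq: dict[str, float]
    effective_dose_msv_per_mbq: float
    provenance: dict[str, str] = field(default_factory=dict)
    administered_mbq: float | None = None
    organ_doses_mgy: dict[str, float] | None = None
    effective_dose_msv: float | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.organ_doses_mgy_per_mbq.values()):
            raise ValueError("absorbed doses must be non-negative")
        if self.effective_dose_msv_per_mbq < 0:
            raise ValueError("effective dose must be non-negative")
        peak = max(self.organ_doses_mgy_per_mbq.values(), default=0.0)
        if self.effective_dose_msv_per_mbq > peak * (1 + 1e-9) and peak > 0:
            raise ValueError("effective dose exceeds the maximum organ equivalent dose")

    def to_json(self) -> str:
        payload = {
            "model_id": self.model_id,
            "organ_doses_mGy_per_MBq": {k: self.organ_doses_mgy_per_mbq[k]
                                        for k in sorted(self.organ_doses_mgy_per_mbq)},
            "effective_dose_mSv_per_MBq": self.effective_dose_msv_per_mbq,
            "provenance": dict(sorted(self.provenance.items())),
        }
        if self.administered_mbq is not None:
            payload["administered_MBq"] = self.administered_mbq
            payload["organ_doses_mGy"] = {k: self.organ_doses_mgy[k]
                                          for k in sorted(self.organ_doses_mgy)}
            payload["effective_dose_mSv"] = self.effective_dose_msv
        return json.dumps(payload, indent=2, sort_keys=False)


def make_report(tiacs: TIACSet, phantom: Phantom, weights: TissueWeights,
                provenance: dict[str, str] | None = None) -> DoseReport:
    doses = absorbed_doses(tiacs, phantom)
    ed = effective_dose(doses, weights, phantom)
    prov = {"smatrix": phantom.s_matrix.matrix_id, "weights": weights.scheme}
    if phantom.s_matrix.matrix_id.startswith("np_only"):
        prov["warning"] = "np-only S mode: photon cross-dose not included"
    prov.update(provenance or {})
    return DoseReport(phantom.model_id, doses, ed, prov)


def scale_to_administered(report: DoseReport, activity_mbq: float) -> DoseReport:
    """Multiply every per-MBq coefficient by the administered activity."""
    if activity_mbq <= 0:
        raise ValueError("administered activity must be positive")
    return DoseReport(
        model_id=report.model_id,
        organ_doses_mgy_per_mbq=dict(report.organ_doses_mgy_per_mbq),
        effective_dose_msv_per_mbq=report.effective_dose_msv_per_mbq,
        provenance=dict(report.provenance),
        administered_mbq=activity_mbq,
        organ_doses_mgy={k: v * activity_mbq for k, v in report.organ_doses_mgy_per_mbq.items()},
        effective_dose_msv=report.effective_dose_msv_per_mbq * activity_mbq,
    )


def exam_budget(per_exam_dose: float, annual_limit: float) -> int:
    """Whole examinations per year under a dose limit: floor(limit / dose)."""
    if per_exam_dose <= 0:
        raise ValueError("per-examination dose must be positive")
    if annual_limit < 0:
        raise ValueError("annual limit must be non-negative")
    return int(math.floor(annual_limit / per_exam_dose + 1e-9))


def pediatric_report(adult_tiacs: TIACSet, pediatric_phantom: Phantom,
                     weights: TissueWeights, provenance: dict[str, str] | None = None) -> DoseReport:
    """Adult TIACs on a child phantom (comparable-biodistribution assumption)."""
    if pediatric_phantom.model_id not in PEDIATRIC_MODELS:
        raise ValueError(f"{pediatric_phantom.model_id!r} is not a pediatric model "
                         f"(expected one of {PEDIATRIC_MODELS})")
    prov = {"tiac_source": "adult", **(provenance or {})}
    return make_report(adult_tiacs, pediatric_phantom, weights, prov)


def cohort_summary(reports: list[DoseReport], union: bool = False) -> pd.DataFrame:
    """Sample mean and SD (n-1) per target across patients, reporting order.

    ``union=True`` pools reports from sex-specific phantoms: sex-specific
    targets (testes, ovaries, uterus) are averaged over the patients that
    have them, as in a pooled mixed-sex cohort table.
    """
    if len(reports) < 2:
        raise ValueError("cohort summary needs at least 2 reports")
    target_sets = [set(r.organ_doses_mgy_per_mbq) for r in reports]
    if not union and any(ts != target_sets[0] for ts in target_sets[1:]):
        raise ValueError("reports have heterogeneous target sets")
    rows = {}
    for r in reports:
        rows[len(rows)] = {**r.organ_doses_mgy_per_mbq,
                           EFFECTIVE_DOSE_ROW: r.effective_dose_msv_per_mbq}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    order = [o for o in TABLE_ORDER if o in frame.columns]
    order += [o for o in frame.columns if o not in order]
    summary = pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)}).loc[order]
    summary.index.name = "site"
    return summary


def load_published_coefficients(path: str | Path | None = None) -> pd.DataFrame:
    """Published cohort mean/SD dose coefficients packaged with the library.

    Columns: model (adult / newborn / one_year / five_year), site, mean, sd,
    unit (mGy_per_MBq for organs, mSv_per_MBq for the effective-dose row).
    """
    p = Path(path) if path is not None else Path(
        str(resources.files("petdose").joinpath("data", "published_dose_coefficients.csv")))
    return pd.read_csv(p, comment="#")


def report_from_published(model: str, path: str | Path | None = None) -> DoseReport:
    """Build a DoseReport from the published mean coefficients for one model."""
    frame = load_published_coefficients(path)
    rows = frame[frame["model"] == model]
    if rows.empty:
        raise ValueError(f"no published coefficients for model {model!r}")
    organs = {r["site"]: float(r["mean"]) for _, r in rows.iterrows()
              if r["site"] != EFFECTIVE_DOSE_ROW}
    effective = float(rows.loc[rows["site"] == EFFECTIVE_DOSE_ROW, "mean"].iloc[0])
    return DoseReport(model, organs, effective,
                      provenance={"source": "published_cohort_coefficients"})


def format_cohort_table(summary: pd.DataFrame, n: int) -> str:
    """Aligned-text cohort table, coefficients rounded to 3 decimals."""
    lines = [f"Site (n = {n})              Mean     SD",
             "-" * 44]
    for site, row in summary.iterrows():
        unit = "mSv/MBq" if site == EFFECTIVE_DOSE_ROW else "mGy/MBq"
        lines.append(f"{site:<26s} {row['mean']:7.3f} {row['sd']:7.3f}  [{unit}]")
    return "\n".join(lines) + "\n"
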