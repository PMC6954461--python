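"""Time-activity curves, cumulated activity and TIACs.

The cumulated activity (total decays expressed as MBq h) of an organ is the
area under its *physical* (non-decay-corrected) time-activity curve:

* head, 0 -> t1: instantaneous uptake at injection followed by pure physical
  decay consistent with the first measured point, integrated analytically;
  a linear rise from zero is available as a sensitivity alternative;
* trapezoid rule across the measured samples;
* tail, t_last -> infinity: pure physical decay, A(t_last)/lambda.

Dividing by the injected activity gives the time-integrated activity
coefficient (TIAC, historically the residence time), bounded above by the
nuclide mean lifetime: no organ can accumulate more decays than complete
in-situ decay of the whole injection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .nucdata_phantoms import RadionuclideData, canonical_organ

log = logging.getLogger(__name__)

HEAD_RULES = ("decay_from_first", "linear_from_zero")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Sampled organ activity vs. time post-injection."""

    organ: str
    times_min: tuple[float, ...]
    activities_mbq: tuple[float, ...]
    injected_activity_mbq: float
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        a = np.asarray(self.activities_mbq, dtype=float)
        if t.size == 0 or t.size != a.size:
            raise ValueError("need >= 1 (t, A) sample with matching lengths")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing (duplicates rejected)")
        if t[0] < 0 or np.any(a < 0):
            raise ValueError("times and activities must be non-negative")
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be positive")
        object.__setattr__(self, "times_min", tuple(float(x) for x in t))
        object.__setattr__(self, "activities_mbq", tuple(float(x) for x in a))


def to_physical(tac: TimeActivityCurve, nuclide: RadionuclideData) -> TimeActivityCurve:
    """Restore physical decay: A_phys(t) = A_dc(t) * exp(-lambda t)."""
    if not tac.decay_corrected:
        log.warning("curve for %s is already physical; to_physical is a no-op", tac.organ)
        return tac
    lam = nuclide.decay_constant_per_min
    a = tuple(A * float(np.exp(-lam * t)) for t, A in zip(tac.times_min, tac.activities_mbq))
    return replace(tac, activities_mbq=a, decay_corrected=False)


def decay_correct(tac: TimeActivityCurve, nuclide: RadionuclideData) -> TimeActivityCurve:
    """Inverse of :func:`to_physical`: reference all activities to t = 0."""
    if tac.decay_corrected:
        log.warning("curve for %s is already decay-corrected; no-op", tac.organ)
        return tac
    lam = nuclide.decay_constant_per_min
    a = tuple(A * float(np.exp(lam * t)) for t, A in zip(tac.times_min, tac.activities_mbq))
    return replace(tac, activities_mbq=a, decay_corrected=True)


def cumulated_activity_mbq_h(tac: TimeActivityCurve, nuclide: RadionuclideData,
                             head_rule: str = "decay_from_first") -> float:
    """Head + trapezoid + analytic tail integral of a physical curve, MBq h."""
    if tac.decay_corrected:
        raise ValueError("cumulated activity must be integrated on a physical "
                         "(non-decay-corrected) curve; call to_physical first")
    if head_rule not in HEAD_RULES:
        raise ValueError(f"unknown head rule {head_rule!r}; choose from {HEAD_RULES}")
    lam = nuclide.decay_constant_per_min
    if lam <= 0:
        raise ValueError("decay constant must be positive")
    t = np.asarray(tac.times_min)
    a = np.asarray(tac.activities_mbq)

    if t[0] > 0:
        if head_rule == "decay_from_first":
            # A(t) = A(t1) exp(lambda (t1 - t)) on [0, t1]: back-extrapolated
            # instantaneous uptake, never under-counting the unobserved head.
            head = a[0] * (np.exp(lam * t[0]) - 1.0) / lam
        else:
            head = 0.5 * t[0] * a[0]
    else:
        head = 0.0
    body = float(np.trapezoid(a, t)) if t.size > 1 else 0.0
    tail = a[-1] / lam
    return float(head + body + tail) / 60.0


def tiac_h(cumulated_mbq_h: float, injected_activity_mbq: float) -> float:
    """Time-integrated activity coefficient: cumulated / injected, hours."""
    if injected_activity_mbq <= 0:
        raise ValueError("injected activity must be positive")
    return cumulated_mbq_h / injected_activity_mbq


def percent_id(tac: TimeActivityCurve, nuclide: RadionuclideData,
               organ_mass_g: float | None = None,
               decay_correct_output: bool = False) -> np.ndarray:
    """Curve of %ID (or %ID/g when a mass is given), optionally decay-corrected."""
    if organ_mass_g is not None and organ_mass_g <= 0:
        raise ValueError("organ mass must be positive")
    curve = tac
    if decay_correct_output and not tac.decay_corrected:
        curve = decay_correct(tac, nuclide)
    elif not decay_correct_output and tac.decay_corrected:
        curve = to_physical(tac, nuclide)
    values = 100.0 * np.asarray(curve.activities_mbq) / curve.injected_activity_mbq
    if organ_mass_g is not None:
        values = values / organ_mass_g
    return values


@dataclass
class TIACSet:
    """Per-organ TIACs (h) plus the remainder-of-body TIAC."""

    organ_tiacs_h: dict[str, float]
    remainder_tiac_h: float
    nuclide: RadionuclideData

    def __post_init__(self) -> None:
        self.organ_tiacs_h = {canonical_organ(k): float(v) for k, v in self.organ_tiacs_h.items()}
        if any(v < 0 for v in self.organ_tiacs_h.values()) or self.remainder_tiac_h < 0:
            raise ValueError("TIACs must be non-negative")
        budget = self.nuclide.mean_lifetime_h
        if self.total_h > budget * (1 + 1e-9):
            raise ValueError(f"total TIAC {self.total_h:.4f} h exceeds the physical "
                             f"budget {budget:.4f} h (complete decay in situ)")

    @property
    def total_h(self) -> float:
        return sum(self.organ_tiacs_h.values()) + self.remainder_tiac_h


def tiacs_from_curves(curves: list[TimeActivityCurve], remainder_curve: TimeActivityCurve,
                      nuclide: RadionuclideData, head_rule: str = "decay_from_first") -> TIACSet:
    """Integrate a set of physical curves into a TIACSet (remainder separate)."""
    organ_tiacs: dict[str, float] = {}
    for tac in curves:
        value = tiac_h(cumulated_activity_mbq_h(tac, nuclide, head_rule), tac.injected_activity_mbq)
        key = canonical_organ(tac.organ)
        organ_tiacs[key] = organ_tiacs.get(key, 0.0) + value
    rem = tiac_h(cumulated_activity_mbq_h(remainder_curve, nuclide, head_rule),
                 remainder_curve.injected_activity_mbq)
    return TIACSet(organ_tiacs, rem, nuclide)
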