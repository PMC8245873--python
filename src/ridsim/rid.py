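"""Retinol isotope dilution (RID) quantities and the TBS prediction equation.

After an oral dose of labeled retinyl acetate, the RID method predicts
vitamin A total body stores from a single plasma measurement:

    TBS (μmol) = Fa × S × 1 / SAp

where, at sampling time t,

* ``Fa``  — fraction of the dose residing in the two storage compartments;
* ``FDp`` — fraction of the dose in plasma;
* ``SAp`` — plasma retinol specific activity, FDp / M(5), with M(5) the
  plasma retinol pool size (μmol);
* ``SAs`` — specific activity of the stores, Fa / TBS;
* ``S``   — the ratio SAp / SAs;
* ``FaS`` — the composite coefficient Fa × S that multiplies 1/SAp.

All quantities are carried as fraction-of-dose (per μmol where applicable),
so the physical dose size cancels throughout.  Two exact algebraic
identities follow from the definitions and are enforced as invariants:
``FaS = SAp × TBS`` and ``FaS / FDp = TBS / M(5)`` — the latter explains why
per-subject FaS curves run parallel to their plasma fraction-of-dose curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (
    CompartmentalSystem,
    MassState,
    TracerTimeCourse,
    assigned_tbs,
    steady_state_masses,
)

__all__ = ["SubjectSpec", "RIDTrajectory", "rid_quantities", "predict_tbs"]


@dataclass(frozen=True)
class SubjectSpec:
    """One theoretical subject: kinetic system, plasma retinol pool size M(5)
    in μmol, and the assigned (true) TBS derived from the steady state."""

    id: str
    group: str  # "adult" or "child"
    system: CompartmentalSystem
    M5: float
    assigned_tbs: float

    def __post_init__(self) -> None:
        if self.group not in ("adult", "child"):
            raise ValueError(f"group must be 'adult' or 'child', got {self.group!r}")
        if not (np.isfinite(self.M5) and self.M5 > 0):
            raise ValueError(f"M5 must be positive, got {self.M5}")
        if not (np.isfinite(self.assigned_tbs) and self.assigned_tbs > 0):
            raise ValueError(f"assigned_tbs must be positive, got {self.assigned_tbs}")

    @classmethod
    def from_system(cls, id: str, group: str, system: CompartmentalSystem, M5: float) -> "SubjectSpec":
        """Build a subject by anchoring the steady state at the plasma pool
        size and deriving assigned TBS from the storage-compartment masses."""
        state = steady_state_masses(system, plasma_pool=M5)
        return cls(id=id, group=group, system=system, M5=float(M5),
                   assigned_tbs=assigned_tbs(state, system))


@dataclass(frozen=True)
class RIDTrajectory:
    """Per-time RID quantities for one subject.

    ``S`` and ``FaS`` are undefined where no tracer has reached the stores
    (``Fa = 0``, so ``SAs = 0``); those entries hold NaN and are flagged
    False in ``defined`` rather than silently propagated.
    """

    subject_id: str
    times: np.ndarray
    Fa: np.ndarray
    FDp: np.ndarray
    SAp: np.ndarray
    SAs: np.ndarray
    S: np.ndarray
    FaS: np.ndarray
    defined: np.ndarray  # bool mask: True where S and FaS are well defined

    def at(self, day: float) -> dict[str, float]:
        """All quantities at one time point (must be on the grid)."""
        k = np.flatnonzero(np.isclose(self.times, day))
        if k.size != 1:
            raise KeyError(f"time {day} not on trajectory grid")
        k = int(k[0])
        return {name: float(getattr(self, name)[k])
                for name in ("Fa", "FDp", "SAp", "SAs", "S", "FaS")}


def rid_quantities(tc: TracerTimeCourse, subject: SubjectSpec) -> RIDTrajectory:
    """Compute the RID equation terms from a solved tracer time course.

    Requires the subject's system to designate plasma and storage
    compartments.  Where ``Fa = 0`` (typically only t = 0 or the earliest
    instants before absorbed tracer reaches the stores), ``S`` and ``FaS``
    are masked as undefined.
    """
    system = subject.system
    if system.plasma_compartment is None or system.storage_compartments is None:
        raise ValueError("subject's system must designate plasma and storage compartments")
    fa = tc.fraction_in(system.storage_compartments)
    fdp = tc.fraction_in(system.plasma_compartment)
    sap = fdp / subject.M5
    sas = fa / subject.assigned_tbs
    defined = sas > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(defined, sap / np.where(defined, sas, 1.0), np.nan)
    fas = np.where(defined, fa * s, np.nan)
    return RIDTrajectory(
        subject_id=subject.id, times=tc.times, Fa=fa, FDp=fdp,
        SAp=sap, SAs=sas, S=s, FaS=fas, defined=defined,
    )


def predict_tbs(fas_coefficient, sap):
    """Predict total body stores: ``TBS = FaS / SAp`` (μmol).

    ``fas_coefficient`` is the composite coefficient Fa × S — in the
    super-subject design, the cohort geometric mean of FaS at the sampling
    day — and ``sap`` is the subject's measured plasma retinol specific
    activity (fraction of dose per μmol).  Both must be positive; inputs may
    be scalars or arrays (broadcast elementwise).
    """
    fas_coefficient = np.asarray(fas_coefficient, dtype=float)
    sap = np.asarray(sap, dtype=float)
    if np.any(~(fas_coefficient > 0)) or np.any(~(sap > 0)):
        raise ValueError("FaS coefficient and SAp must be positive and finite")
    out = fas_coefficient / sap
    return float(out) if out.ndim == 0 else out
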