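"""Linear compartmental tracer models of whole-body vitamin A metabolism.

A subject's kinetics are described by an open, linear, constant-coefficient
compartmental system: ``L(i,j)`` is the fraction of compartment *j*'s content
transferred to compartment *i* per day, and ``L(0,j)`` is irreversible loss
from compartment *j*.  After an oral dose of labeled retinyl acetate at
``t = 0`` the tracer content of every compartment, expressed as fraction of
the administered dose, evolves as ``dq/dt = A q`` where ``A`` is the state
matrix assembled from the coefficients.  Because the model class is linear
with constant coefficients, trajectories are evaluated exactly (to floating
point) with the matrix exponential; no integration error enters.

The same coefficients govern the unlabeled (tracee) vitamin A, whose
steady-state masses solve the linear balance ``A m + u = 0`` for a constant
dietary intake ``u``.  Total body stores (TBS) is the steady-state vitamin A
mass summed over the two designated storage compartments; the plasma retinol
pool size M(5) is the mass of the plasma compartment.

Compartments are labeled 1..n.  An optional absorptive delay is modeled as a
chain of first-order stages preceding the dosing compartment; tracer or
tracee in transit through the chain is reported as part of the dosing
compartment so that mass balance holds on the visible state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "Delay",
    "CompartmentalSystem",
    "TracerTimeCourse",
    "MassState",
    "ModelValidationError",
    "SolverError",
    "build_system",
    "solve_tracer",
    "steady_state_masses",
    "assigned_tbs",
]

#: Relative tolerance on the per-time mass balance |sum(q) + loss - 1|.
MASS_BALANCE_TOL = 1e-6

#: Relative residual tolerance on the steady-state balance equations.
STEADY_STATE_TOL = 1e-9


class ModelValidationError(ValueError):
    """A compartmental system or parameter table failed validation."""


class SolverError(RuntimeError):
    """The kinetic solution is non-finite or violates mass balance."""


@dataclass(frozen=True)
class Delay:
    """Absorptive lag: a chain of `stages` first-order sub-compartments with
    total mean transit time `duration` (days)."""

    duration: float
    stages: int = 3

    def __post_init__(self) -> None:
        if not (np.isfinite(self.duration) and self.duration > 0):
            raise ModelValidationError(f"delay duration must be positive, got {self.duration}")
        if self.stages < 1:
            raise ModelValidationError(f"delay stages must be >= 1, got {self.stages}")

    @property
    def rate(self) -> float:
        """Per-stage fractional transfer rate (1/day)."""
        return self.stages / self.duration


@dataclass(frozen=True)
class CompartmentalSystem:
    """Topology and fractional transfer coefficients of one subject's model.

    Parameters
    ----------
    n_compartments
        Number of (visible) compartments, labeled 1..n.
    transfer
        ``(n, n)`` array with ``transfer[i-1, j-1] = L(i,j)`` in 1/day for
        ``i != j``; the diagonal is ignored and must be zero.
    loss
        Length-``n`` array of irreversible-loss coefficients ``L(0,j)``.
    dosing_compartment
        1-based label of the compartment receiving the oral dose.
    plasma_compartment
        1-based label of the plasma retinol compartment (the model's
        compartment 5), or ``None`` for reduced test systems.
    storage_compartments
        The two 1-based labels of the vitamin A storage compartments, or
        ``None`` for reduced test systems.
    absorption_fraction
        Fraction of the oral dose entering the system; the remainder is
        routed to cumulative loss at ``t = 0``.
    delay
        Optional absorptive delay preceding the dosing compartment.
    """

    n_compartments: int
    transfer: np.ndarray
    loss: np.ndarray
    dosing_compartment: int = 1
    plasma_compartment: int | None = None
    storage_compartments: tuple[int, int] | None = None
    absorption_fraction: float = 1.0
    delay: Delay | None = None

    def __post_init__(self) -> None:
        n = self.n_compartments
        if n < 1:
            raise ModelValidationError("need at least one compartment")
        transfer = np.asarray(self.transfer, dtype=float)
        loss = np.asarray(self.loss, dtype=float)
        object.__setattr__(self, "transfer", transfer)
        object.__setattr__(self, "loss", loss)
        if transfer.shape != (n, n):
            raise ModelValidationError(
                f"transfer matrix shape {transfer.shape} != ({n}, {n})")
        if loss.shape != (n,):
            raise ModelValidationError(f"loss vector shape {loss.shape} != ({n},)")
        if not (np.all(np.isfinite(transfer)) and np.all(np.isfinite(loss))):
            raise ModelValidationError("non-finite coefficient")
        if np.any(transfer < 0) or np.any(loss < 0):
            raise ModelValidationError("negative coefficient")
        if np.any(np.diag(transfer) != 0):
            raise ModelValidationError("transfer diagonal must be zero (self-transfer)")
        self._check_label("dosing_compartment", self.dosing_compartment)
        if self.plasma_compartment is not None:
            self._check_label("plasma_compartment", self.plasma_compartment)
        if self.storage_compartments is not None:
            stor = tuple(sorted(self.storage_compartments))
            object.__setattr__(self, "storage_compartments", stor)
            if len(set(stor)) != 2:
                raise ModelValidationError(
                    f"storage set must contain exactly 2 distinct compartments, got {stor}")
            for s in stor:
                self._check_label("storage compartment", s)
            if self.plasma_compartment in stor:
                raise ModelValidationError("plasma compartment cannot be a storage compartment")
        if not (0 < self.absorption_fraction <= 1):
            raise ModelValidationError(
                f"absorption_fraction must be in (0, 1], got {self.absorption_fraction}")
        # Openness: every compartment must drain to irreversible loss, i.e.
        # all eigenvalues of the state matrix have negative real part.
        eigs = np.linalg.eigvals(self.state_matrix())
        if eigs.size and np.max(eigs.real) > -1e-12:
            raise ModelValidationError(
                "system is not open: some compartment has no path to irreversible loss "
                f"(max eigenvalue real part {np.max(eigs.real):.3e})")

    def _check_label(self, what: str, label: int) -> None:
        if not (isinstance(label, (int, np.integer)) and 1 <= label <= self.n_compartments):
            raise ModelValidationError(f"{what} {label!r} not a valid compartment label 1..{self.n_compartments}")

    def state_matrix(self) -> np.ndarray:
        """State matrix A of the visible compartments (delay excluded):
        ``A[i,j] = L(i+1, j+1)`` off-diagonal, ``A[j,j] = -(L(0,j) + sum_i L(i,j))``."""
        a = self.transfer.copy()
        np.fill_diagonal(a, 0.0)
        a -= np.diag(self.loss + self.transfer.sum(axis=0))
        return a

    # -- internal augmented representation ---------------------------------

    def _augmented(self) -> tuple[np.ndarray, np.ndarray, int, int]:
        """State matrix including delay stages and a terminal loss accumulator.

        Returns ``(A_aug, row_loss, entry, n_delay)`` where ``A_aug`` is
        ``(m, m)`` with ``m = n_delay + n + 1`` (last row/column is the loss
        accumulator), ``entry`` is the index of the state receiving the dose,
        and ``n_delay`` is the number of prepended delay stages.
        """
        n = self.n_compartments
        nd = self.delay.stages if self.delay is not None else 0
        m = nd + n + 1
        a = np.zeros((m, m))
        if nd:
            r = self.delay.rate
            for k in range(nd):
                a[k, k] = -r
                a[k + 1, k] = r  # last stage feeds the dosing compartment row nd + dosing-1
            # reroute final stage into the dosing compartment
            a[nd, nd - 1] = 0.0
            a[nd + self.dosing_compartment - 1, nd - 1] = r
        a[nd:nd + n, nd:nd + n] = self.state_matrix()
        a[m - 1, nd:nd + n] = self.loss  # loss accumulator integrates L(0,j) q_j
        row_loss = a[m - 1].copy()
        entry = 0 if nd else self.dosing_compartment - 1
        return a, row_loss, entry, nd

    def _collapse(self, y: np.ndarray, nd: int) -> np.ndarray:
        """Fold delay-stage content into the dosing compartment column."""
        n = self.n_compartments
        q = y[..., nd:nd + n].copy()
        if nd:
            q[..., self.dosing_compartment - 1] += y[..., :nd].sum(axis=-1)
        return q


@dataclass(frozen=True)
class TracerTimeCourse:
    """Fraction-of-dose kinetics on a time grid.

    ``q[k, j]`` is the fraction of the administered dose in compartment
    ``j+1`` at ``times[k]``; ``cumulative_loss[k]`` is the fraction
    irreversibly lost by then (including any unabsorbed dose).
    """

    times: np.ndarray
    q: np.ndarray
    cumulative_loss: np.ndarray

    def fraction_in(self, labels: int | Iterable[int]) -> np.ndarray:
        """Fraction of dose summed over the given compartment label(s)."""
        idx = np.atleast_1d(np.asarray(labels, dtype=int)) - 1
        return self.q[:, idx].sum(axis=1)

    def mass_balance_residual(self) -> float:
        return float(np.max(np.abs(self.q.sum(axis=1) + self.cumulative_loss - 1.0)))


@dataclass(frozen=True)
class MassState:
    """Steady-state tracee masses (μmol vitamin A per compartment) under a
    constant dietary intake (μmol/day)."""

    masses: np.ndarray
    intake: float


def build_system(
    params: Mapping[str, object],
    topology: Mapping[str, object] | None = None,
) -> CompartmentalSystem:
    """Construct a validated :class:`CompartmentalSystem` from a labeled
    coefficient table.

    Parameters
    ----------
    params
        Mapping with fractional transfer coefficients under keys ``"L_i_j"``
        (also accepted: ``"L(i,j)"``), where ``i = 0`` denotes irreversible
        loss, plus optional keys ``delay_duration``, ``delay_stages`` and
        ``absorption_fraction``.  Role labels (``dosing_compartment``,
        ``plasma_compartment``, ``storage_compartments``) may appear either
        here or in ``topology``; ``topology`` wins.
    topology
        Optional mapping of compartment roles, e.g. loaded from a JSON file.

    Construction fails on any negative or non-finite coefficient, an invalid
    storage set, or a closed system; missing coefficients are treated as
    absent flows (zero), but at least one coefficient must be supplied.
    """
    coeffs: dict[tuple[int, int], float] = {}
    key_re = re.compile(r"^L[_(](\d+)[_,](\d+)\)?$")
    extras: dict[str, object] = {}
    for key, value in params.items():
        m = key_re.match(str(key))
        if m:
            i, j = int(m.group(1)), int(m.group(2))
            if value is None or (isinstance(value, float) and np.isnan(value)):
                continue
            coeffs[(i, j)] = float(value)  # type: ignore[arg-type]
        else:
            extras[str(key)] = value
    if not coeffs:
        raise ModelValidationError("no L(i,j) coefficients supplied")
    if any(j < 1 or i < 0 for i, j in coeffs):
        raise ModelValidationError("compartment labels must be >= 1 (0 only as loss target)")
    n = max(max(i for i, _ in coeffs), max(j for _, j in coeffs))
    n = int(max(n, 1))
    transfer = np.zeros((n, n))
    loss = np.zeros(n)
    for (i, j), v in coeffs.items():
        if i == 0:
            loss[j - 1] = v
        elif i == j:
            raise ModelValidationError(f"self-transfer L({i},{j}) is not allowed")
        else:
            transfer[i - 1, j - 1] = v

    roles: dict[str, object] = dict(extras)
    if topology:
        roles.update(topology)

    def _get(key: str, default=None):
        v = roles.get(key, default)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return default
        return v

    storage = _get("storage_compartments")
    if storage is not None:
        storage = tuple(int(s) for s in storage)  # type: ignore[union-attr]
    delay = None
    dur = _get("delay_duration")
    if dur is not None and float(dur) > 0:
        delay = Delay(duration=float(dur), stages=int(_get("delay_stages", 3)))
    plasma = _get("plasma_compartment")
    return CompartmentalSystem(
        n_compartments=n,
        transfer=transfer,
        loss=loss,
        dosing_compartment=int(_get("dosing_compartment", 1)),
        plasma_compartment=int(plasma) if plasma is not None else None,
        storage_compartments=storage,
        absorption_fraction=float(_get("absorption_fraction", 1.0)),
        delay=delay,
    )


def solve_tracer(system: CompartmentalSystem, times: Sequence[float]) -> TracerTimeCourse:
    """Simulate the fraction-of-dose response of every compartment.

    The dose (scaled by ``absorption_fraction``) enters the dosing
    compartment — or the head of the delay chain — at ``t = 0``; the
    unabsorbed remainder is charged to cumulative loss immediately.  The
    linear constant-coefficient system is evaluated with the matrix
    exponential at each requested time, which is exact for this model class.

    Raises
    ------
    SolverError
        If the solution is non-finite or violates mass balance.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    a, _, entry, nd = system._augmented()
    m = a.shape[0]
    fa = system.absorption_fraction
    y0 = np.zeros(m)
    y0[entry] = fa
    y0[m - 1] = 1.0 - fa  # unabsorbed dose is lost at t=0

    y = np.empty((t.size, m))
    for k, tk in enumerate(t):
        y[k] = expm(a * tk) @ y0 if tk > 0 else y0

    if not np.all(np.isfinite(y)):
        bad = t[~np.all(np.isfinite(y), axis=1)]
        raise SolverError(
            f"non-finite tracer solution at t={bad[:5]} "
            f"(state dim {m}, max |A| = {np.max(np.abs(a)):.3g}/d)")

    q = system._collapse(y, nd)
    cumulative_loss = y[:, m - 1]
    tc = TracerTimeCourse(times=t, q=q, cumulative_loss=cumulative_loss)
    resid = tc.mass_balance_residual()
    if resid > MASS_BALANCE_TOL:
        raise SolverError(f"mass balance violated: max residual {resid:.3e} > {MASS_BALANCE_TOL}")
    return tc


def steady_state_masses(
    system: CompartmentalSystem,
    intake: float | None = None,
    plasma_pool: float | None = None,
) -> MassState:
    """Solve the steady-state tracee balance equations.

    Exactly one anchor must be given: either the dietary vitamin A ``intake``
    (μmol/day, entering via the absorption path), or the plasma retinol pool
    size ``plasma_pool`` (μmol), in which case intake is scaled — linearity
    makes the scaling unique — so the plasma compartment mass equals
    ``plasma_pool`` exactly.
    """
    if (intake is None) == (plasma_pool is None):
        raise ValueError("give exactly one anchor: intake or plasma_pool")
    anchor = intake if intake is not None else plasma_pool
    if not (anchor is not None and np.isfinite(anchor) and anchor > 0):
        raise ValueError(f"anchor must be positive and finite, got {anchor}")
    if plasma_pool is not None and system.plasma_compartment is None:
        raise ModelValidationError("plasma_compartment must be set to anchor by plasma pool")

    a, _, entry, nd = system._augmented()
    # Drop the loss-accumulator row/column: at steady state it is irrelevant.
    a = a[:-1, :-1]
    u = 1.0 if plasma_pool is not None else float(intake) * system.absorption_fraction
    b = np.zeros(a.shape[0])
    b[entry] = u
    try:
        y = np.linalg.solve(a, -b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - openness already validated
        raise ModelValidationError(f"singular balance system: {exc}") from exc

    masses = system._collapse(y, nd)
    eff_intake = float(intake) if intake is not None else 1.0 / system.absorption_fraction
    if plasma_pool is not None:
        scale = plasma_pool / masses[system.plasma_compartment - 1]
        masses = masses * scale
        y = y * scale
        eff_intake = scale / system.absorption_fraction

    # Residual check on the balance equations at the solved scale.
    b_final = np.zeros(a.shape[0])
    b_final[entry] = eff_intake * system.absorption_fraction
    resid = np.abs(a @ y + b_final)
    scale_ref = max(np.max(np.abs(y)) * np.max(np.abs(a)), np.max(np.abs(b_final)))
    if np.max(resid) > STEADY_STATE_TOL * max(scale_ref, 1.0):
        raise SolverError(f"steady-state balance residual {np.max(resid):.3e} too large")
    if np.any(masses < -1e-12 * max(np.max(np.abs(masses)), 1.0)):
        raise SolverError("negative steady-state mass")
    return MassState(masses=np.maximum(masses, 0.0), intake=eff_intake)


def assigned_tbs(state: MassState, system: CompartmentalSystem) -> float:
    """Total body stores: steady-state vitamin A mass (μmol) summed over the
    system's two storage compartments."""
    if system.storage_compartments is None:
        raise ModelValidationError("system has no storage compartments designated")
    if state.masses.shape != (system.n_compartments,):
        raise ValueError("mass state does not match system dimension")
    i, j = system.storage_compartments
    return float(state.masses[i - 1] + state.masses[j - 1])
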