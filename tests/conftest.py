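"""Shared fixtures: baseline systems, solved subjects, and small cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ridsim import (
    BASELINE_COEFFS,
    DEFAULT_TOPOLOGY,
    CohortDesign,
    SubjectSpec,
    build_system,
    generate_cohort,
    rid_quantities,
    solve_tracer,
)

DAY_GRID = np.arange(0.0, 31.0)


def make_adult_system(**overrides):
    """Adult baseline 8-compartment system with delay and absorption set."""
    params = dict(BASELINE_COEFFS["adult"])
    params.update({"delay_duration": 0.4, "delay_stages": 3, "absorption_fraction": 0.8})
    params.update(overrides)
    return build_system(params, topology=DEFAULT_TOPOLOGY)


@pytest.fixture(scope="session")
def adult_system():
    return make_adult_system()


@pytest.fixture(scope="session")
def adult_subject(adult_system):
    return SubjectSpec.from_system("a01", "adult", adult_system, M5=4.0)


@pytest.fixture(scope="session")
def adult_trajectory(adult_subject):
    tc = solve_tracer(adult_subject.system, DAY_GRID)
    return rid_quantities(tc, adult_subject)


def solve_cohort(subjects, times=DAY_GRID):
    return [rid_quantities(solve_tracer(s.system, times), s) for s in subjects]


@pytest.fixture(scope="session")
def small_cohort():
    """Eight generated adults with solved RID trajectories (fast fixture)."""
    subjects = generate_cohort(CohortDesign(n_subjects=8, group="adult", seed=11))
    return subjects, solve_cohort(subjects)


@pytest.fixture(scope="session")
def adult_cohort_20():
    subjects = generate_cohort(CohortDesign(n_subjects=20, group="adult", seed=42))
    return subjects, solve_cohort(subjects)


@pytest.fixture(scope="session")
def child_cohort_20():
    subjects = generate_cohort(CohortDesign(n_subjects=20, group="child", seed=42))
    return subjects, solve_cohort(subjects)


def random_open_system(rng: np.random.Generator, n_max: int = 6):
    """A random open delay-free compartmental system (for oracle checks)."""
    from ridsim import CompartmentalSystem

    from ridsim import ModelValidationError

    while True:  # redraw on the rare closed/trap configuration
        n = int(rng.integers(2, n_max + 1))
        transfer = np.where(rng.random((n, n)) < 0.6, rng.uniform(0.05, 3.0, (n, n)), 0.0)
        np.fill_diagonal(transfer, 0.0)
        loss = np.where(rng.random(n) < 0.7, rng.uniform(0.05, 1.0, n), 0.0)
        if not loss.any():
            loss[int(rng.integers(0, n))] = rng.uniform(0.1, 1.0)
        try:
            return CompartmentalSystem(
                n_compartments=n, transfer=transfer, loss=loss, dosing_compartment=1)
        except ModelValidationError:
            continue
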