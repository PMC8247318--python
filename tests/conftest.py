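"""Shared fixtures.

The expensive full-scale study runs (38 windows x 1e5 steps plus block
bootstrap) are session-scoped and shared between the recovery, plateau and
free-energy tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from claybind import (
    ModelPotentialSpec,
    Well,
    build_model_potential,
    bootstrap_pmf,
    generate_window_set,
    histogram_windows,
    pmf_from_solution,
    solve_wham,
)
from claybind.presets import get_preset

MASTER_SEED = 1
BOOT_SEED = 1001
N_BOOT = 16


@pytest.fixture(scope="session")
def single_well_potential():
    """One inverted-Gaussian well, handy for quick recovery checks."""
    spec = ModelPotentialSpec(
        wells=(Well(center=0.5, depth=6.0, width=0.05),), z_max=1.5
    )
    return build_model_potential(spec)


def _run_study(name: str, with_bootstrap: bool = True):
    preset = get_preset(name)
    potential = preset.potential()
    trajs = generate_window_set(
        potential, preset.layout, preset.window, master_seed=MASTER_SEED
    )
    z_range = (potential.spec.wall_position, preset.layout.limit)
    if with_bootstrap:
        pmf, reps = bootstrap_pmf(
            trajs, n_boot=N_BOOT, seed=BOOT_SEED, z_range=z_range,
            convention="plateau",
        )
    else:
        h = histogram_windows(trajs, z_range=z_range)
        pmf = pmf_from_solution(solve_wham(h), convention="plateau")
        reps = None
    return {
        "preset": preset,
        "potential": potential,
        "trajectories": trajs,
        "pmf": pmf,
        "replicates": reps,
        "z_range": z_range,
    }


@pytest.fixture(scope="session")
def slab_neutral_study():
    return _run_study("slab-neutral")


@pytest.fixture(scope="session")
def slab_anion_study():
    return _run_study("slab-anion")


@pytest.fixture(scope="session")
def periodic_anion_study():
    return _run_study("periodic-anion", with_bootstrap=False)
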