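"""Study presets: slab / periodic emulation for neutral and anionic adsorbate.

Each preset bundles a model free-energy profile, the umbrella-window layout
and sampler settings, the dipole-field coupling for the frame generator, and
the thermodynamic inputs of the standard-state analysis.

The contact minima of the slab profiles sit at the positions where the
reconstructed surface PMFs locate them (0.32/0.46/0.57 nm for the neutral
species, with the periodic layout shifted to 0.35/0.45/0.62 nm; 0.33/0.44 nm
for the anion), plus a shallow solvation ripple near 0.75 nm that keeps the
profile structured until the plateau onset at ~0.9-1.0 nm.  Well depths are
calibrated by a deterministic root-find so each plateau-forming profile has an
analytic standard adsorption free energy equal to its reported headline value
(-5.1 slab / -5.0 periodic for the neutral species, -14.5 for the anion,
kJ/mol).  The periodic-anion profile instead carries a linear drift: the
induced field of fully periodic electrostatics acting on the net charge, under
which no plateau, and hence no standard free energy, exists.

The cross-sectional area A = 12.91 nm^2 is a documented placeholder
reconstructed from a 4 x 7 kaolinite unit-cell surface (a = 0.5154 nm,
b = 0.8942 nm); the source simulations never state their box cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .free_energy import ThermoState, standard_adsorption_free_energy
from .potentials import ModelPotential, ModelPotentialSpec, Well, build_model_potential
from .sampling import UmbrellaWindowSpec, WindowLayout
from .wham import PMFProfile

PRESET_NAMES = ("slab-neutral", "slab-anion", "periodic-neutral", "periodic-anion")

#: 4 x 7 kaolinite unit cells: 4*0.5154 nm x 7*0.8942 nm
DEFAULT_AREA = 4 * 0.5154 * 7 * 0.8942


@dataclass(frozen=True)
class Preset:
    name: str
    potential_spec: ModelPotentialSpec
    layout: WindowLayout
    window: UmbrellaWindowSpec
    area: float
    field_ez: float  # dipole-field coupling for frame generation, kJ/mol/D
    form: str  # adsorbate form: "neutral" | "anion"
    analytic_dg0: float | None  # kJ/mol; None when no plateau exists
    center_tolerance: float = 0.005  # validator tolerance for realized minima

    def potential(self) -> ModelPotential:
        return build_model_potential(
            self.potential_spec, center_tolerance=self.center_tolerance
        )


def analytic_pmf(
    potential: ModelPotential, bin_width: float = 0.002
) -> PMFProfile:
    """Exact profile evaluated on a fine grid, as a PMFProfile (plateau ref)."""
    s = potential.spec
    z = np.arange(s.wall_position + bin_width, s.z_max, bin_width)
    w = potential(z)
    return PMFProfile(z=z, w=w - s.plateau_value, err=np.zeros_like(z), convention="plateau")


def analytic_dg0(
    potential: ModelPotential,
    area: float,
    thermo: ThermoState = ThermoState(),
    **kwargs,
) -> float:
    """Standard adsorption free energy of an exact model profile."""
    res = standard_adsorption_free_energy(
        analytic_pmf(potential), area=area, thermo=thermo, n_resample=0, **kwargs
    )
    return res.dg_standard


def _calibrated_spec(
    centers: tuple[float, ...],
    ratios: tuple[float, ...],
    widths: tuple[float, ...],
    target_dg0: float,
    area: float = DEFAULT_AREA,
    field_slope: float = 0.0,
) -> ModelPotentialSpec:
    """Scale well depths so the analytic dG0 hits the target exactly."""

    def spec_for(scale: float) -> ModelPotentialSpec:
        wells = tuple(
            Well(center=c, depth=scale * r, width=w)
            for c, r, w in zip(centers, ratios, widths)
        )
        return ModelPotentialSpec(wells=wells, field_slope=field_slope)

    def objective(scale: float) -> float:
        pot = ModelPotential(spec_for(scale))  # skip minima validation inside solver
        try:
            return analytic_dg0(pot, area=area) - target_dg0
        except ValueError:
            # wells too shallow for plateau/minima detection: dG0 is far above
            # any (negative) target there, so report a positive mismatch
            return 50.0

    scale = brentq(objective, 0.05, 40.0, xtol=1e-10)
    spec = spec_for(scale)
    build_model_potential(spec)  # validate the calibrated well layout
    return spec


@lru_cache(maxsize=None)
def get_preset(name: str) -> Preset:
    """Look up one of the four study presets by name."""
    base_window = UmbrellaWindowSpec(
        center=0.0, force_constant=1000.0, n_steps=100_000,
        timestep=0.003, friction=1.0, mass=169.073, temperature=300.0,
    )
    layout = WindowLayout(first_center=0.3, spacing=0.1, limit=4.0)
    if name == "slab-neutral":
        spec = _calibrated_spec(
            centers=(0.32, 0.46, 0.57, 0.75),
            ratios=(1.0, 1.15, 0.7, 1.1),
            widths=(0.025, 0.025, 0.025, 0.06),
            target_dg0=-5.1,
        )
        return Preset(name, spec, layout, base_window, DEFAULT_AREA,
                      field_ez=0.0, form="neutral", analytic_dg0=-5.1)
    if name == "periodic-neutral":
        # neutral species: the induced field exerts no net force (flat tail)
        # but still couples to the molecular dipole in the frame ensembles
        spec = _calibrated_spec(
            centers=(0.35, 0.45, 0.62, 0.78),
            ratios=(1.0, 1.1, 0.7, 1.1),
            widths=(0.025, 0.025, 0.025, 0.06),
            target_dg0=-5.0,
        )
        return Preset(name, spec, layout, base_window, DEFAULT_AREA,
                      field_ez=1.5, form="neutral", analytic_dg0=-5.0)
    if name == "slab-anion":
        spec = _calibrated_spec(
            centers=(0.33, 0.44, 0.75),
            ratios=(1.0, 0.55, 0.14),
            widths=(0.04, 0.035, 0.06),
            target_dg0=-14.5,
        )
        window = replace(base_window, timestep=0.0015)
        return Preset(name, spec, layout, window, DEFAULT_AREA,
                      field_ez=0.0, form="anion", analytic_dg0=-14.5)
    if name == "periodic-anion":
        # same contact wells as the slab anion but with the induced-field
        # drift retained: the PMF rises continuously and never plateaus.
        # the drift shifts the shallow solvation ripple by ~0.02 nm, so the
        # layout validator runs with a loosened centre tolerance here
        slab = get_preset("slab-anion")
        spec = ModelPotentialSpec(
            wells=slab.potential_spec.wells, field_slope=5.0
        )
        build_model_potential(spec, center_tolerance=0.05)
        window = replace(base_window, timestep=0.0015)
        return Preset(name, spec, layout, window, DEFAULT_AREA,
                      field_ez=1.5, form="anion", analytic_dg0=None,
                      center_tolerance=0.05)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
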