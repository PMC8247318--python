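"""Analytic one-dimensional model free-energy surfaces along the surface normal.

The reaction coordinate z is the distance between the adsorbate centre of mass
and the plane of surface oxygen atoms.  A model profile is a superposition of

* a hard repulsive wall just above the surface (half-harmonic, very stiff),
* one or more inverted-Gaussian adsorption wells,
* a constant plateau level far from the surface, and
* an optional linear drift term emulating the induced electrostatic field a
  charged adsorbate feels when the artificial polarization of fully periodic
  electrostatics is retained (slab-corrected models have no drift).

These profiles serve as ground truth: umbrella windows are sampled on them and
the reconstruction pipeline is expected to recover them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class PotentialSpecError(ValueError):
    """Raised when a model-potential specification is inconsistent."""


@dataclass(frozen=True)
class Well:
    """One inverted-Gaussian adsorption well.

    Parameters
    ----------
    center : float
        Position of the well minimum, nm.
    depth : float
        Well depth epsilon >= 0, kJ/mol.  The profile passes through
        ``plateau_value - depth`` at the centre (up to neighbour overlap).
    width : float
        Gaussian width w > 0, nm; the well term is
        ``-depth * exp(-(z - center)^2 / (2 w^2))``.
    """

    center: float
    depth: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise PotentialSpecError(f"well width must be > 0, got {self.width}")
        if self.depth < 0:
            raise PotentialSpecError(f"well depth must be >= 0, got {self.depth}")


@dataclass(frozen=True)
class ModelPotentialSpec:
    """Specification of a model free-energy profile U(z).

    Attributes
    ----------
    wells : sequence of Well
        Adsorption wells, any order.
    wall_position : float
        Position of the repulsive wall, nm.  Must lie below every well centre.
    plateau_value : float
        Free-energy level far from the surface, kJ/mol (conventionally 0).
    field_slope : float
        Linear drift d U/d z beyond the wall, kJ mol^-1 nm^-1; 0 for slab
        (polarization-corrected) models, > 0 emulates the induced field acting
        on an anion in the fully periodic model.
    z_max : float
        Upper end of the modelled coordinate range, nm.
    wall_stiffness : float
        Half-harmonic wall stiffness, kJ mol^-1 nm^-2.
    """

    wells: tuple[Well, ...] = ()
    wall_position: float = 0.15
    plateau_value: float = 0.0
    field_slope: float = 0.0
    z_max: float = 4.0
    wall_stiffness: float = 1.0e5

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        if self.z_max <= self.wall_position:
            raise PotentialSpecError(
                f"z_max ({self.z_max}) must exceed wall_position ({self.wall_position})"
            )
        if self.wall_stiffness <= 0:
            raise PotentialSpecError("wall_stiffness must be positive")
        for w in self.wells:
            if not (self.wall_position < w.center < self.z_max):
                raise PotentialSpecError(
                    f"well centre {w.center} nm outside (wall_position, z_max) "
                    f"= ({self.wall_position}, {self.z_max})"
                )


class ModelPotential:
    """Evaluable model profile U(z) with analytic gradient.

    Instances are callable: ``U(z)`` returns energies in kJ/mol for scalar or
    array ``z`` (nm).  The linear field term is referenced to the wall position
    so that with ``field_slope = 0`` the profile equals ``plateau_value``
    wherever the wells have decayed.
    """

    def __init__(self, spec: ModelPotentialSpec):
        self.spec = spec
        ws = spec.wells
        self._centers = np.array([w.center for w in ws], dtype=float)
        self._depths = np.array([w.depth for w in ws], dtype=float)
        self._widths = np.array([w.width for w in ws], dtype=float)

    def _wells_energy(self, z: np.ndarray) -> np.ndarray:
        if self._centers.size == 0:
            return np.zeros_like(z)
        d = (z[..., None] - self._centers) / self._widths
        return -(self._depths * np.exp(-0.5 * d * d)).sum(axis=-1)

    def _wells_gradient(self, z: np.ndarray) -> np.ndarray:
        if self._centers.size == 0:
            return np.zeros_like(z)
        dz = z[..., None] - self._centers
        g = self._depths * dz / self._widths**2 * np.exp(-0.5 * (dz / self._widths) ** 2)
        return g.sum(axis=-1)

    def __call__(self, z, include_wall: bool = True):
        s = self.spec
        z = np.asarray(z, dtype=float)
        u = s.plateau_value + s.field_slope * (z - s.wall_position) + self._wells_energy(z)
        if include_wall:
            pen = np.minimum(z - s.wall_position, 0.0)
            u = u + 0.5 * s.wall_stiffness * pen * pen
        return u if u.ndim else float(u)

    def gradient(self, z, include_wall: bool = True):
        """dU/dz in kJ mol^-1 nm^-1."""
        s = self.spec
        z = np.asarray(z, dtype=float)
        g = np.full_like(z, s.field_slope) + self._wells_gradient(z)
        if include_wall:
            pen = np.minimum(z - s.wall_position, 0.0)
            g = g + s.wall_stiffness * pen
        return g if g.ndim else float(g)


def build_model_potential(
    spec: ModelPotentialSpec,
    *,
    center_tolerance: float = 0.005,
    grid_step: float = 5.0e-4,
) -> ModelPotential:
    """Build and validate an evaluable profile from a specification.

    Validation rejects well layouts whose superposition creates minima other
    than the declared ones, or shifts a declared minimum by more than
    ``center_tolerance`` nm (0.005 by default): overlapping Gaussians can merge
    or displace minima silently, which would break every recovery guarantee
    downstream.

    Raises
    ------
    PotentialSpecError
        If the realized minima do not correspond one-to-one with the declared
        well centres (diagnostic lists both sets).
    """
    pot = ModelPotential(spec)
    if spec.wells:
        z = np.arange(spec.wall_position + grid_step, spec.z_max, grid_step)
        u = pot(z)
        interior = (u[1:-1] < u[:-2]) & (u[1:-1] < u[2:])
        minima = z[1:-1][interior]
        centers = np.sort(pot._centers)
        # with a strong positive drift the outermost shallow wells may cease to
        # be minima at all; that is an invalid construction for recovery work
        if minima.size != centers.size or np.any(
            np.abs(np.sort(minima) - centers) > center_tolerance
        ):
            raise PotentialSpecError(
                "well superposition does not reproduce the declared minima: "
                f"declared centres {centers.tolist()} nm, realized minima "
                f"{np.round(minima, 4).tolist()} nm (tolerance "
                f"{center_tolerance} nm); separate the wells or reduce widths"
            )
    return pot
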