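"""Standard adsorption free energy from a PMF.

The standard (1 M) adsorption free energy splits into a PMF-integration term
and a standard-state volume correction,

    dG0 = dG + dG_V
    dG  = -k_B T ln( (1/dz_u) * integral_bound exp(-beta W(z)) dz )
    dG_V = -k_B T ln( A * dz_u / V0 )

with W zero-referenced to the plateau of the unbound region, A the surface
cross-sectional area sampled by the unbound adsorbate, V0 = 1.66054 nm^3 the
volume per molecule at 1 M and dz_u an arbitrary reference length that cancels
exactly in the sum.  The bound region runs from the repulsive wall to the
plateau onset; a profile that never levels off (the drifting PMF of a charged
adsorbate under the induced field of fully periodic electrostatics) has no
defined unbound state and therefore no standard adsorption free energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .constants import KB, STANDARD_VOLUME_1M, beta
from .wham import PMFProfile


class NoPlateauError(RuntimeError):
    """The PMF has no unbound plateau; dG0 is undefined for this profile."""


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic reference state.

    ``standard_concentration`` is in mol/L; the per-molecule standard volume
    is ``V0 = 1.66054 / C0`` nm^3 (1.66054 nm^3 at 1 M).
    """

    temperature: float = 300.0
    standard_concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.standard_concentration <= 0:
            raise ValueError("standard_concentration must be positive")

    @property
    def kt(self) -> float:
        return KB * self.temperature

    @property
    def standard_volume(self) -> float:
        """Volume per molecule at the standard concentration, nm^3."""
        return STANDARD_VOLUME_1M / self.standard_concentration


@dataclass(frozen=True)
class PlateauResult:
    found: bool
    onset: float | None = None
    level: float | None = None


@dataclass(frozen=True)
class AdsorptionResult:
    """Standard adsorption free energy and its ingredients (kJ/mol, nm)."""

    dg: float
    dg_volume: float
    dg_standard: float
    dg_standard_err: float
    bound_region: tuple[float, float]
    plateau_onset: float
    plateau_level: float
    area: float
    reference_length: float
    minima: tuple[tuple[float, float], ...] = ()


def find_minima(
    pmf: PMFProfile, prominence: float = 1.0
) -> list[tuple[float, float]]:
    """Locate local PMF minima with at least ``prominence`` kJ/mol prominence.

    Positions are refined below the bin width by a quadratic fit through the
    minimum bin and its two neighbours.  A monotone profile yields an empty
    list.
    """
    if pmf.z.size < 3:
        raise ValueError("PMF must have at least 3 defined bins")
    idx, _ = find_peaks(-pmf.w, prominence=prominence)
    out = []
    for i in idx:
        if 0 < i < pmf.z.size - 1:
            z3, w3 = pmf.z[i - 1 : i + 2], pmf.w[i - 1 : i + 2]
            a, b, c = np.polyfit(z3 - z3[1], w3, 2)
            if a > 0:
                dz = -b / (2 * a)
                out.append((float(z3[1] + dz), float(a * dz * dz + b * dz + c)))
                continue
        out.append((float(pmf.z[i]), float(pmf.w[i])))
    return sorted(out)


def detect_plateau(
    pmf: PMFProfile,
    slope_tol: float = 1.0,
    run_length: float = 0.3,
    min_prominence: float = 1.0,
) -> PlateauResult:
    """Find where the PMF levels off into its unbound plateau.

    Scans sliding linear fits of length ``run_length`` (nm) starting beyond
    the last detected minimum.  A fit qualifies when its slope magnitude is
    below ``slope_tol`` (kJ mol^-1 nm^-1) plus twice the slope's standard
    error propagated from the PMF's per-bin uncertainties, so statistical
    noise in a genuinely flat reconstructed tail cannot veto the plateau while
    a real drift still fails the test.  The onset is the smallest start from
    which the fit and every fit starting within the following ``run_length``
    qualify (flatness must persist, so a chance-flat stretch bridging a dip
    does not masquerade as the plateau).  The level is the mean PMF beyond the
    onset.  Returns a no-plateau result when nothing qualifies, as for a
    profile drifting under an induced field.
    """
    minima = find_minima(pmf, prominence=min_prominence) if pmf.z.size >= 3 else []
    z_start = minima[-1][0] if minima else float(pmf.z[0])
    starts = np.flatnonzero(
        (pmf.z >= z_start) & (pmf.z + 0.999 * run_length <= pmf.z[-1])
    )
    ok = np.zeros(starts.size, dtype=bool)
    for j, i in enumerate(starts):
        z0 = pmf.z[i]
        sel = (pmf.z >= z0) & (pmf.z <= z0 + run_length)
        x, y = pmf.z[sel], pmf.w[sel]
        if x.size < 3:
            continue
        slope = np.polyfit(x, y, 1)[0]
        dx = x - x.mean()
        sxx = float(dx @ dx)
        se = float(np.sqrt((dx * dx) @ (pmf.err[sel] ** 2))) / sxx if sxx else 0.0
        # noise allowance is capped at slope_tol so statistical uncertainty can
        # at most double the threshold, never drown out a real drift
        ok[j] = abs(slope) < slope_tol + min(2.0 * se, slope_tol)
    for j in range(starts.size):
        if not ok[j]:
            continue
        z0 = float(pmf.z[starts[j]])
        ahead = ok[(pmf.z[starts] >= z0) & (pmf.z[starts] <= z0 + run_length)]
        if np.all(ahead):
            tail = pmf.z >= z0
            return PlateauResult(
                found=True, onset=z0, level=float(pmf.w[tail].mean())
            )
    return PlateauResult(found=False)


def _bound_slice(pmf: PMFProfile, bound_region: tuple[float, float]) -> np.ndarray:
    lo, hi = bound_region
    if hi <= lo:
        raise ValueError(f"empty bound region [{lo}, {hi}]")
    sel = (pmf.z >= lo) & (pmf.z <= hi)
    if not np.any(sel):
        raise ValueError(f"no defined PMF bins inside bound region [{lo}, {hi}]")
    zb = pmf.z[sel]
    step = np.median(np.diff(pmf.z))
    gaps = np.flatnonzero(np.diff(zb) > 1.5 * step)
    if gaps.size:
        missing = [(float(zb[g]), float(zb[g + 1])) for g in gaps]
        raise ValueError(
            f"bound region [{lo}, {hi}] nm contains undefined bins between {missing}"
        )
    return sel


def integrate_bound_state(
    pmf: PMFProfile,
    bound_region: tuple[float, float],
    thermo: ThermoState,
    reference_length: float = 1.0,
) -> float:
    """PMF-integration term dG (kJ/mol) over the bound region.

    The PMF must already be zero-referenced to its plateau level; the choice
    of ``reference_length`` (dz_u, nm) shifts dG but cancels against the
    volume correction.
    """
    sel = _bound_slice(pmf, bound_region)
    b = beta(thermo.temperature)
    integral = np.trapezoid(np.exp(-b * pmf.w[sel]), pmf.z[sel])
    return float(-thermo.kt * np.log(integral / reference_length))


def volume_correction(
    area: float, reference_length: float, thermo: ThermoState
) -> float:
    """Standard-state volume correction dG_V = -k_B T ln(A dz_u / V0), kJ/mol."""
    if area <= 0 or reference_length <= 0:
        raise ValueError("area and reference_length must be positive")
    return float(
        -thermo.kt * np.log(area * reference_length / thermo.standard_volume)
    )


def standard_adsorption_free_energy(
    pmf: PMFProfile,
    area: float,
    thermo: ThermoState = ThermoState(),
    slope_tol: float = 1.0,
    run_length: float = 0.3,
    min_prominence: float = 1.0,
    reference_length: float = 1.0,
    n_resample: int = 200,
    seed: int = 0,
    replicates: np.ndarray | None = None,
) -> AdsorptionResult:
    """Full chain: plateau detection -> re-reference -> integration -> dG0.

    The bound region is [first defined bin, plateau onset].  The uncertainty
    on dG0 is preferably the std over bootstrap PMF ``replicates`` (one row
    per replicate, aligned with ``pmf.z``, NaN where undefined), which carry
    the between-bin correlation of the reconstruction error; without them it
    falls back to ``n_resample`` profiles perturbed per-bin independently by
    ``pmf.err``.  The plateau level is re-estimated per replicate; the onset
    is held fixed.

    Raises
    ------
    NoPlateauError
        If the profile never levels off (e.g. the continuously rising PMF of
        an anion under the periodic model's induced field).
    """
    plateau = detect_plateau(
        pmf, slope_tol=slope_tol, run_length=run_length, min_prominence=min_prominence
    )
    if not plateau.found:
        raise NoPlateauError(
            "PMF shows no plateau within the profile (continuously trending tail); "
            "the unbound reference state is undefined and dG0 cannot be computed"
        )
    bound = (float(pmf.z[0]), plateau.onset)
    minima = tuple(find_minima(pmf, prominence=min_prominence))

    def _dg0(w: np.ndarray) -> float:
        level = float(w[pmf.z >= plateau.onset].mean())
        shifted = PMFProfile(
            z=pmf.z, w=w - level, err=np.zeros_like(w),
            convention=pmf.convention, temperature=pmf.temperature,
        )
        dg = integrate_bound_state(shifted, bound, thermo, reference_length)
        return dg + volume_correction(area, reference_length, thermo)

    dg_v = volume_correction(area, reference_length, thermo)
    dg0 = _dg0(pmf.w)
    err = 0.0
    if replicates is not None:
        draws = []
        for row in np.asarray(replicates, dtype=float):
            if np.all(np.isfinite(row[(pmf.z >= bound[0]) & (pmf.z <= bound[1])])):
                w = np.where(np.isfinite(row), row, pmf.w)
                draws.append(_dg0(w))
        if len(draws) >= 2:
            err = float(np.std(draws, ddof=1))
    elif np.any(pmf.err > 0) and n_resample >= 2:
        rng = np.random.default_rng(seed)
        draws = [
            _dg0(pmf.w + pmf.err * rng.standard_normal(pmf.w.size))
            for _ in range(n_resample)
        ]
        err = float(np.std(draws, ddof=1))
    return AdsorptionResult(
        dg=dg0 - dg_v,
        dg_volume=dg_v,
        dg_standard=dg0,
        dg_standard_err=err,
        bound_region=bound,
        plateau_onset=plateau.onset,
        plateau_level=plateau.level,
        area=area,
        reference_length=reference_length,
        minima=minima,
    )
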