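# Methods

## The model and what it stands in for

The package studies adsorption of a small polar molecule (glyphosate-like,
neutral or −1 anion) on a hydroxylated mineral face through a one-dimensional
reaction coordinate z: the distance between the adsorbate's centre of mass
and the plane of surface oxygen atoms. Real studies obtain the free-energy
profile W(z) from all-atom molecular dynamics with explicit water; here the
profile is an analytic *model potential* that the sampling, reconstruction
and analysis machinery must recover. That inversion of roles is the point:
every quantity the pipeline reports has an exact reference value.

A model profile is

    U(z) = plateau + s·(z − z_wall) − Σ_i ε_i exp(−(z − z_i)² / 2w_i²) + wall(z)

with inverted-Gaussian adsorption wells (centre z_i, depth ε_i, width w_i), a
half-harmonic wall of stiffness 10⁵ kJ mol⁻¹ nm⁻² below z_wall = 0.15 nm,
and a linear drift s ≥ 0. The drift emulates the induced electrostatic field
that acts on a *charged* adsorbate when the artificial polarization of fully
periodic 3-D electrostatics is not removed; slab-corrected models have s = 0
and a genuine plateau. A builder validates that the superposed wells realize
exactly the declared minima (within 0.005 nm): overlapping Gaussians merge or
displace minima silently, which would invalidate every recovery statement
downstream.

### Study presets

Four presets fix the study conditions. Contact-minimum positions follow the
reconstructed surface PMFs: 0.32/0.46/0.57 nm (slab, neutral),
0.35/0.45/0.62 nm (periodic, neutral), 0.33/0.44 nm (slab, anion). Each
plateau-forming profile also carries one shallow, broad "solvation ripple"
well near 0.75 nm: real PMFs in water keep oscillatory structure out to
0.9–1.0 nm before levelling, and the ripple places the synthetic plateau
onset in that band instead of at ~0.65 nm. Well depths are not free
parameters: a deterministic root-find rescales them (fixed ratios, fixed
widths) until the profile's analytic standard adsorption free energy equals
the preset's headline value — −5.1 kJ/mol (slab-neutral), −5.0
(periodic-neutral), −14.5 (slab-anion) — evaluated with the same plateau
detection and integration code the pipeline itself uses. The periodic-anion
preset reuses the slab-anion wells with drift s = 5 kJ mol⁻¹ nm⁻¹; it has no
plateau and deliberately no ΔG⁰.

The cross-sectional area A = 12.91 nm² is a documented placeholder
reconstructed from a 4 × 7 kaolinite unit-cell surface (a = 0.5154 nm,
b = 0.8942 nm); any real analysis must supply its own box cross-section,
and `A` is therefore a required input of the `dg` stage.

## Umbrella sampling

Windows restrain z with ½k(z − z₀)², k = 1,000 kJ mol⁻¹ nm⁻² at 300 K, on
ladders of 0.1 nm spacing (38 windows from 0.3 to 4.0 nm by default; the
44-window protocol layout counts from 0.0 nm). Dynamics are overdamped
Langevin integrated by Euler–Maruyama in GROMACS-consistent units (amu, nm,
ps, kJ/mol; k_B = 0.0083144621 kJ mol⁻¹ K⁻¹), with mass 169.073 amu
(glyphosate) and friction 1 ps⁻¹. Each window runs 10⁵ retained steps after
discarding a leading 10 % as equilibration — a desk-scale stand-in for the
100 ps equilibration / 10 ns production protocol of surface studies; all
statistical tolerances in the tests are set for this problem size.

Two numerical choices matter:

- **Implicit wall.** An explicit Euler step on a 10⁵ kJ mol⁻¹ nm⁻² wall is
  unstable at any timestep the soft forces allow, so the wall force (linear)
  is integrated implicitly — a closed-form solve per step, unconditionally
  stable, leaving the wall model and stiffness unchanged.
- **Per-window timesteps.** The stationary-distribution bias of
  Euler–Maruyama scales with a = k_eff·Δt/(mγ) (variance inflated by
  1/(1 − a/2)), while decorrelation *improves* with Δt. Each window therefore
  gets Δt = 0.05·mγ/k_eff from the stiffness local to its bias centre
  (well curvature plus k): windows riding a stiff well step at ~1 fs,
  windows on the flat tail at ~8 fs and decorrelate an order of magnitude
  faster within the same sample budget. At a = 0.05 the variance bias is
  under 3 %, well inside the bootstrap uncertainty at these run lengths.

Per-window seeds are master_seed + window index; a window simulated alone is
bit-identical to the same window inside the vectorized ladder.

## WHAM and uncertainties

The self-consistent WHAM equations are iterated to max|Δf_i| < 10⁻⁶ kJ/mol
(cap 10⁵ iterations), gauge f₁ = 0, on 0.01 nm bins — fine enough to resolve
minima 0.1 nm apart. Bins with zero total counts are excluded; a zero-count
gap splitting the sampled support is an error (denser windows needed), except
that stray fringe fragments holding < 0.5 % of all counts (single outlier
samples beyond the last window) are dropped rather than fatal — this case
arises routinely in bootstrap replicates. Non-convergence returns the best
iterate flagged, and downstream use must be forced explicitly.

Per-bin uncertainties come from a moving-block bootstrap *within* each
window: block length is the window's integrated autocorrelation time (Sokal
windowing, minimum 10 samples), replicates are re-binned and re-solved, and
the per-bin standard deviation over replicates is reported. The replicate
matrix itself is kept, because the dominant reconstruction error is a
correlated "stitching" drift accumulated across window joins; propagating
independent per-bin noise into ΔG⁰ would underestimate its uncertainty
severalfold. ΔG⁰'s error is therefore the spread of ΔG⁰ recomputed over
bootstrap replicates (per-bin Gaussian resampling remains as a fallback when
only a PMF file with error bars is available, as in the `dg` CLI stage).

## Minima, plateau, ΔG⁰

Minima are local PMF minima above a prominence threshold (default
1 kJ/mol), refined below the bin width by a 3-point quadratic fit. The
plateau onset is found by sliding linear fits over 0.3 nm: a fit qualifies
when |slope| < 1 kJ mol⁻¹ nm⁻¹ plus twice the slope's standard error
propagated from the per-bin uncertainties — capped at one extra
slope-tolerance, so noise can at most double the threshold and a real drift
(5 kJ mol⁻¹ nm⁻¹ in the periodic-anion preset) always fails. The onset is
the first start from which flatness persists for a further full run length;
this rejects chance-flat stretches bridging later structure. No qualifying
onset ⇒ an explicit no-plateau result and a refusal to compute ΔG⁰.

The bound region is [wall, onset]; W is re-referenced to the mean level
beyond the onset; ΔG is a trapezoidal integral of e^(−βW); ΔG_V =
−k_B T ln(A·Δz_u/V⁰) with V⁰ = 1.66054/C⁰ nm³. Δz_u (default 1 nm) cancels
identically in ΔG⁰ — asserted to 10⁻⁹ in the tests. The split point is
insensitive because e^(−βW) ≈ 1 near the plateau, where the integrand and
the reference cancel.

## Toy molecular frames and structural analyses

The rigid glyphosate model has group-resolved charges (COOH, PO(OH)₂, NH,
backbone) with a −0.25/+0.25 carboxyl→phosphonic polarity so the molecular
dipole is large and roughly end-to-end; neutral-form charges are uniformly
rescaled so |μ| about the centre of mass is exactly 8 D, inside the observed
7.5–9 D band of field-aligned orientation peaks. The anion (carboxylate −1)
keeps its constructed charges. The surface is a regular lattice of neutral
OH pairs (O at z = 0, H at 0.097 nm, laterally jittered per frame) standing
in for the aluminol face; O atoms accept and (through their H) donate
hydrogen bonds.

Frame ensembles draw the rigid-body orientation from the Boltzmann
distribution of a dipole in a uniform z-field, energy −μ_z E (exact
inverse-CDF sampling of cos θ; uniform azimuth and spin), and reject poses
that dip a heavy atom below 0.24 nm (hydrogens 0.14 nm) above the oxygen
plane — the hard-core exclusion a thermal ensemble imposes, which at contact
favours surface-parallel poses. E = 0 reproduces free tumbling (slab); the
periodic presets carry E > 0 for the orientation analyses. Note what this
generator does **not** emulate: internal flexibility, explicit water,
counterions, and energy-weighted (beyond hard-core) orientation statistics —
so passing tests validate the analysis machinery and the dipole physics, not
force-field realism.

Analyses use the minimum image in x and y only (open z, single surface).
Hydrogen bonds use the community-standard geometric criterion — donor to
acceptor ≤ 0.35 nm and D–H···A deviation from linearity ≤ 30°, both
configurable; donor and acceptor must belong to different functional groups.
Interaction energies are bare Coulomb (f = 138.935485 kJ mol⁻¹ nm e⁻²) plus
Lennard-Jones with Lorentz–Berthelot combination, hard-truncated at 1.4 nm
with no shift or tail corrections. Occurrence tables report, per functional
group and centre-of-mass distance bin (0.33/0.44/0.60 nm neutral,
0.33/0.37/0.55 nm anion), the fraction of frames with at least one hydrogen
bond involving the group.

## Known limitations

- The reconstruction error at 10⁵ steps/window is dominated by the
  window-stitching random walk (~0.15–0.4 kJ/mol per bin); headline ΔG⁰
  recoveries are accurate to their quoted bootstrap sigma, not better.
- Plateau-onset detection quantizes to the bin grid and, on noisy profiles,
  can move the bound/unbound split by a few bins; the effect on ΔG⁰ is
  within the bootstrap error but visible in the onset itself.
- The dipole-ensemble generator conditions on hard-core feasibility only;
  interaction-energy histograms are realistic in scale but not
  Boltzmann-weighted over orientations.
- Charged selections' dipole moments use the centre-of-mass origin gauge;
  values for the anion are gauge-dependent by construction and documented as
  such.
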