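"""Weighted histogram analysis method (WHAM) for 1-D umbrella sampling.

The unbiased probability profile P(z) and per-window free-energy shifts f_i
solve the coupled equations

    P(z_b) = sum_i n_i(z_b) / sum_i N_i exp(-beta (V_i(z_b) - f_i))
    f_i    = -k_B T ln sum_b P(z_b) exp(-beta V_i(z_b)) dz

with V_i the harmonic bias of window i.  They are solved by direct
self-consistent iteration with the gauge f_1 = 0; the PMF follows as
W(z) = -k_B T ln P(z) shifted to a stated zero-reference convention.
Uncertainties come from a moving-block bootstrap over the window time series,
which respects the serial correlation of Langevin samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import KB, beta
from .sampling import WindowTrajectory


class WhamError(RuntimeError):
    """Raised for invalid WHAM inputs (empty windows, disconnected support)."""


@dataclass(frozen=True)
class BiasedHistogramSet:
    """Binned biased counts of a set of umbrella windows.

    ``counts[i, b]`` holds window i's samples in bin b; ``centers``/
    ``force_constants`` are the harmonic bias parameters; ``bias_offsets``
    (kJ/mol, default 0) allow a constant shift per window bias, which must not
    affect the PMF.
    """

    edges: np.ndarray
    counts: np.ndarray
    centers: np.ndarray
    force_constants: np.ndarray
    temperature: float
    bias_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        counts = np.asarray(self.counts)
        if np.any(np.diff(edges) <= 0):
            raise WhamError("bin edges must be strictly increasing")
        if counts.shape != (len(self.centers), edges.size - 1):
            raise WhamError("counts shape must be (n_windows, n_bins)")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        object.__setattr__(
            self, "force_constants", np.asarray(self.force_constants, dtype=float)
        )
        off = self.bias_offsets
        off = np.zeros(len(self.centers)) if off is None else np.asarray(off, float)
        object.__setattr__(self, "bias_offsets", off)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def totals(self) -> np.ndarray:
        """Per-window sample totals N_i."""
        return self.counts.sum(axis=1)

    def bias_energies(self) -> np.ndarray:
        """V_i(z_b), shape (n_windows, n_bins), kJ/mol."""
        dz = self.bin_centers[None, :] - self.centers[:, None]
        return 0.5 * self.force_constants[:, None] * dz * dz + self.bias_offsets[:, None]


@dataclass(frozen=True)
class WhamSolution:
    bin_centers: np.ndarray
    probability: np.ndarray  # density over defined bins; sum(P * dz) = 1
    shifts: np.ndarray  # f_i, kJ/mol, gauge f_1 = 0
    n_iterations: int
    converged: bool
    residual: float
    bin_width: float
    temperature: float
    defined: np.ndarray  # mask over the original bins


@dataclass(frozen=True)
class PMFProfile:
    """Reconstructed potential of mean force over defined bins."""

    z: np.ndarray
    w: np.ndarray
    err: np.ndarray
    convention: str = "global-min"
    temperature: float = 300.0

    def __post_init__(self) -> None:
        for name in ("z", "w", "err"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.err < 0):
            raise ValueError("uncertainties must be non-negative")


def histogram_windows(
    trajectories: Sequence[WindowTrajectory],
    bin_width: float = 0.01,
    z_range: tuple[float, float] | None = None,
) -> BiasedHistogramSet:
    """Bin window samples on a common grid.

    The grid spans ``z_range`` (default: the sampled range padded to whole
    bins).  Sample counts are conserved exactly; empty bins are kept as zeros.

    Raises
    ------
    WhamError
        For fewer than two windows, inconsistent temperatures, or a window
        whose retained samples fall entirely outside the grid.
    """
    if len(trajectories) < 2:
        raise WhamError(f"need >= 2 windows, got {len(trajectories)}")
    temps = {t.spec.temperature for t in trajectories}
    if len(temps) != 1:
        raise WhamError(f"windows disagree on temperature: {sorted(temps)}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if z_range is None:
        lo = min(t.samples.min() for t in trajectories)
        hi = max(t.samples.max() for t in trajectories)
    else:
        lo, hi = z_range
    first = np.floor(lo / bin_width) * bin_width
    n_bins = int(np.ceil((hi - first) / bin_width)) + 1
    edges = first + bin_width * np.arange(n_bins + 1)

    counts = np.empty((len(trajectories), n_bins), dtype=np.int64)
    for i, t in enumerate(trajectories):
        c, _ = np.histogram(t.samples, bins=edges)
        if c.sum() == 0:
            raise WhamError(
                f"window {i} (z0={t.spec.center} nm) has no samples inside the grid"
            )
        counts[i] = c
    return BiasedHistogramSet(
        edges=edges,
        counts=counts,
        centers=np.array([t.spec.center for t in trajectories]),
        force_constants=np.array([t.spec.force_constant for t in trajectories]),
        temperature=temps.pop(),
    )


def solve_wham(
    h: BiasedHistogramSet,
    tol: float = 1.0e-6,
    max_iter: int = 100_000,
) -> WhamSolution:
    """Self-consistent WHAM iteration.

    Iterates the coupled equations until ``max_i |delta f_i| < tol`` (kJ/mol).
    Bins with zero total counts are excluded from the solution; a zero-count
    gap inside the sampled support is rejected since the profile across it is
    not determined by the data.
    """
    total = h.counts.sum(axis=0)
    defined = total > 0
    idx = np.flatnonzero(defined)
    if idx.size == 0:
        raise WhamError("all bins are empty")
    if np.any(total[idx[0] : idx[-1] + 1] == 0):
        # segments of contiguous nonzero bins; stray single-sample fringe
        # fragments are dropped, a substantive split is a real error
        breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        segments = np.split(idx, breaks)
        seg_counts = np.array([total[s].sum() for s in segments])
        main = int(np.argmax(seg_counts))
        stray = seg_counts.sum() - seg_counts[main]
        if stray > 0.005 * seg_counts.sum():
            gaps = np.flatnonzero(total[idx[0] : idx[-1] + 1] == 0) + idx[0]
            zc = h.bin_centers[gaps]
            raise WhamError(
                "sampled support is disconnected: zero-count bins at z = "
                f"{np.round(zc, 4).tolist()} nm split the histogram; add "
                "windows to bridge the gap"
            )
        defined = np.zeros_like(defined)
        defined[segments[main]] = True
    if np.any(h.totals == 0):
        bad = np.flatnonzero(h.totals == 0).tolist()
        raise WhamError(f"windows {bad} have zero retained samples")

    b = beta(h.temperature)
    dz = float(np.mean(np.diff(h.edges)))
    v = h.bias_energies()[:, defined]  # (nw, nb_def)
    m_b = total[defined].astype(float)  # total counts per defined bin
    n_i = h.totals.astype(float)
    boltz = np.exp(-b * v)

    f = np.zeros(len(n_i))
    converged = False
    residual = np.inf
    for it in range(1, max_iter + 1):
        denom = (n_i * np.exp(b * f)) @ boltz  # sum_i N_i e^{beta f_i} e^{-beta V_ib}
        p = m_b / denom
        p /= p.sum() * dz
        z_i = boltz @ (p * dz)
        f_new = -np.log(z_i) / b
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            converged = True
            break
    # final probability consistent with the converged shifts
    denom = (n_i * np.exp(b * f)) @ boltz
    p = m_b / denom
    p /= p.sum() * dz
    return WhamSolution(
        bin_centers=h.bin_centers[defined],
        probability=p,
        shifts=f,
        n_iterations=it,
        converged=converged,
        residual=residual,
        bin_width=dz,
        temperature=h.temperature,
        defined=defined,
    )


def pmf_from_solution(
    solution: WhamSolution,
    convention: str = "global-min",
    err: np.ndarray | None = None,
    force: bool = False,
) -> PMFProfile:
    """Turn a WHAM solution into a zero-referenced PMF.

    ``convention`` is ``"global-min"`` (lowest value set to zero, as used when
    comparing energy profiles) or ``"plateau"`` (mean over the outermost 10 %
    of defined bins set to zero).  Unconverged solutions are refused unless
    ``force`` is given.
    """
    if not solution.converged and not force:
        raise WhamError(
            f"WHAM did not converge (residual {solution.residual:.2e} kJ/mol); "
            "pass force=True to use the best iterate"
        )
    p = solution.probability
    if np.all(p <= 0):
        raise WhamError("probability profile is identically zero")
    w = -KB * solution.temperature * np.log(p)
    if convention == "global-min":
        w = w - w.min()
    elif convention == "plateau":
        n_tail = max(1, p.size // 10)
        w = w - w[-n_tail:].mean()
    else:
        raise ValueError(f"unknown zero-reference convention {convention!r}")
    if err is None:
        err = np.zeros_like(w)
    return PMFProfile(
        z=solution.bin_centers,
        w=w,
        err=err,
        convention=convention,
        temperature=solution.temperature,
    )


def integrated_autocorrelation_time(x: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time (in samples) via Sokal's windowing rule."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 or np.allclose(x, x[0]):
        return 1.0
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(xc, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n].real
    acf = acf / acf[0]
    tau = 1.0
    for m in range(1, n):
        tau += 2.0 * acf[m]
        if m >= c * tau:
            break
    return max(tau, 1.0)


def bootstrap_pmf(
    trajectories: Sequence[WindowTrajectory],
    n_boot: int = 20,
    seed: int = 0,
    bin_width: float = 0.01,
    z_range: tuple[float, float] | None = None,
    tol: float = 1.0e-6,
    max_iter: int = 100_000,
    convention: str = "global-min",
    min_block: int = 10,
) -> tuple[PMFProfile, np.ndarray]:
    """PMF with moving-block-bootstrap uncertainties.

    Each replicate resamples every window's time series in contiguous blocks
    of length equal to the window's integrated autocorrelation time (at least
    ``min_block`` samples), re-bins and re-solves WHAM.  Returns the reference
    PMF (uncertainty = per-bin std over replicates; bins a replicate leaves
    undefined are ignored for that replicate) and the replicate matrix
    ``(n_boot, n_bins)`` with NaN where undefined.
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    h0 = histogram_windows(trajectories, bin_width=bin_width, z_range=z_range)
    sol0 = solve_wham(h0, tol=tol, max_iter=max_iter)
    full_range = (float(h0.edges[0]), float(h0.edges[-1]))

    blocks = [
        max(min_block, int(round(integrated_autocorrelation_time(t.samples))))
        for t in trajectories
    ]
    rng = np.random.default_rng(seed)
    n_def = sol0.bin_centers.size
    reps = np.full((n_boot, n_def), np.nan)
    for r in range(n_boot):
        resampled = []
        for t, blk in zip(trajectories, blocks):
            n = t.samples.size
            blk = min(blk, n)
            n_blocks = int(np.ceil(n / blk))
            starts = rng.integers(0, n - blk + 1, size=n_blocks)
            take = (starts[:, None] + np.arange(blk)[None, :]).ravel()[:n]
            resampled.append(WindowTrajectory(spec=t.spec, samples=t.samples[take]))
        hr = histogram_windows(resampled, bin_width=bin_width, z_range=full_range)
        sr = solve_wham(hr, tol=tol, max_iter=max_iter)
        wr = pmf_from_solution(sr, convention=convention, force=True)
        # align replicate bins onto the reference defined bins
        common = np.isin(np.round(sol0.bin_centers, 9), np.round(wr.z, 9))
        src = np.isin(np.round(wr.z, 9), np.round(sol0.bin_centers, 9))
        reps[r, common] = wr.w[src]
    err = np.nanstd(reps, axis=0, ddof=1)
    err = np.where(np.isfinite(err), err, 0.0)
    pmf = pmf_from_solution(sol0, convention=convention, err=err)
    return pmf, reps
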