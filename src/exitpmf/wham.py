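"""Weighted Histogram Analysis Method: free-energy profiles from umbrella
windows, barrier extraction, bootstrap errors, and the Kd↔ΔG conversion.

The solver iterates the two standard WHAM self-consistency equations for a
set of harmonically biased windows::

    P(x_b) = sum_i n_i(x_b) / sum_i N_i exp((f_i - w_i(x_b)) / kT)
    exp(-f_i / kT) = sum_b c_i(x_b) P(x_b),   c_i = exp(-w_i/kT)

with ``w_i(x) = 0.5 k_i (x - d_i)²`` until the largest change of any window
offset ``f_i`` falls below the tolerance.  Iteration is performed in log
space; bins never visited by any window are masked, not interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .system import KB

__all__ = [
    "HistogramSet", "PMFProfile", "build_histograms", "histograms_from_samples",
    "histograms_from_metadata", "wham_solve", "barrier_height",
    "kd_to_free_energy", "bootstrap_error",
]

#: gas constant, kcal·mol⁻¹·K⁻¹ (same constant as KB; named for the Kd formula)
R_GAS = KB


@dataclass
class HistogramSet:
    """Binned window samples with the bias parameters needed by WHAM."""

    bin_edges: np.ndarray                 # (n_bins + 1,)
    counts: np.ndarray                    # (n_windows, n_bins)
    window_d_eq: np.ndarray               # (n_windows,)
    window_k: np.ndarray                  # (n_windows,)
    temperature: float = 298.0
    samples: Optional[list] = None        # raw per-window samples (for bootstrap)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.window_d_eq = np.asarray(self.window_d_eq, dtype=float)
        self.window_k = np.asarray(self.window_k, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=1) < 1):
            raise ValueError("every window must contribute at least one count")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def empty_bins(self) -> np.ndarray:
        """Indices of bins with zero total counts (coverage gaps)."""
        return np.flatnonzero(self.counts.sum(axis=0) == 0)


@dataclass
class PMFProfile:
    """Free energy on a distance grid, anchored so the minimum is zero.

    Unvisited bins carry NaN.  ``offsets`` are the converged per-window free
    energies f_i (the WHAM normalisation constants).
    """

    grid: np.ndarray
    free_energy: np.ndarray
    offsets: np.ndarray
    converged: bool
    iterations: int
    residual: float
    temperature: float
    residual_history: Optional[np.ndarray] = None

    @property
    def visited(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def to_tsv(self, path, errors: Optional[np.ndarray] = None) -> None:
        err = errors if errors is not None else np.full_like(self.grid, np.nan)
        with open(path, "w") as fh:
            fh.write("# distance_A\tfree_energy_kcal_mol\terror_kcal_mol\n")
            for g, f, e in zip(self.grid, self.free_energy, err):
                fh.write(f"{g:.6f}\t{f:.6f}\t{e:.6f}\n")


def histograms_from_samples(samples, d_eqs, ks, bin_width: float = 0.1,
                            temperature: float = 298.0) -> HistogramSet:
    """Shared-grid histograms from raw per-window sample arrays.

    Bin edges are anchored at integer multiples of ``bin_width`` so that
    histograms from different runs share a common grid.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if not samples or all(s.size == 0 for s in samples):
        raise ValueError("no samples in any window")
    lo = min(s.min() for s in samples)
    hi = max(s.max() for s in samples)
    first = np.floor(lo / bin_width) * bin_width
    n_bins = max(int(np.ceil((hi - first) / bin_width - 1e-9)), 1)
    edges = first + bin_width * np.arange(n_bins + 1)
    counts = np.stack([np.histogram(s, bins=edges)[0] for s in samples])
    hset = HistogramSet(
        bin_edges=edges, counts=counts,
        window_d_eq=np.asarray(d_eqs, dtype=float),
        window_k=np.asarray(ks, dtype=float),
        temperature=temperature, samples=samples,
    )
    if hset.empty_bins.size:
        warnings.warn(f"{hset.empty_bins.size} bins have no samples "
                      f"(coverage gaps near "
                      f"{np.round(hset.bin_centers[hset.empty_bins][:5], 2)} ...)",
                      RuntimeWarning)
    return hset


def build_histograms(ladder, bin_width: float = 0.1,
                     temperature: float = 298.0) -> HistogramSet:
    """Histogram the sampled windows of a ladder on one shared binning."""
    windows = [w for w in ladder.windows if w.samples is not None and not w.failed]
    if not windows:
        raise ValueError("no samples in any window")
    return histograms_from_samples([w.samples for w in windows],
                                   [w.d_eq for w in windows],
                                   [w.k for w in windows],
                                   bin_width=bin_width, temperature=temperature)


def histograms_from_metadata(metadata_path, bin_width: float = 0.1,
                             temperature: float = 298.0) -> HistogramSet:
    """Histogram umbrella windows described by a Grossfield-dialect metadata
    file (one line per window: timeseries path, d_eq, k)."""
    from .io import read_timeseries, read_wham_metadata
    entries = read_wham_metadata(metadata_path)
    if not entries:
        raise ValueError(f"no window entries in {metadata_path}")
    samples, d_eqs, ks = [], [], []
    for path, d_eq, k in entries:
        _, values = read_timeseries(path)
        samples.append(values)
        d_eqs.append(d_eq)
        ks.append(k)
    return histograms_from_samples(samples, d_eqs, ks,
                                   bin_width=bin_width, temperature=temperature)


def _check_overlap(hset: HistogramSet) -> None:
    order = np.argsort(hset.window_d_eq)
    occ = hset.counts[order] > 0
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hset.counts[a] > 0) & (hset.counts[b] > 0)):
            warnings.warn(
                f"windows at d_eq={hset.window_d_eq[a]:.2f} and "
                f"{hset.window_d_eq[b]:.2f} Å share no occupied bin; the "
                f"profile may be disconnected", RuntimeWarning)
            return


def wham_solve(histograms: HistogramSet, tolerance: float = 1e-6,
               max_iterations: int = 100_000,
               f_init: Optional[np.ndarray] = None) -> PMFProfile:
    """Self-consistent WHAM solution of a histogram set.

    ``tolerance`` is on the maximum change of any window offset f_i per
    iteration, in kcal/mol.  The result is gauge-fixed by anchoring the
    minimum of the profile (and f_1 during iteration) to zero; unvisited
    bins are masked as NaN.
    """
    hset = histograms
    _check_overlap(hset)
    kt = KB * hset.temperature
    x = hset.bin_centers
    counts = hset.counts
    n_i = counts.sum(axis=1)                      # samples per window
    n_b = counts.sum(axis=0)                      # samples per bin
    visited = n_b > 0
    # log bias factor: -w_i(x_b)/kT
    log_c = -0.5 * hset.window_k[:, None] * (x[None, :] - hset.window_d_eq[:, None]) ** 2 / kt

    f = np.zeros(counts.shape[0]) if f_init is None else np.array(f_init, dtype=float)
    f -= f[0]
    log_nb = np.where(visited, np.log(np.maximum(n_b, 1e-300)), -np.inf)
    log_ni = np.log(n_i)
    residual = np.inf
    history = []
    it = 0
    for it in range(1, max_iterations + 1):
        # log denominator per bin: logsumexp_i [ log N_i + (f_i - w_i(x))/kT ]
        log_den = logsumexp(log_ni[:, None] + f[:, None] / kt + log_c, axis=0)
        log_p = np.where(visited, log_nb - log_den, -np.inf)
        # new offsets: f_i = -kT log sum_b c_i(x_b) p(x_b)
        with np.errstate(invalid="ignore"):
            f_new = -kt * logsumexp(log_c + log_p[None, :], axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        history.append(residual)
        f = f_new
        if residual < tolerance:
            break
    converged = residual < tolerance
    if not converged:
        warnings.warn(f"WHAM did not converge in {max_iterations} iterations "
                      f"(residual {residual:.3g} kcal/mol)", RuntimeWarning)

    log_den = logsumexp(log_ni[:, None] + f[:, None] / kt + log_c, axis=0)
    with np.errstate(invalid="ignore"):
        free = np.where(visited, -kt * (log_nb - log_den), np.nan)
    free = free - np.nanmin(free)
    return PMFProfile(grid=x, free_energy=free, offsets=f, converged=converged,
                      iterations=it, residual=residual,
                      temperature=hset.temperature,
                      residual_history=np.array(history))


def barrier_height(profile: PMFProfile, bound_region, unbound_region) -> float:
    """Free-energy cost of moving from the bound region to the unbound region:
    the maximum along the connecting stretch minus the bound-region minimum.

    Raises if any bin between the two regions is unvisited (masked), listing
    the gap — masked free energies are never bridged by interpolation.
    """
    lo = min(bound_region[0], unbound_region[0])
    hi = max(bound_region[1], unbound_region[1])
    g = profile.grid
    span = (g >= lo) & (g <= hi)
    bound = (g >= bound_region[0]) & (g <= bound_region[1])
    if not np.any(span & profile.visited) or not np.any(bound & profile.visited):
        raise ValueError("regions contain no visited bins")
    gaps = g[span & ~profile.visited]
    if gaps.size:
        raise ValueError(f"masked bins along the path near {np.round(gaps[:8], 2)} Å; "
                         "cannot evaluate the barrier across a coverage gap")
    return float(np.max(profile.free_energy[span]) -
                 np.min(profile.free_energy[bound]))


def kd_to_free_energy(kd: float, temperature: float = 298.0) -> float:
    """Standard binding free energy from a dissociation constant:
    ΔG = -R·T·ln(Kd / 1 M), in kcal/mol (positive for sub-molar Kd)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(-R_GAS * temperature * np.log(kd))


def bootstrap_error(histograms: HistogramSet, n_resamples: int = 50,
                    seed: int = 0, tolerance: float = 1e-5,
                    max_iterations: int = 50_000) -> np.ndarray:
    """Bayesian-bootstrap per-bin standard deviation of the PMF.

    Each resample reweights every window's samples with Dirichlet(1,…,1)
    weights, re-bins, re-solves WHAM, and anchors each replica at its mean
    over visited bins before taking the per-bin spread (the profile is only
    defined up to a constant).
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    if histograms.samples is None:
        raise ValueError("histogram set carries no raw samples")
    rng = np.random.default_rng(seed)
    edges = histograms.bin_edges
    profiles = []
    base = wham_solve(histograms, tolerance=tolerance, max_iterations=max_iterations)
    for _ in range(n_resamples):
        counts = np.empty_like(histograms.counts)
        for i, s in enumerate(histograms.samples):
            w = rng.dirichlet(np.ones(s.size)) * s.size
            counts[i] = np.histogram(s, bins=edges, weights=w)[0]
        hs = HistogramSet(bin_edges=edges, counts=np.maximum(counts, 0),
                          window_d_eq=histograms.window_d_eq,
                          window_k=histograms.window_k,
                          temperature=histograms.temperature)
        prof = wham_solve(hs, tolerance=tolerance, max_iterations=max_iterations,
                          f_init=base.offsets)
        fe = prof.free_energy - np.nanmean(prof.free_energy)
        profiles.append(fe)
    stack = np.stack(profiles)
    out = np.full(stack.shape[1], np.nan)
    ok = np.isfinite(stack).sum(axis=0) >= 2
    out[ok] = np.nanstd(stack[:, ok], axis=0)
    return out
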