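"""Self-validation benchmarks: each function runs one stage of the pipeline
under its study conditions against an analytic oracle and returns the
measured figure(s) of merit.

These are the package's own quantitative checks — WHAM against exactly
solvable landscapes, barrier-ordering recovery across seeds, and planted-mode
recovery — used by the test suite and the reproduction script alike.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .app import RunConfig, run_full_study
from .dynamics import LangevinParams
from .mode_compare import displace_along_mode, displacement_matrix, mantel_correlation
from .modes import enm_normal_modes, quasi_modes
from .pathways import UmbrellaWindow, WindowLadder, run_ladder
from .system import Trajectory
from .toy_system import (DoubleWellAxialPotential, HarmonicAxialPotential,
                         ToySpec, build_toy_system, make_axial_fixture)
from .wham import barrier_height, build_histograms, wham_solve

__all__ = ["harmonic_wham_benchmark", "double_well_wham_benchmark",
           "ordering_screen", "planted_mode_benchmark"]


def _sample_ladder(potential, d_eqs, k, seed, steps_per_window, friction=5.0):
    topo, start, com_ids, rep = make_axial_fixture(potential)
    wins = []
    for d in d_eqs:
        c = start.copy()
        c.coordinates[rep] = np.asarray(potential.axis) * float(d)
        wins.append(UmbrellaWindow(d_eq=float(d), k=k, seed_conformation=c))
    ladder = WindowLadder(windows=wins, source_pathway="oracle",
                          com_site_ids=com_ids, reporter_site_id=rep)
    params = LangevinParams(rng_seed=seed, friction=friction)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_ladder(topo, ladder, params, steps_per_window=steps_per_window)


def harmonic_wham_benchmark(seed: int = 0, kappa: float = 2.0, d0: float = 9.0,
                            steps_per_window: int = 50_000) -> float:
    """RMS error (kcal/mol) of the WHAM profile against the analytic
    harmonic landscape, from 25 Langevin-sampled windows (k = 10, 0.5 Å)."""
    pot = HarmonicAxialPotential(kappa=kappa, s0=d0, k_perp=50.0)
    d_eqs = np.arange(d0 - 6.0, d0 + 6.01, 0.5)          # 25 windows
    ladder = _sample_ladder(pot, d_eqs, k=10.0, seed=seed,
                            steps_per_window=steps_per_window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = wham_solve(build_histograms(ladder, bin_width=0.1))
    ref = 0.5 * kappa * (profile.grid - d0) ** 2
    sel = profile.visited & (np.abs(profile.grid - d0) < 5.0)
    diff = profile.free_energy[sel] - ref[sel]
    diff -= diff.mean()
    return float(np.sqrt(np.mean(diff ** 2)))


def double_well_wham_benchmark(seed: int = 0, height: float = 4.0,
                               steps_per_window: int = 100_000) -> float:
    """Recovered barrier (kcal/mol) of a quartic double well with analytic
    barrier ``height`` (wells 2 Å either side of the top)."""
    pot = DoubleWellAxialPotential(height=height, center=8.0, half_width=2.0,
                                   k_perp=50.0)
    d_eqs = np.arange(6.0, 10.01, 0.5)
    ladder = _sample_ladder(pot, d_eqs, k=10.0, seed=seed,
                            steps_per_window=steps_per_window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = wham_solve(build_histograms(ladder, bin_width=0.1))
    return barrier_height(profile, (5.8, 6.5), (9.5, 10.2))


def ordering_screen(base_seed: int = 0, n_seeds: int = 10) -> dict:
    """Run the barrier-ranking pipeline for ``n_seeds`` master seeds; returns
    the success fraction and the per-seed barriers."""
    results = []
    for i in range(n_seeds):
        cfg = RunConfig(master_seed=base_seed + i, n_replicas=1,
                        run_energetics=False, run_modes=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rep = run_full_study(cfg)
        v = rep["verdict"]
        results.append((v.get("barrier_A_kcal_mol"), v.get("barrier_B_kcal_mol"),
                        bool(v.get("ordering_matches_construction", False))))
    frac = float(np.mean([r[2] for r in results]))
    return {"success_fraction": frac, "results": results}


def planted_mode_benchmark(seed: int = 0, mode_index: int = 0,
                           n_frames: int = 400) -> dict:
    """Thermally excite one elastic-network mode; measure how the
    essential-dynamics analysis recovers it (Mantel r of the displacement
    matrices and direct dot-product overlap of the mode vectors)."""
    topology, start = build_toy_system(ToySpec(rng_seed=seed))
    nm = enm_normal_modes(topology, start)
    subset = nm.site_subset
    u = nm.displacement(mode_index)
    u /= np.linalg.norm(u)
    rng = np.random.default_rng(seed + 1000)
    amp = rng.normal(0.0, 0.8, n_frames)
    frames = np.repeat(start.coordinates[None], n_frames, axis=0)
    frames[:, subset, :] += amp[:, None, None] * u[None]
    traj = Trajectory(frames=frames, times=np.arange(1.0, n_frames + 1))
    qm = quasi_modes(traj, topology, n_modes=10)
    overlap = float(abs(qm.vectors[0] @ nm.vectors[mode_index]))
    m_q = displacement_matrix(start, displace_along_mode(start, qm, 0), subset)
    m_n = displacement_matrix(start, displace_along_mode(start, nm, mode_index),
                              subset)
    r, _ = mantel_correlation(m_q, m_n, n_permutations=0)
    return {"mantel_r": float(r), "overlap": overlap}
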