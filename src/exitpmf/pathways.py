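"""Extraction protocol: steered (TMD) pulls along configured exit channels,
umbrella-window selection along the recorded exit coordinate, gap filling,
and the restrained window runs that feed WHAM.

The window-construction rules follow the umbrella-sampling protocol for
nucleotide extraction from a G-protein pocket: windows are picked greedily
at a minimal 0.5 Å increment of the ligand:pocket-COM distance, gaps wider
than 0.5 Å are filled with extra windows restrained at intermediate
distances using an escalated force constant (20 instead of 10 kcal/mol/Å²),
and every window is then sampled by restrained Langevin dynamics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .dynamics import (LangevinParams, LinearSchedule, TMDBias, UmbrellaBias,
                       integrate_batch)
from .system import Conformation, SiteTopology, Trajectory, pocket_com
from .toy_system import pocket_site_ids

__all__ = [
    "ExtractionPathway", "UmbrellaWindow", "WindowLadder",
    "run_tmd_extraction", "select_windows", "fill_gaps", "run_ladder",
    "DEFAULT_TMD_RATE", "DEFAULT_UMBRELLA_K", "ESCALATED_UMBRELLA_K",
    "DEFAULT_MIN_INCREMENT",
]

#: default targeted-RMSD decrease rate, Å/ps
DEFAULT_TMD_RATE = 2.5e-3
#: umbrella force constant, kcal/mol/Å²
DEFAULT_UMBRELLA_K = 10.0
#: escalated force constant for gap-filling windows, kcal/mol/Å²
ESCALATED_UMBRELLA_K = 20.0
#: minimal increment between successive window distances, Å
DEFAULT_MIN_INCREMENT = 0.5


@dataclass
class ExtractionPathway:
    """One steered extraction: trajectory, steering-force trace, exit-coordinate trace."""

    label: str
    target: Conformation
    trajectory: Trajectory
    force_trace: np.ndarray
    com_site_ids: np.ndarray
    reporter_site_id: int
    complete: bool = True

    def __post_init__(self):
        nf = self.trajectory.n_frames
        if len(self.force_trace) != nf:
            raise ValueError("force trace length must match trajectory")
        if self.trajectory.rc_trace is None or len(self.trajectory.rc_trace) != nf:
            raise ValueError("pathway trajectory must carry an rc_trace")

    @property
    def rc_trace(self) -> np.ndarray:
        return self.trajectory.rc_trace


@dataclass
class UmbrellaWindow:
    """One restrained window: target distance, force constant, seed structure, samples."""

    d_eq: float
    k: float
    seed_conformation: Conformation
    inserted: bool = False
    samples: Optional[np.ndarray] = None
    failed: bool = False
    rng_seed: Optional[int] = None


@dataclass
class WindowLadder:
    """Ordered set of umbrella windows along one extraction pathway."""

    windows: list
    source_pathway: str
    com_site_ids: np.ndarray
    reporter_site_id: int

    def __post_init__(self):
        d = self.d_eq_values
        if d.size > 1 and not np.all(np.diff(d) > 0):
            raise ValueError("window d_eq values must be strictly increasing")

    @property
    def d_eq_values(self) -> np.ndarray:
        return np.array([w.d_eq for w in self.windows])

    @property
    def inserted_flags(self) -> np.ndarray:
        return np.array([w.inserted for w in self.windows])

    def __len__(self):
        return len(self.windows)


def run_tmd_extraction(topology: SiteTopology, start: Conformation,
                       target: Conformation, k_per_atom: float = 0.5,
                       duration: Optional[float] = None,
                       anchors: Sequence[int] = (),
                       params: Optional[LangevinParams] = None,
                       rate: float = DEFAULT_TMD_RATE,
                       record_every: int = 20,
                       com_site_ids: Optional[np.ndarray] = None,
                       rmsd_tolerance: float = 0.5,
                       hold_fraction: float = 0.2,
                       label: str = "pathway") -> ExtractionPathway:
    """Steered extraction of the ligand toward ``target``.

    The targeted RMSD decreases linearly from the initial observed RMSD to
    zero over ``duration`` ps; when ``duration`` is omitted it is derived
    from the initial RMSD at ``rate`` (default 2.5×10⁻³ Å/ps).  The run then
    continues for ``hold_fraction``·duration with the target RMSD held at
    zero so the ligand can relax onto the target.  Steered sites are the
    ligand sites plus the given anchor sites, which co-restrains the protein
    frame.  The extraction is flagged incomplete when the final RMSD misses
    the tolerance or the ligand's final distance from the pocket COM falls
    short of 95 % of the target's.
    """
    params = params or LangevinParams()
    steered = np.concatenate([topology.ligand_ids, np.asarray(anchors, dtype=int)])
    dv = start.coordinates[steered] - target.coordinates[steered]
    r0 = float(np.sqrt(np.sum(dv ** 2) / steered.size))
    if r0 <= 0:
        raise ValueError("target must differ from start on the steered sites")
    if duration is None:
        duration = r0 / rate
    n_steps = max(int(round(duration * (1.0 + hold_fraction) / params.timestep)),
                  record_every)
    schedule = LinearSchedule(initial_rmsd=r0, rate=r0 / duration)
    bias = TMDBias(k_per_atom=k_per_atom, steered_site_ids=steered,
                   target=target, rmsd_schedule=schedule)
    if com_site_ids is None:
        com_site_ids = pocket_site_ids(topology, start)
    reporter = int(topology.ligand_ids[0])
    res = integrate_batch(topology, start.coordinates, params, [bias],
                          n_steps=n_steps, record_every=record_every,
                          seeds=[params.rng_seed],
                          rc_spec=(reporter, com_site_ids),
                          record_frames=True, force_trace_bias=bias)
    traj = Trajectory(frames=res["frames"], times=res["times"], rc_trace=res["rc"][0])

    final = traj.frames[-1]
    dvf = final[steered] - target.coordinates[steered]
    final_rmsd = float(np.sqrt(np.sum(dvf ** 2) / steered.size))
    target_rc = float(np.linalg.norm(
        target.coordinates[reporter]
        - pocket_com(target.coordinates, topology.masses, com_site_ids)))
    complete = final_rmsd <= rmsd_tolerance and traj.rc_trace[-1] >= 0.95 * target_rc
    if not complete:
        warnings.warn(f"extraction '{label}' incomplete: final RMSD "
                      f"{final_rmsd:.2f} Å, final distance {traj.rc_trace[-1]:.2f} Å "
                      f"(target {target_rc:.2f} Å)", RuntimeWarning)
    return ExtractionPathway(label=label, target=target, trajectory=traj,
                             force_trace=res["force_trace"],
                             com_site_ids=np.asarray(com_site_ids, dtype=int),
                             reporter_site_id=reporter, complete=complete)


def select_windows(pathway: ExtractionPathway,
                   min_increment: float = DEFAULT_MIN_INCREMENT,
                   k: float = DEFAULT_UMBRELLA_K,
                   max_distance: Optional[float] = None) -> WindowLadder:
    """Greedy window selection along the recorded exit coordinate.

    A frame becomes a window seed when its distance exceeds the last selected
    distance by at least ``min_increment``; the bound start frame seeds the
    scan but is not itself a window.  Each window is restrained at its
    observed distance with force constant ``k``.  ``max_distance`` truncates
    the ladder once the coordinate has left the region of interest.
    """
    rc = pathway.rc_trace
    windows = []
    if rc.size == 0 or np.ptp(rc) < min_increment:
        warnings.warn("reaction-coordinate trace too short or constant: empty ladder",
                      RuntimeWarning)
        return WindowLadder(windows=[], source_pathway=pathway.label,
                            com_site_ids=pathway.com_site_ids,
                            reporter_site_id=pathway.reporter_site_id)
    last = rc[0]
    for i in range(1, rc.size):
        if rc[i] >= last + min_increment - 1e-9:  # tolerate float ties
            if max_distance is None or rc[i] <= max_distance:
                windows.append(UmbrellaWindow(d_eq=float(rc[i]), k=k,
                                              seed_conformation=pathway.trajectory.conformation(i)))
                last = rc[i]
            else:
                break
    return WindowLadder(windows=windows, source_pathway=pathway.label,
                        com_site_ids=pathway.com_site_ids,
                        reporter_site_id=pathway.reporter_site_id)


def fill_gaps(ladder: WindowLadder, max_gap: float = DEFAULT_MIN_INCREMENT,
              escalated_k: float = ESCALATED_UMBRELLA_K) -> WindowLadder:
    """Insert windows into gaps wider than ``max_gap``.

    Each gap ``g`` receives ``ceil(g/max_gap) - 1`` equally spaced windows
    seeded from the nearer existing window (ties toward the smaller
    distance), restrained with the escalated force constant, and flagged as
    inserted.  After filling, no successive gap exceeds ``max_gap``.
    """
    if len(ladder) < 2:
        return ladder
    out = [ladder.windows[0]]
    for lo, hi in zip(ladder.windows[:-1], ladder.windows[1:]):
        g = hi.d_eq - lo.d_eq
        n_insert = max(math.ceil(g / max_gap * (1 - 1e-12)) - 1, 0)
        for j in range(1, n_insert + 1):
            d = lo.d_eq + g * j / (n_insert + 1)
            near = lo if (d - lo.d_eq) <= (hi.d_eq - d) else hi
            out.append(UmbrellaWindow(d_eq=float(d), k=escalated_k,
                                      seed_conformation=near.seed_conformation.copy(),
                                      inserted=True))
        out.append(hi)
    return WindowLadder(windows=out, source_pathway=ladder.source_pathway,
                        com_site_ids=ladder.com_site_ids,
                        reporter_site_id=ladder.reporter_site_id)


def run_ladder(topology: SiteTopology, ladder: WindowLadder,
               params: Optional[LangevinParams] = None,
               steps_per_window: int = 50_000, record_every: int = 10,
               equilibration_fraction: float = 0.1) -> WindowLadder:
    """Sample every window with restrained Langevin dynamics.

    All windows advance in one batched integration; window ``i`` consumes
    the noise stream seeded ``params.rng_seed + i`` so results are bitwise
    reproducible under the master seed.  The first
    ``equilibration_fraction`` of each window's recorded distances is
    discarded.  Diverged windows are flagged failed and carry no samples.
    """
    params = params or LangevinParams()
    if not len(ladder):
        raise ValueError("ladder has no windows")
    coords = np.stack([w.seed_conformation.coordinates for w in ladder.windows])
    d_eq = ladder.d_eq_values
    k = np.array([w.k for w in ladder.windows])
    bias = UmbrellaBias(com_site_ids=ladder.com_site_ids,
                        reporter_site_id=ladder.reporter_site_id,
                        d_eq=d_eq, k=k)
    seeds = [params.rng_seed + i for i in range(len(ladder))]
    res = integrate_batch(topology, coords, params, [bias],
                          n_steps=steps_per_window, record_every=record_every,
                          seeds=seeds,
                          rc_spec=(ladder.reporter_site_id, ladder.com_site_ids))
    discard = int(equilibration_fraction * res["rc"].shape[1])
    windows = []
    for i, w in enumerate(ladder.windows):
        failed = bool(res["diverged"][i])
        if failed:
            warnings.warn(f"window {i} (d_eq={w.d_eq:.2f} Å) diverged; excluded",
                          RuntimeWarning)
        windows.append(replace(w, samples=None if failed else res["rc"][i, discard:].copy(),
                               failed=failed, rng_seed=seeds[i]))
    return WindowLadder(windows=windows, source_pathway=ladder.source_pathway,
                        com_site_ids=ladder.com_site_ids,
                        reporter_site_id=ladder.reporter_site_id)
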