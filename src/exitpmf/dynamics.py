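"""Langevin dynamics with the energy model and the two bias potentials.

The force field has four terms: elastic-network bonds, weak positional
anchors, the analytic channel potential acting on the ligand centre of mass,
and ligand–protein nonbonded interactions (12-6 Lennard-Jones with
Lorentz–Berthelot combination plus Coulomb).  Protein–protein cohesion is
carried entirely by the elastic network, so the nonbonded pair list is the
ligand × protein block only.

Two bias potentials are provided:

* :class:`TMDBias` — a one-sided harmonic penalty on the RMSD of the steered
  sites to a target structure, with a time-decreasing targeted RMSD
  (targeted / steered molecular dynamics).
* :class:`UmbrellaBias` — a harmonic restraint on the distance between a
  reporter ligand site and the mass-weighted centre of mass of the pocket
  sites (umbrella sampling along the exit coordinate).

The integrator is BAOAB-discretised Langevin dynamics; with friction 0 and
T = 0 it reduces to velocity Verlet.  Runs are bitwise reproducible for a
fixed seed.  The integrator accepts a leading batch dimension so that a whole
ladder of umbrella windows advances in lock-step with per-window noise
streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .system import (KB, COULOMB, KCAL_TO_AMU_A2_PS2, ChannelPotential, Conformation,
                     SiteTopology, Trajectory, pocket_com)

__all__ = [
    "LangevinParams", "TMDBias", "UmbrellaBias",
    "nonbonded_pair_energy", "potential_energy_forces", "total_forces",
    "tmd_energy_forces", "umbrella_energy_forces", "run_langevin",
    "EnergyDivergence",
]


class EnergyDivergence(RuntimeError):
    """Raised when the potential energy exceeds the configured bound."""

    def __init__(self, step: int, energy: float):
        self.step = step
        self.energy = energy
        super().__init__(f"energy diverged at step {step}: U = {energy:.3g} kcal/mol")


@dataclass(frozen=True)
class LangevinParams:
    timestep: float = 0.002     # ps
    friction: float = 1.0      # ps⁻¹
    temperature: float = 298.0  # K
    rng_seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


# ---------------------------------------------------------------------------
# plain force-field terms
# ---------------------------------------------------------------------------

def nonbonded_pair_energy(topology: SiteTopology, conformation: Conformation, pair) -> tuple:
    """LJ and Coulomb energy (kcal/mol) of one site pair.

    12-6 Lennard-Jones with Lorentz–Berthelot combination rules; Coulomb is
    ``COULOMB * q1 * q2 / r`` with no cutoff.
    """
    i, j = pair
    if i == j:
        raise ValueError("pair sites must be distinct")
    r = float(np.linalg.norm(conformation.coordinates[j] - conformation.coordinates[i]))
    if r <= 0:
        raise ValueError("coincident sites: nonbonded energy singular")
    sig = 0.5 * (topology.lj_sigma[i] + topology.lj_sigma[j])
    eps = np.sqrt(topology.lj_epsilon[i] * topology.lj_epsilon[j])
    sr6 = (sig / r) ** 6
    lj = 4.0 * eps * (sr6 ** 2 - sr6)
    coulomb = COULOMB * topology.charges[i] * topology.charges[j] / r
    return lj, coulomb


_FF_CACHE: "weakref.WeakKeyDictionary" = None  # initialised below


def _ff_tables(topology: SiteTopology) -> dict:
    """Precomputed force-field tables, cached per topology identity.

    Topologies are treated as immutable once used for dynamics.
    """
    global _FF_CACHE
    if _FF_CACHE is None:
        import weakref
        _FF_CACHE = weakref.WeakKeyDictionary()
    tab = _FF_CACHE.get(topology)
    if tab is not None:
        return tab
    lig = topology.ligand_ids
    prot = topology.protein_ids
    n = topology.n_sites
    nb = topology.bond_pairs.shape[0]
    incidence = np.zeros((n, nb))
    if nb:
        incidence[topology.bond_pairs[:, 0], np.arange(nb)] = 1.0
        incidence[topology.bond_pairs[:, 1], np.arange(nb)] -= 1.0
    mlig = topology.masses[lig]
    tab = {
        "lig": lig, "prot": prot,
        "sig2": (0.5 * (topology.lj_sigma[lig][:, None] + topology.lj_sigma[prot][None, :])) ** 2,
        "eps": np.sqrt(topology.lj_epsilon[lig][:, None] * topology.lj_epsilon[prot][None, :]),
        "qq": COULOMB * topology.charges[lig][:, None] * topology.charges[prot][None, :],
        "incidence": incidence,
        "lig_w": mlig / mlig.sum(),
    }
    _FF_CACHE[topology] = tab
    return tab


def potential_energy_forces(topology: SiteTopology, coords: np.ndarray):
    """Energy (…,) and forces (…, n, 3) of the unbiased force field.

    ``coords`` may carry a leading batch dimension.
    """
    coords = np.asarray(coords, dtype=float)
    squeeze = coords.ndim == 2
    if squeeze:
        coords = coords[None]
    B = coords.shape[0]
    energy = np.zeros(B)
    forces = np.zeros_like(coords)
    tab = _ff_tables(topology)

    # bonds
    if topology.bond_pairs.shape[0]:
        i, j = topology.bond_pairs[:, 0], topology.bond_pairs[:, 1]
        dv = coords[:, j] - coords[:, i]                      # (B, nb, 3)
        r = np.sqrt(np.sum(dv * dv, axis=-1))
        dr = r - topology.bond_r0
        energy += 0.5 * np.sum(topology.bond_k * dr ** 2, axis=-1)
        f = (topology.bond_k * dr / np.maximum(r, 1e-12))[..., None] * dv
        forces += np.einsum("ab,Bbc->Bac", tab["incidence"], f)

    # positional anchors
    if topology.anchor_ids.size and topology.anchor_k > 0:
        a = topology.anchor_ids
        dv = coords[:, a] - topology.anchor_ref
        energy += 0.5 * topology.anchor_k * np.sum(dv ** 2, axis=(-1, -2))
        forces[:, a] -= topology.anchor_k * dv

    # analytic channel potential on the ligand centre of mass
    if topology.external is not None:
        lig = tab["lig"]
        w = tab["lig_w"]
        com = np.einsum("bij,i->bj", coords[:, lig], w)
        e, g = topology.external.energy_gradient(com)
        energy += e
        forces[:, lig] -= w[None, :, None] * g[:, None, :]

    # ligand × protein nonbonded (unique indices: plain fancy-index updates)
    lig, prot = tab["lig"], tab["prot"]
    if lig.size and prot.size:
        dv = coords[:, lig][:, :, None, :] - coords[:, prot][:, None, :, :]
        r2 = np.sum(dv * dv, axis=-1)
        r = np.sqrt(r2)
        sr6 = (tab["sig2"] / r2) ** 3
        eps, qq = tab["eps"], tab["qq"]
        energy += np.sum(4.0 * eps * (sr6 ** 2 - sr6) + qq / r, axis=(-1, -2))
        dudr = (-24.0 * eps * (2.0 * sr6 ** 2 - sr6) / r) - qq / r2
        fpair = (-dudr / r)[..., None] * dv                   # force on ligand sites
        forces[:, lig] += np.sum(fpair, axis=2)
        forces[:, prot] -= np.sum(fpair, axis=1)

    if squeeze:
        return energy[0], forces[0]
    return energy, forces


# ---------------------------------------------------------------------------
# biases
# ---------------------------------------------------------------------------

@dataclass
class TMDBias:
    """Harmonic steering penalty on the RMSD to a target structure.

    ``U = (k_per_atom * N / 2) * (RMSD_obs - RMSD_targ(t))²`` when
    ``RMSD_obs > RMSD_targ(t)``, else 0.  The RMSD is computed over the N
    steered sites without rotational/translational fitting (the protein frame
    is pinned by anchor restraints instead).
    """

    k_per_atom: float
    steered_site_ids: np.ndarray
    target: Conformation
    rmsd_schedule: Callable[[float], float]

    def __post_init__(self):
        self.steered_site_ids = np.asarray(self.steered_site_ids, dtype=int)
        if self.k_per_atom <= 0:
            raise ValueError("k_per_atom must be positive")
        if self.steered_site_ids.size == 0:
            raise ValueError("steered set must be non-empty")
        if self.target.n_sites < self.steered_site_ids.max() + 1:
            raise ValueError("target conformation does not cover the steered sites")

    def energy_forces(self, topology: SiteTopology, coords: np.ndarray, time: float):
        return tmd_energy_forces(self, Conformation(np.asarray(coords)), time)


def tmd_energy_forces(bias: TMDBias, conformation: Conformation, time: float):
    """Energy and per-site forces of the steering bias at time ``time`` (ps)."""
    ids = bias.steered_site_ids
    n = ids.size
    dv = conformation.coordinates[ids] - bias.target.coordinates[ids]
    rmsd = float(np.sqrt(np.sum(dv ** 2) / n))
    target_rmsd = float(bias.rmsd_schedule(time))
    gap = rmsd - target_rmsd
    forces = np.zeros_like(conformation.coordinates)
    if gap <= 0.0:
        return 0.0, forces
    energy = 0.5 * bias.k_per_atom * n * gap ** 2
    if rmsd > 0:
        # dU/dr_i = k_per_atom * N * gap * (r_i - t_i) / (N * rmsd)
        forces[ids] = -bias.k_per_atom * gap / rmsd * dv
    return energy, forces


@dataclass
class UmbrellaBias:
    """Harmonic distance restraint between a reporter site and the pocket COM.

    ``U = 0.5 * k * (d - d_eq)²`` with ``d = |r_reporter - COM|`` and the COM
    mass-weighted over ``com_site_ids``.  ``d_eq`` and ``k`` may be arrays for
    batched window runs.
    """

    com_site_ids: np.ndarray
    reporter_site_id: int
    d_eq: float
    k: float

    def __post_init__(self):
        self.com_site_ids = np.asarray(self.com_site_ids, dtype=int)
        if self.com_site_ids.size == 0:
            raise ValueError("com set must be non-empty")
        if np.any(np.asarray(self.k) <= 0):
            raise ValueError("force constant k must be positive")
        if np.any(np.asarray(self.d_eq) < 0):
            raise ValueError("d_eq must be non-negative")
        if int(self.reporter_site_id) in set(self.com_site_ids.tolist()):
            raise ValueError("reporter site must not belong to the COM set")

    def distance(self, topology: SiteTopology, coords: np.ndarray):
        com = pocket_com(coords, topology.masses, self.com_site_ids)
        dv = coords[..., self.reporter_site_id, :] - com
        return np.linalg.norm(dv, axis=-1)

    def energy_forces(self, topology: SiteTopology, coords: np.ndarray, time: float = 0.0):
        coords = np.asarray(coords, dtype=float)
        squeeze = coords.ndim == 2
        c = coords[None] if squeeze else coords
        m = topology.masses[self.com_site_ids]
        w = m / m.sum()
        com = np.einsum("bij,i->bj", c[:, self.com_site_ids], w)
        dv = c[:, self.reporter_site_id] - com
        d = np.linalg.norm(dv, axis=-1)
        d_eq = np.broadcast_to(np.asarray(self.d_eq, dtype=float), d.shape)
        k = np.broadcast_to(np.asarray(self.k, dtype=float), d.shape)
        energy = 0.5 * k * (d - d_eq) ** 2
        unit = np.empty_like(dv)
        ok = d > 0
        unit[ok] = dv[ok] / d[ok, None]
        if np.any(~ok):
            bad = ~ok & (d_eq > 0)
            if np.any(bad):
                warnings.warn("reporter coincides with pocket COM; restraint force "
                              "direction chosen along +x", RuntimeWarning)
            unit[~ok] = np.array([1.0, 0.0, 0.0])
        g = (k * (d - d_eq))[:, None] * unit     # dU/dr_reporter
        forces = np.zeros_like(c)
        forces[:, self.reporter_site_id] -= g
        forces[:, self.com_site_ids] += w[None, :, None] * g[:, None, :]
        if squeeze:
            return energy[0], forces[0]
        return energy, forces


def umbrella_energy_forces(bias: UmbrellaBias, topology: SiteTopology,
                           conformation: Conformation):
    """Energy and forces of the umbrella restraint on one conformation."""
    return bias.energy_forces(topology, conformation.coordinates)


def total_forces(topology: SiteTopology, conformation: Conformation,
                 biases: Sequence = (), time: float = 0.0):
    """Total energy and forces: force field plus all biases.

    Forces are the exact negative gradient of the returned energy.
    """
    energy, forces = potential_energy_forces(topology, conformation.coordinates)
    for b in biases:
        e, f = b.energy_forces(topology, conformation.coordinates, time)
        energy = energy + e
        forces = forces + f
    return energy, forces


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearSchedule:
    """Linear targeted-RMSD schedule: ``max(0, initial_rmsd - rate * t)``."""

    initial_rmsd: float
    rate: float  # Å/ps

    def __call__(self, t: float) -> float:
        return max(0.0, self.initial_rmsd - self.rate * t)


def _batch_energy_forces(topology, coords, biases, time):
    energy, forces = potential_energy_forces(topology, coords)
    for b in biases:
        if isinstance(b, TMDBias):
            for bi in range(coords.shape[0]):
                e, f = tmd_energy_forces(b, Conformation(coords[bi]), time)
                energy[bi] += e
                forces[bi] += f
        else:
            e, f = b.energy_forces(topology, coords, time)
            energy = energy + e
            forces = forces + f
    return energy, forces


def _fast_kernel_args(topology: SiteTopology, biases, B: int):
    """Pack force-field and bias tables for the numba kernel, or return
    None when the bias combination is outside the fast path."""
    try:
        from . import _kernels  # noqa: F401
    except ImportError:  # pragma: no cover - numba always present in practice
        return None
    ext = topology.external
    if ext is not None and not hasattr(ext, "kernel_code"):
        return None
    umb = [b for b in biases if isinstance(b, UmbrellaBias)]
    tmd = [b for b in biases if isinstance(b, TMDBias)]
    if len(umb) > 1 or len(tmd) > 1 or len(umb) + len(tmd) != len(biases):
        return None
    if tmd and not isinstance(tmd[0].rmsd_schedule, LinearSchedule):
        return None
    tab = _ff_tables(topology)
    args = {
        "bond_i": topology.bond_pairs[:, 0].astype(np.int64),
        "bond_j": topology.bond_pairs[:, 1].astype(np.int64),
        "bond_kk": topology.bond_k, "bond_r0": topology.bond_r0,
        "anchor_ids": topology.anchor_ids.astype(np.int64),
        "anchor_k": float(topology.anchor_k),
        "anchor_ref": (topology.anchor_ref if topology.anchor_ref is not None
                       else np.zeros((0, 3))),
        "lig": tab["lig"].astype(np.int64), "prot": tab["prot"].astype(np.int64),
        "sig2": tab["sig2"], "eps": tab["eps"], "qq": tab["qq"], "lig_w": tab["lig_w"],
        "ext_code": 0 if ext is None else int(ext.kernel_code),
        "ext_params": np.zeros(1) if ext is None else np.asarray(ext.kernel_params, dtype=float),
        "ext_kperp": 0.0 if ext is None else float(ext.k_perp),
        "ext_axis": np.zeros(3) if ext is None else np.asarray(ext.axis, dtype=float),
        "ext_origin": np.zeros(3) if ext is None else np.asarray(ext.origin, dtype=float),
    }
    if umb:
        u = umb[0]
        m = topology.masses[u.com_site_ids]
        args.update(umb_on=True, umb_com=u.com_site_ids.astype(np.int64),
                    umb_w=m / m.sum(), umb_rep=int(u.reporter_site_id),
                    umb_deq=np.broadcast_to(np.asarray(u.d_eq, dtype=float), (B,)).copy(),
                    umb_k=np.broadcast_to(np.asarray(u.k, dtype=float), (B,)).copy())
    else:
        args.update(umb_on=False, umb_com=np.zeros(0, dtype=np.int64),
                    umb_w=np.zeros(0), umb_rep=0,
                    umb_deq=np.zeros(B), umb_k=np.zeros(B))
    if tmd:
        tb = tmd[0]
        sched = tb.rmsd_schedule
        args.update(tmd_on=True, tmd_ids=tb.steered_site_ids.astype(np.int64),
                    tmd_target=tb.target.coordinates[tb.steered_site_ids].copy(),
                    tmd_kpa=float(tb.k_per_atom),
                    tmd_r0=float(sched.initial_rmsd), tmd_rate=float(sched.rate))
    else:
        args.update(tmd_on=False, tmd_ids=np.zeros(0, dtype=np.int64),
                    tmd_target=np.zeros((0, 3)), tmd_kpa=0.0, tmd_r0=0.0, tmd_rate=0.0)
    return args


def integrate_batch(topology: SiteTopology, coords0: np.ndarray, params: LangevinParams,
                    biases: Sequence = (), n_steps: int = 1000, record_every: int = 10,
                    seeds: Optional[Sequence[int]] = None,
                    rc_spec: Optional[tuple] = None,
                    record_frames: bool = False,
                    force_trace_bias=None,
                    energy_bound: float = 1e8,
                    noise_chunk: int = 500,
                    use_fast_path: bool = True):
    """BAOAB Langevin integration with a leading batch dimension.

    ``seeds`` gives one RNG seed per batch member (independent noise streams,
    consumed chunk-wise so the whole batch still advances in lock-step).  A
    numba-compiled fast path handles the standard bias combinations; the
    generic numpy path (``use_fast_path=False``) is the reference
    implementation.  Returns a dict with final coordinates, recorded times,
    the reaction-coordinate trace per batch member (if
    ``rc_spec=(reporter, com_ids)``), recorded energies, optional frames
    (batch of 1 only), an optional steering-force-magnitude trace, and a
    per-member divergence mask.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    coords = np.array(coords0, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    B, n, _ = coords.shape
    if seeds is None:
        seeds = [params.rng_seed + b for b in range(B)]
    gens = [np.random.default_rng(int(s)) for s in seeds]
    dt = params.timestep
    masses = topology.masses
    kT = KB * params.temperature

    # masses in "acceleration units": a [Å/ps²] = force [kcal/mol/Å] / m_acc
    m_acc = masses / KCAL_TO_AMU_A2_PS2
    vel = np.zeros_like(coords)
    if kT > 0:
        sd = np.sqrt(kT / m_acc[:, None])
        for b in range(B):
            vel[b] = gens[b].standard_normal((n, 3)) * sd

    c1 = float(np.exp(-params.friction * dt))
    c2 = np.sqrt(kT * (1.0 - c1 ** 2) / m_acc) if kT > 0 else np.zeros(n)
    stochastic = bool(kT > 0 and params.friction > 0)

    n_rec = n_steps // record_every
    rec_times = np.empty(n_rec)
    rc = np.empty((B, n_rec)) if rc_spec is not None else None
    rec_energy = np.empty((B, n_rec))
    frames = np.empty((n_rec, n, 3)) if (record_frames and B == 1) else None
    want_ftrace = force_trace_bias is not None
    ftrace = np.empty(n_rec) if want_ftrace else None

    fast = _fast_kernel_args(topology, biases, B) if use_fast_path else None

    if fast is not None:
        from ._kernels import baoab_chunk, compute_forces
        energy = np.zeros(B)
        forces = np.zeros_like(coords)
        compute_forces(coords, forces,
                       fast["bond_i"], fast["bond_j"], fast["bond_kk"], fast["bond_r0"],
                       fast["anchor_ids"], fast["anchor_k"], fast["anchor_ref"],
                       fast["lig"], fast["prot"], fast["sig2"], fast["eps"], fast["qq"],
                       fast["lig_w"], fast["ext_code"], fast["ext_params"],
                       fast["ext_kperp"], fast["ext_axis"], fast["ext_origin"],
                       fast["umb_on"], fast["umb_com"], fast["umb_w"], fast["umb_rep"],
                       fast["umb_deq"], fast["umb_k"],
                       fast["tmd_on"], fast["tmd_ids"], fast["tmd_target"],
                       fast["tmd_kpa"], fast["tmd_r0"], fast["tmd_rate"],
                       0.0, energy)
        rc_on = rc_spec is not None
        if rc_on:
            reporter, com_ids = rc_spec
            com_ids = np.asarray(com_ids, dtype=np.int64)
            mcom = masses[com_ids]
            rc_w = mcom / mcom.sum()
        else:
            reporter, com_ids, rc_w = 0, np.zeros(0, dtype=np.int64), np.zeros(0)
        dummy_rc = rc if rc_on else np.zeros((B, max(n_rec, 1)))
        dummy_frames = frames if frames is not None else np.zeros((0, n, 3))
        dummy_ft = ftrace if want_ftrace else np.zeros(max(n_rec, 1))
        rec_i = 0
        step = 0
        while step < n_steps:
            chunk = min(noise_chunk, n_steps - step)
            if stochastic:
                noise = np.stack([g.standard_normal((chunk, n, 3)) for g in gens], axis=1)
            else:
                noise = np.zeros((chunk, B, n, 3))
            rec_i = baoab_chunk(
                coords, vel, forces, energy, m_acc, dt, c1, c2, noise, stochastic,
                fast["bond_i"], fast["bond_j"], fast["bond_kk"], fast["bond_r0"],
                fast["anchor_ids"], fast["anchor_k"], fast["anchor_ref"],
                fast["lig"], fast["prot"], fast["sig2"], fast["eps"], fast["qq"],
                fast["lig_w"], fast["ext_code"], fast["ext_params"],
                fast["ext_kperp"], fast["ext_axis"], fast["ext_origin"],
                fast["umb_on"], fast["umb_com"], fast["umb_w"], fast["umb_rep"],
                fast["umb_deq"], fast["umb_k"],
                fast["tmd_on"], fast["tmd_ids"], fast["tmd_target"],
                fast["tmd_kpa"], fast["tmd_r0"], fast["tmd_rate"],
                step, record_every,
                rc_on, int(reporter), com_ids, rc_w,
                rec_times, dummy_rc, rec_energy, dummy_frames, frames is not None,
                dummy_ft, want_ftrace, rec_i)
            step += chunk
    else:
        energy, forces = _batch_energy_forces(topology, coords, biases, 0.0)
        m = m_acc[:, None]
        noise = None
        noise_pos = noise_chunk
        rec_i = 0
        for step in range(1, n_steps + 1):
            t = step * dt
            vel += 0.5 * dt * forces / m
            coords += 0.5 * dt * vel
            if stochastic:
                if noise_pos >= noise_chunk:
                    chunk = min(noise_chunk, n_steps - step + 1)
                    noise = np.stack([g.standard_normal((chunk, n, 3)) for g in gens], axis=1)
                    noise_pos = 0
                vel = c1 * vel + c2[:, None] * noise[noise_pos]
                noise_pos += 1
            elif params.friction > 0:
                vel = c1 * vel
            coords += 0.5 * dt * vel
            energy, forces = _batch_energy_forces(topology, coords, biases, t)
            vel += 0.5 * dt * forces / m

            if step % record_every == 0:
                rec_times[rec_i] = t
                rec_energy[:, rec_i] = energy
                if rc is not None:
                    reporter, com_ids = rc_spec
                    com = pocket_com(coords, masses, com_ids)
                    rc[:, rec_i] = np.linalg.norm(coords[:, reporter] - com, axis=-1)
                if frames is not None:
                    frames[rec_i] = coords[0]
                if want_ftrace:
                    _, fb = tmd_energy_forces(force_trace_bias, Conformation(coords[0]), t)
                    ftrace[rec_i] = float(np.linalg.norm(fb))
                rec_i += 1

    bad = ~np.isfinite(rec_energy) | (np.abs(rec_energy) > energy_bound)
    diverged = bad.any(axis=1)
    diverge_step = np.where(diverged, bad.argmax(axis=1) * record_every + record_every, -1)
    if B == 1 and diverged[0]:
        raise EnergyDivergence(int(diverge_step[0]), float(rec_energy[0, bad[0].argmax()]))

    return {
        "coords": coords, "velocities": vel, "times": rec_times, "rc": rc,
        "frames": frames, "energies": rec_energy, "force_trace": ftrace,
        "diverged": diverged, "diverge_step": diverge_step,
    }


def run_langevin(topology: SiteTopology, start: Conformation, params: LangevinParams,
                 biases: Sequence = (), n_steps: int = 1000, record_every: int = 10,
                 rc_spec: Optional[tuple] = None, record_frames: bool = True,
                 energy_bound: float = 1e8) -> Trajectory:
    """Run one Langevin trajectory; bitwise reproducible under a fixed seed.

    The reaction-coordinate trace is filled when an :class:`UmbrellaBias` is
    supplied or when ``rc_spec=(reporter_id, com_site_ids)`` is given.
    """
    if rc_spec is None:
        for b in biases:
            if isinstance(b, UmbrellaBias):
                rc_spec = (b.reporter_site_id, b.com_site_ids)
                break
    res = integrate_batch(topology, start.coordinates, params, biases,
                          n_steps=n_steps, record_every=record_every,
                          seeds=[params.rng_seed], rc_spec=rc_spec,
                          record_frames=record_frames, energy_bound=energy_bound)
    frames = res["frames"]
    if frames is None:
        frames = res["coords"]  # final frame only
        times = np.array([n_steps * params.timestep])
        rc = None if res["rc"] is None else res["rc"][0, -1:]
    else:
        times = res["times"]
        rc = None if res["rc"] is None else res["rc"][0]
    return Trajectory(frames=frames, times=times, rc_trace=rc)
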