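"""Synthetic two-lobe pocket system with analytic free-energy oracles.

The toy system stands in for a nucleotide-bound heterotrimer: a ligand bead
sits in a pocket between two quasi-rigid lobes of coarse residue sites that
are connected by soft hinge springs.  Two candidate exit channels run along
the ±y axis with configurable Gaussian barrier ridges — a low-barrier
"phosphate-analog" channel (A, +y) and a high-barrier "base-analog" channel
(B, −y).  The channel terms are additive analytic contributions to the
ligand–environment potential, so the exact PMF along each channel axis is
known in closed form and the whole umbrella-sampling/WHAM machinery can be
validated against it.

Scale defaults: 2 lobes × 20 sites + 1 ligand site.  Units: Å, kcal/mol,
amu, ps, elementary charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .system import KB, AxialPotentialMixin, ChannelPotential, Conformation, SiteTopology

__all__ = [
    "ToySpec", "AnalyticPMF", "build_toy_system", "analytic_pmf",
    "pocket_site_ids", "HarmonicAxialPotential", "DoubleWellAxialPotential",
    "make_axial_fixture",
]


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the synthetic system.

    The default barrier heights (5 vs 12 kcal/mol) encode the "one easy, one
    hard exit" structure; ``ligand_well_depth`` is the depth of the bound
    pocket well, so the channel barrier measured from the well bottom is
    achieved by calibrating the ridge amplitudes.
    """

    n_lobe_sites: int = 20
    hinge_stiffness: float = 2.0        # kcal/mol/Å²
    channel_a_barrier: float = 5.0      # kcal/mol, +y exit
    channel_b_barrier: float = 12.0     # kcal/mol, −y exit
    ligand_well_depth: float = 2.0      # kcal/mol
    temperature: float = 298.0          # K
    rng_seed: int = 0
    n_ligand_sites: int = 1             # 1 (bead) or 4 (rigid group)
    # geometry / force-field shape parameters
    lobe_separation: float = 5.5
    lobe_radius: float = 4.0
    pocket_radius: float = 3.6
    min_site_separation: float = 1.7
    path_clearance: float = 3.0
    intra_lobe_k: float = 20.0
    intra_lobe_cutoff: float = 4.5
    anchor_k: float = 1.0
    well_sigma: float = 1.5
    barrier_pos: float = 6.0
    barrier_sigma: float = 1.0
    k_perp: float = 10.0

    def __post_init__(self):
        if self.n_lobe_sites < 6:
            raise ValueError("need at least 6 sites per lobe")
        if self.hinge_stiffness <= 0 or self.intra_lobe_k <= 0:
            raise ValueError("spring stiffnesses must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.channel_a_barrier <= 0 or self.channel_b_barrier <= 0:
            raise ValueError("channel barriers must be positive")
        if min(self.channel_a_barrier, self.channel_b_barrier) <= self.ligand_well_depth:
            raise ValueError("channel barriers must exceed the ligand well depth")
        if self.n_ligand_sites not in (1, 4):
            raise ValueError("ligand is a single bead or a 4-site rigid group")


@dataclass
class AnalyticPMF:
    """Free energy (kcal/mol) on a distance grid, anchored so min = 0."""

    grid: np.ndarray
    free_energy: np.ndarray
    potential_spec: object = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    def barrier(self) -> float:
        return float(self.free_energy.max() - self.free_energy.min())


# ---------------------------------------------------------------------------
# extra axial potentials used as WHAM validation fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicAxialPotential(AxialPotentialMixin):
    """``f(s) = 0.5 * kappa * (s - s0)²`` with transverse confinement."""

    kappa: float
    s0: float
    k_perp: float = 10.0
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    kernel_code = 2

    @property
    def kernel_params(self) -> np.ndarray:
        return np.array([self.kappa, self.s0])

    def profile(self, s):
        return 0.5 * self.kappa * (np.asarray(s, dtype=float) - self.s0) ** 2

    def profile_grad(self, s):
        return self.kappa * (np.asarray(s, dtype=float) - self.s0)


@dataclass(frozen=True)
class DoubleWellAxialPotential(AxialPotentialMixin):
    """Quartic double well ``f(s) = h*(((s-c)/w)² - 1)²``.

    Wells at ``c ± w`` (f = 0), barrier top at ``s = c`` (f = h exactly).
    """

    height: float
    center: float
    half_width: float
    k_perp: float = 10.0
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    kernel_code = 3

    @property
    def kernel_params(self) -> np.ndarray:
        return np.array([self.height, self.center, self.half_width])

    def profile(self, s):
        u = ((np.asarray(s, dtype=float) - self.center) / self.half_width) ** 2 - 1.0
        return self.height * u ** 2

    def profile_grad(self, s):
        s = np.asarray(s, dtype=float)
        u = ((s - self.center) / self.half_width) ** 2 - 1.0
        return self.height * 4.0 * u * (s - self.center) / self.half_width ** 2


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------

def _calibrated_channel(spec: ToySpec) -> ChannelPotential:
    """Fix ridge amplitudes so each channel's 1-D barrier (max − min of the
    axial profile on its side) equals the configured height."""
    s_hi = np.linspace(0.0, spec.barrier_pos + 6.0, 4001)
    amp_plus = spec.channel_a_barrier - spec.ligand_well_depth
    amp_minus = spec.channel_b_barrier - spec.ligand_well_depth
    for _ in range(12):
        pot = ChannelPotential(
            well_depth=spec.ligand_well_depth, well_sigma=spec.well_sigma,
            barrier_pos=spec.barrier_pos, barrier_sigma=spec.barrier_sigma,
            amp_plus=amp_plus, amp_minus=amp_minus, k_perp=spec.k_perp)
        fa = pot.profile(s_hi)
        fb = pot.profile(-s_hi)
        amp_plus += spec.channel_a_barrier - (fa.max() - fa.min())
        amp_minus += spec.channel_b_barrier - (fb.max() - fb.min())
    return ChannelPotential(
        well_depth=spec.ligand_well_depth, well_sigma=spec.well_sigma,
        barrier_pos=spec.barrier_pos, barrier_sigma=spec.barrier_sigma,
        amp_plus=amp_plus, amp_minus=amp_minus, k_perp=spec.k_perp)


def _lobe_sites(spec: ToySpec, sign: int, rng: np.random.Generator) -> np.ndarray:
    """Coordinates of one lobe: 4 pocket-lining sites plus bulk sites."""
    center = np.array([sign * spec.lobe_separation, 0.0, 0.0])
    pocket_dirs = np.array([
        [sign, 0.45, 0.45], [sign, -0.45, 0.45],
        [sign, 0.45, -0.45], [sign, -0.45, -0.45],
    ])
    pocket_dirs /= np.linalg.norm(pocket_dirs, axis=1, keepdims=True)
    # inner face of the lobe, at pocket_radius from the ligand at the origin
    pocket = pocket_dirs * spec.pocket_radius
    pocket += 0.08 * rng.standard_normal(pocket.shape)

    sites = list(pocket)
    n_bulk = spec.n_lobe_sites - 4
    min_sep = spec.min_site_separation
    attempts = 0
    while len(sites) < spec.n_lobe_sites:
        attempts += 1
        if attempts % 20000 == 0:
            min_sep *= 0.9  # relax packing if the lobe is too crowded
        p = center + (rng.random(3) * 2 - 1) * spec.lobe_radius
        if np.linalg.norm(p - center) > spec.lobe_radius:
            continue
        if np.linalg.norm(p) < spec.pocket_radius + 0.6:
            continue  # keep the pocket interior and COM set clean
        if np.hypot(p[0], p[2]) < spec.path_clearance:
            continue  # keep the ±y exit channel sterically open
        if any(np.linalg.norm(p - q) < min_sep for q in sites):
            continue
        sites.append(p)
    return np.asarray(sites)


def _intra_lobe_bonds(coords: np.ndarray, offset: int, spec: ToySpec):
    """Elastic network inside one lobe; guaranteed connected."""
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
             if d[i, j] <= spec.intra_lobe_cutoff]
    # connect stray components to their nearest neighbour in the network
    while True:
        rows = [p[0] for p in pairs] + [p[1] for p in pairs]
        cols = [p[1] for p in pairs] + [p[0] for p in pairs]
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        ncomp, labels = connected_components(adj, directed=False)
        if ncomp == 1:
            break
        main = labels == np.bincount(labels).argmax()
        stray = np.flatnonzero(~main)
        dist_to_main = d[np.ix_(stray, np.flatnonzero(main))]
        si, mi = np.unravel_index(dist_to_main.argmin(), dist_to_main.shape)
        pairs.append((int(stray[si]), int(np.flatnonzero(main)[mi])))
    out = [(i + offset, j + offset, spec.intra_lobe_k, d[i, j]) for i, j in pairs]
    return out


def build_toy_system(spec: ToySpec):
    """Generate the two-lobe pocket system; deterministic for a fixed seed.

    Returns ``(SiteTopology, Conformation)``.  Total charge is zero by
    construction (ligand −1 balanced by +1/8 on each of the 8 pocket-lining
    sites).
    """
    if not isinstance(spec, ToySpec):
        raise TypeError("spec must be a ToySpec")
    rng = np.random.default_rng(spec.rng_seed)

    lobe_a = _lobe_sites(spec, -1, rng)
    lobe_b = _lobe_sites(spec, +1, rng)
    n_l = spec.n_lobe_sites
    protein = np.vstack([lobe_a, lobe_b])

    if spec.n_ligand_sites == 1:
        ligand = np.zeros((1, 3))
        lig_masses = np.array([150.0])
        lig_charges = np.array([-0.2])
    else:
        # small rigid tetrahedral group around the pocket centre
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / np.sqrt(3.0) * 0.7
        ligand = tet
        lig_masses = np.full(4, 40.0)
        lig_charges = np.full(4, -0.05)

    coords = np.vstack([protein, ligand])
    n_prot = protein.shape[0]
    n = coords.shape[0]

    labels = [f"A{i+1}" for i in range(n_l)] + [f"B{i+1}" for i in range(n_l)]
    labels += ["LIG"] * spec.n_ligand_sites

    masses = np.concatenate([np.full(n_prot, 100.0), lig_masses])
    charges = np.zeros(n)
    # the 4 pocket sites of each lobe carry the neutralizing charge; the
    # magnitudes are kept small so the analytic channel terms dominate the
    # exit thermodynamics and the barrier oracle stays meaningful
    pocket_idx = np.concatenate([np.arange(4), n_l + np.arange(4)])
    charges[pocket_idx] = -lig_charges.sum() / 8.0
    charges[n_prot:] = lig_charges
    lj_eps = np.concatenate([np.full(n_prot, 0.10), np.full(spec.n_ligand_sites, 0.15)])
    lj_sig = np.concatenate([np.full(n_prot, 3.0), np.full(spec.n_ligand_sites, 3.0)])

    bonds = _intra_lobe_bonds(lobe_a, 0, spec) + _intra_lobe_bonds(lobe_b, n_l, spec)
    # hinge springs: each pocket site of lobe A to its nearest pocket site of B
    for i in range(4):
        d = np.linalg.norm(lobe_b[:4] - lobe_a[i], axis=1)
        j = int(d.argmin())
        bonds.append((i, n_l + j, spec.hinge_stiffness, float(d[j])))
    # rigid ligand group: stiff springs between all ligand-site pairs
    if spec.n_ligand_sites == 4:
        for i in range(4):
            for j in range(i + 1, 4):
                r0 = float(np.linalg.norm(ligand[j] - ligand[i]))
                bonds.append((n_prot + i, n_prot + j, 400.0, r0))

    bond_pairs = np.array([(b[0], b[1]) for b in bonds], dtype=int)
    bond_k = np.array([b[2] for b in bonds])
    bond_r0 = np.array([b[3] for b in bonds])

    ligand_mask = np.zeros(n, dtype=bool)
    ligand_mask[n_prot:] = True

    topology = SiteTopology(
        site_ids=np.arange(n), residue_labels=labels, masses=masses,
        charges=charges, lj_epsilon=lj_eps, lj_sigma=lj_sig,
        bond_pairs=bond_pairs, bond_k=bond_k, bond_r0=bond_r0,
        ligand_mask=ligand_mask,
        anchor_ids=np.arange(n_prot), anchor_k=spec.anchor_k,
        anchor_ref=protein.copy(),
        external=_calibrated_channel(spec),
    )
    return topology, Conformation(coords)


def pocket_site_ids(topology: SiteTopology, reference: Conformation,
                    cutoff: float = 4.0) -> np.ndarray:
    """Protein sites within ``cutoff`` of any ligand site in the reference
    structure — the COM-defining set for the exit coordinate."""
    lig = reference.coordinates[topology.ligand_ids]
    prot_ids = topology.protein_ids
    d = np.linalg.norm(reference.coordinates[prot_ids][:, None] - lig[None], axis=-1)
    return prot_ids[d.min(axis=1) <= cutoff]


# ---------------------------------------------------------------------------
# analytic PMF oracle
# ---------------------------------------------------------------------------

def analytic_pmf(potential_spec, grid, temperature: float,
                 transverse_points: int = 129) -> AnalyticPMF:
    """Exact (quadrature) PMF along the grid, anchored so min F = 0.

    ``F(d) = -kT ln ∫ exp(-U/kT)`` over transverse coordinates at fixed d.
    ``potential_spec`` is either a plain callable ``f(d)`` (1-D potential, in
    which case the PMF equals the potential up to a constant) or an axial
    potential object exposing ``profile(s)`` and ``k_perp``, whose two
    transverse degrees of freedom are integrated numerically.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kt = KB * temperature

    if hasattr(potential_spec, "profile"):
        f = np.asarray(potential_spec.profile(grid), dtype=float)
        k_perp = getattr(potential_spec, "k_perp", 0.0)
        if k_perp > 0:
            sig = np.sqrt(kt / k_perp)
            u = np.linspace(-8 * sig, 8 * sig, transverse_points)
            w1 = np.trapezoid(np.exp(-0.5 * k_perp * u ** 2 / kt), u)
            log_z = -f / kt + 2.0 * np.log(w1)
        else:
            log_z = -f / kt
    elif callable(potential_spec):
        f = np.asarray(potential_spec(grid), dtype=float)
        log_z = -f / kt
    else:
        raise TypeError("potential_spec must be callable or an axial potential")

    if not np.all(np.isfinite(log_z)):
        raise ValueError("potential is not integrable on the grid")
    free = -kt * log_z
    free = free - free.min()
    return AnalyticPMF(grid=grid, free_energy=free, potential_spec=potential_spec)


def channel_profile_oracle(topology: SiteTopology, channel: str,
                           temperature: float, s_max: float = 12.0,
                           n_points: int = 1201) -> AnalyticPMF:
    """Analytic PMF of one exit channel of a built toy system.

    ``channel`` is ``"A"`` (+axis) or ``"B"`` (−axis); the returned grid is
    the distance from the pocket centre along that channel.
    """
    if topology.external is None:
        raise ValueError("topology carries no channel potential")
    s = np.linspace(0.0, s_max, n_points)
    pot = topology.external
    if channel.upper() == "A":
        prof = pot.profile(s)
    elif channel.upper() == "B":
        prof = pot.profile(-s)
    else:
        raise ValueError("channel must be 'A' or 'B'")
    free = prof - prof.min()
    return AnalyticPMF(grid=s, free_energy=free, potential_spec=pot)


# ---------------------------------------------------------------------------
# two-site fixtures for WHAM validation
# ---------------------------------------------------------------------------

def make_axial_fixture(potential, reporter_mass: float = 50.0,
                       start_s: Optional[float] = None):
    """Minimal two-site system for sampling a known 1-D free-energy profile.

    Site 0 is a heavy, stiffly anchored reference bead at the origin (the
    "pocket COM"); site 1 is the mobile reporter moving in the given axial
    potential.  The umbrella distance coordinate then tracks the axial
    coordinate ``s`` to within the tiny transverse width.

    Returns ``(topology, start_conformation, com_ids, reporter_id)``.
    """
    if start_s is None:
        start_s = getattr(potential, "s0", getattr(potential, "center", 1.0))
    coords = np.array([[0.0, 0.0, 0.0],
                       np.asarray(potential.axis) * float(start_s)])
    topology = SiteTopology(
        site_ids=np.arange(2), residue_labels=["REF", "LIG"],
        masses=np.array([500.0, reporter_mass]),
        charges=np.zeros(2), lj_epsilon=np.zeros(2), lj_sigma=np.ones(2) * 3.0,
        bond_pairs=np.empty((0, 2), dtype=int), bond_k=np.empty(0), bond_r0=np.empty(0),
        ligand_mask=np.array([False, True]),
        anchor_ids=np.array([0]), anchor_k=1e5, anchor_ref=coords[:1].copy(),
        external=potential,
    )
    return topology, Conformation(coords), np.array([0]), 1
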