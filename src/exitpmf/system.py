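"""Core data containers shared across the pipeline.

Units are fixed globally: Å (length), kcal/mol (energy), amu (mass), ps
(time), elementary charge (charge).  The gas constant in these units is
``KB = 1.987e-3`` kcal/mol/K and the Coulomb prefactor is
``COULOMB = 332.0636`` kcal·Å/mol/e².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: gas constant / Boltzmann constant, kcal·mol⁻¹·K⁻¹
KB = 1.987e-3
#: Coulomb prefactor, kcal·Å·mol⁻¹·e⁻²
COULOMB = 332.0636
#: 1 kcal/mol expressed in amu·Å²·ps⁻² (converts forces to accelerations)
KCAL_TO_AMU_A2_PS2 = 418.4


class AxialPotentialMixin:
    """Shared 3-D evaluation for potentials of the separable form
    ``U(r) = f(s) + 0.5 * k_perp * rho²`` with ``s`` the signed projection on
    ``axis`` (measured from ``origin``) and ``rho`` the off-axis distance.

    Subclasses provide ``profile(s)`` and ``profile_grad(s)`` plus the fields
    ``axis``, ``origin`` and ``k_perp``.  Because the transverse confinement
    is independent of ``s``, the exact PMF along the axis equals ``f(s)`` up
    to an additive constant.
    """

    def energy_gradient(self, points):
        """Energy (…,) and gradient (…, 3) at Cartesian point(s) (…, 3)."""
        p = np.asarray(points, dtype=float) - self.origin
        s = p @ self.axis
        perp = p - s[..., None] * self.axis
        e = self.profile(s) + 0.5 * self.k_perp * np.sum(perp ** 2, axis=-1)
        grad = self.profile_grad(s)[..., None] * self.axis + self.k_perp * perp
        return e, grad


@dataclass(frozen=True)
class ChannelPotential(AxialPotentialMixin):
    """Analytic external potential acting on the ligand centre of mass.

    The potential is separable into a 1-D profile along the channel axis and
    a harmonic transverse confinement::

        U(r) = f(s) + 0.5 * k_perp * rho^2

    with ``s = r · axis`` (signed projection onto the exit axis measured from
    ``origin``) and ``rho`` the distance from the axis.  The 1-D profile is a
    bound-state Gaussian well flanked by one Gaussian barrier ridge on each
    side (the two candidate exit channels)::

        f(s) = -well_depth * exp(-s²/2σw²)
               + amp_plus  * exp(-(s - barrier_pos)²/2σb²)
               + amp_minus * exp(-(s + barrier_pos)²/2σb²)

    Because the transverse part does not depend on ``s``, the exact potential
    of mean force along the axis equals ``f(s)`` up to an additive constant —
    this is what makes the toy system an analytic oracle for WHAM.
    """

    well_depth: float
    well_sigma: float
    barrier_pos: float
    barrier_sigma: float
    amp_plus: float
    amp_minus: float
    k_perp: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    kernel_code = 1  # fast-path dispatch tag

    @property
    def kernel_params(self) -> np.ndarray:
        return np.array([self.well_depth, self.well_sigma, self.barrier_pos,
                         self.barrier_sigma, self.amp_plus, self.amp_minus])

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n <= 0:
            raise ValueError("channel axis must be non-zero")
        object.__setattr__(self, "axis", ax / n)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        for name in ("well_sigma", "barrier_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_perp < 0:
            raise ValueError("k_perp must be non-negative")

    # ---- 1-D profile along the axis -------------------------------------
    def profile(self, s):
        """Axial profile f(s) in kcal/mol (s may be an array)."""
        s = np.asarray(s, dtype=float)
        return (
            -self.well_depth * np.exp(-(s ** 2) / (2 * self.well_sigma ** 2))
            + self.amp_plus * np.exp(-((s - self.barrier_pos) ** 2) / (2 * self.barrier_sigma ** 2))
            + self.amp_minus * np.exp(-((s + self.barrier_pos) ** 2) / (2 * self.barrier_sigma ** 2))
        )

    def profile_grad(self, s):
        s = np.asarray(s, dtype=float)
        g = (
            self.well_depth * s / self.well_sigma ** 2
            * np.exp(-(s ** 2) / (2 * self.well_sigma ** 2))
        )
        g -= (
            self.amp_plus * (s - self.barrier_pos) / self.barrier_sigma ** 2
            * np.exp(-((s - self.barrier_pos) ** 2) / (2 * self.barrier_sigma ** 2))
        )
        g -= (
            self.amp_minus * (s + self.barrier_pos) / self.barrier_sigma ** 2
            * np.exp(-((s + self.barrier_pos) ** 2) / (2 * self.barrier_sigma ** 2))
        )
        return g


@dataclass(eq=False)
class SiteTopology:
    """Coarse site-level description of the two-lobe pocket system.

    One "site" stands in for one residue (protein lobes) or one ligand bead.
    Bonds carry the elastic-network springs; ``anchors`` are weak positional
    restraints emulating the membrane anchoring of the real complex, which
    also pin the analytic channel potential's laboratory frame.
    """

    site_ids: np.ndarray
    residue_labels: list
    masses: np.ndarray
    charges: np.ndarray
    lj_epsilon: np.ndarray
    lj_sigma: np.ndarray
    bond_pairs: np.ndarray          # (n_bonds, 2) int
    bond_k: np.ndarray              # kcal/mol/Å²
    bond_r0: np.ndarray             # Å
    ligand_mask: np.ndarray         # bool per site
    anchor_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    anchor_k: float = 0.0
    anchor_ref: Optional[np.ndarray] = None
    external: Optional[ChannelPotential] = None

    def __post_init__(self):
        self.site_ids = np.asarray(self.site_ids, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.bond_pairs = np.asarray(self.bond_pairs, dtype=int).reshape(-1, 2)
        self.bond_k = np.asarray(self.bond_k, dtype=float)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float)
        self.ligand_mask = np.asarray(self.ligand_mask, dtype=bool)
        self.anchor_ids = np.asarray(self.anchor_ids, dtype=int)
        n = self.n_sites
        if len(set(self.site_ids.tolist())) != n:
            raise ValueError("site_ids must be unique")
        if not (len(self.residue_labels) == self.masses.size == self.charges.size
                == self.lj_epsilon.size == self.lj_sigma.size == self.ligand_mask.size == n):
            raise ValueError("per-site arrays must all have the same length")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if np.any(self.lj_sigma <= 0):
            raise ValueError("lj_sigma must be positive")
        if self.bond_pairs.shape[0] != self.bond_k.size or self.bond_k.size != self.bond_r0.size:
            raise ValueError("bond arrays must have matching lengths")
        if np.any(self.bond_r0 <= 0):
            raise ValueError("bond rest lengths must be positive")
        if not self.ligand_mask.any():
            raise ValueError("ligand sites must form a non-empty group")
        # ligand sites must be a contiguous label group
        idx = np.flatnonzero(self.ligand_mask)
        if idx.size and not np.array_equal(idx, np.arange(idx[0], idx[0] + idx.size)):
            raise ValueError("ligand sites must be contiguous")

    @property
    def n_sites(self) -> int:
        return self.site_ids.size

    @property
    def ligand_ids(self) -> np.ndarray:
        return np.flatnonzero(self.ligand_mask)

    @property
    def protein_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.ligand_mask)


@dataclass
class Conformation:
    """One set of site coordinates (Å); box lengths optional (orthorhombic)."""

    coordinates: np.ndarray
    box: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_sites, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    def copy(self) -> "Conformation":
        return Conformation(self.coordinates.copy(),
                            None if self.box is None else np.asarray(self.box).copy())

    @property
    def n_sites(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Ordered conformations with times (ps) and optional reaction-coordinate trace (Å)."""

    frames: np.ndarray              # (n_frames, n_sites, 3)
    times: np.ndarray               # (n_frames,) ps
    rc_trace: Optional[np.ndarray] = None
    labels: Optional[list] = None   # provenance, one per frame (optional)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != self.times.size:
            raise ValueError("frames must be (n_frames, n_sites, 3) matching times")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.rc_trace is not None:
            self.rc_trace = np.asarray(self.rc_trace, dtype=float)
            if self.rc_trace.size != self.times.size:
                raise ValueError("rc_trace length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def conformation(self, i: int) -> Conformation:
        return Conformation(self.frames[i].copy())


def pocket_com(coords: np.ndarray, masses: np.ndarray, com_ids: Sequence[int]) -> np.ndarray:
    """Mass-weighted centre of mass of the pocket sites.

    Supports a leading batch dimension on ``coords``.
    """
    com_ids = np.asarray(com_ids, dtype=int)
    m = masses[com_ids]
    return np.einsum("...ij,i->...j", coords[..., com_ids, :], m) / m.sum()
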