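"""Per-residue nonbonded interaction-energy profiles along the exit
coordinate, and cross-pathway profile correlations.

For every residue within the contact cutoff of the ligand anywhere along the
explored pathways, the ligand:residue Lennard-Jones + Coulomb energy is
re-computed frame by frame and averaged inside fine bins (0.02 Å) of the
exit coordinate.  Strongly negative profile values mark favourable
(stabilising) contacts, positive values repulsive ones; comparing profiles
between independent extractions of the same channel measures how conserved
the interaction sequence is (Pearson correlation per residue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .system import COULOMB, SiteTopology, Trajectory

__all__ = [
    "InteractionProfile", "contact_residues", "interaction_profile",
    "profile_correlation", "classify_profile",
]

#: contact cutoff for building the residue roster, Å
DEFAULT_CONTACT_CUTOFF = 4.0
#: exit-coordinate bin width for the profiles, Å
DEFAULT_PROFILE_BIN = 0.02
#: |energy| below which a bin is classified neutral, kcal/mol
NEUTRAL_DEADBAND = 0.5


@dataclass
class InteractionProfile:
    """Residue × distance-bin matrix of mean interaction energies (kcal/mol).

    Bins with zero assigned frames are NaN.  Bin edges are anchored at
    multiples of the bin width, so profiles from different runs share a grid.
    """

    residue_labels: list
    bin_edges: np.ndarray
    energies: np.ndarray        # (n_residues, n_bins), NaN where no frames
    counts: np.ndarray          # (n_bins,), frames per bin

    def __post_init__(self):
        if self.energies.shape != (len(self.residue_labels), self.bin_edges.size - 1):
            raise ValueError("energy matrix shape inconsistent with labels/bins")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.energies, index=self.residue_labels,
                            columns=np.round(self.bin_centers, 4))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="residue")


def _residue_site_map(topology: SiteTopology) -> dict:
    out: dict = {}
    for i in topology.protein_ids:
        out.setdefault(topology.residue_labels[i], []).append(int(i))
    return out


def contact_residues(trajectories: Sequence[Trajectory], topology: SiteTopology,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF) -> list:
    """Residues with any site within ``cutoff`` of any ligand site in any
    frame of any trajectory, ordered by site index."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    lig = topology.ligand_ids
    prot = topology.protein_ids
    hit = np.zeros(prot.size, dtype=bool)
    for traj in trajectories:
        # (F, n_prot, n_lig) distances, min over frames and ligand sites
        d = np.linalg.norm(traj.frames[:, prot, None, :] - traj.frames[:, None, lig, :],
                           axis=-1)
        hit |= d.min(axis=(0, 2)) <= cutoff
    seen = []
    for i in prot[hit]:
        lab = topology.residue_labels[i]
        if lab not in seen:
            seen.append(lab)
    return seen


def interaction_profile(trajectory: Trajectory, topology: SiteTopology,
                        residues: Sequence[str],
                        bin_width: float = DEFAULT_PROFILE_BIN) -> InteractionProfile:
    """Mean ligand:residue nonbonded energy as a function of the exit
    coordinate, binned every ``bin_width`` Å.

    Per frame, the energy of a residue is the sum of LJ + Coulomb over all
    ligand-site × residue-site pairs; frames are assigned to bins by their
    reaction-coordinate value and averaged (unweighted) within each bin.
    """
    if trajectory.rc_trace is None:
        raise ValueError("trajectory has no reaction-coordinate trace")
    res_map = _residue_site_map(topology)
    missing = [r for r in residues if r not in res_map]
    if missing:
        raise ValueError(f"unknown residues: {missing}")
    lig = topology.ligand_ids
    frames = trajectory.frames
    F = frames.shape[0]

    per_res = np.empty((len(residues), F))
    for ri, lab in enumerate(residues):
        sites = np.array(res_map[lab])
        dv = frames[:, lig, None, :] - frames[:, None, sites, :]
        r2 = np.sum(dv * dv, axis=-1)
        r = np.sqrt(r2)
        sig = 0.5 * (topology.lj_sigma[lig][:, None] + topology.lj_sigma[sites][None, :])
        eps = np.sqrt(topology.lj_epsilon[lig][:, None] * topology.lj_epsilon[sites][None, :])
        qq = COULOMB * topology.charges[lig][:, None] * topology.charges[sites][None, :]
        sr6 = (sig[None] ** 2 / r2) ** 3
        per_res[ri] = np.sum(4.0 * eps[None] * (sr6 ** 2 - sr6) + qq[None] / r,
                             axis=(1, 2))

    rc = trajectory.rc_trace
    first = np.floor(rc.min() / bin_width) * bin_width
    n_bins = int(np.ceil((rc.max() - first) / bin_width)) + 1
    edges = first + bin_width * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(rc, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    energies = np.full((len(residues), n_bins), np.nan)
    occupied = counts > 0
    for ri in range(len(residues)):
        sums = np.bincount(idx, weights=per_res[ri], minlength=n_bins)
        energies[ri, occupied] = sums[occupied] / counts[occupied]
    return InteractionProfile(residue_labels=list(residues), bin_edges=edges,
                              energies=energies, counts=counts)


def classify_profile(profile: InteractionProfile,
                     deadband: float = NEUTRAL_DEADBAND) -> np.ndarray:
    """Qualitative colouring of the profile matrix: −1 favourable (green
    analog), +1 repulsive (red analog), 0 neutral within ±deadband or no data."""
    out = np.zeros_like(profile.energies, dtype=int)
    with np.errstate(invalid="ignore"):
        out[profile.energies < -deadband] = -1
        out[profile.energies > deadband] = 1
    return out


def profile_correlation(a: InteractionProfile, b: InteractionProfile,
                        min_joint_bins: int = 10):
    """Per-residue Pearson correlation of two profiles on their common grid.

    Profiles must list the same residues; bins are matched by their centres
    (nearest-bin matching on the shared anchored grid, never interpolation).
    Returns ``(per_residue, mean, sd)`` where the summary covers residues
    with at least ``min_joint_bins`` jointly occupied bins.
    """
    if list(a.residue_labels) != list(b.residue_labels):
        raise ValueError("profiles must cover the same residues, in order")
    ca = np.round(a.bin_centers, 6)
    cb = np.round(b.bin_centers, 6)
    common, ia, ib = np.intersect1d(ca, cb, return_indices=True)
    if common.size == 0:
        raise ValueError("profiles share no overlapping bins")
    per = {}
    usable = []
    for ri, lab in enumerate(a.residue_labels):
        xa = a.energies[ri, ia]
        xb = b.energies[ri, ib]
        ok = np.isfinite(xa) & np.isfinite(xb)
        if ok.sum() < 2:
            warnings.warn(f"residue {lab}: no joint coverage; omitted", RuntimeWarning)
            continue
        sa, sb = np.std(xa[ok]), np.std(xb[ok])
        if sa == 0 or sb == 0:
            warnings.warn(f"residue {lab}: constant profile; omitted", RuntimeWarning)
            continue
        r = float(np.corrcoef(xa[ok], xb[ok])[0, 1])
        per[lab] = r
        if ok.sum() >= min_joint_bins:
            usable.append(r)
    per = pd.Series(per, dtype=float)
    if usable:
        mean, sd = float(np.mean(usable)), float(np.std(usable))
    else:
        mean, sd = float("nan"), float("nan")
    return per, mean, sd
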