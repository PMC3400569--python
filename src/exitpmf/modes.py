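"""Essential dynamics (quasi-modes) and elastic-network normal modes.

Quasi-modes are the principal components of the mass-weighted covariance of
trajectory coordinates after rigid-body removal by least-squares
superposition onto the mean structure; large variance corresponds to low
effective frequency, so "lowest-frequency quasi-modes" are the
largest-variance components.  The reference mode set is an elastic-network
model (ENM): Hookean springs of uniform stiffness between backbone-analog
sites within a cutoff, whose mass-weighted Hessian eigenvectors are the
normal modes (the six near-zero rigid-body modes are identified and
excluded from matching).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .system import Conformation, SiteTopology, Trajectory

__all__ = ["ModeSet", "quasi_modes", "enm_normal_modes", "concatenate",
           "DEFAULT_N_QUASI_MODES", "DEFAULT_ENM_CUTOFF"]

#: number of quasi-modes retained from an essential-dynamics analysis
DEFAULT_N_QUASI_MODES = 50
#: elastic-network spring cutoff, Å
DEFAULT_ENM_CUTOFF = 8.0
#: eigenvalue threshold below which an ENM mode counts as rigid-body
RIGID_EIGENVALUE_TOL = 1e-8


@dataclass
class ModeSet:
    """Orthonormal mass-weighted displacement vectors with eigenvalues.

    ``vectors[k]`` is the k-th mode as a 3·M mass-weighted vector over the
    ``site_subset``; the Gram matrix of the vectors is the identity.  For
    quasi-modes the eigenvalues are variances (Ų·amu, descending); for
    normal modes they are mass-weighted stiffnesses (kcal·mol⁻¹·Å⁻²·amu⁻¹,
    ascending, rigid-body modes excluded).
    """

    vectors: np.ndarray          # (n_modes, 3*M)
    eigenvalues: np.ndarray
    kind: str                    # "quasi" | "normal"
    site_subset: np.ndarray
    masses: np.ndarray           # per subset site
    all_eigenvalues: Optional[np.ndarray] = None  # incl. rigid-body (normal)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.site_subset = np.asarray(self.site_subset, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.kind not in ("quasi", "normal"):
            raise ValueError("kind must be 'quasi' or 'normal'")
        if self.vectors.shape != (self.eigenvalues.size, 3 * self.site_subset.size):
            raise ValueError("vectors shape inconsistent with eigenvalues/subset")

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[0]

    def displacement(self, index: int) -> np.ndarray:
        """Cartesian (de-mass-weighted) displacement field (M, 3) of one mode."""
        v = self.vectors[index].reshape(-1, 3)
        return v / np.sqrt(self.masses)[:, None]

    def gram(self) -> np.ndarray:
        return self.vectors @ self.vectors.T


def _kabsch(mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray):
    """Weighted least-squares superposition of ``mobile`` onto ``reference``."""
    w = weights / weights.sum()
    mc = mobile - (w[:, None] * mobile).sum(axis=0)
    rc = reference - (w[:, None] * reference).sum(axis=0)
    h = (w[:, None] * mc).T @ rc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return mc @ rot.T + (w[:, None] * reference).sum(axis=0)


def superpose_frames(frames: np.ndarray, masses: np.ndarray,
                     n_iter: int = 2) -> np.ndarray:
    """Superpose every frame onto the (iteratively refined) mean structure."""
    out = np.array(frames, dtype=float)
    ref = out[0]
    for _ in range(n_iter):
        for i in range(out.shape[0]):
            out[i] = _kabsch(out[i], ref, masses)
        ref = out.mean(axis=0)
    return out


def quasi_modes(trajectory: Trajectory, topology: SiteTopology,
                site_subset: Optional[Sequence[int]] = None,
                n_modes: int = DEFAULT_N_QUASI_MODES) -> ModeSet:
    """Essential-dynamics quasi-modes of a trajectory.

    Frames restricted to ``site_subset`` (default: all protein sites, the
    backbone analogs) are superposed onto the mean structure, the
    mass-weighted covariance is diagonalised, and the top ``n_modes`` by
    variance are returned (capped at 3·M − 6 with a warning).
    """
    if trajectory.n_frames < 2:
        raise ValueError("need at least 2 frames for a covariance analysis")
    subset = (topology.protein_ids if site_subset is None
              else np.asarray(site_subset, dtype=int))
    masses = topology.masses[subset]
    m3 = 3 * subset.size
    if trajectory.n_frames <= m3:
        warnings.warn(f"only {trajectory.n_frames} frames for {m3} degrees of "
                      "freedom; covariance estimate is noisy", RuntimeWarning)
    cap = m3 - 6
    if n_modes > cap:
        warnings.warn(f"requested {n_modes} modes; returning {cap} "
                      f"(3N−6 for {subset.size} sites)", RuntimeWarning)
        n_modes = cap

    frames = superpose_frames(trajectory.frames[:, subset, :], masses)
    mean = frames.mean(axis=0)
    dev = (frames - mean) * np.sqrt(masses)[None, :, None]
    flat = dev.reshape(trajectory.n_frames, -1)
    cov = flat.T @ flat / trajectory.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_modes]
    return ModeSet(vectors=evecs[:, order].T, eigenvalues=evals[order],
                   kind="quasi", site_subset=subset, masses=masses)


def enm_normal_modes(topology: SiteTopology, reference: Conformation,
                     site_subset: Optional[Sequence[int]] = None,
                     cutoff: float = DEFAULT_ENM_CUTOFF,
                     stiffness: float = 1.0) -> ModeSet:
    """Normal modes of a uniform elastic network built on the reference.

    Springs connect subset sites within ``cutoff``; the Hessian of the
    network energy at its minimum is mass-weighted and diagonalised.  Exactly
    six near-zero rigid-body modes are expected for a connected 3-D network;
    they are excluded from the returned set (kept in ``all_eigenvalues``).
    """
    subset = (topology.protein_ids if site_subset is None
              else np.asarray(site_subset, dtype=int))
    coords = reference.coordinates[subset]
    masses = topology.masses[subset]
    m = subset.size
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)
             if d[i, j] <= cutoff]
    if pairs:
        rows = [p[0] for p in pairs] + [p[1] for p in pairs]
        cols = [p[1] for p in pairs] + [p[0] for p in pairs]
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
        ncomp, labels = connected_components(adj, directed=False)
    else:
        ncomp, labels = m, np.arange(m)
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise ValueError(f"elastic network is disconnected: {ncomp} components "
                         f"of sizes {sizes.tolist()}")

    hess = np.zeros((3 * m, 3 * m))
    for i, j in pairs:
        dv = coords[j] - coords[i]
        u = dv / np.linalg.norm(dv)
        block = stiffness * np.outer(u, u)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        hess[si, si] += block
        hess[sj, sj] += block
        hess[si, sj] -= block
        hess[sj, si] -= block
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)
    hess_mw = hess * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    evals, evecs = np.linalg.eigh(hess_mw)
    rigid = evals < RIGID_EIGENVALUE_TOL
    return ModeSet(vectors=evecs[:, ~rigid].T, eigenvalues=evals[~rigid],
                   kind="normal", site_subset=subset, masses=masses,
                   all_eigenvalues=evals)


def concatenate(trajectories: Sequence[Trajectory]) -> Trajectory:
    """Concatenate trajectories end to end, re-offsetting times monotonically."""
    if not trajectories:
        raise ValueError("nothing to concatenate")
    n_sites = trajectories[0].frames.shape[1]
    for t in trajectories[1:]:
        if t.frames.shape[1] != n_sites:
            raise ValueError("site-count mismatch between trajectories")
    frames = np.concatenate([t.frames for t in trajectories])
    times = []
    offset = 0.0
    for t in trajectories:
        times.append(t.times + offset)
        offset = times[-1][-1] + (t.times[1] - t.times[0] if t.times.size > 1 else 1.0)
    times = np.concatenate(times)
    rcs = [t.rc_trace for t in trajectories]
    rc = np.concatenate(rcs) if all(r is not None for r in rcs) else None
    labels = []
    for i, t in enumerate(trajectories):
        labels.extend(t.labels if t.labels is not None else [str(i)] * t.n_frames)
    return Trajectory(frames=frames, times=times, rc_trace=rc, labels=labels)
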