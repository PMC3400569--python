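"""Motion comparison through displacement matrices and the Mantel test.

A collective motion (mode) is fingerprinted by displacing the reference
structure along the mode to a +1 Å amplitude and recording, for every pair
of sites, the absolute change of the inter-site distance.  The resulting 2-D
matrix is invariant under rigid-body transformations, so motions from
different analyses (essential dynamics vs normal modes) can be compared
directly: the Mantel statistic is the Pearson correlation of the
upper-triangle entries, with significance from simultaneous row/column
permutations.  Two maps with r above 0.5–0.6 describe closely related
motions in Cartesian space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .modes import ModeSet
from .system import Conformation

__all__ = [
    "DisplacementMatrix", "MatchTable", "displace_along_mode",
    "displacement_matrix", "mantel_correlation", "match_modes",
    "DEFAULT_AMPLITUDE", "DEFAULT_MATCH_THRESHOLD",
]

#: displacement amplitude used to build the matrices, Å
DEFAULT_AMPLITUDE = 1.0
#: Mantel-r threshold above which two motions count as highly related
DEFAULT_MATCH_THRESHOLD = 0.5


@dataclass
class DisplacementMatrix:
    """|Δd_ij| between two structures for all site pairs (symmetric, zero
    diagonal, non-negative)."""

    labels: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = self.labels.size
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


@dataclass
class MatchTable:
    """All quasi × normal Mantel correlations plus per-quasi-mode best match."""

    r_matrix: pd.DataFrame        # rows: quasi index, cols: normal index
    best_match: pd.Series         # per quasi-mode: argmax-r normal mode
    best_r: pd.Series
    significant: pd.Series        # best_r > threshold
    threshold: float

    def to_tsv(self, path) -> None:
        self.r_matrix.to_csv(path, sep="\t", index_label="quasi_mode")


def displace_along_mode(reference: Conformation, modes: ModeSet, index: int,
                        amplitude: float = DEFAULT_AMPLITUDE) -> Conformation:
    """Reference displaced along one mode, normalised so the largest per-site
    displacement equals ``amplitude`` (Å)."""
    disp = modes.displacement(index)
    norms = np.linalg.norm(disp, axis=1)
    peak = norms.max()
    if peak <= 0:
        raise ValueError("zero mode vector")
    out = reference.copy()
    out.coordinates[modes.site_subset] += (amplitude / peak) * disp
    return out


def displacement_matrix(a: Conformation, b: Conformation,
                        subset: np.ndarray) -> DisplacementMatrix:
    """Pairwise |Δd_ij| between two structures over ``subset`` sites."""
    subset = np.asarray(subset, dtype=int)
    if a.n_sites != b.n_sites:
        raise ValueError("structures have different site counts")
    da = pdist(a.coordinates[subset])
    db = pdist(b.coordinates[subset])
    return DisplacementMatrix(labels=subset, values=squareform(np.abs(db - da)))


def mantel_correlation(m1: DisplacementMatrix, m2: DisplacementMatrix,
                       n_permutations: int = 9999, seed: int = 0):
    """Mantel statistic between two displacement matrices.

    r is the Pearson correlation over upper-triangle entries; the two-sided
    p-value comes from ``n_permutations`` simultaneous row/column
    relabelings of the second matrix (deterministic under ``seed``).  With
    ``n_permutations=0`` only r is computed (p = NaN).
    """
    if m1.labels.size != m2.labels.size or not np.array_equal(m1.labels, m2.labels):
        raise ValueError("matrices must share the same labels, in order")
    x = m1.upper()
    y = m2.upper()
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant matrix: Mantel r undefined", RuntimeWarning)
        return float("nan"), float("nan")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    if n_permutations < 1:
        return r_obs, float("nan")
    rng = np.random.default_rng(seed)
    n = m1.labels.size
    iu = np.triu_indices(n, k=1)
    xc = x - x.mean()
    xs = np.sqrt((xc ** 2).sum())
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = m2.values[np.ix_(perm, perm)][iu]
        yc = yp - yp.mean()
        denom = xs * np.sqrt((yc ** 2).sum())
        r_perm = float(xc @ yc / denom) if denom > 0 else 0.0
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return r_obs, float(p)


def match_modes(quasi: ModeSet, normal: ModeSet, reference: Conformation,
                threshold: float = DEFAULT_MATCH_THRESHOLD,
                amplitude: float = DEFAULT_AMPLITUDE,
                n_permutations: int = 0, seed: int = 0) -> MatchTable:
    """Compare every quasi-mode against every normal mode.

    Each mode is rendered as the displacement matrix between the reference
    and the structure displaced to +1 Å along the mode; the full Mantel-r
    matrix is computed, and each quasi-mode is assigned its argmax-r normal
    mode, flagged significant when r exceeds the threshold.
    """
    if not np.array_equal(quasi.site_subset, normal.site_subset):
        raise ValueError("mode sets must share the same site subset")
    subset = quasi.site_subset
    dm_q = [displacement_matrix(reference,
                                displace_along_mode(reference, quasi, i, amplitude),
                                subset)
            for i in range(quasi.n_modes)]
    dm_n = [displacement_matrix(reference,
                                displace_along_mode(reference, normal, j, amplitude),
                                subset)
            for j in range(normal.n_modes)]
    r = np.empty((quasi.n_modes, normal.n_modes))
    for i, mq in enumerate(dm_q):
        for j, mn in enumerate(dm_n):
            r[i, j], _ = mantel_correlation(mq, mn, n_permutations=n_permutations,
                                            seed=seed)
    rm = pd.DataFrame(r, index=range(quasi.n_modes), columns=range(normal.n_modes))
    best = rm.idxmax(axis=1)
    best_r = rm.max(axis=1)
    return MatchTable(r_matrix=rm, best_match=best, best_r=best_r,
                      significant=best_r > threshold, threshold=threshold)
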