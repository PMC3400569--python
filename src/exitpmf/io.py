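"""Plain-text file formats.

* umbrella time series: two whitespace-separated columns (time ps, distance
  Å), ``#`` comments ignored — the classic Grossfield WHAM dialect;
* window metadata: one line per window, ``<timeseries-path> <d_eq> <k>``;
* coordinates as PDB (one site per ATOM record, residue label in the
  residue-name field, multi-model for trajectories) and plain XYZ;
* topologies as JSON; mode sets as a documented text block format.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .system import ChannelPotential, Conformation, SiteTopology, Trajectory
from .modes import ModeSet

__all__ = [
    "write_timeseries", "read_timeseries", "write_wham_metadata",
    "read_wham_metadata", "write_ladder_files", "write_pdb", "write_xyz",
    "write_topology_json", "read_topology_json", "write_modes", "read_modes",
    "write_mode_animation",
]


# ---------------------------------------------------------------------------
# Grossfield-dialect umbrella files
# ---------------------------------------------------------------------------

def write_timeseries(path, times: np.ndarray, values: np.ndarray,
                     header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.6f} {v:.8f}\n")


def read_timeseries(path):
    times, values = [], []
    with open(path) as fh:
        for line in fh:
            s = line.split("#", 1)[0].strip()
            if not s:
                continue
            parts = s.split()
            times.append(float(parts[0]))
            values.append(float(parts[1]))
    return np.array(times), np.array(values)


def write_wham_metadata(path, entries) -> None:
    """``entries``: iterable of (timeseries_path, d_eq, k)."""
    with open(path, "w") as fh:
        fh.write("# timeseries d_eq(A) k(kcal/mol/A^2)\n")
        for ts, d_eq, k in entries:
            fh.write(f"{ts} {d_eq:.6f} {k:.6f}\n")


def read_wham_metadata(path):
    """Returns list of (timeseries_path, d_eq, k); paths resolved relative to
    the metadata file."""
    base = Path(path).parent
    out = []
    with open(path) as fh:
        for line in fh:
            s = line.split("#", 1)[0].strip()
            if not s:
                continue
            parts = s.split()
            ts = Path(parts[0])
            if not ts.is_absolute():
                ts = base / ts
            out.append((str(ts), float(parts[1]), float(parts[2])))
    return out


def write_ladder_files(ladder, out_dir, record_dt: float = 1.0) -> str:
    """Write per-window time series plus the metadata file; returns the
    metadata path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, w in enumerate(ladder.windows):
        if w.samples is None or w.failed:
            continue
        name = f"window_{i:03d}.dat"
        times = record_dt * np.arange(1, w.samples.size + 1)
        write_timeseries(out / name, times, w.samples,
                         header=f"d_eq={w.d_eq:.4f} k={w.k:.2f} seed={w.rng_seed}")
        entries.append((name, w.d_eq, w.k))
    meta = out / "metadata.dat"
    write_wham_metadata(meta, entries)
    return str(meta)


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial, name, resname, resseq, xyz, element="C"):
    return (f"ATOM  {serial:>5d} {name:<4s}{resname:<4s}A{resseq:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {element:>2s}\n")


def write_pdb(path, topology: SiteTopology,
              data: Union[Conformation, Trajectory]) -> None:
    """One site per ATOM record; residue label in the residue-name field;
    multi-model output for trajectories."""
    frames = (data.frames if isinstance(data, Trajectory)
              else data.coordinates[None])
    with open(path, "w") as fh:
        multi = frames.shape[0] > 1
        for mi, coords in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {mi:>4d}\n")
            for i in range(topology.n_sites):
                name = "LIG" if topology.ligand_mask[i] else "CA"
                elem = "P" if topology.ligand_mask[i] else "C"
                fh.write(_pdb_atom_line(i + 1, name, topology.residue_labels[i][:4],
                                        i + 1, coords[i], elem))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_xyz(path, topology: SiteTopology,
              data: Union[Conformation, Trajectory],
              comment: str = "") -> None:
    frames = (data.frames if isinstance(data, Trajectory)
              else data.coordinates[None])
    with open(path, "w") as fh:
        for coords in frames:
            fh.write(f"{topology.n_sites}\n{comment}\n")
            for i in range(topology.n_sites):
                lab = topology.residue_labels[i]
                fh.write(f"{lab:<6s} {coords[i, 0]:.6f} {coords[i, 1]:.6f} "
                         f"{coords[i, 2]:.6f}\n")


def write_mode_animation(path, topology: SiteTopology, reference: Conformation,
                         modes: ModeSet, index: int, amplitude: float = 1.0,
                         n_frames: int = 11) -> None:
    """Multi-model PDB sweeping one mode from −amplitude to +amplitude."""
    from .mode_compare import displace_along_mode
    amps = np.linspace(-amplitude, amplitude, n_frames)
    frames = np.stack([displace_along_mode(reference, modes, index, a).coordinates
                       if a != 0 else reference.coordinates for a in amps])
    traj = Trajectory(frames=frames, times=np.arange(1.0, n_frames + 1))
    write_pdb(path, topology, traj)


# ---------------------------------------------------------------------------
# topology JSON
# ---------------------------------------------------------------------------

def write_topology_json(path, topology: SiteTopology) -> None:
    ext = topology.external
    doc = {
        "site_ids": topology.site_ids.tolist(),
        "residue_labels": list(topology.residue_labels),
        "masses": topology.masses.tolist(),
        "charges": topology.charges.tolist(),
        "lj_epsilon": topology.lj_epsilon.tolist(),
        "lj_sigma": topology.lj_sigma.tolist(),
        "bonds": [[int(i), int(j), float(k), float(r0)]
                  for (i, j), k, r0 in zip(topology.bond_pairs,
                                           topology.bond_k, topology.bond_r0)],
        "ligand_mask": topology.ligand_mask.tolist(),
        "anchor_ids": topology.anchor_ids.tolist(),
        "anchor_k": topology.anchor_k,
        "anchor_ref": None if topology.anchor_ref is None else topology.anchor_ref.tolist(),
        "channel": None if not isinstance(ext, ChannelPotential) else {
            "well_depth": ext.well_depth, "well_sigma": ext.well_sigma,
            "barrier_pos": ext.barrier_pos, "barrier_sigma": ext.barrier_sigma,
            "amp_plus": ext.amp_plus, "amp_minus": ext.amp_minus,
            "k_perp": ext.k_perp, "axis": ext.axis.tolist(),
            "origin": ext.origin.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_topology_json(path) -> SiteTopology:
    with open(path) as fh:
        doc = json.load(fh)
    bonds = np.array(doc["bonds"], dtype=float).reshape(-1, 4)
    ext = None
    if doc.get("channel"):
        ext = ChannelPotential(**doc["channel"])
    return SiteTopology(
        site_ids=np.array(doc["site_ids"], dtype=int),
        residue_labels=list(doc["residue_labels"]),
        masses=np.array(doc["masses"]), charges=np.array(doc["charges"]),
        lj_epsilon=np.array(doc["lj_epsilon"]), lj_sigma=np.array(doc["lj_sigma"]),
        bond_pairs=bonds[:, :2].astype(int), bond_k=bonds[:, 2], bond_r0=bonds[:, 3],
        ligand_mask=np.array(doc["ligand_mask"], dtype=bool),
        anchor_ids=np.array(doc["anchor_ids"], dtype=int),
        anchor_k=float(doc["anchor_k"]),
        anchor_ref=None if doc["anchor_ref"] is None else np.array(doc["anchor_ref"]),
        external=ext,
    )


# ---------------------------------------------------------------------------
# mode sets
# ---------------------------------------------------------------------------

def write_modes(path, modes: ModeSet) -> None:
    """Text block format: a header with kind/subset/masses, then one block
    per mode with its eigenvalue and 3M vector components."""
    with open(path, "w") as fh:
        fh.write(f"# exitpmf ModeSet\nkind {modes.kind}\n")
        fh.write("subset " + " ".join(map(str, modes.site_subset.tolist())) + "\n")
        fh.write("masses " + " ".join(f"{m:.6f}" for m in modes.masses) + "\n")
        for i in range(modes.n_modes):
            fh.write(f"mode {i} eigenvalue {modes.eigenvalues[i]:.12g}\n")
            fh.write(" ".join(f"{v:.12g}" for v in modes.vectors[i]) + "\n")


def read_modes(path) -> ModeSet:
    kind = None
    subset = masses = None
    eigenvalues, vectors = [], []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            key, rest = s.split(None, 1)
            if key == "kind":
                kind = rest.strip()
            elif key == "subset":
                subset = np.array(rest.split(), dtype=int)
            elif key == "masses":
                masses = np.array(rest.split(), dtype=float)
            elif key == "mode":
                eigenvalues.append(float(rest.split()[-1]))
                vectors.append(None)
            elif vectors and vectors[-1] is None:
                raise ValueError("malformed mode file")
            if key == "mode":
                vec = next(fh).split()
                vectors[-1] = np.array(vec, dtype=float)
    return ModeSet(vectors=np.stack(vectors), eigenvalues=np.array(eigenvalues),
                   kind=kind, site_subset=subset, masses=masses)
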