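"""End-to-end study driver and the optional PDB coordinate adapter.

``run_full_study`` executes the whole pipeline on the synthetic system:
build → steered extraction along both exit channels → umbrella-window
construction (0.5 Å increments, gap filling at escalated force constant) →
restrained sampling → WHAM profiles and barriers → per-residue interaction
profiles with cross-replica correlations → essential dynamics vs
elastic-network normal modes with Mantel-test matching — and emits a
structured report whose headline is the preferred (lower-barrier) exit
channel.  Everything is reproducible from one master seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import io as efio
from .dynamics import LangevinParams
from .energetics import (DEFAULT_CONTACT_CUTOFF, DEFAULT_PROFILE_BIN,
                         contact_residues, interaction_profile,
                         profile_correlation)
from .mode_compare import (DEFAULT_AMPLITUDE, DEFAULT_MATCH_THRESHOLD,
                           match_modes)
from .modes import (DEFAULT_ENM_CUTOFF, DEFAULT_N_QUASI_MODES, concatenate,
                    enm_normal_modes, quasi_modes)
from .pathways import (DEFAULT_MIN_INCREMENT, DEFAULT_TMD_RATE,
                       DEFAULT_UMBRELLA_K, ESCALATED_UMBRELLA_K, fill_gaps,
                       run_ladder, run_tmd_extraction, select_windows)
from .system import Conformation, SiteTopology, Trajectory
from .toy_system import ToySpec, build_toy_system, pocket_site_ids
from .wham import barrier_height, build_histograms, wham_solve

__all__ = ["RunConfig", "run_full_study", "read_pdb_coordinates"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of the one-command study.

    Defaults carry the protocol constants: 0.5 Å window increment, umbrella
    k = 10 (escalated to 20 for inserted windows), TMD force 0.5
    kcal/mol/Å² per steered atom, 4 Å contact cutoff, 0.02 Å interaction
    bins, 50 quasi-modes compared to the 20 softest network modes at +1 Å
    amplitude with a 0.5 Mantel threshold.
    """

    toy: ToySpec = field(default_factory=ToySpec)
    master_seed: int = 0
    # steered extraction
    tmd_k_per_atom: float = 0.5
    tmd_rate: float = DEFAULT_TMD_RATE        # Å/ps; used when duration is None
    tmd_duration: Optional[float] = 60.0      # ps (desk-scale pulls)
    exit_distance: float = 20.0               # Å, ligand target along the channel axis
    ladder_max_distance: float = 13.0         # Å, windows beyond this are dropped
    tmd_rmsd_tolerance: float = 1.0           # Å (~2 thermal sd of the soft bias)
    n_replicas: int = 2
    # umbrella protocol
    umbrella_k: float = DEFAULT_UMBRELLA_K
    escalated_k: float = ESCALATED_UMBRELLA_K
    min_increment: float = DEFAULT_MIN_INCREMENT
    max_gap: float = DEFAULT_MIN_INCREMENT
    steps_per_window: int = 50_000
    # WHAM
    wham_bin_width: float = 0.1
    wham_tolerance: float = 1e-6
    wham_max_iterations: int = 100_000
    # energetics
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    profile_bin: float = DEFAULT_PROFILE_BIN
    # modes
    n_quasi_modes: int = DEFAULT_N_QUASI_MODES
    n_normal_modes: int = 20
    enm_cutoff: float = DEFAULT_ENM_CUTOFF
    amplitude: float = DEFAULT_AMPLITUDE
    match_threshold: float = DEFAULT_MATCH_THRESHOLD
    # stage toggles (barrier-only screens switch the last two off)
    run_energetics: bool = True
    run_modes: bool = True

    def stage_seed(self, stage: int, channel: int = 0, replica: int = 0) -> int:
        """Deterministic fan-out of the master seed: stage·10⁶ + channel·10³ +
        replica, offset from the master."""
        return int(self.master_seed + stage * 1_000_000 + channel * 1_000 + replica)


def default_anchor_ids(com_ids: np.ndarray) -> np.ndarray:
    """Four anchor sites for the TMD co-restraint: the outermost pocket sites
    of each lobe (the toy analog of restraining four pocket Cα atoms)."""
    return np.concatenate([com_ids[:2], com_ids[-2:]])


def _channel_target(topology: SiteTopology, start: Conformation,
                    channel: str, distance: float) -> Conformation:
    axis = topology.external.axis if topology.external is not None else np.array([0, 1.0, 0])
    sign = +1.0 if channel.upper() == "A" else -1.0
    lig = topology.ligand_ids
    target = start.copy()
    lig_com = start.coordinates[lig].mean(axis=0)
    target.coordinates[lig] += sign * distance * axis - lig_com
    return target


def run_full_study(config: RunConfig, out_dir: Optional[Union[str, Path]] = None) -> dict:
    """Run the complete study; returns (and optionally writes) the report.

    Any stage failure marks the stage in the report and skips what depends
    on it.  With ``out_dir`` set, data files (profiles, window series,
    structures) and figures regenerated from those files are written there.
    """
    report: dict = {"master_seed": config.master_seed, "stages": {}, "channels": {}}
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

    # ---- stage 0: system ---------------------------------------------------
    try:
        spec = replace(config.toy, rng_seed=config.stage_seed(0))
        topology, start = build_toy_system(spec)
        com_ids = pocket_site_ids(topology, start, cutoff=config.contact_cutoff)
        anchors = default_anchor_ids(com_ids)
        report["stages"]["build"] = "ok"
        if out is not None:
            efio.write_topology_json(out / "topology.json", topology)
            efio.write_pdb(out / "start.pdb", topology, start)
    except Exception as exc:  # pragma: no cover - defensive
        report["stages"]["build"] = f"failed: {exc}"
        return report

    params = LangevinParams(temperature=config.toy.temperature)

    # ---- per-channel extraction + umbrella + WHAM ---------------------------
    pathways_by_channel: dict = {}
    barriers: dict = {}
    for ci, channel in enumerate(("A", "B")):
        ch_rep: dict = {}
        try:
            target = _channel_target(topology, start, channel, config.exit_distance)
            paths = []
            for r in range(config.n_replicas):
                p = replace(params, rng_seed=config.stage_seed(1, ci, r))
                paths.append(run_tmd_extraction(
                    topology, start, target, k_per_atom=config.tmd_k_per_atom,
                    duration=config.tmd_duration, rate=config.tmd_rate,
                    anchors=anchors, params=p, com_site_ids=com_ids,
                    rmsd_tolerance=config.tmd_rmsd_tolerance,
                    label=f"channel-{channel}-r{r}"))
            pathways_by_channel[channel] = paths
            ch_rep["extractions_complete"] = [bool(p.complete) for p in paths]
            ch_rep["peak_steering_force"] = float(max(p.force_trace.max() for p in paths))
            report["stages"][f"tmd_{channel}"] = "ok"
        except Exception as exc:
            report["stages"][f"tmd_{channel}"] = f"failed: {exc}"
            report["channels"][channel] = ch_rep
            continue

        try:
            ladder = select_windows(paths[0], min_increment=config.min_increment,
                                    k=config.umbrella_k,
                                    max_distance=config.ladder_max_distance)
            ladder = fill_gaps(ladder, max_gap=config.max_gap,
                               escalated_k=config.escalated_k)
            lp = replace(params, rng_seed=config.stage_seed(2, ci))
            ladder = run_ladder(topology, ladder, lp,
                                steps_per_window=config.steps_per_window)
            ch_rep["n_windows"] = len(ladder)
            ch_rep["n_inserted"] = int(ladder.inserted_flags.sum())
            hset = build_histograms(ladder, bin_width=config.wham_bin_width,
                                    temperature=config.toy.temperature)
            profile = wham_solve(hset, tolerance=config.wham_tolerance,
                                 max_iterations=config.wham_max_iterations)
            g_vis = profile.grid[profile.visited]
            bound = (float(g_vis[0]), float(g_vis[0] + 2.0))
            unbound = (float(g_vis[-1] - 2.0), float(g_vis[-1]))
            barrier = barrier_height(profile, bound, unbound)
            barriers[channel] = barrier
            ch_rep["wham_converged"] = bool(profile.converged)
            ch_rep["wham_iterations"] = int(profile.iterations)
            ch_rep["barrier_kcal_mol"] = float(barrier)
            report["stages"][f"wham_{channel}"] = "ok"
            if out is not None:
                wdir = out / f"windows_{channel}"
                efio.write_ladder_files(ladder, wdir,
                                        record_dt=params.timestep * 10)
                profile.to_tsv(out / f"pmf_{channel}.tsv")
        except Exception as exc:
            report["stages"][f"wham_{channel}"] = f"failed: {exc}"
        report["channels"][channel] = ch_rep

    # ---- verdict -------------------------------------------------------------
    if len(barriers) == 2:
        preferred = min(barriers, key=barriers.get)
        report["verdict"] = {
            "preferred_channel": preferred,
            "barrier_A_kcal_mol": float(barriers["A"]),
            "barrier_B_kcal_mol": float(barriers["B"]),
            "ordering_matches_construction": bool(
                (barriers["A"] < barriers["B"])
                == (config.toy.channel_a_barrier < config.toy.channel_b_barrier)),
        }
    else:
        report["verdict"] = {"preferred_channel": None}

    # ---- energetics -----------------------------------------------------------
    if config.run_energetics and all(c in pathways_by_channel for c in ("A", "B")):
        try:
            all_trajs = [p.trajectory for c in ("A", "B") for p in pathways_by_channel[c]]
            residues = contact_residues(all_trajs, topology, cutoff=config.contact_cutoff)
            report["energetics"] = {"n_contact_residues": len(residues)}
            for channel in ("A", "B"):
                profs = [interaction_profile(p.trajectory, topology, residues,
                                             bin_width=config.profile_bin)
                         for p in pathways_by_channel[channel]]
                if len(profs) >= 2:
                    _, mean_r, sd_r = profile_correlation(profs[0], profs[1])
                    report["energetics"][f"replica_correlation_{channel}"] = {
                        "mean": float(mean_r), "sd": float(sd_r)}
                if out is not None:
                    profs[0].to_tsv(out / f"interactions_{channel}.tsv")
            report["stages"]["energetics"] = "ok"
        except Exception as exc:
            report["stages"]["energetics"] = f"failed: {exc}"
    elif config.run_energetics:
        report["stages"]["energetics"] = "skipped: extraction failed"

    # ---- essential dynamics vs network modes ----------------------------------
    if config.run_modes and "A" in pathways_by_channel:
        try:
            concat = concatenate([p.trajectory for p in pathways_by_channel["A"]])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                qm = quasi_modes(concat, topology, n_modes=config.n_quasi_modes)
                nm = enm_normal_modes(topology, start, cutoff=config.enm_cutoff)
            nm = dataclasses.replace(
                nm, vectors=nm.vectors[:config.n_normal_modes],
                eigenvalues=nm.eigenvalues[:config.n_normal_modes])
            table = match_modes(qm, nm, start, threshold=config.match_threshold,
                                amplitude=config.amplitude)
            sig = table.significant[table.significant].index.tolist()
            report["modes"] = {
                "n_quasi_modes": int(qm.n_modes),
                "n_normal_modes": int(nm.n_modes),
                "significant_quasi_modes": [int(i) for i in sig],
                "best_matches": {int(i): {"normal_mode": int(table.best_match[i]),
                                          "mantel_r": float(table.best_r[i])}
                                 for i in table.best_r.nlargest(5).index},
            }
            report["stages"]["modes"] = "ok"
            if out is not None:
                efio.write_modes(out / "quasi_modes.txt", qm)
                efio.write_modes(out / "normal_modes.txt", nm)
                table.to_tsv(out / "mode_match.tsv")
        except Exception as exc:
            report["stages"]["modes"] = f"failed: {exc}"
    elif config.run_modes:
        report["stages"]["modes"] = "skipped: extraction failed"

    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        _write_figures(out)
    return report


def _write_figures(out: Path) -> None:
    """Regenerate figures from the data files just written."""
    from . import plots
    pmfs = sorted(out.glob("pmf_*.tsv"))
    if pmfs:
        plots.plot_pmf(pmfs, out / "pmf.png", labels=[p.stem for p in pmfs])
    for tsv in sorted(out.glob("interactions_*.tsv")):
        plots.plot_profile_heatmap(tsv, out / (tsv.stem + ".png"))
    match = out / "mode_match.tsv"
    if match.exists():
        plots.plot_match_heatmap(match, out / "mode_match.png")


# ---------------------------------------------------------------------------
# PDB adapter
# ---------------------------------------------------------------------------

_ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                   "P": 30.974, "S": 32.06, "NA": 22.990, "MG": 24.305}


def read_pdb_coordinates(path):
    """Read ATOM/HETATM records into an analysis-only topology and coordinates.

    Masses come from the element field (fallback: first letter of the atom
    name); charges and LJ parameters are zeroed, bonds empty.  HETATM records
    are flagged as ligand sites; when none are present the final residue is
    taken as the ligand group.  Multi-model files return a
    :class:`Trajectory` with one frame per MODEL; single-model files return a
    :class:`Conformation`.  Malformed records raise with their line number.
    """
    labels, masses, het, resids = [], [], [], []
    models: list = [[]]
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL" and models[-1]:
                models.append([])
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed coordinate record at line {ln}: {exc}")
            models[-1].append((x, y, z))
            if len(models) == 1:
                elem = line[76:78].strip().upper() or line[12:16].strip()[:1].upper()
                masses.append(_ELEMENT_MASSES.get(elem, 12.011))
                labels.append(line[17:21].strip() or "UNK")
                het.append(rec == "HETATM")
                try:
                    resids.append(int(line[22:26]))
                except ValueError:
                    resids.append(len(resids))
    models = [m for m in models if m]
    if not models or not models[0]:
        raise ValueError("no ATOM/HETATM records found")
    n = len(models[0])
    for mi, m in enumerate(models):
        if len(m) != n:
            raise ValueError(f"model {mi + 1} has {len(m)} atoms, expected {n}")

    ligand = np.array(het, dtype=bool)
    if not ligand.any():
        last = resids[-1]
        ligand = np.array([lab_res == last for lab_res in resids], dtype=bool)
    topology = SiteTopology(
        site_ids=np.arange(n), residue_labels=labels,
        masses=np.array(masses), charges=np.zeros(n),
        lj_epsilon=np.zeros(n), lj_sigma=np.full(n, 3.0),
        bond_pairs=np.empty((0, 2), dtype=int), bond_k=np.empty(0),
        bond_r0=np.empty(0), ligand_mask=ligand)
    frames = np.array(models, dtype=float)
    if frames.shape[0] == 1:
        return topology, Conformation(frames[0])
    return topology, Trajectory(frames=frames, times=np.arange(1.0, frames.shape[0] + 1))
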