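"""Per-residue interaction profiles and cross-pathway correlations."""

import numpy as np
import pytest

from exitpmf.dynamics import nonbonded_pair_energy
from exitpmf.energetics import (classify_profile, contact_residues,
                                interaction_profile, profile_correlation)
from exitpmf.system import Conformation, SiteTopology, Trajectory


def tiny_topology():
    """Three protein residues (one site each) plus one ligand site."""
    return SiteTopology(
        site_ids=np.arange(4), residue_labels=["R1", "R2", "R3", "LIG"],
        masses=np.full(4, 10.0), charges=np.array([0.1, -0.1, 0.0, -0.2]),
        lj_epsilon=np.full(4, 0.1), lj_sigma=np.full(4, 3.0),
        bond_pairs=np.empty((0, 2), dtype=int), bond_k=np.empty(0),
        bond_r0=np.empty(0), ligand_mask=np.array([False, False, False, True]))


def traj_with_ligand_at(xs):
    frames = np.zeros((len(xs), 4, 3))
    frames[:, 0] = [0.0, 0.0, 0.0]
    frames[:, 1] = [0.0, 5.0, 0.0]
    frames[:, 2] = [0.0, -8.0, 0.0]
    for i, x in enumerate(xs):
        frames[i, 3] = [x, 0.0, 0.0]
    return Trajectory(frames=frames, times=np.arange(1.0, len(xs) + 1),
                      rc_trace=np.asarray(xs, dtype=float))


class TestContactResidues:
    def test_four_angstrom_rule(self):
        topo = tiny_topology()
        # ligand at x=3.9 from R1 in one frame; R2 at 5.0, never nearer than 4.1
        traj = traj_with_ligand_at([3.9, 10.0])
        res = contact_residues([traj], topo, cutoff=4.0)
        assert "R1" in res
        assert "R2" not in res

    def test_empty_when_ligand_far(self):
        topo = tiny_topology()
        traj = traj_with_ligand_at([50.0, 60.0])
        assert contact_residues([traj], topo, cutoff=4.0) == []

    def test_matches_brute_force_double_loop(self, toy, channel_a_pathways):
        _, topology, _, _, _ = toy
        traj = channel_a_pathways[0].trajectory
        fast = contact_residues([traj], topology, cutoff=4.0)
        lig = topology.ligand_ids
        brute = []
        for i in topology.protein_ids:
            hit = False
            for f in range(traj.n_frames):
                for j in lig:
                    if np.linalg.norm(traj.frames[f, i] - traj.frames[f, j]) <= 4.0:
                        hit = True
            if hit and topology.residue_labels[i] not in brute:
                brute.append(topology.residue_labels[i])
        assert fast == brute


class TestInteractionProfile:
    def test_single_frame_values_exact(self):
        topo = tiny_topology()
        traj = traj_with_ligand_at([2.5])
        prof = interaction_profile(traj, topo, ["R1", "R2"], bin_width=0.02)
        conf = Conformation(traj.frames[0])
        for ri, site in [(0, 0), (1, 1)]:
            lj, coul = nonbonded_pair_energy(topo, conf, (site, 3))
            col = np.flatnonzero(np.isfinite(prof.energies[ri]))
            assert col.size == 1
            assert prof.energies[ri, col[0]] == pytest.approx(lj + coul, rel=1e-12)

    def test_matches_brute_force(self, toy, channel_a_pathways):
        _, topology, _, _, _ = toy
        traj = channel_a_pathways[0].trajectory
        # subsample frames to keep the brute-force loop cheap
        sub = Trajectory(frames=traj.frames[::40], times=traj.times[::40],
                         rc_trace=traj.rc_trace[::40])
        residues = ["A1", "B3"]
        prof = interaction_profile(sub, topology, residues, bin_width=0.02)
        res_sites = {lab: [i for i in topology.protein_ids
                           if topology.residue_labels[i] == lab] for lab in residues}
        for f in range(sub.n_frames):
            conf = Conformation(sub.frames[f])
            b = np.flatnonzero((prof.bin_edges[:-1] <= sub.rc_trace[f])
                               & (sub.rc_trace[f] < prof.bin_edges[1:]))
            if b.size != 1:
                continue
            for ri, lab in enumerate(residues):
                e = sum(sum(nonbonded_pair_energy(topology, conf, (i, j)))
                        for i in topology.ligand_ids for j in res_sites[lab])
                # bins holding a single frame must equal that frame's energy
                if prof.counts[b[0]] == 1:
                    assert prof.energies[ri, b[0]] == pytest.approx(e, rel=1e-10)

    def test_energy_conservation_per_frame(self, toy, channel_a_pathways):
        # sum over all listed residues equals the total ligand:listed-residue
        # nonbonded energy, frame by frame (tested through single-frame bins)
        _, topology, _, _, _ = toy
        traj = channel_a_pathways[0].trajectory
        one = Trajectory(frames=traj.frames[:1], times=traj.times[:1],
                         rc_trace=traj.rc_trace[:1])
        residues = [topology.residue_labels[i] for i in topology.protein_ids]
        seen = list(dict.fromkeys(residues))
        prof = interaction_profile(one, topology, seen, bin_width=0.02)
        conf = Conformation(one.frames[0])
        total = sum(sum(nonbonded_pair_energy(topology, conf, (i, j)))
                    for i in topology.ligand_ids for j in topology.protein_ids)
        col = np.flatnonzero(prof.counts > 0)[0]
        assert np.nansum(prof.energies[:, col]) == pytest.approx(total, rel=1e-10)

    def test_invariant_under_frame_reordering(self):
        topo = tiny_topology()
        xs = [2.5, 3.1, 2.8, 4.0, 3.3]
        t1 = traj_with_ligand_at(xs)
        t2 = traj_with_ligand_at(xs[::-1])
        p1 = interaction_profile(t1, topo, ["R1"])
        p2 = interaction_profile(t2, topo, ["R1"])
        assert np.array_equal(p1.bin_edges, p2.bin_edges)
        assert np.allclose(p1.energies, p2.energies, equal_nan=True)

    def test_missing_rc_trace_rejected(self):
        topo = tiny_topology()
        traj = traj_with_ligand_at([2.5])
        traj.rc_trace = None
        with pytest.raises(ValueError):
            interaction_profile(traj, topo, ["R1"])

    def test_attractive_contact_profile_shape(self, toy, channel_a_pathways):
        # a charged pocket site: negative energy while bound, → 0 when out
        _, topology, _, com_ids, _ = toy
        traj = channel_a_pathways[0].trajectory
        lab = topology.residue_labels[com_ids[0]]
        prof = interaction_profile(traj, topology, [lab])
        e = prof.energies[0]
        c = prof.bin_centers
        near = np.nanmean(e[np.isfinite(e) & (c < 2.0)])
        far = np.nanmean(e[np.isfinite(e) & (c > 10.0)])
        assert near < -0.3
        assert abs(far) < 0.15

    def test_classification_deadband(self):
        topo = tiny_topology()
        prof = interaction_profile(traj_with_ligand_at([2.5, 9.0]), topo, ["R1"])
        cls = classify_profile(prof, deadband=0.5)
        assert set(np.unique(cls)).issubset({-1, 0, 1})


class TestProfileCorrelation:
    def test_self_correlation_is_one(self, toy, channel_a_pathways):
        _, topology, _, _, _ = toy
        prof = interaction_profile(channel_a_pathways[0].trajectory, topology,
                                   ["A1", "B1"])
        per, mean, sd = profile_correlation(prof, prof)
        assert np.allclose(per.values, 1.0)
        assert mean == pytest.approx(1.0) and sd == pytest.approx(0.0, abs=1e-12)

    def test_negated_profile_anticorrelates(self, toy, channel_a_pathways):
        _, topology, _, _, _ = toy
        prof = interaction_profile(channel_a_pathways[0].trajectory, topology,
                                   ["A1"])
        import copy
        neg = copy.deepcopy(prof)
        neg.energies = -neg.energies
        per, mean, _ = profile_correlation(prof, neg)
        assert np.allclose(per.values, -1.0)

    def test_symmetry(self, toy, channel_a_pathways):
        _, topology, _, _, _ = toy
        a = interaction_profile(channel_a_pathways[0].trajectory, topology, ["A1", "A2"])
        b = interaction_profile(channel_a_pathways[1].trajectory, topology, ["A1", "A2"])
        pab, mab, _ = profile_correlation(a, b)
        pba, mba, _ = profile_correlation(b, a)
        assert np.allclose(pab.values, pba.values)
        assert mab == pytest.approx(mba)

    def test_replicas_show_conserved_interactions(self, toy, channel_a_pathways):
        # two independent extractions of the same channel share the same
        # interaction sequence: mean per-residue correlation is high
        _, topology, _, _, _ = toy
        residues = contact_residues([p.trajectory for p in channel_a_pathways],
                                    topology)
        profs = [interaction_profile(p.trajectory, topology, residues)
                 for p in channel_a_pathways]
        _, mean_r, sd_r = profile_correlation(profs[0], profs[1])
        assert mean_r > 0.8

    def test_mismatched_residues_rejected(self, toy, channel_a_pathways):
        _, topology, _, _, _ = toy
        a = interaction_profile(channel_a_pathways[0].trajectory, topology, ["A1"])
        b = interaction_profile(channel_a_pathways[0].trajectory, topology, ["A2"])
        with pytest.raises(ValueError):
            profile_correlation(a, b)
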