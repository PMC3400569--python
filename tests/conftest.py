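"""Shared fixtures: a default toy system, short steered extractions, and a
synthetic-pathway factory for window-protocol tests."""

import numpy as np
import pytest

from exitpmf.app import _channel_target, default_anchor_ids
from exitpmf.dynamics import LangevinParams
from exitpmf.pathways import ExtractionPathway, run_tmd_extraction
from exitpmf.system import Conformation, Trajectory
from exitpmf.toy_system import ToySpec, build_toy_system, pocket_site_ids


@pytest.fixture(scope="session")
def toy():
    """Default two-lobe system: (spec, topology, start, pocket ids, reporter)."""
    spec = ToySpec(rng_seed=0)
    topology, start = build_toy_system(spec)
    com_ids = pocket_site_ids(topology, start)
    return spec, topology, start, com_ids, int(topology.ligand_ids[0])


@pytest.fixture(scope="session")
def channel_a_pathways(toy):
    """Two independent channel-A extractions (different seeds)."""
    _, topology, start, com_ids, _ = toy
    target = _channel_target(topology, start, "A", 20.0)
    anchors = default_anchor_ids(com_ids)
    out = []
    for seed in (11, 12):
        out.append(run_tmd_extraction(
            topology, start, target, duration=50.0, anchors=anchors,
            params=LangevinParams(rng_seed=seed), com_site_ids=com_ids,
            rmsd_tolerance=1.0, label=f"A-{seed}"))
    return out


def synthetic_pathway(rc_values, n_sites=3, label="synthetic"):
    """ExtractionPathway with a prescribed reaction-coordinate trace and
    dummy frames (for window-selection logic tests)."""
    rc = np.asarray(rc_values, dtype=float)
    frames = np.zeros((rc.size, n_sites, 3))
    frames[:, -1, 0] = rc  # encode the coordinate so seeds are distinguishable
    traj = Trajectory(frames=frames, times=np.arange(1.0, rc.size + 1),
                      rc_trace=rc)
    return ExtractionPathway(label=label, target=Conformation(frames[-1]),
                             trajectory=traj, force_trace=np.zeros(rc.size),
                             com_site_ids=np.array([0]), reporter_site_id=n_sites - 1)


@pytest.fixture
def make_pathway():
    return synthetic_pathway
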