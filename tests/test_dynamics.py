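"""Force field, bias potentials, and the Langevin integrator."""

import numpy as np
import pytest
from scipy import integrate, stats

from exitpmf.dynamics import (LangevinParams, LinearSchedule, TMDBias,
                              UmbrellaBias, integrate_batch,
                              nonbonded_pair_energy, potential_energy_forces,
                              run_langevin, tmd_energy_forces, total_forces,
                              umbrella_energy_forces)
from exitpmf.system import (COULOMB, KB, KCAL_TO_AMU_A2_PS2, Conformation,
                            SiteTopology)
from exitpmf.toy_system import (HarmonicAxialPotential, ToySpec,
                                build_toy_system, make_axial_fixture)


def two_site_topology(q1=0.0, q2=0.0, eps=0.2, sigma=3.0):
    return SiteTopology(
        site_ids=np.arange(2), residue_labels=["R1", "LIG"],
        masses=np.array([50.0, 50.0]), charges=np.array([q1, q2]),
        lj_epsilon=np.full(2, eps), lj_sigma=np.full(2, sigma),
        bond_pairs=np.empty((0, 2), dtype=int), bond_k=np.empty(0),
        bond_r0=np.empty(0), ligand_mask=np.array([False, True]))


def conf_at(r):
    return Conformation(np.array([[0.0, 0, 0], [r, 0, 0]]))


class TestNonbonded:
    def test_lj_zero_crossing_at_sigma(self):
        topo = two_site_topology()
        lj, _ = nonbonded_pair_energy(topo, conf_at(3.0), (0, 1))
        assert lj == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_at_rmin(self):
        topo = two_site_topology(eps=0.2)
        lj, _ = nonbonded_pair_energy(topo, conf_at(2 ** (1 / 6) * 3.0), (0, 1))
        assert lj == pytest.approx(-0.2, abs=1e-12)

    def test_coulomb_constant_at_unit_separation(self):
        topo = two_site_topology(q1=1.0, q2=1.0, eps=0.0)
        _, coul = nonbonded_pair_energy(topo, conf_at(1.0), (0, 1))
        assert coul == pytest.approx(COULOMB, rel=1e-12)

    def test_degenerate_pairs_rejected(self):
        topo = two_site_topology()
        with pytest.raises(ValueError):
            nonbonded_pair_energy(topo, conf_at(1.0), (1, 1))
        with pytest.raises(ValueError):
            nonbonded_pair_energy(topo, Conformation(np.zeros((2, 3))), (0, 1))


class TestTotalForces:
    def test_energy_matches_brute_force_sum(self, toy):
        _, topology, start, _, _ = toy
        rng = np.random.default_rng(1)
        x = start.coordinates + 0.05 * rng.standard_normal(start.coordinates.shape)
        conf = Conformation(x)
        energy, _ = total_forces(topology, conf)
        # brute-force re-evaluation term by term
        e = 0.0
        for (i, j), k, r0 in zip(topology.bond_pairs, topology.bond_k,
                                 topology.bond_r0):
            e += 0.5 * k * (np.linalg.norm(x[j] - x[i]) - r0) ** 2
        for a, i in enumerate(topology.anchor_ids):
            e += 0.5 * topology.anchor_k * np.sum((x[i] - topology.anchor_ref[a]) ** 2)
        lig = topology.ligand_ids
        w = topology.masses[lig] / topology.masses[lig].sum()
        e += topology.external.energy_gradient((w[:, None] * x[lig]).sum(0))[0]
        for i in lig:
            for j in topology.protein_ids:
                lj, coul = nonbonded_pair_energy(topology, conf, (i, j))
                e += lj + coul
        assert energy == pytest.approx(e, rel=1e-10)

    @pytest.mark.parametrize("bias_kind", ["none", "umbrella", "tmd"])
    def test_forces_are_negative_gradients(self, toy, bias_kind):
        _, topology, start, com_ids, rep = toy
        rng = np.random.default_rng(7)
        x = start.coordinates + 0.05 * rng.standard_normal(start.coordinates.shape)
        biases = []
        if bias_kind == "umbrella":
            biases = [UmbrellaBias(com_site_ids=com_ids, reporter_site_id=rep,
                                   d_eq=2.0, k=10.0)]
        elif bias_kind == "tmd":
            target = Conformation(start.coordinates.copy())
            target.coordinates[rep] += np.array([0.0, 8.0, 0.0])
            biases = [TMDBias(k_per_atom=0.5,
                              steered_site_ids=np.array([rep, 0, 1]),
                              target=target, rmsd_schedule=LinearSchedule(1.0, 0.1))]
        _, forces = total_forces(topology, Conformation(x), biases, time=1.0)
        h = 1e-5
        err = 0.0
        for i in range(0, topology.n_sites, 7):
            for axis in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, axis] += h
                xm[i, axis] -= h
                ep, _ = total_forces(topology, Conformation(xp), biases, time=1.0)
                em, _ = total_forces(topology, Conformation(xm), biases, time=1.0)
                err = max(err, abs((ep - em) / (2 * h) + forces[i, axis]))
        assert err < 1e-4

    def test_isolated_spring_at_rest_has_zero_force(self):
        topo = SiteTopology(
            site_ids=np.arange(2), residue_labels=["R1", "LIG"],
            masses=np.full(2, 10.0), charges=np.zeros(2),
            lj_epsilon=np.zeros(2), lj_sigma=np.full(2, 3.0),
            bond_pairs=np.array([[0, 1]]), bond_k=np.array([5.0]),
            bond_r0=np.array([2.0]), ligand_mask=np.array([False, True]))
        energy, forces = total_forces(topo, conf_at(2.0))
        assert energy == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(forces, 0.0, atol=1e-12)


class TestTMDBias:
    def test_zero_when_on_schedule(self, toy):
        _, topology, start, _, rep = toy
        bias = TMDBias(k_per_atom=0.5, steered_site_ids=np.array([rep]),
                       target=start, rmsd_schedule=lambda t: 0.0)
        e, f = tmd_energy_forces(bias, start, 0.0)
        assert e == 0.0 and np.allclose(f, 0.0)

    def test_closed_form_energy_forty_atoms(self):
        # 40 steered atoms each displaced so RMSD exceeds the target by 1 Å
        n = 40
        rng = np.random.default_rng(0)
        ref = rng.standard_normal((n, 3)) * 5
        disp = rng.standard_normal((n, 3))
        disp *= 1.0 / np.sqrt(np.sum(disp ** 2) / n)  # RMSD exactly 1
        bias = TMDBias(k_per_atom=0.5, steered_site_ids=np.arange(n),
                       target=Conformation(ref), rmsd_schedule=lambda t: 0.0)
        e, _ = tmd_energy_forces(bias, Conformation(ref + disp), 0.0)
        assert e == pytest.approx(10.0, rel=1e-10)  # (0.5*40/2)*1²

    def test_single_site_force_magnitude(self):
        ref = np.zeros((1, 3))
        bias = TMDBias(k_per_atom=0.5, steered_site_ids=np.array([0]),
                       target=Conformation(ref), rmsd_schedule=lambda t: 0.0)
        e, f = tmd_energy_forces(bias, Conformation(np.array([[2.0, 0, 0]])), 0.0)
        assert np.linalg.norm(f[0]) == pytest.approx(0.5 * 2.0, rel=1e-12)
        assert f[0, 0] < 0  # toward the target

    def test_one_sided(self):
        ref = np.zeros((1, 3))
        bias = TMDBias(k_per_atom=0.5, steered_site_ids=np.array([0]),
                       target=Conformation(ref), rmsd_schedule=lambda t: 5.0)
        e, f = tmd_energy_forces(bias, Conformation(np.array([[2.0, 0, 0]])), 0.0)
        assert e == 0.0 and np.allclose(f, 0.0)


class TestUmbrellaBias:
    def fixture(self, toy):
        _, topology, start, com_ids, rep = toy
        return topology, start, com_ids, rep

    def test_zero_at_equilibrium_distance(self, toy):
        topology, start, com_ids, rep = self.fixture(toy)
        bias = UmbrellaBias(com_site_ids=com_ids, reporter_site_id=rep,
                            d_eq=float(bias_d := bias_distance(topology, start, com_ids, rep)),
                            k=10.0)
        e, _ = umbrella_energy_forces(bias, topology, start)
        assert e == pytest.approx(0.0, abs=1e-20)

    def test_half_k_delta_squared(self, toy):
        topology, start, com_ids, rep = self.fixture(toy)
        d = bias_distance(topology, start, com_ids, rep)
        bias = UmbrellaBias(com_site_ids=com_ids, reporter_site_id=rep,
                            d_eq=d + 1.0, k=10.0)
        e, _ = umbrella_energy_forces(bias, topology, start)
        assert e == pytest.approx(5.0, rel=1e-9)

    def test_coincident_reporter_warns_and_is_deterministic(self):
        topo = two_site_topology()
        conf = Conformation(np.zeros((2, 3)))
        bias = UmbrellaBias(com_site_ids=np.array([0]), reporter_site_id=1,
                            d_eq=1.0, k=10.0)
        with pytest.warns(RuntimeWarning):
            e, f = bias.energy_forces(topo, conf.coordinates)
        assert e == pytest.approx(5.0)
        assert f[1, 0] > 0 and f[1, 1] == 0  # pushed along +x

    def test_reporter_in_com_set_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaBias(com_site_ids=np.array([1, 2]), reporter_site_id=1,
                         d_eq=1.0, k=10.0)


def bias_distance(topology, conf, com_ids, rep):
    from exitpmf.system import pocket_com
    return float(np.linalg.norm(conf.coordinates[rep]
                                - pocket_com(conf.coordinates, topology.masses, com_ids)))


class TestIntegrator:
    def test_stationary_at_zero_temperature_zero_force(self):
        topo = two_site_topology(eps=0.0)
        start = conf_at(5.0)
        params = LangevinParams(temperature=0.0, friction=0.0, rng_seed=0)
        traj = run_langevin(topo, start, params, n_steps=100, record_every=10)
        assert np.allclose(traj.frames[-1], start.coordinates, atol=1e-14)

    def test_bitwise_deterministic_under_seed(self, toy):
        _, topology, start, com_ids, rep = toy
        bias = UmbrellaBias(com_site_ids=com_ids, reporter_site_id=rep,
                            d_eq=1.0, k=10.0)
        params = LangevinParams(rng_seed=123)
        t1 = run_langevin(topology, start, params, [bias], n_steps=500)
        t2 = run_langevin(topology, start, params, [bias], n_steps=500)
        assert np.array_equal(t1.rc_trace, t2.rc_trace)
        assert np.array_equal(t1.frames, t2.frames)

    def test_fast_and_generic_paths_agree(self, toy):
        _, topology, start, com_ids, rep = toy
        bias = UmbrellaBias(com_site_ids=com_ids, reporter_site_id=rep,
                            d_eq=2.0, k=10.0)
        params = LangevinParams(rng_seed=5)
        kw = dict(n_steps=300, record_every=10, rc_spec=(rep, com_ids))
        r_fast = integrate_batch(topology, start.coordinates, params, [bias], **kw)
        r_ref = integrate_batch(topology, start.coordinates, params, [bias],
                                use_fast_path=False, **kw)
        assert np.allclose(r_fast["rc"], r_ref["rc"], atol=1e-12)
        assert np.allclose(r_fast["coords"], r_ref["coords"], atol=1e-12)

    def test_nve_energy_conservation(self, toy):
        # friction 0: BAOAB reduces to velocity Verlet; total energy drift
        # over 1000 steps stays below 1e-4 kcal/mol
        _, topology, start, _, _ = toy
        params = LangevinParams(temperature=150.0, friction=0.0,
                                timestep=0.0002, rng_seed=3)
        res = integrate_batch(topology, start.coordinates, params, [],
                              n_steps=1000, record_every=1000)

        def total_energy(coords, vel):
            u, _ = potential_energy_forces(topology, coords[0])
            ke = 0.5 * np.sum(topology.masses[:, None] / KCAL_TO_AMU_A2_PS2
                              * vel[0] ** 2)
            return u + ke

        # reconstruct the initial state (same seed → same initial velocities)
        rng = np.random.default_rng(params.rng_seed)
        m_acc = topology.masses / KCAL_TO_AMU_A2_PS2
        v0 = rng.standard_normal((topology.n_sites, 3)) * np.sqrt(
            KB * params.temperature / m_acc)[:, None]
        e0 = total_energy(start.coordinates[None], v0[None])
        e1 = total_energy(res["coords"], res["velocities"])
        assert abs(e1 - e0) < 1e-4

    def test_equipartition_position_variance(self):
        # single reporter in an isotropic harmonic well: var(x) = kT/kappa
        kappa = 2.0
        pot = HarmonicAxialPotential(kappa=kappa, s0=6.0, k_perp=kappa)
        topo, start, com_ids, rep = make_axial_fixture(pot, start_s=6.0,
                                                       reporter_mass=20.0)
        params = LangevinParams(rng_seed=9, friction=10.0)
        res = integrate_batch(topo, start.coordinates, params, [],
                              n_steps=1_000_000, record_every=50,
                              record_frames=True)
        x = res["frames"][200:, rep, 0]
        assert np.var(x) == pytest.approx(KB * 298.0 / kappa, rel=0.05)

    def test_restrained_boltzmann_distribution(self):
        # long restrained run reproduces the analytic biased distribution
        pot = HarmonicAxialPotential(kappa=2.0, s0=9.0, k_perp=50.0)
        topo, start, com_ids, rep = make_axial_fixture(pot, start_s=9.0)
        bias = UmbrellaBias(com_site_ids=com_ids, reporter_site_id=rep,
                            d_eq=9.5, k=10.0)
        params = LangevinParams(rng_seed=4, friction=10.0)
        res = integrate_batch(topo, start.coordinates, params, [bias],
                              n_steps=250_000, record_every=5,
                              rc_spec=(rep, com_ids))
        samples = res["rc"][0, -50_000:]
        grid = np.linspace(samples.min() - 0.5, samples.max() + 0.5, 4001)
        u = pot.profile(grid) + 0.5 * 10.0 * (grid - 9.5) ** 2
        w = np.exp(-(u - u.min()) / (KB * 298.0))
        cdf = integrate.cumulative_trapezoid(w, grid, initial=0.0)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(samples), grid) / samples.size
        ks = np.max(np.abs(emp - cdf))
        assert ks < 0.05

    def test_divergence_detected(self):
        # a stiff spring integrated far beyond its stability limit blows up
        topo = SiteTopology(
            site_ids=np.arange(2), residue_labels=["R1", "LIG"],
            masses=np.full(2, 1.0), charges=np.zeros(2),
            lj_epsilon=np.zeros(2), lj_sigma=np.full(2, 3.0),
            bond_pairs=np.array([[0, 1]]), bond_k=np.array([1000.0]),
            bond_r0=np.array([2.0]), ligand_mask=np.array([False, True]))
        start = conf_at(2.5)
        params = LangevinParams(rng_seed=0, timestep=0.01, friction=0.0,
                                temperature=0.0)
        from exitpmf.dynamics import EnergyDivergence
        with pytest.raises(EnergyDivergence):
            run_langevin(topo, start, params, n_steps=2000, record_every=10,
                         energy_bound=1e6)
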