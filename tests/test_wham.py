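"""WHAM solver: exact small cases, statistical recovery from analytically
sampled windows, cross-check against a test-local MBAR estimator, barrier
extraction, Kd conversion, and bootstrap errors."""

import numpy as np
import pytest

from exitpmf.system import KB
from exitpmf.wham import (HistogramSet, barrier_height, bootstrap_error,
                          build_histograms, histograms_from_samples,
                          kd_to_free_energy, wham_solve)

T = 298.0
KT = KB * T


def gaussian_window_samples(kappa=2.0, d0=9.0, k=10.0,
                            d_eqs=None, n=2000, seed=0):
    """Exact samples from harmonically biased windows over a harmonic
    landscape: the biased density is Gaussian with known mean/variance."""
    if d_eqs is None:
        d_eqs = np.arange(3.0, 15.01, 0.5)  # 25 windows, 0.5 Å spacing
    rng = np.random.default_rng(seed)
    prec = (kappa + k) / KT
    out = []
    for d in d_eqs:
        mean = (kappa * d0 + k * d) / (kappa + k)
        out.append(rng.normal(mean, 1.0 / np.sqrt(prec), size=n))
    return out, np.asarray(d_eqs), np.full(len(d_eqs), k)


@pytest.fixture(scope="module")
def harmonic_hset():
    samples, d_eqs, ks = gaussian_window_samples(seed=3)
    return histograms_from_samples(samples, d_eqs, ks, bin_width=0.1,
                                   temperature=T)


def mbar_pmf(samples, d_eqs, ks, bin_edges):
    """Test-local MBAR estimator on the unbinned samples (independent of the
    package's histogram WHAM route): minimises the convex MBAR objective."""
    from scipy.optimize import minimize
    from scipy.special import logsumexp
    x = np.concatenate(samples)
    n_k = np.array([len(s) for s in samples])
    u = 0.5 * ks[:, None] * (x[None, :] - d_eqs[:, None]) ** 2 / KT  # (K, N)
    log_nk = np.log(n_k)

    def objective(f):
        a = log_nk[:, None] + f[:, None] - u
        lse = logsumexp(a, axis=0)
        grad_w = np.exp(a - lse[None, :])          # (K, N) responsibilities
        val = lse.sum() - np.dot(n_k, f)
        grad = grad_w.sum(axis=1) - n_k
        return val, grad

    res = minimize(objective, np.zeros(len(d_eqs)), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    f = res.x - res.x[0]
    log_w = -np.logaddexp.reduce(np.log(n_k)[:, None] + f[:, None] - u, axis=0)
    w = np.exp(log_w - log_w.max())
    idx = np.digitize(x, bin_edges) - 1
    n_bins = len(bin_edges) - 1
    p = np.zeros(n_bins)
    ok = (idx >= 0) & (idx < n_bins)
    np.add.at(p, idx[ok], w[ok])
    with np.errstate(divide="ignore"):
        fe = -KT * np.log(p)
    fe[~np.isfinite(fe)] = np.nan
    return fe - np.nanmin(fe)


class TestHistograms:
    def test_direct_counting(self):
        hs = histograms_from_samples([[5.1, 5.3]], [5.0], [10.0], bin_width=0.5)
        assert hs.counts.shape == (1, 1)
        assert hs.counts[0, 0] == 2
        assert hs.bin_edges[0] == pytest.approx(5.0)

    def test_count_conservation(self, harmonic_hset):
        assert harmonic_hset.counts.sum() == sum(len(s) for s in harmonic_hset.samples)

    def test_coverage_report_flags_removed_window(self):
        rng = np.random.default_rng(0)
        samples = [rng.normal(1.0, 0.1, 500), rng.normal(3.0, 0.1, 500)]
        with pytest.warns(RuntimeWarning, match="coverage gaps"):
            hs = histograms_from_samples(samples, [1.0, 3.0], [10.0, 10.0],
                                         bin_width=0.1)
        centers = hs.bin_centers[hs.empty_bins]
        assert np.any((centers > 1.5) & (centers < 2.5))

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError):
            histograms_from_samples([], [], [])


class TestWhamSolve:
    def test_flat_profile_from_uniform_counts(self):
        edges = np.arange(0.0, 5.01, 0.5)
        hs = HistogramSet(bin_edges=edges, counts=np.full((1, 10), 100.0),
                          window_d_eq=np.array([2.5]), window_k=np.array([1e-12]),
                          temperature=T)
        prof = wham_solve(hs)
        assert np.allclose(prof.free_energy, 0.0, atol=1e-10)

    def test_gauge_invariance_of_initial_offsets(self, harmonic_hset):
        p1 = wham_solve(harmonic_hset)
        p2 = wham_solve(harmonic_hset,
                        f_init=np.full(harmonic_hset.counts.shape[0], 7.3))
        assert np.allclose(p1.free_energy, p2.free_energy, atol=1e-5,
                           equal_nan=True)

    def test_recovers_harmonic_profile(self, harmonic_hset):
        prof = wham_solve(harmonic_hset)
        ref = 0.5 * 2.0 * (prof.grid - 9.0) ** 2
        sel = prof.visited & (prof.grid > 4.0) & (prof.grid < 14.0)
        diff = prof.free_energy[sel] - ref[sel]
        diff -= diff.mean()
        assert np.sqrt(np.mean(diff ** 2)) < 0.3

    def test_agrees_with_unbinned_mbar(self, harmonic_hset):
        prof = wham_solve(harmonic_hset)
        samples, d_eqs, ks = gaussian_window_samples(seed=3)
        fe_mbar = mbar_pmf(samples, d_eqs, ks, harmonic_hset.bin_edges)
        sel = prof.visited & np.isfinite(fe_mbar) & \
            (prof.grid > 4.0) & (prof.grid < 14.0)
        diff = prof.free_energy[sel] - fe_mbar[sel]
        diff -= diff.mean()
        assert np.max(np.abs(diff)) < 0.2

    def test_profile_stable_under_bin_halving(self):
        samples, d_eqs, ks = gaussian_window_samples(seed=5, n=20_000)
        h1 = histograms_from_samples(samples, d_eqs, ks, bin_width=0.1)
        h2 = histograms_from_samples(samples, d_eqs, ks, bin_width=0.05)
        p1 = wham_solve(h1)
        p2 = wham_solve(h2)
        # compare coarse bins against the mean of the fine bins they contain
        sel1 = np.flatnonzero(p1.visited & (p1.grid > 5.0) & (p1.grid < 13.0))
        diffs = []
        for i in sel1:
            inside = np.abs(p2.grid - p1.grid[i]) < 0.05
            if np.any(inside & p2.visited):
                diffs.append(p1.free_energy[i]
                             - np.nanmean(p2.free_energy[inside]))
        diffs = np.array(diffs)
        diffs -= diffs.mean()
        assert np.max(np.abs(diffs)) < 0.05

    def test_residual_non_increasing(self, harmonic_hset):
        prof = wham_solve(harmonic_hset)
        h = prof.residual_history
        tail = h[int(0.1 * h.size):]
        assert np.all(np.diff(tail) <= tail[:-1] * 1e-6 + 1e-15)

    def test_single_window_closed_form_at_two_temperatures(self):
        # one window: F(x) = -kT ln n(x) - w(x) + const, so doubling T
        # rescales the count term exactly as the WHAM equations dictate
        rng = np.random.default_rng(1)
        samples = [rng.normal(5.0, 0.3, 50_000)]
        for temp in (T, 2 * T):
            hs = histograms_from_samples(samples, [5.0], [10.0],
                                         bin_width=0.1, temperature=temp)
            prof = wham_solve(hs)
            kt = KB * temp
            n_b = hs.counts[0]
            w = 0.5 * 10.0 * (hs.bin_centers - 5.0) ** 2
            with np.errstate(divide="ignore"):
                ref = -kt * np.log(n_b) - w
            ref = ref - np.nanmin(ref[np.isfinite(ref)])
            sel = prof.visited & (n_b > 0)
            d = prof.free_energy[sel] - ref[sel]
            assert np.max(np.abs(d - d.mean())) < 1e-8

    def test_nonconvergence_flagged(self, harmonic_hset):
        with pytest.warns(RuntimeWarning, match="did not converge"):
            prof = wham_solve(harmonic_hset, tolerance=1e-12, max_iterations=5)
        assert not prof.converged


class TestBarrier:
    def flat_profile(self):
        from exitpmf.wham import PMFProfile
        g = np.linspace(0, 10, 101)
        return PMFProfile(grid=g, free_energy=np.zeros_like(g),
                          offsets=np.zeros(1), converged=True, iterations=1,
                          residual=0.0, temperature=T)

    def test_flat_profile_has_zero_barrier(self):
        assert barrier_height(self.flat_profile(), (0, 2), (8, 10)) == 0.0

    def test_masked_gap_refused(self):
        prof = self.flat_profile()
        prof.free_energy[40:45] = np.nan
        with pytest.raises(ValueError, match="masked bins"):
            barrier_height(prof, (0, 2), (8, 10))

    def test_empty_region_refused(self):
        with pytest.raises(ValueError):
            barrier_height(self.flat_profile(), (20, 22), (30, 32))


class TestKd:
    def test_reference_state_is_zero(self):
        assert kd_to_free_energy(1.0, 298.0) == pytest.approx(0.0, abs=1e-12)

    def test_submicromolar_kd_gives_about_ten(self):
        dg = kd_to_free_energy(0.2e-6, 298.0)
        assert dg == pytest.approx(9.13, abs=0.01)
        assert dg == pytest.approx(10.0, abs=1.0)  # the "~10 kcal/mol" scale

    def test_micromolar_at_300K(self):
        assert kd_to_free_energy(1e-6, 300.0) == pytest.approx(8.24, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kd_to_free_energy(0.0)
        with pytest.raises(ValueError):
            kd_to_free_energy(1e-6, 0.0)


class TestBootstrap:
    def test_deterministic_under_seed(self, harmonic_hset):
        e1 = bootstrap_error(harmonic_hset, n_resamples=3, seed=11)
        e2 = bootstrap_error(harmonic_hset, n_resamples=3, seed=11)
        assert np.array_equal(e1, e2, equal_nan=True)

    def test_errors_shrink_with_sample_size(self):
        d_eqs = np.arange(6.0, 12.01, 0.5)
        small, de, ks = gaussian_window_samples(d_eqs=d_eqs, n=500, seed=7)
        big, _, _ = gaussian_window_samples(d_eqs=d_eqs, n=2000, seed=7)
        hs_small = histograms_from_samples(small, de, ks, bin_width=0.1)
        hs_big = histograms_from_samples(big, de, ks, bin_width=0.1)
        e_small = bootstrap_error(hs_small, n_resamples=25, seed=1)
        e_big = bootstrap_error(hs_big, n_resamples=25, seed=2)

        def central_median(hs, err):
            sel = (hs.bin_centers > 7.0) & (hs.bin_centers < 11.0) & np.isfinite(err)
            return np.median(err[sel])

        ratio = central_median(hs_big, e_big) / central_median(hs_small, e_small)
        assert 0.5 / 1.5 < ratio < 0.5 * 1.5  # ~1/sqrt(4) scaling

    def test_flat_fixture_errors_roughly_uniform(self):
        rng = np.random.default_rng(2)
        # windows with negligible bias on a flat landscape: uniform samples
        samples = [rng.uniform(4.0, 6.0, 4000) for _ in range(3)]
        hs = histograms_from_samples(samples, [4.5, 5.0, 5.5],
                                     [1e-9, 1e-9, 1e-9], bin_width=0.2)
        err = bootstrap_error(hs, n_resamples=30, seed=3)
        ok = np.isfinite(err) & (err > 0)
        assert err[ok].max() / err[ok].min() < 2.0
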