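"""Phylogeographic engine: analytic oracles, sampler cross-checks."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from shapely.geometry import MultiPoint, Point

from phylospread.core import (FossilRecord, LocationTable, TimedTree,
                              ValidationError)
from phylospread.phylogeo import (ModelSpec, attach_fossils,
                                  branch_log_density, diagnostics,
                                  effective_sample_size, mcmc_sample,
                                  rw_loglik, rw_root_posterior)

from conftest import random_timed_tree


def dense_loglik(tree, tipnames, locs, sigma2, root_loc):
    """Oracle: joint MVN of tip locations with covariance sigma2 * shared
    path time from the (fixed) root."""
    def path(i):
        out = set()
        while i >= 0:
            out.add(i)
            i = tree.parents[i]
        return out
    name_to = tree.name_to_index()
    idx = [name_to[nm] for nm in tipnames]
    n = len(idx)
    C = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            shared = path(idx[a]) & path(idx[b])
            tmrca = max(tree.times[i] for i in shared)
            C[a, b] = sigma2 * (tmrca - tree.times[tree.root])
    xs = np.array([locs[nm] for nm in tipnames])
    total = 0.0
    for coord in range(2):
        total += multivariate_normal.logpdf(
            xs[:, coord], np.full(n, root_loc[coord]), C,
            allow_singular=True)
    return total


class TestBranchLogDensity:
    def test_standard_normal_arithmetic(self):
        # sigma2*r*t = 1, displacement (1, 0) off the drift-adjusted mean
        val = branch_log_density((0, 0), (1 + 0.5, 0), t=1.0, sigma2=1.0,
                                 rate=1.0, drift=(0.5, 0.0))
        assert val == pytest.approx(-math.log(2 * math.pi) - 0.5)

    def test_mode_at_drift_adjusted_mean(self):
        base = branch_log_density((1, 2), (1 + 3 * 0.2, 2), 3.0, 2.0,
                                  drift=(0.2, 0.0))
        for dx in (-1.0, -0.1, 0.1, 1.0):
            off = branch_log_density((1, 2), (1 + 3 * 0.2 + dx, 2), 3.0, 2.0,
                                     drift=(0.2, 0.0))
            assert off < base

    def test_zero_length_equality_constraint(self):
        assert branch_log_density((1, 1), (1, 1), 0.0, 1.0) == 0.0
        assert branch_log_density((1, 1), (2, 1), 0.0, 1.0) == -math.inf

    @pytest.mark.parametrize("seed", range(5))
    def test_sum_over_branches_equals_dense_mvn(self, seed):
        rng = np.random.default_rng(seed)
        tree, tipnames = random_timed_tree(5, rng)
        locs = LocationTable()
        for nm in tipnames:
            locs[nm] = tuple(rng.normal(0, 5, 2))
        sigma2 = float(rng.uniform(0.5, 3))
        x0 = rng.normal(0, 2, 2)
        ll = rw_loglik(tree, locs, sigma2, root_location=x0)
        assert ll == pytest.approx(dense_loglik(tree, tipnames, locs,
                                                sigma2, x0), abs=1e-8)


class TestRwRootPosterior:
    def test_single_tip(self):
        tree = TimedTree([-1, 0], [0.0, 7.0], ["r", "A"])
        tips = LocationTable()
        tips["A"] = (3.0, 4.0)
        mean, var = rw_root_posterior(tree, tips, sigma2=1.0)
        assert mean == pytest.approx([3.0, 4.0])
        assert var == pytest.approx(7.0)

    def test_symmetric_cherry(self, cherry):
        tree, tips = cherry
        mean, var = rw_root_posterior(tree, tips, sigma2=1.0)
        assert mean == pytest.approx([5.0, 0.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_gls_oracle(self, seed):
        """Pruning result equals the generalized-least-squares solution."""
        rng = np.random.default_rng(100 + seed)
        tree, tipnames = random_timed_tree(6, rng)
        locs = LocationTable()
        for nm in tipnames:
            locs[nm] = tuple(rng.normal(0, 5, 2))
        sigma2 = 1.7
        mean, var = rw_root_posterior(tree, locs, sigma2)
        # GLS: X ~ N(1 x0, C); x0_hat = (1' C^-1 1)^-1 1' C^-1 X
        def path(i):
            out = set()
            while i >= 0:
                out.add(i)
                i = tree.parents[i]
            return out
        name_to = tree.name_to_index()
        idx = [name_to[nm] for nm in tipnames]
        n = len(idx)
        C = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                shared = path(idx[a]) & path(idx[b])
                C[a, b] = sigma2 * max(tree.times[i] for i in shared)
        Ci = np.linalg.inv(C)
        ones = np.ones(n)
        denom = ones @ Ci @ ones
        xs = np.array([locs[nm] for nm in tipnames])
        for coord in range(2):
            gls = (ones @ Ci @ xs[:, coord]) / denom
            assert mean[coord] == pytest.approx(gls, abs=1e-8)
        assert var == pytest.approx(1.0 / denom, abs=1e-8)

    def test_mean_is_convex_combination_of_tips(self):
        """The RW root estimate always falls inside the tip convex hull."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            tree, tipnames = random_timed_tree(int(rng.integers(3, 10)), rng)
            locs = LocationTable()
            for nm in tipnames:
                locs[nm] = tuple(rng.normal(0, 1000, 2))
            mean, _ = rw_root_posterior(tree, locs, sigma2=1.0)
            hull = MultiPoint([locs[nm] for nm in tipnames]).convex_hull
            assert hull.buffer(1e-6).contains(Point(mean))

    def test_translation_equivariance(self, five_tip_tree):
        tree, tips = five_tip_tree
        mean, _ = rw_root_posterior(tree, tips, 1.0)
        shifted = LocationTable()
        for nm, (x, y) in tips.items():
            shifted[nm] = (x + 100.0, y - 50.0)
        mean2, _ = rw_root_posterior(tree, shifted, 1.0)
        assert mean2 == pytest.approx(mean + np.array([100.0, -50.0]))


class TestAttachFossils:
    def test_zero_fossils_unchanged(self, five_tip_tree):
        tree, _ = five_tip_tree
        aug, table = attach_fossils(tree, [])
        assert aug is tree and table == {}

    def test_mid_branch_conserves_lengths(self, five_tip_tree):
        tree, _ = five_tip_tree
        fos = [FossilRecord("a", 1.0, 5.0, 5.0)]  # branch r->a spans (0, 2)
        aug, table = attach_fossils(tree, fos)
        assert aug.n_nodes == tree.n_nodes + 1
        name_to = aug.name_to_index()
        fossil = name_to["fossil0"]
        a = name_to["a"]
        assert aug.branch_length(fossil) + aug.branch_length(a) == \
            pytest.approx(2.0)
        assert table["fossil0"] == (5.0, 5.0)

    def test_multiple_on_one_branch_ordered(self, five_tip_tree):
        tree, _ = five_tip_tree
        fos = [FossilRecord("a", 1.5, 0, 0), FossilRecord("a", 0.5, 1, 1)]
        aug, _ = attach_fossils(tree, fos)
        name_to = aug.name_to_index()
        t0 = aug.times[name_to["fossil0"]]
        t1 = aug.times[name_to["fossil1"]]
        assert {t0, t1} == {0.5, 1.5}
        assert aug.times[aug.parents[name_to["a"]]] == 1.5

    def test_outside_interval_errors(self, five_tip_tree):
        tree, _ = five_tip_tree
        with pytest.raises(ValidationError, match="outside"):
            attach_fossils(tree, [FossilRecord("a", 2.5, 0, 0)])

    def test_unknown_branch_errors(self, five_tip_tree):
        tree, _ = five_tip_tree
        with pytest.raises(ValidationError, match="not in tree"):
            attach_fossils(tree, [FossilRecord("zz", 1.0, 0, 0)])


class TestMcmc:
    def test_rw_on_cherry_matches_analytic(self, cherry):
        tree, tips = cherry
        spec = ModelSpec(kind="rw", iterations=8000, burn_in=0.25,
                         thinning=2)
        s = mcmc_sample(tree, tips, spec, seed=1)
        obs = np.array(list(tips.values()))
        c = obs.mean(0)
        bb = max(float(np.linalg.norm(obs.max(0) - obs.min(0))), 1.0)
        mean, _ = rw_root_posterior(tree, tips, 1.0,
                                    root_prior=(c, (10 * bb) ** 2))
        ess = min(effective_sample_size(s.root[:, 0]),
                  effective_sample_size(s.root[:, 1]))
        mc_se = s.root.std(axis=0) / math.sqrt(ess)
        assert np.all(np.abs(s.root.mean(axis=0) - mean) < 3 * mc_se)

    def test_posterior_root_mean_inside_hull(self, five_tip_tree):
        tree, tips = five_tip_tree
        spec = ModelSpec(kind="rrw", iterations=4000, burn_in=0.25,
                         thinning=2)
        s = mcmc_sample(tree, tips, spec, seed=2)
        hull = MultiPoint(list(tips.values())).convex_hull
        assert hull.buffer(0.5).contains(Point(s.root.mean(axis=0)))

    def test_reproducible_under_seed(self, five_tip_tree):
        tree, tips = five_tip_tree
        spec = ModelSpec(kind="cdrw", iterations=600, burn_in=0.2,
                         thinning=2)
        a = mcmc_sample(tree, tips, spec, seed=3)
        b = mcmc_sample(tree, tips, spec, seed=3)
        assert np.array_equal(a.root, b.root)
        assert np.array_equal(a.drift, b.drift)

    def test_cdrw_with_tight_drift_prior_collapses_to_rrw(self, five_tip_tree):
        """A drift prior pinned at zero reproduces the drift-free model."""
        tree, tips = five_tip_tree
        base = ModelSpec(kind="rrw", iterations=8000, burn_in=0.25,
                         thinning=2)
        tight = ModelSpec(kind="cdrw", iterations=8000, burn_in=0.25,
                          thinning=2, drift_prior_sd=1e-9)
        s1 = mcmc_sample(tree, tips, base, seed=4)
        s2 = mcmc_sample(tree, tips, tight, seed=5)
        assert np.all(np.abs(s2.drift) < 1e-6)
        ess = min(effective_sample_size(s1.root[:, 0]),
                  effective_sample_size(s2.root[:, 0]))
        se = (s1.root.std(axis=0) + s2.root.std(axis=0)) / math.sqrt(ess)
        assert np.all(np.abs(s1.root.mean(0) - s2.root.mean(0)) < 3 * se)

    def test_fossil_at_true_root_shrinks_error(self):
        """A fossil at the homeland pins the reconstruction to it."""
        from phylospread.migsim import MigSimParams, simulate_migration
        from phylospread.evalmetrics import rmse
        from conftest import collect_migsim_runs
        r = collect_migsim_runs(1, MigSimParams(mu=(4000.0, 0.0)),
                                keep_trajectories=True, start_seed=20)[0]
        # place a pseudo-fossil on the founder's first segment, near t=0
        founder = r.lineages[0]
        step = founder.birth_step + 1
        loc = founder.location_at(step)
        nm = {"split": "n", "dead": "X", "alive": "L"}[founder.fate]
        fos = [FossilRecord(f"{nm}{founder.id}", float(step),
                            float(loc[0]), float(loc[1]))]
        spec = ModelSpec(kind="rrw", iterations=3000, burn_in=0.3,
                         thinning=2)
        plain = mcmc_sample(r.tree, r.tip_locations, spec, seed=6)
        pinned = mcmc_sample(r.tree, r.tip_locations, spec, fossils=fos,
                             seed=6)
        assert rmse(pinned.root, r.root_location) < \
            0.5 * rmse(plain.root, r.root_location)


class TestDiagnostics:
    def test_iid_draws_ess_near_n(self):
        rng = np.random.default_rng(0)
        n = 4000
        ess = effective_sample_size(rng.standard_normal(n))
        assert 0.8 * n < ess <= n

    def test_constant_chain_flagged(self):
        from phylospread.phylogeo import PosteriorSamples
        s = PosteriorSamples(root=np.ones((50, 2)), sigma2=np.ones(50),
                             model="rw")
        d = diagnostics(s)
        assert "root_x" in d["flagged"]

    def test_ar1_oracle(self):
        """ESS within 20% of n(1-phi)/(1+phi) for an AR(1) chain."""
        rng = np.random.default_rng(1)
        phi = 0.7
        n = 40_000
        z = np.empty(n)
        z[0] = 0.0
        eps = rng.standard_normal(n)
        for t in range(1, n):
            z[t] = phi * z[t - 1] + eps[t]
        expected = n * (1 - phi) / (1 + phi)
        ours = effective_sample_size(z)
        assert ours == pytest.approx(expected, rel=0.2)
        # independent cross-check against the reference MCMC toolkit
        import arviz as az
        assert ours == pytest.approx(float(az.ess(z)), rel=0.2)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.array([1.0]))
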