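"""Descriptive tree statistics: imbalance, overlap, dependence."""

import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from phylospread.core import LocationTable, TimedTree
from phylospread.expsim import ExpSimParams, simulate_expansion
from phylospread.treestats import (clade_overlap, compute_stats,
                                   diversity_space_dependence,
                                   tree_imbalance)


def caterpillar(n_tips: int) -> TimedTree:
    """Fully pectinate tree: each spine node bears one tip, last bears two."""
    parents, times, names = [-1], [0.0], ["i0"]
    spine = 0
    for k in range(1, n_tips - 1):
        parents.append(spine)
        times.append(float(n_tips))
        names.append(f"T{k}")
        parents.append(spine)
        times.append(float(k))
        names.append(f"i{k}")
        spine = len(parents) - 1
    for nm in (f"T{n_tips - 1}", f"T{n_tips}"):
        parents.append(spine)
        times.append(float(n_tips))
        names.append(nm)
    return TimedTree(parents, times, names)


def comb_of_clades(sizes, present=20.0):
    """Balanced clades of the given tip counts hanging off a spine.

    Returns (tree, clade_membership) where clade_membership maps each tip
    name to its clade index.
    """
    parents, times, names = [-1], [0.0], ["s0"]
    membership = {}

    def build_balanced(parent, n, t0):
        if n == 1:
            nm = f"T{len(parents)}"
            parents.append(parent)
            times.append(present)
            names.append(nm)
            return [nm]
        node = len(parents)
        parents.append(parent)
        times.append(t0)
        names.append(f"b{node}")
        out = []
        for half in (n // 2, n - n // 2):
            out.extend(build_balanced(node, half, t0 + 1.0))
        return out

    spine = 0
    for k, size in enumerate(sizes):
        t_attach = float(k + 1)
        for nm in build_balanced(spine, size, t_attach + 1.0):
            membership[nm] = k
        if k < len(sizes) - 1:
            parents.append(spine)
            times.append(t_attach)
            names.append(f"s{k + 1}")
            spine = len(parents) - 1
        else:
            # last clade shares the deepest spine node with the previous one
            pass
    return TimedTree(parents, times, names), membership


def balanced(depth: int) -> TimedTree:
    """Fully balanced binary tree with 2**depth tips."""
    parents, times, names = [-1], [0.0], ["i0"]
    level = [0]
    for d in range(1, depth + 1):
        nxt = []
        for p in level:
            for _ in range(2):
                parents.append(p)
                times.append(float(d))
                names.append(f"n{len(parents) - 1}")
                nxt.append(len(parents) - 1)
        level = nxt
    return TimedTree(parents, times, names)


class TestImbalance:
    def test_balanced_tree_is_zero(self):
        assert tree_imbalance(balanced(3)) == pytest.approx(0.0)

    def test_caterpillar_near_one(self):
        # every split is (1, S-1): the raw index is 1 at every node and the
        # even-S correction pulls the mean only slightly below 1
        assert tree_imbalance(caterpillar(9)) > 0.9
        assert tree_imbalance(caterpillar(16)) > 0.9

    def test_small_tree_undefined(self):
        tree = TimedTree([-1, 0, 0], [0, 1, 1], ["r", "A", "B"])
        assert tree_imbalance(tree) is None

    def test_extinct_tips_excluded(self):
        # 5 tips, one extinct: imbalance computed on the 4 extant
        tree = TimedTree([-1, 0, 0, 1, 1, 2, 2, 3, 3],
                         [0, 1, 1, 2, 2, 3, 3, 3, 3],
                         list("rabcdefgh"),
                         [False] * 8 + [True])
        assert tree_imbalance(tree) is not None


class TestOverlap:
    def _tree_two_clades(self):
        # root -> two clades of 3 tips each
        parents = [-1, 0, 0, 1, 1, 3, 3, 2, 2, 7, 7]
        times = [0, 1, 1, 2, 3, 3, 3, 2, 3, 3, 3]
        names = ["r", "a", "b", "a1", "A3", "A1", "A2", "b1", "B3",
                 "B1", "B2"]
        return TimedTree(parents, times, names)

    def test_disjoint_half_planes(self):
        tree = self._tree_two_clades()
        tips = LocationTable()
        for nm, xy in [("A1", (0, 0)), ("A2", (1, 2)), ("A3", (0.5, -1)),
                       ("B1", (10, 0)), ("B2", (11, 2)), ("B3", (10.5, -1))]:
            tips[nm] = xy
        assert clade_overlap(tree, tips) == pytest.approx(0.0)

    def test_identical_locations(self):
        tree = self._tree_two_clades()
        tips = LocationTable()
        for nm, xy in [("A1", (0, 0)), ("A2", (1, 2)), ("A3", (0.5, -1)),
                       ("B1", (0, 0)), ("B2", (1, 2)), ("B3", (0.5, -1))]:
            tips[nm] = xy
        assert clade_overlap(tree, tips) == pytest.approx(1.0)

    def test_no_qualifying_node_undefined(self, cherry):
        tree, tips = cherry
        assert clade_overlap(tree, tips) is None

    def test_collinear_hull_skipped(self):
        tree = self._tree_two_clades()
        tips = LocationTable()
        # clade A collinear (zero-area hull) -> only... no other node
        for nm, xy in [("A1", (0, 0)), ("A2", (1, 0)), ("A3", (2, 0)),
                       ("B1", (0, 1)), ("B2", (1, 2)), ("B3", (0.5, 3))]:
            tips[nm] = xy
        assert clade_overlap(tree, tips) is None


class TestDependence:
    def test_identical_sister_sizes_undefined(self):
        tree = balanced(3)
        rng = np.random.default_rng(0)
        tips = LocationTable()
        for i in tree.tips:
            tips[tree.names[i]] = tuple(rng.normal(0, 1, 2))
        assert diversity_space_dependence(tree, tips) is None

    def test_proportional_scaling_gives_strong_positive(self):
        """Bigger clades given much wider scatter score strongly positive."""
        rng = np.random.default_rng(1)
        tree, membership = comb_of_clades([2, 4, 8, 16, 32])
        tips = LocationTable()
        for nm, clade in membership.items():
            scale = 4.0 ** clade  # scatter grows steeply with clade size
            tips[nm] = tuple(rng.normal(0, scale, 2))
        val = diversity_space_dependence(tree, tips)
        assert val is not None and val > 0.5

    def test_range_bounds(self, migsim_batch_small):
        for r in migsim_batch_small[:10]:
            v = diversity_space_dependence(r.tree.prune_to_extant(),
                                           r.tip_locations)
            if v is not None:
                assert -1.0 <= v <= 1.0


class TestInvariance:
    def _rigid(self, tips, angle=0.7, shift=(123.0, -45.0)):
        out = LocationTable()
        c, s = math.cos(angle), math.sin(angle)
        for nm, (x, y) in tips.items():
            out[nm] = (c * x - s * y + shift[0], s * x + c * y + shift[1])
        return out

    def test_rigid_motion_invariance(self, migsim_batch_small):
        r = migsim_batch_small[0]
        tree = r.tree.prune_to_extant()
        tips = r.tip_locations
        a = compute_stats(tree, tips)
        b = compute_stats(tree, self._rigid(tips))
        assert a.tree_imbalance == pytest.approx(b.tree_imbalance)
        assert a.clade_overlap == pytest.approx(b.clade_overlap, abs=1e-9)
        assert a.diversity_space_dependence == pytest.approx(
            b.diversity_space_dependence, abs=1e-9)

    def test_relabeling_invariance(self, migsim_batch_small):
        r = migsim_batch_small[1]
        tree = r.tree.prune_to_extant()
        tips = r.tip_locations
        a = compute_stats(tree, tips)
        new_names = [f"z{k}" for k in range(tree.n_nodes)]
        tree2 = TimedTree(tree.parents, tree.times, new_names, tree.extinct)
        tips2 = LocationTable()
        for k, nm in enumerate(tree.names):
            if nm in tips:
                tips2[new_names[k]] = tips[nm]
        b = compute_stats(tree2, tips2)
        assert a.tree_imbalance == pytest.approx(b.tree_imbalance)
        assert a.clade_overlap == pytest.approx(b.clade_overlap)
        assert a.diversity_space_dependence == pytest.approx(
            b.diversity_space_dependence)


class TestScenarioSeparation:
    def test_expansion_vs_migration_signature(self, migsim_batch_small):
        """Expansions: higher imbalance, lower overlap (rank-sum, a=0.01)."""
        mig = migsim_batch_small[:10]
        mig_imb = [tree_imbalance(r.tree.prune_to_extant()) for r in mig]
        mig_ov = [clade_overlap(r.tree.prune_to_extant(), r.tip_locations)
                  for r in mig]
        exp_imb, exp_ov = [], []
        k = 0
        seed = 0
        while k < 10:
            seed += 1
            e = simulate_expansion(
                ExpSimParams(steps=2500, alpha=(0.4 + 0.2 * (seed % 5))
                             * math.pi), seed=seed)
            if e.n_extant < 10:
                continue
            imb = tree_imbalance(e.tree)
            ov = clade_overlap(e.tree, e.tip_locations)
            if imb is None or ov is None:
                continue
            exp_imb.append(imb)
            exp_ov.append(ov)
            k += 1
        assert mannwhitneyu(exp_imb, mig_imb,
                            alternative="greater").pvalue < 0.01
        assert mannwhitneyu(exp_ov, mig_ov,
                            alternative="less").pvalue < 0.01
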