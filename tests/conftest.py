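"""Shared fixtures: fixed small trees and cached simulator batches."""

import math

import numpy as np
import pytest

from phylospread.core import LocationTable, TimedTree
from phylospread.migsim import MigSimParams, is_outlier, simulate_migration


@pytest.fixture
def cherry():
    """Root with a symmetric two-tip cherry at time 1."""
    tree = TimedTree([-1, 0, 0], [0.0, 1.0, 1.0], ["r", "A", "B"])
    tips = LocationTable()
    tips["A"] = (0.0, 0.0)
    tips["B"] = (10.0, 0.0)
    return tree, tips


@pytest.fixture
def five_tip_tree():
    tree = TimedTree([-1, 0, 0, 1, 1, 2, 2],
                     [0.0, 2.0, 3.0, 5.0, 5.0, 5.0, 5.0],
                     ["r", "a", "b", "A", "B", "C", "D"])
    tips = LocationTable()
    for nm, xy in zip("ABCD", [(0, 0), (10, 2), (4, -3), (8, 8)]):
        tips[nm] = xy
    return tree, tips


def random_timed_tree(n_tips: int, rng: np.random.Generator,
                      present: float = 10.0) -> tuple[TimedTree, list[str]]:
    """Random ultrametric binary tree by sequential pairwise joins."""
    times = {i: present for i in range(n_tips)}
    parents: dict[int, int] = {}
    active = list(range(n_tips))
    next_id = n_tips
    depth = present
    while len(active) > 1:
        depth -= rng.uniform(0.5, 2.0)
        a = active.pop(int(rng.integers(len(active))))
        b = active.pop(int(rng.integers(len(active))))
        times[next_id] = depth
        parents[a] = next_id
        parents[b] = next_id
        active.append(next_id)
        next_id += 1
    root = active[0]
    shift = -times[root]
    ids = sorted(times)
    idx = {nid: k for k, nid in enumerate(ids)}
    par = [idx[parents[nid]] if nid in parents else -1 for nid in ids]
    tm = [times[nid] + shift for nid in ids]
    nm = [f"T{nid}" if nid < n_tips else f"I{nid}" for nid in ids]
    return TimedTree(par, tm, nm), [f"T{i}" for i in range(n_tips)]


def collect_migsim_runs(n_runs: int, params: MigSimParams | None = None,
                        start_seed: int = 1, keep_trajectories: bool = False,
                        max_seeds: int = 10_000):
    """Non-outlier migration runs (outliers and extinctions skipped)."""
    params = params or MigSimParams()
    runs = []
    seed = start_seed
    while len(runs) < n_runs and seed < start_seed + max_seeds:
        r = simulate_migration(params, seed=seed,
                               keep_trajectories=keep_trajectories)
        seed += 1
        if r.tree is None or is_outlier(r):
            continue
        runs.append(r)
    return runs


@pytest.fixture(scope="session")
def migsim_batch_small():
    """20 non-outlier default-parameter migration runs (session cache)."""
    return collect_migsim_runs(20)
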