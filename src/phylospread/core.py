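"""Shared domain types and file formats.

The objects here are the currency of the whole package: a rooted,
time-calibrated binary tree (:class:`TimedTree`), planar node locations in
kilometres (:class:`LocationTable`), historical samples along branches
(:class:`FossilRecord`) and run configuration (:class:`RunConfig`).

Time convention: the process starts at time 0 and runs forward, so a child's
time is strictly greater than its parent's and all extant tips share the same
time ``T``.  Branch lengths are in years.  Coordinates are planar, in km,
with no map projection.  Newick parsing and writing is delegated to dendropy;
per-node locations travel as BEAST-style bracketed comments ``[&x=…,y=…]``.
"""

from __future__ import annotations

import configparser
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger("phylospread")

#: Tolerance (years) when deciding whether a tip is extant (at time T).
EXTANT_TIME_TOL = 1e-6


class ValidationError(ValueError):
    """A tree or table violates a structural invariant."""


class ParseError(ValueError):
    """Malformed input text (Newick, TSV or config)."""


# ---------------------------------------------------------------------------
# TimedTree
# ---------------------------------------------------------------------------

class TimedTree:
    """Rooted binary tree with absolute node times in years.

    Nodes are stored in arrays indexed 0..n-1.  ``parents[i]`` is the parent
    index (-1 for the root), ``times[i]`` the absolute time of node ``i``
    (root at 0 by convention), ``names[i]`` a unique node name (taxon label
    for tips).  ``extinct[i]`` marks tips that died before the present.

    The root may have a single child (the stem of the first split); all other
    internal nodes are binary.  Degree-2 nodes elsewhere only appear after
    explicit fossil augmentation (see :func:`phylospread.phylogeo.attach_fossils`).
    """

    def __init__(self, parents: Sequence[int], times: Sequence[float],
                 names: Sequence[str] | None = None,
                 extinct: Sequence[bool] | None = None):
        self.parents = np.asarray(parents, dtype=np.int64)
        self.times = np.asarray(times, dtype=float)
        n = len(self.parents)
        if len(self.times) != n:
            raise ValidationError("parents and times length mismatch")
        if names is None:
            names = [f"nd{i}" for i in range(n)]
        if len(names) != n or len(set(names)) != n:
            raise ValidationError("node names must be unique and cover all nodes")
        self.names = list(names)
        if extinct is None:
            extinct = [False] * n
        self.extinct = np.asarray(extinct, dtype=bool)
        roots = np.flatnonzero(self.parents < 0)
        if len(roots) != 1:
            raise ValidationError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self._children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parents):
            if p >= 0:
                self._children[p].append(i)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parents)

    def children(self, i: int) -> list[int]:
        return self._children[i]

    def is_tip(self, i: int) -> bool:
        return not self._children[i]

    @property
    def tips(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if self.is_tip(i)])

    @property
    def n_tips(self) -> int:
        return int(sum(1 for i in range(self.n_nodes) if self.is_tip(i)))

    @property
    def T(self) -> float:
        """Present time = maximum tip time."""
        return float(self.times[self.tips].max())

    def extant_tips(self) -> np.ndarray:
        return np.array([i for i in self.tips if not self.extinct[i]],
                        dtype=np.int64)

    def branch_length(self, i: int) -> float:
        p = self.parents[i]
        return float(self.times[i] - self.times[p]) if p >= 0 else 0.0

    def name_to_index(self) -> dict[str, int]:
        return {nm: i for i, nm in enumerate(self.names)}

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self._children[i]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    def depths(self) -> np.ndarray:
        """Number of edges from the root to each node."""
        d = np.zeros(self.n_nodes, dtype=np.int64)
        for i in self.preorder():
            p = self.parents[i]
            if p >= 0:
                d[i] = d[p] + 1
        return d

    def clade_tips(self) -> list[list[int]]:
        """Tip indices under each node (including the node itself for tips)."""
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in self.postorder():
            if self.is_tip(i):
                out[i].append(i)
            else:
                for c in self._children[i]:
                    out[i].extend(out[c])
        return out

    # -- derived trees -----------------------------------------------------
    def prune_to_extant(self) -> "TimedTree":
        """Subtree spanning the extant tips.

        Extinct lineages are removed and the resulting unary nodes are
        suppressed (their branches merged), except for the root, which is
        retained at time 0 even if it ends up with a single child.
        """
        extant = set(self.extant_tips().tolist())
        if not extant:
            raise ValidationError("tree has no extant tips")
        keep = set(extant)
        for i in self.postorder():
            if not self.is_tip(i) and any(c in keep for c in self._children[i]):
                keep.add(i)
        # suppress unary kept nodes (single kept child), except the root
        order = [i for i in self.preorder() if i in keep]
        suppressed = set()
        for i in order:
            if i == self.root:
                continue
            kept_children = [c for c in self._children[i] if c in keep]
            if not self.is_tip(i) and len(kept_children) == 1:
                suppressed.add(i)
        final = list(dict.fromkeys([self.root] + [i for i in order
                                                  if i not in suppressed]))
        remap = {old: new for new, old in enumerate(final)}
        parents, times, names, extinct = [], [], [], []
        for old in final:
            if old == self.root:
                parents.append(-1)
            else:
                p = self.parents[old]
                while p in suppressed:
                    p = self.parents[p]
                parents.append(remap[p])
            times.append(self.times[old])
            names.append(self.names[old])
            extinct.append(bool(self.extinct[old]))
        return TimedTree(parents, times, names, extinct)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"TimedTree(n_nodes={self.n_nodes}, n_tips={self.n_tips}, "
                f"T={self.T:.6g})")


# ---------------------------------------------------------------------------
# LocationTable
# ---------------------------------------------------------------------------

class LocationTable(dict):
    """Mapping node/taxon name -> planar (x, y) in km."""

    def __setitem__(self, key: str, value) -> None:
        xy = np.asarray(value, dtype=float)
        if xy.shape != (2,) or not np.all(np.isfinite(xy)):
            raise ValidationError(f"location for {key!r} must be a finite"
                                  " (x, y) pair")
        super().__setitem__(key, (float(xy[0]), float(xy[1])))

    def array_for(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self[nm] for nm in names], dtype=float)

    def to_tsv(self) -> str:
        lines = ["taxon\tx_km\ty_km"]
        for nm, (x, y) in self.items():
            lines.append(f"{nm}\t{x:.6f}\t{y:.6f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "LocationTable":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or lines[0].split("\t")[:3] != ["taxon", "x_km", "y_km"]:
            raise ParseError("locations TSV must start with header"
                             " 'taxon\\tx_km\\ty_km'")
        table = cls()
        for k, ln in enumerate(lines[1:], start=2):
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ParseError(f"locations TSV line {k}: expected 3 columns")
            try:
                table[parts[0]] = (float(parts[1]), float(parts[2]))
            except ValueError as e:
                raise ParseError(f"locations TSV line {k}: {e}") from e
        return table


# ---------------------------------------------------------------------------
# FossilRecord
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FossilRecord:
    """A known historical location of one lineage.

    ``branch`` names the tree node *below* the branch the fossil sits on;
    ``time_yr`` is the absolute time of the observation, which must lie within
    that branch's time interval.
    """
    branch: str
    time_yr: float
    x_km: float
    y_km: float

    @property
    def location(self) -> tuple[float, float]:
        return (self.x_km, self.y_km)


def fossils_to_tsv(fossils: Sequence[FossilRecord]) -> str:
    lines = ["taxon\tx_km\ty_km\ttime_yr\tbranch"]
    for k, f in enumerate(fossils):
        lines.append(f"fossil{k}\t{f.x_km:.6f}\t{f.y_km:.6f}"
                     f"\t{f.time_yr:.6f}\t{f.branch}")
    return "\n".join(lines) + "\n"


def fossils_from_tsv(text: str) -> list[FossilRecord]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = ["taxon", "x_km", "y_km", "time_yr", "branch"]
    if not lines or lines[0].split("\t") != header:
        raise ParseError("fossils TSV must start with header "
                         + "\\t".join(header))
    out = []
    for k, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != 5:
            raise ParseError(f"fossils TSV line {k}: expected 5 columns")
        try:
            out.append(FossilRecord(branch=parts[4], time_yr=float(parts[3]),
                                    x_km=float(parts[1]), y_km=float(parts[2])))
        except ValueError as e:
            raise ParseError(f"fossils TSV line {k}: {e}") from e
    return out


# ---------------------------------------------------------------------------
# Newick IO (via dendropy)
# ---------------------------------------------------------------------------

def read_newick(text: str, expect_ultrametric: bool = False
                ) -> tuple[TimedTree, LocationTable | None]:
    """Parse a Newick string into a :class:`TimedTree`.

    Node times are reconstructed from branch lengths with the root at time 0.
    Bracketed ``[&x=…,y=…]`` comments, if present on every node, are returned
    as a :class:`LocationTable` keyed by node name.  Tips strictly older than
    the latest tip are flagged extinct; with ``expect_ultrametric=True`` such
    tips raise :class:`ValidationError` instead.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  extract_comment_metadata=True,
                                  suppress_internal_node_taxa=True)
    except Exception as e:  # dendropy raises schema-specific subclasses
        raise ParseError(str(e)) from e

    nodes = list(dtree.preorder_node_iter())
    if not nodes or all(nd.is_leaf() and nd.taxon is None for nd in nodes):
        raise ParseError("empty tree")
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parents, times, names, locs = [], [], [], {}
    auto = 0
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is None:
            parents.append(-1)
            times.append(0.0)
        else:
            bl = nd.edge.length
            if bl is None:
                raise ParseError(f"missing branch length above node {i}")
            if bl < 0:
                raise ValidationError(f"negative branch length {bl} above"
                                      f" node {i}")
            parents.append(index[id(nd.parent_node)])
            times.append(times[parents[-1]] + float(bl))
        if nd.taxon is not None:
            names.append(str(nd.taxon.label))
        elif nd.label:
            names.append(str(nd.label))
        else:
            names.append(f"nd{auto}")
            auto += 1
        ann = {a.name: a.value for a in nd.annotations}
        if "x" in ann and "y" in ann:
            locs[names[-1]] = (float(ann["x"]), float(ann["y"]))
    tip_idx = [i for i, nd in enumerate(nodes) if nd.is_leaf()]
    tmax = max(times[i] for i in tip_idx)
    extinct = [False] * len(nodes)
    for i in tip_idx:
        if times[i] < tmax - EXTANT_TIME_TOL:
            if expect_ultrametric:
                raise ValidationError(
                    f"tip {names[i]!r} at time {times[i]:.6g} but present is"
                    f" {tmax:.6g}: extant tips must share the same time")
            extinct[i] = True
    tree = TimedTree(parents, times, names, extinct)
    if locs:
        table = LocationTable()
        for nm, xy in locs.items():
            table[nm] = xy
        return tree, table
    return tree, None


def write_newick(tree: TimedTree, locations: LocationTable | None = None,
                 internal_labels: bool = False) -> str:
    """Serialize a tree (and optional per-node locations) to Newick."""
    if tree.n_nodes == 0:
        raise ValidationError("cannot write an empty tree")
    taxa = dendropy.TaxonNamespace()
    dnodes = [dendropy.Node() for _ in range(tree.n_nodes)]
    for i in range(tree.n_nodes):
        nd = dnodes[i]
        if tree.is_tip(i):
            nd.taxon = taxa.new_taxon(tree.names[i])
        elif internal_labels:
            nd.label = tree.names[i]
        p = tree.parents[i]
        if p >= 0:
            dnodes[p].add_child(nd)
            nd.edge.length = tree.branch_length(i)
        if locations is not None and tree.names[i] in locations:
            x, y = locations[tree.names[i]]
            nd.annotations.add_new("x", f"{x:.6f}")
            nd.annotations.add_new("y", f"{y:.6f}")
    dtree = dendropy.Tree(taxon_namespace=taxa, seed_node=dnodes[tree.root])
    s = dtree.as_string(schema="newick", suppress_annotations=False,
                        suppress_rooting=True,
                        unquoted_underscores=True)
    return s.strip() + "\n"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(tree: TimedTree) -> list[str]:
    """Check TimedTree invariants; return human-readable violations.

    An empty list means the tree is valid.  The root may be unary (stem of
    the first split); every other internal node must be binary.
    """
    issues: list[str] = []
    for i in range(tree.n_nodes):
        p = tree.parents[i]
        if p >= 0 and tree.times[i] <= tree.times[p]:
            issues.append(f"node {tree.names[i]!r} (t={tree.times[i]:.6g}) is"
                          f" not strictly later than its parent"
                          f" (t={tree.times[p]:.6g})")
        nc = len(tree.children(i))
        if nc > 2:
            issues.append(f"node {tree.names[i]!r} is multifurcating"
                          f" ({nc} children)")
        if nc == 1 and i != tree.root:
            issues.append(f"non-root node {tree.names[i]!r} is unary")
    tmax = tree.T
    for i in tree.tips:
        if not tree.extinct[i] and tree.times[i] < tmax - EXTANT_TIME_TOL:
            issues.append(f"extant tip {tree.names[i]!r} not at present time"
                          f" {tmax:.6g}")
    return issues


def check_locations_cover(tree: TimedTree, locations: Mapping[str, tuple]
                          ) -> None:
    missing = [tree.names[i] for i in tree.extant_tips()
               if tree.names[i] not in locations]
    if missing:
        raise ValidationError(f"locations missing for extant tips: "
                              f"{missing[:5]}{'…' if len(missing) > 5 else ''}")


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat run configuration; round-trips through INI-style text."""
    scenario: str = "mig"
    model: str = "rrw"
    seed: int = 0
    scenario_params: dict[str, float] = field(default_factory=dict)
    chain: dict[str, float] = field(default_factory=dict)

    def to_text(self) -> str:
        cp = configparser.ConfigParser()
        cp["run"] = {"scenario": self.scenario, "model": self.model,
                     "seed": str(self.seed)}
        cp["scenario"] = {k: repr(v) for k, v in self.scenario_params.items()}
        cp["chain"] = {k: repr(v) for k, v in self.chain.items()}
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        cp = configparser.ConfigParser()
        try:
            cp.read_string(text)
        except configparser.Error as e:
            raise ParseError(str(e)) from e
        if "run" not in cp or "seed" not in cp["run"]:
            raise ParseError("config must contain [run] with a seed")
        def load(section):
            out = {}
            for k, v in cp[section].items():
                f = float(v)
                out[k] = int(f) if f == int(f) else f
            return out
        return cls(scenario=cp["run"].get("scenario", "mig"),
                   model=cp["run"].get("model", "rrw"),
                   seed=int(cp["run"]["seed"]),
                   scenario_params=load("scenario") if "scenario" in cp else {},
                   chain=load("chain") if "chain" in cp else {})
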