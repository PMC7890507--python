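"""Constrained grid-growth expansion simulator.

Languages are contiguous areas of cells on an integer grid (one cell is
100 x 100 km).  A founder of one cell sits at the apex of a circular sector
of angle ``alpha``; growth is only allowed inside the sector.  Per step,
every language attempts, with probability ``p_grow`` (drawn once per
language from U[0, 1]), to claim one uniformly chosen neighbouring cell.
When a language reaches its split size (drawn per language from
U{70..100} cells) it immediately splits into two connected daughter areas,
each with fresh ``p_grow`` and split size.  The sector angle is the
directional-trend dial: ``alpha = 2*pi`` gives a concentric expansion,
narrow sectors force a one-directional spread.

The growth draw is over the *whole* neighbourhood of the area: if the drawn
cell is occupied (at the cap) or outside the sector, the attempt is wasted.
Crowded languages therefore grow slowly and boxed-in languages not at all,
which keeps tree sizes in the same range as the migration scenario at the
matched split-size calibration.  In open space the draw reduces to a uniform
pick among free neighbours.

There is no language death here; a boxed-in language simply stops growing
(and, if below its split size, never diversifies again) — which is exactly
the mechanism that keeps old, small clades near the homeland and makes the
homeland reconstructable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import LocationTable, TimedTree

NEIGHBORS_4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
NEIGHBORS_8 = NEIGHBORS_4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass
class ExpSimParams:
    steps: int = 5000
    cell_km: float = 100.0
    split_min: int = 70
    split_max: int = 100
    alpha: float = 2 * math.pi      # sector angle, radians
    orientation: float = 0.0        # sector axis direction (radians, +x)
    cap: int = 1                    # max languages per cell (3 = overlap mode)
    neighborhood: int = 4           # 4- or 8-connected growth

    def __post_init__(self):
        if self.steps <= 0:
            raise ValueError("steps must be positive")
        if not (0 < self.alpha <= 2 * math.pi + 1e-12):
            raise ValueError("alpha must lie in (0, 2*pi]")
        if self.split_min < 2:
            raise ValueError("split-size minimum must be at least 2")
        if self.split_min > self.split_max:
            raise ValueError("split-size range inverted")
        if self.cap < 1:
            raise ValueError("cap must be at least 1")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")

    @property
    def offsets(self):
        return NEIGHBORS_4 if self.neighborhood == 4 else NEIGHBORS_8


def in_sector(cell: tuple[int, int], alpha: float,
              apex: tuple[int, int] = (0, 0), orientation: float = 0.0
              ) -> bool:
    """Is the cell's centre inside the circular sector about the apex?

    The sector spans polar angles within alpha/2 of the orientation axis,
    measured about the apex cell's centre.  The apex cell itself is always
    allowed; alpha = 2*pi admits everything.
    """
    if alpha >= 2 * math.pi - 1e-12:
        return True
    if cell == apex:
        return True
    dx = cell[0] - apex[0]
    dy = cell[1] - apex[1]
    ang = math.atan2(dy, dx) - orientation
    ang = (ang + math.pi) % (2 * math.pi) - math.pi
    return abs(ang) <= alpha / 2 + 1e-12


@dataclass
class LanguageArea:
    """One language: a set of grid cells plus its growth/split draws."""
    id: int
    parent: int                 # parent language id, -1 for the founder
    birth_step: int
    cells: set = field(default_factory=set)
    p_grow: float = 0.5
    split_size: int = 85
    end_step: int | None = None
    fate: str = "alive"         # alive | split
    nb: set = field(default_factory=set)  # neighbourhood (adjacent non-own cells)
    failed_attempts: int = 0

    @property
    def size(self) -> int:
        return len(self.cells)

    def centroid_km(self, cell_km: float) -> tuple[float, float]:
        xs = [(i + 0.5) * cell_km for i, _ in self.cells]
        ys = [(j + 0.5) * cell_km for _, j in self.cells]
        return (sum(xs) / len(xs), sum(ys) / len(ys))


@dataclass
class ExpSimResult:
    params: ExpSimParams
    tree: TimedTree
    languages: list[LanguageArea]    # every language ever, split or alive
    tip_locations: LocationTable     # final-area centroids, km
    node_locations: LocationTable    # split locations (parent centroid), km
    root_location: tuple[float, float]
    seed: int | None = None

    @property
    def n_extant(self) -> int:
        return len(self.tip_locations)

    @property
    def observed_trend(self) -> float:
        xy = np.array(list(self.tip_locations.values()))
        return float(np.linalg.norm(xy.mean(axis=0)
                                    - np.asarray(self.root_location)))

    def final_areas(self) -> list[LanguageArea]:
        return [lg for lg in self.languages if lg.fate == "alive"]


def _neighborhood(cells: set, params: ExpSimParams) -> set:
    """All cells adjacent to an area and not part of it."""
    out = set()
    for (i, j) in cells:
        for di, dj in params.offsets:
            c = (i + di, j + dj)
            if c not in cells:
                out.add(c)
    return out


def free_neighbors(area: "LanguageArea", occupancy: dict,
                   params: ExpSimParams) -> set:
    """The claimable subset of an area's neighbourhood (fresh scan)."""
    return {c for c in _neighborhood(area.cells, params)
            if _claimable(c, occupancy, area.id, params)}


def _claimable(c, occupancy: dict, own_id: int, params: ExpSimParams) -> bool:
    owners = occupancy.get(c, ())
    if own_id in owners or len(owners) >= params.cap:
        return False
    return in_sector(c, params.alpha, (0, 0), params.orientation)


def grow_area(area: LanguageArea, occupancy: dict, params: ExpSimParams,
              rng: np.random.Generator) -> bool:
    """One growth attempt; returns True iff a cell was added.

    With probability ``p_grow`` one cell is drawn uniformly from the area's
    neighbourhood; it is claimed if it is free (below the occupancy cap and
    inside the sector), otherwise the attempt is wasted.  With no free
    neighbour at all the area can never grow again.
    """
    if not area.nb or rng.random() >= area.p_grow:
        return False
    cand = list(area.nb)
    c = cand[rng.integers(len(cand))]
    if not _claimable(c, occupancy, area.id, params):
        area.failed_attempts += 1
        return False
    area.cells.add(c)
    area.nb.discard(c)
    occupancy.setdefault(c, []).append(area.id)
    for di, dj in params.offsets:
        n2 = (c[0] + di, c[1] + dj)
        if n2 not in area.cells:
            area.nb.add(n2)
    area.failed_attempts = 0
    return True


def split_area(area: LanguageArea, rng: np.random.Generator
               ) -> tuple[set, set]:
    """Partition an area's cells into two connected daughter cell sets.

    Two distinct seed cells are drawn uniformly; the daughters then claim the
    parent's cells by synchronized breadth-first growth (alternating turns,
    ties broken by the draw order), which guarantees both parts are non-empty,
    4-connected and cover the parent exactly.
    """
    if area.size < 2:
        raise ValueError("cannot split an area of fewer than 2 cells")
    cells = list(area.cells)
    i, j = rng.choice(len(cells), size=2, replace=False)
    seeds = (cells[int(i)], cells[int(j)])
    assigned = {seeds[0]: 0, seeds[1]: 1}
    frontiers = [[seeds[0]], [seeds[1]]]
    cell_set = area.cells
    while frontiers[0] or frontiers[1]:
        for d in (0, 1):
            new_frontier = []
            for c in frontiers[d]:
                for di, dj in NEIGHBORS_4:
                    nb = (c[0] + di, c[1] + dj)
                    if nb in cell_set and nb not in assigned:
                        assigned[nb] = d
                        new_frontier.append(nb)
            frontiers[d] = new_frontier
    # cells unreachable by 4-connectivity (possible under 8-connected growth)
    # are given to the nearest seed
    for c in cell_set:
        if c not in assigned:
            d0 = (c[0] - seeds[0][0]) ** 2 + (c[1] - seeds[0][1]) ** 2
            d1 = (c[0] - seeds[1][0]) ** 2 + (c[1] - seeds[1][1]) ** 2
            assigned[c] = 0 if d0 <= d1 else 1
    part = ({c for c, d in assigned.items() if d == 0},
            {c for c, d in assigned.items() if d == 1})
    return part


def simulate_expansion(params: ExpSimParams, seed=None) -> ExpSimResult:
    """Run one expansion simulation.

    The founder occupies the sector apex cell (0, 0).  Per step, the living
    languages are visited in freshly shuffled order; each attempts one growth
    move and splits immediately upon reaching its split size.  A language
    whose neighbourhood holds no free cell goes dormant permanently (cells
    never become free again); dormancy is detected by a full neighbourhood
    scan after a run of failed attempts.  Tips are placed at their
    final-area centroids in km.
    """
    rng = np.random.default_rng(seed)

    def fresh_draws():
        return (float(rng.uniform(0.0, 1.0)),
                int(rng.integers(params.split_min, params.split_max + 1)))

    p0, s0 = fresh_draws()
    founder = LanguageArea(id=0, parent=-1, birth_step=0, cells={(0, 0)},
                           p_grow=p0, split_size=s0)
    occupancy: dict = {(0, 0): [0]}
    founder.nb = _neighborhood(founder.cells, params)
    languages = [founder]
    active = [founder]          # alive, not known to be boxed in
    for step in range(1, params.steps + 1):
        if not active:
            break
        order = rng.permutation(len(active))
        next_active = []
        born: list[LanguageArea] = []
        for k in order:
            lg = active[int(k)]
            grow_area(lg, occupancy, params, rng)
            dormant = False
            if lg.failed_attempts >= 50:
                lg.failed_attempts = 0
                dormant = not free_neighbors(lg, occupancy, params)
            # no splits on the final step (a split at exactly t = steps
            # would create zero-length tip branches)
            if lg.size >= lg.split_size and step < params.steps:
                part = split_area(lg, rng)
                lg.end_step, lg.fate = step, "split"
                for cells in part:
                    p, s = fresh_draws()
                    child = LanguageArea(id=len(languages), parent=lg.id,
                                         birth_step=step, cells=cells,
                                         p_grow=p, split_size=s)
                    for c in cells:
                        owners = occupancy[c]
                        owners[owners.index(lg.id)] = child.id
                    child.nb = _neighborhood(cells, params)
                    languages.append(child)
                    born.append(child)
            elif not dormant:
                next_active.append(lg)
        active = next_active + born
    return _build_result(params, languages, seed)


def _build_result(params: ExpSimParams, languages: list[LanguageArea], seed
                  ) -> ExpSimResult:
    parents = [-1]
    times = [0.0]
    names = ["root"]
    node_of: dict[int, int] = {}
    node_locs = LocationTable()
    root_loc = (0.5 * params.cell_km, 0.5 * params.cell_km)
    node_locs["root"] = root_loc
    tips = LocationTable()
    for lg in languages:
        node_of[lg.id] = len(parents)
        parents.append(0 if lg.parent < 0 else node_of[lg.parent])
        end = lg.end_step if lg.end_step is not None else params.steps
        times.append(float(end))
        name = f"n{lg.id}" if lg.fate == "split" else f"L{lg.id}"
        names.append(name)
        node_locs[name] = lg.centroid_km(params.cell_km)
        if lg.fate == "alive":
            tips[name] = lg.centroid_km(params.cell_km)
    extinct = [False] * len(parents)
    tree = TimedTree(parents, times, names, extinct)
    return ExpSimResult(params=params, tree=tree, languages=languages,
                        tip_locations=tips, node_locations=node_locs,
                        root_location=root_loc, seed=seed)
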