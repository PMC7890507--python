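"""Directional random-walk migration simulator.

Languages are points on a plane.  Starting from a single founder at the
origin at time 0, every lineage makes a Gaussian step each year: the steps
have mean ``mu/T`` and per-coordinate variance ``sigma**2/T``, so that over
the whole period ``T`` the total displacement is N(mu, sigma**2) per
coordinate.  ``mu`` is the *total directional bias* in km and ``sigma`` the
total expected undirected diffusion distance.  In parallel, lineages split
(rate ``lam`` per year) and die (rate ``nu`` per year), a standard
birth–death process.  With the defaults ``nu = ln(N)/(4 T)`` and
``lam = 5 nu`` the expected number of extant languages after T = 5000 years
is N = 100.

Runs whose extant count falls below 40 or above 200 are flagged as outliers
and excluded from downstream aggregates, keeping tree sizes comparable
across scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import FossilRecord, LocationTable, TimedTree

DEFAULT_T = 5000.0
DEFAULT_N = 100
DEFAULT_SIGMA = 2000.0
#: death rate nu = ln(N) / (4 T); birth rate lam = 5 nu (printed 0.00023 / 0.00115)
DEFAULT_NU = math.log(DEFAULT_N) / (4 * DEFAULT_T)
DEFAULT_LAM = 5 * DEFAULT_NU


@dataclass
class MigSimParams:
    T: float = DEFAULT_T
    dt: float = 1.0
    mu: tuple[float, float] = (0.0, 0.0)   # total bias vector, km
    sigma: float = DEFAULT_SIGMA           # total diffusion distance, km
    lam: float = DEFAULT_LAM               # birth rate per year
    nu: float = DEFAULT_NU                 # death rate per year
    outlier_min: int = 40
    outlier_max: int = 200

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be positive")
        n_steps = self.T / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("dt must divide T")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not (self.lam >= self.nu >= 0):
            raise ValueError("need lam >= nu >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))

    @property
    def step_mean(self) -> np.ndarray:
        """Per-step displacement mean mu * dt / T (km)."""
        return np.asarray(self.mu, dtype=float) * self.dt / self.T

    @property
    def step_sd(self) -> float:
        """Per-step, per-coordinate displacement s.d. sigma * sqrt(dt/T) (km)."""
        return self.sigma * math.sqrt(self.dt / self.T)


@dataclass
class Lineage:
    """One language lineage: a maximal branch between tree events."""
    id: int
    parent: int            # parent lineage id, -1 for the founder
    birth_step: int
    birth_loc: np.ndarray
    end_step: int | None = None
    fate: str = "alive"    # alive | split | dead
    traj: list = field(default_factory=list)  # locations after steps birth..end

    def location_at(self, step: int) -> np.ndarray:
        if step < self.birth_step or (self.end_step is not None
                                      and step > self.end_step):
            raise ValueError(f"lineage {self.id} not alive at step {step}")
        if step == self.birth_step:
            return self.birth_loc
        return self.traj[step - self.birth_step - 1]


@dataclass
class MigSimResult:
    params: MigSimParams
    tree: TimedTree | None           # None when all lineages died out
    lineages: list[Lineage]
    tip_locations: LocationTable     # extant tips only
    node_locations: LocationTable    # true locations of every tree node
    root_location: tuple[float, float]
    seed: int | None = None
    has_trajectories: bool = True

    @property
    def n_extant(self) -> int:
        return len(self.tip_locations)

    @property
    def all_extinct(self) -> bool:
        return self.tree is None

    @property
    def observed_trend(self) -> float:
        """Distance between extant-tip centroid and the true root (km)."""
        if self.n_extant == 0:
            raise ValueError("no extant tips")
        xy = np.array(list(self.tip_locations.values()))
        return float(np.linalg.norm(xy.mean(axis=0)
                                    - np.asarray(self.root_location)))


def step_displacement(params: MigSimParams, rng: np.random.Generator
                      ) -> np.ndarray:
    """One per-step Gaussian move: N(mu*dt/T, sigma^2*dt/T) per coordinate."""
    return rng.normal(params.step_mean, params.step_sd, size=2)


def is_outlier(result_or_count, outlier_min: int = 40, outlier_max: int = 200
               ) -> bool:
    """True iff the extant-language count is below 40 or above 200."""
    n = (result_or_count.n_extant if isinstance(result_or_count, MigSimResult)
         else int(result_or_count))
    return n < outlier_min or n > outlier_max


def simulate_migration(params: MigSimParams, seed=None,
                       keep_trajectories: bool = True) -> MigSimResult:
    """Run one migration simulation.

    Per step, every live lineage moves, then splits with probability
    ``lam*dt`` (two daughters continue independently from the same place),
    otherwise dies with probability ``nu*dt``.  The genealogy of all
    lineages, extinct included, is returned; if everything dies out before
    T the result is flagged (``tree is None``) rather than raising.

    ``keep_trajectories=False`` drops per-step positions (event locations are
    always kept); fossil sampling requires trajectories.
    """
    rng = np.random.default_rng(seed)
    founder = Lineage(id=0, parent=-1, birth_step=0,
                      birth_loc=np.zeros(2))
    lineages = [founder]
    live = [founder]
    p_split = params.lam * params.dt
    p_die = params.nu * params.dt
    for step in range(1, params.n_steps + 1):
        n = len(live)
        if n == 0:
            break
        pos = np.array([(ln.traj[-1] if ln.traj else ln.birth_loc)
                        for ln in live])
        pos = pos + rng.normal(params.step_mean, params.step_sd, size=(n, 2))
        u = rng.random(n)
        v = rng.random(n)
        # no events on the final step: a split or death at exactly t = T
        # would create a zero-length branch / an "extinct" tip at present
        final = step == params.n_steps
        next_live = []
        for k, ln in enumerate(live):
            if keep_trajectories:
                ln.traj.append(pos[k])
            else:
                ln.traj = [pos[k]]  # keep only the latest location
            if final:
                next_live.append(ln)
            elif u[k] < p_split:
                ln.end_step, ln.fate = step, "split"
                for _ in range(2):
                    child = Lineage(id=len(lineages), parent=ln.id,
                                    birth_step=step, birth_loc=pos[k].copy())
                    lineages.append(child)
                    next_live.append(child)
            elif v[k] < p_die:
                ln.end_step, ln.fate = step, "dead"
            else:
                next_live.append(ln)
        live = next_live
    for ln in live:
        ln.end_step = params.n_steps
    return _build_result(params, lineages, seed, keep_trajectories)


def _build_result(params: MigSimParams, lineages: list[Lineage], seed,
                  has_trajectories: bool = True) -> MigSimResult:
    """Assemble the TimedTree and location tables from lineage records."""
    extant = [ln for ln in lineages if ln.fate == "alive"]
    if not extant:
        return MigSimResult(params=params, tree=None, lineages=lineages,
                            tip_locations=LocationTable(),
                            node_locations=LocationTable(),
                            root_location=(0.0, 0.0), seed=seed,
                            has_trajectories=has_trajectories)
    # one tree node per lineage end + a root node for the founder's birth
    parents = [-1]
    times = [0.0]
    names = ["root"]
    extinct = [False]
    node_of: dict[int, int] = {}   # lineage id -> index of its end node
    for ln in lineages:
        node_of[ln.id] = len(parents)
        parents.append(0 if ln.parent < 0 else node_of[ln.parent])
        times.append(ln.end_step * params.dt)
        if ln.fate == "split":
            names.append(f"n{ln.id}")
            extinct.append(False)
        elif ln.fate == "dead":
            names.append(f"X{ln.id}")
            extinct.append(True)
        else:
            names.append(f"L{ln.id}")
            extinct.append(False)
    tree = TimedTree(parents, times, names, extinct)
    node_locs = LocationTable()
    node_locs["root"] = (0.0, 0.0)
    tips = LocationTable()
    for ln in lineages:
        loc = ln.traj[-1] if ln.traj else ln.birth_loc
        nm = tree.names[node_of[ln.id]]
        node_locs[nm] = tuple(loc)
        if ln.fate == "alive":
            tips[nm] = tuple(loc)
    return MigSimResult(params=params, tree=tree, lineages=lineages,
                        tip_locations=tips, node_locations=node_locs,
                        root_location=(0.0, 0.0), seed=seed,
                        has_trajectories=has_trajectories)


def sample_fossils(result: MigSimResult, count: int, max_age: float,
                   rng: np.random.Generator) -> list[FossilRecord]:
    """Sample historical locations uniformly over (lineage, time) pairs.

    Eligible pairs are steps in the window [T - max_age, T] at which a
    lineage was alive; the fossil location is read off the true trajectory.
    If fewer pairs exist than ``count``, all of them are returned (without
    replacement sampling is used either way, so each (lineage, step) pair
    appears at most once).
    """
    if count == 0:
        return []
    if result.tree is None:
        return []
    if not result.has_trajectories:
        raise ValueError("fossil sampling requires keep_trajectories=True")
    params = result.params
    lo = max(0, int(math.ceil((params.T - max_age) / params.dt)))
    pairs = []
    for ln in result.lineages:
        # exclude the birth step: the location there is the parent split
        # node itself, which would put the fossil at a zero-length offset
        start = max(ln.birth_step + 1, lo)
        for step in range(start, ln.end_step + 1):
            pairs.append((ln.id, step))
    if not pairs:
        return []
    k = min(count, len(pairs))
    if k < count:
        import warnings
        warnings.warn(f"only {k} (lineage, time) pairs available;"
                      f" returning {k} fossils instead of {count}")
    chosen = rng.choice(len(pairs), size=k, replace=False)
    lineage_by_id = {ln.id: ln for ln in result.lineages}
    out = []
    for idx in chosen:
        lid, step = pairs[int(idx)]
        ln = lineage_by_id[lid]
        loc = ln.location_at(step)
        # branch = node below the branch = the lineage's end node
        prefix = {"split": "n", "dead": "X", "alive": "L"}[ln.fate]
        out.append(FossilRecord(branch=f"{prefix}{lid}",
                                time_yr=step * params.dt,
                                x_km=float(loc[0]), y_km=float(loc[1])))
    return out


def simulate_extant_counts(params: MigSimParams, n_reps: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Extant-lineage counts at time T for many replicates (counts only).

    Vectorized across replicates: per step, the number of splitting lineages
    is Binomial(n, lam*dt) and, among the non-splitters, the number dying is
    Binomial(n - splits, nu*dt) — the same per-lineage law as
    :func:`simulate_migration` without the spatial component.
    """
    n = np.ones(n_reps, dtype=np.int64)
    p_split = params.lam * params.dt
    p_die = params.nu * params.dt
    for _ in range(params.n_steps):
        alive = n > 0
        if not alive.any():
            break
        splits = rng.binomial(n, p_split)
        deaths = rng.binomial(n - splits, p_die)
        n = n + splits - deaths
    return n
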