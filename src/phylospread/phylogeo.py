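"""Bayesian continuous phylogeographic reconstruction on a fixed tree.

The generative model is Brownian diffusion along the tree: the displacement
along a branch of duration t is bivariate normal with mean ``drift * t`` and
per-coordinate variance ``sigma2 * rate * t`` (isotropic, coordinates
independent).  Four model flavours:

* ``rw``   — homogeneous random walk: rate = 1, drift = 0 on every branch.
* ``rrw``  — relaxed random walk: per-branch rate multipliers with a mean-1
  lognormal prior whose spread is itself sampled (the lognormal-clock
  analogue of relaxing the diffusion rate).
* ``cdrw`` — relaxed rates plus one *constant* drift vector (km/year)
  shared by all branches, with a zero-centred Gaussian prior.
* ``rdrw`` — relaxed rates plus *per-branch* drift vectors, exchangeable
  around a global drift with an inverse-gamma-controlled spread.

For the homogeneous walk the root posterior is available in closed form by
Gaussian message passing (:func:`rw_root_posterior`); the general case is
handled by a Metropolis-within-Gibbs sampler (:func:`mcmc_sample`) whose
location updates are exact Gaussian full-conditionals applied to
checkerboard (depth-parity) blocks — nodes of equal parity are conditionally
independent, so each half-sweep is a single vectorized draw.

Known historical locations ("fossils") enter as observed degree-2 nodes
inserted on their branch (:func:`attach_fossils`); without them the drift
parameter is informed only by its prior, which is exactly why directed
migrations defeat reconstruction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (FossilRecord, LocationTable, TimedTree,
                   ValidationError, check_locations_cover)

logger = logging.getLogger("phylospread")

#: Lower clamp (years) for branch durations in the sampler: zero-length
#: branches (fossil at a node's exact time) act as equality constraints.
MIN_BRANCH_YEARS = 1e-9

MODEL_KINDS = ("rw", "rrw", "cdrw", "rdrw")


@dataclass
class ModelSpec:
    """Model flavour, priors and chain settings."""
    kind: str = "rrw"
    iterations: int = 50_000
    burn_in: float = 0.2
    thinning: int = 10
    seed: int | None = None
    # priors
    sigma2_shape: float = 0.001        # inverse-gamma on sigma2
    sigma2_rate: float = 0.001
    root_prior_sd: float | None = None  # None -> 10 x tip bounding-box diagonal
    rate_hyper_scale: float = 1.0       # half-normal scale for lognormal sd s
    drift_prior_sd: float | None = None  # None -> bbox diagonal / tree span
    # proposal scales
    rate_step: float = 0.6
    hyper_step: float = 0.3

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"model kind must be one of {MODEL_KINDS}")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must lie in [0, 1)")
        if self.thinning < 1 or self.iterations < 1:
            raise ValueError("iterations and thinning must be positive")
        for name in ("sigma2_shape", "sigma2_rate", "rate_hyper_scale",
                     "rate_step", "hyper_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def relaxed_rates(self) -> bool:
        return self.kind in ("rrw", "cdrw", "rdrw")

    @property
    def drift_kind(self) -> str:
        return {"rw": "none", "rrw": "none",
                "cdrw": "constant", "rdrw": "branch"}[self.kind]


@dataclass
class PosteriorSamples:
    """Retained MCMC draws (after burn-in and thinning)."""
    root: np.ndarray                   # (M, 2) km
    sigma2: np.ndarray                 # (M,) km^2 / year
    model: str
    seed: int | None = None
    drift: np.ndarray | None = None    # (M, 2) km/year (global / constant)
    rate_sd: np.ndarray | None = None  # (M,) lognormal sd of rate multipliers
    node_locations: np.ndarray | None = None   # (M, L, 2)
    node_names: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return len(self.root)

    def to_frame(self):
        import pandas as pd
        data = {"draw": np.arange(self.n_draws),
                "root_x_km": self.root[:, 0], "root_y_km": self.root[:, 1],
                "sigma2": self.sigma2}
        data["drift_x"] = (self.drift[:, 0] if self.drift is not None
                           else np.zeros(self.n_draws))
        data["drift_y"] = (self.drift[:, 1] if self.drift is not None
                           else np.zeros(self.n_draws))
        if self.rate_sd is not None:
            data["rate_sd"] = self.rate_sd
        df = pd.DataFrame(data)
        if self.node_locations is not None:
            for k, nm in enumerate(self.node_names):
                df[f"{nm}_x"] = self.node_locations[:, k, 0]
                df[f"{nm}_y"] = self.node_locations[:, k, 1]
        return df


# ---------------------------------------------------------------------------
# Single-branch density
# ---------------------------------------------------------------------------

def branch_log_density(parent_loc, child_loc, t: float, sigma2: float,
                       rate: float = 1.0, drift=(0.0, 0.0)) -> float:
    """Log density of a child location given its parent.

    Bivariate normal with mean ``parent + drift*t`` and per-coordinate
    variance ``sigma2 * rate * t``.  A zero-length branch is an equality
    constraint: 0.0 if the locations match, -inf otherwise.
    """
    if t < 0:
        raise ValueError("branch duration must be non-negative")
    p = np.asarray(parent_loc, float)
    c = np.asarray(child_loc, float)
    if t == 0:
        return 0.0 if np.allclose(p, c, atol=1e-9) else -math.inf
    v = sigma2 * rate * t
    resid = c - p - np.asarray(drift, float) * t
    return float(-math.log(2 * math.pi * v) - np.dot(resid, resid) / (2 * v))


# ---------------------------------------------------------------------------
# Fossil augmentation
# ---------------------------------------------------------------------------

def attach_fossils(tree: TimedTree, fossils: list[FossilRecord]
                   ) -> tuple[TimedTree, LocationTable]:
    """Insert observed degree-2 nodes at the fossils' (branch, time) spots.

    Each fossil names the node *below* its branch; its time must lie within
    (parent time, node time].  Multiple fossils on one branch are inserted
    in time order.  Returns the augmented tree plus the table of the new
    nodes' observed locations.
    """
    if not fossils:
        return tree, LocationTable()
    name_to = tree.name_to_index()
    per_branch: dict[int, list[FossilRecord]] = {}
    for f in fossils:
        if f.branch not in name_to:
            raise ValidationError(f"fossil branch {f.branch!r} not in tree")
        i = name_to[f.branch]
        p = tree.parents[i]
        if p < 0:
            raise ValidationError(f"fossil {f.branch!r}: root has no branch")
        if not (tree.times[p] < f.time_yr <= tree.times[i]):
            raise ValidationError(
                f"fossil on branch {f.branch!r} at t={f.time_yr:.6g} outside"
                f" ({tree.times[p]:.6g}, {tree.times[i]:.6g}]")
        per_branch.setdefault(i, []).append(f)

    parents = list(tree.parents)
    times = list(tree.times)
    names = list(tree.names)
    extinct = list(tree.extinct)
    table = LocationTable()
    counter = 0
    for i, recs in per_branch.items():
        recs = sorted(recs, key=lambda f: f.time_yr)
        upper = int(tree.parents[i])
        for f in recs:
            nm = f"fossil{counter}"
            counter += 1
            parents.append(upper)
            times.append(float(f.time_yr))
            names.append(nm)
            extinct.append(False)
            table[nm] = f.location
            upper = len(parents) - 1
        parents[i] = upper
    return TimedTree(parents, times, names, extinct), table


# ---------------------------------------------------------------------------
# Exact Gaussian message passing for the homogeneous walk
# ---------------------------------------------------------------------------

def _upward_messages(tree: TimedTree, observed: dict[int, np.ndarray]
                     ) -> list[tuple[np.ndarray, float] | None]:
    """Upward (pruning) pass of Gaussian messages.

    Message at node i summarizes the evidence in i's subtree as a Gaussian
    over x_i with mean m and variance ``sigma2 * w`` (w in years; w = 0 for
    an observed node).  Nodes with no observed descendants carry None.
    """
    msgs: list[tuple[np.ndarray, float] | None] = [None] * tree.n_nodes
    for i in tree.postorder():
        if i in observed:
            msgs[i] = (observed[i], 0.0)
            continue
        parts = []
        for c in tree.children(i):
            if msgs[c] is None:
                continue
            m, w = msgs[c]
            parts.append((m, w + max(tree.branch_length(c),
                                     MIN_BRANCH_YEARS)))
        if not parts:
            continue
        if len(parts) == 1:
            msgs[i] = parts[0]
        else:
            prec = sum(1.0 / w for _, w in parts)
            mean = sum(m / w for m, w in parts) / prec
            msgs[i] = (mean, 1.0 / prec)
    return msgs


def rw_root_posterior(tree: TimedTree, tips: LocationTable, sigma2: float,
                      root_prior: tuple | None = None
                      ) -> tuple[np.ndarray, float]:
    """Exact Gaussian root posterior under the homogeneous random walk.

    Returns (mean (2,), per-coordinate variance in km^2).  With
    ``root_prior=None`` the prior is flat and the posterior is the upward
    pruning message — a convex combination of tip locations, hence inside
    their convex hull.  ``root_prior=(mean, var_km2)`` adds a proper
    Gaussian prior.  A single-tip tree yields N(tip, sigma2 * T).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    observed = {}
    for i in tree.tips:
        nm = tree.names[i]
        if not tree.extinct[i]:
            if nm not in tips:
                raise ValidationError(f"no location for extant tip {nm!r}")
            observed[i] = np.asarray(tips[nm], float)
    if not observed:
        raise ValidationError("no observed tips")
    msgs = _upward_messages(tree, observed)
    m = msgs[tree.root]
    if m is None:  # cannot happen: extant tips always subtend the root
        raise ValidationError("root received no evidence")
    mean, w = m
    if root_prior is None:
        return np.asarray(mean, float), sigma2 * w
    m0 = np.asarray(root_prior[0], float)
    v0 = float(root_prior[1])
    if w == 0.0:
        return np.asarray(mean, float), 0.0
    prec = 1.0 / (sigma2 * w) + 1.0 / v0
    mean_post = (mean / (sigma2 * w) + m0 / v0) / prec
    return mean_post, 1.0 / prec


def rw_loglik(tree: TimedTree, tips: LocationTable, sigma2: float,
              root_location=None, root_prior: tuple | None = None) -> float:
    """Marginal log likelihood of the observed tip locations under the
    homogeneous walk, latent nodes integrated out by pruning.

    Exactly one of ``root_location`` (condition on a fixed root) or
    ``root_prior=(mean, var)`` (integrate the root against a Gaussian) must
    be given.
    """
    if (root_location is None) == (root_prior is None):
        raise ValueError("give exactly one of root_location / root_prior")
    observed = {i: np.asarray(tips[tree.names[i]], float)
                for i in tree.tips if not tree.extinct[i]}
    # sequential pruning with explicit log-normalizer bookkeeping
    logz = 0.0
    msgs: list[tuple[np.ndarray, float] | None] = [None] * tree.n_nodes
    for i in tree.postorder():
        if i in observed:
            msgs[i] = (observed[i], 0.0)
            continue
        acc = None
        for c in tree.children(i):
            if msgs[c] is None:
                continue
            m, w = msgs[c]
            part = (m, w + max(tree.branch_length(c), MIN_BRANCH_YEARS))
            if acc is None:
                acc = part
            else:
                m1, w1 = acc
                m2, w2 = part
                v = sigma2 * (w1 + w2)
                diff = m1 - m2
                logz += (-math.log(2 * math.pi * v)
                         - float(np.dot(diff, diff)) / (2 * v))
                prec = 1.0 / w1 + 1.0 / w2
                acc = ((m1 / w1 + m2 / w2) / prec, 1.0 / prec)
        msgs[i] = acc
    m, w = msgs[tree.root]
    if root_location is not None:
        x0 = np.asarray(root_location, float)
        v = sigma2 * w
        diff = m - x0
        if w == 0.0:
            return logz if np.allclose(diff, 0, atol=1e-9) else -math.inf
        return logz + (-math.log(2 * math.pi * v)
                       - float(np.dot(diff, diff)) / (2 * v))
    m0 = np.asarray(root_prior[0], float)
    v = sigma2 * w + float(root_prior[1])
    diff = m - m0
    return logz + (-math.log(2 * math.pi * v)
                   - float(np.dot(diff, diff)) / (2 * v))


# ---------------------------------------------------------------------------
# Metropolis-within-Gibbs sampler
# ---------------------------------------------------------------------------

class _TreeArrays:
    """Flat arrays for fast conditional updates."""

    def __init__(self, tree: TimedTree, observed: dict[int, np.ndarray]):
        n = tree.n_nodes
        self.n = n
        self.root = tree.root
        self.parent = tree.parents.copy()
        self.t = np.array([max(tree.branch_length(i), MIN_BRANCH_YEARS)
                           for i in range(n)])  # branch above node i
        self.t[tree.root] = np.nan
        self.obs_mask = np.zeros(n, bool)
        self.x = np.zeros((n, 2))
        for i, loc in observed.items():
            self.obs_mask[i] = True
            self.x[i] = loc
        self.latent = np.flatnonzero(~self.obs_mask)
        self.branches = np.array([i for i in range(n) if i != tree.root])
        # checkerboard groups: latent nodes split by depth parity
        depth = tree.depths()
        self.groups = []
        for par in (0, 1):
            grp = np.array([i for i in self.latent if depth[i] % 2 == par],
                           dtype=np.int64)
            if len(grp):
                self.groups.append(self._pack_group(tree, grp))

    def _pack_group(self, tree: TimedTree, grp: np.ndarray):
        kids = [tree.children(int(i)) for i in grp]
        width = max((len(k) for k in kids), default=0)
        child = -np.ones((len(grp), max(width, 1)), dtype=np.int64)
        for r, k in enumerate(kids):
            child[r, :len(k)] = k
        return grp, child


def _prepare(tree: TimedTree, tips: LocationTable,
             fossil_table: LocationTable | None):
    observed: dict[int, np.ndarray] = {}
    for i in tree.tips:
        nm = tree.names[i]
        if not tree.extinct[i]:
            if nm not in tips:
                raise ValidationError(f"no location for extant tip {nm!r}")
            observed[i] = np.asarray(tips[nm], float)
    if fossil_table:
        name_to = tree.name_to_index()
        for nm, loc in fossil_table.items():
            observed[name_to[nm]] = np.asarray(loc, float)
    if not observed:
        raise ValidationError("nothing observed: no extant tips or fossils")
    return observed


def mcmc_sample(tree: TimedTree, tips: LocationTable, spec: ModelSpec,
                fossils: list[FossilRecord] | None = None,
                seed: int | None = None,
                keep_node_locations: bool = False) -> PosteriorSamples:
    """Posterior sampling of node locations, diffusion rate and drift.

    Metropolis-within-Gibbs: internal-node locations by exact Gaussian
    full-conditionals on checkerboard blocks; ``sigma2`` by a conjugate
    inverse-gamma step; relaxed-rate multipliers by parallel random-walk
    Metropolis on the log scale under a mean-1 lognormal prior whose spread
    is itself sampled; constant drift by a conjugate Gaussian step;
    per-branch drifts (rdrw) hierarchically centred on a sampled global
    drift.  Latent extinct tips, if present in the tree, are sampled like
    internal nodes.  Reproducible under a fixed seed.
    """
    check_locations_cover(tree, tips)
    if fossils:
        tree, fossil_table = attach_fossils(tree, fossils)
    else:
        fossil_table = None
    observed = _prepare(tree, tips, fossil_table)
    arr = _TreeArrays(tree, observed)
    rng = np.random.default_rng(seed if seed is not None else spec.seed)

    obs_xy = np.array([observed[i] for i in sorted(observed)])
    centroid = obs_xy.mean(axis=0)
    bbox_diag = float(np.linalg.norm(obs_xy.max(0) - obs_xy.min(0)))
    bbox_diag = max(bbox_diag, 1.0)
    root_sd = (spec.root_prior_sd if spec.root_prior_sd is not None
               else 10.0 * bbox_diag)
    root_prec = 1.0 / root_sd ** 2
    span_years = max(tree.T - tree.times[tree.root], 1.0)
    tau = (spec.drift_prior_sd if spec.drift_prior_sd is not None
           else bbox_diag / span_years)

    # --- state ---------------------------------------------------------
    x = arr.x.copy()
    # initialize latent nodes from the upward-message means (cheap smoother)
    msgs = _upward_messages(tree, observed)
    for i in tree.preorder():
        if arr.obs_mask[i]:
            continue
        if msgs[i] is not None:
            x[i] = msgs[i][0]
        elif tree.parents[i] >= 0:
            x[i] = x[tree.parents[i]]
        else:
            x[i] = centroid
    B = len(arr.branches)
    t_b = arr.t[arr.branches]
    rates = np.ones(arr.n)          # rate multiplier of branch above node
    log_rates = np.zeros(B)
    rate_sd = 0.5                   # lognormal sd s of the multipliers
    drift_b = np.zeros((arr.n, 2))  # drift of branch above node (km/yr)
    g_drift = np.zeros(2)           # constant / global drift
    omega2 = tau ** 2               # rdrw spread of branch drifts
    resid0 = x[arr.branches] - x[arr.parent[arr.branches]]
    sigma2 = max(float(np.mean(np.sum(resid0 ** 2, axis=1) / (2 * t_b))),
                 1e-6)

    n_iter = spec.iterations
    burn = int(spec.burn_in * n_iter)
    keep = [k for k in range(n_iter) if k >= burn
            and (k - burn) % spec.thinning == 0]
    keep_set = set(keep)
    M = len(keep)
    out_root = np.empty((M, 2))
    out_sig = np.empty(M)
    out_drift = np.empty((M, 2)) if spec.drift_kind != "none" else None
    out_rsd = np.empty(M) if spec.relaxed_rates else None
    latent_names = [tree.names[i] for i in arr.latent]
    out_nodes = (np.empty((M, len(arr.latent), 2))
                 if keep_node_locations else None)

    half_s2 = spec.rate_hyper_scale ** 2
    m_idx = 0
    for it in range(n_iter):
        # -- node locations: checkerboard exact Gibbs --------------------
        for grp, child in arr.groups:
            prec = np.zeros(len(grp))
            num = np.zeros((len(grp), 2))
            has_parent = arr.parent[grp] >= 0
            if has_parent.any():
                gi = grp[has_parent]
                v_up = sigma2 * rates[gi] * arr.t[gi]
                mean_up = x[arr.parent[gi]] + drift_b[gi] * arr.t[gi][:, None]
                prec[has_parent] += 1.0 / v_up
                num[has_parent] += mean_up / v_up[:, None]
            for col in range(child.shape[1]):
                cc = child[:, col]
                mask = cc >= 0
                if not mask.any():
                    continue
                ci = cc[mask]
                v_dn = sigma2 * rates[ci] * arr.t[ci]
                mean_dn = x[ci] - drift_b[ci] * arr.t[ci][:, None]
                prec[mask] += 1.0 / v_dn
                num[mask] += mean_dn / v_dn[:, None]
            is_root = grp == arr.root
            if is_root.any():
                prec[is_root] += root_prec
                num[is_root] += root_prec * centroid
            var = 1.0 / prec
            mean = num * var[:, None]
            x[grp] = mean + np.sqrt(var)[:, None] * rng.standard_normal(
                (len(grp), 2))

        resid = (x[arr.branches] - x[arr.parent[arr.branches]]
                 - drift_b[arr.branches] * t_b[:, None])
        sq = np.sum(resid ** 2, axis=1)

        # -- sigma2: conjugate inverse-gamma ------------------------------
        shape = spec.sigma2_shape + B
        rate_param = spec.sigma2_rate + 0.5 * float(
            np.sum(sq / (rates[arr.branches] * t_b)))
        sigma2 = 1.0 / rng.gamma(shape, 1.0 / rate_param)

        # -- relaxed rates: parallel log-scale Metropolis -----------------
        if spec.relaxed_rates:
            prop = log_rates + spec.rate_step * rng.standard_normal(B)
            r_old = np.exp(log_rates)
            r_new = np.exp(prop)
            # branch likelihood: two coords -> -log(v) - sq/(2 v)
            ll_old = -np.log(r_old * t_b * sigma2) - sq / (
                2 * sigma2 * r_old * t_b)
            ll_new = -np.log(r_new * t_b * sigma2) - sq / (
                2 * sigma2 * r_new * t_b)
            mu_lr = -0.5 * rate_sd ** 2
            lp_old = -(log_rates - mu_lr) ** 2 / (2 * rate_sd ** 2)
            lp_new = -(prop - mu_lr) ** 2 / (2 * rate_sd ** 2)
            accept = (np.log(rng.random(B))
                      < ll_new + lp_new - ll_old - lp_old)
            log_rates = np.where(accept, prop, log_rates)
            rates[arr.branches] = np.exp(log_rates)

            # hyper sd of the lognormal, half-normal prior
            prop_s = rate_sd * math.exp(spec.hyper_step
                                        * rng.standard_normal())
            def s_logpost(s):
                mu = -0.5 * s ** 2
                return (-B * math.log(s)
                        - float(np.sum((log_rates - mu) ** 2)) / (2 * s ** 2)
                        - s ** 2 / (2 * half_s2) + math.log(s))  # log-scale jacobian
            if (math.log(rng.random())
                    < s_logpost(prop_s) - s_logpost(rate_sd)):
                rate_sd = prop_s

        # -- drift --------------------------------------------------------
        if spec.drift_kind == "constant":
            delta = x[arr.branches] - x[arr.parent[arr.branches]]
            w = 1.0 / (sigma2 * rates[arr.branches])
            prec_d = 1.0 / tau ** 2 + float(np.sum(t_b * w))
            mean_d = (delta * w[:, None]).sum(axis=0) / prec_d
            g_drift = mean_d + rng.standard_normal(2) / math.sqrt(prec_d)
            drift_b[arr.branches] = g_drift
        elif spec.drift_kind == "branch":
            delta = x[arr.branches] - x[arr.parent[arr.branches]]
            v_like = sigma2 * rates[arr.branches] / t_b   # var of delta/t
            prec_b = 1.0 / omega2 + 1.0 / v_like
            mean_b = ((delta / t_b[:, None]) / v_like[:, None]
                      + g_drift / omega2) / prec_b[:, None]
            db = mean_b + rng.standard_normal((B, 2)) / np.sqrt(
                prec_b)[:, None]
            drift_b[arr.branches] = db
            prec_g = 1.0 / tau ** 2 + B / omega2
            mean_g = db.sum(axis=0) / omega2 / prec_g
            g_drift = mean_g + rng.standard_normal(2) / math.sqrt(prec_g)
            dev = db - g_drift
            omega2 = 1.0 / rng.gamma(1.0 + B,
                                     1.0 / (tau ** 2 + 0.5 * float(
                                         np.sum(dev ** 2))))

        if it in keep_set:
            out_root[m_idx] = x[arr.root]
            out_sig[m_idx] = sigma2
            if out_drift is not None:
                out_drift[m_idx] = g_drift
            if out_rsd is not None:
                out_rsd[m_idx] = rate_sd
            if out_nodes is not None:
                out_nodes[m_idx] = x[arr.latent]
            m_idx += 1

    if not np.all(np.isfinite(out_root)):
        raise RuntimeError("sampler produced non-finite draws")
    return PosteriorSamples(root=out_root, sigma2=out_sig, model=spec.kind,
                            seed=seed if seed is not None else spec.seed,
                            drift=out_drift, rate_sd=out_rsd,
                            node_locations=out_nodes,
                            node_names=latent_names)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def effective_sample_size(chain: np.ndarray) -> float:
    """ESS by the initial-positive-sequence autocorrelation estimator."""
    z = np.asarray(chain, float)
    n = len(z)
    if n < 2:
        raise ValueError("need at least 2 draws")
    z = z - z.mean()
    var = float(np.dot(z, z)) / n
    if var == 0:
        return 1.0
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(z, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    s = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        s += 2 * pair
        k += 2
    return float(min(n, max(1.0, n / s)))


def diagnostics(samples: PosteriorSamples, ess_threshold: float = 100.0
                ) -> dict:
    """Per-parameter ESS and split-half discrepancy, with low-ESS flags."""
    params = {"root_x": samples.root[:, 0], "root_y": samples.root[:, 1],
              "sigma2": samples.sigma2}
    if samples.drift is not None:
        params["drift_x"] = samples.drift[:, 0]
        params["drift_y"] = samples.drift[:, 1]
    if samples.rate_sd is not None:
        params["rate_sd"] = samples.rate_sd
    out = {}
    flagged = []
    for name, chain in params.items():
        if len(chain) < 2:
            raise ValueError("need at least 2 retained draws")
        ess = effective_sample_size(chain)
        half = len(chain) // 2
        sd = float(chain.std()) or 1.0
        split = abs(float(chain[:half].mean() - chain[half:].mean())) / sd
        out[name] = {"ess": ess, "split_half": split}
        if ess < ess_threshold:
            flagged.append(name)
    out["flagged"] = flagged
    return out
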