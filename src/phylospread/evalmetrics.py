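"""Evaluation statistics for homeland reconstructions.

Given posterior draws of the root location and the true (simulated) root,
this module computes

* the observed trend ``mu_hat`` — distance between the extant-tip centroid
  and the true root, the scenario-independent measure of directional trend;
* the RMSE — root mean squared Euclidean distance of posterior draws to the
  truth (draws may be pooled across runs);
* the bias — distance from the posterior mean to the truth (so bias <= RMSE
  always, with equality only for a point-mass posterior);
* HPD-region coverage — whether the truth lies inside the highest posterior
  density region of a given level, decided by a Gaussian kernel density
  estimate over the draws: the HPD set collects the points whose density
  reaches the (1 - level) quantile of the draws' own densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde


def _as_draws(samples) -> np.ndarray:
    a = np.asarray(samples, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 1:
        raise ValueError("expected an (M, 2) array of root draws")
    return a


def observed_trend(tips, root) -> float:
    """Distance (km) between the tip centroid and the true root.

    ``tips`` may be a LocationTable or an (N, 2) array.
    """
    if hasattr(tips, "values") and not isinstance(tips, np.ndarray):
        tips = list(tips.values())
    xy = np.asarray(tips, dtype=float)
    if xy.size == 0:
        raise ValueError("no tip locations given")
    return float(np.linalg.norm(xy.mean(axis=0) - np.asarray(root, float)))


def rmse(samples, root) -> float:
    """Root mean squared distance (km) of posterior draws to the truth."""
    draws = _as_draws(samples)
    d2 = np.sum((draws - np.asarray(root, float)) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def bias(samples, root) -> float:
    """Distance (km) from the posterior mean to the truth."""
    draws = _as_draws(samples)
    return float(np.linalg.norm(draws.mean(axis=0) - np.asarray(root, float)))


def hpd_covers(samples, level: float, point) -> bool:
    """Does the ``level`` HPD region of the draws cover ``point``?

    The region is defined through a Gaussian KDE with Scott's-rule bandwidth:
    the point is covered iff its estimated density is at least the
    (1 - level) quantile of the densities of the draws themselves.  Coverage
    is monotone in ``level`` by construction.
    """
    draws = _as_draws(samples)
    if len(draws) < 10:
        raise ValueError("need at least 10 draws for an HPD region")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    spread = draws.std(axis=0)
    if np.all(spread < 1e-12):  # degenerate point cloud
        return bool(np.allclose(draws[0], point, atol=1e-9))
    if np.any(spread < 1e-12):  # KDE needs full-rank scatter; add tiny jitter
        draws = draws + 1e-9 * np.random.default_rng(0).standard_normal(
            draws.shape)
    kde = gaussian_kde(draws.T)
    dens = kde(draws.T)
    # leave-one-out correction: a draw's density includes its own kernel,
    # which an independent point lacks; uncorrected thresholds undercover
    m = len(draws)
    self_term = 1.0 / (2 * math.pi * math.sqrt(
        np.linalg.det(kde.covariance)) * m)
    dens_loo = np.maximum((dens - self_term) * m / (m - 1), 0.0)
    threshold = np.quantile(dens_loo, 1.0 - level)
    return bool(kde(np.asarray(point, float).reshape(2, 1))[0] >= threshold)


@dataclass
class EvalReport:
    """Per-run evaluation summary."""
    observed_trend: float
    rmse: float
    bias: float
    covered_80: bool
    covered_95: bool
    n_extant: int
    scenario_params: dict = field(default_factory=dict)
    seed: int | None = None


def evaluate_run(root_draws, true_root, tips, n_extant: int | None = None,
                 scenario_params: dict | None = None,
                 seed: int | None = None,
                 levels: tuple[float, float] = (0.80, 0.95)) -> EvalReport:
    """Bundle all metrics for one reconstruction run."""
    if hasattr(tips, "values") and not isinstance(tips, np.ndarray):
        tips = np.asarray(list(tips.values()), float)
    if n_extant is None:
        n_extant = len(tips)
    return EvalReport(
        observed_trend=observed_trend(tips, true_root),
        rmse=rmse(root_draws, true_root),
        bias=bias(root_draws, true_root),
        covered_80=hpd_covers(root_draws, levels[0], true_root),
        covered_95=hpd_covers(root_draws, levels[1], true_root),
        n_extant=int(n_extant),
        scenario_params=dict(scenario_params or {}),
        seed=seed,
    )


def coverage_rate(reports: list[EvalReport], level: float) -> float:
    """Fraction of runs whose HPD region at ``level`` covered the truth."""
    if not reports:
        raise ValueError("no reports given")
    if abs(level - 0.80) < 1e-9:
        flags = [r.covered_80 for r in reports]
    elif abs(level - 0.95) < 1e-9:
        flags = [r.covered_95 for r in reports]
    else:
        raise ValueError("reports carry coverage flags at levels 0.80/0.95")
    return float(np.mean(flags))
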