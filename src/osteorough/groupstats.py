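"""Group statistics for arthritic-versus-control comparisons.

The headline quantity is the roughness ratio ``mu_AR/CO = mu_AR / mu_CO``
with its uncertainty from standard propagation of relative errors; group
differences are assessed by non-overlap of 95 % percentile-bootstrap
confidence intervals, supplemented by the two-tailed Mann-Whitney U test and
Spearman rank correlation.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)


def ratio_with_propagation(
    mu_AR: float, sigma_AR: float, mu_CO: float, sigma_CO: float
) -> tuple[float, float]:
    """Mean ratio and its propagated SD.

    ``mu_ratio = mu_AR / mu_CO``;
    ``sigma_ratio = |mu_ratio| * sqrt((sigma_AR/mu_AR)^2 + (sigma_CO/mu_CO)^2)``.
    """
    if mu_CO == 0:
        raise ZeroDivisionError("control mean is zero: ratio undefined")
    if sigma_AR < 0 or sigma_CO < 0:
        raise ValueError("standard deviations must be >= 0")
    if mu_AR == 0 and sigma_AR > 0:
        raise ZeroDivisionError("mu_AR = 0 with sigma_AR > 0: relative error undefined")
    mu_ratio = mu_AR / mu_CO
    rel_AR = sigma_AR / mu_AR if sigma_AR else 0.0
    rel_CO = sigma_CO / mu_CO
    sigma_ratio = abs(mu_ratio) * math.sqrt(rel_AR**2 + rel_CO**2)
    return mu_ratio, sigma_ratio


def _resample_means(x: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    return x[idx].mean(axis=1)


def bootstrap_ratio_ci(
    samples_AR,
    samples_CO,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int | None = None,
    return_samples: bool = False,
):
    """Percentile bootstrap CI of mean(AR resample) / mean(CO resample).

    Resampling is with replacement within each group; control resamples with
    mean exactly zero are redrawn (counted and logged).  Reproducible for a
    given ``seed``.
    """
    a = np.asarray(samples_AR, dtype=np.float64)
    c = np.asarray(samples_CO, dtype=np.float64)
    if a.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    ma = _resample_means(a, n_boot, rng)
    mc = _resample_means(c, n_boot, rng)
    n_redrawn = 0
    for _ in range(1000):
        bad = mc == 0.0
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        mc[bad] = _resample_means(c, int(bad.sum()), rng)
    else:
        raise RuntimeError("control resamples keep producing zero means")
    if n_redrawn:
        log.info("redrew %d zero-mean control resamples", n_redrawn)
    ratios = ma / mc
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(ratios, [alpha, 1.0 - alpha])
    if return_samples:
        return float(lo), float(hi), ratios
    return float(lo), float(hi)


def bootstrap_mean_ci(
    samples, n_boot: int = 10000, level: float = 0.95, seed: int | None = None
) -> tuple[float, float]:
    """Percentile bootstrap CI of a single group mean."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty sample")
    means = _resample_means(x, n_boot, np.random.default_rng(seed))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def intervals_overlap(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> bool:
    """Closed-interval overlap test: a shared endpoint counts as overlap."""
    return ci_a[0] <= ci_b[1] and ci_b[0] <= ci_a[1]


@dataclass
class GroupComparison:
    """Summary of an arthritic-vs-control comparison for one metric."""

    metric: str
    mu_AR: float
    sigma_AR: float
    mu_CO: float
    sigma_CO: float
    mu_ratio: float
    sigma_ratio: float
    ci_low: float  # bootstrap CI of the ratio
    ci_high: float
    ci_AR: tuple[float, float]  # bootstrap CI of each group mean
    ci_CO: tuple[float, float]
    n_boot: int
    seed: int | None
    significant: bool  # group-mean CIs do not overlap (closed intervals)


def compare_groups(
    results_AR,
    results_CO,
    metric: str = "",
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int | None = None,
) -> GroupComparison:
    """Per-group mean/SD, propagated ratio, bootstrap CIs, and the
    CI-non-overlap significance decision.

    Group SDs are sample SDs (ddof=1) when n > 1.  Significance holds when
    the two groups' bootstrap mean CIs are disjoint as closed intervals
    (touching endpoints count as overlap, hence not significant).
    """
    a = np.asarray(results_AR, dtype=np.float64)
    c = np.asarray(results_CO, dtype=np.float64)
    if a.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    mu_AR, mu_CO = float(a.mean()), float(c.mean())
    sd_AR = float(a.std(ddof=1)) if a.size > 1 else 0.0
    sd_CO = float(c.std(ddof=1)) if c.size > 1 else 0.0
    mu_ratio, sigma_ratio = ratio_with_propagation(mu_AR, sd_AR, mu_CO, sd_CO)
    lo, hi = bootstrap_ratio_ci(a, c, n_boot=n_boot, level=level, seed=seed)
    ci_AR = bootstrap_mean_ci(a, n_boot=n_boot, level=level, seed=None if seed is None else seed + 1)
    ci_CO = bootstrap_mean_ci(c, n_boot=n_boot, level=level, seed=None if seed is None else seed + 2)
    return GroupComparison(
        metric=metric, mu_AR=mu_AR, sigma_AR=sd_AR, mu_CO=mu_CO, sigma_CO=sd_CO,
        mu_ratio=mu_ratio, sigma_ratio=sigma_ratio, ci_low=lo, ci_high=hi,
        ci_AR=ci_AR, ci_CO=ci_CO, n_boot=n_boot, seed=seed,
        significant=not intervals_overlap(ci_AR, ci_CO),
    )


def rank_tests(x, y, method: str = "mannwhitney_two_tailed") -> tuple[float, float]:
    """Mann-Whitney U (two-tailed) or Spearman correlation, ``(stat, p)``.

    Mann-Whitney uses exact enumeration when ``min(n, m) <= 8`` and the data
    are tie-free, otherwise the tie-corrected normal approximation with
    continuity correction.  Spearman uses mid-rank ties and the
    t-approximation for p.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if method == "mannwhitney_two_tailed":
        if x.size < 1 or y.size < 1:
            raise ValueError("both samples need at least one observation")
        pooled = np.concatenate([x, y])
        has_ties = np.unique(pooled).size < pooled.size
        use_exact = min(x.size, y.size) <= 8 and not has_ties
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided",
            method="exact" if use_exact else "asymptotic",
        )
        return float(res.statistic), float(res.pvalue)
    if method == "spearman":
        if x.size != y.size or x.size < 3:
            raise ValueError("spearman needs paired vectors of length >= 3")
        rho, p = sps.spearmanr(x, y)
        return float(rho), float(p)
    raise ValueError(f"unknown method {method!r}")
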