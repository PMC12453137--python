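"""Permutation-enrichment engine for family-size vs. per-family metrics.

The question each stage asks is the same: is the Spearman correlation
between gene-family size and some per-family metric (proportion of
context-dependently expressed genes; fitness-associated SNP density)
stronger in the AM-expanded family set than in random family sets of the
same size? The null is built by drawing, without replacement, subsamples
of matched size from the pool of all eligible families and recording the
subsample's rank correlation. Empirical p-values follow the plain
counting formula

    p_greater = #{null rho >= observed rho} / n_perm

with no +1 correction; a conservative variant (+1 in numerator and
denominator) is available behind a flag for users who want strictly
positive p-values.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .models import EnrichmentResult, FamilyMetric

__all__ = ["spearman_rho", "subsample_null", "enrichment_test"]

DEFAULT_N_PERM = 10_000
_MAX_REDRAWS = 100


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (midranks for ties).

    Returns NaN (the null marker) when either side is constant; vectors
    shorter than 3 are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations for a rank correlation")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _rho_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho for matrices of draws (n_draws × k)."""
    rx = stats.rankdata(xs, axis=1)
    ry = stats.rankdata(ys, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / den
    return rho


def subsample_null(
    all_metrics: Sequence[FamilyMetric],
    k: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null distribution of rho over random size-k family subsamples.

    Each draw samples k families without replacement from the full eligible
    pool (expanded families included) and records spearman_rho(size,
    metric). Draws where either side comes out constant are redrawn a
    bounded number of times, then recorded as 0 with a warning.
    """
    pool = list(all_metrics)
    n = len(pool)
    if k > n:
        raise ValueError(f"subsample size {k} exceeds pool size {n}")
    if k < 3:
        raise ValueError("subsample size must be ≥ 3 for a rank correlation")
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = np.array([m.size for m in pool], dtype=float)
    metrics = np.array([m.metric for m in pool], dtype=float)

    if k == n:
        rho = _rho_rows(sizes[None, :], metrics[None, :])[0]
        if np.isnan(rho):
            warnings.warn("degenerate pool: constant side; null rho recorded as 0", stacklevel=2)
            rho = 0.0
        return np.full(n_perm, rho)

    idx = np.empty((n_perm, k), dtype=np.int64)
    for i in range(n_perm):
        idx[i] = rng.choice(n, size=k, replace=False)
    rho = _rho_rows(sizes[idx], metrics[idx])
    bad = np.isnan(rho)
    tries = 0
    while bad.any() and tries < _MAX_REDRAWS:
        redraw = np.empty((int(bad.sum()), k), dtype=np.int64)
        for i in range(redraw.shape[0]):
            redraw[i] = rng.choice(n, size=k, replace=False)
        rho[bad] = _rho_rows(sizes[redraw], metrics[redraw])
        bad = np.isnan(rho)
        tries += 1
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} null draws remained constant-sided after "
            f"{_MAX_REDRAWS} redraws; recorded as 0",
            stacklevel=2,
        )
        rho[bad] = 0.0
    return rho


def enrichment_test(
    focal_metrics: Sequence[FamilyMetric],
    all_metrics: Sequence[FamilyMetric],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    conservative_p: bool = False,
) -> EnrichmentResult:
    """Observed size–metric rho on the focal set against the subsample null.

    p_greater counts null draws with rho ≥ observed (ties included);
    p_less the mirror; p_two_sided = min(1, 2·min of the tails).
    ``conservative_p`` applies the (x+1)/(N+1) correction to both tails.
    Fold (rho_obs / null mean) is reported only when the null mean is
    positive.
    """
    focal = list(focal_metrics)
    if len(focal) < 3:
        raise ValueError("focal set must hold at least 3 families")
    pool_ids = {m.family_id for m in all_metrics}
    missing = [m.family_id for m in focal if m.family_id not in pool_ids]
    if missing:
        raise ValueError(f"focal families missing from pool: {missing[:5]}")
    rho_obs = spearman_rho([m.size for m in focal], [m.metric for m in focal])
    if np.isnan(rho_obs):
        raise ValueError("focal set has a constant side; observed rho undefined")
    null = subsample_null(all_metrics, k=len(focal), n_perm=n_perm, seed=seed)
    eps = 1e-12  # "or equal" must tolerate floating noise between rho routes
    n_ge = int(np.sum(null >= rho_obs - eps))
    n_le = int(np.sum(null <= rho_obs + eps))
    if conservative_p:
        p_greater = (n_ge + 1) / (n_perm + 1)
        p_less = (n_le + 1) / (n_perm + 1)
    else:
        p_greater = n_ge / n_perm
        p_less = n_le / n_perm
    p_two = min(1.0, 2.0 * min(p_greater, p_less))
    null_mean = float(np.mean(null))
    fold: Optional[float] = rho_obs / null_mean if null_mean > 0 else None
    return EnrichmentResult(
        rho_obs=float(rho_obs),
        null_rhos=null,
        null_mean=null_mean,
        null_sd=float(np.std(null, ddof=1)) if n_perm > 1 else 0.0,
        p_greater=float(p_greater),
        p_less=float(p_less),
        p_two_sided=float(p_two),
        n_perm=int(n_perm),
        subsample_size=len(focal),
        fold=fold,
    )
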