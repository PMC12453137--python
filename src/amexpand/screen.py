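"""Cross-species gene-family expansion screen.

For each orthogroup the per-species gene counts of AM-associating species
are compared against non-mycorrhizal species with a one-sided Mann–Whitney
U-test (alternative: AM stochastically larger), followed by
Benjamini–Hochberg correction over all tested families. A family is called
AM-expanded when its adjusted value clears the threshold *and* its AM
median exceeds its NM median — the median guard prevents tie artefacts
from flagging NM-larger families. A binomial enrichment helper quantifies
how over-represented a candidate gene set is among expanded families.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import (
    BinomialEnrichment,
    FamilySizeMatrix,
    MycStatus,
    ScreenResult,
    SpeciesRecord,
)

__all__ = [
    "mann_whitney_greater",
    "bh_adjust",
    "screen_expanded",
    "binomial_enrichment",
]


def mann_whitney_greater(
    am_sizes: Sequence[int], nm_sizes: Sequence[int], alternative: str = "greater"
) -> tuple[float, float]:
    """Mann–Whitney U-test of AM sizes against NM sizes.

    Returns (U, p) where U counts AM-over-NM wins (ties as ½). The exact
    null distribution is used for small tie-free samples
    (min(n1, n2) ≤ 8, no ties); otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    am = np.asarray(am_sizes, dtype=float)
    nm = np.asarray(nm_sizes, dtype=float)
    if am.size == 0 or nm.size == 0:
        raise ValueError("both groups must be non-empty")
    if (am < 0).any() or (nm < 0).any():
        raise ValueError("family sizes must be non-negative")
    pooled = np.concatenate([am, nm])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(am.size, nm.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(am, nm, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_expanded(
    matrix: FamilySizeMatrix,
    species: Sequence[SpeciesRecord],
    alpha: float = 0.05,
    alternative: str = "greater",
) -> list[ScreenResult]:
    """Run the per-family AM-vs-NM size screen with BH correction.

    Families with zero genes in every species are excluded before testing
    (and hence from the BH family). ``alternative='two-sided'`` is exposed
    for sensitivity analysis; the expansion call always additionally
    requires am_median > nm_median.
    """
    status = {s.species_id: s.status for s in species}
    missing = [sp for sp in matrix.species_ids if sp not in status]
    if missing:
        raise ValueError(f"species in matrix missing from species table: {missing}")
    am_cols = [sp for sp in matrix.species_ids if status[sp] is MycStatus.AM]
    nm_cols = [sp for sp in matrix.species_ids if status[sp] is MycStatus.NM]
    if len(am_cols) < 2 or len(nm_cols) < 2:
        raise ValueError("need at least 2 species per status group")

    counts = matrix.counts
    nonzero = counts.sum(axis=1) > 0
    tested = counts.loc[nonzero].sort_index()
    am = tested[am_cols].to_numpy(dtype=float)
    nm = tested[nm_cols].to_numpy(dtype=float)

    u_stats = np.empty(len(tested))
    p_raw = np.empty(len(tested))
    for i in range(len(tested)):
        u_stats[i], p_raw[i] = mann_whitney_greater(am[i], nm[i], alternative=alternative)
    q = bh_adjust(p_raw) if len(tested) else np.array([])
    am_median = np.median(am, axis=1) if len(tested) else np.array([])
    nm_median = np.median(nm, axis=1) if len(tested) else np.array([])

    results = [
        ScreenResult(
            family_id=fam,
            u_stat=float(u_stats[i]),
            p_raw=float(p_raw[i]),
            q=float(q[i]),
            am_median=float(am_median[i]),
            nm_median=float(nm_median[i]),
            expanded=bool(q[i] < alpha and am_median[i] > nm_median[i]),
        )
        for i, fam in enumerate(tested.index)
    ]
    # report in the matrix's original family order
    order = {fam: i for i, fam in enumerate(matrix.family_ids)}
    results.sort(key=lambda r: order[r.family_id])
    return results


def binomial_enrichment(k: int, n: int, baseline: float) -> BinomialEnrichment:
    """Fold enrichment of k/n successes over a baseline probability.

    ``fold = (k/n)/baseline``; ``p`` is the exact upper-tail binomial
    probability P(X ≥ k) under X ~ Binomial(n, baseline).
    """
    if not (0 < baseline < 1):
        raise ValueError(f"baseline must lie in (0, 1), got {baseline}")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 ≤ k ≤ n, got k={k}, n={n}")
    fold = (k / n) / baseline
    p = float(stats.binom.sf(k - 1, n, baseline))  # P(X ≥ k)
    return BinomialEnrichment(k=k, n=n, baseline=baseline, fold=fold, p=p)
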