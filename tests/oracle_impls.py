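"""Independent brute-force oracles used to validate the library's statistics.

Everything here is written from first principles (enumeration, hand-rolled
rank arithmetic) and deliberately shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bh_stepup_oracle(pvalues):
    """Benjamini–Hochberg step-up adjusted values, literal definition."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, val)
        q[i] = min(1.0, running_min)
    return q


def mwu_u_statistic(x, y):
    """U counting x-over-y wins, ties as one half."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mwu_enumeration_p(x, y):
    """One-sided (x greater) exact p by enumerating all label assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = mwu_u_statistic(x, y)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(comb)]
        if mwu_u_statistic(xs, ys) >= u_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Rank both sides with midranks, then Pearson by the textbook formula."""
    rx = midranks(list(x))
    ry = midranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def brute_force_dup_classifier(genes, blocks, proximal_max=20):
    """Classify duplication origin by enumerating all co-member distances.

    ``genes``: GeneRecord list with ranks and family_id set. ``blocks``:
    the collinear blocks (shared input; block finding is not re-derived).
    """
    block_genes = set()
    for b in blocks:
        block_genes |= b.gene_ids()
    by_fam = {}
    for g in genes:
        if g.family_id is not None:
            by_fam.setdefault(g.family_id, []).append(g)
    out = {}
    for g in genes:
        members = [m for m in by_fam.get(g.family_id, []) if m.gene_id != g.gene_id]
        if not members:
            out[g.gene_id] = "singleton"
            continue
        if g.gene_id in block_genes:
            out[g.gene_id] = "wgd"
            continue
        dists = [
            abs(m.rank - g.rank)
            for m in members
            if m.chromosome == g.chromosome
        ]
        if any(d == 1 for d in dists):
            out[g.gene_id] = "tandem"
        elif any(2 <= d <= proximal_max + 1 for d in dists):
            out[g.gene_id] = "proximal"
        else:
            out[g.gene_id] = "dispersed"
    return out
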