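"""Per-family fitness-associated SNP density.

SNPs are filtered on minor allele frequency and missingness (sites with
maf < 5% or with more than 10% of accessions missing are dropped; boundary
values survive), missing genotype calls can be imputed with the site's
modal allele, and each family's normalised SNP density is the number of
significantly trait-associated SNPs inside the family's gene bodies
divided by the family's concatenated gene length in bp. Association
significance is consumed as an input column (a q-value dichotomised at
0.05, or an explicit flag); the upstream association model is not part of
this package.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Optional, Sequence

from .models import GeneRecord, SnpDensityMetric, SnpRecord

__all__ = ["filter_snps", "impute_major_allele", "family_snp_density"]

MAF_MIN = 0.05
MISSING_MAX = 0.10
SIG_Q_THRESHOLD = 0.05


def filter_snps(
    snps: Sequence[SnpRecord],
    maf_min: float = MAF_MIN,
    missing_max: float = MISSING_MAX,
) -> list[SnpRecord]:
    """Keep SNPs with maf ≥ maf_min and missing_fraction ≤ missing_max.

    Records lacking the summaries but carrying genotypes have them computed
    on construction; a record with neither is an error.
    """
    kept = []
    for s in snps:
        if s.maf is None or s.missing_fraction is None:
            raise ValueError(f"SNP {s.snp_id}: no maf/missingness and no genotypes")
        if s.maf >= maf_min and s.missing_fraction <= missing_max:
            kept.append(s)
    return kept


def impute_major_allele(snps: Sequence[SnpRecord]) -> list[SnpRecord]:
    """Replace every missing genotype call with the site's modal allele.

    Ties between equally common alleles break to the allele that sorts
    first (deterministic). maf and missing_fraction are recomputed. A site
    with all calls missing cannot be imputed and is an error.
    """
    out = []
    for s in snps:
        if s.genotypes is None:
            raise ValueError(f"SNP {s.snp_id}: genotypes required for imputation")
        calls = [g for g in s.genotypes if g is not None and g != "."]
        if not calls:
            raise ValueError(f"SNP {s.snp_id}: all calls missing, cannot impute")
        counts = Counter(calls)
        top = max(counts.values())
        modal = min(a for a, c in counts.items() if c == top)
        filled = [modal if (g is None or g == ".") else g for g in s.genotypes]
        out.append(
            SnpRecord(
                snp_id=s.snp_id,
                chromosome=s.chromosome,
                position=s.position,
                genotypes=filled,
                assoc_q=s.assoc_q,
                significant=s.significant,
            )
        )
    return out


def family_snp_density(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneRecord],
    gene_to_family: Optional[dict[str, str]] = None,
    q_threshold: float = SIG_Q_THRESHOLD,
) -> list[SnpDensityMetric]:
    """Normalised significant-SNP density per family.

    A SNP belongs to a gene when chromosomes match and
    start ≤ position ≤ end (1-based closed, as in GFF3). A SNP overlapping
    genes of several families counts once per family. The metric is
    n_sig_snps / summed gene-body length; families with ≥1 focal-species
    gene are reported, including zero-density ones.
    """
    by_fam: dict[str, list[GeneRecord]] = {}
    genes_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        fam = g.family_id if g.family_id is not None else (
            gene_to_family.get(g.gene_id) if gene_to_family else None
        )
        if fam is None:
            continue
        by_fam.setdefault(fam, []).append(g)
        genes_by_chrom.setdefault(g.chromosome, []).append((g.start, g.end, fam))
    max_len: dict[str, int] = {}
    for chrom in genes_by_chrom:
        genes_by_chrom[chrom].sort()
        max_len[chrom] = max(e - s + 1 for s, e, _ in genes_by_chrom[chrom])

    n_sig: dict[str, int] = {fam: 0 for fam in by_fam}
    warned: set[str] = set()
    import bisect

    for s in snps:
        if not s.is_significant(q_threshold):
            continue
        intervals = genes_by_chrom.get(s.chromosome)
        if intervals is None:
            if s.chromosome not in warned:
                warnings.warn(
                    f"SNP chromosome {s.chromosome!r} absent from annotation; ignoring",
                    stacklevel=2,
                )
                warned.add(s.chromosome)
            continue
        # genes may overlap, so scan back through intervals whose start is
        # ≤ position until no gene could be long enough to reach it
        hit_fams: set[str] = set()
        i = bisect.bisect_right(intervals, (s.position, float("inf"), ""))
        for start, end, fam in reversed(intervals[:i]):
            if end >= s.position:
                hit_fams.add(fam)
            elif s.position - start >= max_len[s.chromosome]:
                break
        for fam in hit_fams:
            n_sig[fam] += 1

    metrics = []
    for fam in sorted(by_fam):
        members = by_fam[fam]
        concat = sum(g.length for g in members)
        metrics.append(
            SnpDensityMetric(
                family_id=fam,
                size=len(members),
                concat_length=concat,
                n_sig_snps=n_sig[fam],
                metric=n_sig[fam] / concat,
            )
        )
    return metrics
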