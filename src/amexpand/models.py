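"""Domain types shared across the pipeline.

The pipeline links three per-family quantities — size across species,
context-dependent expression, and fitness-associated SNP density — so the
types here are deliberately small, explicit containers rather than ad-hoc
dicts: a family-size matrix (families × species), positioned gene records
for one focal species, a 2×2 factorial expression experiment, SNP records,
and the result rows each analysis stage emits.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MycStatus",
    "SpeciesRecord",
    "FamilySizeMatrix",
    "GeneRecord",
    "ExpressionExperiment",
    "SnpRecord",
    "ScreenResult",
    "BinomialEnrichment",
    "InteractionTestResult",
    "FamilyMetric",
    "SnpDensityMetric",
    "EnrichmentResult",
    "AnchorPair",
    "CollinearBlock",
    "DupClass",
    "DuplicationCall",
    "DupEnrichmentResult",
]


class MycStatus(str, enum.Enum):
    """Mycorrhizal status of a plant species: AM-associating or non-mycorrhizal."""

    AM = "AM"
    NM = "NM"


@dataclass(frozen=True)
class SpeciesRecord:
    species_id: str
    status: MycStatus

    def __post_init__(self) -> None:
        if not isinstance(self.status, MycStatus):
            object.__setattr__(self, "status", MycStatus(self.status))


@dataclass
class FamilySizeMatrix:
    """Orthogroup × species table of per-species gene counts.

    ``counts`` is an integer DataFrame whose index holds orthogroup IDs and
    whose columns hold species IDs. Counts are gene numbers, hence ≥ 0.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate family IDs: {dups}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate species columns")
        arr = self.counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("family sizes must be integers")
            self.counts = self.counts.astype(int)
        if arr.size and (self.counts.to_numpy() < 0).any():
            raise ValueError("family sizes must be non-negative")

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_families(self) -> int:
        return self.counts.shape[0]


@dataclass
class GeneRecord:
    """A positioned gene of the focal species (GFF3 1-based inclusive coordinates)."""

    gene_id: str
    species_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    family_id: Optional[str] = None
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        """Gene-body length in bp (1-based inclusive: end − start + 1)."""
        return self.end - self.start + 1


@dataclass
class ExpressionExperiment:
    """A 2×2 factorial RNA-seq count experiment (±mycorrhizae, ±stressor).

    ``counts``: non-negative integer DataFrame, genes × samples.
    ``design``: DataFrame indexed by sample with integer columns ``myc`` and
    ``stress`` in {0, 1}. Columns of ``counts`` and rows of ``design`` are
    kept in the same (sorted) sample order.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.counts.columns) != set(self.design.index):
            missing = set(self.counts.columns) ^ set(self.design.index)
            raise ValueError(f"samples mismatch between counts and design: {missing}")
        order = sorted(self.design.index)
        self.design = self.design.loc[order, ["myc", "stress"]].astype(int)
        self.counts = self.counts.loc[:, order]
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        bad = ~self.design[["myc", "stress"]].isin([0, 1]).all(axis=1)
        if bad.any():
            raise ValueError(f"design factors must be 0/1; bad samples: {list(self.design.index[bad])}")

    @property
    def cells(self) -> pd.Series:
        """Per-sample design cell label 'myc:stress'."""
        return self.design["myc"].astype(str) + ":" + self.design["stress"].astype(str)

    def require_full_factorial(self) -> None:
        present = set(zip(self.design["myc"], self.design["stress"]))
        needed = {(0, 0), (0, 1), (1, 0), (1, 1)}
        if present != needed:
            raise ValueError(
                f"incomplete factorial: missing design cells {sorted(needed - present)}"
            )


@dataclass
class SnpRecord:
    """One SNP with frequency/missingness summaries and association evidence.

    Either genotypes (list of allele tokens, ``None``/'.' for missing) or the
    (maf, missing_fraction) summary must be available. Association evidence
    is a q-value and/or a boolean significance flag.
    """

    snp_id: str
    chromosome: str
    position: int
    genotypes: Optional[list[Optional[str]]] = None
    maf: Optional[float] = None
    missing_fraction: Optional[float] = None
    assoc_q: Optional[float] = None
    significant: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be ≥ 1")
        if self.genotypes is not None and (self.maf is None or self.missing_fraction is None):
            self._summarise_genotypes()
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"SNP {self.snp_id}: maf {self.maf} outside [0, 0.5]")
        if self.missing_fraction is not None and not (0.0 <= self.missing_fraction <= 1.0):
            raise ValueError(
                f"SNP {self.snp_id}: missing_fraction {self.missing_fraction} outside [0, 1]"
            )
        if self.assoc_q is not None and not (0.0 <= self.assoc_q <= 1.0):
            raise ValueError(f"SNP {self.snp_id}: assoc_q outside [0, 1]")

    def _summarise_genotypes(self) -> None:
        calls = [g for g in self.genotypes if g is not None and g != "."]
        n = len(self.genotypes)
        self.missing_fraction = (n - len(calls)) / n if n else 0.0
        if calls:
            vals, counts = np.unique(calls, return_counts=True)
            if len(vals) == 1:
                self.maf = 0.0
            else:
                minor = counts.sum() - counts.max()
                self.maf = float(minor / counts.sum())
        else:
            self.maf = 0.0

    def is_significant(self, q_threshold: float = 0.05) -> bool:
        if self.significant is not None:
            return bool(self.significant)
        if self.assoc_q is not None:
            return self.assoc_q < q_threshold
        return False


@dataclass
class ScreenResult:
    """Per-family outcome of the AM-vs-NM size screen."""

    family_id: str
    u_stat: float
    p_raw: float
    q: float
    am_median: float
    nm_median: float
    expanded: bool


@dataclass
class BinomialEnrichment:
    """Fold enrichment of k/n successes over a baseline rate, with exact upper-tail p."""

    k: int
    n: int
    baseline: float
    fold: float
    p: float


@dataclass
class InteractionTestResult:
    """Per-gene mycorrhizae × stressor interaction likelihood-ratio test."""

    gene_id: str
    llr: Optional[float]
    p: Optional[float]
    q: Optional[float]
    significant: bool
    dispersion: float
    df: int = 1
    converged: bool = True


@dataclass
class FamilyMetric:
    """Per-family (size, metric) pair — the substrate of the permutation engine."""

    family_id: str
    size: int
    metric: float
    n_tested: int = 0


@dataclass
class SnpDensityMetric:
    """Per-family normalised significant-SNP density over concatenated gene bodies."""

    family_id: str
    size: int
    concat_length: int
    n_sig_snps: int
    metric: float

    def as_family_metric(self) -> FamilyMetric:
        return FamilyMetric(
            family_id=self.family_id,
            size=self.size,
            metric=self.metric,
            n_tested=self.n_sig_snps,
        )


@dataclass
class EnrichmentResult:
    """Observed Spearman ρ against a subsample null distribution."""

    rho_obs: float
    null_rhos: np.ndarray
    null_mean: float
    null_sd: float
    p_greater: float
    p_less: float
    p_two_sided: float
    n_perm: int
    subsample_size: int
    fold: Optional[float] = None

    def __post_init__(self) -> None:
        self.null_rhos = np.asarray(self.null_rhos, dtype=float)
        for name in ("p_greater", "p_less", "p_two_sided"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) and not math.isnan(v):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class AnchorPair:
    """An unordered within-species pair of genes sharing a family (stored canonically)."""

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("anchor pair must join two distinct genes")


class DupClass(str, enum.Enum):
    """Duplication-origin class, in increasing classification priority order."""

    SINGLETON = "singleton"
    DISPERSED = "dispersed"
    PROXIMAL = "proximal"
    TANDEM = "tandem"
    WGD = "wgd"


#: Priority used when a gene qualifies for several classes.
DUP_PRIORITY: tuple[DupClass, ...] = (
    DupClass.WGD,
    DupClass.TANDEM,
    DupClass.PROXIMAL,
    DupClass.DISPERSED,
    DupClass.SINGLETON,
)


@dataclass
class CollinearBlock:
    """A chain of anchor pairs with conserved (same or inverted) gene order."""

    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[AnchorPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def gene_ids(self) -> set[str]:
        out: set[str] = set()
        for a in self.anchors:
            out.add(a.gene_a)
            out.add(a.gene_b)
        return out


@dataclass
class DuplicationCall:
    gene_id: str
    dup_class: DupClass


@dataclass
class DupEnrichmentResult:
    """Per-species, per-class enrichment of duplication origins in a focal family set."""

    species_id: str
    dup_class: DupClass
    prop_obs: float
    null_mean: float
    fold: Optional[float]
    p_two_sided: float
    q: Optional[float] = None


def genes_by_family(
    genes: Sequence[GeneRecord], gene_to_family: Optional[dict[str, str]] = None
) -> dict[str, list[GeneRecord]]:
    """Group gene records by family, using the map when a record lacks family_id."""
    out: dict[str, list[GeneRecord]] = {}
    for g in genes:
        fam = g.family_id
        if fam is None and gene_to_family is not None:
            fam = gene_to_family.get(g.gene_id)
        if fam is None:
            continue
        out.setdefault(fam, []).append(g)
    return out
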