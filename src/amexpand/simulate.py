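"""Synthetic pipeline inputs with known ground truth.

The generator emulates the study design end to end: a family-size matrix
over 32 AM and 10 NM species in which ~1.5% of families are planted as
AM-expanded; a focal-species genome whose expanded families are laid out
as tandem arrays, proximal runs, duplicated collinear segments or
dispersed copies with known class labels; a 2×2 factorial expression
experiment in which the probability of a true mycorrhizae × stressor
interaction increases with family size inside expanded families; and a
SNP table whose per-SNP significance probability likewise increases with
family size. Every stage draws from a generator spawned off one root
seed, so one seed reproduces every emitted file byte-identically. Null
switches turn each planted effect off for calibration suites.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as amio
from .models import (
    DupClass,
    ExpressionExperiment,
    FamilySizeMatrix,
    GeneRecord,
    MycStatus,
    SnpRecord,
    SpeciesRecord,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "species_records",
    "simulate_family_sizes",
    "simulate_genome",
    "simulate_expression",
    "simulate_snps",
    "simulate_dataset",
]

# fixed per-stage RNG stream tags, so each stage is independently reproducible
_STREAM_SIZES = 1
_STREAM_GENOME = 2
_STREAM_EXPRESSION = 3
_STREAM_SNPS = 4


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the study conditions."""

    seed: int = 0
    # family-size screen substrate
    n_am: int = 32
    n_nm: int = 10
    n_families: int = 2000
    frac_expanded: float = 0.015
    size_mean_expanded_am: float = 8.0
    size_mean_expanded_nm: float = 2.0
    size_mean_background: float = 3.0
    size_dispersion: float = 1.0  # variance-to-mean ratio; 1.0 = Poisson-like
    # focal genome layout
    n_chromosomes: int = 5
    tandem_prob_expanded: float = 0.5
    tandem_prob_background: float = 0.05
    proximal_prob_expanded: float = 0.2
    proximal_prob_background: float = 0.05
    n_segmental_blocks: int = 3
    segmental_block_length: int = 10
    gene_length: int = 1000
    intergenic_length: int = 200
    proximal_max: int = 20
    # factorial expression experiment
    expr_baseline_mean: float = 100.0
    expr_dispersion: float = 0.1
    reps_per_cell: int = 3
    interaction_effect: float = math.log(8.0)
    interaction_logit_intercept: float = -3.5
    interaction_logit_slope: float = 0.55
    interaction_background_prob: float = 0.02
    # SNP table
    snp_spacing: int = 100
    snp_intergenic_frac: float = 0.10
    snp_sig_logit_intercept: float = -3.0
    snp_sig_logit_slope: float = 0.35
    snp_sig_background_prob: float = 0.05
    # null switches (calibration modes: planted effects off)
    null_expansion: bool = False
    null_interaction: bool = False
    null_snp: bool = False

    def __post_init__(self) -> None:
        for name in (
            "frac_expanded",
            "tandem_prob_expanded",
            "tandem_prob_background",
            "proximal_prob_expanded",
            "proximal_prob_background",
            "snp_intergenic_frac",
            "interaction_background_prob",
            "snp_sig_background_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_am", "n_nm", "n_families", "n_chromosomes", "reps_per_cell",
                     "gene_length", "snp_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted effects, recorded while generating so every stage is testable."""

    expanded_family_ids: list[str] = field(default_factory=list)
    dup_class: dict[str, str] = field(default_factory=dict)  # gene -> class value
    interaction: dict[str, bool] = field(default_factory=dict)  # gene -> beta3 != 0
    snp_significant: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "expanded_family_ids": self.expanded_family_ids,
                    "dup_class": self.dup_class,
                    "interaction": self.interaction,
                    "snp_significant": self.snp_significant,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            expanded_family_ids=list(d["expanded_family_ids"]),
            dup_class=dict(d["dup_class"]),
            interaction={k: bool(v) for k, v in d["interaction"].items()},
            snp_significant={k: bool(v) for k, v in d["snp_significant"].items()},
        )


def species_records(config: SyntheticConfig) -> list[SpeciesRecord]:
    am = [SpeciesRecord(f"AM{i + 1:02d}", MycStatus.AM) for i in range(config.n_am)]
    nm = [SpeciesRecord(f"NM{i + 1:02d}", MycStatus.NM) for i in range(config.n_nm)]
    return am + nm


def focal_species_id(config: SyntheticConfig) -> str:
    """The focal species (genome, expression, SNPs) is the first AM species."""
    return "AM01"


def _nb_draw(rng: np.random.Generator, mean: float, vmr: float, size) -> np.ndarray:
    """Count draws with variance-to-mean ratio ``vmr``: Poisson at 1,
    negative binomial (r = m/(vmr−1)) above 1."""
    if vmr <= 1.0:
        return rng.poisson(mean, size=size)
    r = mean / (vmr - 1.0)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_family_sizes(
    config: SyntheticConfig,
) -> tuple[FamilySizeMatrix, GroundTruth]:
    """Family-size matrix with ~frac_expanded families planted as AM-expanded.

    Background families draw sizes i.i.d. NB across all species; expanded
    families draw AM columns from the high-mean NB and NM columns from the
    low-mean NB.
    """
    rng = config.rng(_STREAM_SIZES)
    species = species_records(config)
    n_sp = len(species)
    fam_ids = [f"OG{i:07d}" for i in range(config.n_families)]
    n_exp = 0 if config.null_expansion else int(round(config.frac_expanded * config.n_families))
    if not config.null_expansion and n_exp < 1:
        raise ValueError("frac_expanded · n_families < 1: no expanded family to plant")
    expanded_idx = rng.choice(config.n_families, size=n_exp, replace=False)
    is_exp = np.zeros(config.n_families, dtype=bool)
    is_exp[expanded_idx] = True

    counts = _nb_draw(
        rng, config.size_mean_background, config.size_dispersion,
        (config.n_families, n_sp),
    ).astype(int)
    am_cols = np.array([s.status is MycStatus.AM for s in species])
    if n_exp:
        counts[np.ix_(is_exp, am_cols)] = _nb_draw(
            rng, config.size_mean_expanded_am, config.size_dispersion,
            (n_exp, int(am_cols.sum())),
        )
        counts[np.ix_(is_exp, ~am_cols)] = _nb_draw(
            rng, config.size_mean_expanded_nm, config.size_dispersion,
            (n_exp, int((~am_cols).sum())),
        )
    matrix = FamilySizeMatrix(
        counts=pd.DataFrame(counts, index=fam_ids, columns=[s.species_id for s in species])
    )
    truth = GroundTruth(expanded_family_ids=sorted(np.array(fam_ids)[is_exp].tolist()))
    return matrix, truth


# ---------------------------------------------------------------------------
# focal genome
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SyntheticConfig,
    matrix: FamilySizeMatrix,
    truth: GroundTruth,
) -> list[GeneRecord]:
    """Lay out the focal species' genes with planted duplication classes.

    Multi-copy families become tandem arrays, proximal runs (1–20 filler
    genes between copies), anchors of duplicated collinear segments, or
    dispersed copies on distinct chromosomes; the planted class of every
    gene is recorded in ``truth.dup_class``. Single-copy families are
    singletons and double as proximal filler material.
    """
    rng = config.rng(_STREAM_GENOME)
    focal = focal_species_id(config)
    if focal not in matrix.species_ids:
        raise ValueError(f"focal species {focal} absent from matrix")
    counts = matrix.counts[focal]
    expanded = set(truth.expanded_family_ids)
    fams = list(matrix.family_ids)

    gene_counter = 0

    def new_gene(fam: str) -> str:
        nonlocal gene_counter
        gid = f"{focal}_g{gene_counter:05d}"
        gene_counter += 1
        truth_fam[gid] = fam
        return gid

    truth_fam: dict[str, str] = {}

    multi = [f for f in fams if counts[f] >= 2]
    single = [f for f in fams if counts[f] == 1]

    # segmental blocks come from background multi-copy families so expanded
    # families keep their exact tandem/proximal/dispersed mix
    bg_multi = [f for f in multi if f not in expanded]
    n_block_fams = config.n_segmental_blocks * config.segmental_block_length
    if len(bg_multi) < n_block_fams:
        raise ValueError("not enough multi-copy background families for segmental blocks")
    block_fams = list(rng.choice(bg_multi, size=n_block_fams, replace=False))
    block_set = set(block_fams)

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    # per-chromosome: atomic units (lists of (gene_id, class)) and loose singles
    units: dict[str, list[list[tuple[str, str]]]] = {c: [] for c in chroms}
    singles: dict[str, list[tuple[str, str]]] = {c: [] for c in chroms}
    proximal_units: list[tuple[list[str], list[int]]] = []  # (gene_ids, gaps)

    # 1. segmental blocks: two same-order copies on two distinct chromosomes
    for b in range(config.n_segmental_blocks):
        fams_b = block_fams[
            b * config.segmental_block_length : (b + 1) * config.segmental_block_length
        ]
        ca, cb = rng.choice(len(chroms), size=2, replace=False)
        copy_a, copy_b = [], []
        for f in fams_b:
            g1, g2 = new_gene(f), new_gene(f)
            truth.dup_class[g1] = DupClass.WGD.value
            truth.dup_class[g2] = DupClass.WGD.value
            copy_a.append((g1, DupClass.WGD.value))
            copy_b.append((g2, DupClass.WGD.value))
            for _ in range(int(counts[f]) - 2):
                ge = new_gene(f)
                truth.dup_class[ge] = DupClass.DISPERSED.value
                singles[chroms[int(rng.integers(len(chroms)))]].append(
                    (ge, DupClass.DISPERSED.value)
                )
        units[chroms[ca]].append(copy_a)
        units[chroms[cb]].append(copy_b)

    # 2. tandem / proximal / dispersed for the remaining multi-copy families
    for f in multi:
        if f in block_set:
            continue
        c = int(counts[f])
        if f in expanded:
            pt, pp = config.tandem_prob_expanded, config.proximal_prob_expanded
        else:
            pt, pp = config.tandem_prob_background, config.proximal_prob_background
        u = rng.random()
        if u < pt:
            cls = DupClass.TANDEM
        elif u < pt + pp:
            cls = DupClass.PROXIMAL
        else:
            cls = DupClass.DISPERSED
        gids = [new_gene(f) for _ in range(c)]
        for g in gids:
            truth.dup_class[g] = cls.value
        if cls is DupClass.TANDEM:
            chrom = chroms[int(rng.integers(len(chroms)))]
            units[chrom].append([(g, cls.value) for g in gids])
        elif cls is DupClass.PROXIMAL:
            gaps = [int(rng.integers(1, config.proximal_max + 1)) for _ in range(c - 1)]
            proximal_units.append((gids, gaps))
        else:
            offset = int(rng.integers(len(chroms)))
            perm = rng.permutation(len(chroms))
            for i, g in enumerate(gids):
                chrom = chroms[perm[(offset + i) % len(chroms)]]
                singles[chrom].append((g, cls.value))

    # 3. singleton families: loose singles, also the proximal filler pool
    for f in single:
        g = new_gene(f)
        truth.dup_class[g] = DupClass.SINGLETON.value
        singles[chroms[int(rng.integers(len(chroms)))]].append((g, DupClass.SINGLETON.value))

    # 4. weave proximal runs, consuming singles as the intervening genes;
    # shuffle the filler pools first, otherwise fillers keep the family
    # generation order and co-members form artificial diagonals across
    # chromosomes
    for chrom in chroms:
        idx = rng.permutation(len(singles[chrom]))
        singles[chrom] = [singles[chrom][i] for i in idx]
    for gids, gaps in proximal_units:
        chrom = max(chroms, key=lambda c: len(singles[c]))
        avail = len(singles[chrom])
        if avail < len(gaps):  # cannot even place one filler per gap
            raise ValueError(
                "chromosome capacity exceeded while planting proximal duplicates; "
                "increase n_chromosomes or n_families"
            )
        if avail < sum(gaps):
            # small genomes: shrink gaps (still ≥1 intervening gene, so the
            # planted class stays proximal) to fit the filler pool
            spare = avail - len(gaps)
            shrunk = []
            for g in gaps:
                extra = min(g - 1, spare)
                shrunk.append(1 + extra)
                spare -= extra
            gaps = shrunk
        woven: list[tuple[str, str]] = [(gids[0], DupClass.PROXIMAL.value)]
        for g, gap in zip(gids[1:], gaps):
            for _ in range(gap):
                woven.append(singles[chrom].pop())
            woven.append((g, DupClass.PROXIMAL.value))
        units[chrom].append(woven)

    # 5. shuffle unit order per chromosome and assign coordinates
    genes: list[GeneRecord] = []
    for chrom in chroms:
        all_units = units[chrom] + [[s] for s in singles[chrom]]
        perm = rng.permutation(len(all_units))
        flat: list[tuple[str, str]] = []
        for i in perm:
            flat.extend(all_units[i])
        pos = 1
        for gid, _cls in flat:
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    species_id=focal,
                    chromosome=chrom,
                    start=pos,
                    end=pos + config.gene_length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    family_id=truth_fam[gid],
                )
            )
            pos += config.gene_length + config.intergenic_length
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return genes


# ---------------------------------------------------------------------------
# factorial expression experiment
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SyntheticConfig,
    genes: list[GeneRecord],
    truth: GroundTruth,
    family_sizes: Optional[dict[str, int]] = None,
) -> ExpressionExperiment:
    """NB counts for a 2×2 factorial with size-dependent planted interactions.

    log-mean = b0 + b1·myc + b2·stress + b3·myc·stress (+ log library
    factor); b3 = ±log 4 with probability logistic in the focal-species
    family size for genes of expanded families, a small constant
    probability elsewhere, and 0 everywhere under the null switch.
    """
    rng = config.rng(_STREAM_EXPRESSION)
    if family_sizes is None:
        family_sizes = {}
        for g in genes:
            if g.family_id is not None:
                family_sizes[g.family_id] = family_sizes.get(g.family_id, 0) + 1
    expanded = set(truth.expanded_family_ids)

    design_rows = []
    for myc in (0, 1):
        for stress in (0, 1):
            for r in range(config.reps_per_cell):
                design_rows.append((f"m{myc}s{stress}_r{r + 1}", myc, stress))
    design = pd.DataFrame(design_rows, columns=["sample", "myc", "stress"]).set_index("sample")
    myc = design["myc"].to_numpy(float)
    stress = design["stress"].to_numpy(float)
    lib = np.exp(rng.normal(0.0, 0.2, size=len(design)))  # uneven library sizes

    n = len(genes)
    b0 = np.log(config.expr_baseline_mean) + rng.normal(0.0, 0.3, size=n)
    b1 = rng.normal(0.0, 0.3, size=n)
    b2 = rng.normal(0.0, 0.3, size=n)
    b3 = np.zeros(n)
    for i, g in enumerate(genes):
        fam = g.family_id
        if config.null_interaction:
            p_eff = 0.0
        elif fam in expanded:
            z = config.interaction_logit_intercept + config.interaction_logit_slope * family_sizes.get(fam, 1)
            p_eff = 1.0 / (1.0 + math.exp(-z))
        else:
            p_eff = config.interaction_background_prob
        flag = bool(rng.random() < p_eff)
        truth.interaction[g.gene_id] = flag
        if flag:
            b3[i] = config.interaction_effect * (1 if rng.random() < 0.5 else -1)

    log_mu = (
        b0[:, None]
        + b1[:, None] * myc[None, :]
        + b2[:, None] * stress[None, :]
        + b3[:, None] * (myc * stress)[None, :]
        + np.log(lib)[None, :]
    )
    mu = np.exp(log_mu)
    r = 1.0 / config.expr_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=[g.gene_id for g in genes], columns=design.index)
    return ExpressionExperiment(counts=counts_df, design=design)


# ---------------------------------------------------------------------------
# SNP table
# ---------------------------------------------------------------------------

def simulate_snps(
    config: SyntheticConfig,
    genes: list[GeneRecord],
    truth: GroundTruth,
    family_sizes: Optional[dict[str, int]] = None,
) -> list[SnpRecord]:
    """SNPs every ~spacing bp in gene bodies plus ~10% intergenic ones.

    maf ~ U(0.01, 0.5) and missing_fraction ~ U(0, 0.2), so the standard
    filters have work to do. Significance is Bernoulli with a logit linear
    in family size for expanded-family genes, constant elsewhere (and for
    intergenic SNPs), all off under the null switch.
    """
    rng = config.rng(_STREAM_SNPS)
    if family_sizes is None:
        family_sizes = {}
        for g in genes:
            if g.family_id is not None:
                family_sizes[g.family_id] = family_sizes.get(g.family_id, 0) + 1
    expanded = set(truth.expanded_family_ids)

    chrom_list, pos_list, p_sig = [], [], []
    for g in genes:
        offs = np.arange(config.snp_spacing // 2, g.length, config.snp_spacing)
        if config.null_snp or g.family_id not in expanded:
            p = config.snp_sig_background_prob
        else:
            z = config.snp_sig_logit_intercept + config.snp_sig_logit_slope * family_sizes.get(g.family_id, 1)
            p = 1.0 / (1.0 + math.exp(-z))
        for off in offs:
            chrom_list.append(g.chromosome)
            pos_list.append(g.start + int(off))
            p_sig.append(p)
    n_genic = len(pos_list)
    n_inter = int(round(config.snp_intergenic_frac * n_genic))
    if n_inter and config.intergenic_length > 1:
        pick = rng.integers(0, len(genes), size=n_inter)
        for i in pick:
            g = genes[i]
            chrom_list.append(g.chromosome)
            pos_list.append(g.end + int(rng.integers(1, config.intergenic_length)))
            p_sig.append(config.snp_sig_background_prob)

    n = len(pos_list)
    maf = rng.uniform(0.01, 0.5, size=n)
    missing = rng.uniform(0.0, 0.2, size=n)
    sig = rng.random(n) < np.asarray(p_sig)
    snps = []
    for i in range(n):
        sid = f"s{i:06d}"
        truth.snp_significant[sid] = bool(sig[i])
        snps.append(
            SnpRecord(
                snp_id=sid,
                chromosome=chrom_list[i],
                position=int(pos_list[i]),
                maf=float(maf[i]),
                missing_fraction=float(missing[i]),
                significant=bool(sig[i]),
            )
        )
    return snps


# ---------------------------------------------------------------------------
# whole dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    species: list[SpeciesRecord]
    matrix: FamilySizeMatrix
    genes: list[GeneRecord]
    experiment: ExpressionExperiment
    snps: list[SnpRecord]
    truth: GroundTruth

    @property
    def gene_to_family(self) -> dict[str, str]:
        return {g.gene_id: g.family_id for g in self.genes if g.family_id is not None}


def simulate_dataset(
    config: SyntheticConfig, outdir: Optional[str | Path] = None
) -> SyntheticDataset:
    """Generate every pipeline input; optionally write them all to ``outdir``.

    Files written: species.tsv, orthogroups.tsv (membership dialect),
    genome.gff3, counts.tsv, design.tsv, snps.tsv, truth.json.
    """
    species = species_records(config)
    matrix, truth = simulate_family_sizes(config)
    genes = simulate_genome(config, matrix, truth)
    focal_sizes: dict[str, int] = {}
    for g in genes:
        focal_sizes[g.family_id] = focal_sizes.get(g.family_id, 0) + 1
    experiment = simulate_expression(config, genes, truth, focal_sizes)
    snps = simulate_snps(config, genes, truth, focal_sizes)
    ds = SyntheticDataset(
        config=config, species=species, matrix=matrix, genes=genes,
        experiment=experiment, snps=snps, truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        amio.write_species_table(species, outdir / "species.tsv")
        _write_membership(ds, outdir / "orthogroups.tsv")
        amio.write_gff3(genes, outdir / "genome.gff3")
        amio.write_counts_and_design(
            experiment, outdir / "counts.tsv", outdir / "design.tsv"
        )
        amio.write_snp_table(snps, outdir / "snps.tsv")
        truth.to_json(outdir / "truth.json")
        with open(outdir / "config.json", "w") as fh:
            json.dump(asdict(config), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return ds


def _write_membership(ds: SyntheticDataset, path: Path) -> None:
    """Membership table: real gene IDs for the focal species, synthesised
    IDs for the rest (their identities never matter downstream)."""
    focal = focal_species_id(ds.config)
    by_fam_focal: dict[str, list[str]] = {}
    for g in ds.genes:
        by_fam_focal.setdefault(g.family_id, []).append(g.gene_id)
    families: dict[str, dict[str, list[str]]] = {}
    for fam in ds.matrix.family_ids:
        row = ds.matrix.counts.loc[fam]
        cell: dict[str, list[str]] = {}
        for sp in ds.matrix.species_ids:
            if sp == focal:
                cell[sp] = sorted(by_fam_focal.get(fam, []))
            else:
                cell[sp] = [f"{sp}_{fam}_{j}" for j in range(int(row[sp]))]
        families[fam] = cell
    amio.write_orthogroup_membership(families, ds.matrix.species_ids, path)
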