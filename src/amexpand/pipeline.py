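"""Pipeline orchestration: run stages in dependency order, write a run report.

Stages: ``screen`` (AM/NM expansion screen), ``ctx`` (context-dependent
expression + enrichment), ``snp`` (SNP density + enrichment), ``dup``
(duplication classification + enrichment). The three downstream stages
need the screen's expanded-family set and will load it from a previous
run's output if the screen is not part of the requested stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as amio
from .duplication import (
    assign_gene_ranks,
    classify_duplications,
    dup_enrichment,
    family_pairs,
    find_collinear_blocks,
)
from .enrichment import enrichment_test
from .expression import family_context_proportion, run_interaction_tests
from .models import FamilyMetric
from .screen import screen_expanded
from .snp_density import family_snp_density, filter_snps

logger = logging.getLogger(__name__)

ALL_STAGES = ("screen", "ctx", "snp", "dup")

# fixed per-stage RNG stream tags derived from the root seed
_STAGE_STREAMS = {"ctx": 11, "snp": 12, "dup": 13}


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for one pipeline run.

    A flat JSON config file may supply any of these; CLI flags override the
    config, and the config overrides the defaults.
    """

    species_path: Optional[str] = None
    orthogroups_path: Optional[str] = None
    orthogroups_format: str = "membership"
    gff_path: Optional[str] = None
    counts_path: Optional[str] = None
    design_path: Optional[str] = None
    snps_path: Optional[str] = None
    snps_format: str = "tsv"
    outdir: str = "results"
    alpha: float = 0.05
    fdr: float = 0.05
    n_perm: int = 10_000
    min_anchors: int = 5
    max_gap: int = 25
    proximal_max: int = 20
    maf_min: float = 0.05
    missing_max: float = 0.10
    size_mode: str = "focal"
    conservative_p: bool = False
    focal_species: str = "AM01"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr", "maf_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be ≥ 100")
        if self.size_mode not in ("focal", "total"):
            raise ValueError("size_mode must be 'focal' or 'total'")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE_STREAMS[stage]])


def _apply_size_mode(
    metrics: list[FamilyMetric], config: RunConfig, matrix
) -> list[FamilyMetric]:
    if config.size_mode == "focal":
        return metrics
    totals = matrix.counts.sum(axis=1)
    return [
        FamilyMetric(
            family_id=m.family_id,
            size=int(totals[m.family_id]),
            metric=m.metric,
            n_tested=m.n_tested,
        )
        for m in metrics
    ]


def _enrichment_payload(res) -> dict:
    return {
        "rho_obs": res.rho_obs,
        "null_mean": res.null_mean,
        "null_sd": res.null_sd,
        "p_greater": res.p_greater,
        "p_less": res.p_less,
        "p_two_sided": res.p_two_sided,
        "n_perm": res.n_perm,
        "subsample_size": res.subsample_size,
        "fold": res.fold,
    }


def run_pipeline(config: RunConfig, stages: Sequence[str] = ALL_STAGES) -> dict:
    """Run the requested stages in dependency order; return the JSON report.

    The report records every parameter, the seed, library versions and
    per-stage headline numbers. It is also written to ``<outdir>/report.json``.
    Timestamps are deliberately omitted so identical config + seed give a
    byte-identical report.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in ALL_STAGES if s in set(stages)]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    import scipy
    import pandas as pd

    report: dict = {
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }

    if config.orthogroups_path is None:
        raise ValueError("orthogroups_path is required")
    matrix, gene_map = amio.read_orthogroups(
        config.orthogroups_path, format=config.orthogroups_format
    )

    screen_path = outdir / "screen.tsv"
    expanded_ids: Optional[list[str]] = None

    if "screen" in stages:
        if config.species_path is None:
            raise ValueError("species_path is required for the screen stage")
        species = amio.read_species_table(config.species_path)
        logger.info(
            "screen: %d families, alpha=%g", matrix.n_families, config.alpha
        )
        results = screen_expanded(matrix, species, alpha=config.alpha)
        amio.write_screen_results(results, screen_path)
        expanded_ids = [r.family_id for r in results if r.expanded]
        report["stages"]["screen"] = {
            "n_families_tested": len(results),
            "n_expanded": len(expanded_ids),
            "frac_expanded": len(expanded_ids) / len(results) if results else 0.0,
        }

    def need_expanded(stage: str) -> list[str]:
        nonlocal expanded_ids
        if expanded_ids is None:
            if not screen_path.exists():
                raise ValueError(
                    f"stage '{stage}' needs the expanded-family set; "
                    "run the 'screen' stage first"
                )
            expanded_ids = [
                r.family_id for r in amio.read_screen_results(screen_path) if r.expanded
            ]
        return expanded_ids

    genes = None

    def need_genes():
        nonlocal genes
        if genes is None:
            if config.gff_path is None:
                raise ValueError("gff_path is required for this stage")
            genes = amio.read_gene_annotations(config.gff_path, config.focal_species)
            for g in genes:
                g.family_id = gene_map.get(g.gene_id)
        return genes

    if "ctx" in stages:
        exp_ids = need_expanded("ctx")
        if config.counts_path is None or config.design_path is None:
            raise ValueError("counts_path and design_path are required for the ctx stage")
        experiment = amio.read_counts_and_design(config.counts_path, config.design_path)
        logger.info("ctx: %d genes × %d samples", *experiment.counts.shape)
        itx = run_interaction_tests(experiment, fdr=config.fdr)
        amio.write_interaction_results(itx, outdir / "interaction_tests.tsv")
        metrics = family_context_proportion(itx, gene_map, need_genes())
        metrics = _apply_size_mode(metrics, config, matrix)
        amio.write_family_metrics(metrics, outdir / "ctx_family_metrics.tsv")
        focal = [m for m in metrics if m.family_id in set(exp_ids)]
        res = enrichment_test(
            focal, metrics, n_perm=config.n_perm,
            seed=config.stage_rng("ctx"), conservative_p=config.conservative_p,
        )
        amio.write_enrichment_result(res, outdir / "ctx_enrichment.json")
        report["stages"]["ctx"] = {
            "n_tested_genes": sum(1 for r in itx if r.p is not None),
            "n_significant_genes": sum(1 for r in itx if r.significant),
            "enrichment": _enrichment_payload(res),
        }

    if "snp" in stages:
        exp_ids = need_expanded("snp")
        if config.snps_path is None:
            raise ValueError("snps_path is required for the snp stage")
        snps = amio.read_snp_table(config.snps_path, format=config.snps_format)
        kept = filter_snps(snps, maf_min=config.maf_min, missing_max=config.missing_max)
        logger.info("snp: %d SNPs, %d after filters", len(snps), len(kept))
        density = family_snp_density(kept, need_genes(), gene_map)
        amio.write_snp_density_metrics(density, outdir / "snp_density.tsv")
        metrics = [m.as_family_metric() for m in density]
        metrics = _apply_size_mode(metrics, config, matrix)
        focal = [m for m in metrics if m.family_id in set(exp_ids)]
        res = enrichment_test(
            focal, metrics, n_perm=config.n_perm,
            seed=config.stage_rng("snp"), conservative_p=config.conservative_p,
        )
        amio.write_enrichment_result(res, outdir / "snp_enrichment.json")
        report["stages"]["snp"] = {
            "n_snps": len(snps),
            "n_snps_filtered": len(kept),
            "enrichment": _enrichment_payload(res),
        }

    if "dup" in stages:
        exp_ids = need_expanded("dup")
        gg = assign_gene_ranks(need_genes())
        pairs = family_pairs(gg, gene_map)
        blocks = find_collinear_blocks(
            pairs, min_anchors=config.min_anchors, max_gap=config.max_gap
        )
        calls = classify_duplications(gg, pairs, blocks, proximal_max=config.proximal_max)
        amio.write_duplication_calls(calls, outdir / "duplication_calls.tsv")
        _write_blocks(blocks, outdir / "collinear_blocks.tsv")
        enr = dup_enrichment(
            calls, gene_map, exp_ids, n_perm=config.n_perm,
            seed=config.stage_rng("dup"), species_id=config.focal_species,
        )
        amio.write_dup_enrichment(enr, outdir / "dup_enrichment.tsv")
        report["stages"]["dup"] = {
            "n_genes": len(gg),
            "n_pairs": len(pairs),
            "n_blocks": len(blocks),
            "class_counts": {
                c.value: sum(1 for x in calls if x.dup_class is c)
                for c in {x.dup_class for x in calls}
            },
            "enrichment": [
                {
                    "dup_class": r.dup_class.value,
                    "prop_obs": r.prop_obs,
                    "null_mean": r.null_mean,
                    "fold": r.fold,
                    "p_two_sided": r.p_two_sided,
                    "q": r.q,
                }
                for r in enr
            ],
        }

    amio.write_run_summary(report, outdir / "report.json")
    return report


def _write_blocks(blocks, path: Path) -> None:
    import pandas as pd

    rows = []
    for i, b in enumerate(blocks):
        rows.append(
            {
                "block_id": f"B{i:03d}",
                "chrom_a": b.chrom_a,
                "chrom_b": b.chrom_b,
                "orientation": b.orientation,
                "n_anchors": b.n_anchors,
                "anchors": ";".join(f"{a.gene_a}|{a.gene_b}" for a in b.anchors),
            }
        )
    pd.DataFrame(
        rows, columns=["block_id", "chrom_a", "chrom_b", "orientation", "n_anchors", "anchors"]
    ).to_csv(path, sep="\t", index=False)
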