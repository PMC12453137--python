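"""Readers and writers for the pipeline's standard file formats.

Inputs: OrthoFinder ``Orthogroups.tsv`` / ``Orthogroups.GeneCount.tsv``
dialects, GFF3 gene annotations, counts + design TSVs for the factorial
expression experiment, SNP tables (TSV or minimal VCF), and a species
status table. Outputs are plain TSV result tables plus one JSON run
summary. Floats are written with 12 significant digits so result tables
round-trip.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    DuplicationCall,
    DupClass,
    DupEnrichmentResult,
    EnrichmentResult,
    ExpressionExperiment,
    FamilyMetric,
    FamilySizeMatrix,
    GeneRecord,
    InteractionTestResult,
    MycStatus,
    ScreenResult,
    SnpDensityMetric,
    SnpRecord,
    SpeciesRecord,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


# ---------------------------------------------------------------------------
# species table
# ---------------------------------------------------------------------------

def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read a species metadata table (columns: species_id, status ∈ {AM, NM})."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    df = pd.read_csv(path, sep=sep, engine="python")
    if not {"species_id", "status"} <= set(df.columns):
        raise ValueError("species table needs columns species_id, status")
    if df["species_id"].duplicated().any():
        raise ValueError("duplicate species_id in species table")
    return [
        SpeciesRecord(species_id=str(r.species_id), status=MycStatus(r.status))
        for r in df.itertuples()
    ]


def write_species_table(species: Sequence[SpeciesRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"species_id": [s.species_id for s in species],
         "status": [s.status.value for s in species]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# orthogroups
# ---------------------------------------------------------------------------

def read_orthogroups(
    path: str | Path, format: str = "membership"
) -> tuple[FamilySizeMatrix, dict[str, str]]:
    """Read an orthogroup table into a family-size matrix and gene→family map.

    ``format='membership'`` expects the ``Orthogroups.tsv`` dialect: one row
    per orthogroup, one tab-separated column per species, cells holding
    comma-separated gene IDs (empty cell = no genes). ``format='counts'``
    expects the ``Orthogroups.GeneCount.tsv`` dialect of integer counts (a
    trailing ``Total`` column, if present, is dropped) and yields an empty map.
    """
    if format not in ("membership", "counts"):
        raise ValueError(f"unknown orthogroups format {format!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty orthogroups file") from None
        species = [h.strip() for h in header[1:]]
        if format == "counts" and species and species[-1].lower() == "total":
            species = species[:-1]
        ncol = len(header)
        fam_ids: list[str] = []
        rows: list[list[int]] = []
        gene_map: dict[str, str] = {}
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncol} tab-separated columns, got {len(row)}"
                )
            fam = row[0].strip()
            if fam in seen:
                raise ValueError(f"{path}:{lineno}: duplicate orthogroup ID {fam!r}")
            seen.add(fam)
            fam_ids.append(fam)
            if format == "membership":
                counts_row = []
                for sp, cell in zip(species, row[1:]):
                    genes = [tok.strip() for tok in cell.split(",")]
                    genes = [g for g in genes if g]
                    counts_row.append(len(genes))
                    for g in genes:
                        if g in gene_map and gene_map[g] != fam:
                            raise ValueError(
                                f"{path}:{lineno}: gene {g!r} in two orthogroups "
                                f"({gene_map[g]} and {fam})"
                            )
                        gene_map[g] = fam
                rows.append(counts_row)
            else:
                try:
                    rows.append([int(c) for c in row[1 : len(species) + 1]])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer count in counts-format table"
                    ) from None
    counts = pd.DataFrame(rows, index=fam_ids, columns=species, dtype=int)
    return FamilySizeMatrix(counts=counts), gene_map


def write_orthogroup_membership(
    families: dict[str, dict[str, list[str]]],
    species_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write a membership table: families is {family: {species: [gene_ids]}}."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["Orthogroup", *species_ids])
        for fam in families:
            row = [fam]
            for sp in species_ids:
                row.append(", ".join(families[fam].get(sp, [])))
            w.writerow(row)


# ---------------------------------------------------------------------------
# GFF3 gene annotations
# ---------------------------------------------------------------------------

def read_gene_annotations(
    path: str | Path, focal_species: str = "focal"
) -> list[GeneRecord]:
    """Read ``gene`` features from a GFF3 file into GeneRecords.

    Non-gene features are ignored. Coordinates stay 1-based inclusive as in
    GFF3. A gene feature without an ID attribute, or with start > end, is an
    error naming the offending line.
    """
    import gffutils

    path = Path(path)
    # pre-scan so errors can cite the line; gffutils then does the parsing
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            if parts[2] != "gene":
                continue
            if "ID=" not in parts[8]:
                raise ValueError(f"{path}:{lineno}: gene feature without ID attribute")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        from_string=False,
    )
    records = [
        GeneRecord(
            gene_id=f.id,
            species_id=focal_species,
            chromosome=f.seqid,
            start=f.start,
            end=f.end,
            strand=f.strand if f.strand in ("+", "-") else ".",
        )
        for f in db.features_of_type("gene", order_by=("seqid", "start"))
    ]
    if not records:
        warnings.warn(f"{path}: no gene features found", stacklevel=2)
    return records


def write_gff3(genes: Sequence[GeneRecord], path: str | Path, source: str = "amexpand") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.end, g.gene_id)):
            fh.write(
                f"{g.chromosome}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# expression counts + design
# ---------------------------------------------------------------------------

def read_counts_and_design(
    counts_path: str | Path, design_path: str | Path
) -> ExpressionExperiment:
    """Read a genes × samples count TSV and a (sample, myc, stress) design TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    if not {"sample", "myc", "stress"} <= set(design.columns):
        raise ValueError("design table needs columns sample, myc, stress")
    if design["sample"].duplicated().any():
        raise ValueError("duplicate sample names in design")
    design = design.set_index("sample")
    arr = counts.to_numpy()
    if arr.size and not np.all(np.isfinite(arr) & (np.mod(arr, 1) == 0)):
        raise ValueError("counts table contains non-integer values")
    if arr.size and (arr < 0).any():
        raise ValueError("counts table contains negative values")
    exp = ExpressionExperiment(counts=counts.astype(int), design=design)
    exp.require_full_factorial()
    return exp


def write_counts_and_design(
    exp: ExpressionExperiment, counts_path: str | Path, design_path: str | Path
) -> None:
    exp.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    exp.design.reset_index(names="sample").to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

_SNP_TSV_COLS = ["snp_id", "chromosome", "position"]


def read_snp_table(path: str | Path, format: str = "tsv") -> list[SnpRecord]:
    """Read SNPs from a TSV (summary columns) or a minimal VCF.

    TSV columns: snp_id, chromosome, position, then any of maf,
    missing_fraction, assoc_q, significant. VCF input computes maf and
    missing_fraction from the GT fields; association evidence may ride in
    the INFO field as ``Q=`` / ``SIG=``.
    """
    if format == "tsv":
        return _read_snp_tsv(path)
    if format == "vcf_min":
        return _read_snp_vcf(path)
    raise ValueError(f"unknown SNP format {format!r}")


def _read_snp_tsv(path: str | Path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in _SNP_TSV_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"SNP table missing columns {missing_cols}")
    records = []
    for r in df.itertuples():
        sig = getattr(r, "significant", None)
        if sig is not None and not (isinstance(sig, float) and np.isnan(sig)):
            sig = bool(int(sig)) if not isinstance(sig, (bool, np.bool_)) else bool(sig)
        else:
            sig = None
        q = getattr(r, "assoc_q", None)
        if q is not None and isinstance(q, float) and np.isnan(q):
            q = None
        maf = getattr(r, "maf", None)
        if maf is not None and isinstance(maf, float) and np.isnan(maf):
            maf = None
        mf = getattr(r, "missing_fraction", None)
        if mf is not None and isinstance(mf, float) and np.isnan(mf):
            mf = None
        records.append(
            SnpRecord(
                snp_id=str(r.snp_id),
                chromosome=str(r.chromosome),
                position=int(r.position),
                maf=None if maf is None else float(maf),
                missing_fraction=None if mf is None else float(mf),
                assoc_q=None if q is None else float(q),
                significant=sig,
            )
        )
    return records


def _read_snp_vcf(path: str | Path) -> list[SnpRecord]:
    from cyvcf2 import VCF

    records = []
    for i, v in enumerate(VCF(str(path))):
        gts = []
        for gt in v.genotypes:  # [allele_a, allele_b, phased]
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                gts.append(None)
            else:
                gts.append("/".join(str(a) for a in alleles))
        snp_id = v.ID or f"{v.CHROM}_{v.POS}"
        q = v.INFO.get("Q")
        sig = v.INFO.get("SIG")
        rec = SnpRecord(
            snp_id=snp_id,
            chromosome=v.CHROM,
            position=v.POS,
            genotypes=gts,
            assoc_q=None if q is None else float(q),
            significant=None if sig is None else bool(int(sig)),
        )
        records.append(rec)
    return records


def write_snp_table(snps: Sequence[SnpRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snps],
            "chromosome": [s.chromosome for s in snps],
            "position": [s.position for s in snps],
            "maf": [s.maf for s in snps],
            "missing_fraction": [s.missing_fraction for s in snps],
            "assoc_q": [s.assoc_q for s in snps],
            "significant": [None if s.significant is None else int(s.significant) for s in snps],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_screen_results(results: Sequence[ScreenResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "family_id": r.family_id,
                "u_stat": r.u_stat,
                "p_raw": r.p_raw,
                "q": r.q,
                "am_median": r.am_median,
                "nm_median": r.nm_median,
                "expanded": int(r.expanded),
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_screen_results(path: str | Path) -> list[ScreenResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        ScreenResult(
            family_id=str(r.family_id),
            u_stat=float(r.u_stat),
            p_raw=float(r.p_raw),
            q=float(r.q),
            am_median=float(r.am_median),
            nm_median=float(r.nm_median),
            expanded=bool(r.expanded),
        )
        for r in df.itertuples()
    ]


def write_interaction_results(
    results: Sequence[InteractionTestResult], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "llr": r.llr,
                "p": r.p,
                "q": r.q,
                "significant": int(r.significant),
                "dispersion": r.dispersion,
                "converged": int(r.converged),
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_family_metrics(metrics: Sequence[FamilyMetric], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "family_id": m.family_id,
                "size": m.size,
                "n_tested": m.n_tested,
                "metric": m.metric,
            }
            for m in metrics
        ]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_family_metrics(path: str | Path) -> list[FamilyMetric]:
    df = pd.read_csv(path, sep="\t")
    return [
        FamilyMetric(
            family_id=str(r.family_id),
            size=int(r.size),
            metric=float(r.metric),
            n_tested=int(r.n_tested),
        )
        for r in df.itertuples()
    ]


def write_snp_density_metrics(
    metrics: Sequence[SnpDensityMetric], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "family_id": m.family_id,
                "size": m.size,
                "concat_length": m.concat_length,
                "n_sig_snps": m.n_sig_snps,
                "metric": m.metric,
            }
            for m in metrics
        ]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_enrichment_result(
    result: EnrichmentResult, path: str | Path, dump_null: bool = False
) -> None:
    payload = {
        "rho_obs": result.rho_obs,
        "null_mean": result.null_mean,
        "null_sd": result.null_sd,
        "p_greater": result.p_greater,
        "p_less": result.p_less,
        "p_two_sided": result.p_two_sided,
        "n_perm": result.n_perm,
        "subsample_size": result.subsample_size,
        "fold": result.fold,
    }
    if dump_null:
        payload["null_rhos"] = [float(x) for x in result.null_rhos]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_duplication_calls(
    calls: Sequence[DuplicationCall], path: str | Path
) -> None:
    pd.DataFrame(
        [{"gene_id": c.gene_id, "dup_class": c.dup_class.value} for c in calls]
    ).to_csv(path, sep="\t", index=False)


def read_duplication_calls(path: str | Path) -> list[DuplicationCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        DuplicationCall(gene_id=str(r.gene_id), dup_class=DupClass(r.dup_class))
        for r in df.itertuples()
    ]


def write_dup_enrichment(
    results: Sequence[DupEnrichmentResult], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "dup_class": r.dup_class.value,
                "prop_obs": r.prop_obs,
                "null_mean": r.null_mean,
                "fold": r.fold,
                "p_two_sided": r.p_two_sided,
                "q": r.q,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_run_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
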