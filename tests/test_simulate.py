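"""Synthetic-data generator: contracts, determinism, recoverability."""

import filecmp
import json
import math

import numpy as np
import pytest

from amexpand import io as amio
from amexpand.models import DupClass, MycStatus
from amexpand.simulate import (
    GroundTruth,
    SyntheticConfig,
    simulate_dataset,
    simulate_family_sizes,
    species_records,
)


class TestSimulateFamilySizes:
    def test_expanded_fraction_near_target(self):
        cfg = SyntheticConfig(seed=1)
        m, truth = simulate_family_sizes(cfg)
        frac = len(truth.expanded_family_ids) / m.n_families
        assert abs(frac - 0.015) <= 0.005

    def test_expanded_families_larger_in_am(self):
        cfg = SyntheticConfig(seed=2)
        m, truth = simulate_family_sizes(cfg)
        am = [s.species_id for s in species_records(cfg) if s.status is MycStatus.AM]
        nm = [s.species_id for s in species_records(cfg) if s.status is MycStatus.NM]
        bigger = [
            m.counts.loc[f, am].mean() > m.counts.loc[f, nm].mean()
            for f in truth.expanded_family_ids
        ]
        assert np.mean(bigger) >= 0.95

    def test_same_seed_identical_matrix(self):
        a, _ = simulate_family_sizes(SyntheticConfig(seed=9))
        b, _ = simulate_family_sizes(SyntheticConfig(seed=9))
        assert a.counts.equals(b.counts)

    def test_too_few_expanded_rejected(self):
        with pytest.raises(ValueError, match="frac_expanded"):
            simulate_family_sizes(SyntheticConfig(seed=0, n_families=20, frac_expanded=0.01))

    def test_null_mode_plants_nothing(self):
        _, truth = simulate_family_sizes(SyntheticConfig(seed=0, null_expansion=True))
        assert truth.expanded_family_ids == []


class TestSimulateGenome:
    def test_planted_tandem_pairs_adjacent(self, default_dataset):
        ds = default_dataset
        by_fam = {}
        for g in ds.genes:
            by_fam.setdefault(g.family_id, []).append(g)
        from amexpand.duplication import assign_gene_ranks

        assign_gene_ranks(ds.genes)
        checked = 0
        for fam, members in by_fam.items():
            if len(members) < 2:
                continue
            if all(ds.truth.dup_class[g.gene_id] == "tandem" for g in members):
                ranks = sorted(g.rank for g in members)
                assert ranks == list(range(ranks[0], ranks[0] + len(ranks)))
                checked += 1
        assert checked > 10

    def test_planted_segments_are_matched_runs(self, default_dataset):
        ds = default_dataset
        wgd = [g for g in ds.genes if ds.truth.dup_class[g.gene_id] == "wgd"]
        cfg = ds.config
        assert len(wgd) == 2 * cfg.n_segmental_blocks * cfg.segmental_block_length

    def test_gene_coordinates_do_not_overlap(self, default_dataset):
        by_chrom = {}
        for g in default_dataset.genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for members in by_chrom.values():
            members = sorted(members, key=lambda g: g.start)
            for a, b in zip(members, members[1:]):
                assert a.end < b.start

    def test_counts_match_matrix_focal_column(self, default_dataset):
        ds = default_dataset
        focal_counts = {}
        for g in ds.genes:
            focal_counts[g.family_id] = focal_counts.get(g.family_id, 0) + 1
        col = ds.matrix.counts["AM01"]
        for fam, n in focal_counts.items():
            assert col[fam] == n
        assert sum(focal_counts.values()) == int(col.sum())


class TestSimulateExpression:
    def test_shape_and_design_cells(self, default_dataset):
        exp = default_dataset.experiment
        assert exp.counts.shape == (len(default_dataset.genes), 12)
        assert (exp.counts.to_numpy() >= 0).all()
        exp.require_full_factorial()

    def test_null_interaction_plants_no_flags(self):
        ds = simulate_dataset(SyntheticConfig(seed=3, n_families=200, null_interaction=True))
        assert not any(ds.truth.interaction.values())

    def test_interaction_probability_increases_with_size(self, default_dataset):
        ds = default_dataset
        sizes, flags = [], []
        fam_size = {}
        for g in ds.genes:
            fam_size[g.family_id] = fam_size.get(g.family_id, 0) + 1
        expanded = set(ds.truth.expanded_family_ids)
        for g in ds.genes:
            if g.family_id in expanded:
                sizes.append(fam_size[g.family_id])
                flags.append(ds.truth.interaction[g.gene_id])
        sizes, flags = np.array(sizes), np.array(flags, dtype=float)
        med = np.median(sizes)
        assert flags[sizes > med].mean() > flags[sizes <= med].mean()


class TestSimulateSnps:
    def test_maf_filter_removes_expected_fraction(self, default_dataset):
        mafs = np.array([s.maf for s in default_dataset.snps])
        # maf ~ U(0.01, 0.5): below-0.05 mass is 0.04/0.49 ≈ 8.2%
        assert abs(np.mean(mafs < 0.05) - 0.082) < 0.01

    def test_intergenic_snps_outside_gene_bodies(self, default_dataset):
        ds = default_dataset
        import bisect

        starts, intervals = {}, {}
        for g in sorted(ds.genes, key=lambda g: (g.chromosome, g.start)):
            starts.setdefault(g.chromosome, []).append(g.start)
            intervals.setdefault(g.chromosome, []).append((g.start, g.end))
        n_genic = sum(
            1 for g in ds.genes
            for _ in range(len(range(ds.config.snp_spacing // 2, g.length,
                                     ds.config.snp_spacing)))
        )
        n_out = 0
        for s in ds.snps[n_genic:]:
            i = bisect.bisect_right(starts[s.chromosome], s.position) - 1
            inside = i >= 0 and intervals[s.chromosome][i][1] >= s.position
            n_out += not inside
        assert n_out == len(ds.snps) - n_genic  # all extras are intergenic

    def test_null_snp_mode_uniform_significance(self):
        ds = simulate_dataset(SyntheticConfig(seed=5, n_families=400, null_snp=True))
        sig = np.array([s.significant for s in ds.snps])
        assert abs(sig.mean() - ds.config.snp_sig_background_prob) < 0.01


class TestDatasetFiles:
    def test_outputs_readable_and_consistent(self, default_dataset_dir, default_dataset):
        d = default_dataset_dir
        species = amio.read_species_table(d / "species.tsv")
        assert len(species) == 42
        matrix, gmap = amio.read_orthogroups(d / "orthogroups.tsv")
        assert matrix.counts.equals(default_dataset.matrix.counts)
        genes = amio.read_gene_annotations(d / "genome.gff3", "AM01")
        assert len(genes) == len(default_dataset.genes)
        for g in genes[:50]:
            assert gmap[g.gene_id] == default_dataset.gene_to_family[g.gene_id]
        exp = amio.read_counts_and_design(d / "counts.tsv", d / "design.tsv")
        assert exp.counts.equals(default_dataset.experiment.counts)
        snps = amio.read_snp_table(d / "snps.tsv")
        assert len(snps) == len(default_dataset.snps)
        truth = GroundTruth.from_json(d / "truth.json")
        assert truth.expanded_family_ids == default_dataset.truth.expanded_family_ids

    def test_byte_identical_regeneration(self, tmp_path):
        cfg = SyntheticConfig(seed=11, n_families=300)
        simulate_dataset(cfg, outdir=tmp_path / "a")
        simulate_dataset(cfg, outdir=tmp_path / "b")
        for name in ("species.tsv", "orthogroups.tsv", "genome.gff3",
                     "counts.tsv", "design.tsv", "snps.tsv", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name
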