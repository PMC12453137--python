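"""Duplication classifier: ranks, pairs, collinear blocks, classes, enrichment."""

import numpy as np
import pytest

from amexpand.duplication import (
    assign_gene_ranks,
    classify_duplications,
    dup_enrichment,
    family_pairs,
    find_collinear_blocks,
)
from amexpand.models import DupClass, GeneRecord
from oracle_impls import brute_force_dup_classifier


def _gene(gid, chrom, start, fam=None, end=None):
    return GeneRecord(gid, "sp", chrom, start, end or start + 999, family_id=fam)


class TestAssignGeneRanks:
    def test_sorts_by_start(self):
        genes = [_gene("a", "chr1", 100), _gene("b", "chr1", 50), _gene("c", "chr1", 200)]
        assign_gene_ranks(genes)
        assert [g.rank for g in genes] == [1, 0, 2]

    def test_single_gene(self):
        genes = [_gene("a", "chr1", 5)]
        assign_gene_ranks(genes)
        assert genes[0].rank == 0

    def test_tie_breaks_by_end_then_id(self):
        genes = [
            _gene("long", "chr1", 100, end=500),
            _gene("short", "chr1", 100, end=300),
        ]
        assign_gene_ranks(genes)
        assert {g.gene_id: g.rank for g in genes} == {"short": 0, "long": 1}

    def test_duplicate_id_rejected(self):
        genes = [_gene("a", "chr1", 1), _gene("a", "chr2", 1)]
        with pytest.raises(ValueError, match="duplicate gene_id"):
            assign_gene_ranks(genes)


class TestFamilyPairs:
    def test_triple_family_gives_three_pairs(self):
        genes = [_gene(f"g{i}", "chr1", 1 + 2000 * i, fam="F") for i in range(3)]
        assign_gene_ranks(genes)
        assert len(family_pairs(genes)) == 3

    def test_singletons_give_no_pairs(self):
        genes = [_gene(f"g{i}", "chr1", 1 + 2000 * i, fam=f"F{i}") for i in range(4)]
        assign_gene_ranks(genes)
        assert family_pairs(genes) == []

    def test_two_pair_families(self):
        genes = [
            _gene("a1", "chr1", 1, fam="A"), _gene("a2", "chr2", 1, fam="A"),
            _gene("b1", "chr1", 5000, fam="B"), _gene("b2", "chr2", 5000, fam="B"),
        ]
        assign_gene_ranks(genes)
        assert len(family_pairs(genes)) == 2


def _collinear_genes(n, invert=False, gap_at=None, gap=30):
    """n families laid in identical (or inverted) order on chr1 and chr2."""
    genes = []
    offset = 0
    for i in range(n):
        genes.append(_gene(f"a{i}", "chr1", 1 + 2000 * i, fam=f"F{i}"))
    for i in range(n):
        j = n - 1 - i if invert else i
        if gap_at is not None and i >= gap_at:
            offset = gap
        genes.append(_gene(f"b{j}", "chr2", 1 + 2000 * (i + offset), fam=f"F{j}"))
    # pad chr2 with singleton filler so rank gaps are real
    if gap_at is not None:
        for k in range(gap):
            genes.append(_gene(f"fill{k}", "chr2", 1 + 2000 * (gap_at + k) + 500,
                               fam=f"X{k}"))
    return genes


class TestFindCollinearBlocks:
    def test_six_anchor_same_order_block(self):
        genes = _collinear_genes(6)
        assign_gene_ranks(genes)
        blocks = find_collinear_blocks(family_pairs(genes))
        assert len(blocks) == 1
        assert blocks[0].orientation == "same"
        assert blocks[0].n_anchors == 6

    def test_inverted_order_block(self):
        genes = _collinear_genes(6, invert=True)
        assign_gene_ranks(genes)
        blocks = find_collinear_blocks(family_pairs(genes))
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_four_anchors_below_threshold(self):
        genes = _collinear_genes(4)
        assign_gene_ranks(genes)
        assert find_collinear_blocks(family_pairs(genes)) == []

    def test_gap_beyond_max_splits_chain(self):
        genes = _collinear_genes(6, gap_at=3, gap=30)
        assign_gene_ranks(genes)
        assert find_collinear_blocks(family_pairs(genes), max_gap=25) == []

    def test_tandem_arrays_do_not_seed_blocks(self):
        genes = [_gene(f"t{i}", "chr1", 1 + 2000 * i, fam="T") for i in range(8)]
        assign_gene_ranks(genes)
        assert find_collinear_blocks(family_pairs(genes)) == []

    def test_symmetric_under_chromosome_relabelling(self):
        genes = _collinear_genes(7)
        relabel = {"chr1": "chr9", "chr2": "chr0"}  # flips canonical order
        swapped = [
            GeneRecord(g.gene_id, g.species_id, relabel[g.chromosome], g.start,
                       g.end, g.strand, g.family_id)
            for g in genes
        ]
        assign_gene_ranks(genes)
        assign_gene_ranks(swapped)
        b1 = find_collinear_blocks(family_pairs(genes))
        b2 = find_collinear_blocks(family_pairs(swapped))
        assert len(b1) == len(b2) == 1
        assert b1[0].orientation == b2[0].orientation
        assert {frozenset((a.gene_a, a.gene_b)) for a in b1[0].anchors} == {
            frozenset((a.gene_a, a.gene_b)) for a in b2[0].anchors
        }


class TestClassifyDuplications:
    def _classified(self, genes):
        assign_gene_ranks(genes)
        pairs = family_pairs(genes)
        blocks = find_collinear_blocks(pairs)
        calls = classify_duplications(genes, pairs, blocks)
        return {c.gene_id: c.dup_class for c in calls}

    def test_adjacent_co_members_are_tandem(self):
        out = self._classified([
            _gene("g1", "chr1", 1, fam="F"), _gene("g2", "chr1", 2000, fam="F"),
        ])
        assert out["g1"] is DupClass.TANDEM and out["g2"] is DupClass.TANDEM

    def test_five_intervening_genes_is_proximal(self):
        genes = [_gene("p1", "chr1", 1, fam="F")]
        for i in range(5):
            genes.append(_gene(f"x{i}", "chr1", 2000 * (i + 1), fam=f"X{i}"))
        genes.append(_gene("p2", "chr1", 2000 * 6, fam="F"))
        out = self._classified(genes)
        assert out["p1"] is DupClass.PROXIMAL and out["p2"] is DupClass.PROXIMAL

    def test_beyond_proximal_window_is_dispersed(self):
        genes = [_gene("p1", "chr1", 1, fam="F")]
        for i in range(21):
            genes.append(_gene(f"x{i}", "chr1", 2000 * (i + 1), fam=f"X{i}"))
        genes.append(_gene("p2", "chr1", 2000 * 22, fam="F"))
        out = self._classified(genes)
        assert out["p1"] is DupClass.DISPERSED

    def test_other_chromosome_without_block_is_dispersed(self):
        out = self._classified([
            _gene("g1", "chr1", 1, fam="F"), _gene("g2", "chr2", 1, fam="F"),
        ])
        assert out["g1"] is DupClass.DISPERSED

    def test_no_co_member_is_singleton(self):
        out = self._classified([_gene("g1", "chr1", 1, fam="F")])
        assert out["g1"] is DupClass.SINGLETON

    def test_block_anchor_outranks_tandem(self):
        # 6-anchor collinear block; the first block family also has a
        # tandem partner adjacent to its chr1 copy
        genes = _collinear_genes(6)
        genes.append(_gene("twin", "chr1", 900, fam="F0"))  # adjacent to a0
        out = self._classified(genes)
        assert out["a0"] is DupClass.WGD  # priority: wgd over tandem
        assert out["twin"] in (DupClass.TANDEM, DupClass.WGD)

    def test_planted_segment_recovered_as_wgd(self, default_dataset):
        ds = default_dataset
        genes = assign_gene_ranks(ds.genes)
        pairs = family_pairs(genes)
        blocks = find_collinear_blocks(pairs)
        calls = {c.gene_id: c.dup_class for c in classify_duplications(genes, pairs, blocks)}
        planted = [g for g, cls in ds.truth.dup_class.items() if cls == "wgd"]
        assert planted
        recovered = np.mean([calls[g] is DupClass.WGD for g in planted])
        assert recovered >= 0.95

    def test_matches_brute_force_on_default_genome(self, default_dataset):
        ds = default_dataset
        genes = assign_gene_ranks(ds.genes)
        pairs = family_pairs(genes)
        blocks = find_collinear_blocks(pairs)
        calls = classify_duplications(genes, pairs, blocks)
        oracle = brute_force_dup_classifier(genes, blocks)
        assert all(c.dup_class.value == oracle[c.gene_id] for c in calls)


class TestDupEnrichment:
    def test_planted_tandem_enrichment(self, default_dataset):
        ds = default_dataset
        genes = assign_gene_ranks(ds.genes)
        pairs = family_pairs(genes)
        blocks = find_collinear_blocks(pairs)
        calls = classify_duplications(genes, pairs, blocks)
        res = dup_enrichment(
            calls, ds.gene_to_family, ds.truth.expanded_family_ids,
            n_perm=2000, seed=3,
        )
        tandem = next(r for r in res if r.dup_class is DupClass.TANDEM)
        assert tandem.fold > 2
        assert tandem.q < 0.05
        props = {r.dup_class: r.prop_obs for r in res}
        assert sum(props.values()) == pytest.approx(1.0)

    def test_all_singletons(self):
        genes = [_gene(f"g{i}", "chr1", 1 + 2000 * i, fam=f"F{i}") for i in range(10)]
        assign_gene_ranks(genes)
        pairs = family_pairs(genes)
        calls = classify_duplications(genes, pairs, [])
        res = dup_enrichment(
            calls, {g.gene_id: g.family_id for g in genes},
            ["F0", "F1", "F2"], n_perm=500, seed=0,
        )
        props = {r.dup_class: r.prop_obs for r in res}
        assert props[DupClass.SINGLETON] == 1.0
        assert all(props[c] == 0.0 for c in props if c is not DupClass.SINGLETON)
        assert not any(r.q < 0.05 for r in res)

    def test_empty_expanded_set_warns_and_skips(self):
        genes = [_gene("g", "chr1", 1, fam="F")]
        assign_gene_ranks(genes)
        calls = classify_duplications(genes, [], [])
        with pytest.warns(UserWarning, match="empty expanded set"):
            assert dup_enrichment(calls, {"g": "F"}, ["nope"], n_perm=100) == []

    def test_random_focal_sets_are_calibrated(self, default_dataset, rng):
        ds = default_dataset
        genes = assign_gene_ranks(ds.genes)
        pairs = family_pairs(genes)
        blocks = find_collinear_blocks(pairs)
        calls = classify_duplications(genes, pairs, blocks)
        fams = sorted({f for f in ds.gene_to_family.values()})
        hits = 0
        n_rep = 40  # light version; acceptance runs the full 200
        for _ in range(n_rep):
            focal = list(rng.choice(fams, size=30, replace=False))
            res = dup_enrichment(calls, ds.gene_to_family, focal, n_perm=500, seed=rng)
            tandem = next(r for r in res if r.dup_class is DupClass.TANDEM)
            hits += tandem.p_two_sided < 0.05
        assert hits / n_rep <= 0.15
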