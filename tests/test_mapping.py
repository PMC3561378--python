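"""Locus->gene assignment and gene-link construction vs a brute-force oracle."""

import numpy as np
import pytest

import chromexpr as cx
from chromexpr.mapping import build_gene_links

from conftest import (
    brute_force_links,
    make_annotation,
    make_contacts,
    make_expression,
    random_toy_instance,
)


@pytest.fixture
def two_chrom_ann():
    return make_annotation(
        [("gA", "c1", 1000, 2000, "+"), ("gB", "c2", 5000, 6000, "-")],
        {"c1": 50_000, "c2": 50_000})


class TestAssignment:
    def test_locus_inside_gene_assigned_at_offset_zero(self, two_chrom_ann):
        assert cx.assign_genes_to_locus("c1", 1500, two_chrom_ann, 0) == {"gA"}

    def test_boundary_distance_arithmetic(self, two_chrom_ann):
        # locus 2400 is 400 bp past the gene end
        assert cx.assign_genes_to_locus("c1", 2400, two_chrom_ann, 500) == {"gA"}
        assert cx.assign_genes_to_locus("c1", 2400, two_chrom_ann, 399) == set()
        assert cx.assign_genes_to_locus("c1", 2400, two_chrom_ann, 400) == {"gA"}

    def test_multiple_overlapping_genes_all_returned(self):
        ann = make_annotation([("g1", "c1", 100, 200, "+"), ("g2", "c1", 260, 400, "+")],
                              {"c1": 10_000})
        assert cx.assign_genes_to_locus("c1", 230, ann, 50) == {"g1", "g2"}

    def test_five_prime_mode_is_strand_aware(self, two_chrom_ann):
        # gB is minus strand: its 5' end is the interval end (6000)
        assert cx.assign_genes_to_locus("c2", 6100, two_chrom_ann, 100,
                                        anchor_mode="five_prime") == {"gB"}
        assert cx.assign_genes_to_locus("c2", 5000, two_chrom_ann, 100,
                                        anchor_mode="five_prime") == set()

    def test_unknown_chromosome_rejected(self, two_chrom_ann):
        with pytest.raises(ValueError, match="unknown chromosome"):
            cx.assign_genes_to_locus("c9", 100, two_chrom_ann, 500)


class TestBuildLinks:
    def test_single_contact_single_link(self, two_chrom_ann):
        contacts = make_contacts([("c1", 1500, "c2", 5500, 7)])
        lt = build_gene_links(contacts, two_chrom_ann, offset_bp=0, min_count=1)
        assert len(lt) == 1
        row = lt.links.iloc[0]
        assert (row.gene_a, row.gene_b, row.frequency, row.n_support) == ("gA", "gB", 7, 1)

    def test_max_aggregation_over_supporting_contacts(self, two_chrom_ann):
        contacts = make_contacts([("c1", 1500, "c2", 5500, 5),
                                  ("c1", 1700, "c2", 5900, 9)])
        lt = build_gene_links(contacts, two_chrom_ann, offset_bp=0, min_count=1,
                              aggregation="max")
        assert lt.links.iloc[0].frequency == 9 and lt.links.iloc[0].n_support == 2
        lt_sum = build_gene_links(contacts, two_chrom_ann, offset_bp=0, min_count=1,
                                  aggregation="sum")
        assert lt_sum.links.iloc[0].frequency == 14

    def test_empty_annotation_rejected(self):
        import pandas as pd

        empty = cx.GenomeAnnotation(
            pd.DataFrame(columns=["chrom", "start", "end", "strand", "status"]),
            {"c1": 1000})
        with pytest.raises(ValueError, match="no genes"):
            build_gene_links(make_contacts([("c1", 1, "c1", 2, 5)]), empty)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("offset_bp,min_count,anchor_mode,aggregation", [
        (0, 1, "boundary", "max"),
        (500, 1, "boundary", "sum"),
        (500, 5, "five_prime", "max"),
        (2000, 3, "boundary", "max"),
        (2000, 1, "five_prime", "sum"),
    ])
    def test_matches_bruteforce_oracle(self, seed, offset_bp, min_count,
                                       anchor_mode, aggregation):
        rng = np.random.default_rng(1000 + seed)
        ann, contacts = random_toy_instance(rng, max_genes=20, max_contacts=40)
        for inter_only in (True, False):
            lt = build_gene_links(contacts, ann, offset_bp=offset_bp,
                                  min_count=min_count, inter_only=inter_only,
                                  anchor_mode=anchor_mode, aggregation=aggregation)
            got = {(r.gene_a, r.gene_b): (r.frequency, r.n_support)
                   for r in lt.links.itertuples(index=False)}
            want = brute_force_links(contacts, ann, offset_bp, min_count,
                                     inter_only, anchor_mode, aggregation)
            assert got == want

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_in_min_count_and_offset(self, seed):
        rng = np.random.default_rng(2000 + seed)
        ann, contacts = random_toy_instance(rng, max_genes=30, max_contacts=60)

        def pairs(offset, mc):
            lt = build_gene_links(contacts, ann, offset_bp=offset, min_count=mc)
            return set(map(tuple, lt.links[["gene_a", "gene_b"]].to_numpy()))

        assert pairs(500, 6) <= pairs(500, 5) <= pairs(500, 1)
        assert pairs(0, 1) <= pairs(500, 1) <= pairs(2000, 1)

    def test_symmetric_under_end_permutation(self):
        rng = np.random.default_rng(77)
        ann, contacts = random_toy_instance(rng, max_genes=25, max_contacts=50)
        rec = contacts.records.rename(columns={
            "chrom_a": "chrom_b", "chrom_b": "chrom_a",
            "pos_a": "pos_b", "pos_b": "pos_a"})
        flipped = cx.ContactTable(rec)
        a = build_gene_links(contacts, ann, min_count=1).links
        b = build_gene_links(flipped, ann, min_count=1).links
        assert a.equals(b)


class TestOffsetSweep:
    def test_npairs_nondecreasing_and_signal_decays(self, small_dataset, small_expr):
        ds = small_dataset
        tab = cx.offset_sweep(ds.contacts, ds.annotation, small_expr,
                              offsets=(0, 500, 10_000), min_count=1)
        n = tab["n_pairs"].to_numpy()
        assert (np.diff(n) >= 0).all()
        # planted loci lie inside genes: widening to 10 kbp only adds
        # uncorrelated neighbour pairs, diluting the mean toward background
        r = tab["mean_linked_correlation"].to_numpy()
        assert r[0] >= r[2]

    def test_unsorted_offsets_rejected(self, small_dataset, small_expr):
        with pytest.raises(ValueError, match="sorted"):
            cx.offset_sweep(small_dataset.contacts, small_dataset.annotation,
                            small_expr, offsets=(500, 0))


class TestWindowProfile:
    def test_minus_strand_window_center(self):
        # minus-strand gene [1000, 2000]: 5' end at 2000, shift +100 (in
        # transcription direction) puts the window centre at 1900
        ann = make_annotation([("gA", "c1", 1000, 2000, "-"),
                               ("gB", "c2", 500, 1500, "+")],
                              {"c1": 50_000, "c2": 50_000})
        contacts = make_contacts([("c1", 1900, "c2", 600, 6)])
        tab = cx.window_position_profile(contacts, ann, make_expression({
            "gA": np.arange(40.0), "gB": np.arange(40.0)[::-1] + 1}),
            window_bp=10, center_shifts=(0, 100), min_count=1)
        # at shift 0 the window sits at 2000 and misses the locus at 1900;
        # at shift +100 it covers it
        assert tab.loc[tab["shift"] == 0, "n_pairs"].item() == 0
        assert tab.loc[tab["shift"] == 100, "n_pairs"].item() == 1

    def test_shift_zero_equals_five_prime_assignment(self):
        rng = np.random.default_rng(5)
        ann, contacts = random_toy_instance(rng, max_genes=20, max_contacts=40)
        profiles = {g: rng.random(40) + 0.1 for g in ann.gene_ids}
        expr = make_expression(profiles)
        window = 4000
        tab = cx.window_position_profile(contacts, ann, expr, window_bp=window,
                                         center_shifts=(0,), min_count=1)
        lt = build_gene_links(contacts, ann, offset_bp=window // 2, min_count=1,
                              anchor_mode="five_prime")
        assert tab["n_pairs"].item() == len(lt)
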