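"""Expression normalization, the correlation engine, and the linked-vs-
background co-expression analyses."""

import numpy as np
import pandas as pd
import pytest

import chromexpr as cx
from chromexpr.coexpression import CorrelationEngine
from chromexpr.mapping import GeneLinkTable, LINK_COLUMNS

from conftest import make_annotation, make_expression


def links_from_pairs(pairs, annotation, frequency=6):
    chrom = annotation.genes["chrom"]
    rows = [(min(a, b), max(a, b), chrom[min(a, b)], chrom[max(a, b)],
             f if not np.isscalar(frequency) else frequency, 1, "t")
            for (a, b), f in zip(pairs, np.broadcast_to(frequency, len(pairs)))]
    return GeneLinkTable(pd.DataFrame(rows, columns=LINK_COLUMNS), min_count=1)


class TestNormalizeSamples:
    def test_sample_divided_by_its_mean(self):
        em = make_expression({"g1": [2.0, 1.0], "g2": [4.0, 3.0]})
        out = cx.normalize_samples(em)
        assert np.allclose(out.values["S0"], [2 / 3, 4 / 3])
        assert out.normalized

    def test_idempotent(self):
        em = make_expression({"g1": [2.0, 1.0], "g2": [4.0, 3.0]})
        once = cx.normalize_samples(em)
        twice = cx.normalize_samples(once)
        assert np.array_equal(once.values.to_numpy(), twice.values.to_numpy())

    def test_log2_input_exponentiated_first(self):
        em = make_expression({"g1": [1.0], "g2": [3.0]})
        out = cx.normalize_samples(em, from_log2=True)
        # 2**(1,3) = (2,8), mean 5 -> (0.4, 1.6)
        assert np.allclose(out.values["S0"], [0.4, 1.6])

    def test_zero_mean_sample_rejected(self):
        em = make_expression({"g1": [0.0], "g2": [0.0]})
        with pytest.raises(ValueError, match="zero"):
            cx.normalize_samples(em)


class TestPearson:
    def test_perfect_correlation_signs(self):
        em = make_expression({"a": [1, 2, 3], "b": [2, 4, 6], "c": [3, 2, 1]})
        r = cx.pearson(em, [("a", "b"), ("a", "c")], min_shared=3)
        assert np.allclose(r, [1.0, -1.0])

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        x, y = rng.random(10), rng.random(10)
        em = make_expression({"a": x, "b": y})
        r = cx.pearson(em, [("a", "b")], min_shared=10)[0]
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_and_min_shared(self):
        x = np.arange(40.0)
        y = 2 * x + 1
        y_nan = y.copy()
        y_nan[:15] = np.nan  # 25 shared samples
        em = make_expression({"a": x, "b": y_nan, "c": y})
        r = cx.pearson(em, [("a", "b"), ("a", "c")], min_shared=30)
        assert np.isnan(r[0]) and r[1] == pytest.approx(1.0)
        r2 = cx.pearson(em, [("a", "b")], min_shared=20)
        assert r2[0] == pytest.approx(1.0)

    def test_zero_variance_pair_excluded(self):
        em = make_expression({"a": np.arange(40.0), "b": np.full(40, 2.0)})
        assert np.isnan(cx.pearson(em, [("a", "b")], min_shared=10)[0])


@pytest.fixture
def grid4():
    """4 chromosomes x 3 genes with controlled profiles."""
    genes = [(f"g{c}{i}", f"c{c}", 1000 * i, 1000 * i + 500, "+")
             for c in range(1, 5) for i in range(1, 4)]
    ann = make_annotation(genes, {f"c{c}": 50_000 for c in range(1, 5)})
    rng = np.random.default_rng(0)
    factor = rng.standard_normal(80)
    profiles = {}
    for gid in ann.gene_ids:
        noise = rng.standard_normal(80)
        profiles[gid] = np.exp(0.3 * (0.6 * factor + 0.8 * noise)) \
            if gid in ("g11", "g21", "g31") else np.exp(0.3 * noise)
    return ann, cx.normalize_samples(make_expression(profiles))


class TestLinkedVsBackground:
    def test_empty_links_rejected(self, grid4):
        ann, expr = grid4
        empty = GeneLinkTable(pd.DataFrame(columns=LINK_COLUMNS))
        with pytest.raises(ValueError, match="no links"):
            cx.linked_vs_background(empty, expr, ann)

    def test_linked_equal_all_pairs_means_coincide(self, grid4):
        ann, expr = grid4
        genes = ann.gene_ids
        chrom = ann.genes["chrom"]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]
                 if chrom[a] != chrom[b]]
        lt = links_from_pairs(pairs, ann)
        s = cx.linked_vs_background(lt, expr, ann, min_shared=10)
        assert s.mean_linked == pytest.approx(s.mean_background, abs=1e-12)
        assert s.ks_statistic == pytest.approx(0.0)
        assert s.n_linked == s.n_background

    def test_correlated_subset_detected(self, grid4):
        ann, expr = grid4
        lt = links_from_pairs([("g11", "g21"), ("g11", "g31"), ("g21", "g31")], ann)
        s = cx.linked_vs_background(lt, expr, ann, min_shared=10)
        assert s.mean_linked > s.mean_background + 0.1

    def test_background_subsample_close_to_exact(self, grid4):
        ann, expr = grid4
        lt = links_from_pairs([("g11", "g21")], ann)
        exact = cx.linked_vs_background(lt, expr, ann, min_shared=10,
                                        background_cap=None)
        approx = cx.linked_vs_background(lt, expr, ann, min_shared=10,
                                         background_cap=30, seed=4)
        assert exact.background_exact and not approx.background_exact
        r_all = cx.pearson(expr, [(a, b) for i, a in enumerate(ann.gene_ids)
                                  for b in ann.gene_ids[i + 1:]
                                  if ann.genes["chrom"][a] != ann.genes["chrom"][b]],
                           min_shared=10)
        se = np.nanstd(r_all) / np.sqrt(30)
        assert abs(approx.mean_background - exact.mean_background) < 3 * se


class TestFrequencyCurve:
    def test_equal_frequencies_give_identical_rows(self, grid4):
        ann, expr = grid4
        lt = links_from_pairs([("g11", "g21"), ("g11", "g31")], ann, frequency=6)
        tab = cx.frequency_threshold_curve(lt, expr, ann, thresholds=(0, 1, 5),
                                           min_shared=10)
        assert tab.loc[1, "mean_correlation"] == tab.loc[2, "mean_correlation"]
        assert (np.diff(tab["n_pairs"].to_numpy()[1:]) <= 0).all()

    def test_threshold_with_no_pairs_emits_nan_row(self, grid4):
        ann, expr = grid4
        lt = links_from_pairs([("g11", "g21")], ann, frequency=3)
        tab = cx.frequency_threshold_curve(lt, expr, ann, thresholds=(0, 1, 10),
                                           min_shared=10)
        last = tab.iloc[-1]
        assert last["n_pairs"] == 0 and np.isnan(last["mean_correlation"])

    def test_thresholds_must_ascend_from_zero(self, grid4):
        ann, expr = grid4
        lt = links_from_pairs([("g11", "g21")], ann)
        with pytest.raises(ValueError):
            cx.frequency_threshold_curve(lt, expr, ann, thresholds=(1, 2))


class TestChromosomePairs:
    def test_row_count_is_chromosome_pairs(self, grid4):
        ann, expr = grid4
        lt = links_from_pairs([("g11", "g21")], ann)
        tab, r, t, p = cx.chromosome_pair_analysis(lt, expr, ann, min_count=1,
                                                   min_shared=10)
        assert len(tab) == 6  # C(4,2)

    def test_zero_correlation_gives_half_p(self, grid4):
        ann, expr = grid4
        # no links at this threshold: density column all zero -> r = 0
        lt = links_from_pairs([("g11", "g21")], ann, frequency=1)
        tab, r, t, p = cx.chromosome_pair_analysis(lt, expr, ann, min_count=99,
                                                   min_shared=10)
        assert (r, t) == (0.0, 0.0)
        assert p == pytest.approx(0.5)

    def test_planted_coupling_recovered(self, small_dataset, small_links, small_expr):
        tab, r, t, p = cx.chromosome_pair_analysis(
            small_links, small_expr, small_dataset.annotation, min_count=1)
        assert r > 0
        assert p < 0.05


class TestRankEnrichment:
    def test_single_bin_ratio_exactly_one(self, grid4):
        ann, expr = grid4
        lt = links_from_pairs([("g11", "g21"), ("g21", "g31")], ann)
        tab = cx.expression_rank_link_enrichment(expr, lt, ann,
                                                 bin_size=len(ann.gene_ids),
                                                 n_perm=10, seed=0)
        assert len(tab) == 1
        assert tab["enrichment_ratio"].iloc[0] == pytest.approx(1.0)

    def test_uniform_links_ratios_near_one(self, small_dataset, small_expr):
        ds = small_dataset
        rng = np.random.default_rng(12)
        genes = ds.annotation.gene_ids
        chrom = ds.annotation.genes["chrom"]
        pairs = []
        while len(pairs) < 150:
            a, b = rng.choice(genes, 2, replace=False)
            if chrom[a] != chrom[b]:
                pairs.append((min(a, b), max(a, b)))
        lt = links_from_pairs(sorted(set(pairs)), ds.annotation)
        tab = cx.expression_rank_link_enrichment(small_expr, lt, ds.annotation,
                                                 bin_size=40, n_perm=400, seed=1)
        for row in tab.itertuples(index=False):
            se = row.expected_sd / max(row.expected_endpoints, 1)
            assert abs(row.enrichment_ratio - 1) < max(3 * se, 0.35)

    def test_concentrated_links_match_closed_form(self, grid4):
        ann, _ = grid4
        # all endpoints on genes of one bin of size 3 out of 12:
        # expected endpoints for a random 3-gene group = total_endpoints*3/12
        lt = links_from_pairs([("g11", "g21"), ("g11", "g31"), ("g21", "g31")], ann)
        linked = {"g11", "g21", "g31"}
        # give the three linked genes the lowest expression so they share a bin
        expr = cx.normalize_samples(make_expression(
            {g: np.full(40, (1.0 if g in linked else 10.0) + i)
             for i, g in enumerate(ann.gene_ids)}))
        tab = cx.expression_rank_link_enrichment(expr, lt, ann, bin_size=3,
                                                 n_perm=4000, seed=2)
        linked_bin = tab[tab["observed_endpoints"] == 6].iloc[0]
        assert linked_bin["expected_endpoints"] == pytest.approx(6 * 3 / 12, rel=0.1)


class TestArmPositionProfile:
    @pytest.fixture
    def arm_ann(self):
        return make_annotation(
            [("tel", "c1", 99_000, 99_800, "+"),   # at the right telomere
             ("cen", "c1", 40_300, 40_700, "+"),   # midpoint inside centromere
             ("mid", "c1", 70_000, 70_400, "+"),
             ("oth", "c2", 10_000, 10_400, "+")],
            {"c1": 100_000, "c2": 100_000},
            {"c1": (40_000, 41_000), "c2": (40_000, 41_000)})

    def test_relative_positions(self, arm_ann):
        from chromexpr.coexpression import relative_arm_position

        assert relative_arm_position(arm_ann, "cen") == 0.0
        assert relative_arm_position(arm_ann, "tel") == pytest.approx(0.993, abs=0.01)
        # mid gene: (70200-40500)/(100000-40500) = 0.499
        assert relative_arm_position(arm_ann, "mid") == pytest.approx(0.499, abs=0.01)

    def test_uniform_data_bins_flat(self, small_dataset, small_expr):
        tab = cx.centromere_telomere_profile(small_expr, small_dataset.annotation,
                                             n_bins=5)
        vals = tab["mean_within_bin_correlation"].dropna()
        # no positional structure planted: bins scatter around zero
        assert np.nanmax(np.abs(vals)) < 0.15


class TestExclusion:
    def test_empty_exclusion_zero_delta(self, grid4):
        ann, expr = grid4
        lt = links_from_pairs([("g11", "g21"), ("g11", "g31")], ann)
        rep = cx.exclude_pairs_recompute(lt, expr, ann, min_shared=10)
        assert rep["masked_delta_linked"] == 0.0
        assert rep["removed_delta_background"] == 0.0

    def test_excluding_every_gene_rejected(self, grid4):
        ann, expr = grid4
        lt = links_from_pairs([("g11", "g21")], ann)
        with pytest.raises(ValueError):
            cx.exclude_pairs_recompute(lt, expr, ann, excluded_genes=ann.gene_ids,
                                       min_shared=10)

    def test_masked_delta_matches_hand_recomputation(self, grid4):
        ann, expr = grid4
        pairs = [("g11", "g21"), ("g11", "g31"), ("g21", "g31")]
        lt = links_from_pairs(pairs, ann)
        rep = cx.exclude_pairs_recompute(lt, expr, ann,
                                         excluded_pairs=[("g11", "g21")],
                                         min_shared=10)
        r = cx.pearson(expr, pairs, min_shared=10)
        expected_masked = np.mean(r[1:])
        assert rep["masked_mean_linked"] == pytest.approx(expected_masked, abs=1e-12)
        assert rep["masked_delta_linked"] == pytest.approx(
            expected_masked - np.mean(r), abs=1e-12)
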