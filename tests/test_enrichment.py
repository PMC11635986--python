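"""Annotation overlap, odds-ratio enrichment, loops, gene distances."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pleioqtl.enrichment import (
    annotate_overlap,
    closest_gene_distance,
    consequence_enrichment,
    enrichment_odds_ratio,
    link_in_loop,
    links_in_loops,
    odds_ratio,
)
from pleioqtl.io import GenomicInterval, LoopPair
from pleioqtl.pleiotropy import PleioAnnotation


class TestAnnotateOverlap:
    def test_distinct_names_counted_once(self):
        variants = {"v1": ("chr1", 1000)}
        peaks = [
            GenomicInterval("chr1", 995, 1005, "A"),
            GenomicInterval("chr1", 990, 1010, "A"),
            GenomicInterval("chr1", 999, 1001, "B"),
        ]
        df = annotate_overlap(variants, peaks, flank=10)
        assert bool(df.loc["v1", "annotated"]) is True
        assert df.loc["v1", "distinct_names"] == 2

    def test_window_boundary_closed(self):
        variants = {"v1": ("chr1", 1000)}
        touching = [GenomicInterval("chr1", 980, 990, "A")]  # ends at pos-flank
        df = annotate_overlap(variants, touching, flank=10)
        assert bool(df.loc["v1", "annotated"]) is True
        outside = [GenomicInterval("chr1", 980, 989, "A")]  # ends at pos-flank-1
        df = annotate_overlap(variants, outside, flank=10)
        assert bool(df.loc["v1", "annotated"]) is False

    def test_zero_flank_is_point_membership(self):
        variants = {"in": ("chr1", 100), "edge": ("chr1", 200), "out": ("chr1", 201)}
        ivs = [GenomicInterval("chr1", 100, 200)]
        df = annotate_overlap(variants, ivs, flank=0)
        assert bool(df.loc["in", "annotated"]) and bool(df.loc["edge", "annotated"])
        assert not bool(df.loc["out", "annotated"])

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            annotate_overlap({}, [], flank=-1)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        variants = {
            f"v{i}": (f"chr{rng.integers(1, 3)}", int(rng.integers(1, 100_000)))
            for i in range(300)
        }
        intervals = []
        for i in range(300):
            start = int(rng.integers(1, 100_000))
            intervals.append(
                GenomicInterval(
                    f"chr{rng.integers(1, 3)}", start, start + int(rng.integers(1, 500)),
                    name=f"tf{rng.integers(1, 20)}",
                )
            )
        flank = 10
        df = annotate_overlap(variants, intervals, flank=flank)
        for vid, (chrom, pos) in variants.items():
            hits = {
                iv.name
                for iv in intervals
                if iv.chrom == chrom and iv.start <= pos + flank and pos - flank <= iv.end
            }
            assert bool(df.loc[vid, "annotated"]) == bool(hits)
            assert df.loc[vid, "distinct_names"] == len(hits)


class TestOddsRatio:
    def test_point_estimate(self):
        assert odds_ratio(20, 80, 10, 90) == pytest.approx(2.25)

    def test_zero_cell_continuity_correction(self):
        assert odds_ratio(5, 0, 3, 7) == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_reciprocal_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 50, 4))
            assert odds_ratio(a, b, c, d) * odds_ratio(c, d, a, b) == pytest.approx(1.0)


class TestEnrichmentOddsRatio:
    def test_two_by_two_against_baseline(self):
        groups = {f"g{i}": "2" for i in range(100)} | {
            f"b{i}": "1" for i in range(100)
        }
        flags = {f"g{i}": i < 20 for i in range(100)} | {
            f"b{i}": i < 10 for i in range(100)
        }
        (res,) = enrichment_odds_ratio(groups, flags, "1", sided="greater")
        assert (res.a, res.b, res.c, res.d) == (20, 80, 10, 90)
        assert res.odds_ratio == pytest.approx(2.25)

    def test_identical_rates_give_unit_or_and_ns(self):
        groups = {f"g{i}": "2" for i in range(50)} | {f"b{i}": "1" for i in range(50)}
        flags = {f"g{i}": i < 10 for i in range(50)} | {f"b{i}": i < 10 for i in range(50)}
        (res,) = enrichment_odds_ratio(groups, flags, "1", sided="two-sided")
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.fisher_p >= 0.05

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            enrichment_odds_ratio({"v": "2"}, {"v": True}, "1")

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        # exhaustive sweep over small tables with fixed total
        def oracle_two_sided(a, b, c, d):
            n = a + b + c + d
            row1, col1 = a + b, a + c
            kmin = max(0, row1 + col1 - n)
            kmax = min(row1, col1)
            pmf = {k: stats.hypergeom.pmf(k, n, col1, row1) for k in range(kmin, kmax + 1)}
            p_obs = pmf[a]
            return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))

        for n in (8, 12):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
                assert p == pytest.approx(oracle_two_sided(a, b, c, d), rel=1e-8, abs=1e-12)


class TestConsequenceEnrichment:
    def test_planted_double_rate_recovered(self):
        rng = np.random.default_rng(2)
        groups = {}
        table = {}
        for i in range(2000):
            vid = f"v{i}"
            pleio = i < 1000
            groups[vid] = "2" if pleio else "1"
            rate = 0.2 if pleio else 0.111112  # odds 0.25 vs 0.125 -> OR 2
            table[vid] = "missense" if rng.uniform() < rate else "intronic"
        res = consequence_enrichment(groups, table, "1")["missense"][0]
        assert 1.4 < res.odds_ratio < 2.9

    def test_uniform_class_gives_unit_or(self):
        groups = {"a": "2", "b": "2", "c": "1", "d": "1"}
        table = {v: "intronic" for v in groups}
        res = consequence_enrichment(groups, table, "1")["intronic"][0]
        assert res.odds_ratio == pytest.approx(1.0)

    def test_empty_table_classes_unannotated(self):
        groups = {"a": "2", "b": "1"}
        out = consequence_enrichment(groups, {}, "1")
        assert list(out) == ["unannotated"]


class TestLinkInLoop:
    LOOPS = [
        LoopPair(GenomicInterval("chr1", 500, 600), GenomicInterval("chr1", 9_500, 10_000))
    ]

    def test_contained_link(self):
        assert link_in_loop(1_000, 5_000, self.LOOPS, chrom="chr1") is True

    def test_straddling_link_not_contained(self):
        assert link_in_loop(400, 5_000, self.LOOPS, chrom="chr1") is False
        assert link_in_loop(1_000, 10_500, self.LOOPS, chrom="chr1") is False

    def test_cross_chromosome_never_contained(self):
        assert link_in_loop(1_000, 5_000, self.LOOPS, chrom="chr2") is False

    def test_inner_span_mode_stricter(self):
        # between anchors: [600, 9,500]
        assert link_in_loop(550, 5_000, self.LOOPS, chrom="chr1", inner_span=True) is False
        assert link_in_loop(700, 5_000, self.LOOPS, chrom="chr1", inner_span=True) is True

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        loops = []
        for _ in range(50):
            s = int(rng.integers(1, 50_000))
            w1 = int(rng.integers(100, 1000))
            gap = int(rng.integers(1000, 20_000))
            w2 = int(rng.integers(100, 1000))
            loops.append(
                LoopPair(
                    GenomicInterval("chr1", s, s + w1),
                    GenomicInterval("chr1", s + w1 + gap, s + w1 + gap + w2),
                )
            )
        links = [
            (f"l{i}", "chr1", int(rng.integers(1, 80_000)), int(rng.integers(1, 80_000)))
            for i in range(200)
        ]
        got = links_in_loops(links, loops)
        for lid, chrom, vp, gp in links:
            lo, hi = sorted((vp, gp))
            expected = any(lp.span.start <= lo and hi <= lp.span.end for lp in loops)
            assert got[lid] == expected


class TestClosestGeneDistance:
    MODELS = {
        "gene_in": GenomicInterval("chr1", 900, 1_100, "gene_in"),
        "gene_up": GenomicInterval("chr1", 1_500, 2_000, "gene_up"),
        "gene_far": GenomicInterval("chr1", 50_000, 60_000, "gene_far"),
    }

    def _ann(self, vid, pos, n_cats, genes):
        cats = {f"c{i}" for i in range(n_cats)}
        return PleioAnnotation(vid, "chr1", pos, cats, set(genes), {"t"}, [])

    def test_inside_gene_body_distance_zero(self):
        recs, _ = closest_gene_distance(
            [self._ann("v1", 1_000, 1, ["gene_in", "gene_far"])], self.MODELS
        )
        assert recs[0].closest_gene_distance == 0
        assert recs[0].furthest_gene_distance == 49_000

    def test_upstream_distance_to_gene_edge(self):
        recs, _ = closest_gene_distance([self._ann("v1", 1_000, 1, ["gene_up"])], self.MODELS)
        assert recs[0].closest_gene_distance == 500

    def test_missing_gene_model_is_error(self):
        with pytest.raises(KeyError, match="gene_x"):
            closest_gene_distance([self._ann("v1", 1_000, 1, ["gene_x"])], self.MODELS)

    def test_planted_gradient_gives_decreasing_medians(self):
        rng = np.random.default_rng(4)
        models = {}
        anns = []
        base_dists = {1: 35_000, 2: 23_000, 3: 18_000}
        i = 0
        for n_cats, base in base_dists.items():
            for _ in range(30):
                pos = int(rng.integers(1, 10**7))
                gene = f"g{i}"
                d = int(base + rng.integers(-2_000, 2_000))
                models[gene] = GenomicInterval("chr1", pos + d, pos + d + 5_000, gene)
                anns.append(self._ann(f"v{i}", pos, n_cats, [gene]))
                i += 1
        _, summary = closest_gene_distance(anns, models)
        medians = summary.set_index("bin")["median_closest"]
        assert medians["1"] > medians["2"] > medians[">=3"]
        assert summary["mwu_p_vs_prev"].dropna().max() < 0.05
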