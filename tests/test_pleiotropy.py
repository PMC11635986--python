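"""Pleiotropy annotation, region merging, and concentration summaries."""

import math

import numpy as np
import pytest

from pleioqtl.coloc import ColocPair
from pleioqtl.harmonize import LeadVariant
from pleioqtl.io import GenomicInterval
from pleioqtl.pleiotropy import (
    annotate_pleiotropy,
    category_bin,
    explained_by_category,
    explained_loci,
    merge_regions,
    region_summaries,
    specificity_profile,
)

from conftest import make_record


def make_pair(variant_id="rs1", chrom="chr1", pos=1000, trait="t1", gene="g1",
              tissue="ts1", gwas_id=None, beta_eqtl=0.2, snp_pp=0.8):
    return ColocPair(
        variant_id=variant_id, chrom=chrom, pos=pos,
        gwas_id=gwas_id or f"gwas_{trait}", trait_id=trait,
        eqtl_study=f"eqtl_{gene}_{tissue}", gene_id=gene, tissue_id=tissue,
        beta_gwas=0.1, beta_eqtl=beta_eqtl, p_gwas=1e-9, p_eqtl=1e-10,
        eaf=0.3, pp_h4=0.9, snp_pp_h4=snp_pp, n_gwas=50_000,
    )


CATEGORY_MAP = {
    "t_allergy": "allergic disease",
    "t_cvd": "cardiovascular disease",
    "t_htn": "hypertensive disorder",
    "t_mental": "mental or behavioural disorder",
    "t_other": "allergic disease",
}


class TestAnnotatePleiotropy:
    def test_categories_are_set_unions(self):
        pairs = [
            make_pair(trait="t_allergy"),
            make_pair(trait="t_cvd"),
            make_pair(trait="t_other"),  # same category as t_allergy
        ]
        (ann,) = annotate_pleiotropy(pairs, CATEGORY_MAP)
        assert ann.category_count == 2

    def test_four_planted_categories_recovered(self):
        # mirrors a maximally pleiotropic regulatory variant near a gene,
        # colocalized with traits of four distinct categories
        pairs = [
            make_pair("rs301802", "chr1", 8_437_247, trait=t, gene="ENO1")
            for t in ("t_allergy", "t_cvd", "t_htn", "t_mental")
        ]
        (ann,) = annotate_pleiotropy(pairs, CATEGORY_MAP)
        assert ann.category_count == 4
        assert ann.genes == {"ENO1"}

    def test_unmapped_trait_is_error(self):
        with pytest.raises(KeyError, match="t_unknown"):
            annotate_pleiotropy([make_pair(trait="t_unknown")], CATEGORY_MAP)

    def test_one_annotation_per_distinct_variant(self):
        pairs = [
            make_pair("rs1", pos=100, trait="t_allergy"),
            make_pair("rs1", pos=100, trait="t_cvd", gene="g2"),
            make_pair("rs2", pos=200, trait="t_cvd"),
        ]
        anns = annotate_pleiotropy(pairs, CATEGORY_MAP)
        assert [a.variant_id for a in anns] == ["rs1", "rs2"]
        assert anns[0].gene_count == 2


def annotation(variant_id, pos, n_cats, chrom="chr1", genes=("g1",)):
    from pleioqtl.pleiotropy import PleioAnnotation

    cats = {f"cat{i}" for i in range(n_cats)}
    pairs = [make_pair(variant_id, chrom, pos, trait=f"t{i}", gene=g)
             for i, g in enumerate(genes)]
    return PleioAnnotation(variant_id, chrom, pos, cats, set(genes), {"ts1"}, pairs)


def reference_partition(positions, max_gap):
    """O(n^2) transitive closure of the pairwise gap rule via union-find."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, pi = positions[i]
            cj, pj = positions[j]
            if ci == cj and abs(pi - pj) < max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestMergeRegions:
    def test_singleton(self):
        (region,) = merge_regions([annotation("rs1", 500, 2)])
        assert (region.chrom, region.start, region.end) == ("chr1", 500, 500)
        assert region.length == 1 and region.eqtl_count == 1

    def test_gap_boundary_strictly_less_than_threshold(self):
        merged = merge_regions(
            [annotation("rs1", 100_000, 2), annotation("rs2", 199_999, 2)]
        )
        assert len(merged) == 1  # gap 99,999 < 100,000
        split = merge_regions(
            [annotation("rs1", 100_000, 2), annotation("rs2", 200_000, 2)]
        )
        assert len(split) == 2  # gap 100,000 not merged

    def test_min_categories_gate(self):
        regions = merge_regions(
            [annotation("rs1", 100, 1), annotation("rs2", 200, 2)]
        )
        assert len(regions) == 1 and regions[0].members[0].variant_id == "rs2"

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        anns = [
            annotation(
                f"rs{i}",
                int(rng.integers(1, 3_000_000)),
                2,
                chrom=f"chr{rng.integers(1, 4)}",
            )
            for i in range(200)
        ]
        regions = merge_regions(anns)
        got = {
            frozenset(anns.index(m) for m in r.members) for r in regions
        }
        expected = reference_partition([(a.chrom, a.pos) for a in anns], 100_000)
        assert got == expected

    def test_partition_invariants(self):
        rng = np.random.default_rng(7)
        anns = [annotation(f"rs{i}", int(rng.integers(1, 10**6)), 2) for i in range(80)]
        regions = merge_regions(anns)
        seen = set()
        for r in regions:
            for m in r.members:
                assert r.start <= m.pos <= r.end
                assert m.variant_id not in seen
                seen.add(m.variant_id)
        assert seen == {a.variant_id for a in anns}
        assert sum(r.eqtl_count for r in regions) == len(anns)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        anns = [annotation(f"rs{i}", int(rng.integers(1, 10**6)), 2) for i in range(50)]
        regions = merge_regions(anns)
        again = merge_regions([m for r in regions for m in r.members])
        assert {(r.chrom, r.start, r.end) for r in regions} == {
            (r.chrom, r.start, r.end) for r in again
        }

    def test_gene_marker_most_frequent_then_lexicographic(self):
        a1 = annotation("rs1", 100, 2, genes=("gB", "gA"))
        a2 = annotation("rs2", 200, 2, genes=("gA",))
        (region,) = merge_regions([a1, a2])
        assert region.gene_marker == "gA"  # 2 votes beats 1
        a3 = annotation("rs3", 100, 2, genes=("gB",))
        a4 = annotation("rs4", 200, 2, genes=("gA",))
        (region,) = merge_regions([a3, a4])
        assert region.gene_marker == "gA"  # tie broken lexicographically


# printed start/end/length rows of the published pleiotropic-region table
# (1-based inclusive, hg38) — regression fixture for the length convention
PUBLISHED_REGIONS = [
    ("chr5", 132_239_645, 132_497_907, 258_263),
    ("chr9", 21_950_524, 22_207_038, 256_515),
    ("chr9", 133_242_881, 133_278_537, 35_657),
    ("chr11", 65_488_118, 65_638_129, 150_012),
    ("chr11", 65_747_403, 65_909_045, 161_643),
    ("chr15", 74_751_897, 74_843_920, 92_024),
    ("chr15", 78_428_581, 78_762_558, 333_978),
    ("chr15", 90_861_475, 91_070_064, 208_590),
    ("chr16", 89_626_691, 89_808_935, 182_245),
    ("chr17", 2_006_529, 2_311_037, 304_509),
    ("chr17", 7_452_302, 7_718_459, 266_158),
    ("chr20", 63_588_387, 63_857_282, 268_896),
    # largest reported pleiotropic region
    ("chr7", 2_712_518, 7_254_268, 4_541_751),
]


class TestRegionSummaries:
    @pytest.mark.parametrize("chrom,start,end,length", PUBLISHED_REGIONS)
    def test_inclusive_length_matches_published_regions(self, chrom, start, end, length):
        assert GenomicInterval(chrom, start, end).length == length

    def test_cumulative_length_and_proportions(self):
        from pleioqtl.pleiotropy import Region

        r1 = Region("chr1", 1_000, 6_000 - 1, categories={"a", "b"})
        r2 = Region("chr2", 10_000, 60_000 - 1, categories={"a", "b", "c"})
        summary = region_summaries([r1, r2])
        assert r1.length == 5_000 and r2.length == 50_000
        assert summary["cumulative_length_bp"][2] == 55_000
        assert summary["cumulative_length_bp"][3] == 50_000
        assert summary["proportion_le"][10_000] == 0.5

    def test_empty_region_list(self):
        summary = region_summaries([])
        assert summary["n_regions"] == 0
        assert all(v == 0.0 for v in summary["proportion_le"].values())


class TestSpecificityProfile:
    def test_all_single_category(self):
        anns = [annotation(f"rs{i}", 100 * i + 1, 1) for i in range(10)]
        prof = specificity_profile(anns)
        assert prof["proportions"]["category_count"] == {1: 1.0}

    def test_monotone_counts_give_unit_spearman(self):
        from pleioqtl.pleiotropy import PleioAnnotation

        anns = []
        for i in range(1, 4):
            cats = {f"c{j}" for j in range(i)}
            genes = {f"g{j}" for j in range(2 * i)}
            anns.append(PleioAnnotation(f"rs{i}", "chr1", i * 100, cats, genes, {"t"}, []))
        prof = specificity_profile(anns)
        assert prof["spearman"].loc["category_count", "gene_count"] == pytest.approx(1.0)

    def test_cumulative_gene_curves_partitioned_by_bin(self):
        anns = [annotation("rs1", 100, 1, genes=("g1",)),
                annotation("rs2", 200, 3, genes=("g1", "g2", "g3"))]
        prof = specificity_profile(anns)
        curves = prof["cumulative_gene_curves"]
        assert curves["1"][1] == 1.0
        assert curves[">=3"][1] == 0.0 and curves[">=3"][3] == 1.0


def wilson_interval_oracle(k, n, z=1.959963984540054):
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


class TestExplainedLoci:
    def _leads(self, n, study="gwas_a"):
        return [
            LeadVariant(make_record(f"lead{i}", pos=10_000_000 * (i + 1), study_id=study))
            for i in range(n)
        ]

    def test_proportion_and_wilson_interval(self):
        leads = self._leads(4)
        pairs = [
            make_pair(f"rs{i}", pos=10_000_000 * (i + 1) + 500, trait="t",
                      gwas_id="gwas_a")
            for i in range(3)
        ]
        df = explained_loci(leads, pairs)
        row = df.iloc[0]
        assert row["proportion"] == 0.75
        lo, hi = wilson_interval_oracle(3, 4)
        assert row["ci_low"] == pytest.approx(lo, abs=1e-9)
        assert row["ci_high"] == pytest.approx(hi, abs=1e-9)

    def test_zero_pairs_gives_zero(self):
        df = explained_loci(self._leads(3), [])
        assert df["proportion"].iloc[0] == 0.0

    def test_category_aggregation_modes(self):
        leads = self._leads(4, "gwas_a") + self._leads(2, "gwas_b")
        pairs = [
            make_pair(f"rs{i}", pos=10_000_000 * (i + 1) + 500, gwas_id="gwas_a")
            for i in range(2)  # gwas_a: 2/4 explained; gwas_b: 0/2
        ]
        df = explained_loci(
            leads, pairs,
            category_map={"tA": "catX", "tB": "catX"},
            trait_of_study={"gwas_a": "tA", "gwas_b": "tB"},
        )
        averaged = explained_by_category(df)
        assert averaged["proportion"].iloc[0] == pytest.approx((0.5 + 0.0) / 2)
        pooled = explained_by_category(df, pooled=True)
        assert pooled["proportion"].iloc[0] == pytest.approx(2 / 6)
        lo, hi = wilson_interval_oracle(2, 6)
        assert pooled["ci_low"].iloc[0] == pytest.approx(lo, abs=1e-9)

    def test_pair_at_exact_radius_counts(self):
        leads = self._leads(1)
        pair_at = make_pair("rs1", pos=leads[0].pos + 1_000_000, gwas_id="gwas_a")
        assert explained_loci(leads, [pair_at])["n_explained"].iloc[0] == 1
        pair_out = make_pair("rs1", pos=leads[0].pos + 1_000_001, gwas_id="gwas_a")
        assert explained_loci(leads, [pair_out])["n_explained"].iloc[0] == 0


def test_category_bin_labels():
    assert category_bin(1) == "1"
    assert category_bin(2) == "2"
    assert category_bin(3) == ">=3"
    assert category_bin(7) == ">=3"
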