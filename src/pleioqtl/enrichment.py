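"""Overlap and enrichment of colocalized variants with regulatory annotation.

Every enrichment is an odds ratio of an annotation flag in a variant group
against the single-category baseline group, with a Fisher exact test.  Zero
cells get the Haldane-Anscombe +0.5 correction for the odds-ratio point
estimate only; the Fisher p-value is always computed on the raw counts.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import GenomicInterval, LoopPair
from .pleiotropy import PleioAnnotation, category_bin, DEFAULT_BINS

__all__ = [
    "EnrichmentResult",
    "GeneDistanceRecord",
    "annotate_overlap",
    "enrichment_odds_ratio",
    "consequence_enrichment",
    "link_in_loop",
    "links_in_loops",
    "closest_gene_distance",
    "odds_ratio",
]


@dataclass
class EnrichmentResult:
    """2x2 enrichment of one group against the baseline.

    a = group & annotated, b = group & not, c = baseline & annotated,
    d = baseline & not.
    """

    group: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    fisher_p: float
    sided: str


@dataclass
class GeneDistanceRecord:
    variant_id: str
    closest_gene_distance: int
    furthest_gene_distance: int
    bin: str


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c) with +0.5 continuity correction when any cell is zero."""
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be >= 0")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def annotate_overlap(
    variants: Mapping[str, tuple[str, int]],
    intervals: Iterable[GenomicInterval],
    flank: int = 0,
) -> pd.DataFrame:
    """Flag variants overlapped by intervals; count distinct interval names.

    A variant (chrom, pos) is flagged when any interval intersects the closed
    window [pos - flank, pos + flank]; the count is the number of distinct
    interval names intersecting that window (a radius-10 flank reproduces the
    20 bp transcription-factor window convention).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        # tree coordinates half-open on 1-based positions: [start, end + 1)
        trees[iv.chrom].addi(iv.start, iv.end + 1, iv.name)
    rows = []
    for vid in sorted(variants):
        chrom, pos = variants[vid]
        hits = trees[chrom].overlap(pos - flank, pos + flank + 1) if chrom in trees else ()
        names = {h.data for h in hits}
        rows.append(
            {
                "variant_id": vid,
                "annotated": bool(hits),
                "distinct_names": len(names),
            }
        )
    return pd.DataFrame(rows).set_index("variant_id")


def enrichment_odds_ratio(
    group_assignment: Mapping[str, str],
    flags: Mapping[str, bool],
    baseline_label: str,
    sided: str = "greater",
) -> list[EnrichmentResult]:
    """Per non-baseline group: 2x2 table against baseline, OR and Fisher p."""
    if sided not in ("two-sided", "greater", "less"):
        raise ValueError(f"invalid sidedness {sided!r}")
    labels = set(group_assignment.values())
    if baseline_label not in labels:
        raise ValueError(f"baseline label {baseline_label!r} not present")
    members: dict[str, list[str]] = defaultdict(list)
    for vid, lab in group_assignment.items():
        members[lab].append(vid)
    c = sum(flags.get(v, False) for v in members[baseline_label])
    d = len(members[baseline_label]) - c
    out = []
    for lab in sorted(labels - {baseline_label}):
        vids = members[lab]
        if not vids:
            continue
        a = sum(flags.get(v, False) for v in vids)
        b = len(vids) - a
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=sided)
        out.append(EnrichmentResult(lab, a, b, c, d, odds_ratio(a, b, c, d), float(p), sided))
    return out


def consequence_enrichment(
    group_assignment: Mapping[str, str],
    consequence_table: Mapping[str, str],
    baseline_label: str = "1",
    sided: str = "two-sided",
) -> dict[str, list[EnrichmentResult]]:
    """Odds ratios per predicted consequence class vs the baseline group.

    Variants missing from the table are classed ``unannotated``.  The default
    two-sided Fisher test matches the convention for consequence comparisons.
    """
    classes = {
        vid: consequence_table.get(vid, "unannotated") for vid in group_assignment
    }
    out: dict[str, list[EnrichmentResult]] = {}
    for cls in sorted(set(classes.values())):
        flags = {vid: classes[vid] == cls for vid in group_assignment}
        out[cls] = enrichment_odds_ratio(group_assignment, flags, baseline_label, sided)
    return out


def link_in_loop(
    variant_pos: int,
    gene_anchor_pos: int,
    loops: Sequence[LoopPair],
    chrom: str | None = None,
    inner_span: bool = False,
) -> bool:
    """True iff the variant-gene link interval is contained in some loop span.

    The link interval is [min(pos, gene_pos), max(pos, gene_pos)]; the loop
    span is the outer span [anchor_a.start, anchor_b.end] by default, or the
    inner span (between anchors) with ``inner_span=True``.  Cross-chromosome
    links are never contained.
    """
    lo, hi = sorted((variant_pos, gene_anchor_pos))
    for lp in loops:
        if chrom is not None and lp.chrom != chrom:
            continue
        span = lp.inner_span if inner_span else lp.span
        if span.start <= lo and hi <= span.end:
            return True
    return False


def links_in_loops(
    links: Sequence[tuple[str, str, int, int]],
    loops: Sequence[LoopPair],
    inner_span: bool = False,
) -> dict[str, bool]:
    """Vector version: links are (link_id, chrom, variant_pos, gene_pos)."""
    return {
        lid: link_in_loop(vp, gp, loops, chrom=chrom, inner_span=inner_span)
        for lid, chrom, vp, gp in links
    }


def _gene_distance(pos: int, model: GenomicInterval, use_tss: bool) -> int:
    if use_tss:
        return abs(pos - model.start)
    if model.contains(pos):
        return 0
    return min(abs(pos - model.start), abs(pos - model.end))


def closest_gene_distance(
    annotations: Sequence[PleioAnnotation],
    gene_models: Mapping[str, GenomicInterval],
    bins: Sequence[int] = DEFAULT_BINS,
    use_tss: bool = False,
) -> tuple[list[GeneDistanceRecord], pd.DataFrame]:
    """Distance of each variant to its closest and furthest target gene.

    Distance is 0 inside the gene body, else the distance to the nearer gene
    edge (or to the gene start with ``use_tss=True``).  Returns per-variant
    records plus a per-category-bin summary with median closest distances and
    Mann-Whitney p-values between adjacent bins.
    """
    records = []
    for a in annotations:
        if not a.genes:
            continue
        missing = sorted(g for g in a.genes if g not in gene_models)
        if missing:
            raise KeyError(f"gene(s) without model: {', '.join(missing)}")
        dists = [_gene_distance(a.pos, gene_models[g], use_tss) for g in sorted(a.genes)]
        records.append(
            GeneDistanceRecord(
                a.variant_id,
                min(dists),
                max(dists),
                category_bin(a.category_count, bins),
            )
        )
    df = pd.DataFrame(
        {
            "bin": [r.bin for r in records],
            "closest": [r.closest_gene_distance for r in records],
        }
    )
    order = [category_bin(b, bins) for b in sorted(set(bins))]
    rows = []
    prev_label = None
    for label in order:
        vals = df.loc[df["bin"] == label, "closest"]
        row = {"bin": label, "n": len(vals),
               "median_closest": float(vals.median()) if len(vals) else math.nan}
        if prev_label is not None:
            prev_vals = df.loc[df["bin"] == prev_label, "closest"]
            if len(vals) >= 2 and len(prev_vals) >= 2:
                row["mwu_p_vs_prev"] = float(
                    stats.mannwhitneyu(prev_vals, vals, alternative="two-sided").pvalue
                )
            else:
                row["mwu_p_vs_prev"] = math.nan
        prev_label = label
        rows.append(row)
    return records, pd.DataFrame(rows)
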