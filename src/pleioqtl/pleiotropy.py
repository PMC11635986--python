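"""Pleiotropy characterization of colocalized variants.

A colocalized eQTL variant is annotated with the set of trait categories,
target genes, and tissues accumulated over its retained colocalization
pairs; a *pleiotropic eQTL* is one linked to two or more trait categories.
Qualifying variants are merged into pleiotropic regions whenever successive
variants lie less than a gap threshold apart (transitive closure of the
pairwise rule, 100 kb by default), and region-level summaries report
cumulative genomic length by minimum category count and the region length
distribution.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .coloc import ColocPair
from .harmonize import LeadVariant
from .io import chrom_sort_key

__all__ = [
    "PleioAnnotation",
    "Region",
    "annotate_pleiotropy",
    "merge_regions",
    "region_summaries",
    "specificity_profile",
    "explained_loci",
    "category_bin",
    "DEFAULT_BINS",
]

#: Category-count bins used throughout the group comparisons: 1, 2, >= 3.
DEFAULT_BINS = (1, 2, 3)


def category_bin(count: int, bins: Sequence[int] = DEFAULT_BINS) -> str:
    """Bin a category count into the standard {1, 2, >=3} labels."""
    bins = sorted(bins)
    for b in bins[:-1]:
        if count == b:
            return str(b)
    return f">={bins[-1]}"


@dataclass
class PleioAnnotation:
    """Per-variant pleiotropy annotation (unions over retained pairs)."""

    variant_id: str
    chrom: str
    pos: int
    categories: set[str]
    genes: set[str]
    tissues: set[str]
    pairs: list[ColocPair] = field(default_factory=list, repr=False)

    @property
    def category_count(self) -> int:
        return len(self.categories)

    @property
    def gene_count(self) -> int:
        return len(self.genes)

    @property
    def tissue_count(self) -> int:
        return len(self.tissues)


@dataclass
class Region:
    """A merged pleiotropic genomic segment (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    categories: set[str]
    members: list[PleioAnnotation] = field(default_factory=list, repr=False)
    gene_marker: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def eqtl_count(self) -> int:
        return len(self.members)

    @property
    def name(self) -> str:
        return f"{self.gene_marker or 'region'}|{len(self.categories)}cat"


def annotate_pleiotropy(
    pairs: Iterable[ColocPair],
    category_map: Mapping[str, str],
) -> list[PleioAnnotation]:
    """Annotate each distinct colocalized variant with category/gene/tissue sets.

    Raises :class:`KeyError` listing any trait absent from the category map.
    """
    pairs = list(pairs)
    unmapped = sorted({p.trait_id for p in pairs} - set(category_map))
    if unmapped:
        raise KeyError(f"traits missing from category map: {', '.join(unmapped)}")
    by_variant: dict[str, PleioAnnotation] = {}
    for p in pairs:
        ann = by_variant.get(p.variant_id)
        if ann is None:
            ann = PleioAnnotation(p.variant_id, p.chrom, p.pos, set(), set(), set())
            by_variant[ann.variant_id] = ann
        ann.categories.add(category_map[p.trait_id])
        if p.gene_id:
            ann.genes.add(p.gene_id)
        if p.tissue_id:
            ann.tissues.add(p.tissue_id)
        ann.pairs.append(p)
    return sorted(
        by_variant.values(), key=lambda a: (chrom_sort_key(a.chrom), a.pos, a.variant_id)
    )


def merge_regions(
    annotations: Iterable[PleioAnnotation],
    max_gap: int = 100_000,
    min_categories: int = 2,
) -> list[Region]:
    """Merge qualifying variants into regions by transitive gap closure.

    Variants with ``category_count >= min_categories`` are sorted by
    (chrom, pos) and merged while the gap between successive positions is
    strictly less than ``max_gap``; each qualifying variant lands in exactly
    one region.  A region's category set is the union over its members and
    its gene marker is the most frequent gene among member pairs (ties by
    gene id).
    """
    qual = sorted(
        (a for a in annotations if a.category_count >= min_categories),
        key=lambda a: (chrom_sort_key(a.chrom), a.pos, a.variant_id),
    )
    regions: list[Region] = []
    current: list[PleioAnnotation] = []

    def close() -> None:
        if not current:
            return
        cats: set[str] = set()
        gene_votes: Counter[str] = Counter()
        for a in current:
            cats |= a.categories
            for p in a.pairs:
                if p.gene_id:
                    gene_votes[p.gene_id] += 1
        marker = ""
        if gene_votes:
            marker = min(gene_votes, key=lambda g: (-gene_votes[g], g))
        regions.append(
            Region(
                chrom=current[0].chrom,
                start=current[0].pos,
                end=current[-1].pos,
                categories=cats,
                members=list(current),
                gene_marker=marker,
            )
        )
        current.clear()

    for a in qual:
        if current and (
            a.chrom != current[-1].chrom or a.pos - current[-1].pos >= max_gap
        ):
            close()
        current.append(a)
    close()
    return regions


def region_summaries(
    regions: Sequence[Region],
    length_thresholds: Sequence[int] = (10_000, 100_000, 1_000_000),
) -> dict:
    """Cumulative lengths by minimum category count + length distribution.

    ``cumulative_length_bp[k]`` sums region lengths over regions carrying at
    least k trait categories; ``proportion_le[t]`` is the fraction of regions
    with length <= t bp.
    """
    if not regions:
        return {
            "cumulative_length_bp": {},
            "proportion_le": {int(t): 0.0 for t in length_thresholds},
            "n_regions": 0,
        }
    max_k = max(len(r.categories) for r in regions)
    cumulative = {
        k: int(sum(r.length for r in regions if len(r.categories) >= k))
        for k in range(1, max_k + 1)
    }
    lengths = np.array([r.length for r in regions])
    proportions = {
        int(t): float(np.mean(lengths <= t)) for t in length_thresholds
    }
    return {
        "cumulative_length_bp": cumulative,
        "proportion_le": proportions,
        "n_regions": len(regions),
    }


def specificity_profile(
    annotations: Sequence[PleioAnnotation],
    bins: Sequence[int] = DEFAULT_BINS,
) -> dict:
    """Count-specificity summaries of the annotated variants.

    Returns the proportion of variants at each category/gene/tissue count,
    the pairwise Spearman correlations among the three counts, and the
    cumulative proportion of variants at or below each gene count,
    partitioned by category bin ({1, 2, >=3} by default).
    """
    if not annotations:
        raise ValueError("no annotations")
    df = pd.DataFrame(
        {
            "category_count": [a.category_count for a in annotations],
            "gene_count": [a.gene_count for a in annotations],
            "tissue_count": [a.tissue_count for a in annotations],
        }
    )
    proportions = {
        col: (df[col].value_counts(normalize=True).sort_index().to_dict())
        for col in df.columns
    }
    cols = list(df.columns)
    corr = pd.DataFrame(index=cols, columns=cols, dtype=float)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            if a == b:
                rho = 1.0
            elif df[a].nunique() < 2 or df[b].nunique() < 2:
                rho = np.nan
            else:
                rho = float(stats.spearmanr(df[a], df[b]).statistic)
            corr.loc[a, b] = corr.loc[b, a] = rho

    df["bin"] = [category_bin(c, bins) for c in df["category_count"]]
    curves: dict[str, dict[int, float]] = {}
    max_gene = int(df["gene_count"].max())
    for label, sub in df.groupby("bin"):
        curves[str(label)] = {
            g: float(np.mean(sub["gene_count"] <= g)) for g in range(1, max_gene + 1)
        }
    return {"proportions": proportions, "spearman": corr, "cumulative_gene_curves": curves}


def explained_loci(
    leads: Sequence[LeadVariant],
    pairs: Sequence[ColocPair],
    radius: int = 1_000_000,
    category_map: Mapping[str, str] | None = None,
    trait_of_study: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Proportion of lead GWAS variants explained by a colocalized eQTL.

    A lead is explained iff at least one retained pair of the same GWAS lies
    within ``radius`` bp (boundary-inclusive) on the same chromosome.
    Returns one row per GWAS study with Wilson 95% confidence bounds; when a
    category map (and study -> trait map) is supplied, adds the per-category
    average of per-study proportions.
    """
    by_study: dict[str, list[LeadVariant]] = {}
    for lead in leads:
        by_study.setdefault(lead.study_id, []).append(lead)
    pair_pos: dict[str, list[tuple[str, int]]] = {}
    for p in pairs:
        pair_pos.setdefault(p.gwas_id, []).append((p.chrom, p.pos))

    rows = []
    for sid, sleads in sorted(by_study.items()):
        explained = 0
        for lead in sleads:
            hits = pair_pos.get(sid, [])
            if any(c == lead.chrom and abs(pos - lead.pos) <= radius for c, pos in hits):
                explained += 1
        n = len(sleads)
        prop = explained / n
        lo, hi = proportion_confint(explained, n, alpha=0.05, method="wilson")
        rows.append(
            {
                "study_id": sid,
                "n_leads": n,
                "n_explained": explained,
                "proportion": prop,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    df = pd.DataFrame(rows)
    if category_map is not None and trait_of_study is not None and len(df):
        df["category"] = [
            category_map.get(trait_of_study.get(s, ""), "") for s in df["study_id"]
        ]
    return df


def explained_by_category(per_study: pd.DataFrame, pooled: bool = False) -> pd.DataFrame:
    """Aggregate per-study explained proportions to trait categories.

    Default averages the per-study proportions within each category (each
    GWAS weighted equally); ``pooled=True`` instead pools leads across the
    category's studies before computing one proportion and Wilson interval.
    """
    if "category" not in per_study.columns:
        raise ValueError("per-study table lacks a 'category' column")
    rows = []
    for cat, sub in per_study.groupby("category"):
        if pooled:
            k, n = int(sub["n_explained"].sum()), int(sub["n_leads"].sum())
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            rows.append(
                {"category": cat, "n_gwas": len(sub), "n_leads": n,
                 "proportion": k / n, "ci_low": float(lo), "ci_high": float(hi)}
            )
        else:
            rows.append(
                {"category": cat, "n_gwas": len(sub),
                 "n_leads": int(sub["n_leads"].sum()),
                 "proportion": float(sub["proportion"].mean()),
                 "ci_low": math.nan, "ci_high": math.nan}
            )
    return pd.DataFrame(rows)
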