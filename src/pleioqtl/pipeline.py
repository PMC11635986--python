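"""End-to-end orchestration and group-comparison statistics.

``run_pipeline`` drives a cohort directory (the layout written by
:func:`pleioqtl.simulate.simulate_cohort`, or equivalently formatted real
summary statistics) through harmonization, colocalization, pleiotropy
annotation, region building, enrichment and trait similarity, writing every
table plus a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io
from .coloc import ColocPair, ColocPriors, colocalize, filter_colocalized
from .enrichment import annotate_overlap, consequence_enrichment, enrichment_odds_ratio
from .harmonize import (
    MHC_INTERVAL,
    apply_qc_filters,
    extract_window,
    impute_allele_frequency,
    select_lead_variants,
)
from .io import BlockLD
from .pleiotropy import (
    DEFAULT_BINS,
    annotate_pleiotropy,
    category_bin,
    explained_loci,
    merge_regions,
    region_summaries,
    specificity_profile,
)
from .similarity import build_effect_vectors, cluster_traits, filter_traits, spearman_matrix

__all__ = [
    "PipelineConfig",
    "GroupComparison",
    "run_pipeline",
    "compare_groups",
    "significance_stars",
]

#: metrics computable per retained colocalization pair
METRICS = ("abs_beta_eqtl", "abs_beta_gwas", "neg_log10_p_eqtl", "neg_log10_p_gwas", "eaf")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, serialized into all outputs."""

    cohort_dir: str = "."
    out_dir: str = "results"
    lead_p_threshold: float = 5e-8
    clump_r2: float = 0.1
    clump_radius: int = 1_000_000
    window_radius: int = 1_000_000
    pp_h4_min: float = 0.75
    snp_pp_min: float = 0.5
    merge_gap: int = 100_000
    min_categories: int = 2
    mhc: tuple[str, int, int] | None = MHC_INTERVAL
    category_bins: tuple[int, ...] = DEFAULT_BINS
    prior_p1: float = 1e-4
    prior_p2: float = 1e-4
    prior_p12: float = 1e-5
    min_overlap: int = 10
    min_abs_rho: float = 0.05
    min_partners: int = 30
    significant_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pp_h4_min <= 1 and 0 < self.snp_pp_min <= 1):
            raise ValueError("posterior cutoffs must be in (0, 1]")
        if not (0 < self.lead_p_threshold < 1):
            raise ValueError("lead p threshold must be in (0, 1)")
        if self.merge_gap < 1 or self.clump_radius < 1 or self.window_radius < 1:
            raise ValueError("radii and gaps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "mhc" in raw and raw["mhc"] is not None:
            raw["mhc"] = tuple(raw["mhc"])
        if "category_bins" in raw:
            raw["category_bins"] = tuple(raw["category_bins"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        params = {
            k: v for k, v in asdict(self).items() if k not in ("cohort_dir", "out_dir")
        }
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroupComparison:
    """Per-bin medians of one metric with adjacent-bin Mann-Whitney tests."""

    metric: str
    bins: list[str]
    medians: dict[str, float]
    means: dict[str, float]
    n: dict[str, int]
    pvalues: dict[tuple[str, str], float]
    stars: dict[tuple[str, str], str]
    sided: str = "two-sided"


def significance_stars(p: float) -> str:
    """Significance ladder: ns >= 0.05; * < 0.05; ** < 0.01; *** < 0.001; **** < 0.0001."""
    if math.isnan(p) or p >= 0.05:
        return "ns"
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "*"


def _mannwhitney_p(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        return math.nan
    exact = (
        max(len(x), len(y)) <= 50
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_groups(
    annotations,
    metric: str,
    bins: Sequence[int] = DEFAULT_BINS,
    eaf_range: tuple[float, float] | None = None,
    n_range: tuple[float, float] | None = None,
) -> GroupComparison:
    """Compare one per-pair metric across category-count bins.

    Values are taken per retained colocalization pair, grouped by the
    variant's category-count bin.  Optional allele-frequency and sample-size
    range filters (boundary-inclusive) are applied to the pairs first.
    Adjacent bins are compared with a two-sided Mann-Whitney U test (exact
    for small tie-free samples, normal approximation with tie correction
    otherwise); bins with fewer than two values are marked not computable
    (NaN p).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    values: dict[str, list[float]] = {}
    for ann in annotations:
        label = category_bin(ann.category_count, bins)
        for p in ann.pairs:
            if eaf_range is not None:
                if p.eaf is None or not (eaf_range[0] <= p.eaf <= eaf_range[1]):
                    continue
            if n_range is not None:
                if p.n_gwas is None or not (n_range[0] <= p.n_gwas <= n_range[1]):
                    continue
            if metric == "abs_beta_eqtl":
                v = abs(p.beta_eqtl)
            elif metric == "abs_beta_gwas":
                v = abs(p.beta_gwas)
            elif metric == "neg_log10_p_eqtl":
                v = -math.log10(p.p_eqtl)
            elif metric == "neg_log10_p_gwas":
                v = -math.log10(p.p_gwas)
            else:
                if p.eaf is None:
                    continue
                v = p.eaf
            values.setdefault(label, []).append(v)
    order = [category_bin(b, bins) for b in sorted(set(bins))]
    present = [b for b in order if b in values]
    medians = {b: float(np.median(values[b])) for b in present}
    means = {b: float(np.mean(values[b])) for b in present}
    ns = {b: len(values[b]) for b in present}
    pvals: dict[tuple[str, str], float] = {}
    stars: dict[tuple[str, str], str] = {}
    for b1, b2 in zip(present, present[1:]):
        p = _mannwhitney_p(values[b1], values[b2])
        pvals[(b1, b2)] = p
        stars[(b1, b2)] = significance_stars(p)
    if len(present) > 2:
        p = _mannwhitney_p(values[present[0]], values[present[-1]])
        pvals[(present[0], present[-1])] = p
        stars[(present[0], present[-1])] = significance_stars(p)
    return GroupComparison(metric, present, medians, means, ns, pvals, stars)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def pairs_to_frame(pairs: Sequence[ColocPair]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in pairs])


def frame_to_pairs(df: pd.DataFrame) -> list[ColocPair]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["eaf"] = None if pd.isna(d["eaf"]) else float(d["eaf"])
        if "n_gwas" in d and pd.isna(d["n_gwas"]):
            d["n_gwas"] = None
        out.append(ColocPair(**d))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a cohort directory; returns the run manifest."""
    cohort = Path(config.cohort_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {"config": asdict(config), "config_hash": chash, "stages": {}}

    def stage_ok(name: str, **info) -> None:
        manifest["stages"][name] = {"status": "ok", **info}

    try:
        metas = io.read_study_table(cohort / "studies.tsv")
        category_map = io.read_category_map(cohort / "category_map.tsv")
        panel_path = cohort / "reference_panel.tsv"
        panel = io.read_reference_panel(panel_path) if panel_path.exists() else {}
        ld_blocks = [io.read_ld_matrix(p) for p in sorted((cohort / "ld").glob("*.tsv"))]
        ld = BlockLD(ld_blocks)
        gwas_studies = {
            sid: io.read_summary_stats(cohort / "gwas" / f"{sid}.tsv", study_id=sid)
            for sid, m in metas.items()
            if m.kind == "gwas"
        }
        eqtl_studies = {
            sid: io.read_summary_stats(cohort / "eqtl" / f"{sid}.tsv", study_id=sid)
            for sid, m in metas.items()
            if m.kind == "eqtl"
        }
        stage_ok("load", n_gwas=len(gwas_studies), n_eqtl=len(eqtl_studies))
    except Exception as exc:  # noqa: BLE001 - abort carries the stage name
        raise RuntimeError(f"stage load failed: {exc}") from exc

    # harmonize: frequency fill -> QC -> clumped leads, per GWAS
    qc_rows = []
    leads = []
    clean_gwas: dict[str, list] = {}
    clean_eqtl: dict[str, list] = {}
    try:
        for sid, recs in gwas_studies.items():
            recs = impute_allele_frequency(recs, panel)
            recs, report = apply_qc_filters(recs, mhc=config.mhc)
            clean_gwas[sid] = recs
            qc_rows.append({"study_id": sid, **report, "retained": len(recs)})
            leads.extend(
                select_lead_variants(
                    recs, ld, config.lead_p_threshold, config.clump_r2, config.clump_radius
                )
            )
        for sid, recs in eqtl_studies.items():
            recs = impute_allele_frequency(recs, panel)
            recs, report = apply_qc_filters(recs, mhc=config.mhc)
            clean_eqtl[sid] = recs
            qc_rows.append({"study_id": sid, **report, "retained": len(recs)})
        _write_table(pd.DataFrame(qc_rows), out / "qc_report.tsv", chash)
        lead_df = pd.DataFrame(
            [
                {
                    "study_id": l.study_id,
                    "variant_id": l.variant_id,
                    "chrom": l.chrom,
                    "pos": l.pos,
                    "pvalue": l.pvalue,
                }
                for l in leads
            ]
        )
        _write_table(lead_df, out / "leads.tsv", chash)
        stage_ok("harmonize", n_leads=len(leads))
    except Exception as exc:
        raise RuntimeError(f"stage harmonize failed: {exc}") from exc

    # colocalization: per (lead, eqtl study)
    priors = ColocPriors(p1=config.prior_p1, p2=config.prior_p2, p12=config.prior_p12)
    results = []
    try:
        for lead in leads:
            gwas_recs = clean_gwas[lead.study_id]
            for esid, eqtl_recs in clean_eqtl.items():
                window = extract_window(
                    lead,
                    gwas_recs,
                    eqtl_recs,
                    radius=config.window_radius,
                    assoc_p=config.lead_p_threshold,
                    significant_only=config.significant_only,
                )
                if window.is_empty:
                    continue
                results.append(
                    colocalize(window, priors, metas[lead.study_id], metas[esid])
                )
        res_df = pd.DataFrame(
            [
                {
                    "lead": r.lead_id,
                    "gwas_id": r.gwas_id,
                    "eqtl_id": r.eqtl_id,
                    "n_variants": r.n_variants,
                    "pp_h0": r.pp_h0,
                    "pp_h1": r.pp_h1,
                    "pp_h2": r.pp_h2,
                    "pp_h3": r.pp_h3,
                    "pp_h4": r.pp_h4,
                    "best_variant": r.best_variant,
                }
                for r in results
            ]
        )
        _write_table(res_df, out / "coloc_results.tsv", chash)
        pairs = filter_colocalized(results, metas, config.pp_h4_min, config.snp_pp_min)
        _write_table(pairs_to_frame(pairs), out / "coloc_pairs.tsv", chash)
        stage_ok("coloc", n_results=len(results), n_pairs=len(pairs))
    except Exception as exc:
        raise RuntimeError(f"stage coloc failed: {exc}") from exc

    # pleiotropy annotation, regions, summaries, explained loci
    try:
        annotations = annotate_pleiotropy(pairs, category_map) if pairs else []
        ann_df = pd.DataFrame(
            [
                {
                    "variant_id": a.variant_id,
                    "chrom": a.chrom,
                    "pos": a.pos,
                    "categories": ";".join(sorted(a.categories)),
                    "category_count": a.category_count,
                    "genes": ";".join(sorted(a.genes)),
                    "gene_count": a.gene_count,
                    "tissues": ";".join(sorted(a.tissues)),
                    "tissue_count": a.tissue_count,
                }
                for a in annotations
            ]
        )
        _write_table(ann_df, out / "annotations.tsv", chash)
        regions = merge_regions(annotations, config.merge_gap, config.min_categories)
        reg_df = pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "categories": ";".join(sorted(r.categories)),
                    "category_count": len(r.categories),
                    "eqtl_count": r.eqtl_count,
                    "gene_marker": r.gene_marker,
                    "length": r.length,
                }
                for r in regions
            ]
        )
        _write_table(reg_df, out / "regions.tsv", chash)
        if regions:
            io.write_ucsc_track(regions, out / "regions_track.bed", "pleiotropic_regions")
        summaries = region_summaries(regions)
        with open(out / "region_summaries.json", "w") as fh:
            json.dump({"config_hash": chash, **summaries}, fh, indent=1)
        trait_of_study = {sid: m.trait_id for sid, m in metas.items() if m.kind == "gwas"}
        expl = explained_loci(
            leads, pairs, config.window_radius, category_map, trait_of_study
        )
        _write_table(expl, out / "explained_loci.tsv", chash)
        stage_ok("pleiotropy", n_annotations=len(annotations), n_regions=len(regions))
    except Exception as exc:
        raise RuntimeError(f"stage pleiotropy failed: {exc}") from exc

    # enrichment against annotation tracks + group comparisons
    try:
        enrich_rows = []
        if annotations:
            variants = {a.variant_id: (a.chrom, a.pos) for a in annotations}
            groups = {
                a.variant_id: category_bin(a.category_count, config.category_bins)
                for a in annotations
            }
            baseline = category_bin(min(config.category_bins), config.category_bins)
            enh_path = cohort / "enhancers.bed"
            if enh_path.exists() and baseline in groups.values():
                enh = io.read_intervals(enh_path)
                overlap = annotate_overlap(variants, enh)
                flags = overlap["annotated"].to_dict()
                for res in enrichment_odds_ratio(groups, flags, baseline, "greater"):
                    enrich_rows.append({"track": "enhancers", **asdict_result(res)})
            cons_path = cohort / "consequences.tsv"
            if cons_path.exists() and baseline in groups.values():
                cons = io.read_consequence_table(cons_path)
                for cls, results_ in consequence_enrichment(groups, cons, baseline).items():
                    for res in results_:
                        enrich_rows.append({"track": f"vep:{cls}", **asdict_result(res)})
        _write_table(pd.DataFrame(enrich_rows), out / "enrichment.tsv", chash)
        comp_rows = []
        for metric in METRICS:
            gc = compare_groups(annotations, metric, config.category_bins)
            for b in gc.bins:
                comp_rows.append(
                    {
                        "metric": metric,
                        "bin": b,
                        "n": gc.n[b],
                        "median": gc.medians[b],
                        "mean": gc.means[b],
                    }
                )
        _write_table(pd.DataFrame(comp_rows), out / "group_comparisons.tsv", chash)
        stage_ok("enrichment", n_rows=len(enrich_rows))
    except Exception as exc:
        raise RuntimeError(f"stage enrichment failed: {exc}") from exc

    # trait similarity + clustering
    try:
        vectors = build_effect_vectors(pairs)
        n_clustered = 0
        if len(vectors) >= 2:
            sim = spearman_matrix(vectors, min_overlap=config.min_overlap)
            sim.rho.to_csv(out / "similarity.tsv", sep="\t")
            sim.overlap.to_csv(out / "similarity_overlap.tsv", sep="\t")
            filtered = filter_traits(sim, config.min_abs_rho, config.min_partners)
            if len(filtered.traits) >= 2:
                _, leaf_order, newick = cluster_traits(filtered)
                (out / "trait_tree.nwk").write_text(newick + "\n")
                (out / "leaf_order.txt").write_text("\n".join(leaf_order) + "\n")
                n_clustered = len(leaf_order)
        stage_ok("similarity", n_traits=len(vectors), n_clustered=n_clustered)
    except Exception as exc:
        raise RuntimeError(f"stage similarity failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def asdict_result(res) -> dict:
    return {
        "group": res.group,
        "a": res.a,
        "b": res.b,
        "c": res.c,
        "d": res.d,
        "odds_ratio": res.odds_ratio,
        "fisher_p": res.fisher_p,
        "sided": res.sided,
    }
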