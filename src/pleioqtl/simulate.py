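"""Synthetic GWAS + eQTL cohorts with known causal configurations.

Summary statistics are simulated directly in z-score space: for a locus of Q
variants with LD correlation matrix R, the vector of study z-scores follows

    z ~ MVN(R @ lam, R)

where ``lam`` holds the noncentrality (in z units) at the causal indices and
zeros elsewhere.  Effect sizes and standard errors are recovered from
simulated allele frequencies f via ``se = 1 / sqrt(2 n f (1 - f))`` and
``beta = z * se``; p-values are the two-sided normal tail of z.  This is the
minimal sufficient model for ABF colocalization, which consumes (beta, se)
only — no individual-level genotypes are generated.

Loci are planted under five scenario labels (null, gwas_only, eqtl_only,
distinct, shared) and the cohort generator additionally plants pleiotropy:
one locus per requested category count, whose shared causal variant
colocalizes with GWAS traits drawn from that many distinct trait categories.
A truth ledger records every planted configuration so downstream stages can
be checked against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from . import io
from .io import AssocRecord, GenomicInterval, LDMatrix, LoopPair, StudyMeta

__all__ = [
    "LocusScenario",
    "CohortConfig",
    "make_ld_matrix",
    "simulate_locus",
    "simulate_cohort",
    "plant_enrichment",
]

SCENARIOS = ("null", "gwas_only", "eqtl_only", "distinct", "shared")


@dataclass(frozen=True)
class LocusScenario:
    """One locus's latent causal configuration.

    ``causal_gwas`` / ``causal_eqtl`` are variant indices (empty tuples under
    the null); ``noncentrality`` is the causal effect in z units; ``ld_rho``
    is the AR(1) LD decay parameter, r(i, j) = ld_rho ** |i - j|.
    """

    label: str
    q: int
    causal_gwas: tuple[int, ...] = ()
    causal_eqtl: tuple[int, ...] = ()
    noncentrality: float = 8.0
    ld_rho: float = 0.9

    def __post_init__(self) -> None:
        if self.label not in SCENARIOS:
            raise ValueError(f"unknown scenario label {self.label!r}")
        if self.q < 1:
            raise ValueError("Q must be >= 1")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        for idx in (*self.causal_gwas, *self.causal_eqtl):
            if not (0 <= idx < self.q):
                raise ValueError(f"causal index {idx} outside [0, {self.q})")
        if self.label == "shared" and set(self.causal_gwas) != set(self.causal_eqtl):
            raise ValueError("shared scenario requires identical causal indices")
        if self.label == "distinct" and set(self.causal_gwas) & set(self.causal_eqtl):
            raise ValueError("distinct scenario requires disjoint causal indices")
        if self.label == "null" and (self.causal_gwas or self.causal_eqtl):
            raise ValueError("null scenario must have no causal indices")


def make_ld_matrix(q: int, ld_rho: float) -> LDMatrix:
    """AR(1) LD matrix: r(i, j) = ld_rho ** |i - j| (positive definite)."""
    if q < 1:
        raise ValueError("Q must be >= 1")
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must be in [0, 1)")
    idx = np.arange(q)
    r = ld_rho ** np.abs(idx[:, None] - idx[None, :])
    return LDMatrix([f"v{i}" for i in range(q)], r)


def _z_draw(r: np.ndarray, lam: np.ndarray, rng: np.random.Generator,
            chol: np.ndarray | None = None) -> np.ndarray:
    if chol is None:
        chol = np.linalg.cholesky(r)
    return r @ lam + chol @ rng.standard_normal(r.shape[0])


def _records_from_z(
    z: np.ndarray,
    eaf: np.ndarray,
    n: int,
    chrom: str,
    positions: np.ndarray,
    variant_ids: list[str],
    study_id: str,
) -> list[AssocRecord]:
    se = 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))
    beta = z * se
    # floor keeps p inside (0, 1] even for extreme z
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-320)
    return [
        AssocRecord(
            variant_id=variant_ids[i],
            chrom=chrom,
            pos=int(positions[i]),
            ref="A",
            alt="G",
            beta=float(beta[i]),
            se=float(se[i]),
            pvalue=float(p[i]),
            eaf=float(eaf[i]),
            n=n,
            study_id=study_id,
        )
        for i in range(len(z))
    ]


def simulate_locus(
    scenario: LocusScenario,
    n: int,
    seed: int | np.random.Generator,
    chrom: str = "chr1",
    start_pos: int = 1_000_000,
    spacing: int = 1_000,
    variant_prefix: str = "rsS",
    n_eqtl: int | None = None,
) -> tuple[list[AssocRecord], list[AssocRecord], LDMatrix, dict]:
    """Simulate paired GWAS and eQTL summary statistics for one locus.

    Returns (gwas records, eqtl records, LD matrix, truth record).  Both
    studies share the LD matrix and allele frequencies (one population); the
    eQTL study may have its own sample size ``n_eqtl``.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_eqtl = n_eqtl or n
    ld = make_ld_matrix(scenario.q, scenario.ld_rho)
    variant_ids = [f"{variant_prefix}_{i}" for i in range(scenario.q)]
    ld = LDMatrix(variant_ids, ld.r)
    positions = start_pos + spacing * np.arange(scenario.q)
    eaf = rng.uniform(0.05, 0.95, size=scenario.q)

    lam_g = np.zeros(scenario.q)
    lam_g[list(scenario.causal_gwas)] = scenario.noncentrality
    lam_e = np.zeros(scenario.q)
    lam_e[list(scenario.causal_eqtl)] = scenario.noncentrality
    if scenario.label == "gwas_only":
        lam_e[:] = 0.0
    if scenario.label == "eqtl_only":
        lam_g[:] = 0.0

    chol = np.linalg.cholesky(ld.r)
    z_g = _z_draw(ld.r, lam_g, rng, chol)
    z_e = _z_draw(ld.r, lam_e, rng, chol)
    gwas = _records_from_z(z_g, eaf, n, chrom, positions, variant_ids, "gwas_sim")
    eqtl = _records_from_z(z_e, eaf, n_eqtl, chrom, positions, variant_ids, "eqtl_sim")
    truth = {
        "label": scenario.label,
        "causal_gwas": [variant_ids[i] for i in scenario.causal_gwas],
        "causal_eqtl": [variant_ids[i] for i in scenario.causal_eqtl],
        "chrom": chrom,
        "positions": [int(p) for p in positions],
    }
    return gwas, eqtl, ld, truth


@dataclass
class CohortConfig:
    """Design of a synthetic study corpus with planted ground truth.

    One pleiotropy locus is planted per entry of ``planted_category_counts``:
    its shared causal variant colocalizes with that many GWAS traits, each
    from a distinct trait category.  Null / distinct / single-trait loci give
    the pipeline negatives.  Every random draw flows from ``seed``.
    """

    n_categories: int = 6
    traits_per_category: int = 2
    planted_category_counts: tuple[int, ...] = (1, 1, 1, 2, 2, 3, 4)
    genes_per_locus: int = 2
    tissues_per_locus: int = 2
    q: int = 51
    ld_rho: float = 0.9
    noncentrality: float = 8.0
    n_gwas: int = 50_000
    n_eqtl: int = 5_000
    n_null_loci: int = 3
    n_distinct_loci: int = 2
    locus_spacing: int = 10_000_000
    variant_spacing: int = 1_000
    frac_missing_eaf: float = 0.1
    plant_mhc_locus: bool = False
    enhancer_or: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if max(self.planted_category_counts, default=1) > self.n_categories:
            raise ValueError("planted category count exceeds n_categories")
        if self.q < 3:
            raise ValueError("q must be >= 3")
        for name in ("n_categories", "traits_per_category", "genes_per_locus",
                     "tissues_per_locus", "n_gwas", "n_eqtl"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def simulate_cohort(config: CohortConfig, outdir: str | Path) -> dict:
    """Write a full synthetic cohort to ``outdir`` and return its truth ledger.

    Layout: ``gwas/<study>.tsv``, ``eqtl/<study>.tsv``, ``studies.tsv``,
    ``category_map.tsv``, ``ld/<locus>.tsv``, ``gene_models.tsv``,
    ``reference_panel.tsv``, ``enhancers.bed``, ``loops.bedpe``,
    ``consequences.tsv`` and ``truth.json``.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(config.seed)
    (outdir / "gwas").mkdir(parents=True, exist_ok=True)
    (outdir / "eqtl").mkdir(parents=True, exist_ok=True)
    (outdir / "ld").mkdir(parents=True, exist_ok=True)

    categories = [f"category_{c:02d}" for c in range(config.n_categories)]
    traits = []
    category_map: dict[str, str] = {}
    for c, cat in enumerate(categories):
        for t in range(config.traits_per_category):
            trait = f"trait_{c:02d}_{t}"
            traits.append(trait)
            category_map[trait] = cat

    # per-GWAS/eQTL record pools, keyed by study id
    gwas_pool: dict[str, list[AssocRecord]] = {}
    eqtl_pool: dict[str, list[AssocRecord]] = {}
    metas: dict[str, StudyMeta] = {}
    gene_models: dict[str, GenomicInterval] = {}
    truth_loci = []
    tissues = [f"tissue_{t}" for t in range(config.tissues_per_locus)]

    def gwas_meta(trait: str) -> StudyMeta:
        sid = f"gwas_{trait}"
        if sid not in metas:
            metas[sid] = StudyMeta(sid, "gwas", trait_id=trait, n=config.n_gwas,
                                   trait_type="case_control")
            gwas_pool[sid] = []
        return metas[sid]

    def eqtl_meta(gene: str, tissue: str) -> StudyMeta:
        sid = f"eqtl_{gene}_{tissue}"
        if sid not in metas:
            metas[sid] = StudyMeta(sid, "eqtl", gene_id=gene, tissue_id=tissue,
                                   n=config.n_eqtl, trait_type="quantitative")
            eqtl_pool[sid] = []
        return metas[sid]

    chroms = [f"chr{c}" for c in range(1, 23)]
    locus_counter = 0

    def next_site() -> tuple[str, int, str]:
        nonlocal locus_counter
        chrom = chroms[locus_counter % len(chroms)]
        start = 50_000_000 + (locus_counter // len(chroms) + 1) * config.locus_spacing
        lid = f"locus_{locus_counter:03d}"
        locus_counter += 1
        return chrom, start, lid

    causal_idx = config.q // 2

    def plant_locus(label: str, trait_list: list[str], chrom: str, start: int,
                    lid: str) -> None:
        """One locus: every listed GWAS trait and every (gene, tissue) eQTL
        study shares (or not, per label) a causal variant."""
        causal_e = (causal_idx,) if label in ("shared", "eqtl_only", "distinct") else ()
        if label == "distinct":
            # far ends of the locus: AR(1) correlation rho^(q-1) is negligible
            causal_g: tuple[int, ...] = (0,)
            causal_e = (config.q - 1,)
        elif label in ("shared", "gwas_only"):
            causal_g = (causal_idx,)
        else:
            causal_g = ()
        ld = None
        variant_ids = [f"rs{lid}_{i}" for i in range(config.q)]
        positions = start + config.variant_spacing * np.arange(config.q)
        eaf = rng.uniform(0.05, 0.95, size=config.q)
        base = make_ld_matrix(config.q, config.ld_rho)
        ld = LDMatrix(variant_ids, base.r)
        chol = np.linalg.cholesky(ld.r)
        lam_g = np.zeros(config.q)
        lam_g[list(causal_g)] = config.noncentrality
        lam_e = np.zeros(config.q)
        lam_e[list(causal_e)] = config.noncentrality

        for trait in trait_list:
            m = gwas_meta(trait)
            z = _z_draw(ld.r, lam_g, rng, chol)
            recs = _records_from_z(z, eaf, config.n_gwas, chrom, positions,
                                   variant_ids, m.study_id)
            gwas_pool[m.study_id].extend(recs)
        genes = [f"gene_{lid}_{g}" for g in range(config.genes_per_locus)]
        for g, gene in enumerate(genes):
            gstart = int(positions[causal_idx]) + 2_000 * (g + 1)
            gene_models[gene] = GenomicInterval(chrom, gstart, gstart + 10_000, gene)
            for tissue in tissues:
                m = eqtl_meta(gene, tissue)
                z = _z_draw(ld.r, lam_e, rng, chol)
                recs = _records_from_z(z, eaf, config.n_eqtl, chrom, positions,
                                       variant_ids, m.study_id)
                eqtl_pool[m.study_id].extend(recs)
        io.write_ld_matrix(ld, outdir / "ld" / f"{lid}.tsv")
        truth_loci.append(
            {
                "locus_id": lid,
                "label": label,
                "chrom": chrom,
                "start": int(positions[0]),
                "end": int(positions[-1]),
                "causal_variant": variant_ids[causal_idx] if label == "shared" else None,
                "causal_gwas": [variant_ids[i] for i in causal_g],
                "causal_eqtl": [variant_ids[i] for i in causal_e],
                "traits": trait_list,
                "categories": sorted({category_map[t] for t in trait_list}),
                "genes": genes,
                "tissues": tissues,
            }
        )

    # pleiotropy design: one shared locus per requested category count
    for k in config.planted_category_counts:
        chrom, start, lid = next_site()
        cats = rng.choice(config.n_categories, size=k, replace=False)
        trait_list = [f"trait_{c:02d}_0" for c in sorted(cats)]
        plant_locus("shared", trait_list, chrom, start, lid)

    for _ in range(config.n_distinct_loci):
        chrom, start, lid = next_site()
        cat = int(rng.integers(config.n_categories))
        plant_locus("distinct", [f"trait_{cat:02d}_1"], chrom, start, lid)

    for _ in range(config.n_null_loci):
        chrom, start, lid = next_site()
        cat = int(rng.integers(config.n_categories))
        plant_locus("null", [f"trait_{cat:02d}_1"], chrom, start, lid)

    if config.plant_mhc_locus:
        lid = f"locus_{locus_counter:03d}"
        locus_counter += 1
        plant_locus("shared", [traits[0]], "chr6", 30_000_000, lid)

    # mask a fraction of allele frequencies; keep a reference panel to refill
    panel: dict[str, float] = {}
    for pool in (gwas_pool, eqtl_pool):
        for recs in pool.values():
            for r in recs:
                panel[r.variant_id] = r.eaf
                if rng.uniform() < config.frac_missing_eaf:
                    r.eaf = None
                    r.eaf_source = "missing"

    for sid, recs in gwas_pool.items():
        io.write_summary_stats(recs, outdir / "gwas" / f"{sid}.tsv")
    for sid, recs in eqtl_pool.items():
        io.write_summary_stats(recs, outdir / "eqtl" / f"{sid}.tsv")
    io.write_study_table(metas.values(), outdir / "studies.tsv")
    io.write_category_map(category_map, outdir / "category_map.tsv")
    io.write_gene_models(gene_models, outdir / "gene_models.tsv")
    io.write_reference_panel(panel, outdir / "reference_panel.tsv")

    # annotation tracks: enhancers enriched at causal variants of pleiotropic
    # (>= 2 category) loci, loops around every shared locus, consequences
    all_variants = {}
    flagged = set()
    for locus in truth_loci:
        span = range(locus["start"], locus["end"] + 1, config.variant_spacing)
        for vid, pos in zip(
            [f"rs{locus['locus_id']}_{i}" for i in range(config.q)], span
        ):
            all_variants[vid] = (locus["chrom"], pos)
        if locus["label"] == "shared" and len(locus["categories"]) >= 2:
            flagged.add(locus["causal_variant"])
    enhancers = plant_enrichment(
        all_variants, flagged, config.enhancer_or, rng=rng
    ) if flagged else []
    io.write_intervals(enhancers, outdir / "enhancers.bed")

    loops = []
    for locus in truth_loci:
        if locus["label"] != "shared":
            continue
        mid = (locus["start"] + locus["end"]) // 2
        a = GenomicInterval(locus["chrom"], max(1, locus["start"] - 5_000),
                            locus["start"] - 1_000)
        b = GenomicInterval(locus["chrom"], locus["end"] + 20_000,
                            locus["end"] + 24_000)
        loops.append(LoopPair(a, b))
    io.write_loops(loops, outdir / "loops.bedpe")

    consequences = {}
    for vid in all_variants:
        consequences[vid] = "missense" if vid in flagged else (
            "intronic" if rng.uniform() < 0.5 else "intergenic")
    io.write_consequence_table(consequences, outdir / "consequences.tsv")

    ledger = {
        "config": asdict(config),
        "categories": categories,
        "loci": truth_loci,
        "flagged_variants": sorted(flagged),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
    return ledger


def plant_enrichment(
    variants: dict[str, tuple[str, int]],
    flagged_subset: set[str],
    target_or: float,
    base_coverage: float = 0.3,
    halfwidth: int = 50,
    rng: np.random.Generator | int = 0,
) -> list[GenomicInterval]:
    """Annotation intervals whose expected 2x2 odds ratio equals ``target_or``.

    Flagged variants are covered with probability q where
    odds(q) = target_or * odds(base_coverage); unflagged variants with
    probability ``base_coverage``.  ``variants`` maps id -> (chrom, pos).
    """
    if target_or <= 0:
        raise ValueError("target_or must be > 0")
    if not flagged_subset:
        raise ValueError("flagged_subset must be non-empty")
    unknown = flagged_subset - set(variants)
    if unknown:
        raise ValueError(f"flagged variants not in variant set: {sorted(unknown)[:3]}")
    if not (0 < base_coverage < 1):
        raise ValueError("base_coverage must be in (0, 1)")
    odds = base_coverage / (1 - base_coverage)
    q_flag = target_or * odds / (1 + target_or * odds)
    if q_flag >= 1:
        raise ValueError("implied coverage probability >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = []
    for vid in sorted(variants):
        chrom, pos = variants[vid]
        p_cover = q_flag if vid in flagged_subset else base_coverage
        if rng.uniform() < p_cover:
            out.append(
                GenomicInterval(chrom, max(1, pos - halfwidth), pos + halfwidth,
                                name=f"enh_{vid}")
            )
    return out
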