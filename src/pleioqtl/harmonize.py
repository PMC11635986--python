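"""Variant preparation: lead selection with LD clumping, window extraction,
QC filters, MHC exclusion, and allele-frequency fill-in.

Clumping is greedy best-p-first (PLINK style): candidates below the lead
p-value threshold are visited in ascending p order and a candidate is kept
only if its r² with every already-kept lead within the clump radius is below
the r² threshold.  Ties in p break on (chrom, pos, variant_id) so the output
does not depend on input order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .io import AssocRecord, LDMatrix, ValidationError

__all__ = [
    "LeadVariant",
    "LocusWindow",
    "MHC_INTERVAL",
    "select_lead_variants",
    "extract_window",
    "apply_qc_filters",
    "impute_allele_frequency",
]

#: Major histocompatibility complex (hg38), boundary-inclusive.
MHC_INTERVAL = ("chr6", 25_000_000, 35_000_000)


@dataclass
class LeadVariant:
    """A clumped GWAS top hit."""

    record: AssocRecord

    @property
    def variant_id(self) -> str:
        return self.record.variant_id

    @property
    def chrom(self) -> str:
        return self.record.chrom

    @property
    def pos(self) -> int:
        return self.record.pos

    @property
    def pvalue(self) -> float:
        return self.record.pvalue

    @property
    def study_id(self) -> str:
        return self.record.study_id


@dataclass
class LocusWindow:
    """GWAS and eQTL records around a lead, keyed identically by variant id."""

    lead: LeadVariant
    gwas: dict[str, AssocRecord]
    eqtl: dict[str, AssocRecord]
    ld: LDMatrix | None = None

    def shared_ids(self) -> list[str]:
        """Variant ids present in both studies, ordered by position."""
        shared = set(self.gwas) & set(self.eqtl)
        return sorted(shared, key=lambda v: (self.gwas[v].pos, v))

    @property
    def is_empty(self) -> bool:
        return not (set(self.gwas) & set(self.eqtl))


def select_lead_variants(
    gwas_records: Iterable[AssocRecord],
    ld,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
    clump_radius: int = 1_000_000,
) -> list[LeadVariant]:
    """Greedy LD clumping of GWAS hits into independent lead variants.

    ``ld`` is any object supporting ``__contains__`` and ``r2(a, b)`` (an
    :class:`~pleioqtl.io.LDMatrix` or :class:`~pleioqtl.io.BlockLD`).
    Raises :class:`KeyError` naming any candidate absent from ``ld``.
    """
    candidates = [r for r in gwas_records if r.pvalue < p_threshold]
    for r in candidates:
        if r.variant_id not in ld:
            raise KeyError(f"variant {r.variant_id!r} absent from LD matrix")
    candidates.sort(key=lambda r: (r.pvalue, r.chrom, r.pos, r.variant_id))
    leads: list[AssocRecord] = []
    for cand in candidates:
        independent = True
        for kept in leads:
            if kept.chrom != cand.chrom:
                continue
            if abs(kept.pos - cand.pos) > clump_radius:
                continue
            if ld.r2(kept.variant_id, cand.variant_id) >= r2_threshold:
                independent = False
                break
        if independent:
            leads.append(cand)
    return [LeadVariant(r) for r in leads]


def extract_window(
    lead: LeadVariant,
    gwas_records: Iterable[AssocRecord],
    eqtl_records: Iterable[AssocRecord],
    radius: int = 1_000_000,
    assoc_p: float = 5e-8,
    significant_only: bool = False,
    ld: LDMatrix | None = None,
) -> LocusWindow:
    """Extract the coloc candidate set within ``radius`` bp of a lead.

    The candidate set keeps variants present in **both** studies inside the
    (boundary-inclusive) window.  With ``significant_only=True`` each study's
    variants are first restricted to p < ``assoc_p``, the literal reading of
    extracting "significant" variants; the default keeps every shared variant,
    the standard practice for ABF colocalization.
    """

    def in_window(r: AssocRecord) -> bool:
        return r.chrom == lead.chrom and abs(r.pos - lead.pos) <= radius

    gsel = {r.variant_id: r for r in gwas_records if in_window(r)}
    esel = {r.variant_id: r for r in eqtl_records if in_window(r)}
    if significant_only:
        gsel = {v: r for v, r in gsel.items() if r.pvalue < assoc_p}
        esel = {v: r for v, r in esel.items() if r.pvalue < assoc_p}
    shared = set(gsel) & set(esel)
    gsel = {v: gsel[v] for v in shared}
    esel = {v: esel[v] for v in shared}
    sub = None
    if ld is not None and shared:
        order = sorted(shared, key=lambda v: (gsel[v].pos, v))
        sub = ld.submatrix(order)
    return LocusWindow(lead=lead, gwas=gsel, eqtl=esel, ld=sub)


def apply_qc_filters(
    records: Iterable[AssocRecord],
    mhc: tuple[str, int, int] | None = MHC_INTERVAL,
) -> tuple[list[AssocRecord], dict[str, int]]:
    """Remove records failing the retention criteria; report counts per reason.

    Filters, in order: allele frequency not strictly between 0 and 1 (or still
    missing after fill-in) — reason ``frequency``; missing beta/se/p — reason
    ``missing``; duplicated variant ids, **all** copies removed — reason
    ``duplicate``; inside the (boundary-inclusive) MHC interval — reason
    ``mhc``.  Idempotent.
    """
    report = {"frequency": 0, "missing": 0, "duplicate": 0, "mhc": 0}
    kept: list[AssocRecord] = []
    for r in records:
        if r.eaf is None or math.isnan(r.eaf) or not (0 < r.eaf < 1):
            report["frequency"] += 1
            continue
        if r.has_missing_stats():
            report["missing"] += 1
            continue
        kept.append(r)

    counts: dict[str, int] = {}
    for r in kept:
        counts[r.variant_id] = counts.get(r.variant_id, 0) + 1
    deduped = []
    for r in kept:
        if counts[r.variant_id] > 1:
            report["duplicate"] += 1
        else:
            deduped.append(r)

    if mhc is None:
        return deduped, report
    chrom, lo, hi = mhc
    final = []
    for r in deduped:
        if r.chrom == chrom and lo <= r.pos <= hi:
            report["mhc"] += 1
        else:
            final.append(r)
    return final, report


def impute_allele_frequency(
    records: Iterable[AssocRecord],
    reference_panel: Mapping[str, float],
) -> list[AssocRecord]:
    """Fill missing allele frequencies from a reference panel.

    Present frequencies are never touched.  Filled records carry
    ``eaf_source="imputed"``; missing records absent from the panel are
    flagged ``unfillable`` (and fall to the frequency filter at QC).
    """
    out = []
    for r in records:
        if r.eaf is not None and not math.isnan(r.eaf):
            out.append(r)
        elif r.variant_id in reference_panel:
            out.append(replace(r, eaf=float(reference_panel[r.variant_id]),
                               eaf_source="imputed"))
        else:
            out.append(replace(r, eaf_source="unfillable"))
    return out
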