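"""Approximate-Bayes-factor colocalization of two association signals.

For a locus with Q variants measured in two studies (e.g. a GWAS trait and a
gene's expression in one tissue), five hypotheses are weighed:

* H0 — no association with either trait,
* H1 / H2 — association with trait 1 / trait 2 only,
* H3 — both traits, two distinct causal variants,
* H4 — both traits, one shared causal variant.

Each variant's evidence for association in one study is the Wakefield log
approximate Bayes factor computed from its effect estimate and standard
error under a N(0, W) effect prior:

    z = beta / se,  V = se^2,  r = W / (W + V)
    lABF = 0.5 * (ln(1 - r) + z^2 * r)

Hypothesis likelihoods are assembled in log space (log-sum-exp) so that loci
with thousands of variants and |z| up to 40 remain finite.  The per-variant
posterior of being the shared causal variant (``snp_pp_h4``) is the softmax
of ``lABF1 + lABF2`` over the locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, ndtri
from scipy import stats

from .harmonize import LocusWindow
from .io import AssocRecord, StudyMeta

__all__ = [
    "ColocPriors",
    "ColocResult",
    "ColocPair",
    "log_abf",
    "log_abf_from_p",
    "coloc_posteriors",
    "colocalize",
    "filter_colocalized",
]

#: Published defaults of the ABF colocalization method: per-variant prior of
#: association with trait 1 only, trait 2 only, and both.
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5

#: Prior effect standard deviations: 0.15 for quantitative traits, 0.2 for
#: case-control traits on the log-odds scale.
SD_QUANTITATIVE = 0.15
SD_CASE_CONTROL = 0.2


@dataclass(frozen=True)
class ColocPriors:
    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12
    w1: float = SD_CASE_CONTROL**2
    w2: float = SD_QUANTITATIVE**2

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError(
                f"priors must satisfy 0 < p12 <= min(p1, p2) < 1, got "
                f"p1={self.p1}, p2={self.p2}, p12={self.p12}"
            )
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("prior effect variances must be >= 0")


def prior_variance(meta: StudyMeta) -> float:
    """Prior effect variance W for a study, by trait type."""
    sd = SD_CASE_CONTROL if meta.trait_type == "case_control" else SD_QUANTITATIVE
    return sd * sd


def log_abf(beta, se, w: float):
    """Wakefield log approximate Bayes factor; vectorized over beta/se."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be > 0")
    if w < 0:
        raise ValueError("prior variance W must be >= 0")
    v = se**2
    r = w / (w + v)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + z * z * r)
    return out if out.ndim else float(out)


def log_abf_from_p(pvalue, eaf, n, w: float, beta_sign=1.0):
    """Fallback lABF for records lacking a standard error.

    Reconstructs |z| from the two-sided p-value and approximates
    ``se = 1 / sqrt(2 n f (1 - f))`` from the allele frequency — the standard
    additive-model approximation for a standardized quantitative trait.
    """
    pvalue = np.asarray(pvalue, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    z = -ndtri(pvalue / 2)
    se = 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))
    beta = np.sign(beta_sign) * z * se
    return log_abf(beta, se, w)


@dataclass
class ColocResult:
    """Five-hypothesis posterior for one (locus, study 1, study 2) pair."""

    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    snp_pp_h4: dict[str, float]
    n_variants: int
    best_variant: str
    gwas_id: str = ""
    eqtl_id: str = ""
    lead_id: str = ""
    window: "LocusWindow | None" = field(default=None, repr=False)

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


@dataclass
class ColocPair:
    """A retained colocalized variant linking a GWAS trait to an eQTL gene."""

    variant_id: str
    chrom: str
    pos: int
    gwas_id: str
    trait_id: str
    eqtl_study: str
    gene_id: str
    tissue_id: str
    beta_gwas: float
    beta_eqtl: float
    p_gwas: float
    p_eqtl: float
    eaf: float | None
    pp_h4: float
    snp_pp_h4: float
    n_gwas: int | None = None


def coloc_posteriors(
    labf1: np.ndarray,
    labf2: np.ndarray,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior over (H0..H4) and per-variant shared-causal posteriors.

    All sums are log-space; the H3 term uses a guarded log-difference
    (sum_{i != j} BF1_i BF2_j = S1*S2 - S12) clamped to -inf on underflow,
    which makes pp_h3 exactly 0 for single-variant loci.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.ndim != 1 or labf1.size == 0:
        raise ValueError("labf1/labf2 must be equal-length non-empty 1-d arrays")
    lse1 = logsumexp(labf1)
    lse2 = logsumexp(labf2)
    lse12 = logsumexp(labf1 + labf2)
    l0 = 0.0
    l1 = lse1 + math.log(p1)
    l2 = lse2 + math.log(p2)
    l4 = lse12 + math.log(p12)
    d = lse1 + lse2 - lse12
    if d > 1e-13:
        l3 = math.log(p1) + math.log(p2) + lse12 + math.log(math.expm1(d))
    else:
        l3 = -math.inf
    logs = np.array([l0, l1, l2, l3, l4])
    pp = np.exp(logs - logsumexp(logs))
    pp /= pp.sum()
    joint = labf1 + labf2
    snp_pp = np.exp(joint - logsumexp(joint))
    snp_pp /= snp_pp.sum()
    return pp, snp_pp


def colocalize(
    window: LocusWindow,
    priors: ColocPriors = ColocPriors(),
    gwas_meta: StudyMeta | None = None,
    eqtl_meta: StudyMeta | None = None,
) -> ColocResult:
    """Colocalize the GWAS and eQTL signals of one harmonized locus window.

    Prior effect variances follow the study metadata when given (case-control
    GWAS get the log-odds scale prior), otherwise ``priors.w1``/``priors.w2``.
    """
    ids = window.shared_ids()
    if not ids:
        raise ValueError("no shared variants in window")
    w1 = prior_variance(gwas_meta) if gwas_meta is not None else priors.w1
    w2 = prior_variance(eqtl_meta) if eqtl_meta is not None else priors.w2
    g = [window.gwas[v] for v in ids]
    e = [window.eqtl[v] for v in ids]
    labf1 = log_abf([r.beta for r in g], [r.se for r in g], w1)
    labf2 = log_abf([r.beta for r in e], [r.se for r in e], w2)
    pp, snp_pp = coloc_posteriors(labf1, labf2, priors.p1, priors.p2, priors.p12)
    snp_map = dict(zip(ids, snp_pp.tolist()))
    best = ids[int(np.argmax(snp_pp))]
    return ColocResult(
        pp_h0=float(pp[0]),
        pp_h1=float(pp[1]),
        pp_h2=float(pp[2]),
        pp_h3=float(pp[3]),
        pp_h4=float(pp[4]),
        snp_pp_h4=snp_map,
        n_variants=len(ids),
        best_variant=best,
        gwas_id=gwas_meta.study_id if gwas_meta else "",
        eqtl_id=eqtl_meta.study_id if eqtl_meta else "",
        lead_id=window.lead.variant_id,
        window=window,
    )


def filter_colocalized(
    results: list[ColocResult],
    metas: dict[str, StudyMeta] | None = None,
    pp_h4_min: float = 0.75,
    snp_pp_min: float = 0.5,
) -> list[ColocPair]:
    """Apply the retention cutoffs (PP.H4 >= 0.75, SNP.PP.H4 >= 0.5, inclusive).

    For every result passing the locus-level cutoff, each variant at or above
    the per-variant cutoff becomes one :class:`ColocPair` carrying the GWAS
    and eQTL statistics of that variant.
    """
    metas = metas or {}
    pairs: list[ColocPair] = []
    for res in results:
        if res.pp_h4 < pp_h4_min:
            continue
        gmeta = metas.get(res.gwas_id)
        emeta = metas.get(res.eqtl_id)
        for vid, spp in res.snp_pp_h4.items():
            if spp < snp_pp_min:
                continue
            grec = res.window.gwas[vid] if res.window else None
            erec = res.window.eqtl[vid] if res.window else None
            pairs.append(
                ColocPair(
                    variant_id=vid,
                    chrom=grec.chrom if grec else "",
                    pos=grec.pos if grec else 0,
                    gwas_id=res.gwas_id,
                    trait_id=gmeta.trait_id if gmeta else res.gwas_id,
                    eqtl_study=res.eqtl_id,
                    gene_id=emeta.gene_id if emeta else "",
                    tissue_id=emeta.tissue_id if emeta else "",
                    beta_gwas=grec.beta if grec else math.nan,
                    beta_eqtl=erec.beta if erec else math.nan,
                    p_gwas=grec.pvalue if grec else math.nan,
                    p_eqtl=erec.pvalue if erec else math.nan,
                    eaf=grec.eaf if grec else None,
                    pp_h4=res.pp_h4,
                    snp_pp_h4=spp,
                    n_gwas=grec.n if grec else None,
                )
            )
    return pairs
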