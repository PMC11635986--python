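"""Trait similarity from shared colocalized eQTL effects.

Each GWAS trait gets a sparse vector of eQTL effect sizes keyed by
(variant, gene, tissue); trait pairs sharing enough keys get a Spearman
correlation, traits correlated (|rho| >= 0.05) with at least 30 other traits
are retained, and the retained traits are clustered hierarchically with
average linkage on the distance d = 1 - rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from skbio.tree import TreeNode

from .coloc import ColocPair

__all__ = [
    "EffectVector",
    "TraitSimilarity",
    "build_effect_vectors",
    "spearman_matrix",
    "filter_traits",
    "cluster_traits",
]

Key = tuple[str, str, str]  # (variant_id, gene_id, tissue_id)


@dataclass
class EffectVector:
    """One trait's eQTL effect sizes, keyed by (variant, gene, tissue)."""

    trait_id: str
    effects: dict[Key, float] = field(default_factory=dict)
    snp_pp: dict[Key, float] = field(default_factory=dict)


@dataclass
class TraitSimilarity:
    """Symmetric Spearman matrix (NaN below the overlap threshold) + overlaps."""

    rho: pd.DataFrame
    overlap: pd.DataFrame
    min_overlap: int

    @property
    def traits(self) -> list[str]:
        return list(self.rho.index)


def build_effect_vectors(pairs: Iterable[ColocPair]) -> list[EffectVector]:
    """One effect vector per GWAS trait from retained colocalization pairs.

    A key appearing in several studies for the same trait keeps the entry
    with the highest per-variant shared-causal posterior.
    """
    vectors: dict[str, EffectVector] = {}
    for p in pairs:
        vec = vectors.setdefault(p.trait_id, EffectVector(p.trait_id))
        key: Key = (p.variant_id, p.gene_id, p.tissue_id)
        if key not in vec.effects or p.snp_pp_h4 > vec.snp_pp[key]:
            vec.effects[key] = p.beta_eqtl
            vec.snp_pp[key] = p.snp_pp_h4
    return [vectors[t] for t in sorted(vectors)]


def spearman_matrix(
    vectors: Sequence[EffectVector],
    min_overlap: int = 10,
) -> TraitSimilarity:
    """Pairwise Spearman correlation over shared keys; NaN under the threshold."""
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    traits = [v.trait_id for v in vectors]
    rho = pd.DataFrame(np.nan, index=traits, columns=traits)
    overlap = pd.DataFrame(0, index=traits, columns=traits, dtype=int)
    for i, vi in enumerate(vectors):
        rho.iloc[i, i] = 1.0
        overlap.iloc[i, i] = len(vi.effects)
        for j in range(i + 1, len(vectors)):
            vj = vectors[j]
            shared = sorted(set(vi.effects) & set(vj.effects))
            overlap.iloc[i, j] = overlap.iloc[j, i] = len(shared)
            if len(shared) >= min_overlap:
                x = [vi.effects[k] for k in shared]
                y = [vj.effects[k] for k in shared]
                r = float(stats.spearmanr(x, y).statistic)
                rho.iloc[i, j] = rho.iloc[j, i] = r
    return TraitSimilarity(rho=rho, overlap=overlap, min_overlap=min_overlap)


def filter_traits(
    similarity: TraitSimilarity,
    min_abs_rho: float = 0.05,
    min_partners: int = 30,
    iterative: bool = False,
) -> TraitSimilarity:
    """Keep traits correlated (|rho| >= min_abs_rho) with enough other traits.

    Single-pass by default; ``iterative=True`` re-applies the rule until a
    fixed point, re-counting partners among the survivors.
    """
    rho = similarity.rho.copy()
    while True:
        qualifying = (rho.abs() >= min_abs_rho) & ~np.eye(len(rho), dtype=bool)
        keep = [t for t in rho.index if int(qualifying.loc[t].sum()) >= min_partners]
        done = len(keep) == len(rho)
        rho = rho.loc[keep, keep]
        if done or not iterative:
            break
    return TraitSimilarity(
        rho=rho,
        overlap=similarity.overlap.loc[rho.index, rho.index],
        min_overlap=similarity.min_overlap,
    )


def cluster_traits(
    similarity: TraitSimilarity,
) -> tuple[np.ndarray, list[str], str]:
    """Average-linkage hierarchical clustering on d = 1 - rho.

    Missing correlations count as maximal distance (d = 1).  Returns the
    scipy linkage matrix, the deterministic leaf order, and the merge tree in
    Newick text.
    """
    traits = similarity.traits
    if len(traits) < 2:
        raise ValueError("need at least 2 traits to cluster")
    d = 1.0 - similarity.rho.to_numpy(dtype=float)
    d[np.isnan(d)] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    condensed = d[np.triu_indices(len(traits), k=1)]
    z = hierarchy.linkage(condensed, method="average")
    leaf_order = [traits[i] for i in hierarchy.leaves_list(z)]
    tree = TreeNode.from_linkage_matrix(z, traits)
    newick = str(tree).strip()
    return z, leaf_order, newick
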