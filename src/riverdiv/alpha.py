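"""Per-site alpha diversity: six indices across the three facets.

Taxonomic — Shannon entropy (nats) and Shannon evenness; functional — Rao's
quadratic entropy and functional evenness (minimum-spanning-tree regularity in
trait space); phylogenetic — Faith's minimal-subtree branch length and
phylogenetic species evenness from the standardized shared-branch matrix.

Missing-value policy: SEve and PSE are undefined (NaN) for single-species
sites; FEve is undefined below three species or for coincident points; RaoQ of
a single species is 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .data import CommunityMatrix, Phylogeny
from .errors import ValidationError
from .traitspace import TraitSpace

__all__ = [
    "shannon",
    "shannon_evenness",
    "rao_q",
    "functional_evenness",
    "faith_pd",
    "phylo_species_evenness",
    "alpha_table",
]


def _relative(abundances) -> np.ndarray:
    a = np.asarray(abundances, float)
    if a.size == 0 or np.any(a < 0):
        raise ValidationError("abundances must be a non-empty, non-negative vector")
    total = a.sum()
    if total == 0:
        raise ValidationError("all-zero abundance vector")
    return a / total


def shannon(abundances) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log)."""
    p = _relative(abundances)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def shannon_evenness(abundances) -> float:
    """H / ln S; NaN for a single species."""
    p = _relative(abundances)
    s = int((p > 0).sum())
    if s < 2:
        return float("nan")
    return shannon(abundances) / np.log(s)


def rao_q(abundances, distances) -> float:
    """Rao's quadratic entropy Q = sum_ij d_ij p_i p_j."""
    p = _relative(abundances)
    d = np.asarray(distances, float)
    if d.shape != (p.size, p.size):
        raise ValidationError(
            f"distance matrix shape {d.shape} does not match {p.size} species"
        )
    if not np.allclose(d, d.T, atol=1e-10) or np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValidationError("distances must be symmetric with zero diagonal")
    return float(p @ d @ p)


def functional_evenness(abundances, coordinates) -> float:
    """Villeger-style FEve over the minimum spanning tree of the site's points.

    NaN when fewer than 3 species are present or all points coincide.
    """
    p = _relative(abundances)
    pts = np.asarray(coordinates, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] != p.size:
        raise ValidationError("coordinates must have one row per species")
    s = p.size
    if s < 3:
        return float("nan")
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    mst = minimum_spanning_tree(dist).tocoo()
    edges = list(zip(mst.row, mst.col))
    lengths = np.array([dist[i, j] for i, j in edges])
    if lengths.sum() == 0:
        return float("nan")
    ew = lengths / (p[[i for i, _ in edges]] + p[[j for _, j in edges]])
    pew = ew / ew.sum()
    thresh = 1.0 / (s - 1)
    return float((np.minimum(pew, thresh).sum() - thresh) / (1.0 - thresh))


def faith_pd(present_species, tree: Phylogeny, include_root: bool = True) -> float:
    """Total branch length of the minimal subtree spanning the given tips."""
    return tree.faith_pd(present_species, include_root=include_root)


def phylo_species_evenness(abundances, tree: Phylogeny, species=None) -> float:
    """Abundance-weighted phylogenetic species evenness (PSE) in [0, 1].

    Uses the shared-branch covariance standardized per species by its
    root-to-tip depth; equals PSV when abundances are equal. NaN for S = 1.
    """
    m = np.asarray(abundances, float)
    if species is None:
        species = tree.tips
    species = list(species)
    if m.size != len(species):
        raise ValidationError("abundance vector must align with species list")
    keep = m > 0
    m, species = m[keep], [s for s, k in zip(species, keep) if k]
    if m.size < 2:
        return float("nan")
    C, _ = tree.correlation_matrix(species)
    M = m.sum()
    num = M * float(m @ np.diag(C)) - float(m @ C @ m)
    den = M ** 2 - float((m ** 2).sum())
    return float(num / den)


def alpha_table(community: CommunityMatrix, trait_space: TraitSpace, tree: Phylogeny,
                include_root: bool = True, scale_distances: bool = True) -> pd.DataFrame:
    """All six indices per site, plus richness.

    ``scale_distances`` divides functional distances by the global maximum
    pairwise distance so RaoQ is comparable across runs.
    """
    trait_species = set(trait_space.species)
    missing = sorted(set(community.species) - trait_species)
    if missing:
        raise ValidationError(f"species missing from trait space: {missing}")
    tree.check_matches(community)

    dglobal = trait_space.distance_matrix.loc[community.species, community.species].to_numpy(float)
    if scale_distances:
        dmax = dglobal.max()
        if dmax > 0:
            dglobal = dglobal / dmax
    coords = trait_space.coordinates.loc[community.species].to_numpy(float)

    rows = []
    for site in community.sites:
        counts = community.table.loc[site].to_numpy(float)
        present = counts > 0
        a = counts[present]
        sp = [s for s, keep in zip(community.species, present) if keep]
        d_site = dglobal[np.ix_(present, present)]
        rows.append({
            "site": site,
            "richness": int(present.sum()),
            "Shannon": shannon(a),
            "SEve": shannon_evenness(a),
            "RaoQ": rao_q(a, d_site) if len(sp) > 1 else 0.0,
            "FEve": functional_evenness(a, coords[present]),
            "PDfaith": faith_pd(sp, tree, include_root=include_root),
            "PSEve": phylo_species_evenness(a, tree, species=sp),
        })
    return pd.DataFrame(rows).set_index("site")
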