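"""Pairwise Sorensen-family beta diversity for the three facets.

Every facet reduces a site pair to shared / unique quantities (a, b, c):
species counts for the taxonomic facet, minimal-subtree branch lengths for the
phylogenetic facet, and convex-hull volumes in retained trait space for the
functional facet. The total dissimilarity beta_sor = (b+c)/(2a+b+c) is
partitioned into turnover beta_sim = min(b,c)/(a+min(b,c)) and nestedness
beta_nes = beta_sor - beta_sim.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .data import CommunityMatrix, Phylogeny
from .errors import ValidationError
from .traitspace import TraitSpace

logger = logging.getLogger("riverdiv")

__all__ = [
    "BetaComponents",
    "BetaMatrices",
    "sorensen_components",
    "taxonomic_beta",
    "phylogenetic_beta",
    "functional_beta",
    "hull_volume",
    "hull_intersection_volume",
    "monte_carlo_pair_volumes",
    "beta_summary",
    "beta_component_regression",
]


@dataclass(frozen=True)
class BetaComponents:
    a: float
    b: float
    c: float
    beta_sor: float
    beta_sim: float
    beta_nes: float


def sorensen_components(a: float, b: float, c: float) -> BetaComponents:
    """Sorensen total / turnover / nestedness from shared and unique quantities."""
    if min(a, b, c) < -1e-9:
        raise ValidationError("a, b, c must be non-negative")
    a, b, c = max(a, 0.0), max(b, 0.0), max(c, 0.0)  # clip float dust
    if 2 * a + b + c <= 0:
        raise ValidationError("both communities empty (2a + b + c = 0)")
    sor = (b + c) / (2 * a + b + c)
    mn = min(b, c)
    sim = mn / (a + mn) if (a + mn) > 0 else 0.0
    return BetaComponents(a, b, c, sor, sim, sor - sim)


@dataclass
class BetaMatrices:
    """Symmetric site x site grids for one facet (sor / sim / nes).

    ``flags`` marks functional-facet entries that were axis-reduced or left
    missing because a hull was degenerate.
    """

    facet: str
    sor: pd.DataFrame
    sim: pd.DataFrame
    nes: pd.DataFrame
    flags: pd.DataFrame | None = field(default=None)

    @property
    def sites(self) -> list:
        return list(self.sor.index)

    def upper_triangle(self, which: str = "sor") -> pd.Series:
        m = getattr(self, which)
        pairs, vals = [], []
        sites = list(m.index)
        for i, j in itertools.combinations(range(len(sites)), 2):
            pairs.append((sites[i], sites[j]))
            vals.append(m.iat[i, j])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(pairs, names=["site1", "site2"]))


def _empty_grids(sites):
    z = pd.DataFrame(0.0, index=sites, columns=sites)
    return z.copy(), z.copy(), z.copy()


def taxonomic_beta(community: CommunityMatrix) -> BetaMatrices:
    """Sorensen family on presence/absence species counts."""
    pa = community.presence_absence().to_numpy().astype(float)
    shared = pa @ pa.T
    rich = pa.sum(axis=1).astype(float)
    b = rich[:, None] - shared
    c = rich[None, :] - shared
    sor, sim, nes = _componentwise(shared, b, c)
    sites = community.sites
    return BetaMatrices(
        "TD",
        pd.DataFrame(sor, index=sites, columns=sites),
        pd.DataFrame(sim, index=sites, columns=sites),
        pd.DataFrame(nes, index=sites, columns=sites),
    )


def _componentwise(a, b, c):
    denom = 2 * a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        sor = np.where(denom > 0, (b + c) / denom, 0.0)
        mn = np.minimum(b, c)
        sim = np.where(a + mn > 0, mn / (a + mn), 0.0)
    nes = sor - sim
    for m in (sor, sim, nes):
        np.fill_diagonal(m, 0.0)
    return sor, sim, nes


def phylogenetic_beta(community: CommunityMatrix, tree: Phylogeny,
                      include_root: bool = True) -> BetaMatrices:
    """Sorensen family on shared / unique branch lengths of site subtrees."""
    tree.check_matches(community)
    pa = community.presence_absence()
    n = community.n_sites
    inc = np.zeros((n, len(tree.edge_lengths)), dtype=bool)
    for si, site in enumerate(community.sites):
        present = [sp for sp in community.species if pa.loc[site, sp]]
        inc[si] = tree.branch_mask_vector(tree.mask(present), include_root=include_root)
    lengths = tree.edge_lengths
    shared = (inc * lengths) @ inc.T
    totals = inc @ lengths
    b = totals[:, None] - shared
    c = totals[None, :] - shared
    sor, sim, nes = _componentwise(shared, b, c)
    sites = community.sites
    return BetaMatrices(
        "PD",
        pd.DataFrame(sor, index=sites, columns=sites),
        pd.DataFrame(sim, index=sites, columns=sites),
        pd.DataFrame(nes, index=sites, columns=sites),
    )


# ---------------------------------------------------------------------------
# Convex-hull functional beta
# ---------------------------------------------------------------------------


def hull_volume(points: np.ndarray) -> float:
    return float(ConvexHull(points).volume)


def _interior_point(halfspaces: np.ndarray):
    """Chebyshev center of {x : Ax + b <= 0}; None when (near-)empty."""
    a, b = halfspaces[:, :-1], halfspaces[:, -1]
    norms = np.linalg.norm(a, axis=1, keepdims=True)
    dim = a.shape[1]
    res = linprog(
        c=np.r_[np.zeros(dim), -1.0],
        A_ub=np.hstack([a, norms]),
        b_ub=-b,
        bounds=[(None, None)] * dim + [(0, None)],
        method="highs",
    )
    if not res.success or res.x[-1] <= 1e-12:
        return None
    return res.x[:-1]


def hull_intersection_volume(points1: np.ndarray, points2: np.ndarray) -> float:
    """Exact volume of the intersection of two convex hulls.

    Half-space intersection of the two hulls' facet inequalities; an empty or
    measure-zero intersection returns 0.
    """
    h1, h2 = ConvexHull(points1), ConvexHull(points2)
    halfspaces = np.vstack([h1.equations, h2.equations])
    center = _interior_point(halfspaces)
    if center is None:
        return 0.0
    try:
        hsi = HalfspaceIntersection(halfspaces, center)
        return float(ConvexHull(hsi.intersections).volume)
    except QhullError:
        return 0.0


def monte_carlo_pair_volumes(points1: np.ndarray, points2: np.ndarray,
                             n_points: int = 200_000, seed: int = 0) -> dict:
    """Seeded rejection estimates of vol1, vol2 and the intersection volume."""
    h1, h2 = ConvexHull(points1), ConvexHull(points2)
    allpts = np.vstack([points1, points2])
    lo, hi = allpts.min(axis=0), allpts.max(axis=0)
    box = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, size=(n_points, allpts.shape[1]))
    in1 = np.all(x @ h1.equations[:, :-1].T + h1.equations[:, -1] <= 1e-12, axis=1)
    in2 = np.all(x @ h2.equations[:, :-1].T + h2.equations[:, -1] <= 1e-12, axis=1)
    both = in1 & in2
    return {
        "vol1": box * in1.mean(),
        "vol2": box * in2.mean(),
        "intersection": box * both.mean(),
        "n_hits": int(both.sum()),
        "box_volume": box,
        "n_points": n_points,
    }


def _pair_hull_components(p1: np.ndarray, p2: np.ndarray,
                          mc_fallback: bool, mc_points: int, seed: int):
    v1, v2 = hull_volume(p1), hull_volume(p2)
    try:
        inter = hull_intersection_volume(p1, p2)
    except QhullError:
        if not mc_fallback:
            raise
        inter = monte_carlo_pair_volumes(p1, p2, mc_points, seed)["intersection"]
    inter = min(inter, v1, v2)  # numerical guard
    return inter, v1 - inter, v2 - inter


def functional_beta(community: CommunityMatrix, trait_space: TraitSpace,
                    n_axes_fd: int = 4, mc_fallback: bool = True,
                    mc_points: int = 200_000, seed: int = 0) -> BetaMatrices:
    """Sorensen family on shared / unique convex-hull volumes in trait space.

    A pair whose poorer community has fewer than ``n_axes_fd + 1`` species is
    recomputed in ``min richness - 1`` axes and flagged ``reduced``; pairs with
    min richness < 3, or with a degenerate hull, are missing (NaN) and flagged.
    """
    missing = sorted(set(community.species) - set(trait_space.species))
    if missing:
        raise ValidationError(f"species missing from trait space: {missing}")
    if n_axes_fd > trait_space.n_axes:
        raise ValidationError(
            f"n_axes_fd={n_axes_fd} exceeds trait space axes ({trait_space.n_axes})"
        )
    sites = community.sites
    pa = community.presence_absence()
    pts_by_site = {
        s: trait_space.coordinates.loc[
            [sp for sp in community.species if pa.loc[s, sp]]
        ].to_numpy(float)
        for s in sites
    }
    sor, sim, nes = _empty_grids(sites)
    flags = pd.DataFrame("", index=sites, columns=sites)
    for i, j in itertools.combinations(range(len(sites)), 2):
        s1, s2 = sites[i], sites[j]
        p1, p2 = pts_by_site[s1], pts_by_site[s2]
        min_rich = min(len(p1), len(p2))
        axes = min(n_axes_fd, min_rich - 1)
        flag = ""
        if min_rich < 3:
            _set_pair(sor, sim, nes, s1, s2, np.nan, np.nan, np.nan)
            flags.loc[s1, s2] = flags.loc[s2, s1] = "missing"
            logger.warning("FD beta %s-%s missing: min richness %d < 3", s1, s2, min_rich)
            continue
        if axes < n_axes_fd:
            flag = "reduced"
        try:
            inter, b, c = _pair_hull_components(
                p1[:, :axes], p2[:, :axes], mc_fallback, mc_points, seed
            )
            comp = sorensen_components(inter, max(b, 0.0), max(c, 0.0))
            _set_pair(sor, sim, nes, s1, s2, comp.beta_sor, comp.beta_sim, comp.beta_nes)
            flags.loc[s1, s2] = flags.loc[s2, s1] = flag
        except (QhullError, ValidationError) as exc:
            _set_pair(sor, sim, nes, s1, s2, np.nan, np.nan, np.nan)
            flags.loc[s1, s2] = flags.loc[s2, s1] = "missing"
            logger.warning("FD beta %s-%s missing: degenerate hull (%s)", s1, s2, exc)
    return BetaMatrices("FD", sor, sim, nes, flags=flags)


def _set_pair(sor, sim, nes, s1, s2, vs, vm, vn):
    sor.loc[s1, s2] = sor.loc[s2, s1] = vs
    sim.loc[s1, s2] = sim.loc[s2, s1] = vm
    nes.loc[s1, s2] = nes.loc[s2, s1] = vn


# ---------------------------------------------------------------------------
# Summaries and regressions
# ---------------------------------------------------------------------------


def beta_summary(matrices: BetaMatrices, n_bins: int = 20) -> dict:
    """Upper-triangle statistics and histogram counts for sor/sim/nes."""
    out = {}
    for which in ("sor", "sim", "nes"):
        tri = matrices.upper_triangle(which).dropna()
        if tri.empty:
            raise ValidationError(f"no valid {which} entries in {matrices.facet} matrices")
        counts, edges = np.histogram(tri.to_numpy(), bins=n_bins, range=(0.0, 1.0))
        out[which] = {
            "mean": float(tri.mean()),
            "sd": float(tri.std(ddof=1)) if len(tri) > 1 else 0.0,
            "min": float(tri.min()),
            "max": float(tri.max()),
            "argmin_pair": tuple(tri.idxmin()),
            "argmax_pair": tuple(tri.idxmax()),
            "n_pairs": int(len(tri)),
            "histogram": counts.tolist(),
            "bin_edges": edges.tolist(),
        }
    return out


def beta_component_regression(matrices: BetaMatrices) -> pd.DataFrame:
    """Quadratic OLS between each pair of components over upper-triangle pairs."""
    comps = {w: matrices.upper_triangle(w) for w in ("sor", "sim", "nes")}
    rows = []
    for xname, yname in (("sor", "sim"), ("sor", "nes"), ("sim", "nes")):
        joined = pd.concat([comps[xname], comps[yname]], axis=1, keys=["x", "y"]).dropna()
        x, y = joined["x"].to_numpy(), joined["y"].to_numpy()
        n = len(x)
        if n < 4:
            logger.warning("%s %s~%s: only %d valid pairs, quadratic fit skipped",
                           matrices.facet, yname, xname, n)
            rows.append({
                "facet": matrices.facet, "x": xname, "y": yname,
                "intercept": np.nan, "linear": np.nan, "quadratic": np.nan,
                "r2": np.nan, "r2_adj": np.nan, "n_pairs": n, "relation_sign": 0,
            })
            continue
        design = np.column_stack([np.ones(n), x, x ** 2])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 3)
        rows.append({
            "facet": matrices.facet, "x": xname, "y": yname,
            "intercept": coef[0], "linear": coef[1], "quadratic": coef[2],
            "r2": r2, "r2_adj": r2_adj, "n_pairs": n,
            "relation_sign": (int(np.sign(np.corrcoef(x, y)[0, 1]))
                              if n > 1 and x.std() > 0 and y.std() > 0 else 0),
        })
    return pd.DataFrame(rows)
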