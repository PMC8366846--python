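"""River-network connectivity metrics and spatial/statistical tests.

Network side: Strahler order, downstream-link magnitude (count of first-order
source segments upstream of the link below the next downstream confluence),
and dam categories per site. Statistics side: Moran's I (normal-approximation,
permutation, or exhaustive), Lee's L bivariate spatial association, and
per-index one-way ANOVA over the connectivity factors with compact-letter
pairwise comparisons.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data import Placement, RiverNetwork, SiteAttributes
from .errors import ValidationError

logger = logging.getLogger("riverdiv")

__all__ = [
    "SpatialWeights",
    "TestResult",
    "AnovaResult",
    "strahler_orders",
    "strahler_order",
    "link_magnitudes",
    "downstream_link",
    "dam_category",
    "dlink_bin_label",
    "build_weights",
    "morans_i",
    "lees_l",
    "factor_anova",
]


# ---------------------------------------------------------------------------
# Network metrics
# ---------------------------------------------------------------------------


def strahler_orders(network: RiverNetwork) -> dict:
    """Strahler order of every edge (leaf segments are order 1)."""
    orders: dict = {}
    g = network.graph
    for node in nx.topological_sort(g):
        up = network.upstream_edges_of(node)
        down = network.downstream_edge_of(node)
        if down is None:
            continue
        if not up:
            orders[down] = 1
        else:
            up_orders = [orders[e] for e in up]
            top = max(up_orders)
            orders[down] = top + 1 if up_orders.count(top) >= 2 else top
    return orders


def strahler_order(network: RiverNetwork, site: str) -> int:
    """Order of the segment the site sits on."""
    placement = _site_placement(network, site)
    return strahler_orders(network)[placement.edge]


def link_magnitudes(network: RiverNetwork) -> dict:
    """Magnitude of every edge: number of first-order source segments upstream
    of (and including, for source segments) that edge."""
    mags: dict = {}
    g = network.graph
    for node in nx.topological_sort(g):
        up = network.upstream_edges_of(node)
        down = network.downstream_edge_of(node)
        if down is None:
            continue
        mags[down] = 1 if not up else sum(mags[e] for e in up)
    return mags


def downstream_link(network: RiverNetwork, site: str) -> dict:
    """Magnitude (and log2 bin) of the link below the next downstream confluence.

    A site already below the last confluence takes the outlet link's magnitude.
    """
    placement = _site_placement(network, site)
    mags = link_magnitudes(network)
    g = network.graph
    eid = placement.edge
    while True:
        _, v = network.edge_endpoints(eid)
        nxt = network.downstream_edge_of(v)
        if nxt is None:
            logger.warning("site %r is below the last confluence; using outlet link", site)
            magnitude = mags[eid]
            break
        if g.in_degree(v) >= 2:
            magnitude = mags[nxt]
            break
        eid = nxt
    log2 = math.log2(magnitude) if magnitude > 0 else float("-inf")
    return {"magnitude": magnitude, "log2": log2, "log2_category": dlink_bin_label(log2)}


def dlink_bin_label(log2_value: float) -> str:
    """Unit-interval bin label [lo, lo+1) for a log2 downstream-link value."""
    lo = int(math.floor(log2_value))
    return f"{lo}-{lo + 1}"


def dam_category(network: RiverNetwork, site: str) -> str:
    """'Up', 'Down', 'Up&Down', or 'None' from dam positions relative to the site."""
    placement = _site_placement(network, site)
    up_edges = network.upstream_edge_set(placement.edge)
    down_chain = network.downstream_edge_chain(placement.edge)[1:]
    up = down = False
    for dam in network.dams.values():
        if dam.edge == placement.edge:
            if dam.position < placement.position:
                up = True
            elif dam.position > placement.position:
                down = True
        elif dam.edge in up_edges:
            up = True
        elif dam.edge in down_chain:
            down = True
    if up and down:
        return "Up&Down"
    if up:
        return "Up"
    if down:
        return "Down"
    logger.warning("site %r has no dam up- or downstream; category 'None'", site)
    return "None"


def _site_placement(network: RiverNetwork, site: str) -> Placement:
    try:
        return network.sites[site]
    except KeyError:
        raise ValidationError(f"site {site!r} not placed on the network") from None


# ---------------------------------------------------------------------------
# Spatial weights
# ---------------------------------------------------------------------------


@dataclass
class SpatialWeights:
    matrix: pd.DataFrame
    scheme: str
    row_standardized: bool

    @property
    def sites(self) -> list:
        return list(self.matrix.index)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(float)


def build_weights(coordinates: pd.DataFrame, scheme: str = "inverse-distance",
                  k: int = 4, threshold: float | None = None,
                  row_standardize: bool = True) -> SpatialWeights:
    """Site x site spatial weights from planar coordinates."""
    xy = coordinates.to_numpy(float)
    n = xy.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 sites")
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    off = ~np.eye(n, dtype=bool)
    if np.any(dist[off] == 0):
        raise ValidationError("coincident sites (zero distance) in weights construction")
    if scheme == "inverse-distance":
        w = np.zeros((n, n))
        w[off] = 1.0 / dist[off]
    elif scheme == "k-nearest":
        w = np.zeros((n, n))
        for i in range(n):
            order = np.argsort(dist[i])
            neigh = [j for j in order if j != i][:k]
            w[i, neigh] = 1.0
        w = np.maximum(w, w.T)  # symmetrize
    elif scheme == "binary-threshold":
        if threshold is None:
            raise ValidationError("binary-threshold scheme requires a threshold")
        w = ((dist <= threshold) & off).astype(float)
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    if np.any(w.sum(axis=1) == 0):
        raise ValidationError("every site needs at least one positive weight")
    if row_standardize:
        w = w / w.sum(axis=1, keepdims=True)
    return SpatialWeights(
        pd.DataFrame(w, index=coordinates.index, columns=coordinates.index),
        scheme, row_standardize,
    )


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    statistic: float
    expected: float
    sd: float | None
    p_value: float
    method: str
    n_perm: int | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)


def _moran_stat(z: np.ndarray, w: np.ndarray) -> float:
    n = z.size
    w0 = w.sum()
    return float((n / w0) * (z @ w @ z) / (z @ z))


def morans_i(values, weights: SpatialWeights, mode: str = "normal",
             n_perm: int = 9999, seed: int = 0) -> TestResult:
    """Moran's I spatial autocorrelation with normal, permutation, or
    exhaustive-permutation inference (two-sided)."""
    x = np.asarray(values, float)
    w = weights.values()
    n = x.size
    if w.shape != (n, n):
        raise ValidationError("weights do not match the value vector")
    if np.ptp(x) == 0:
        raise ValidationError("constant value vector (zero variance)")
    z = x - x.mean()
    i_obs = _moran_stat(z, w)
    expected = -1.0 / (n - 1)

    if mode == "normal":
        w0 = w.sum()
        s1 = 0.5 * ((w + w.T) ** 2).sum()
        s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
        var = (n ** 2 * s1 - n * s2 + 3 * w0 ** 2) / (w0 ** 2 * (n ** 2 - 1)) - expected ** 2
        sd = math.sqrt(var)
        zscore = (i_obs - expected) / sd
        p = 2.0 * stats.norm.sf(abs(zscore))
        return TestResult(i_obs, expected, sd, p, "moran_normal")
    if mode == "permutation":
        rng = np.random.default_rng(seed)
        ref = abs(i_obs - expected)
        hits = 0
        for _ in range(n_perm):
            zp = rng.permutation(z)
            if abs(_moran_stat(zp, w) - expected) >= ref - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        sd = None
        return TestResult(i_obs, expected, sd, p, "moran_permutation", n_perm=n_perm, seed=seed)
    if mode == "exhaustive":
        if n > 8:
            raise ValidationError("exhaustive permutation limited to n <= 8")
        ref = abs(i_obs - expected)
        stats_all = [
            _moran_stat(z[list(perm)], w) for perm in itertools.permutations(range(n))
        ]
        p = float(np.mean([abs(s - expected) >= ref - 1e-12 for s in stats_all]))
        return TestResult(i_obs, expected, None, p, "moran_exhaustive",
                          extras={"n_permutations": len(stats_all)})
    raise ValueError(f"unknown mode {mode!r}")


def _lee_stat(zx: np.ndarray, zy: np.ndarray, w: np.ndarray) -> float:
    n = zx.size
    lx, ly = w @ zx, w @ zy
    denom = (w.sum(axis=1) ** 2).sum()
    return float((n / denom) * (lx @ ly) / (np.sqrt((zx ** 2).sum()) * np.sqrt((zy ** 2).sum())))


def lees_l(x, y, weights: SpatialWeights, n_perm: int = 9999, seed: int = 0) -> TestResult:
    """Lee's L bivariate spatial association; p by joint site-label permutation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = weights.values()
    if x.size != y.size or w.shape != (x.size, x.size):
        raise ValidationError("x, y and weights must align")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant value vector (zero variance)")
    zx, zy = x - x.mean(), y - y.mean()
    l_obs = _lee_stat(zx, zy, w)
    rng = np.random.default_rng(seed)
    sim = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(x.size)
        sim[r] = _lee_stat(zx[perm], zy[perm], w)
    expected = float(sim.mean())
    ref = abs(l_obs - expected)
    hits = int(np.sum(np.abs(sim - expected) >= ref - 1e-12))
    p = (hits + 1) / (n_perm + 1)
    return TestResult(l_obs, expected, float(sim.std(ddof=1)), p, "lees_l_permutation",
                      n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Factor ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    index: str
    factor: str
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    level_means: pd.Series
    level_letters: dict
    pairwise_p: pd.DataFrame
    dropped_levels: list


def factor_anova(alpha: pd.DataFrame, attributes: SiteAttributes, index: str,
                 factor: str, alpha_level: float = 0.01) -> AnovaResult:
    """One-way F test of a connectivity factor on one diversity index.

    Levels with < 2 sites are dropped with a warning. Pairwise level
    comparisons use pooled-variance t tests (Fisher LSD) summarized as a
    compact letter display at ``alpha_level``.
    """
    if index not in alpha.columns:
        raise ValidationError(f"index {index!r} not in alpha table")
    values = alpha[index]
    levels = attributes.factor(factor).reindex(values.index)
    if levels.isna().any():
        raise ValidationError("attribute table does not cover all sites")
    counts = levels.value_counts()
    dropped = sorted(counts.index[counts < 2])
    if dropped:
        logger.warning("dropping level(s) with < 2 sites for %s/%s: %s", index, factor, dropped)
    keep = ~levels.isin(dropped)
    values, levels = values[keep], levels[keep]
    groups = {lv: values[levels == lv].to_numpy(float) for lv in sorted(levels.unique())}
    if len(groups) < 2:
        raise ValidationError("need at least 2 levels with >= 2 sites each")

    k = len(groups)
    n = sum(len(g) for g in groups.values())
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_b, df_w = k - 1, n - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f_stat = math.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f_stat = ms_b / ms_w
        p = float(stats.f.sf(f_stat, df_b, df_w))

    level_names = list(groups)
    pairwise = pd.DataFrame(np.nan, index=level_names, columns=level_names)
    for l1, l2 in itertools.combinations(level_names, 2):
        g1, g2 = groups[l1], groups[l2]
        if ms_w == 0:
            pw = 1.0 if g1.mean() == g2.mean() else 0.0
        else:
            se = math.sqrt(ms_w * (1 / len(g1) + 1 / len(g2)))
            t = (g1.mean() - g2.mean()) / se
            pw = 2.0 * float(stats.t.sf(abs(t), df_w))
        pairwise.loc[l1, l2] = pairwise.loc[l2, l1] = pw

    letters = _compact_letters(
        {lv: groups[lv].mean() for lv in level_names}, pairwise, alpha_level
    )
    return AnovaResult(
        index=index, factor=factor, f_statistic=float(f_stat), p_value=p,
        df_between=df_b, df_within=df_w,
        level_means=pd.Series({lv: groups[lv].mean() for lv in level_names}),
        level_letters=letters, pairwise_p=pairwise, dropped_levels=dropped,
    )


def _compact_letters(means: dict, pairwise_p: pd.DataFrame, alpha_level: float) -> dict:
    """Greedy compact letter display: levels sharing a letter are not
    significantly different at ``alpha_level``."""
    order = sorted(means, key=lambda lv: -means[lv])
    letter_groups: list[list] = []
    for lv in order:
        placed = False
        for grp in letter_groups:
            if all(pairwise_p.loc[lv, other] >= alpha_level for other in grp):
                grp.append(lv)
                placed = True
        if not placed:
            letter_groups.append([lv])
    letters = {lv: "" for lv in order}
    for gi, grp in enumerate(letter_groups):
        ch = chr(ord("a") + gi)
        for lv in grp:
            letters[lv] += ch
    return letters


def manova_pillai(alpha: pd.DataFrame, attributes: SiteAttributes, indices,
                  factor: str) -> TestResult:
    """Optional joint multivariate test (Pillai trace) across several indices."""
    y = alpha[list(indices)].to_numpy(float)
    levels = attributes.factor(factor).reindex(alpha.index)
    names = sorted(levels.unique())
    if len(names) < 2:
        raise ValidationError("need >= 2 factor levels")
    n, p = y.shape
    k = len(names)
    grand = y.mean(axis=0)
    h = np.zeros((p, p))
    e = np.zeros((p, p))
    for lv in names:
        sub = y[(levels == lv).to_numpy()]
        d = sub.mean(axis=0) - grand
        h += len(sub) * np.outer(d, d)
        e += (sub - sub.mean(axis=0)).T @ (sub - sub.mean(axis=0))
    eigs = np.linalg.eigvals(np.linalg.solve(e + h, h)).real
    pillai = float(eigs.sum())
    s = min(p, k - 1)
    m = (abs(p - (k - 1)) - 1) / 2
    nn = (n - k - p - 1) / 2
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    f_stat = (pillai / (s - pillai)) * (df2 / df1) if s > pillai else math.inf
    p_val = float(stats.f.sf(f_stat, df1, df2)) if math.isfinite(f_stat) else 0.0
    return TestResult(pillai, 0.0, None, p_val, "manova_pillai",
                      extras={"F": f_stat, "df1": df1, "df2": df2})
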