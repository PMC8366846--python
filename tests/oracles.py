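"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written along a different route from the
package: explicit loops, set arithmetic on dendropy edge paths, Prüfer-sequence
spanning-tree enumeration, normal equations — so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np


# ---------------------------------------------------------------------------
# Alpha indices
# ---------------------------------------------------------------------------


def shannon_oracle(counts) -> float:
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h


def rao_oracle(counts, dist) -> float:
    total = sum(counts)
    q = 0.0
    n = len(counts)
    for i in range(n):
        for j in range(n):
            q += dist[i][j] * (counts[i] / total) * (counts[j] / total)
    return q


def _all_spanning_trees(n):
    """All labeled trees on n nodes via Prüfer sequences (n >= 2)."""
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        edges = []
        seq_list = list(seq)
        avail = sorted(i for i in range(n) if degree[i] == 1)
        deg = degree[:]
        for v in seq_list:
            leaf = min(i for i in range(n) if deg[i] == 1)
            edges.append((leaf, v))
            deg[leaf] -= 1
            deg[v] -= 1
        last = [i for i in range(n) if deg[i] == 1]
        edges.append((last[0], last[1]))
        yield edges


def mst_oracle(points) -> list:
    """Minimum spanning tree by exhaustive enumeration of all spanning trees."""
    pts = np.asarray(points, float)
    n = len(pts)
    best, best_len = None, math.inf
    for edges in _all_spanning_trees(n):
        ln = sum(math.dist(pts[i], pts[j]) for i, j in edges)
        if ln < best_len - 1e-15:
            best, best_len = edges, ln
    return best


def feve_oracle(counts, points) -> float:
    total = sum(counts)
    p = [c / total for c in counts]
    s = len(counts)
    edges = mst_oracle(points)
    ew = [math.dist(points[i], points[j]) / (p[i] + p[j]) for i, j in edges]
    sew = sum(ew)
    pew = [e / sew for e in ew]
    thr = 1.0 / (s - 1)
    return (sum(min(x, thr) for x in pew) - thr) / (1.0 - thr)


# ---------------------------------------------------------------------------
# Phylogenetic oracles (dendropy edge-path sets)
# ---------------------------------------------------------------------------


def _edge_paths(newick: str):
    """Map tip label -> set of edge ids on its root path, plus edge lengths."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    lengths = {}
    paths = {}
    for i, edge in enumerate(tree.preorder_edge_iter()):
        edge.oracle_id = i
        if edge.head_node.parent_node is not None:
            lengths[i] = edge.length if edge.length is not None else 0.0
    for leaf in tree.leaf_node_iter():
        path = set()
        node = leaf
        while node.parent_node is not None:
            path.add(node.edge.oracle_id)
            node = node.parent_node
        paths[leaf.taxon.label.replace("_", " ")] = path
    return paths, lengths


def branch_set_oracle(newick: str, tips, include_root: bool = True) -> set:
    paths, _ = _edge_paths(newick)
    union = set()
    for t in tips:
        union |= paths[t.replace("_", " ")]
    if not include_root:
        common = None
        for t in tips:
            p = paths[t.replace("_", " ")]
            common = p if common is None else (common & p)
        union -= common if len(tips) > 0 else set()
    return union


def pd_oracle(newick: str, tips, include_root: bool = True) -> float:
    paths, lengths = _edge_paths(newick)
    return sum(lengths[e] for e in branch_set_oracle(newick, tips, include_root))


def pse_oracle(newick: str, tips, counts) -> float:
    paths, lengths = _edge_paths(newick)
    tips = [t.replace("_", " ") for t in tips]
    n = len(tips)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = paths[tips[i]] & paths[tips[j]]
            v[i, j] = sum(lengths[e] for e in shared)
    d = np.sqrt(np.diag(v))
    c = v / np.outer(d, d)
    m = np.asarray(counts, float)
    big_m = m.sum()
    num = big_m * sum(m[i] * c[i, i] for i in range(n)) - float(m @ c @ m)
    den = big_m ** 2 - sum(x * x for x in m)
    return num / den


# ---------------------------------------------------------------------------
# Beta oracles
# ---------------------------------------------------------------------------


def sorensen_oracle(a, b, c):
    sor = (b + c) / (2 * a + b + c)
    mn = min(b, c)
    sim = mn / (a + mn) if (a + mn) > 0 else 0.0
    return sor, sim, sor - sim


def td_beta_oracle(species1: set, species2: set):
    a = len(species1 & species2)
    b = len(species1 - species2)
    c = len(species2 - species1)
    return sorensen_oracle(a, b, c)


def pd_beta_oracle(newick: str, tips1, tips2, include_root: bool = True):
    _, lengths = _edge_paths(newick)
    s1 = branch_set_oracle(newick, tips1, include_root)
    s2 = branch_set_oracle(newick, tips2, include_root)
    a = sum(lengths[e] for e in s1 & s2)
    b = sum(lengths[e] for e in s1 - s2)
    c = sum(lengths[e] for e in s2 - s1)
    return sorensen_oracle(a, b, c)


def hull_area_oracle_2d(points1, points2):
    """Shapely-based areas: (area1, area2, intersection area)."""
    from shapely.geometry import MultiPoint

    h1 = MultiPoint([tuple(p) for p in points1]).convex_hull
    h2 = MultiPoint([tuple(p) for p in points2]).convex_hull
    return h1.area, h2.area, h1.intersection(h2).area


def quadratic_fit_oracle(x, y):
    """OLS of y on (1, x, x^2) via explicit normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    design = np.column_stack([np.ones_like(x), x, x * x])
    coef = np.linalg.solve(design.T @ design, design.T @ y)
    resid = y - design @ coef
    n = len(x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - 3)
    return coef, r2, r2_adj


# ---------------------------------------------------------------------------
# Spatial oracles
# ---------------------------------------------------------------------------


def moran_oracle(values, w) -> float:
    x = np.asarray(values, float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    w0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i][j] * z[i] * z[j]
            w0 += w[i][j]
    return (n / w0) * num / sum(zi * zi for zi in z)


def lee_oracle(xs, ys, w) -> float:
    x = np.asarray(xs, float)
    y = np.asarray(ys, float)
    n = len(x)
    zx, zy = x - x.mean(), y - y.mean()
    num = 0.0
    den = 0.0
    for i in range(n):
        sx = sum(w[i][j] * zx[j] for j in range(n))
        sy = sum(w[i][j] * zy[j] for j in range(n))
        num += sx * sy
        den += sum(w[i][j] for j in range(n)) ** 2
    return (n / den) * num / (math.sqrt(sum(zx ** 2)) * math.sqrt(sum(zy ** 2)))


def anova_oracle(groups):
    """(F, df_between, df_within) by explicit sums of squares."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def strahler_oracle(upstream: dict, edge) -> int:
    """Recursive textbook definition; ``upstream`` maps edge -> list of
    immediately upstream edges."""
    ups = upstream.get(edge, [])
    if not ups:
        return 1
    orders = [strahler_oracle(upstream, e) for e in ups]
    top = max(orders)
    return top + 1 if orders.count(top) >= 2 else top


def magnitude_oracle(upstream: dict, edge) -> int:
    """Count of source segments upstream of (including) ``edge``."""
    ups = upstream.get(edge, [])
    if not ups:
        return 1
    return sum(magnitude_oracle(upstream, e) for e in ups)


def gower_oracle(rows, kinds, ranges):
    """Per-trait hand computation; ``kinds`` in {'cont', 'nom', 'ord'},
    ``ranges`` gives the divisor for cont/ord traits (None for nominal)."""
    n = len(rows)
    out = [[0.0] * n for _ in range(n)]
    n_traits = len(kinds)
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for t in range(n_traits):
                if kinds[t] == "nom":
                    acc += 0.0 if rows[i][t] == rows[j][t] else 1.0
                else:
                    rng = ranges[t]
                    acc += abs(rows[i][t] - rows[j][t]) / rng if rng else 0.0
            out[i][j] = acc / n_traits
    return out
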