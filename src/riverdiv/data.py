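"""Core domain types and delimited-text / Newick I-O.

The five shared types (:class:`CommunityMatrix`, :class:`TraitTable`,
:class:`Phylogeny`, :class:`SiteAttributes`, :class:`RiverNetwork`) validate
their invariants on construction; all readers auto-detect tab/comma delimiters
unless one is forced.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .errors import NetworkStructureError, ValidationError

logger = logging.getLogger("riverdiv")

__all__ = [
    "CommunityMatrix",
    "TraitSchema",
    "TraitTable",
    "Phylogeny",
    "SiteAttributes",
    "RiverNetwork",
    "Placement",
    "DEFAULT_TRAIT_SCHEMA",
    "canonical_name",
    "read_community",
    "read_traits",
    "read_tree",
    "read_site_attributes",
    "read_network",
    "read_table",
    "write_table",
    "parse_config",
]


def canonical_name(name: str) -> str:
    """Normalize an identifier: strip, collapse whitespace, '_' == ' '."""
    return re.sub(r"\s+", " ", str(name).replace("_", " ").strip())


def _detect_delimiter(path, override: str | None = None) -> str:
    if override is not None:
        return override
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_table(path, delimiter: str | None = None, index_col=0) -> pd.DataFrame:
    """Read a delimited table with the first column as index."""
    sep = _detect_delimiter(path, delimiter)
    return pd.read_csv(path, sep=sep, index_col=index_col)


def write_table(table: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a result table; round-trip safe to full float precision."""
    table.to_csv(path, sep=delimiter)


def parse_config(path) -> dict:
    """Parse a plain-text ``key = value`` configuration file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


# ---------------------------------------------------------------------------
# Community matrix
# ---------------------------------------------------------------------------


class CommunityMatrix:
    """Site x species grid of non-negative integer abundance counts.

    Invariants: unique identifiers, every site holds >= 1 individual, every
    species occurs at >= 1 site.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        table.index = [canonical_name(s) for s in table.index]
        table.columns = [canonical_name(s) for s in table.columns]
        for axis, kind in ((table.index, "site"), (table.columns, "species")):
            dup = pd.Index(axis)[pd.Index(axis).duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate {kind} identifier(s): {sorted(set(dup))}")
        values = table.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = table.map(lambda v: not isinstance(v, (int, float, np.number)))
            loc = np.argwhere(bad.to_numpy())
            r, c = loc[0]
            raise ValidationError(
                f"non-numeric cell at site {table.index[r]!r}, species {table.columns[c]!r}"
            )
        if np.any(values < 0) or np.any(values != np.floor(values)):
            r, c = np.argwhere((values < 0) | (values != np.floor(values)))[0]
            raise ValidationError(
                f"count at site {table.index[r]!r}, species {table.columns[c]!r} "
                f"is not a non-negative integer: {values[r, c]!r}"
            )
        table = table.astype(int)
        empty_sites = table.index[table.sum(axis=1) == 0].tolist()
        if empty_sites:
            raise ValidationError(f"site(s) with no individuals: {empty_sites}")
        empty_species = table.columns[table.sum(axis=0) == 0].tolist()
        if empty_species:
            raise ValidationError(f"species with no occurrences: {empty_species}")
        self.table = table

    @property
    def sites(self) -> list:
        return list(self.table.index)

    @property
    def species(self) -> list:
        return list(self.table.columns)

    @property
    def n_sites(self) -> int:
        return len(self.table.index)

    @property
    def n_species(self) -> int:
        return len(self.table.columns)

    def presence_absence(self) -> pd.DataFrame:
        return self.table > 0

    def richness(self) -> pd.Series:
        return (self.table > 0).sum(axis=1).rename("richness")

    def prevalence(self) -> pd.Series:
        """Fraction of sites occupied per species, in (0, 1]."""
        return ((self.table > 0).sum(axis=0) / self.n_sites).rename("prevalence")

    def mean_individuals_per_species(self) -> pd.Series:
        return (self.table.sum(axis=1) / self.richness()).rename("mean_individuals")

    def site_abundances(self, site) -> pd.Series:
        row = self.table.loc[site]
        return row[row > 0]

    def __eq__(self, other):
        return isinstance(other, CommunityMatrix) and self.table.equals(other.table)

    def __repr__(self):
        return f"CommunityMatrix({self.n_sites} sites x {self.n_species} species)"


def read_community(path, orientation: str = "sites-as-rows", delimiter: str | None = None) -> CommunityMatrix:
    """Read an abundance matrix; ``orientation`` normalizes to sites x species."""
    if orientation not in ("sites-as-rows", "species-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    table = read_table(path, delimiter)
    if orientation == "species-as-rows":
        table = table.T
    return CommunityMatrix(table)


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitSchema:
    """Declares which trait columns are continuous vs categorical.

    ``ordinal`` names categorical columns whose levels are ordered (their
    declared level order gives ranks 1, 2, ...).
    """

    continuous: tuple
    categorical: dict
    ordinal: frozenset = field(default_factory=frozenset)

    @property
    def columns(self) -> list:
        return list(self.continuous) + list(self.categorical)


DEFAULT_TRAIT_SCHEMA = TraitSchema(
    continuous=("Hl/Sl", "Ed/Hd", "Snl/Hl", "Hd/Bd", "PecFl/Sl", "CPd/CFd", "Bd/Sl"),
    categorical={
        "rheophily": ("rheophilic", "limnophilic", "eurytopic"),
        "water_column": ("benthic", "benthopelagic", "pelagic"),
        "life_span": ("<=10", "10-20", ">20"),
    },
    ordinal=frozenset({"life_span"}),
)


class TraitTable:
    """Species x trait table with a declared continuous/categorical split."""

    def __init__(self, table: pd.DataFrame, schema: TraitSchema = DEFAULT_TRAIT_SCHEMA,
                 allow_missing: bool = False):
        table = table.copy()
        table.index = [canonical_name(s) for s in table.index]
        dup = table.index[table.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate species in trait table: {sorted(set(dup))}")
        missing_cols = [c for c in schema.columns if c not in table.columns]
        if missing_cols:
            raise ValidationError(f"trait column(s) missing: {missing_cols}")
        for col in schema.continuous:
            vals = pd.to_numeric(table[col], errors="coerce")
            if vals.isna().any():
                bad = table.index[vals.isna()].tolist()
                if not allow_missing:
                    raise ValidationError(f"trait {col!r}: non-numeric/missing for {bad}")
            elif (vals <= 0).any():
                bad = table.index[vals <= 0].tolist()
                raise ValidationError(f"trait {col!r} must be strictly positive; offending: {bad}")
            table[col] = vals
        for col, levels in schema.categorical.items():
            bad = ~table[col].isin(levels)
            if bad.any():
                raise ValidationError(
                    f"trait {col!r}: value(s) {sorted(set(table[col][bad]))} outside "
                    f"allowed set {list(levels)}"
                )
        self.table = table[schema.columns]
        self.schema = schema

    @property
    def species(self) -> list:
        return list(self.table.index)

    def check_covers(self, community: CommunityMatrix) -> None:
        missing = sorted(set(community.species) - set(self.species))
        if missing:
            raise ValidationError(f"species missing from trait table: {missing}")

    def subset(self, species) -> "TraitTable":
        return TraitTable(self.table.loc[list(species)], self.schema)

    def ordinal_ranks(self, col: str) -> pd.Series:
        """1-based rank of each species' level for an ordinal categorical trait."""
        levels = list(self.schema.categorical[col])
        return self.table[col].map({lv: i + 1 for i, lv in enumerate(levels)})


def read_traits(path, schema: TraitSchema = DEFAULT_TRAIT_SCHEMA,
                delimiter: str | None = None, allow_missing: bool = False) -> TraitTable:
    return TraitTable(read_table(path, delimiter), schema, allow_missing=allow_missing)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """Rooted, branch-length-bearing tree over the species pool.

    Wraps a :mod:`dendropy` tree and precomputes, for every branch, the bitmask
    of tips below it — the substrate for minimal-subtree lengths, pairwise
    shared-branch covariance, and per-pair branch incidence.
    """

    def __init__(self, tree: dendropy.Tree, missing_length: str = "error"):
        if missing_length not in ("error", "zero"):
            raise ValueError("missing_length must be 'error' or 'zero'")
        self.tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValidationError("tree contains an unlabeled tip")
            labels.append(canonical_name(leaf.taxon.label))
        dup = pd.Index(labels)[pd.Index(labels).duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate tip label(s): {sorted(set(dup))}")
        self.tips: list = labels
        self._tip_index = {lab: i for i, lab in enumerate(labels)}

        lengths, below = [], []
        tip_pos = {}
        i = 0
        for leaf in tree.leaf_node_iter():
            tip_pos[id(leaf)] = i
            i += 1
        # postorder: mask of tips below each node
        mask_of: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                mask_of[id(node)] = 1 << tip_pos[id(node)]
            else:
                m = 0
                for ch in node.child_nodes():
                    m |= mask_of[id(ch)]
                mask_of[id(node)] = m
            if node.parent_node is not None:
                ln = node.edge.length
                if ln is None:
                    if missing_length == "error":
                        raise ValidationError(
                            f"branch above {'tip ' + self.tips[tip_pos[id(node)]] if node.is_leaf() else 'an internal node'} has no length"
                        )
                    ln = 0.0
                if ln < 0:
                    raise ValidationError("negative branch length")
                lengths.append(float(ln))
                below.append(mask_of[id(node)])
        self.edge_lengths = np.asarray(lengths, dtype=float)
        self.edge_below: list = below
        self._all_mask = (1 << len(labels)) - 1

    @classmethod
    def from_newick(cls, newick: str, missing_length: str = "error") -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls(tree, missing_length=missing_length)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    def mask(self, species) -> int:
        m = 0
        unknown = []
        for sp in species:
            i = self._tip_index.get(canonical_name(sp))
            if i is None:
                unknown.append(sp)
            else:
                m |= 1 << i
        if unknown:
            raise ValidationError(f"species not found among tree tips: {sorted(unknown)}")
        return m

    def check_matches(self, community: CommunityMatrix) -> None:
        """The tree may cover a larger pool, but every community species must
        match exactly one tip."""
        tree_set, comm_set = set(self.tips), set(community.species)
        if comm_set - tree_set:
            raise ValidationError(
                "tip/species mismatch; only in tree: "
                f"{sorted(tree_set - comm_set)}; only in community: {sorted(comm_set - tree_set)}"
            )

    def branch_mask_vector(self, present_mask: int, include_root: bool = True) -> np.ndarray:
        """Boolean incidence of each branch in the minimal subtree of ``present_mask``."""
        if present_mask == 0:
            raise ValidationError("empty species set")
        inc = np.fromiter(
            (b & present_mask != 0 for b in self.edge_below), bool, len(self.edge_below)
        )
        if not include_root:
            covers = np.fromiter(
                (b & present_mask == present_mask for b in self.edge_below),
                bool, len(self.edge_below),
            )
            inc &= ~covers
        return inc

    def faith_pd(self, species, include_root: bool = True) -> float:
        inc = self.branch_mask_vector(self.mask(species), include_root)
        return float(self.edge_lengths[inc].sum())

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path length per tip (tree tip order)."""
        depths = np.zeros(self.n_tips)
        for ln, b in zip(self.edge_lengths, self.edge_below):
            for i in _bits(b):
                depths[i] += ln
        return depths

    def covariance_matrix(self, species=None) -> tuple:
        """Shared root-to-tip branch-length covariance V (and species order)."""
        order = self.tips if species is None else [canonical_name(s) for s in species]
        idx = [self._tip_index[s] for s in order]
        n_all = self.n_tips
        V = np.zeros((n_all, n_all))
        for ln, b in zip(self.edge_lengths, self.edge_below):
            members = list(_bits(b))
            V[np.ix_(members, members)] += ln
        return V[np.ix_(idx, idx)], order

    def correlation_matrix(self, species=None) -> tuple:
        """V standardized per species by root-to-tip depth (unit diagonal)."""
        V, order = self.covariance_matrix(species)
        d = np.sqrt(np.diag(V))
        if np.any(d == 0):
            raise ValidationError("zero root-to-tip depth; cannot standardize")
        return V / np.outer(d, d), order


def _bits(mask: int):
    i = 0
    while mask:
        if mask & 1:
            yield i
        mask >>= 1
        i += 1


def read_tree(path, missing_length: str = "error") -> Phylogeny:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return Phylogeny(tree, missing_length=missing_length)


# ---------------------------------------------------------------------------
# Site attributes
# ---------------------------------------------------------------------------

DAM_LEVELS = ("Up", "Down", "Up&Down", "None")
CORE_DLINK_LEVELS = ("1-2", "2-3", "3-4")


class SiteAttributes:
    """Per-site coordinates plus the three connectivity categories."""

    REQUIRED = ("x", "y", "order", "dlink", "dam")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        table.index = [canonical_name(s) for s in table.index]
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValidationError(f"site attribute column(s) missing: {missing}")
        if table.index.duplicated().any():
            raise ValidationError("duplicate site identifiers in attribute table")
        order = pd.to_numeric(table["order"], errors="coerce")
        if order.isna().any() or (order < 1).any() or (order != np.floor(order)).any():
            raise ValidationError("order must be a positive integer Strahler order")
        table["order"] = order.astype(int)
        bad_dam = ~table["dam"].isin(DAM_LEVELS)
        if bad_dam.any():
            raise ValidationError(
                f"dam category outside {DAM_LEVELS}: {sorted(set(table['dam'][bad_dam]))}"
            )
        extra = set(table["dlink"].astype(str)) - set(CORE_DLINK_LEVELS)
        if extra:
            logger.warning("dlink categories outside the core bins %s: %s",
                           CORE_DLINK_LEVELS, sorted(extra))
        self.table = table

    @property
    def sites(self) -> list:
        return list(self.table.index)

    def check_covers(self, community: CommunityMatrix) -> None:
        missing = sorted(set(community.sites) - set(self.sites))
        if missing:
            raise ValidationError(f"sites missing from attribute table: {missing}")

    def factor(self, name: str) -> pd.Series:
        col = {"Order": "order", "log2Dlink": "dlink", "Dam": "dam"}.get(name, name)
        return self.table[col].astype(str)

    def coordinates(self) -> pd.DataFrame:
        return self.table[["x", "y"]].astype(float)


def read_site_attributes(path, delimiter: str | None = None) -> SiteAttributes:
    return SiteAttributes(read_table(path, delimiter))


# ---------------------------------------------------------------------------
# River network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """A point on a network edge; position in [0, 1] runs downstream."""

    edge: str
    position: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.position <= 1.0:
            raise ValidationError(f"position {self.position} outside [0, 1]")


class RiverNetwork:
    """Directed dendritic graph: every edge points downstream to a single outlet."""

    def __init__(self, graph: nx.DiGraph, dams: dict | None = None, sites: dict | None = None):
        if not nx.is_directed_acyclic_graph(graph):
            raise NetworkStructureError("edge list contains a cycle")
        if not nx.is_weakly_connected(graph):
            raise NetworkStructureError("network is not connected")
        outlets = [n for n in graph.nodes if graph.out_degree(n) == 0]
        if len(outlets) != 1:
            raise NetworkStructureError(f"expected exactly one outlet, found {sorted(outlets)}")
        multi = [n for n in graph.nodes if graph.out_degree(n) > 1]
        if multi:
            raise NetworkStructureError(f"node(s) with more than one downstream edge: {sorted(multi)}")
        self.graph = graph
        self.outlet = outlets[0]
        self._edge_by_id = {d["id"]: (u, v) for u, v, d in graph.edges(data=True)}
        if len(self._edge_by_id) != graph.number_of_edges():
            raise NetworkStructureError("duplicate edge identifiers")
        self.dams = dict(dams or {})
        self.sites = dict(sites or {})
        for name, pl in list(self.dams.items()) + list(self.sites.items()):
            if pl.edge not in self._edge_by_id:
                raise NetworkStructureError(f"{name!r} placed on unknown edge {pl.edge!r}")

    @property
    def edge_ids(self) -> list:
        return list(self._edge_by_id)

    def edge_endpoints(self, edge_id: str) -> tuple:
        return self._edge_by_id[edge_id]

    def edge_length(self, edge_id: str) -> float:
        u, v = self._edge_by_id[edge_id]
        return float(self.graph.edges[u, v].get("length", 1.0))

    def sources(self) -> list:
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    def downstream_edge_of(self, node) -> str | None:
        succ = list(self.graph.successors(node))
        if not succ:
            return None
        return self.graph.edges[node, succ[0]]["id"]

    def upstream_edges_of(self, node) -> list:
        return [self.graph.edges[p, node]["id"] for p in self.graph.predecessors(node)]

    def downstream_edge_chain(self, edge_id: str) -> list:
        """Edge ids from ``edge_id`` (inclusive) down to the outlet."""
        chain = [edge_id]
        _, v = self._edge_by_id[edge_id]
        while True:
            nxt = self.downstream_edge_of(v)
            if nxt is None:
                return chain
            chain.append(nxt)
            _, v = self._edge_by_id[nxt]

    def upstream_edge_set(self, edge_id: str) -> set:
        """All edges strictly upstream of ``edge_id`` (not including it)."""
        u, _ = self._edge_by_id[edge_id]
        seen: set = set()
        stack = [u]
        while stack:
            node = stack.pop()
            for eid in self.upstream_edges_of(node):
                if eid not in seen:
                    seen.add(eid)
                    stack.append(self._edge_by_id[eid][0])
        return seen

    def distance_to_outlet(self, placement: Placement) -> float:
        chain = self.downstream_edge_chain(placement.edge)
        dist = self.edge_length(placement.edge) * (1.0 - placement.position)
        for eid in chain[1:]:
            dist += self.edge_length(eid)
        return dist


def read_network(edge_path, dam_path=None, placement_path=None,
                 delimiter: str | None = None) -> RiverNetwork:
    """Assemble a RiverNetwork from edge / dam / site placement tables.

    Edge table columns: ``edge, from, to, length``; dam and placement tables:
    ``<id>, edge, position``.
    """
    edges = read_table(edge_path, delimiter, index_col=None)
    graph = nx.DiGraph()
    for _, row in edges.iterrows():
        graph.add_edge(str(row["from"]), str(row["to"]),
                       id=str(row["edge"]), length=float(row.get("length", 1.0)))
    dams, sites = {}, {}
    if dam_path is not None:
        for _, row in read_table(dam_path, delimiter, index_col=None).iterrows():
            dams[str(row.iloc[0])] = Placement(str(row["edge"]), float(row["position"]))
    if placement_path is not None:
        for _, row in read_table(placement_path, delimiter, index_col=None).iterrows():
            sites[canonical_name(row.iloc[0])] = Placement(str(row["edge"]), float(row["position"]))
    return RiverNetwork(graph, dams=dams, sites=sites)
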