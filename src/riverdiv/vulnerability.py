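"""Quantile-concordance congruence curves, leave-one-out species-removal
vulnerability, and distinctive-species identification.

Vulnerability is a jackknife: each species is removed once from the intact
community (the community is restored between removals) and the drop in each
facet's site-level index is recorded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alpha import faith_pd, rao_q, shannon
from .data import CommunityMatrix, Phylogeny, TraitTable
from .errors import ValidationError
from .traitspace import TraitSpace

logger = logging.getLogger("riverdiv")

__all__ = [
    "CongruenceCurve",
    "VulnerabilityResult",
    "DistinctivenessReport",
    "top_set",
    "congruence_curve",
    "leave_one_out",
    "species_contributions",
    "site_vulnerability",
    "distinctive_species",
]

DEFAULT_QUANTILES = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


def top_set(values: pd.Series, q: float) -> list:
    """The ceil(q*n) items with the highest values; boundary ties broken by
    stable identifier order (deterministic across runs)."""
    if not 0 < q <= 1:
        raise ValidationError(f"quantile fraction {q} outside (0, 1]")
    k = math.ceil(q * len(values))
    order = sorted(values.index, key=lambda it: (-values[it], str(it)))
    return order[:k]


@dataclass
class CongruenceCurve:
    facets: tuple
    mode: str
    quantiles: tuple
    overlap: pd.Series  # indexed by quantile fraction

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q": self.overlap.index, "overlap": self.overlap.values,
                             "facets": " vs ".join(self.facets), "mode": self.mode})


def congruence_curve(values_by_facet: dict, mode: str = "alpha-sites",
                     quantiles=DEFAULT_QUANTILES) -> CongruenceCurve:
    """Fraction of shared members among the facets' top-q sets, per q."""
    if len(values_by_facet) < 2:
        raise ValidationError("need at least 2 facets")
    series = {k: pd.Series(v) for k, v in values_by_facet.items()}
    items = None
    for name, s in series.items():
        if items is None:
            items = set(s.index)
        elif set(s.index) != items:
            raise ValidationError(f"facet {name!r} has a different item set")
    overlaps = {}
    for q in quantiles:
        tops = [set(top_set(s, q)) for s in series.values()]
        k = math.ceil(q * len(items))
        overlaps[q] = len(set.intersection(*tops)) / k
    return CongruenceCurve(tuple(series), mode, tuple(quantiles), pd.Series(overlaps))


# ---------------------------------------------------------------------------
# Leave-one-out vulnerability
# ---------------------------------------------------------------------------

FACET_INDEX = {"TD": "Shannon", "FD": "RaoQ", "PD": "PDfaith"}


@dataclass
class VulnerabilityResult:
    """Site x species delta grids per facet (NaN where the species is absent)."""

    deltas: dict  # facet -> DataFrame (sites x species)
    baseline: pd.DataFrame  # per-site index values of the intact community

    @property
    def facets(self) -> list:
        return list(self.deltas)

    def long_format(self) -> pd.DataFrame:
        frames = []
        for facet, grid in self.deltas.items():
            long = grid.stack().rename("delta").reset_index()
            long.columns = ["site", "species", "delta"]
            long.insert(2, "facet", facet)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)


def _site_indices(counts: np.ndarray, species: list, dist: np.ndarray,
                  tree: Phylogeny, include_root: bool) -> dict:
    present = counts > 0
    if not present.any():
        return {"TD": 0.0, "FD": 0.0, "PD": 0.0}
    a = counts[present]
    sp = [s for s, keep in zip(species, present) if keep]
    d = dist[np.ix_(present, present)]
    return {
        "TD": shannon(a),
        "FD": rao_q(a, d) if len(sp) > 1 else 0.0,
        "PD": faith_pd(sp, tree, include_root=include_root),
    }


def leave_one_out(community: CommunityMatrix, trait_space: TraitSpace, tree: Phylogeny,
                  facets=("TD", "FD", "PD"), include_root: bool = True,
                  scale_distances: bool = True) -> VulnerabilityResult:
    """Delta of each facet index at each site when one present species is
    removed (community restored between removals)."""
    tree.check_matches(community)
    missing = sorted(set(community.species) - set(trait_space.species))
    if missing:
        raise ValidationError(f"species missing from trait space: {missing}")
    species = community.species
    dist = trait_space.distance_matrix.loc[species, species].to_numpy(float)
    if scale_distances and dist.max() > 0:
        dist = dist / dist.max()

    grids = {f: pd.DataFrame(np.nan, index=community.sites, columns=species) for f in facets}
    baseline_rows = []
    for site in community.sites:
        counts = community.table.loc[site].to_numpy(float)
        base = _site_indices(counts, species, dist, tree, include_root)
        baseline_rows.append({"site": site, **{f: base[f] for f in facets}})
        for si, sp in enumerate(species):
            if counts[si] <= 0:
                continue
            reduced = counts.copy()
            reduced[si] = 0
            after = _site_indices(reduced, species, dist, tree, include_root)
            for f in facets:
                grids[f].loc[site, sp] = base[f] - after[f]
    baseline = pd.DataFrame(baseline_rows).set_index("site")
    return VulnerabilityResult(deltas=grids, baseline=baseline)


def species_contributions(result: VulnerabilityResult, q: float = 0.1) -> dict:
    """Mean delta over occupied sites per species, ranked, with per-facet
    top-decile sets and their union (check-mark layout)."""
    contrib = pd.DataFrame({f: g.mean(axis=0, skipna=True) for f, g in result.deltas.items()})
    tops = {f: top_set(contrib[f].fillna(-np.inf), q) for f in result.facets}
    union = sorted(set().union(*tops.values()))
    flags = pd.DataFrame(
        {f: [sp in tops[f] for sp in union] for f in result.facets}, index=union
    )
    return {"contributions": contrib, "top_sets": tops, "union": union, "flags": flags}


def site_vulnerability(result: VulnerabilityResult, q: float = 0.1,
                       dispersion_test: str = "fligner", alpha_level: float = 0.01) -> dict:
    """Per-site mean/variance of deltas per facet, top-decile vulnerable sites,
    and a cross-facet dispersion comparison of the pooled deltas."""
    summaries = {}
    for facet, grid in result.deltas.items():
        summaries[facet] = pd.DataFrame({
            "mean_delta": grid.mean(axis=1, skipna=True),
            "var_delta": grid.var(axis=1, skipna=True, ddof=1),
            "n_species": grid.notna().sum(axis=1),
        })
    tops = {f: top_set(summaries[f]["mean_delta"], q) for f in result.facets}

    pooled = {f: g.stack().dropna().to_numpy() for f, g in result.deltas.items()}
    test = stats.fligner if dispersion_test == "fligner" else stats.levene
    groups = [v for v in pooled.values() if len(v) > 1]
    if len(groups) >= 2 and all(np.ptp(g) > 0 for g in groups):
        stat, p = test(*groups)
    else:
        stat, p = 0.0, 1.0
    variances = {f: float(np.var(v, ddof=1)) if len(v) > 1 else 0.0 for f, v in pooled.items()}
    highest = max(variances, key=variances.get)
    return {
        "site_summaries": summaries,
        "top_sites": tops,
        "dispersion_statistic": float(stat),
        "dispersion_p": float(p),
        "dispersion_test": dispersion_test,
        "facet_variances": variances,
        "higher_variance_facet": highest if p < alpha_level else None,
    }


# ---------------------------------------------------------------------------
# Distinctive species
# ---------------------------------------------------------------------------


@dataclass
class DistinctivenessReport:
    species: pd.DataFrame      # flags per species
    occupancy: pd.Series       # per-site share of distinctive species
    distinctive: list = field(default_factory=list)


def distinctive_species(community: CommunityMatrix, traits: TraitTable,
                        metadata: pd.Series | None = None, q: float = 0.1,
                        restrict_to=None) -> DistinctivenessReport:
    """Flag species in the top/bottom q-quantile of any continuous (or ordinal)
    trait, or the top q-quantile of prevalence; report per-site occupancy.

    ``restrict_to`` limits the occupancy numerator to a given species subset
    (e.g. the top vulnerability contributors).
    """
    traits.check_covers(community)
    pool = community.species
    tab = traits.table.loc[pool]
    rows = []
    scan_cols = list(traits.schema.continuous) + [
        c for c in traits.schema.categorical if c in traits.schema.ordinal
    ]
    quantile_values = {}
    for col in scan_cols:
        x = (tab[col] if col in traits.schema.continuous
             else traits.ordinal_ranks(col).loc[pool]).astype(float)
        quantile_values[col] = (x, np.quantile(x, 1 - q), np.quantile(x, q))
    prevalence = community.prevalence()
    occ_top = set(top_set(prevalence, q))
    for sp in pool:
        high = [c for c, (x, hi, _) in quantile_values.items() if x[sp] >= hi]
        low = [c for c, (x, _, lo) in quantile_values.items() if x[sp] <= lo]
        rows.append({
            "species": sp,
            "trait_high": ";".join(high),
            "trait_low": ";".join(low),
            "occurrence_top": sp in occ_top,
            "distinctive": bool(high or low or sp in occ_top),
            "status": metadata.get(sp, "") if metadata is not None else "",
        })
    table = pd.DataFrame(rows).set_index("species")
    distinct = set(table.index[table["distinctive"]])
    if restrict_to is not None:
        distinct &= set(restrict_to)
    pa = community.presence_absence()
    occupancy = pd.Series({
        site: pa.loc[site, sorted(distinct)].sum() / pa.loc[site].sum() if distinct else 0.0
        for site in community.sites
    }, name="occupancy")
    return DistinctivenessReport(species=table, occupancy=occupancy,
                                 distinctive=sorted(distinct))
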