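"""End-to-end orchestration: config -> full analysis report bundle.

Sections mirror the result surface of the analysis: per-site alpha table,
beta matrices with summaries and component regressions, congruence curves,
spatial autocorrelation and factor-ANOVA tables, leave-one-out vulnerability
tables, and the distinctive-species report. Deterministic given the config.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import spatial as spatial_mod
from . import vulnerability as vuln_mod
from .data import (
    CommunityMatrix,
    Phylogeny,
    SiteAttributes,
    TraitTable,
    parse_config,
    read_community,
    read_network,
    read_site_attributes,
    read_traits,
    read_tree,
    write_table,
)
from .errors import ValidationError
from .simulate import ScenarioConfig, generate_bundle
from .traitspace import build_trait_space

logger = logging.getLogger("riverdiv")

__all__ = ["PipelineInputs", "run_pipeline", "write_report"]

DEFAULTS = {
    "n_axes": 5,
    "n_axes_fd": 4,
    "correction": "lingoes",
    "seed": 0,
    "n_perm": 9999,
    "weights_scheme": "inverse-distance",
    "include_root": True,
    "scale_distances": True,
    "q": 0.1,
    "alpha_level": 0.01,
}


@dataclass
class PipelineInputs:
    community: CommunityMatrix
    traits: TraitTable
    tree: Phylogeny
    site_attributes: SiteAttributes | None = None
    options: dict = field(default_factory=dict)


class _Stage:
    """Context manager that renames any stage failure after the stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, KeyboardInterrupt):
            raise ValidationError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        return False


def _load_inputs(config: dict) -> PipelineInputs:
    options = {k: _coerce(v) for k, v in config.items()}
    if "scenario" in config:
        scenario = ScenarioConfig(
            regime=config.get("scenario", "mixed"),
            seed=int(config.get("seed", 0)),
        )
        bundle = generate_bundle(scenario)
        return PipelineInputs(bundle.community, bundle.traits, bundle.tree,
                              bundle.site_attributes, options)
    community = read_community(config["community"],
                               config.get("orientation", "sites-as-rows"))
    traits = read_traits(config["traits"])
    tree = read_tree(config["tree"])
    attrs = None
    if "site_attributes" in config:
        attrs = read_site_attributes(config["site_attributes"])
    elif "network_edges" in config:
        network = read_network(config["network_edges"], config.get("network_dams"),
                               config.get("network_sites"))
        rows = {}
        orders = spatial_mod.strahler_orders(network)
        for site in community.sites:
            pl = network.sites[site]
            dl = spatial_mod.downstream_link(network, site)
            rows[site] = {
                "x": network.distance_to_outlet(pl), "y": 0.0,
                "order": orders[pl.edge], "dlink": dl["log2_category"],
                "dam": spatial_mod.dam_category(network, site),
            }
        attrs = SiteAttributes(pd.DataFrame(rows).T)
    return PipelineInputs(community, traits, tree, attrs, options)


def _coerce(value):
    if isinstance(value, str):
        low = value.lower()
        if low in ("true", "false"):
            return low == "true"
        for cast in (int, float):
            try:
                return cast(value)
            except ValueError:
                continue
    return value


def run_pipeline(config, outdir=None) -> dict:
    """Run the full analysis; ``config`` is a dict or a key=value file path."""
    if not isinstance(config, dict):
        config = parse_config(config)
    opts = {**DEFAULTS, **{k: _coerce(v) for k, v in config.items()}}
    report: dict = {"options": opts}

    with _Stage("load"):
        inputs = _load_inputs(config)
        community, traits, tree = inputs.community, inputs.traits, inputs.tree
        traits.check_covers(community)
        tree.check_matches(community)
        attrs = inputs.site_attributes

    with _Stage("trait_space"):
        space = build_trait_space(traits, n_axes=int(opts["n_axes"]),
                                  correction=opts["correction"])
        report["trait_space_cumulative_variance"] = space.cumulative_variance.tolist()

    with _Stage("alpha"):
        alpha = alpha_mod.alpha_table(
            community, space, tree,
            include_root=bool(opts["include_root"]),
            scale_distances=bool(opts["scale_distances"]),
        )
        alpha["prevalence_mean"] = float(community.prevalence().mean())
        report["alpha"] = alpha

    with _Stage("beta"):
        betas = {
            "TD": beta_mod.taxonomic_beta(community),
            "PD": beta_mod.phylogenetic_beta(community, tree,
                                            include_root=bool(opts["include_root"])),
            "FD": beta_mod.functional_beta(community, space,
                                           n_axes_fd=int(opts["n_axes_fd"]),
                                           seed=int(opts["seed"])),
        }
        report["beta"] = betas
        report["beta_summary"] = {f: beta_mod.beta_summary(m) for f, m in betas.items()}
        report["beta_regression"] = pd.concat(
            [beta_mod.beta_component_regression(m) for m in betas.values()],
            ignore_index=True,
        )

    with _Stage("congruence"):
        report["congruence"] = _congruence_section(alpha, betas)

    if attrs is not None:
        with _Stage("spatial"):
            report["spatial"] = _spatial_section(alpha, attrs, opts)

    with _Stage("vulnerability"):
        loo = vuln_mod.leave_one_out(
            community, space, tree,
            include_root=bool(opts["include_root"]),
            scale_distances=bool(opts["scale_distances"]),
        )
        q = float(opts["q"])
        contrib = vuln_mod.species_contributions(loo, q=q)
        site_vuln = vuln_mod.site_vulnerability(loo, q=q)
        distinct_all = vuln_mod.distinctive_species(community, traits, q=q)
        distinct_top = vuln_mod.distinctive_species(
            community, traits, q=q, restrict_to=contrib["union"]
        )
        report["vulnerability"] = {
            "result": loo,
            "species_contributions": contrib,
            "site_vulnerability": site_vuln,
            "distinctive_all": distinct_all,
            "distinctive_top_contributors": distinct_top,
        }

    if outdir is not None:
        with _Stage("write"):
            write_report(report, outdir)
    return report


def _congruence_section(alpha: pd.DataFrame, betas: dict) -> dict:
    curves = {}
    richness_vals = {"TD": alpha["Shannon"], "FD": alpha["RaoQ"], "PD": alpha["PDfaith"]}
    evenness_vals = {"TD": alpha["SEve"], "FD": alpha["FEve"], "PD": alpha["PSEve"]}
    for label, vals in (("alpha_richness", richness_vals), ("alpha_evenness", evenness_vals)):
        usable = {k: v.dropna() for k, v in vals.items()}
        common = set.intersection(*(set(v.index) for v in usable.values()))
        usable = {k: v.loc[sorted(common)] for k, v in usable.items()}
        curves[label] = {}
        for pair in (("TD", "FD"), ("TD", "PD"), ("FD", "PD"), ("TD", "FD", "PD")):
            curves[label][" vs ".join(pair)] = vuln_mod.congruence_curve(
                {f: usable[f] for f in pair}, mode="alpha-sites"
            )
    for which in ("sor", "sim", "nes"):
        vals = {f: betas[f].upper_triangle(which).dropna() for f in ("TD", "FD", "PD")}
        common = set.intersection(*(set(v.index) for v in vals.values()))
        vals = {f: v.loc[sorted(common)] for f, v in vals.items()}
        curves[f"beta_{which}"] = {}
        for pair in (("TD", "FD"), ("TD", "PD"), ("FD", "PD"), ("TD", "FD", "PD")):
            curves[f"beta_{which}"][" vs ".join(pair)] = vuln_mod.congruence_curve(
                {f: vals[f] for f in pair}, mode="beta-pairs"
            )
    return curves


def _spatial_section(alpha: pd.DataFrame, attrs: SiteAttributes, opts: dict) -> dict:
    attrs_aligned = SiteAttributes(attrs.table.loc[alpha.index])
    weights = spatial_mod.build_weights(attrs_aligned.coordinates(),
                                       scheme=opts["weights_scheme"])
    indices = ("Shannon", "RaoQ", "PDfaith")
    moran = {
        ix: spatial_mod.morans_i(alpha[ix].to_numpy(), weights, mode="normal")
        for ix in indices
    }
    lee = {}
    for i, ix in enumerate(indices):
        for iy in indices[i + 1:]:
            lee[f"{ix}~{iy}"] = spatial_mod.lees_l(
                alpha[ix].to_numpy(), alpha[iy].to_numpy(), weights,
                n_perm=int(opts["n_perm"]), seed=int(opts["seed"]),
            )
    anova = {}
    for ix in indices:
        for factor in ("Order", "log2Dlink", "Dam"):
            try:
                anova[f"{ix}~{factor}"] = spatial_mod.factor_anova(
                    alpha, attrs_aligned, ix, factor,
                    alpha_level=float(opts["alpha_level"]),
                )
            except ValidationError as exc:
                logger.warning("ANOVA %s on %s skipped: %s", ix, factor, exc)
    return {"weights": weights, "moran": moran, "lee": lee, "anova": anova}


def write_report(report: dict, outdir) -> None:
    """Emit the report bundle as delimited tables plus a plain-text summary."""
    os.makedirs(outdir, exist_ok=True)
    opts = report["options"]
    write_table(report["alpha"], os.path.join(outdir, "alpha.tsv"))
    for facet, m in report["beta"].items():
        for which in ("sor", "sim", "nes"):
            write_table(getattr(m, which),
                        os.path.join(outdir, f"beta_{facet}_{which}.tsv"))
    write_table(report["beta_regression"].set_index(["facet", "x", "y"]),
                os.path.join(outdir, "beta_regression.tsv"))

    curve_rows = []
    for section, curves in report["congruence"].items():
        for label, curve in curves.items():
            for q, v in curve.overlap.items():
                curve_rows.append({"section": section, "facets": label,
                                   "q": q, "overlap": v})
    write_table(pd.DataFrame(curve_rows).set_index(["section", "facets"]),
                os.path.join(outdir, "congruence.tsv"))

    vuln = report["vulnerability"]
    write_table(vuln["result"].long_format().set_index(["site", "species"]),
                os.path.join(outdir, "vulnerability_deltas.tsv"))
    write_table(vuln["species_contributions"]["contributions"],
                os.path.join(outdir, "species_contributions.tsv"))
    for facet, summary in vuln["site_vulnerability"]["site_summaries"].items():
        write_table(summary, os.path.join(outdir, f"site_vulnerability_{facet}.tsv"))
    write_table(vuln["distinctive_all"].species,
                os.path.join(outdir, "distinctive_species.tsv"))

    lines = [
        "analysis report",
        f"seed = {opts['seed']}",
        f"weights scheme = {opts['weights_scheme']}",
        f"axes retained = {opts['n_axes']} (FD beta axes = {opts['n_axes_fd']})",
        "",
    ]
    for facet, summ in report["beta_summary"].items():
        s = summ["sor"]
        lines.append(
            f"beta_sor {facet}: mean {s['mean']:.4f} +/- {s['sd']:.4f}, "
            f"range [{s['min']:.4f}, {s['max']:.4f}] "
            f"(min pair {s['argmin_pair']}, max pair {s['argmax_pair']})"
        )
    if "spatial" in report:
        lines.append("")
        for ix, res in report["spatial"]["moran"].items():
            lines.append(
                f"Moran's I {ix}: observed {res.statistic:.4f}, expected "
                f"{res.expected:.4f}, sd {res.sd:.4f}, p {res.p_value:.4f}"
            )
        for key, res in report["spatial"]["anova"].items():
            lines.append(f"ANOVA {key}: F {res.f_statistic:.3f}, p {res.p_value:.4g}, "
                         f"letters {res.level_letters}")
    disp = vuln["site_vulnerability"]
    lines.append("")
    lines.append(
        f"vulnerability dispersion ({disp['dispersion_test']}): statistic "
        f"{disp['dispersion_statistic']:.4f}, p {disp['dispersion_p']:.4g}, "
        f"higher-variance facet: {disp['higher_variance_facet']}"
    )
    with open(os.path.join(outdir, "summary.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
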