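"""End-to-end orchestration: rarefy -> diversity -> neutral -> core ->
network -> robustness, per habitat group, from one configuration.

The configuration is a flat INI file with one section per stage; every
default matches the standard protocol of this analysis family:
rarefaction to the (lower) median depth, 0.01% mean-relative-abundance
prevalence filter, |rho| > 0.6 and BH q < 0.01 edges, 999 permutations,
1000 bootstraps, removal proportions 10-100% with 50 repetitions.

Every run writes a manifest (parameters, seeds, input checksums,
package version) alongside the stage outputs, so identical manifests
imply identical outputs.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import core_taxa, diversity, network, neutral_model, robustness
from . import tables_io
from .tables_io import OtuTable

log = logging.getLogger("mareco")


@dataclass
class PipelineConfig:
    otu_path: str = ""
    metadata_path: str = ""
    taxonomy_path: str | None = None
    annotations_path: str | None = None
    tree_path: str | None = None
    out_dir: str = "mareco_out"
    seed: int = 0

    rarefaction_depth: str = "median"   # "median" or an integer
    filter_threshold: float = 1e-4
    filter_mode: str = "mean"

    rho_min: float = 0.6
    q_max: float = 0.01
    modularity_method: str = "louvain"

    detection_mode: str = "effective"
    n_boot: int = 1000

    core_threshold: float = 0.02

    n_perm: int = 999
    n_null: int = 999

    proportions: tuple[float, ...] = robustness.DEFAULT_PROPORTIONS
    repetitions: int = 50
    nc_scope: str = "all"

    @classmethod
    def from_ini(cls, path: str | Path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        cp.read(str(path))
        cfg = cls()
        get = cp.get

        def opt(section, key, cast=str, default=None):
            if cp.has_option(section, key):
                return cast(get(section, key))
            return default

        cfg.otu_path = opt("inputs", "otu", default=cfg.otu_path)
        cfg.metadata_path = opt("inputs", "metadata", default=cfg.metadata_path)
        cfg.taxonomy_path = opt("inputs", "taxonomy")
        cfg.annotations_path = opt("inputs", "annotations")
        cfg.tree_path = opt("inputs", "tree")
        cfg.out_dir = opt("run", "out_dir", default=cfg.out_dir)
        cfg.seed = opt("run", "seed", int, cfg.seed)
        cfg.rarefaction_depth = opt("rarefaction", "depth",
                                    default=cfg.rarefaction_depth)
        cfg.filter_threshold = opt("filter", "threshold", float,
                                   cfg.filter_threshold)
        cfg.filter_mode = opt("filter", "mode", default=cfg.filter_mode)
        cfg.rho_min = opt("network", "rho_min", float, cfg.rho_min)
        cfg.q_max = opt("network", "q_max", float, cfg.q_max)
        cfg.modularity_method = opt("network", "modularity",
                                    default=cfg.modularity_method)
        cfg.detection_mode = opt("neutral", "detection_mode",
                                 default=cfg.detection_mode)
        cfg.n_boot = opt("neutral", "n_boot", int, cfg.n_boot)
        cfg.core_threshold = opt("core", "threshold", float,
                                 cfg.core_threshold)
        cfg.n_perm = opt("diversity", "n_perm", int, cfg.n_perm)
        cfg.n_null = opt("diversity", "n_null", int, cfg.n_null)
        cfg.repetitions = opt("robustness", "repetitions", int,
                              cfg.repetitions)
        cfg.nc_scope = opt("robustness", "scope", default=cfg.nc_scope)
        if cp.has_option("robustness", "proportions"):
            cfg.proportions = tuple(
                float(x) for x in get("robustness", "proportions").split(","))
        return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label="id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.6g")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, table: OtuTable | None = None,
                 annotations: pd.Series | None = None,
                 taxonomy: pd.Series | None = None,
                 tree=None) -> dict:
    """Execute all stages and write artifacts under ``config.out_dir``.

    Inputs may be passed in memory (used by the simulation workflow and
    tests) or read from the paths in the config.  Returns the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}
    if table is None:
        table = tables_io.read_otu_table(config.otu_path,
                                         config.metadata_path)
        checksums["otu"] = _sha256(config.otu_path)
        checksums["metadata"] = _sha256(config.metadata_path)
    if annotations is None and config.annotations_path:
        annotations = tables_io.read_annotations(config.annotations_path)
        checksums["annotations"] = _sha256(config.annotations_path)
    if taxonomy is None and config.taxonomy_path:
        taxonomy = tables_io.read_taxonomy(config.taxonomy_path)
        checksums["taxonomy"] = _sha256(config.taxonomy_path)
    if tree is None and config.tree_path:
        tree = tables_io.read_tree(config.tree_path)
        checksums["tree"] = _sha256(config.tree_path)
    if annotations is None:
        warnings.warn("no SRB annotations supplied: SRB comparisons and "
                      "robustness experiments are skipped", stacklevel=2)

    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "input_checksums": checksums,
        "stages": {},
        "child_seeds": {},
    }
    master = np.random.SeedSequence(config.seed)
    seed_rarefy, seed_div, seed_neutral, seed_net, seed_rob = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in master.spawn(5)]
    manifest["child_seeds"] = {
        "rarefy": seed_rarefy, "diversity": seed_div,
        "neutral": seed_neutral, "network": seed_net,
        "robustness": seed_rob,
    }

    # --- stage: rarefaction -----------------------------------------------
    log.info("stage rarefy: %d taxa x %d samples", table.n_taxa,
             table.n_samples)
    depth = (tables_io.median_depth(table)
             if config.rarefaction_depth == "median"
             else int(config.rarefaction_depth))
    rare = tables_io.rarefy(table, depth, seed_rarefy)
    tables_io.write_otu_table(rare, out / "rarefied_otu_table.tsv")
    manifest["stages"]["rarefy"] = {
        "depth": depth, "n_samples": rare.n_samples, "n_taxa": rare.n_taxa}

    # --- stage: diversity --------------------------------------------------
    alpha = diversity.alpha_diversity_table(rare)
    _write_tsv(alpha, out / "alpha_diversity.tsv", "sample_id")
    div_summary: dict = {}
    groups = rare.groups
    if len(groups) >= 2:
        by_group = {g: alpha.loc[alpha["group"] == g, "shannon"].to_numpy()
                    for g in groups}
        g1, g2 = groups[:2]
        stat, p = diversity.wilcoxon_rank_sum(by_group[g1], by_group[g2])
        div_summary["shannon_wilcoxon"] = {"groups": [g1, g2],
                                           "statistic": stat, "p_value": p}
        dm = diversity.bray_curtis(rare)
        coords = diversity.pcoa(dm, k=2)
        _write_tsv(coords.coordinates, out / "pcoa_coordinates.tsv",
                   "sample_id")
        r_anosim, p_anosim = diversity.anosim(
            dm, rare.sample_group, n_perm=config.n_perm, seed=seed_div)
        div_summary["anosim"] = {"R": r_anosim, "p_value": p_anosim}
    if tree is not None:
        ses = diversity.ses_mntd(rare, tree, n_null=config.n_null,
                                 seed=seed_div)
        _write_tsv(ses.table, out / "ses_mntd.tsv", "sample_id")
        div_summary["ses_mntd_mean"] = {
            g: float(ses.table.loc[[s for s in rare.sample_ids
                                    if rare.sample_group[s] == g], "ses"]
                     .mean()) for g in groups}
    _write_json(div_summary, out / "diversity_summary.json")
    manifest["stages"]["diversity"] = div_summary

    # --- per-habitat stages -----------------------------------------------
    for group, sub in rare.per_group():
        gdir = out / group
        gdir.mkdir(exist_ok=True)
        sub = sub.drop_empty_taxa()
        view = tables_io.to_relative(sub)
        log.info("habitat %s: %d taxa x %d samples", group, sub.n_taxa,
                 sub.n_samples)

        # neutral model
        fit = neutral_model.fit_neutral_model(
            view, detection_mode=config.detection_mode)
        _write_tsv(fit.taxa, gdir / "neutral_fit.tsv", "taxon_id")
        summary = fit.summary()
        if config.n_boot:
            boot = neutral_model.bootstrap_aic(
                view, n_boot=config.n_boot, seed=seed_neutral,
                detection_mode=config.detection_mode)
            summary["bootstrap"] = {
                k: boot[k] for k in ("mean_aic_neutral", "mean_aic_binomial",
                                     "ci_aic_neutral", "ci_aic_binomial",
                                     "n_failures")}
        _write_json(summary, gdir / "neutral_summary.json")
        manifest["stages"].setdefault("neutral", {})[group] = {
            "m": fit.m, "r_squared": fit.r_squared, "ratio": fit.ratio}

        # core taxa
        sel = core_taxa.core_selection(sub, annotations,
                                       threshold=config.core_threshold)
        _write_tsv(sel.table(view), gdir / "core_taxa.tsv", "rank")
        _write_json(sel.summary, gdir / "core_summary.json")
        manifest["stages"].setdefault("core", {})[group] = sel.summary

        # co-occurrence network
        taxa = tables_io.abundance_filter(view, config.filter_threshold,
                                          mode=config.filter_mode)
        if len(taxa) < 2 or sub.n_samples < 4:
            warnings.warn(f"habitat {group}: too few taxa/samples for a "
                          "network; skipping", stacklevel=2)
            continue
        g = network.infer_network(sub, taxa, rho_min=config.rho_min,
                                  q_max=config.q_max,
                                  annotations=annotations,
                                  taxonomy=taxonomy)
        network.write_graphml(g, gdir / "network.graphml")
        _write_tsv(network.edge_table(g), gdir / "edges.tsv", "edge")
        topo = network.global_topology(g, seed=seed_net,
                                       method=config.modularity_method)
        nodes = network.node_topology(g)
        nodes["module"] = pd.Series(topo.modules)
        _write_tsv(nodes, gdir / "nodes.tsv", "taxon_id")
        _write_json(topo.as_dict(), gdir / "global_topology.json")
        manifest["stages"].setdefault("network", {})[group] = topo.as_dict()

        if annotations is not None:
            srb_nodes = [t for t in g.nodes if g.nodes[t].get("is_srb")]
            if srb_nodes and len(srb_nodes) < g.number_of_nodes():
                comp = network.compare_srb_topology(nodes)
                _write_tsv(comp, gdir / "srb_vs_other.tsv", "metric")
                traj = robustness.robustness_experiment(
                    g, srb_nodes, proportions=config.proportions,
                    repetitions=config.repetitions, seed=seed_rob,
                    scope=config.nc_scope)
                _write_tsv(traj, gdir / "robustness.tsv", "record")
                summ = robustness.summarize_trajectory(traj)
                _write_json({"slopes": summ["slopes"]},
                            gdir / "robustness_summary.json")
                manifest["stages"].setdefault("robustness", {})[group] = \
                    summ["slopes"]
            else:
                warnings.warn(f"habitat {group}: no (or only) SRB nodes in "
                              "the network; robustness skipped",
                              stacklevel=2)

    _write_json(manifest, out / "manifest.json")
    return manifest
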