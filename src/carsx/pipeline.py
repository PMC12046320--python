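"""End-to-end pipeline driver over synthetic (or user-supplied) cohorts.

Runs the full chain: simulate (optional) -> per-species DE -> ortholog merge
-> anchor selection + overlap test -> joint PCA score + ROC -> Stouffer
ranking -> regulon-population network inference -> activity -> DA -> hidden
drivers -> signed-regulon GSEA; writes every stage artifact plus a JSON
summary. Fully seeded: each stage draws from a seed derived from the root
seed by a fixed offset, and the summary records all thresholds and seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .containers import ExpressionMatrix
from .diffexpr import moderated_two_group
from .enrich import signed_regulon_gsea
from .network import (compute_activity, differential_activity, hidden_drivers,
                      infer_network)
from .simulate import (SimConfig, group_series, simulate_cross_species_cohort,
                       simulate_regulon_population)
from .xspecies import (joint_pca_score, merge_orthologs, overlap_test,
                       roc_auc, select_anchors, stouffer_rank)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds, and seeds for one pipeline run.

    When the expression paths are ``None`` the corresponding inputs are
    simulated with :class:`carsx.simulate.SimConfig` defaults at the given
    seed.
    """

    out_dir: str = "carsx_out"
    expr_human: str | None = None
    expr_mouse: str | None = None
    groups_human: str | None = None
    groups_mouse: str | None = None
    expr_population: str | None = None
    groups_population: str | None = None
    drivers: str | None = None
    orthologs: str | None = None
    case: str = "responder"
    control: str = "nonresponder"
    z_thresh: float = 1.96
    n_bootstraps: int = 50
    consensus_p: float = 0.01
    dpi_tolerance: float = 0.0
    z_da: float = 1.96
    z_de: float = 0.0
    n_perm: int = 1000
    seed: int = 0
    sim_cross: dict = field(default_factory=dict)
    sim_regulon: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.z_thresh < np.inf and self.z_thresh != np.inf:
            raise ValueError(f"z_thresh out of range: {self.z_thresh}")
        for p in (self.expr_human, self.expr_mouse, self.expr_population,
                  self.groups_human, self.groups_mouse, self.groups_population,
                  self.drivers, self.orthologs):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis chain; returns the JSON-able summary report."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in asdict(cfg).items()},
                    "stages": {}}

    def _stage(name):
        logger.info("pipeline stage: %s", name)
        return report["stages"].setdefault(name, {})

    # ----- inputs ---------------------------------------------------------
    st = _stage("inputs")
    if cfg.expr_human and cfg.expr_mouse:
        expr_h = cio.read_expression(cfg.expr_human, species="human")
        expr_m = cio.read_expression(cfg.expr_mouse, species="mouse")
        groups_h = cio.read_annotation(cfg.groups_human)
        groups_m = cio.read_annotation(cfg.groups_mouse)
        st["source"] = "files"
    else:
        sim_cfg = SimConfig.cross_species_defaults(seed=cfg.seed,
                                                   **cfg.sim_cross)
        expr_h, expr_m, truth = simulate_cross_species_cohort(sim_cfg)
        groups_h = group_series(truth, expr_h.samples)
        groups_m = group_series(truth, expr_m.samples)
        cio.write_expression(expr_h, out / "expr_human.tsv")
        cio.write_expression(expr_m, out / "expr_mouse.tsv")
        cio.write_annotation(truth.group_labels, out / "groups.tsv")
        truth.to_json(out / "truth_cross_species.json")
        st["source"] = "simulated"
        st["planted_driver"] = truth.driver_gene
        st["sim_seed"] = sim_cfg.seed

    # ----- per-species DE -------------------------------------------------
    st = _stage("de")
    de_h = moderated_two_group(expr_h, groups_h, cfg.case, cfg.control)
    de_m = moderated_two_group(expr_m, groups_m, cfg.case, cfg.control)
    cio.write_de_table(de_h, out / "de_human.tsv")
    cio.write_de_table(de_m, out / "de_mouse.tsv")
    st["n_genes_human"] = len(de_h)
    st["n_genes_mouse"] = len(de_m)

    # ----- integration ----------------------------------------------------
    st = _stage("integrate")
    ortho = pd.read_csv(cfg.orthologs, sep="\t") if cfg.orthologs else None
    merged = merge_orthologs(de_h, de_m, ortho)
    sig = select_anchors(merged, cfg.z_thresh)
    st["universe"] = sig.universe_size
    st["n_anchor_human"] = len(sig.equalized.get("human", []))
    st["n_anchor_mouse"] = len(sig.equalized.get("mouse", []))
    st["n_anchors_shared"] = len(sig)
    if len(sig) == 0:
        logger.warning("empty anchor set; stopping after integration")
        report["status"] = "empty_anchor_set"
        _write_report(report, out)
        return report
    sig.anchors.to_csv(out / "anchors.tsv", sep="\t")
    n_eq = len(sig.equalized["human"])
    k, p_overlap = overlap_test(sig.equalized["human"], sig.equalized["mouse"],
                                sig.universe_size)
    st["overlap"] = {"n_human": n_eq, "n_mouse": n_eq, "overlap": k,
                     "p": p_overlap}
    (out / "overlap.json").write_text(json.dumps(_jsonable(st["overlap"])))

    scores = joint_pca_score(expr_h, expr_m, sig)
    cio.write_ranking(scores, out / "scores.tsv")
    labels = pd.concat([
        (groups_h.loc[expr_h.samples] == cfg.case).astype(int),
        (groups_m.loc[expr_m.samples] == cfg.case).astype(int)])
    # orient so that the case group scores high, then evaluate
    if scores[labels.values == 1].mean() < scores[labels.values == 0].mean():
        scores = -scores
    roc = roc_auc(scores, labels.values, seed=cfg.seed)
    st["roc"] = roc.to_dict()
    (out / "roc.json").write_text(json.dumps(_jsonable(roc.to_dict())))

    ranking = stouffer_rank(merged)
    cio.write_de_table(ranking, out / "ranking.tsv")
    st["top10_combined"] = ranking.head(10).index.tolist()

    # ----- regulon population / network -----------------------------------
    st = _stage("network")
    if cfg.expr_population:
        expr_ref = expr_pop = cio.read_expression(cfg.expr_population)
        groups_pop = cio.read_annotation(cfg.groups_population)
        if cfg.drivers:
            drivers = Path(cfg.drivers).read_text().split()
        else:  # fall back to top-ranked genes present in the population
            pop_upper = {str(g).upper(): g for g in expr_pop.genes}
            drivers = [pop_upper[str(g).upper()] for g in ranking.index
                       if str(g).upper() in pop_upper][:5]
        if not drivers:
            raise ValueError("no candidate drivers found in the population "
                             "matrix; provide a drivers list")
        truth_pop = None
    else:
        # Reference population (no group effect, driver mRNA tracking its
        # activity) for interactome inference; comparison cohort with the
        # planted hidden driver (activity up, mRNA slightly down) for DA/DE.
        ref_cfg = SimConfig.regulon_defaults(
            seed=cfg.seed + 1, structure_seed=cfg.seed + 1,
            driver_effect=0.0, **cfg.sim_regulon)
        expr_ref, _ = simulate_regulon_population(ref_cfg)
        cio.write_expression(expr_ref, out / "expr_reference.tsv")
        sim_cfg = SimConfig.regulon_defaults(
            seed=cfg.seed + 4, structure_seed=cfg.seed + 1,
            driver_mrna_coupled=False, driver_mrna_shift=-0.3,
            **cfg.sim_regulon)
        expr_pop, truth_pop = simulate_regulon_population(sim_cfg)
        groups_pop = group_series(truth_pop, expr_pop.samples)
        cio.write_expression(expr_pop, out / "expr_population.tsv")
        cio.write_annotation(truth_pop.group_labels,
                             out / "groups_population.tsv")
        truth_pop.to_json(out / "truth_population.json")
        drivers = sorted(truth_pop.driver_regulons)
        st["planted_driver"] = truth_pop.driver_gene
    net = infer_network(expr_ref, drivers, n_bootstraps=cfg.n_bootstraps,
                        consensus_p=cfg.consensus_p,
                        dpi_tolerance=cfg.dpi_tolerance, seed=cfg.seed + 2)
    cio.write_network(net, out / "network.tsv")
    cio.regulons_to_gmt(net, out / "regulons.gmt")
    st["n_nodes"] = net.n_nodes
    st["n_edges"] = net.n_edges

    # ----- activity / DA / hidden drivers ---------------------------------
    st = _stage("drivers")
    activity = compute_activity(expr_pop, net)
    cio.write_expression(activity, out / "activity.tsv")
    da = differential_activity(activity, groups_pop, cfg.case, cfg.control)
    de_pop = moderated_two_group(expr_pop, groups_pop, cfg.case, cfg.control)
    cio.write_de_table(da, out / "da.tsv")
    hidden = hidden_drivers(da, de_pop.loc[da.index.intersection(de_pop.index)],
                            z_da_thresh=cfg.z_da, z_de_max=cfg.z_de)
    cio.write_de_table(hidden, out / "hidden_drivers.tsv")
    st["top10_hidden"] = hidden.head(10).index.tolist()
    st["n_hidden"] = len(hidden)

    # ----- GSEA of the top driver regulon ----------------------------------
    st = _stage("gsea")
    top_driver = (hidden.index[0] if len(hidden)
                  else da["z"].abs().idxmax())
    ranking_pop = de_pop["z"]
    res_pos, res_neg = signed_regulon_gsea(
        ranking_pop, net.regulons[top_driver], n_perm=cfg.n_perm,
        seed=cfg.seed + 3)
    st["driver"] = top_driver
    st["positive_targets"] = res_pos.to_dict() if res_pos else None
    st["negative_targets"] = res_neg.to_dict() if res_neg else None

    report["status"] = "ok"
    report["thresholds"] = {"z_thresh": cfg.z_thresh, "z_da": cfg.z_da,
                            "z_de": cfg.z_de, "consensus_p": cfg.consensus_p,
                            "dpi_tolerance": cfg.dpi_tolerance}
    report["seeds"] = {"root": cfg.seed, "simulate_cross": cfg.seed,
                       "simulate_regulon": cfg.seed + 1,
                       "network": cfg.seed + 2, "gsea": cfg.seed + 3}
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "summary.json").write_text(
        json.dumps(_jsonable(report), indent=1, sort_keys=True))
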