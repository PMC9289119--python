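"""End-to-end orchestration: simulate/load -> densities -> SSI -> traits
-> consensus/VCV -> single-predictor models -> dredge/average -> stability.

Every stage writes its artifact under the output directory, so any stage
can be re-run from the saved intermediates; all randomness flows from one
seed through named substreams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import density, pgls, phylo, ssi as ssi_mod, synth, traits as traits_mod
from .habitats import (
    AGGREGATED_CLASSES,
    FIELD_CLASSES,
    FIELD_TO_AGGREGATED,
    HABITAT_PREFERENCE_CLASSES,
    IDENTITY_AGGREGATION,
    PREFERENCE_TO_AGGREGATED,
)

logger = logging.getLogger(__name__)

FULL_MODEL_TERMS = ["nest_type", "ssi_habitat", "ssi_diet", "breeding_range"]
NEST_BLOCK = pgls.Term("nest_type", ("nest_GC", "nest_H", "nest_OA"))


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one of ``sim`` (generate data) or ``inputs`` (paths to
    counts/habitat/prefs/traits/trees files) must be set.
    """

    outdir: str = "results/run"
    seed: int = 0
    sim: synth.SimConfig | None = None
    inputs: dict[str, str] | None = None
    density_mode: str = "presence"
    log_response: bool = False
    consensus_threshold: float = 0.5
    delta_cut: float = 2.0
    method: str = "ML"
    stability_trees: int | None = None
    include_forest_dependency: bool = False

    def __post_init__(self):
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("set exactly one of sim / inputs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("sim", None)
        if sim is not None:
            if "habitat_classes" in sim:
                sim["habitat_classes"] = tuple(sim["habitat_classes"])
            sim = synth.SimConfig(**sim)
        return cls(sim=sim, **raw)


def infer_aggregation(columns: list[str], kind: str) -> dict[str, str]:
    """Pick the aggregation map matching a table's habitat columns."""
    cols = set(columns)
    if cols <= set(AGGREGATED_CLASSES):
        return IDENTITY_AGGREGATION
    if kind == "composition" and cols <= set(FIELD_CLASSES):
        return FIELD_TO_AGGREGATED
    if kind == "preference" and cols <= set(HABITAT_PREFERENCE_CLASSES):
        return PREFERENCE_TO_AGGREGATED
    raise ValueError(
        f"cannot infer an aggregation map for {kind} columns {sorted(cols)}"
    )


def _load_inputs(inputs: dict[str, str]):
    counts = pd.read_csv(inputs["counts"])
    habitat = pd.read_csv(inputs["habitat"], index_col=0)
    transect = habitat.pop("transect") if "transect" in habitat.columns else None
    prefs_habitat = pd.read_csv(inputs["prefs_habitat"], index_col=0)
    prefs_diet = pd.read_csv(inputs["prefs_diet"], index_col=0)
    traits = pd.read_csv(inputs["traits"], index_col=0)
    trees = phylo.read_trees(inputs["trees"])
    agg_map = (
        yaml.safe_load(open(inputs["aggregation"]))
        if "aggregation" in inputs
        else infer_aggregation(list(prefs_habitat.columns), "preference")
    )
    comp_map = infer_aggregation(list(habitat.columns), "composition")
    if comp_map is not IDENTITY_AGGREGATION:
        habitat = density.aggregate_habitats(habitat, comp_map)
    return counts, habitat, transect, prefs_habitat, prefs_diet, traits, trees, agg_map


def run_all(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the JSON-serializable run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "warnings": [], "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return report["stages"].setdefault(name, {})

    # -- data ---------------------------------------------------------------
    if cfg.sim is not None:
        info = stage("simulate")
        sim_cfg = synth.SimConfig(**{**vars(cfg.sim), "seed": cfg.seed})
        sim = synth.simulate(sim_cfg)
        synth.write_outputs(sim, outdir / "sim")
        counts = sim.counts
        habitat = sim.landscape.composition
        prefs_habitat, prefs_diet = sim.truth.niche, sim.truth.diet
        traits = sim.truth.traits
        trees = sim.trees.all_trees()
        agg_map = {c: c for c in sim_cfg.habitat_classes}
        info["n_points"] = sim_cfg.n_points
        info["n_species"] = sim_cfg.n_species
        info["n_trees"] = len(trees)
    else:
        info = stage("load")
        (counts, habitat, _transect, prefs_habitat, prefs_diet,
         traits, trees, agg_map) = _load_inputs(cfg.inputs)
        info["n_points"] = habitat.shape[0]
        info["n_species"] = prefs_habitat.shape[0]
        info["n_trees"] = len(trees)

    # -- densities ----------------------------------------------------------
    info = stage("densities")
    dens = density.density_table(
        counts, habitat, prefs_habitat, agg_map, mode=cfg.density_mode
    )
    dens.to_csv(outdir / "densities.csv")
    info["n_species_with_density"] = int(dens.shape[0])
    dropped = sorted(set(prefs_habitat.index) - set(dens.index))
    if dropped:
        report["warnings"].append(
            f"{len(dropped)} species never recorded; excluded from models"
        )
    n_flagged = int((dens["flags"] != "").sum())
    if n_flagged:
        report["warnings"].append(
            f"{n_flagged} species recorded at zero-suitable-habitat points"
        )

    # -- specialization ------------------------------------------------------
    info = stage("ssi")
    ssi_tab = ssi_mod.ssi_table(prefs_habitat, "habitat").join(
        ssi_mod.ssi_table(prefs_diet, "diet")
    )
    ssi_tab.to_csv(outdir / "ssi.csv")
    info["n_species"] = int(ssi_tab.shape[0])

    # -- traits --------------------------------------------------------------
    info = stage("traits")
    traits = traits_mod.sex_average(
        traits, traits_mod.MORPHOLOGY_TRAITS + ["body_mass"]
    )
    ss_pc = traits_mod.pca_reduce(traits[traits_mod.MORPHOLOGY_TRAITS])
    sf_pc = traits_mod.pca_reduce(traits[traits_mod.REPRODUCTIVE_TRAITS])
    predictors, corrs = traits_mod.prepare_predictors(
        traits, ssi_tab, ss_pc, sf_pc,
        include_forest_dependency=cfg.include_forest_dependency,
    )
    predictors.to_csv(outdir / "predictors.csv")
    with open(outdir / "pca_report.json", "w") as fh:
        json.dump(
            {
                "ssPC": {
                    "variance_explained_pc1": ss_pc.variance_explained_pc1,
                    "loadings": ss_pc.loadings.round(6).to_dict(),
                },
                "sfPC": {
                    "variance_explained_pc1": sf_pc.variance_explained_pc1,
                    "loadings": sf_pc.loadings.round(6).to_dict(),
                },
                "correlations": corrs,
            },
            fh, indent=1,
        )
    info["correlations"] = corrs
    info["ssPC_variance_explained"] = ss_pc.variance_explained_pc1
    info["sfPC_variance_explained"] = sf_pc.variance_explained_pc1

    # -- model frame ---------------------------------------------------------
    data = predictors.join(dens[["geo_density", "eco_density"]], how="inner")
    data = data.dropna()
    if cfg.log_response:
        data["geo_density"] = np.log(data["geo_density"])
        data["eco_density"] = np.log(data["eco_density"])
    data = data.sort_index()
    stage("model_frame")["n_species"] = int(data.shape[0])

    # -- phylogeny -----------------------------------------------------------
    info = stage("phylogeny")
    consensus = phylo.consensus_tree(trees, threshold=cfg.consensus_threshold)
    with open(outdir / "consensus.nwk", "w") as fh:
        fh.write(consensus.as_string(schema="newick", suppress_rooting=True))
    V = phylo.brownian_vcv(consensus, list(data.index))
    V.to_csv(outdir / "vcv.csv")
    info["n_tips"] = len(phylo.tip_labels(consensus))

    # -- single-predictor models (table 1) ------------------------------------
    info = stage("single_predictor")
    table1 = pgls.single_predictor_suite(data, V, method=cfg.method)
    table1.to_csv(outdir / "table1.csv", index=False)
    info["n_models"] = int(table1[["response", "predictor"]].drop_duplicates().shape[0])

    # -- dredging + averaging (table 2) ---------------------------------------
    info = stage("dredge")
    table2_rows = []
    headline = {}
    for response in ("geo_density", "eco_density"):
        for pc in ("ssPC", "sfPC"):
            terms = (NEST_BLOCK, pgls.Term.single(pc),
                     pgls.Term.single("ssi_habitat"),
                     pgls.Term.single("ssi_diet"),
                     pgls.Term.single("breeding_range"))
            spec = pgls.ModelSpec(response=response, terms=terms)
            fits = pgls.dredge(spec, data, V, method=cfg.method)
            avg = pgls.select_and_average(fits, delta_cut=cfg.delta_cut)
            avg.models.to_csv(
                outdir / f"dredge_{response}_{pc}.csv", index=False
            )
            block = avg.coef.reset_index()
            block.insert(0, "pc_axis", pc)
            block.insert(0, "response", response)
            table2_rows.append(block)
            key = f"{response}_{pc}"
            headline[key] = {
                "ssi_habitat": float(avg.coef.loc["ssi_habitat", "estimate"]),
                "n_retained": int(avg.models["retained"].sum()),
            }
    table2 = pd.concat(table2_rows, ignore_index=True)
    table2.to_csv(outdir / "table2.csv", index=False)
    info["averaged_models"] = headline
    report["headline_signs"] = {
        k: ("positive" if v["ssi_habitat"] > 0 else "negative")
        for k, v in headline.items()
    }

    # -- robustness over the tree sample --------------------------------------
    if len(trees) > 1:
        info = stage("stability")
        sample = trees[1:]
        if cfg.stability_trees is not None:
            sample = sample[: cfg.stability_trees]
        spec = pgls.ModelSpec(
            response="eco_density",
            terms=(NEST_BLOCK, pgls.Term.single("ssPC"),
                   pgls.Term.single("ssi_habitat"),
                   pgls.Term.single("ssi_diet"),
                   pgls.Term.single("breeding_range")),
        )
        stability = pgls.dredge_over_trees(
            spec, data, sample, delta_cut=cfg.delta_cut,
            consensus=V, method=cfg.method,
        )
        stability.to_csv(outdir / "stability.csv")
        info["n_trees"] = len(sample)
        info["ssi_habitat_sign_agreement"] = float(
            stability.loc["ssi_habitat", "sign_agreement"]
        )

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
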