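import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ecodensity import density, pgls, phylo, ssi as ssi_mod, synth, traits as traits_mod

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_sim():
    """A compact synthetic census shared by read-only tests."""
    cfg = synth.SimConfig(n_points=200, n_species=30, n_trees=5, seed=42)
    return synth.simulate(cfg)


def random_census(rng, n_points=6, n_species=4, n_classes=3):
    """A tiny random census table with matching preference vectors."""
    classes = [f"c{i}" for i in range(n_classes)]
    species = [f"s{i}" for i in range(n_species)]
    points = [f"p{i}" for i in range(n_points)]
    comp = rng.dirichlet(np.ones(n_classes), size=n_points)
    composition = pd.DataFrame(comp, index=pd.Index(points, name="point"), columns=classes)
    prefs = pd.DataFrame(0, index=pd.Index(species, name="species"), columns=classes)
    for i in range(n_species):
        h = rng.integers(1, n_classes + 1)
        prefs.iloc[i, rng.choice(n_classes, size=h, replace=False)] = 1
    rows = []
    for p in points:
        for v in (1, 2):
            for s in species:
                c = int(rng.poisson(1.0))
                if c:
                    rows.append({"point": p, "visit": v, "species": s, "count": c})
    counts = pd.DataFrame(rows, columns=["point", "visit", "species", "count"])
    agg = {c: c for c in classes}
    return counts, composition, prefs, agg


def headline_replicate(seed, gamma, with_dredge=True, mode="presence"):
    """One generator -> densities -> traits -> PGLS replicate.

    Returns the averaged SSI-habitat coefficients for both density
    responses (when dredging) and the single-predictor SSI-habitat fit on
    ecological density.
    """
    cfg = synth.SimConfig(ssi_effect=gamma, n_trees=0, seed=seed)
    sim = synth.simulate(cfg)
    agg = {c: c for c in cfg.habitat_classes}
    dens = density.density_table(
        sim.counts, sim.landscape.composition, sim.truth.niche, agg, mode=mode
    )
    ssi_tab = ssi_mod.ssi_table(sim.truth.niche, "habitat").join(
        ssi_mod.ssi_table(sim.truth.diet, "diet")
    )
    ss_pc = traits_mod.pca_reduce(sim.truth.traits[traits_mod.MORPHOLOGY_TRAITS])
    sf_pc = traits_mod.pca_reduce(sim.truth.traits[traits_mod.REPRODUCTIVE_TRAITS])
    pred, _ = traits_mod.prepare_predictors(sim.truth.traits, ssi_tab, ss_pc, sf_pc)
    data = pred.join(dens[["geo_density", "eco_density"]], how="inner")
    data = data.dropna().sort_index()
    V = phylo.brownian_vcv(sim.trees.base, list(data.index))
    out = {}
    if with_dredge:
        for resp in ("eco_density", "geo_density"):
            spec = pgls.ModelSpec(
                resp,
                (
                    pgls.Term("nest_type", ("nest_GC", "nest_H", "nest_OA")),
                    pgls.Term.single("ssPC"),
                    pgls.Term.single("ssi_habitat"),
                    pgls.Term.single("ssi_diet"),
                    pgls.Term.single("breeding_range"),
                ),
            )
            avg = pgls.select_and_average(pgls.dredge(spec, data, V))
            out[resp] = float(avg.coef.loc["ssi_habitat", "estimate"])
    fit = pgls.fit_pgls(
        pgls.ModelSpec("eco_density", (pgls.Term.single("ssi_habitat"),)), data, V
    )
    out["single_p"] = float(fit.pvalues["ssi_habitat"])
    out["single_slope"] = float(fit.params["ssi_habitat"])
    return out
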