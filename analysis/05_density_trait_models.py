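#!/usr/bin/env python
"""Phylogenetic regressions of density on traits and specialization.

First the single-predictor suite (body mass, SSI habitat, SSI diet, each
against geographical and ecological density), then AIC dredging of the
full models (nest type + PC axis + SSI habitat + SSI diet + breeding
range, with ssPC and sfPC in separate sets) and full-model averaging over
the delta-AIC < 2 set.  Writes results/table1.csv, results/table2.csv and
the per-model results/dredge_*.csv tables.
"""

from pathlib import Path

import pandas as pd

from ecodensity import pgls

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"

NEST_BLOCK = pgls.Term("nest_type", ("nest_GC", "nest_H", "nest_OA"))


def model_frame():
    dens = pd.read_csv(RES / "densities.csv", index_col=0)
    pred = pd.read_csv(RES / "predictors.csv", index_col=0)
    data = pred.join(dens[["geo_density", "eco_density"]], how="inner")
    return data.dropna().sort_index()


def main() -> None:
    data = model_frame()
    V = pd.read_csv(RES / "vcv.csv", index_col=0).loc[data.index, data.index]
    print(f"model frame: {data.shape[0]} species")

    table1 = pgls.single_predictor_suite(data, V)
    table1.to_csv(RES / "table1.csv", index=False)
    slopes = table1[table1["coefficient"] != "(Intercept)"]
    print("\nsingle-predictor models (slope, p):")
    for _, r in slopes.iterrows():
        print(f"  {r['response']:<12} ~ {r['predictor']:<14} "
              f"{r['estimate']:+.4f}  p = {r['p_value']:.3g}")

    rows = []
    for response in ("geo_density", "eco_density"):
        for pc in ("ssPC", "sfPC"):
            terms = (NEST_BLOCK, pgls.Term.single(pc),
                     pgls.Term.single("ssi_habitat"),
                     pgls.Term.single("ssi_diet"),
                     pgls.Term.single("breeding_range"))
            fits = pgls.dredge(pgls.ModelSpec(response, terms), data, V)
            avg = pgls.select_and_average(fits, delta_cut=2.0)
            avg.models.to_csv(RES / f"dredge_{response}_{pc}.csv", index=False)
            block = avg.coef.reset_index()
            block.insert(0, "pc_axis", pc)
            block.insert(0, "response", response)
            rows.append(block)
            n_kept = int(avg.models["retained"].sum())
            est = avg.coef.loc["ssi_habitat", "estimate"]
            p = avg.coef.loc["ssi_habitat", "p_value"]
            print(f"\n{response} / {pc}: {len(fits)} models dredged, "
                  f"{n_kept} retained (delta AIC < 2)")
            print(f"  averaged SSI-habitat coefficient {est:+.4f}  p = {p:.3g}")
    pd.concat(rows, ignore_index=True).to_csv(RES / "table2.csv", index=False)


if __name__ == "__main__":
    main()
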