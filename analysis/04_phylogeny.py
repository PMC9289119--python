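#!/usr/bin/env python
"""Consensus tree and Brownian variance-covariance matrix.

Builds the 50% majority-rule consensus (mean branch lengths) of the tree
sample and the Brownian VCV over the species that enter the models (those
with densities and predictors).  Writes results/consensus.nwk and
results/vcv.csv.
"""

from pathlib import Path

import pandas as pd

from ecodensity import phylo

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"


def main() -> None:
    trees = phylo.read_trees(RES / "sim" / "trees.nwk")
    consensus = phylo.consensus_tree(trees, threshold=0.5)
    (RES / "consensus.nwk").write_text(
        consensus.as_string(schema="newick", suppress_rooting=True)
    )

    dens = pd.read_csv(RES / "densities.csv", index_col=0)
    pred = pd.read_csv(RES / "predictors.csv", index_col=0)
    species = sorted(set(dens.index) & set(pred.dropna().index))
    V = phylo.brownian_vcv(consensus, species)
    V.to_csv(RES / "vcv.csv")
    print(f"consensus of {len(trees)} trees "
          f"({len(phylo.tip_labels(consensus))} tips); "
          f"VCV over {len(species)} model species")
    print(f"root-to-tip depth range on the consensus: "
          f"{V.to_numpy().diagonal().min():.3f}-{V.to_numpy().diagonal().max():.3f}")


if __name__ == "__main__":
    main()
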