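#!/usr/bin/env python
"""Generate the synthetic museum study all later steps analyse.

Simulates a 200-species phylogeny (unit depth), evolves the 3-state plumage
character (monochromic / dichromic / FLP) under the equal-rates Markov model
at rate 0.9, and writes the specimen score table (30 females + 10 males per
species; androchrome frequency 0.3 within FLP species), the 17-patch color
and morphometric panel for 16 FLP species (with one planted negative and
one planted positive bill-length slope), and the species covariate table
with a planted negative migration association.

Outputs under results/study/: tree.nwk, specimens.csv, colors.csv,
morphometrics.csv, covariates.csv, true_states.csv.
"""

from pathlib import Path

import pandas as pd

from flpscape import mk, synthdata, trees
from flpscape.synthdata import SimulationSpec

SEED = 20240915
OUT = Path(__file__).resolve().parent.parent / "results" / "study"

PLANTED_SLOPES = {"negative": -2.5, "positive": 1.7}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SimulationSpec(n_species=200, n_females=30, seed=SEED,
                          covariate_effects={"migratory": -2.0})
    tree = spec.simulate_tree()
    tip_states, node_states = synthdata.simulate_mk_tips(
        tree, spec.q_matrix, mk.UNIFORM_PRIOR, seed=SEED)
    species = trees.tip_labels(tree)
    flp_species = [sp for sp in species if tip_states[sp] == "FLP"]

    freq = {sp: (spec.androchrome_freq if sp in flp_species else 0.0)
            for sp in species}
    specimens = synthdata.simulate_specimen_scores(
        spec, seed=SEED, species=species, freq_by_species=freq)

    panel = flp_species[:16]
    slopes = {panel[0]: PLANTED_SLOPES["negative"],
              panel[1]: PLANTED_SLOPES["positive"]}
    colors, morpho = synthdata.simulate_color_morphometrics(
        spec, seed=SEED, species=panel, slope_by_species=slopes)

    covariates = synthdata.simulate_covariates(
        tree, flp_states=tip_states, effects=spec.covariate_effects,
        seed=SEED)

    trees.write_newick(tree, OUT / "tree.nwk")
    specimens.to_csv(OUT / "specimens.csv", index=False)
    colors.to_csv(OUT / "colors.csv", index=False)
    morpho.to_csv(OUT / "morphometrics.csv", index=False)
    covariates.to_csv(OUT / "covariates.csv", index=False)
    pd.DataFrame({"species": list(tip_states),
                  "state": list(tip_states.values())}
                 ).to_csv(OUT / "true_states.csv", index=False)
    pd.DataFrame({"species": list(slopes), "planted_slope": list(slopes.values())}
                 ).to_csv(OUT / "planted_slopes.csv", index=False)

    n_flp = len(flp_species)
    print(f"study written to {OUT}")
    print(f"  {len(species)} species, {len(specimens)} specimens, "
          f"{n_flp} truly FLP ({100 * n_flp / len(species):.0f}%)")
    print(f"  color panel: {len(panel)} FLP species; planted slopes "
          f"{slopes}")


if __name__ == "__main__":
    main()
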