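#!/usr/bin/env python
"""Habitat controls on recent growth and stratified climate sensitivity.

Averages each tree's ring-width index over 2003-2012, relates it to plot
locational and structural covariates with a BRT, classifies plots as
good or poor habitat using the fixed per-species thresholds, builds
separate signal-free chronologies per stratum (>= 25 trees) and
correlates them with the monthly climate variables.
"""

import argparse
from pathlib import Path

import pandas as pd

from borealrings import climate as cl
from borealrings import detrend, habitat, ringio, synth
from borealrings.brt import BRTConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/habitat"))
    ap.add_argument("--nboot", type=int, default=1000)
    ap.add_argument("--learning-rate", type=float, default=0.001)
    ap.add_argument("--max-trees", type=int, default=30000)
    ap.add_argument("--skip-brt", action="store_true")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = cl.ClimateTable.from_csv(args.data / "climate.csv")
    variables = cl.build_variable_set(table)

    for species in ("white_spruce", "black_spruce"):
        series = ringio.read_rwl(args.data / f"{species}.rwl")
        meta = pd.read_csv(args.data / f"{species}_trees.csv")
        meta["series_id"] = meta["tree_id"]
        meta["species"] = species
        series = ringio.attach_metadata(series, meta)
        arcs = pd.read_csv(args.data / f"{species}_arcs.csv", index_col="series_id")
        series = ringio.correct_missing_pith(series, arcs)

        result = detrend.signal_free_rcs(series, seed=args.seed, n_boot=0)
        recent = habitat.recent_mean_rwi(result.indices)
        plots = pd.read_csv(args.data / f"{species}_plots.csv",
                            index_col="plot_id")
        trees = pd.read_csv(args.data / f"{species}_trees.csv",
                            index_col="tree_id")
        htable = trees.join(recent, how="inner").merge(
            plots.drop(columns="habitat_class"), left_on="plot_id",
            right_index=True,
        )
        htable.to_csv(args.out / f"{species}_habitat_table.csv")

        if not args.skip_brt:
            model = habitat.brt_habitat_model(
                htable,
                config=BRTConfig(learning_rate=args.learning_rate,
                                 max_trees=args.max_trees, seed=args.seed),
            )
            model.relative_influence.rename("relative_influence").to_csv(
                args.out / f"{species}_influence.csv"
            )
            print(f"{species}: BRT R^2 = {model.r2:.2f}; most influential: "
                  f"{', '.join(model.relative_influence.index[:4])}")

        classes = {
            tid: habitat.classify_habitat(row, species)
            for tid, row in htable.iterrows()
        }
        counts = pd.Series(classes).value_counts()
        print(f"{species}: habitat classes {counts.to_dict()}")
        grid, chrons = habitat.stratified_climate_sensitivity(
            series, variables, classes, species=[species],
            min_n=25, n_boot=args.nboot, seed=args.seed,
        )
        grid.to_csv(args.out / f"{species}_stratified.csv", index=False)
        for (sp, hab), res in chrons.items():
            res.chronology.to_frame().to_csv(
                args.out / f"{sp}_{hab}_chronology.csv", index=False
            )
        if {"good", "poor"} <= set(grid["habitat"]):
            good = grid[grid["habitat"] == "good"].set_index("variable")["r"]
            poor = grid[grid["habitat"] == "poor"].set_index("variable")["r"]
            stronger = sum(
                abs(poor[v]) > abs(good[v]) for v in cl.TEMPERATURE_VARIABLES
            )
            print(f"  temperature sensitivity stronger in poor habitat for "
                  f"{stronger} of {len(cl.TEMPERATURE_VARIABLES)} variables")


if __name__ == "__main__":
    main()
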