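#!/usr/bin/env python
"""Climate-growth analysis: static, moving-window and BRT.

Correlates each species' chronology with monthly temperature and
(log-transformed) precipitation for the growth and previous year, runs
25-year moving windows with a 1-year step and the low-frequency
variation test, and fits a boosted regression tree (tree complexity 2,
learning rate 0.001, bag fraction 0.5, up to 30000 trees selected by
10-fold cross-validation) to characterize the form of each response.
"""

import argparse
from pathlib import Path

import pandas as pd

from borealrings import climate as cl
from borealrings.brt import BRTConfig, interaction_screen, partial_dependence


def load_chronology(path: Path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df["index"].to_numpy(), index=df["year"].to_numpy())


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--chron", type=Path, default=Path("results/chronologies"))
    ap.add_argument("--out", type=Path, default=Path("results/climate_growth"))
    ap.add_argument("--nboot", type=int, default=1000)
    ap.add_argument("--learning-rate", type=float, default=0.001)
    ap.add_argument("--max-trees", type=int, default=30000)
    ap.add_argument("--skip-brt", action="store_true")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = cl.ClimateTable.from_csv(args.data / "climate.csv")
    variables = cl.build_variable_set(table)

    for species in ("white_spruce", "black_spruce"):
        chron = load_chronology(args.chron / f"{species}_chronology.csv")

        static = cl.static_correlations(chron, variables, n_boot=args.nboot,
                                        seed=args.seed)
        static.to_csv(args.out / f"{species}_static.csv")
        sig = static[static["significant"]]
        top = static["r"].abs().idxmax()
        print(f"{species}: {len(sig)}/{len(static)} variables significant; "
              f"strongest: {top} (r = {static.loc[top, 'r']:.3f})")

        moving = cl.moving_correlations(chron, variables, window=25, step=1,
                                        n_boot=args.nboot, seed=args.seed)
        moving.to_csv(args.out / f"{species}_moving.csv", index=False)

        lf_rows = []
        common = chron.index.intersection(variables.dropna().index)
        for var in cl.MONTHLY_VARIABLES:
            x = variables.loc[common, var].to_numpy(float)
            if cl.is_precip_variable(var):
                x = cl.log_precip(x)
            p = cl.low_frequency_test(chron.loc[common].to_numpy(), x,
                                      window=25, n_boot=max(args.nboot, 100),
                                      seed=args.seed)
            lf_rows.append({"variable": var, "low_freq_p": p})
        lf = pd.DataFrame(lf_rows)
        lf.to_csv(args.out / f"{species}_low_frequency.csv", index=False)
        print(f"  low-frequency test: {int((lf['low_freq_p'] < 0.05).sum())} of "
              f"{len(lf)} variables show more change over time than chance")

        if not args.skip_brt:
            result = cl.brt_climate_model(
                chron, variables,
                BRTConfig(learning_rate=args.learning_rate,
                          max_trees=args.max_trees, seed=args.seed),
            )
            result.relative_influence.rename("relative_influence").to_csv(
                args.out / f"{species}_brt_influence.csv"
            )
            pds = []
            for var in result.relative_influence.index[:6]:
                p = partial_dependence(result, var)
                p.insert(0, "variable", var)
                pds.append(p)
            pd.concat(pds).to_csv(args.out / f"{species}_brt_partial.csv",
                                  index=False)
            h2 = interaction_screen(result, seed=args.seed)
            h2.to_csv(args.out / f"{species}_brt_interactions.csv", index=False)
            print(f"  BRT: {result.n_trees} trees, training R^2 = "
                  f"{result.r2:.2f}; top variables: "
                  f"{', '.join(result.relative_influence.index[:3])}; "
                  f"max interaction H^2 = {h2['h2'].max():.3f}")


if __name__ == "__main__":
    main()
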