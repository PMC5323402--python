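"""Refit the crop-yield R-function analysis on user-supplied field data.

The long-term cropping-system tables this analysis was designed for (annual
grain yields, weed species biomass, daily weather from the KBS LTER site,
https://lter.kbs.msu.edu/datatables/) are not redistributed here.  Download
them yourself, reshape to the documented CSV schema, and point this script at
the directory:

    yields.csv : year,crop,treatment,replicate,yield_kg_ha
    weeds.csv  : year,crop,treatment,replicate,species_code,biomass_g_m2
    climate.csv: date,precip_mm,tmin_c,tmax_c

Example:

    python scripts/fit_real_data.py --data path/to/tables --crop maize \
        --covariates shannon,simpson,tM,tMin --out results/maize

Covariate names may be any diversity index (richness, shannon, simpson,
invsimpson, Jevenness, Eevenness) or growing-season climate summary
(tM, tmax, tmin, tMax, tMin, precM, precMax); interactions are ratio pairs
like ``--interactions shannon:tMin``.  Note that ratio covariates involving
variables that cross zero (e.g. freezing-season tMin) need
``--transform identity``.
"""

import argparse
import sys

from cropdyn.pipeline import RunConfig, run_pipeline


def build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=__doc__,
                                formatter_class=argparse.RawDescriptionHelpFormatter)
    p.add_argument("--data", required=True, help="directory with the three CSVs")
    p.add_argument("--crop", default="maize")
    p.add_argument("--covariates", default="shannon",
                   help="comma-separated covariate names")
    p.add_argument("--interactions", default="",
                   help="comma-separated colon pairs, e.g. shannon:tMin")
    p.add_argument("--transform", default="log", choices=["log", "identity"])
    p.add_argument("--lags", default="0,1", help="covariate lags d' to try")
    p.add_argument("--level", type=float, default=0.99)
    p.add_argument("--out", required=True)
    p.add_argument("--seed", type=int, default=0)
    return p


def main(argv=None) -> int:
    args = build_parser().parse_args(argv)
    interactions = [tuple(pair.split(":")) for pair in args.interactions.split(",")
                    if pair]
    config = RunConfig(
        crop=args.crop,
        input_dir=args.data,
        out_dir=args.out,
        seed=args.seed,
        covariates=[c for c in args.covariates.split(",") if c],
        interactions=interactions,
        transform=args.transform,
        covariate_lags=tuple(int(x) for x in args.lags.split(",") if x),
        level=args.level,
    )
    results = run_pipeline(config)
    print(results["selection"].head(10).to_string(index=False))
    print(f"\nreport bundle written to {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
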