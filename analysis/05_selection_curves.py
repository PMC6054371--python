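"""Relative selection along the crop/wetland gradient, by season.

For each season's winning model, evaluates the fixed-effects selection
probability for locations covered by a crop (proportion P) and wetlands
(1 - P), at the 0/50/100% quantiles of distance to the nearest flowline.
Writes the curves as CSV and one figure per run.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import DERIVED, get_config, parse_args

from rsfpipe.design import UseAvailableTable
from rsfpipe.predict import selection_curves
from rsfpipe.rsf import FittedRSF


def main() -> None:
    args = parse_args(__doc__)
    cfg = get_config(args.small)
    fits = {
        p.stem.removeprefix("fit_"): FittedRSF.read(p)
        for p in sorted(DERIVED.glob("fit_*.json"))
    }
    rows = []
    fig, axes = plt.subplots(1, len(fits), figsize=(4 * len(fits), 3.2), squeeze=False)
    for ax, (season, fit) in zip(axes[0], fits.items()):
        table = UseAvailableTable.read(DERIVED / f"design_{fit.scheme}.csv")
        if "prop_Wetland" not in fit.beta:
            print(f"{season}: winner {fit.scheme} has no wetland category; skipped")
            continue
        curves = selection_curves(fit, list(cfg.curve_crops), table,
                                  cfg.dist_quantiles, cfg.curve_grid_size)
        for c in curves:
            for P, p in zip(c.P, c.p_values):
                rows.append({"season": season, "crop": c.crop,
                             "distance_m": c.distance, "P": P, "p": p})
            if c.distance == curves[0].distance:
                ax.plot(c.P, c.p_values, label=c.crop)
        ax.set_title(season)
        ax.set_xlabel("proportion crop (1 - P wetland)")
        ax.set_ylabel("relative selection p(l)")
        ax.legend(fontsize=7)
        trends = {c.crop: c.slope_sign for c in curves if c.distance == curves[0].distance}
        print(f"{season}: curve trend vs wetland "
              + ", ".join(f"{k}:{'up' if v > 0 else 'down' if v < 0 else 'flat'}"
                          for k, v in trends.items()))
    pd.DataFrame(rows).to_csv(DERIVED / "selection_curves.csv", index=False)
    fig.tight_layout()
    fig.savefig(DERIVED / "selection_curves.png", dpi=120)
    print(f"wrote {len(rows)} curve points")


if __name__ == "__main__":
    main()
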