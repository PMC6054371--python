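"""Project the seasonal models across the landscape.

Per raster cell: proportional coverage within the 100 m buffer of the cell
center, distance to the nearest flowline, then the winning model's
fixed-effects selection probability.  Writes one prediction grid per
season plus a heatmap figure.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from common import DERIVED, STUDY, get_config, parse_args

from rsfpipe.flowlines import read_flowlines
from rsfpipe.predict import project_landscape
from rsfpipe.rasters import read_ascii_grid, write_ascii_grid
from rsfpipe.rsf import FittedRSF


def main() -> None:
    args = parse_args(__doc__)
    cfg = get_config(args.small)
    landscape = read_ascii_grid(STUDY / "landcover.asc", categorical=True)
    flows = read_flowlines(STUDY / "flowlines.wkt")
    scheme_by_name = {s.name: s for s in cfg.schemes}
    fit_paths = sorted(DERIVED.glob("fit_*.json"))
    fig, axes = plt.subplots(1, len(fit_paths), figsize=(4 * len(fit_paths), 3.6),
                             squeeze=False)
    for ax, path in zip(axes[0], fit_paths):
        fit = FittedRSF.read(path)
        pred = project_landscape(fit, landscape, flows,
                                 scheme_by_name[fit.scheme], cfg.buffer_radius)
        write_ascii_grid(pred, DERIVED / f"prediction_{fit.season}.asc")
        vals = pred.values[~np.isnan(pred.values)]
        print(f"{fit.season}: p(l) range {vals.min():.3f}-{vals.max():.3f}, "
              f"median {np.median(vals):.3f}")
        im = ax.imshow(pred.values, vmin=0, vmax=1, cmap="viridis")
        ax.set_title(fit.season)
        ax.set_axis_off()
    fig.colorbar(im, ax=axes[0], shrink=0.8, label="relative selection")
    fig.savefig(DERIVED / "prediction_maps.png", dpi=120, bbox_inches="tight")
    print(f"wrote {len(fit_paths)} seasonal prediction rasters")


if __name__ == "__main__":
    main()
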