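"""Assign seasons and build the used/available design tables.

Each cleaned track is split over the four agricultural seasons (animals
must span a season to contribute); per individual-season, availability is
one uniform point per used fix from the 100% minimum convex polygon, and
every location gets proportional-coverage and standardized flowline
predictors.  One table per aggregation hypothesis (H1-H4), sharing the
same points, lands under results/derived/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DERIVED, STUDY, get_config, parse_args

from rsfpipe.design import assign_seasons, build_design_tables
from rsfpipe.flowlines import read_flowlines
from rsfpipe.pipeline import _spawn_seeds
from rsfpipe.rasters import read_ascii_grid
from rsfpipe.tracks import read_tracks


def main() -> None:
    args = parse_args(__doc__)
    cfg = get_config(args.small)
    tracks = read_tracks(DERIVED / "tracks_clean.csv")
    landscape = read_ascii_grid(STUDY / "landcover.asc", categorical=True)
    flows = read_flowlines(STUDY / "flowlines.wkt")

    used_by_season = {s.name: [] for s in cfg.seasons}
    for tr in tracks:
        for name, (sub, included) in assign_seasons(
            tr, cfg.seasons, cfg.span_tolerance_days
        ).items():
            if included and len(sub) >= 3:
                used_by_season[name].append(sub)
    for name, lst in used_by_season.items():
        sizes = [len(t) for t in lst]
        mean = sum(sizes) / len(sizes) if sizes else 0
        print(f"{name}: n = {len(lst)} individuals, "
              f"mean {mean:.0f} fixes/individual"
              + (f", range {min(sizes)}-{max(sizes)}" if sizes else ""))
    used_by_season = {k: v for k, v in used_by_season.items() if len(v) >= 2}

    seeds = _spawn_seeds(cfg.master_seed + 1, 4)
    tables = build_design_tables(
        used_by_season, landscape, flows, cfg.schemes, cfg.buffer_radius, seeds[1]
    )
    for name, table in tables.items():
        table.write(DERIVED / f"design_{name}.csv")
        print(f"scheme {name}: {len(table.df)} used+available rows, "
              f"{len(table.predictor_columns)} predictors")


if __name__ == "__main__":
    main()
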