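"""Pairwise similarity between seasonal prediction maps.

Computes S = 1 - sum(d^2)/sum(Delta^2) for every ordered pair of seasonal
rasters (the column raster is the target defining Delta), and prints the
lower triangle at 7 decimal places.  Raster paths may be passed explicitly;
by default all prediction grids under results/derived/ are compared.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DERIVED

from rsfpipe.rasters import read_ascii_grid
from rsfpipe.similarity import pairwise_similarity


def main() -> None:
    args = [a for a in sys.argv[1:] if not a.startswith("-")]
    paths = [Path(p) for p in args] or sorted(DERIVED.glob("prediction_*.asc"))
    if len(paths) < 2:
        raise SystemExit("need at least 2 prediction rasters to compare")
    rasters = {
        p.stem.removeprefix("prediction_"): read_ascii_grid(p, categorical=False)
        for p in paths
    }
    matrix = pairwise_similarity(rasters)
    matrix.write(DERIVED / "similarity_matrix.tsv")
    print("pairwise similarity, lower triangle (row raster A vs column target B):")
    print(matrix.lower_triangle())
    off = [matrix.S[i, j] for i in range(len(paths)) for j in range(len(paths)) if i != j]
    print(f"\noff-diagonal range: {min(off):.7f}-{max(off):.7f}")


if __name__ == "__main__":
    main()
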