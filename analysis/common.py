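"""Shared configuration for the numbered analysis scripts.

Every script reads and writes under ``results/`` relative to the
repository root, and shares one pipeline configuration so the stages
compose into a single reproducible study.  ``--small`` runs a scaled-down
study (fewer animals, smaller landscape) for a quick look.
"""

import argparse
from pathlib import Path

from rsfpipe.pipeline import PipelineConfig, SyntheticStudyConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
STUDY = RESULTS / "study"  # raw synthetic inputs
DERIVED = RESULTS / "derived"  # everything the analysis produces

MASTER_SEED = 20160301  # study start date, fixed once


def get_config(small: bool = False) -> PipelineConfig:
    cfg = PipelineConfig(master_seed=MASTER_SEED)
    if small:
        cfg.synthetic = SyntheticStudyConfig(
            n_rows=120, n_cols=120, n_individuals=6, home_radius=900.0,
            n_late_start=1, n_early_end=1,
        )
    return cfg


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--small", action="store_true", help="run a scaled-down study")
    return ap.parse_args()
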