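"""Shared plumbing for the numbered analysis drivers.

Generates (or reloads) the default synthetic two-environment dataset
under ``scratch/analysis`` — large intermediates stay out of version
control; the drivers write only small summary tables to ``results/``.
"""

from __future__ import annotations

import json
from pathlib import Path

from lncpop import (SimulationConfig, simulate_expression, simulate_trait)
from lncpop import io as lio

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 0


def get_dataset(seed: int = SEED):
    """The default-condition simulated dataset (matrix, truth, trait, cfg)."""
    cfg = SimulationConfig(seed=seed)
    matrix, truth = simulate_expression(cfg)
    trait = simulate_trait(matrix, truth, cfg)
    return matrix, truth, trait, cfg


def write_result(name: str, payload: dict) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True,
                  default=lio._json_default)
        fh.write("\n")
    return path
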