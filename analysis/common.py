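"""Shared configuration for the analysis drivers.

All drivers operate on the same 6 km x 6 km synthetic study region (seed 11,
five 500-ha lidar scenes) so their outputs are mutually consistent. Each
driver re-derives the pipeline state it needs by calling the library; the
landscape is deterministic under the shared seed, so every driver sees
identical inputs.
"""

from __future__ import annotations

import functools
import logging
from pathlib import Path

from chocoforest.height_map import EnsembleConfig
from chocoforest.pipeline import PipelineConfig, PipelineResult, run_pipeline
from chocoforest.simulate import SimulationConfig

logging.basicConfig(level=logging.INFO, format="%(message)s")

RESULTS = Path(__file__).resolve().parent.parent / "results"


def demo_config(seed: int = 11) -> PipelineConfig:
    return PipelineConfig(
        simulation=SimulationConfig(size=(6000.0, 6000.0), seed=seed),
        n_scenes=5,
        scene_lengths=(5000.0,),
        bootstrap_iterations=25,
        cv_iterations=200,
        rf=EnsembleConfig(n_trees=500, seed=seed),
        seed=seed,
    )


@functools.lru_cache(maxsize=1)
def result(seed: int = 11) -> PipelineResult:
    """The full pipeline state for the shared demo region (cached per process)."""
    RESULTS.mkdir(exist_ok=True)
    return run_pipeline(demo_config(seed))
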