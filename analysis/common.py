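"""Shared configuration for the numbered analysis drivers.

All drivers operate on one desk-scale synthetic study (seed 2024),
chained through a cached pipeline working directory under ``scratch/``
(large per-subject artifacts) while each driver writes its small summary
tables under ``results/``.
"""

from pathlib import Path

from morphotx.config import RunConfig, SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
WORKDIR = ROOT / "scratch" / "analysis_pipeline"
RESULTS = ROOT / "results"

STUDY = RunConfig(simulation=SimulationConfig(seed=2024), seed=2024)


def ensure(through: str):
    """Run the cached pipeline up to (and including) the given stage."""
    from morphotx.pipeline import run_pipeline

    RESULTS.mkdir(exist_ok=True)
    return run_pipeline(STUDY, WORKDIR, resume=True, through=through)
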