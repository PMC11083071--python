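"""Shared run configuration for the numbered analysis scripts.

All scripts operate on one pipeline run directory (large intermediate
data under scratch/, small result tables under results/) with a fixed
seed, so each script can be re-run independently after 01.
"""

from pathlib import Path

from recland.cli import RunConfig

REPO = Path(__file__).resolve().parent.parent
RUN_DIR = REPO / "scratch" / "analysis_run"
RESULTS = REPO / "results"

SEED = 1


def run_config() -> RunConfig:
    RESULTS.mkdir(exist_ok=True)
    return RunConfig(seed=SEED, outdir=str(RUN_DIR))
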