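"""Zinc-finger recognition motif enrichment in hotspot sequences.

Scans hotspot and coldspot sequences with the PWM (max log-odds over
both strands per sequence) and tests for hotspot enrichment with a
one-sided rank-sum on the per-sequence maxima.
"""

import json
import shutil
import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from _common import RESULTS, RUN_DIR, run_config

from recland.cli import run_pipeline


def main() -> None:
    cfg = run_config()
    run_pipeline(cfg, ["motif-test", "report"])
    motif = json.loads((RUN_DIR / "motif_test.json").read_text())
    motif.pop("_provenance", None)
    (RESULTS / "06_motif_test.json").write_text(json.dumps(motif, indent=1))
    shutil.copy(RUN_DIR / "motif_scores.tsv", RESULTS / "06_motif_scores.tsv")
    shutil.copy(RUN_DIR / "report.json", RESULTS / "pipeline_report.json")
    print(
        f"motif enrichment (hot > cold, rank-sum): U={motif['statistic']:.1f}, "
        f"p={motif['p']:.3g} over {motif['n_hot']} hotspot and "
        f"{motif['n_cold']} coldspot sequences"
    )


if __name__ == "__main__":
    main()
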