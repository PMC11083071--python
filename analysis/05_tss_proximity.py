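"""Are recombination hotspots near transcription start sites?

Counts hotspots whose midpoint falls within +-3 kb of any TSS, compares
the count against 1000 sets of uniformly placed random points, and also
reports promoter-proxy peak overlaps with TSS regions and hotspots.
"""

import json
import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from _common import RESULTS, RUN_DIR, run_config

from recland.cli import run_pipeline


def main() -> None:
    cfg = run_config()
    run_pipeline(cfg, ["tss-test"])
    tss = json.loads((RUN_DIR / "tss_test.json").read_text())
    tss.pop("_provenance", None)
    (RESULTS / "05_tss_test.json").write_text(json.dumps(tss, indent=1))
    print(
        f"{tss['observed']}/{tss['n_hotspots']} hotspot midpoints within "
        f"3 kb of a TSS (null mean {tss['null_mean']:.2f} +- "
        f"{tss['null_sd']:.2f})"
    )
    print(
        f"direction: {tss['direction']}; empirical p={tss['empirical_p']:.4g} "
        f"(t-test p={tss['t_test_p']:.3g})"
    )
    pk = tss["peak_tss_overlap"]
    print(
        f"peaks near TSS: {pk['a_overlapping_b']}/{pk['n_a']} "
        f"({100 * pk['frac_a']:.1f}%)"
    )
    ph = tss["peak_hotspot_overlap"]
    print(f"peaks overlapping hotspots: {ph['a_overlapping_b']}/{ph['n_a']}")


if __name__ == "__main__":
    main()
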