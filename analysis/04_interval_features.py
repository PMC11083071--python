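"""GC content and nucleotide diversity of hotspots vs coldspots.

Compares both interval classes against 1000 sets of length-matched
random genomic fragments (empirical p with the +1 convention) and
against each other (two-sided Wilcoxon rank-sum).
"""

import json
import shutil
import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from _common import RESULTS, RUN_DIR, run_config

from recland.cli import run_pipeline


def main() -> None:
    cfg = run_config()
    run_pipeline(cfg, ["features"])
    tests = json.loads((RUN_DIR / "features_tests.json").read_text())
    tests.pop("_provenance", None)
    (RESULTS / "04_features_tests.json").write_text(json.dumps(tests, indent=1))
    shutil.copy(RUN_DIR / "features.tsv", RESULTS / "04_features.tsv")
    hot, cold = tests["hotspot"], tests["coldspot"]
    print(
        f"GC: hotspots {100 * hot['mean_gc']:.2f}% vs coldspots "
        f"{100 * cold['mean_gc']:.2f}% (matched-random null "
        f"{100 * hot['null_mean_gc']:.2f}%)"
    )
    print(
        f"pi: hotspots {hot['mean_pi']:.5f} vs coldspots "
        f"{cold['mean_pi']:.5f} (null {hot['null_mean_pi']:.5f})"
    )
    hv = tests["hot_vs_cold"]
    print(
        f"hot vs cold Wilcoxon: GC p={hv['gc_wilcoxon_p']:.3g}, "
        f"pi p={hv['pi_wilcoxon_p']:.3g}"
    )
    print(
        f"vs matched random fragments: hotspot GC p={hot['gc_empirical_p']:.4g}, "
        f"coldspot GC p={cold['gc_empirical_p']:.4g}"
    )


if __name__ == "__main__":
    main()
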