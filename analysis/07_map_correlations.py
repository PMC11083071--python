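"""Meiotic vs historical recombination maps at the 1 Mb scale.

Aggregates the fine-scale (population/LD-style) map to 1 Mb windows and
correlates it, per sex and population, with the pedigree-based meiotic
window maps (Spearman over shared non-missing windows).
"""

import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from _common import RESULTS, RUN_DIR, run_config

import numpy as np
import pandas as pd

from recland.core import WindowMap
from recland.finescale_map import aggregate_to_windows, map_correlation
from recland.io_formats import read_rate_map


def load_window_map(path) -> WindowMap:
    df = pd.read_csv(path, sep="\t")
    return WindowMap(
        str(df["chrom"].iloc[0]),
        df["start"].to_numpy(),
        df["end"].to_numpy(),
        pd.to_numeric(df["rate_cM_per_Mb"], errors="coerce").to_numpy(),
    )


def main() -> None:
    cfg = run_config()
    fmap = read_rate_map(RUN_DIR / "rate_map.tsv")
    historical = aggregate_to_windows(fmap, cfg.window, cfg.sim.chrom_length)
    rows = []
    for tag in ("both", "male", "female"):
        path = RUN_DIR / f"window_map.{tag}.1.tsv"
        if not path.exists():
            continue
        meiotic = load_window_map(path)
        r = map_correlation(meiotic, historical, "spearman")
        rows.append({"meiotic_map": tag, **r})
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "07_map_correlations.tsv", sep="\t", index=False)
    print("meiotic vs historical 1 Mb map correlations (Spearman):")
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
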