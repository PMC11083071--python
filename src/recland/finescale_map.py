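"""Window aggregation of fine-scale recombination maps and between-map
correlation comparisons.

Fine-scale maps carry one rate per inter-SNP interval; to compare maps
from different estimators (or against pedigree-based meiotic maps) they
are aggregated to fixed windows (default 1 Mb) by length-weighted
averaging, then correlated over shared non-missing windows. Rank
(Spearman) correlation is the default, which also makes the comparison
insensitive to units (rho/bp vs cM/Mb).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import FineScaleMap, WindowMap

__all__ = [
    "FineScaleMap",
    "aggregate_to_windows",
    "chromosome_mean_rate",
    "map_correlation",
    "group_correlation_contrast",
    "scale_rates",
]


def aggregate_to_windows(
    fmap: FineScaleMap, window: int = 1_000_000, chrom_length: int | None = None
) -> WindowMap:
    """Length-weighted window means of interval rates.

    An interval contributes to a window in proportion to its overlap
    length; windows with zero covered bp get NaN (missing, not zero).
    ``chrom_length`` extends the tiling beyond the last SNP if given.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    span_end = int(fmap.positions[-1]) if chrom_length is None else chrom_length
    n_win = max(1, int(np.ceil(span_end / window)))
    starts = np.arange(n_win, dtype=np.int64) * window
    ends = np.minimum(starts + window, span_end)
    ends = np.maximum(ends, starts + 1)  # degenerate tail guard

    mass = np.zeros(n_win)  # sum rate x overlap
    cover = np.zeros(n_win)  # sum overlap bp
    s = fmap.positions[:-1]
    e = fmap.positions[1:]
    first_w = s // window
    last_w = np.minimum((e - 1) // window, n_win - 1)
    for i in range(fmap.n_intervals):
        for w in range(int(first_w[i]), int(last_w[i]) + 1):
            ov = min(int(e[i]), int(starts[w]) + window) - max(
                int(s[i]), int(starts[w])
            )
            if ov > 0:
                mass[w] += fmap.rates[i] * ov
                cover[w] += ov
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(cover > 0, mass / np.where(cover > 0, cover, 1), np.nan)
    return WindowMap(
        chrom=fmap.chrom,
        starts=starts,
        ends=ends,
        rates=rates,
        sex="both",
        rate_units=fmap.units,
    )


def chromosome_mean_rate(fmap: FineScaleMap, weighted: bool = True) -> float:
    """Mean chromosomal recombination rate.

    ``weighted`` (default) is the physical-length-weighted mean,
    sum(rate x length) / sum(length); otherwise the plain arithmetic mean
    of interval rates.
    """
    if fmap.n_intervals == 0:
        raise ValueError("empty map")
    if weighted:
        lens = fmap.interval_lengths
        return float(np.sum(fmap.rates * lens) / np.sum(lens))
    return float(np.mean(fmap.rates))


def scale_rates(fmap: FineScaleMap, factor: float, units: str) -> FineScaleMap:
    """Unit conversion helper (e.g. rho/bp -> cM/Mb given an Ne estimate)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return FineScaleMap(
        fmap.chrom, fmap.positions.copy(), fmap.rates * factor, units, fmap.source
    )


def _aligned_rates(a: WindowMap, b: WindowMap) -> tuple[np.ndarray, np.ndarray]:
    sa = pd.Series(a.rates, index=a.to_series_index())
    sb = pd.Series(b.rates, index=b.to_series_index())
    df = pd.concat([sa, sb], axis=1, join="inner").dropna()
    return df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()


def map_correlation(
    a: WindowMap, b: WindowMap, method: str = "spearman"
) -> dict:
    """Correlation between two window maps over shared non-missing windows."""
    x, y = _aligned_rates(a, b)
    if x.size < 3:
        raise ValueError(
            f"need >=3 shared non-missing windows, got {x.size}"
        )
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"coefficient": float(rho), "p": float(p), "n": int(x.size), "method": method}


def group_correlation_contrast(
    corr_matrix: pd.DataFrame, groups: dict[str, str]
) -> dict:
    """Within-group vs between-group correlation contrast (Welch t-test).

    ``corr_matrix`` is a symmetric DataFrame of pairwise map correlations;
    ``groups`` labels each map (e.g. Chinese vs Western breeds). The
    off-diagonal coefficients are split into within- and between-group
    sets and compared.
    """
    names = list(corr_matrix.index)
    if set(names) != set(corr_matrix.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    labels = {n: groups[n] for n in names}
    if len(set(labels.values())) < 2:
        raise ValueError("need at least two groups")
    within, between = [], []
    for i, ni in enumerate(names):
        for nj in names[i + 1 :]:
            v = float(corr_matrix.loc[ni, nj])
            (within if labels[ni] == labels[nj] else between).append(v)
    if len(within) < 2 or len(between) < 1:
        raise ValueError("insufficient within/between pairs for the contrast")
    na, nb = len(within), len(between)
    va = np.var(within, ddof=1)
    vb = np.var(between, ddof=1) if nb > 1 else 0.0
    if va == 0 and vb == 0:
        equal = np.mean(within) == np.mean(between)
        t = 0.0 if equal else np.inf * np.sign(np.mean(within) - np.mean(between))
        p, df = (1.0 if equal else 0.0), float(na + nb - 2)
    elif nb == 1:
        # single between pair: one-sample t of within values against it
        t, p = stats.ttest_1samp(within, between[0])
        df = float(na - 1)
    else:
        t, p = stats.ttest_ind(within, between, equal_var=False)
        num = (va / na + vb / nb) ** 2
        den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        df = float(num / den) if den > 0 else float(na + nb - 2)
    return {
        "within_mean": float(np.mean(within)),
        "between_mean": float(np.mean(between)),
        "t": float(t),
        "df": df,
        "p": float(p),
        "n_within": na,
        "n_between": nb,
    }
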