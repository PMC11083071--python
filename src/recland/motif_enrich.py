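"""PWM representation, log-odds scanning, and the hotspot-vs-coldspot
motif enrichment test (PRDM9-style zinc-finger recognition motifs).

Scores are log2 odds against a 0-order background (uniform by default),
with a small pseudocount blended into the motif probabilities. A
sequence's score is the maximum windowed sum over all offsets and both
strands; windows containing ambiguous bases are skipped. Enrichment of
hotspot over coldspot sequences is tested either by a one-sided rank-sum
on the per-sequence maxima (default) or by a one-sided Fisher exact test
on hit counts above a score threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

_BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G


@dataclass
class PWM:
    """Position probability matrix (L x 4 over A, C, G, T)."""

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01
    name: str = "motif"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if np.any(self.matrix < 0):
            raise ValueError("PWM probabilities must be non-negative")
        if np.any(np.abs(self.matrix.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if np.any(self.background <= 0) or abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background must be a positive distribution")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    def log_odds(self) -> np.ndarray:
        """log2(((p + pc*bg) / (1 + pc)) / bg) per cell (bits)."""
        blended = (self.matrix + self.pseudocount * self.background) / (
            1.0 + self.pseudocount
        )
        return np.log2(blended / self.background)

    def consensus(self) -> str:
        return "".join(_BASE_ORDER[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.matrix[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
            self.name + "_rc",
        )


def example_zinc_finger_pwm(dominant: float = 0.85) -> PWM:
    """Synthetic stand-in for a predicted zinc-finger recognition motif.

    A fixed, moderately GC-rich 15-mer (one dominant base per position at
    probability ``dominant``, remainder spread evenly), matching the
    length and composition bias typical of C2H2 zinc-finger DNA
    recognition sequences. Purely synthetic: used by the simulator and
    examples where no externally predicted PWM is supplied.
    """
    consensus = "CCGCATGCAGGCTGA"
    rest = (1.0 - dominant) / 3.0
    mat = np.full((len(consensus), 4), rest)
    for i, b in enumerate(consensus):
        mat[i, _BASE_INDEX[b]] = dominant
    return PWM(mat, name="zf_15mer_synthetic")


def read_meme_minimal(path: str | Path) -> list:
    """Parse motifs from MEME minimal motif format (letter-probability
    matrices; background line honoured when present)."""
    motifs = []
    background = np.full(4, 0.25)
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            vals = lines[i].split()
            freq = {vals[k]: float(vals[k + 1]) for k in range(0, len(vals), 2)}
            background = np.array([freq.get(b, 0.25) for b in _BASE_ORDER])
            background = background / background.sum()
        elif line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else "motif"
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability"
            ):
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {name}: missing letter-probability matrix")
            header = lines[i].strip()
            w = None
            for tok_i, tok in enumerate(header.split()):
                if tok == "w=":
                    w = int(header.split()[tok_i + 1])
            rows = []
            i += 1
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) == 4:
                    try:
                        rows.append([float(x) for x in parts])
                    except ValueError:
                        break
                    i += 1
                else:
                    break
            if w is not None and len(rows) != w:
                raise ValueError(
                    f"motif {name}: expected {w} rows, found {len(rows)}"
                )
            mat = np.array(rows)
            mat = mat / mat.sum(axis=1, keepdims=True)
            motifs.append(PWM(mat, background.copy(), name=name))
            continue
        i += 1
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def write_meme_minimal(pwms: list, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {bg[i]:.5f}" for i, b in enumerate(_BASE_ORDER)) + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3; ambiguous bases -> -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _strand_scores(idx: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Windowed log-odds sums for one strand; NaN where the window holds
    an ambiguous base."""
    L = lom.shape[0]
    n_win = idx.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n_win, np.nan)
    if valid.any():
        vw = windows[valid]
        scores[valid] = lom[np.arange(L), vw].sum(axis=1)
    return scores


def max_logodds_score(seq: str, pwm: PWM) -> float:
    """Best log-odds window score over both strands; NaN when no valid
    window exists (short sequence or ambiguity everywhere)."""
    idx = encode_sequence(seq)
    if idx.size < pwm.length:
        return float("nan")
    lom = pwm.log_odds()
    fwd = _strand_scores(idx, lom)
    # reverse strand: scan the reverse complement with the same matrix
    rev_idx = _COMPLEMENT_IDX[idx[::-1]].astype(np.int8)
    rev_idx[idx[::-1] < 0] = -1
    rev = _strand_scores(rev_idx, lom)
    allscores = np.concatenate([fwd, rev])
    if np.all(np.isnan(allscores)):
        return float("nan")
    return float(np.nanmax(allscores))


@dataclass
class EnrichmentResult:
    method: str
    statistic: float
    p: float
    n_hot: int
    n_cold: int
    hot_hits: int | None = None
    cold_hits: int | None = None
    threshold: float | None = None
    n_hot_missing: int = 0
    n_cold_missing: int = 0


def pwm_enrichment_test(
    hot_seqs: list,
    cold_seqs: list,
    pwm: PWM,
    method: str = "ranksum",
    fisher_threshold: float | None = None,
) -> EnrichmentResult:
    """Is the motif enriched in hotspot over coldspot sequences?

    ``ranksum``: one-sided Mann-Whitney that hotspot max scores exceed
    coldspot max scores. ``fisher``: one-sided exact test on the 2x2
    table of (class x has a window scoring >= fisher_threshold).
    Sequences without a valid scan window are excluded (counts reported).
    """
    if not hot_seqs or not cold_seqs:
        raise ValueError("both sequence classes must be non-empty")
    hot = np.array([max_logodds_score(s, pwm) for s in hot_seqs])
    cold = np.array([max_logodds_score(s, pwm) for s in cold_seqs])
    hot_miss = int(np.isnan(hot).sum())
    cold_miss = int(np.isnan(cold).sum())
    hot = hot[~np.isnan(hot)]
    cold = cold[~np.isnan(cold)]
    if hot.size == 0 or cold.size == 0:
        raise ValueError("a class has no scorable sequences")

    if method == "ranksum":
        if np.unique(np.concatenate([hot, cold])).size == 1:
            u, p = hot.size * cold.size / 2.0, 1.0
        else:
            u, p = stats.mannwhitneyu(hot, cold, alternative="greater")
        return EnrichmentResult(
            method="ranksum",
            statistic=float(u),
            p=float(p),
            n_hot=hot.size,
            n_cold=cold.size,
            n_hot_missing=hot_miss,
            n_cold_missing=cold_miss,
        )
    if method == "fisher":
        if fisher_threshold is None:
            raise ValueError("fisher method requires fisher_threshold")
        h_hit = int(np.sum(hot >= fisher_threshold))
        c_hit = int(np.sum(cold >= fisher_threshold))
        table = [[h_hit, hot.size - h_hit], [c_hit, cold.size - c_hit]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        return EnrichmentResult(
            method="fisher",
            statistic=float(odds),
            p=float(p),
            n_hot=hot.size,
            n_cold=cold.size,
            hot_hits=h_hit,
            cold_hits=c_hit,
            threshold=float(fisher_threshold),
            n_hot_missing=hot_miss,
            n_cold_missing=cold_miss,
        )
    raise ValueError(f"unknown method {method!r}")


def extract_interval_sequences(fasta, intervals: list) -> list:
    """Sequence of each interval from an indexed FASTA or dict of strings."""
    return [str(fasta[iv.chrom][iv.start : iv.end]) for iv in intervals]


def background_from_sequences(seqs: list) -> np.ndarray:
    """0-order background estimated from sequences (e.g. coldspots),
    for GC-aware conservative scanning."""
    counts = np.zeros(4)
    for s in seqs:
        idx = encode_sequence(s)
        counts += np.bincount(idx[idx >= 0], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases in sequences")
    counts = np.maximum(counts, 1.0)
    return counts / counts.sum()
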