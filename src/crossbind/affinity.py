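"""Relative binding-affinity scoring under a position-specific affinity
matrix (PSAM) and rank-based comparison of affinity distributions.

A PSAM stores one relative affinity per (position, base), each column's
maximum being exactly 1; the affinity of a window is the product of its
per-position entries, so the consensus scores 1 and every substitution
multiplies in a penalty <= 1. This is a deliberate simplification of
free-energy occupancy models: the parameters are inputs (MEME motif file or
TSV), never fitted here.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import BASES, PWM, _BASE_INDEX, encode


@dataclass(frozen=True)
class PSAM:
    """Position-specific affinity matrix; entries in (0, 1], column max 1."""

    name: str
    matrix: np.ndarray  # width x 4

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PSAM matrix must be width x 4")
        if np.any(m <= 0) or np.any(m > 1):
            raise ValueError("PSAM entries must be in (0, 1]")
        if not np.allclose(m.max(axis=1), 1.0):
            raise ValueError("each PSAM column must have maximum exactly 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PSAM":
        return PSAM(self.name + "_rc", self.matrix[::-1, ::-1].copy())


def psam_from_pwm(pwm: PWM) -> PSAM:
    """Column-max normalization of a PWM into a PSAM."""
    m = np.clip(pwm.matrix, 1e-9, None)
    return PSAM(pwm.name, m / m.max(axis=1, keepdims=True))


def read_psam_tsv(path: str | Path, name: str | None = None) -> PSAM:
    """Read a PSAM from a 4-column TSV (A C G T, one row per position).

    Rows are column-max normalized on read, so raw relative-affinity tables
    are accepted as-is.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    cols = [c for c in frame.columns if c.upper() in _BASE_INDEX]
    if len(cols) != 4:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#")
        cols = list(frame.columns[:4])
    m = frame[cols].to_numpy(dtype=float)
    m = np.clip(m, 1e-9, None)
    return PSAM(name or Path(path).stem, m / m.max(axis=1, keepdims=True))


@dataclass(frozen=True)
class AffinityScore:
    sequence_id: str
    category: str
    score: float
    offset: int | None  # best window (max mode); None for sum mode
    strand: str | None


def window_affinity(window: str, psam: PSAM) -> float:
    """Product of per-position relative affinities for one window."""
    if len(window) != psam.width:
        raise ValueError(
            f"window length {len(window)} != PSAM width {psam.width}"
        )
    codes = encode(window)
    if np.any(codes >= 4):
        raise ValueError("window contains a non-ACGT base")
    return float(np.prod(psam.matrix[np.arange(psam.width), codes]))


def _all_window_affinities(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    w = matrix.shape[0]
    if len(codes) < w:
        return np.empty(0)
    log_m = np.column_stack([np.log(matrix), np.full(w, np.nan)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    sums = log_m[np.arange(w)[None, :], windows].sum(axis=1)
    out = np.exp(sums)
    out[np.isnan(sums)] = np.nan  # windows containing N are undefined
    return out


def sequence_affinity(
    sequence: str,
    psam: PSAM,
    mode: str = "max",
    sequence_id: str = "",
    category: str = "",
) -> AffinityScore:
    """Best-window (``max``) or total-occupancy (``sum``) affinity of a
    sequence, scanning both strands. Windows containing N are skipped."""
    if mode not in ("max", "sum"):
        raise ValueError(f"mode must be 'max' or 'sum', got {mode!r}")
    if len(sequence) < psam.width:
        raise ValueError(
            f"sequence shorter ({len(sequence)}) than PSAM width ({psam.width})"
        )
    codes = encode(sequence)
    fwd = _all_window_affinities(codes, psam.matrix)
    rev = _all_window_affinities(codes, psam.reverse_complement().matrix)
    if mode == "sum":
        total = float(np.nansum(fwd) + np.nansum(rev))
        return AffinityScore(sequence_id, category, total, None, None)
    best_score, best_offset, best_strand = 0.0, None, None
    for arr, strand in ((fwd, "+"), (rev, "-")):
        if arr.size and not np.all(np.isnan(arr)):
            i = int(np.nanargmax(arr))
            if arr[i] > best_score:
                best_score, best_offset, best_strand = float(arr[i]), i, strand
    return AffinityScore(sequence_id, category, best_score, best_offset, best_strand)


def score_sequences(
    sequences: Mapping[str, str], psam: PSAM, category: str = "", mode: str = "max"
) -> pd.DataFrame:
    rows = []
    for sid, seq in sequences.items():
        s = sequence_affinity(seq, psam, mode=mode, sequence_id=sid, category=category)
        rows.append(
            {
                "sequence_id": s.sequence_id,
                "category": s.category,
                "score": s.score,
                "offset": s.offset,
                "strand": s.strand,
            }
        )
    return pd.DataFrame(rows, columns=["sequence_id", "category", "score", "offset", "strand"])


# ---------------------------------------------------------------------------
# Rank-sum comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankTestResult:
    group_a: str
    group_b: str
    u_statistic: float
    p_one_sided: float
    p_two_sided: float
    stars: str


def significance_stars(p: float) -> str:
    """Star convention: '***' below 0.001, '*' below 0.05, '' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) of ``x`` vs ``y``.

    Uses exact enumeration when the combined sample is small (n <= 20) and
    tie-free, else the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_affinity_distributions(
    scores_by_category: Mapping[str, Sequence[float]]
) -> list[RankTestResult]:
    """Pairwise Wilcoxon rank-sum tests between score distributions.

    The one-sided p is for the direction suggested by the data (smaller of
    the two one-sided tests); stars follow the two-sided p.
    """
    names = list(scores_by_category)
    if len(names) < 2:
        raise ValueError("need at least two categories")
    for name in names:
        if len(scores_by_category[name]) < 3:
            raise ValueError(f"category {name!r} has fewer than 3 scores")
    results = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            u, p_two = rank_sum_test(
                scores_by_category[a], scores_by_category[b], "two-sided"
            )
            _, p_less = rank_sum_test(
                scores_by_category[a], scores_by_category[b], "less"
            )
            _, p_greater = rank_sum_test(
                scores_by_category[a], scores_by_category[b], "greater"
            )
            results.append(
                RankTestResult(
                    group_a=a,
                    group_b=b,
                    u_statistic=u,
                    p_one_sided=min(p_less, p_greater),
                    p_two_sided=p_two,
                    stars=significance_stars(p_two),
                )
            )
    return results


def rank_results_to_frame(results: Sequence[RankTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": r.group_a,
                "group_b": r.group_b,
                "u_statistic": r.u_statistic,
                "p_one_sided": r.p_one_sided,
                "p_two_sided": r.p_two_sided,
                "stars": r.stars,
            }
            for r in results
        ]
    )
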