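"""Cross-tissue comparison: gene categories, binding frequency, the 2 kb
co-binding peak subdivision, and an occupancy-matrix correlation/PCA
surrogate for read-count differential-binding analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Peak, merge_intervals

COMMON = "common"


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# Gene categories and binding frequency
# ---------------------------------------------------------------------------

def bound_genes(assignments: pd.DataFrame) -> set[str]:
    return set(assignments["gene_id"].dropna().unique())


def categorize_genes(
    assignments_a: pd.DataFrame,
    assignments_b: pd.DataFrame,
    tissue_a: str = "A",
    tissue_b: str = "B",
) -> pd.DataFrame:
    """Categorize genes as common / tissue-A-specific / tissue-B-specific.

    Returns a frame with columns gene_id, category where the categories are
    ``common``, ``{tissue_a}_specific`` and ``{tissue_b}_specific``.
    """
    import warnings as _warnings

    genes_a, genes_b = bound_genes(assignments_a), bound_genes(assignments_b)
    if not genes_a or not genes_b:
        _warnings.warn("one tissue has no assigned genes; all genes are specific")
    rows = []
    for g in sorted(genes_a | genes_b):
        if g in genes_a and g in genes_b:
            cat = COMMON
        elif g in genes_a:
            cat = f"{tissue_a}_specific"
        else:
            cat = f"{tissue_b}_specific"
        rows.append({"gene_id": g, "category": cat})
    return pd.DataFrame(rows, columns=["gene_id", "category"])


def category_percentages(counts: Mapping[str, int]) -> dict[str, int]:
    """Integer percentages (round half-up) of category counts."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0 for k in counts}
    return {k: round_half_up(100.0 * v / total) for k, v in counts.items()}


def binding_frequency(assignments: pd.DataFrame, tissue: str = "") -> pd.DataFrame:
    """Per-gene peak count and singlePeak/multiPeak class for one tissue.

    Counts distinct peaks assigned to each gene in the given assignment
    table. Returns columns gene_id, tissue, n_peaks, binding_class.
    """
    assigned = assignments.dropna(subset=["gene_id"])
    counts = assigned.groupby("gene_id")["peak_id"].nunique().sort_index()
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "tissue": tissue,
            "n_peaks": counts.values,
            "binding_class": np.where(counts.values == 1, "singlePeak", "multiPeak"),
        }
    ).reset_index(drop=True)


def peak_count_histogram(frequency: pd.DataFrame) -> pd.Series:
    """Histogram of genes by number of assigned peaks."""
    return frequency["n_peaks"].value_counts().sort_index()


# ---------------------------------------------------------------------------
# 2 kb co-binding subdivision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSubdivision:
    peak_id: str
    category: str  # "<A>_only", "<B>_only" or "shared_2kb"
    partner_peak_id: str | None = None


def _pair_distance(a: Peak, b: Peak, metric: str) -> float | None:
    if a.chrom != b.chrom:
        return None
    if metric == "edge":
        return a.interval.gap_to(b.interval)
    if metric == "midpoint":
        return abs(a.interval.midpoint - b.interval.midpoint)
    raise ValueError(f"unknown distance metric {metric!r}")


def subdivide_common_peaks(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    gap: int = 2000,
    tissue_a: str = "A",
    tissue_b: str = "B",
    distance: str = "edge",
    method: str = "greedy",
) -> list[PeakSubdivision]:
    """Split cross-tissue peaks into A-only / B-only / shared-within-gap.

    Candidate cross-tissue pairs on the same chromosome with distance
    <= ``gap`` (edge-to-edge by default; overlap counts as 0) are matched
    one-to-one; matched peaks become ``shared_2kb``, the rest are
    tissue-specific. ``method="greedy"`` (default) pairs by increasing
    distance and is deterministic and near-optimal at realistic peak
    densities; ``method="optimal"`` computes the maximum-cardinality,
    minimum-total-distance matching. The two can differ on dense pile-ups
    where a greedy nearest pair blocks two other feasible pairs.

    Callers are expected to restrict the inputs to enhancer-class peaks of
    commonly bound genes before subdividing.
    """
    if gap < 0:
        raise ValueError(f"gap must be non-negative, got {gap}")
    if method not in ("greedy", "optimal"):
        raise ValueError(f"method must be 'greedy' or 'optimal', got {method!r}")
    candidates = []
    by_chrom_b: dict[str, list[Peak]] = {}
    for b in peaks_b:
        by_chrom_b.setdefault(b.chrom, []).append(b)
    for chrom_peaks in by_chrom_b.values():
        chrom_peaks.sort(key=lambda p: p.interval.start)
    for a in peaks_a:
        group = by_chrom_b.get(a.chrom, ())
        for b in group:
            # prune with edge distance, which lower-bounds both metrics
            if b.interval.start - a.interval.end > gap:
                break
            d = _pair_distance(a, b, distance)
            if d is not None and d <= gap:
                candidates.append((d, a.id, b.id))
    used_a: set[str] = set()
    used_b: set[str] = set()
    partner: dict[str, str] = {}
    if method == "greedy":
        candidates.sort()
        for d, aid, bid in candidates:
            if aid in used_a or bid in used_b:
                continue
            used_a.add(aid)
            used_b.add(bid)
            partner[aid] = bid
            partner[bid] = aid
    elif candidates:
        from scipy.optimize import linear_sum_assignment

        ids_a = sorted({aid for _, aid, _ in candidates})
        ids_b = sorted({bid for _, _, bid in candidates})
        ia = {aid: i for i, aid in enumerate(ids_a)}
        ib = {bid: j for j, bid in enumerate(ids_b)}
        BIG = 1e12  # any infeasible assignment dominates all feasible costs
        cost = np.full((len(ids_a), len(ids_b)), BIG)
        for d, aid, bid in candidates:
            cost[ia[aid], ib[bid]] = d
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < BIG:
                aid, bid = ids_a[i], ids_b[j]
                used_a.add(aid)
                used_b.add(bid)
                partner[aid] = bid
                partner[bid] = aid
    out = []
    for a in peaks_a:
        if a.id in used_a:
            out.append(PeakSubdivision(a.id, "shared_2kb", partner[a.id]))
        else:
            out.append(PeakSubdivision(a.id, f"{tissue_a}_only"))
    for b in peaks_b:
        if b.id in used_b:
            out.append(PeakSubdivision(b.id, "shared_2kb", partner[b.id]))
        else:
            out.append(PeakSubdivision(b.id, f"{tissue_b}_only"))
    return out


def subdivision_to_frame(subdivisions: Iterable[PeakSubdivision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peak_id": s.peak_id,
                "category": s.category,
                "partner_peak_id": s.partner_peak_id,
            }
            for s in subdivisions
        ],
        columns=["peak_id", "category", "partner_peak_id"],
    )


def tissue_specific_fraction(subdivisions: Sequence[PeakSubdivision]) -> float:
    """Fraction of peaks not part of a shared pair."""
    if not subdivisions:
        return float("nan")
    specific = sum(1 for s in subdivisions if s.category != "shared_2kb")
    return specific / len(subdivisions)


# ---------------------------------------------------------------------------
# Occupancy matrix, correlation and PCA surrogate
# ---------------------------------------------------------------------------

def occupancy_matrix(
    peak_sets: Mapping[str, Sequence[Peak]], use_scores: bool = False
) -> pd.DataFrame:
    """Consensus-region x sample occupancy matrix.

    Consensus regions are the union of all peaks merged at overlap. Entry
    (r, s) is 1 when sample ``s`` has a peak overlapping region ``r`` (or
    the maximum overlapping peak score with ``use_scores``).
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least two peak sets")
    all_intervals = [p.interval for peaks in peak_sets.values() for p in peaks]
    if not all_intervals:
        raise ValueError("no peaks in any set")
    regions = merge_intervals(all_intervals)
    index = [f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    data = np.zeros((len(regions), len(peak_sets)))
    region_pos: dict[str, list[tuple[int, int, int]]] = {}
    for i, r in enumerate(regions):
        region_pos.setdefault(r.chrom, []).append((r.start, r.end, i))
    for j, (sample, peaks) in enumerate(peak_sets.items()):
        for p in peaks:
            for start, end, i in region_pos.get(p.chrom, ()):
                if p.interval.start < end and start < p.interval.end:
                    value = p.score if use_scores else 1.0
                    data[i, j] = max(data[i, j], value)
    return pd.DataFrame(data, index=index, columns=list(peak_sets.keys()))


def sample_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of samples (columns); unit diagonal.

    Columns with zero variance yield NaN correlations (undefined, not 0).
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 regions")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    n = X.shape[1]
    corr = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if sd[i] > 0 and sd[j] > 0:
                corr[i, j] = float(np.dot(Xc[:, i], Xc[:, j]) / (len(X) * sd[i] * sd[j]))
    for i in range(n):
        if sd[i] > 0:
            corr[i, i] = 1.0
    return pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)


def pca_scores(matrix: pd.DataFrame, n_components: int = 2):
    """PCA of samples over consensus regions.

    Samples (columns of the occupancy matrix) are the observations; the
    matrix is centered over samples internally. Returns ``(scores,
    explained)`` where scores is a samples x components frame and
    ``explained`` the explained-variance fractions. The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    n_samples, n_features = matrix.shape[1], matrix.shape[0]
    if n_components > min(n_samples, n_features):
        raise ValueError(
            f"n_components={n_components} exceeds min(dims)={min(n_samples, n_features)}"
        )
    X = matrix.to_numpy(dtype=float).T  # samples x regions
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(len(S)):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U[:, :n_components] * S[:n_components]
    total_var = float(np.sum(S**2))
    explained = (S[:n_components] ** 2 / total_var) if total_var > 0 else np.zeros(n_components)
    frame = pd.DataFrame(
        scores,
        index=matrix.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return frame, explained
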