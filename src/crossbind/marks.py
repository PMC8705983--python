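"""Histone-mark coverage over peaks and the four-way cross-tissue class.

For tissue-specific TF peaks the classifier asks which of H3K27ac (active)
or H3K27me3 (repressive, Polycomb) covers the peak in its own (focal)
tissue, and whether the same mark is present in the other tissue:

* active in focal tissue, active in the other     -> ``active_shared``
* active in focal tissue only                     -> ``active_focal_only``
* repressed in focal tissue, repressed in other   -> ``repressed_shared``
* repressed in focal tissue only                  -> ``repressed_focal_only``
* neither mark, or both marks, in the focal tissue -> ``unclassified``

"Covered" means the coverage fraction of the peak reaches a threshold
(default 0.25 of the peak length).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, Peak, merge_intervals

H3K27AC = "H3K27ac"
H3K27ME3 = "H3K27me3"

CLASSES = (
    "active_shared",
    "active_focal_only",
    "repressed_shared",
    "repressed_focal_only",
    "unclassified",
)


@dataclass
class MarkTrack:
    """Interval track for one histone mark in one tissue (merged on init)."""

    mark: str
    tissue: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def covered_bases(self, interval: GenomicInterval) -> int:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return 0
        total = 0
        for hit in tree.overlap(interval.start, interval.end):
            total += min(hit.end, interval.end) - max(hit.begin, interval.start)
        return total  # merged intervals are disjoint, so no double counting


def coverage_fraction(peak: Peak, track: MarkTrack) -> float:
    """Fraction of the peak interval covered by the (merged) track."""
    length = len(peak.interval)
    if length <= 0:
        raise ValueError("zero-length peak")
    return track.covered_bases(peak.interval) / length


def classify_from_booleans(
    ac_focal: bool, me3_focal: bool, ac_other: bool, me3_other: bool
) -> str:
    """Cross-tissue class from the four 'marked' booleans."""
    if ac_focal and not me3_focal:
        return "active_shared" if ac_other else "active_focal_only"
    if me3_focal and not ac_focal:
        return "repressed_shared" if me3_other else "repressed_focal_only"
    return "unclassified"  # neither mark, or bivalent, in the focal tissue


def classify_cross_tissue(
    peaks: Sequence[Peak],
    tracks: Mapping[tuple[str, str], MarkTrack],
    focal_tissue: str,
    other_tissue: str,
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Classify focal-tissue-specific peaks by cross-tissue mark status.

    ``tracks`` maps ``(mark, tissue)`` to its MarkTrack for both marks in
    both tissues. Returns per-peak coverage fractions, marked booleans and
    the class.
    """
    required = [
        (H3K27AC, focal_tissue),
        (H3K27ME3, focal_tissue),
        (H3K27AC, other_tissue),
        (H3K27ME3, other_tissue),
    ]
    for key in required:
        if key not in tracks:
            raise KeyError(f"missing mark track for (mark, tissue) = {key}")
    rows = []
    for p in peaks:
        cov = {key: coverage_fraction(p, tracks[key]) for key in required}
        marked = {key: cov[key] >= threshold for key in required}
        cls = classify_from_booleans(
            marked[(H3K27AC, focal_tissue)],
            marked[(H3K27ME3, focal_tissue)],
            marked[(H3K27AC, other_tissue)],
            marked[(H3K27ME3, other_tissue)],
        )
        rows.append(
            {
                "peak_id": p.id,
                "cov_ac_focal": cov[(H3K27AC, focal_tissue)],
                "cov_me3_focal": cov[(H3K27ME3, focal_tissue)],
                "cov_ac_other": cov[(H3K27AC, other_tissue)],
                "cov_me3_other": cov[(H3K27ME3, other_tissue)],
                "mark_class": cls,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "cov_ac_focal",
            "cov_me3_focal",
            "cov_ac_other",
            "cov_me3_other",
            "mark_class",
        ],
    )


def aggregate_mark_profile(
    peaks: Sequence[Peak],
    track: MarkTrack,
    flank: int = 2000,
    n_bins: int = 40,
    chrom_lengths: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Mean per-bin coverage in a window of ``+-flank`` around peak centers.

    Strand-agnostic. Windows clipped at position 0 (and at the chromosome
    end when ``chrom_lengths`` is given) contribute only their available
    bases; each bin is normalized by the bases actually averaged.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    covered = np.zeros(n_bins)
    available = np.zeros(n_bins)
    edges = np.linspace(-flank, flank, n_bins + 1)
    for p in peaks:
        center = p.representative_point
        limit = chrom_lengths.get(p.chrom) if chrom_lengths else None
        for b in range(n_bins):
            lo = center + int(edges[b])
            hi = center + int(edges[b + 1])
            lo_c = max(lo, 0)
            hi_c = min(hi, limit) if limit is not None else hi
            if hi_c <= lo_c:
                continue
            span = GenomicInterval(p.chrom, lo_c, hi_c)
            covered[b] += track.covered_bases(span)
            available[b] += hi_c - lo_c
    with np.errstate(invalid="ignore"):
        profile = np.where(available > 0, covered / np.maximum(available, 1), 0.0)
    return profile
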