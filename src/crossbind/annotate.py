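"""Peak-to-gene association and genomic-location classification.

A peak is represented by a single point (summit if present, else floor of
the midpoint) and classified relative to gene models with the window scheme

* promoter:        strand-aware [TSS - 1000, TSS + 10], plus the 5' UTR
* distal enhancer: strand-aware [TSS - 2000, TSS - 1000), plus the 3' UTR,
                   plus a 1000 bp window downstream of the gene 3' end
* intron:          inside the gene body but in no exon
* other:           inside an exon and in none of the classes above
* intergenic:      none of the above

Labels of several genes are resolved by priority
promoter > distal_enhancer > intron > other > intergenic; among genes
giving the same priority the nearest TSS wins, remaining ties go to the
lexicographically smallest gene_id.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GeneModel, Peak

PROMOTER_UP = 1000
PROMOTER_DOWN = 10
DISTAL_UP = 2000
DOWNSTREAM_WINDOW = 1000


class LocationLabel(str, Enum):
    PROMOTER = "promoter"
    DISTAL_ENHANCER = "distal_enhancer"
    INTRON = "intron"
    OTHER = "other"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - display convenience
        return self.value


#: enhancer-class labels used for the cross-tissue peak subdivision
ENHANCER_LABELS = frozenset(
    {LocationLabel.DISTAL_ENHANCER, LocationLabel.INTRON, LocationLabel.INTERGENIC}
)

_PRIORITY = {
    LocationLabel.PROMOTER: 0,
    LocationLabel.DISTAL_ENHANCER: 1,
    LocationLabel.INTRON: 2,
    LocationLabel.OTHER: 3,
    LocationLabel.INTERGENIC: 4,
}


@dataclass(frozen=True)
class PeakGeneAssignment:
    """One (peak, gene) association with its strand-aware TSS distance."""

    peak_id: str
    gene_id: str | None
    distance_to_tss: int | None
    location: LocationLabel


def tss_offset(point: int, gene: GeneModel) -> int:
    """Signed strand-aware offset of a point from the TSS (negative = upstream)."""
    return point - gene.tss if gene.strand == "+" else gene.tss - point


def label_for_gene(point: int, gene: GeneModel) -> LocationLabel | None:
    """Location label of a point relative to one gene, or None if unrelated."""
    off = tss_offset(point, gene)
    if -PROMOTER_UP <= off <= PROMOTER_DOWN:
        return LocationLabel.PROMOTER
    if any(iv.contains(point) for iv in gene.utr5):
        return LocationLabel.PROMOTER
    if -DISTAL_UP <= off < -PROMOTER_UP:
        return LocationLabel.DISTAL_ENHANCER
    if any(iv.contains(point) for iv in gene.utr3):
        return LocationLabel.DISTAL_ENHANCER
    if gene.strand == "+":
        downstream = gene.interval.end <= point < gene.interval.end + DOWNSTREAM_WINDOW
    else:
        downstream = gene.interval.start - DOWNSTREAM_WINDOW <= point < gene.interval.start
    if downstream:
        return LocationLabel.DISTAL_ENHANCER
    if gene.interval.contains(point):
        if any(exon.contains(point) for exon in gene.exons):
            return LocationLabel.OTHER
        return LocationLabel.INTRON
    return None


class GeneIndex:
    """Chromosome-keyed interval index over genes with a query margin.

    The margin covers every window a gene projects around itself (promoter,
    distal, downstream) plus the nearest-TSS search radius, so a point query
    returns every gene that could possibly matter.
    """

    def __init__(self, genes: Iterable[GeneModel], margin: int = 12000):
        self.margin = margin
        self.trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self.trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.interval.start - margin, g.interval.end + margin, g)

    def query(self, chrom: str, point: int) -> list[GeneModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(point)), key=lambda g: g.gene_id)


def _best_label(point: int, candidates: Sequence[GeneModel]):
    """(label, gene) with highest priority; ties by |TSS distance| then id."""
    best = None
    for gene in candidates:
        label = label_for_gene(point, gene)
        if label is None:
            continue
        key = (_PRIORITY[label], abs(point - gene.tss), gene.gene_id)
        if best is None or key < best[0]:
            best = (key, label, gene)
    if best is None:
        return LocationLabel.INTERGENIC, None
    return best[1], best[2]


def classify_location(
    peak: Peak, genes: Sequence[GeneModel] | GeneIndex
) -> LocationLabel:
    """Single location label for a peak against a whole annotation."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    point = peak.representative_point
    candidates = index.query(peak.chrom, point)
    if not candidates and peak.chrom not in index.trees and index.trees:
        warnings.warn(f"peak {peak.id}: chromosome {peak.chrom!r} absent from annotation")
    label, _ = _best_label(point, candidates)
    return label


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel] | GeneIndex,
    flank_up: int = 2000,
    flank_down: int = 1000,
    max_tss_distance: int = 10000,
) -> list[PeakGeneAssignment]:
    """Associate peaks with genes.

    A peak is assigned to every gene whose flank-extended body (``flank_up``
    upstream, ``flank_down`` downstream, strand-aware) contains its
    representative point; failing that, to the gene with the nearest TSS
    within ``max_tss_distance``; otherwise it is reported unassigned
    (gene_id None). Each assignment carries the location label relative to
    its gene.
    """
    if isinstance(genes, GeneIndex):
        index = genes
    else:
        margin = max(12000, max_tss_distance + 2000)
        index = GeneIndex(genes, margin=margin)
    out: list[PeakGeneAssignment] = []
    for peak in peaks:
        point = peak.representative_point
        candidates = index.query(peak.chrom, point)
        containing = []
        for g in candidates:
            if g.strand == "+":
                lo, hi = g.interval.start - flank_up, g.interval.end + flank_down
            else:
                lo, hi = g.interval.start - flank_down, g.interval.end + flank_up
            if lo <= point < hi:
                containing.append(g)
        if containing:
            for g in containing:
                label = label_for_gene(point, g) or LocationLabel.INTERGENIC
                out.append(
                    PeakGeneAssignment(peak.id, g.gene_id, tss_offset(point, g), label)
                )
            continue
        nearest = None
        for g in candidates:
            key = (abs(point - g.tss), g.gene_id)
            if key[0] <= max_tss_distance and (nearest is None or key < nearest[0]):
                nearest = (key, g)
        if nearest is not None:
            g = nearest[1]
            label = label_for_gene(point, g) or LocationLabel.INTERGENIC
            out.append(
                PeakGeneAssignment(peak.id, g.gene_id, tss_offset(point, g), label)
            )
        else:
            label, _ = _best_label(point, candidates)
            out.append(PeakGeneAssignment(peak.id, None, None, label))
    return out


def assignments_to_frame(assignments: Iterable[PeakGeneAssignment]) -> pd.DataFrame:
    """Assignment table with columns peak_id, gene_id, distance_to_tss, location."""
    return pd.DataFrame(
        [
            {
                "peak_id": a.peak_id,
                "gene_id": a.gene_id,
                "distance_to_tss": a.distance_to_tss,
                "location": a.location.value,
            }
            for a in assignments
        ],
        columns=["peak_id", "gene_id", "distance_to_tss", "location"],
    )


def peak_labels(assignments: Iterable[PeakGeneAssignment]) -> dict[str, LocationLabel]:
    """Best (highest-priority) label per peak across its assignments."""
    best: dict[str, LocationLabel] = {}
    for a in assignments:
        if a.peak_id not in best or _PRIORITY[a.location] < _PRIORITY[best[a.peak_id]]:
            best[a.peak_id] = a.location
    return best
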