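"""Readers and writers for BED/narrowPeak, GTF and FASTA.

BED is consumed natively (0-based half-open); GTF coordinates (1-based,
inclusive) are converted to the internal convention on read and back on
write.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import GenomicInterval, GeneModel, Peak


class ParseError(ValueError):
    """Raised for malformed input lines; carries the file and line number."""


# ---------------------------------------------------------------------------
# BED / narrowPeak peaks
# ---------------------------------------------------------------------------

def read_peaks(
    path: str | Path,
    tissue: str = "",
    stage: str = "",
    id_prefix: str | None = None,
) -> list[Peak]:
    """Read peaks from BED3+ or narrowPeak.

    narrowPeak column 10 (0-based summit offset), when present and >= 0,
    becomes the peak summit. Peak ids come from the BED name column when
    present and unique, else are synthesized as ``<prefix>_<n>``.
    """
    path = Path(path)
    prefix = id_prefix if id_prefix is not None else (tissue or path.stem)
    records: list[tuple[str, int, int, str, float, str, int | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start ({start}, {end})")
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else ""
            score = 0.0
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = max(0.0, float(fields[4]))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            summit: int | None = None
            if len(fields) >= 10:  # narrowPeak
                try:
                    s = int(fields[9])
                except ValueError:
                    s = -1
                if 0 <= s < end - start:
                    summit = s
            records.append((chrom, start, end, name, score, strand, summit))

    names = [r[3] for r in records]
    unique = all(names) and len(set(names)) == len(names)
    peaks = []
    for i, (chrom, start, end, name, score, strand, summit) in enumerate(records):
        pid = name if unique else f"{prefix}_{i}"
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, end, strand),
                id=pid,
                tissue=tissue,
                stage=stage,
                score=score,
                summit=summit,
            )
        )
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path, name_field: str = "id") -> None:
    """Write peaks as BED6 (+ summit column when any peak has one).

    ``name_field`` selects what goes into the BED name column (an attribute
    name on Peak, e.g. ``"id"``).
    """
    peaks = list(peaks)
    has_summit = any(p.summit is not None for p in peaks)
    with open(path, "w") as fh:
        for p in peaks:
            name = str(getattr(p, name_field))
            row = [
                p.chrom,
                str(p.interval.start),
                str(p.interval.end),
                name,
                f"{p.score:g}",
                p.interval.strand,
            ]
            if has_summit:
                # pad to narrowPeak geometry so column 10 is the summit
                row += ["-1", "-1", "-1", str(p.summit if p.summit is not None else -1)]
            fh.write("\t".join(row) + "\n")


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a plain BED3+ file as bare intervals (for mark tracks)."""
    return [p.interval for p in read_peaks(path, id_prefix="iv")]


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

def _gtf_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, value = chunk.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF (gene/exon/UTR features).

    GTF 1-based inclusive coordinates become 0-based half-open. A gene with
    no exon features gets its body as a single exon (with a warning); genes
    with unknown strand are rejected.
    """
    path = Path(path)
    bodies: dict[str, tuple[str, int, int, str]] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    utr5: dict[str, list[GenomicInterval]] = {}
    utr3: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attr = fields[:9]
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            gene_id = _gtf_attributes(attr).get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                if strand not in ("+", "-"):
                    raise ParseError(
                        f"{path}:{lineno}: gene {gene_id} has unknown strand {strand!r}"
                    )
                bodies[gene_id] = (chrom, start, end, strand)
                order.append(gene_id)
            elif feature == "exon":
                exons.setdefault(gene_id, []).append(GenomicInterval(chrom, start, end, strand if strand in "+-" else "."))
            elif feature in ("five_prime_utr", "5UTR"):
                utr5.setdefault(gene_id, []).append(GenomicInterval(chrom, start, end))
            elif feature in ("three_prime_utr", "3UTR"):
                utr3.setdefault(gene_id, []).append(GenomicInterval(chrom, start, end))

    genes = []
    for gene_id in order:
        chrom, start, end, strand = bodies[gene_id]
        body = GenomicInterval(chrom, start, end, strand)
        gene_exons = sorted(exons.get(gene_id, []), key=lambda iv: iv.start)
        if not gene_exons:
            warnings.warn(f"gene {gene_id} has no exons; using body as single exon")
            gene_exons = [body]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=body,
                strand=strand,
                exons=tuple(gene_exons),
                utr5=tuple(sorted(utr5.get(gene_id, []), key=lambda iv: iv.start)),
                utr3=tuple(sorted(utr3.get(gene_id, []), key=lambda iv: iv.start)),
            )
        )
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path, source: str = "crossbind") -> None:
    """Write gene models as GTF (gene + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attr = f'gene_id "{g.gene_id}";'
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        source,
                        "gene",
                        str(g.interval.start + 1),
                        str(g.interval.end),
                        ".",
                        g.strand,
                        ".",
                        attr,
                    ]
                )
                + "\n"
            )
            for exon in g.exons:
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            g.strand,
                            ".",
                            attr,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read an (uncompressed) FASTA into a dict of upper-case sequences."""
    from Bio import SeqIO

    return {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }


def extract_sequences(
    fasta: dict[str, str], peaks: Sequence[Peak]
) -> dict[str, str]:
    """Extract peak sequences (forward strand) keyed by peak id."""
    out = {}
    for p in peaks:
        seq = fasta[p.chrom][p.interval.start : p.interval.end]
        out[p.id] = seq
    return out
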