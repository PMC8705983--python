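"""Synthetic genome / peak / motif / mark generator with a truth manifest.

The generator emulates the study design the analysis modules expect: a
multi-chromosome toy genome with non-overlapping multi-exon genes, two
tissue peak sets with controlled common / tissue-specific gene proportions
and per-gene peak multiplicities, cross-tissue peak pairs planted within
2 kb, motif instances embedded at controlled rates per peak category, and
histone-mark tracks realizing the four cross-tissue coverage classes.
Everything is deterministic under the configured seed, and every planted
fact is recorded in a machine-readable truth manifest that downstream
parameter-recovery tests read back.

Default proportions mirror the study's printed values: a 35/29/36 gene
split between commonly and specifically bound genes, ~90% of common genes
bound multiple times, and ~75% of common-gene enhancer peaks specific to
one tissue (shared fraction 0.25). The background is AT-rich (0.3/0.2/0.2/
0.3) to stress AT-rich motif discovery.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from bisect import bisect_left, insort
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .intervals import GenomicInterval, GeneModel, Peak
from .io import write_fasta, write_genes, write_intervals, write_peaks
from .marks import H3K27AC, H3K27ME3, MarkTrack
from .motifs import BASES, PWM, hox_classical_pwm, hox_divergent_pwm, reverse_complement

CATEGORIES = ("common", "A_specific", "B_specific")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 22_000_000
    n_genes: int = 2000
    exon_count_range: tuple[int, int] = (4, 5)
    exon_length_range: tuple[int, int] = (150, 250)
    intron_length_range: tuple[int, int] = (5800, 6400)
    intergenic_gap_range: tuple[int, int] = (13_400, 16_000)
    # gene-category proportions: common, tissue-A-specific, tissue-B-specific
    category_props: tuple[float, float, float] = (0.35, 0.29, 0.36)
    single_peak_fraction_common: float = 0.10
    single_peak_fraction_specific: float = 0.375
    multi_peak_range: tuple[int, int] = (2, 4)
    shared_2kb_fraction: float = 0.25
    peak_width_range: tuple[int, int] = (150, 400)
    promoter_fraction_specific_single: float = 0.7
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    tissue_a: str = "mesoderm"
    tissue_b: str = "neuronal"
    stage: str = "10-13"
    # motif-embedding rates per subdivision category
    classical_motif_rate: float = 0.7  # B_only and shared_2kb peaks
    divergent_motif_rate: float = 0.7  # A_only peaks
    # fraction of tissue-specific peaks carrying the active (H3K27ac) mark;
    # the rest carry the repressive (H3K27me3) mark
    mark_active_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.category_props), 1.0):
            raise ValueError("category_props must sum to 1")
        for name in (
            "single_peak_fraction_common",
            "single_peak_fraction_specific",
            "shared_2kb_fraction",
            "classical_motif_rate",
            "divergent_motif_rate",
            "mark_active_fraction",
            "promoter_fraction_specific_single",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "exon_count_range",
            "exon_length_range",
            "intron_length_range",
            "intergenic_gap_range",
            "multi_peak_range",
            "peak_width_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"{name} must be a non-empty positive range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class Simulation:
    """Generated data plus the truth manifest."""

    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    peaks_a: list[Peak]
    peaks_b: list[Peak]
    mark_tracks: dict[tuple[str, str], MarkTrack]
    manifest: dict


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, comp: Sequence[float]) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(comp, float)).astype(np.int8)


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], list[GeneModel]]:
    """Random genome (as base-code arrays) with placed multi-exon genes."""
    codes: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    gene_no = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        codes[chrom] = _random_sequence(
            rng, config.chromosome_length, config.base_composition
        )
        pos = 0
        for _ in range(per_chrom[c]):
            gap = int(rng.integers(*config.intergenic_gap_range, endpoint=True))
            n_exons = int(rng.integers(*config.exon_count_range, endpoint=True))
            exon_lens = rng.integers(
                *config.exon_length_range, size=n_exons, endpoint=True
            )
            intron_lens = rng.integers(
                *config.intron_length_range, size=n_exons - 1, endpoint=True
            )
            body_len = int(exon_lens.sum() + intron_lens.sum())
            start = pos + gap
            if start + body_len > config.chromosome_length:
                raise ValueError(
                    f"cannot place {per_chrom[c]} genes on {chrom}: "
                    "increase chromosome_length or shrink genes/gaps"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            cursor = start
            for j in range(n_exons):
                exons.append(
                    GenomicInterval(chrom, cursor, cursor + int(exon_lens[j]), strand)
                )
                cursor += int(exon_lens[j])
                if j < n_exons - 1:
                    cursor += int(intron_lens[j])
            gene_no += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gene_no:05d}",
                    interval=GenomicInterval(chrom, start, start + body_len, strand),
                    strand=strand,
                    exons=tuple(exons),
                )
            )
            pos = start + body_len
    return codes, genes


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

SLOT_WIDTH = 3000
INTERGENIC_NEAR = 2500  # slot inner edge, beyond the distal-enhancer window
INTERGENIC_FAR = 5500


def _gene_slots(gene: GeneModel, chrom_len: int) -> list[tuple[int, int, str]]:
    """Enhancer-class placement slots: one per (wide) intron + one upstream
    intergenic slot. Slots are mutually > 2 kb apart by construction: an
    intron hosts a slot only when the slot margins on both sides exceed
    1 kb, so peaks in adjacent slots stay > 2 kb apart."""
    slots = []
    for intron in gene.introns:
        if len(intron) >= SLOT_WIDTH + 2000:
            off = (len(intron) - SLOT_WIDTH) // 2
            slots.append((intron.start + off, intron.start + off + SLOT_WIDTH, "intron"))
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss - INTERGENIC_FAR, tss - INTERGENIC_NEAR
    else:
        lo, hi = tss + INTERGENIC_NEAR, tss + INTERGENIC_FAR
    if lo >= 0 and hi <= chrom_len:
        slots.append((lo, hi, "intergenic"))
    return slots


def _point_peak(
    gene: GeneModel, offset: int, width: int, chrom_len: int
) -> tuple[int, int]:
    """Peak interval whose midpoint sits at the given strand-aware TSS offset."""
    point = gene.tss + offset if gene.strand == "+" else gene.tss - offset
    start = max(0, point - width // 2)
    end = min(chrom_len, start + width)
    return start, end


def simulate_peaks(
    config: SimulationConfig, genes: Sequence[GeneModel], rng: np.random.Generator
) -> tuple[list[Peak], list[Peak], dict]:
    """Two tissue peak sets and the per-gene/per-peak truth records."""
    a_only_cat = f"{config.tissue_a}_only"
    b_only_cat = f"{config.tissue_b}_only"
    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []
    gene_truth: dict[str, dict] = {}
    peak_truth: dict[str, dict] = {}
    counters = {config.tissue_a: 0, config.tissue_b: 0}
    chrom_len = config.chromosome_length

    def new_peak(tissue: str, gene: GeneModel, start: int, end: int,
                 location: str, subdivision: str | None, partner: str | None = None) -> Peak:
        counters[tissue] += 1
        pid = f"{tissue}_{counters[tissue]:05d}"
        peak = Peak(
            interval=GenomicInterval(gene.chrom, start, end),
            id=pid,
            tissue=tissue,
            stage=config.stage,
            score=float(np.round(rng.uniform(50, 1000), 1)),
        )
        (peaks_a if tissue == config.tissue_a else peaks_b).append(peak)
        peak_truth[pid] = {
            "tissue": tissue,
            "gene": gene.gene_id,
            "location": location,
            "subdivision": subdivision,
            "partner": partner,
            "motif": None,
            "mark_class": None,
        }
        return peak

    def place_single(tissue: str, gene: GeneModel, location: str) -> None:
        width = int(rng.integers(*config.peak_width_range, endpoint=True))
        if location == "promoter":
            offset = int(rng.integers(-800, 1))
        else:  # distal_enhancer
            offset = int(rng.integers(-1900, -1099))
        start, end = _point_peak(gene, offset, width, chrom_len)
        new_peak(tissue, gene, start, end, location, None)

    def place_in_slot(tissue: str, gene: GeneModel, slot, subdivision) -> None:
        lo, hi, kind = slot
        width = int(rng.integers(*config.peak_width_range, endpoint=True))
        start = int(rng.integers(lo, hi - width))
        new_peak(tissue, gene, start, start + width, kind, subdivision)

    def place_pair(gene: GeneModel, slot) -> None:
        lo, hi, kind = slot
        wa = int(rng.integers(*config.peak_width_range, endpoint=True))
        wb = int(rng.integers(*config.peak_width_range, endpoint=True))
        gap = int(rng.integers(-100, 1900))
        extent = wa + max(gap, 0) + wb if gap >= 0 else max(wa, wa + gap + wb)
        start_a = int(rng.integers(lo, hi - extent))
        start_b = start_a + wa + gap
        pa = new_peak(config.tissue_a, gene, start_a, start_a + wa, kind, "shared_2kb")
        pb = new_peak(
            config.tissue_b, gene, start_b, start_b + wb, kind, "shared_2kb", pa.id
        )
        peak_truth[pa.id]["partner"] = pb.id

    for gene in genes:
        cat = CATEGORIES[rng.choice(3, p=np.asarray(config.category_props))]
        slots = _gene_slots(gene, chrom_len)
        rng.shuffle(slots)
        if cat == "common":
            single = rng.random() < config.single_peak_fraction_common
            if single:
                place_single(config.tissue_a, gene, "promoter")
                place_single(config.tissue_b, gene, "promoter")
                na = nb = 1
            else:
                na = int(rng.integers(*config.multi_peak_range, endpoint=True))
                nb = int(rng.integers(*config.multi_peak_range, endpoint=True))
                # clamp counts to slot capacity BEFORE drawing shared pairs,
                # so the realized shared fraction stays at the configured
                # value (a pair occupies a single slot)
                while na + nb > len(slots) and na + nb > 2:
                    if nb >= na and nb > 1:
                        nb -= 1
                    elif na > 1:
                        na -= 1
                    else:
                        break
                q = min(
                    1.0,
                    config.shared_2kb_fraction * (na + nb) / (2.0 * min(na, nb)),
                )
                pairs = int(rng.binomial(min(na, nb), q))
                a_only = na - pairs
                b_only = nb - pairs
                it = iter(slots)
                for _ in range(pairs):
                    place_pair(gene, next(it))
                for _ in range(a_only):
                    place_in_slot(config.tissue_a, gene, next(it), a_only_cat)
                for _ in range(b_only):
                    place_in_slot(config.tissue_b, gene, next(it), b_only_cat)
            gene_truth[gene.gene_id] = {
                "category": "common",
                "binding": "single" if single else "multi",
                "n_peaks": {config.tissue_a: na, config.tissue_b: nb},
            }
        else:
            tissue = config.tissue_a if cat == "A_specific" else config.tissue_b
            single = rng.random() < config.single_peak_fraction_specific
            if single:
                loc = (
                    "promoter"
                    if rng.random() < config.promoter_fraction_specific_single
                    else "distal_enhancer"
                )
                place_single(tissue, gene, loc)
                n = 1
            else:
                n = int(rng.integers(*config.multi_peak_range, endpoint=True))
                n = min(n, len(slots))
                for k in range(n):
                    place_in_slot(tissue, gene, slots[k], None)
            gene_truth[gene.gene_id] = {
                "category": cat,
                "binding": "single" if single else "multi",
                "n_peaks": {
                    tissue: n,
                    (config.tissue_b if tissue == config.tissue_a else config.tissue_a): 0,
                },
            }
    truth = {"genes": gene_truth, "peaks": peak_truth}
    return peaks_a, peaks_b, truth


# ---------------------------------------------------------------------------
# Motif embedding
# ---------------------------------------------------------------------------

def _sample_instance(
    pwm: PWM, rng: np.random.Generator, min_score_fraction: float = 0.6
) -> str:
    """Draw a motif instance from the PWM, resampling until it scores at
    least ``min_score_fraction`` of the maximum log-odds (a planted site
    should be a functional one, not a low-probability outlier)."""
    lo = pwm.log_odds
    floor = min_score_fraction * pwm.max_score
    instance = pwm.consensus
    for _ in range(50):
        draws = [int(rng.choice(4, p=col / col.sum())) for col in pwm.matrix]
        if sum(lo[j, b] for j, b in enumerate(draws)) >= floor:
            instance = "".join(BASES[b] for b in draws)
            break
    return instance


def embed_motifs(
    codes: dict[str, np.ndarray],
    peaks: Sequence[Peak],
    peak_truth: dict[str, dict],
    config: SimulationConfig,
    rng: np.random.Generator,
    classical: PWM | None = None,
    divergent: PWM | None = None,
) -> None:
    """Plant motif instances into peak sequences (mutates ``codes``).

    Classical-motif instances go into shared and tissue-B-only peaks,
    divergent instances into tissue-A-only peaks, each at the configured
    rate; plants never overlap one another (offsets are re-drawn, with an
    error after 100 tries). The exact planted instance, offset and strand
    are recorded in the peak truth records.
    """
    classical = classical or hox_classical_pwm()
    divergent = divergent or hox_divergent_pwm()
    b_only_cat = f"{config.tissue_b}_only"
    a_only_cat = f"{config.tissue_a}_only"
    planted: dict[str, list[int]] = {}  # chrom -> sorted plant starts
    plant_ends: dict[str, dict[int, int]] = {}

    def collides(chrom: str, start: int, end: int) -> bool:
        starts = planted.get(chrom, [])
        i = bisect_left(starts, start)
        for j in (i - 1, i):
            if 0 <= j < len(starts):
                s = starts[j]
                e = plant_ends[chrom][s]
                if s < end and start < e:
                    return True
        return False

    for peak in peaks:
        truth = peak_truth[peak.id]
        sub = truth["subdivision"]
        if sub == a_only_cat:
            pwm, rate = divergent, config.divergent_motif_rate
        elif sub in ("shared_2kb", b_only_cat):
            pwm, rate = classical, config.classical_motif_rate
        else:
            continue
        if rng.random() >= rate:
            continue
        width = pwm.width
        if width >= len(peak.interval):
            continue
        instance = _sample_instance(pwm, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        written = instance if strand == "+" else reverse_complement(instance)
        arr = codes[peak.chrom]
        for _ in range(100):
            offset = int(rng.integers(0, len(peak.interval) - width + 1))
            abs_start = peak.interval.start + offset
            if not collides(peak.chrom, abs_start, abs_start + width):
                break
        else:
            raise RuntimeError(f"could not place motif in peak {peak.id} without overlap")
        arr[abs_start : abs_start + width] = [
            "ACGT".index(ch) for ch in written
        ]
        insort(planted.setdefault(peak.chrom, []), abs_start)
        plant_ends.setdefault(peak.chrom, {})[abs_start] = abs_start + width
        truth["motif"] = {
            "name": pwm.name,
            "offset": offset,
            "strand": strand,
            "instance": instance,
        }


# ---------------------------------------------------------------------------
# Marks
# ---------------------------------------------------------------------------

def simulate_marks(
    config: SimulationConfig,
    peaks: Sequence[Peak],
    peak_truth: dict[str, dict],
    rng: np.random.Generator,
) -> dict[tuple[str, str], MarkTrack]:
    """Mark tracks realizing the four cross-tissue classes at coverage 1.

    Tissue-A-specific peaks are split between ``active_shared`` (H3K27ac in
    both tissues) and ``repressed_focal_only`` (H3K27me3 in A only);
    tissue-B-specific peaks between ``active_focal_only`` (H3K27ac in B
    only) and ``repressed_shared`` (H3K27me3 in both). No bivalent plants.
    """
    a_only_cat = f"{config.tissue_a}_only"
    b_only_cat = f"{config.tissue_b}_only"
    intervals: dict[tuple[str, str], list[GenomicInterval]] = {
        (H3K27AC, config.tissue_a): [],
        (H3K27AC, config.tissue_b): [],
        (H3K27ME3, config.tissue_a): [],
        (H3K27ME3, config.tissue_b): [],
    }
    for peak in peaks:
        truth = peak_truth[peak.id]
        sub = truth["subdivision"]
        if sub not in (a_only_cat, b_only_cat):
            continue
        active = rng.random() < config.mark_active_fraction
        iv = peak.interval
        if sub == a_only_cat:
            if active:
                truth["mark_class"] = "active_shared"
                intervals[(H3K27AC, config.tissue_a)].append(iv)
                intervals[(H3K27AC, config.tissue_b)].append(iv)
            else:
                truth["mark_class"] = "repressed_focal_only"
                intervals[(H3K27ME3, config.tissue_a)].append(iv)
        else:
            if active:
                truth["mark_class"] = "active_focal_only"
                intervals[(H3K27AC, config.tissue_b)].append(iv)
            else:
                truth["mark_class"] = "repressed_shared"
                intervals[(H3K27ME3, config.tissue_b)].append(iv)
                intervals[(H3K27ME3, config.tissue_a)].append(iv)
    return {key: MarkTrack(key[0], key[1], ivs) for key, ivs in intervals.items()}


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------

_CODE_TO_BASE = np.array(list("ACGT"))
_CODE_TO_BYTE = np.frombuffer(b"ACGT", dtype=np.uint8)


def codes_to_string(arr: np.ndarray) -> str:
    return _CODE_TO_BYTE[arr].tobytes().decode("ascii")


def simulate(config: SimulationConfig) -> Simulation:
    """Run the whole generator under one seed and assemble the manifest."""
    rng = np.random.default_rng(config.seed)
    codes, genes = simulate_genome(config, rng)
    peaks_a, peaks_b, truth = simulate_peaks(config, genes, rng)
    embed_motifs(codes, peaks_a + peaks_b, truth["peaks"], config, rng)
    mark_tracks = simulate_marks(config, peaks_a + peaks_b, truth["peaks"], rng)
    genome = {chrom: codes_to_string(arr) for chrom, arr in codes.items()}
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "tissues": [config.tissue_a, config.tissue_b],
        "genes": truth["genes"],
        "peaks": truth["peaks"],
    }
    return Simulation(
        config=config,
        genome=genome,
        genes=genes,
        peaks_a=peaks_a,
        peaks_b=peaks_b,
        mark_tracks=mark_tracks,
        manifest=manifest,
    )


def write_fixture(sim: Simulation, outdir: str | Path, overwrite: bool = False) -> dict:
    """Write all fixture files; returns a path index (also saved as YAML).

    Refuses a non-empty output directory unless ``overwrite`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {outdir} is not empty")
    cfg = sim.config
    paths = {
        "genome_fasta": str(outdir / "genome.fa"),
        "genes_gtf": str(outdir / "genes.gtf"),
        "peaks": {
            cfg.tissue_a: str(outdir / f"peaks_{cfg.tissue_a}.bed"),
            cfg.tissue_b: str(outdir / f"peaks_{cfg.tissue_b}.bed"),
        },
        "marks": {},
        "manifest": str(outdir / "manifest.json"),
        "config": str(outdir / "config.yaml"),
    }
    write_fasta(sim.genome, paths["genome_fasta"])
    write_genes(sim.genes, paths["genes_gtf"])
    write_peaks(sim.peaks_a, paths["peaks"][cfg.tissue_a])
    write_peaks(sim.peaks_b, paths["peaks"][cfg.tissue_b])
    for (mark, tissue), track in sim.mark_tracks.items():
        p = str(outdir / f"{mark}_{tissue}.bed")
        paths["marks"][f"{mark}:{tissue}"] = p
        write_intervals(track.intervals, p)
    with open(paths["manifest"], "w") as fh:
        json.dump(sim.manifest, fh, indent=1)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# Small focused generators for targeted experiments
# ---------------------------------------------------------------------------

def random_sequences(
    n: int, length: int, rng: np.random.Generator,
    composition: Sequence[float] = (0.3, 0.2, 0.2, 0.3),
) -> list[str]:
    comp = np.asarray(composition, float)
    return [
        "".join(_CODE_TO_BASE[rng.choice(4, size=length, p=comp)]) for _ in range(n)
    ]


def affinity_contrast_groups(
    n_per_group: int = 100,
    length: int = 300,
    seed: int = 0,
    mismatches: int = 2,
) -> tuple[list[str], list[str], str, str]:
    """Sequences embedding the classical consensus vs a divergent variant.

    Returns (consensus_group, variant_group, consensus, variant) where the
    variant differs from the classical consensus at ``mismatches``
    positions. Used for the high- vs low-affinity contrast experiment.
    """
    rng = np.random.default_rng(seed)
    consensus = hox_classical_pwm().consensus
    positions = rng.choice(len(consensus), size=mismatches, replace=False)
    variant = list(consensus)
    for pos in positions:
        others = [b for b in BASES if b != variant[pos]]
        variant[pos] = others[rng.integers(3)]
    variant = "".join(variant)
    groups = []
    for instance in (consensus, variant):
        seqs = []
        for s in random_sequences(n_per_group, length, rng):
            off = int(rng.integers(0, length - len(instance) + 1))
            seqs.append(s[:off] + instance + s[off + len(instance):])
        groups.append(seqs)
    return groups[0], groups[1], consensus, variant
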