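"""Config-driven end-to-end orchestration.

Stages hand data to one another through files in the output directory
(TSV/BED/JSON), so each stage can also be run alone from the CLI once its
predecessors have written their outputs:

1. annotate  — peak-gene assignment tables per tissue
2. compare   — gene categories, binding frequency, 2 kb subdivision,
               occupancy matrix, correlation, PCA
3. motifs    — enrichment per subdivision category, de novo discovery
4. affinity  — PSAM scores per category, rank-sum tests
5. marks     — cross-tissue histone-mark classification

``run_full_analysis`` executes all five and writes ``summary.json``.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    ENHANCER_LABELS,
    GeneIndex,
    LocationLabel,
    assign_peaks_to_genes,
    assignments_to_frame,
    peak_labels,
)
from .affinity import (
    compare_affinity_distributions,
    psam_from_pwm,
    rank_results_to_frame,
    read_psam_tsv,
    score_sequences,
)
from .compare import (
    binding_frequency,
    categorize_genes,
    category_percentages,
    occupancy_matrix,
    pca_scores,
    sample_correlation,
    subdivide_common_peaks,
    subdivision_to_frame,
    tissue_specific_fraction,
)
from .intervals import Peak
from .io import read_fasta, read_genes, read_intervals, read_peaks, write_peaks
from .marks import MarkTrack, classify_cross_tissue
from .motifs import (
    discover_motifs,
    hox_classical_pwm,
    motif_enrichment,
    motif_location_distribution,
    read_meme,
    scan,
    shuffle_background,
    trl_gaga_pwm,
    write_meme,
)

log = logging.getLogger("crossbind")


@dataclass
class RunConfig:
    """Validated inputs and parameters for one analysis run."""

    peaks: dict[str, str]  # tissue -> BED/narrowPeak path (exactly 2 tissues)
    gtf: str
    fasta: str
    marks: dict[str, str] = field(default_factory=dict)  # "mark:tissue" -> BED
    outdir: str = "crossbind_out"
    motif_meme: str | None = None  # known-motif set; default = built-in stand-ins
    psam_tsv: str | None = None  # affinity matrix; default from classical PWM
    stage: str = ""
    flank_up: int = 2000
    flank_down: int = 1000
    max_tss_distance: int = 10000
    subdivision_gap: int = 2000
    scan_threshold_fraction: float = 0.7
    mark_threshold: float = 0.25
    enrichment_alpha: float = 0.05
    shuffle_seed: int = 1
    discovery_seed: int = 1

    def __post_init__(self) -> None:
        if len(self.peaks) < 2:
            raise ValueError("need peak files for at least two tissues")

    @property
    def tissues(self) -> list[str]:
        return list(self.peaks.keys())

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [self.gtf, self.fasta, *self.peaks.values(), *self.marks.values()]
            if p and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _out(cfg: RunConfig, name: str) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out / name


def _load_peaks(cfg: RunConfig) -> dict[str, list[Peak]]:
    return {
        tissue: read_peaks(path, tissue=tissue, stage=cfg.stage, id_prefix=tissue)
        for tissue, path in cfg.peaks.items()
    }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_annotate(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Assign peaks to genes per tissue; write assignment tables."""
    genes = read_genes(cfg.gtf)
    index = GeneIndex(genes, margin=max(12000, cfg.max_tss_distance + 2000))
    peaks = _load_peaks(cfg)
    frames = {}
    for tissue, tissue_peaks in peaks.items():
        assignments = assign_peaks_to_genes(
            tissue_peaks,
            index,
            flank_up=cfg.flank_up,
            flank_down=cfg.flank_down,
            max_tss_distance=cfg.max_tss_distance,
        )
        frame = assignments_to_frame(assignments)
        frame.to_csv(_out(cfg, f"assignments_{tissue}.tsv"), sep="\t", index=False)
        labels = peak_labels(assignments)
        annotated = [
            dataclasses.replace(p, id=f"{p.id}|{labels.get(p.id, LocationLabel.INTERGENIC)}")
            for p in tissue_peaks
        ]
        write_peaks(annotated, _out(cfg, f"peaks_annotated_{tissue}.bed"))
        frames[tissue] = frame
    return frames


def _read_assignments(cfg: RunConfig, tissue: str) -> pd.DataFrame:
    path = _out(cfg, f"assignments_{tissue}.tsv")
    if not path.exists():
        raise FileNotFoundError(f"{path} missing; run the annotate stage first")
    return pd.read_csv(path, sep="\t")


def _enhancer_peaks_in_common_genes(
    cfg: RunConfig,
    peaks: dict[str, list[Peak]],
    assignments: dict[str, pd.DataFrame],
    common_genes: set[str],
) -> dict[str, list[Peak]]:
    """Peaks with an enhancer-class assignment to a commonly bound gene."""
    enhancer_values = {lab.value for lab in ENHANCER_LABELS}
    out = {}
    for tissue, frame in assignments.items():
        keep = frame[
            frame["gene_id"].isin(common_genes)
            & frame["location"].isin(enhancer_values)
        ]["peak_id"].unique()
        keep = set(keep)
        out[tissue] = [p for p in peaks[tissue] if p.id in keep]
    return out


def stage_compare(cfg: RunConfig) -> dict:
    """Gene categories, binding frequency, 2 kb subdivision, occupancy."""
    ta, tb = cfg.tissues[:2]
    assignments = {t: _read_assignments(cfg, t) for t in (ta, tb)}
    peaks = _load_peaks(cfg)

    categories = categorize_genes(assignments[ta], assignments[tb], ta, tb)
    categories.to_csv(_out(cfg, "gene_categories.tsv"), sep="\t", index=False)
    counts = categories["category"].value_counts().to_dict()
    ordered = {
        "common": counts.get("common", 0),
        f"{ta}_specific": counts.get(f"{ta}_specific", 0),
        f"{tb}_specific": counts.get(f"{tb}_specific", 0),
    }
    percentages = category_percentages(ordered)

    frequency = {}
    for tissue in (ta, tb):
        freq = binding_frequency(assignments[tissue], tissue)
        freq.to_csv(_out(cfg, f"binding_frequency_{tissue}.tsv"), sep="\t", index=False)
        frequency[tissue] = freq

    common_genes = set(categories[categories["category"] == "common"]["gene_id"])
    enhancer = _enhancer_peaks_in_common_genes(cfg, peaks, assignments, common_genes)
    subdivision = subdivide_common_peaks(
        enhancer[ta], enhancer[tb], gap=cfg.subdivision_gap, tissue_a=ta, tissue_b=tb
    )
    sub_frame = subdivision_to_frame(subdivision)
    sub_frame.to_csv(_out(cfg, "peak_subdivision.tsv"), sep="\t", index=False)
    by_id = {p.id: p for t in (ta, tb) for p in peaks[t]}
    for category in sub_frame["category"].unique():
        ids = sub_frame[sub_frame["category"] == category]["peak_id"]
        write_peaks(
            [by_id[i] for i in ids], _out(cfg, f"peaks_{category}.bed")
        )
    specific_fraction = tissue_specific_fraction(subdivision)

    matrix = occupancy_matrix({t: peaks[t] for t in (ta, tb)})
    corr = sample_correlation(matrix)
    corr.to_csv(_out(cfg, "sample_correlation.tsv"), sep="\t")
    scores, explained = pca_scores(matrix, n_components=min(2, len(cfg.tissues)))
    scores.assign(explained_variance=list(explained)).to_csv(
        _out(cfg, "pca_scores.tsv"), sep="\t"
    )

    summary = {
        "gene_category_counts": ordered,
        "gene_category_percentages": percentages,
        "multi_peak_fraction": {
            t: float((frequency[t]["binding_class"] == "multiPeak").mean())
            for t in (ta, tb)
        },
        "n_consensus_regions": int(matrix.shape[0]),
        "subdivision_counts": sub_frame["category"].value_counts().to_dict(),
        "tissue_specific_peak_fraction": specific_fraction,
    }
    with open(_out(cfg, "compare_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary


def _category_sequences(cfg: RunConfig) -> tuple[dict[str, dict[str, str]], dict[str, Peak]]:
    """Peak sequences per subdivision category, keyed by peak id."""
    sub = pd.read_csv(_out(cfg, "peak_subdivision.tsv"), sep="\t")
    peaks = _load_peaks(cfg)
    by_id = {p.id: p for t in cfg.tissues for p in peaks[t]}
    fasta = read_fasta(cfg.fasta)
    out: dict[str, dict[str, str]] = {}
    for category, group in sub.groupby("category"):
        seqs = {}
        for pid in group["peak_id"]:
            p = by_id[pid]
            seqs[pid] = fasta[p.chrom][p.interval.start : p.interval.end]
        out[str(category)] = seqs
    return out, by_id


def _known_motifs(cfg: RunConfig):
    if cfg.motif_meme:
        return read_meme(cfg.motif_meme)
    return [hox_classical_pwm(), trl_gaga_pwm()]


def stage_motifs(cfg: RunConfig) -> dict:
    """Known-motif enrichment per subdivision category + de novo discovery."""
    ta = cfg.tissues[0]
    sequences, by_id = _category_sequences(cfg)
    pwms = _known_motifs(cfg)
    enrichment_rows = []
    for category, seqs in sorted(sequences.items()):
        if not seqs:
            continue
        bg = shuffle_background(list(seqs.values()), order=2, seed=cfg.shuffle_seed)
        table = motif_enrichment(
            seqs,
            bg,
            pwms,
            alpha=cfg.enrichment_alpha,
            threshold_fraction=cfg.scan_threshold_fraction,
        )
        table.insert(0, "category", category)
        enrichment_rows.append(table)
    enrichment = pd.concat(enrichment_rows, ignore_index=True)
    enrichment.to_csv(_out(cfg, "motif_enrichment.tsv"), sep="\t", index=False)

    a_only = sequences.get(f"{ta}_only", {})
    discovered = []
    if len(a_only) >= 10:
        bg = shuffle_background(list(a_only.values()), order=2, seed=cfg.shuffle_seed)
        discovered = discover_motifs(
            list(a_only.values()), bg, seed=cfg.discovery_seed
        )
    disc_frame = pd.DataFrame(
        [
            {
                "rank": m.rank,
                "consensus": m.consensus,
                "seed": m.seed,
                "p_value": m.p_value,
                "p_adjusted": m.p_adjusted,
            }
            for m in discovered
        ],
        columns=["rank", "consensus", "seed", "p_value", "p_adjusted"],
    )
    disc_frame.to_csv(_out(cfg, "discovered_motifs.tsv"), sep="\t", index=False)
    if discovered:
        write_meme([m.pwm for m in discovered], _out(cfg, "discovered_motifs.meme"))

    # location distribution of known-motif hits across all categorized peaks
    labels = {}
    for tissue in cfg.tissues:
        frame = _read_assignments(cfg, tissue)
        for pid, group in frame.groupby("peak_id"):
            order = ["promoter", "distal_enhancer", "intron", "other", "intergenic"]
            best = min(group["location"], key=order.index)
            labels[pid] = best
    hits = []
    for category, seqs in sequences.items():
        for pid, seq in seqs.items():
            for pwm in pwms:
                if scan(
                    seq,
                    pwm,
                    sequence_id=pid,
                    threshold_fraction=cfg.scan_threshold_fraction,
                ):
                    hits.append({"motif": pwm.name, "peak_id": pid, "category": category})
    hit_frame = pd.DataFrame(hits, columns=["motif", "peak_id", "category"])
    locations = motif_location_distribution(hit_frame, labels)
    locations.to_csv(_out(cfg, "motif_locations.tsv"), sep="\t", index=False)

    summary = {
        "enrichment": {
            f"{row.category}:{row.motif}": {
                "p_adjusted": float(row.p_adjusted),
                "enriched": bool(row.enriched),
            }
            for row in enrichment.itertuples()
        },
        "n_discovered": len(discovered),
        "top_discovered_consensus": discovered[0].pwm.consensus if discovered else None,
    }
    with open(_out(cfg, "motifs_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def stage_affinity(cfg: RunConfig) -> dict:
    """PSAM affinity scores per subdivision category + rank-sum tests."""
    sequences, _ = _category_sequences(cfg)
    psam = (
        read_psam_tsv(cfg.psam_tsv)
        if cfg.psam_tsv
        else psam_from_pwm(hox_classical_pwm())
    )
    frames = [
        score_sequences(seqs, psam, category=category)
        for category, seqs in sorted(sequences.items())
        if seqs
    ]
    scores = pd.concat(frames, ignore_index=True)
    scores.to_csv(_out(cfg, "affinity_scores.tsv"), sep="\t", index=False)
    groups = {
        c: g["score"].tolist()
        for c, g in scores.groupby("category")
        if len(g) >= 3
    }
    results = compare_affinity_distributions(groups) if len(groups) >= 2 else []
    table = rank_results_to_frame(results)
    table.to_csv(_out(cfg, "affinity_tests.tsv"), sep="\t", index=False)
    summary = {
        "median_affinity": {c: float(np.median(v)) for c, v in groups.items()},
        "tests": [
            {
                "groups": f"{r.group_a} vs {r.group_b}",
                "p_two_sided": r.p_two_sided,
                "stars": r.stars,
            }
            for r in results
        ],
    }
    with open(_out(cfg, "affinity_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def stage_marks(cfg: RunConfig) -> dict:
    """Cross-tissue histone-mark classification of tissue-specific peaks."""
    ta, tb = cfg.tissues[:2]
    tracks = {}
    for key, path in cfg.marks.items():
        mark, _, tissue = key.partition(":")
        tracks[(mark, tissue)] = MarkTrack(mark, tissue, read_intervals(path))
    sub = pd.read_csv(_out(cfg, "peak_subdivision.tsv"), sep="\t")
    peaks = _load_peaks(cfg)
    by_id = {p.id: p for t in cfg.tissues for p in peaks[t]}
    frames = []
    for focal, other in ((ta, tb), (tb, ta)):
        ids = sub[sub["category"] == f"{focal}_only"]["peak_id"]
        focal_peaks = [by_id[i] for i in ids]
        if not focal_peaks:
            continue
        frame = classify_cross_tissue(
            focal_peaks, tracks, focal, other, threshold=cfg.mark_threshold
        )
        frame.insert(0, "focal_tissue", focal)
        frames.append(frame)
    classes = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["focal_tissue", "peak_id", "mark_class"])
    )
    classes.to_csv(_out(cfg, "mark_classes.tsv"), sep="\t", index=False)
    for cls, group in classes.groupby("mark_class"):
        write_peaks(
            [by_id[i] for i in group["peak_id"]], _out(cfg, f"peaks_mark_{cls}.bed")
        )
    summary = {
        "mark_class_counts": {
            focal: classes[classes["focal_tissue"] == focal]["mark_class"]
            .value_counts()
            .to_dict()
            for focal in classes.get("focal_tissue", pd.Series(dtype=str)).unique()
        }
    }
    with open(_out(cfg, "marks_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary


STAGES = ("annotate", "compare", "motifs", "affinity", "marks")


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run all stages in order and write ``summary.json``.

    Any stage failure aborts with the stage name; outputs of completed
    stages are retained in the output directory.
    """
    cfg.validate_paths()
    report: dict = {
        "version": __version__,
        "config_hash": cfg.hash(),
        "tissues": cfg.tissues,
        "stages": {},
    }
    stage_funcs = {
        "annotate": lambda: {"n_tables": len(stage_annotate(cfg))},
        "compare": lambda: stage_compare(cfg),
        "motifs": lambda: stage_motifs(cfg),
        "affinity": lambda: stage_affinity(cfg),
        "marks": lambda: stage_marks(cfg) if cfg.marks else {"skipped": "no mark tracks"},
    }
    for name in STAGES:
        t0 = time.monotonic()
        log.info("stage %s: starting", name)
        try:
            report["stages"][name] = stage_funcs[name]()
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.1fs", name, time.monotonic() - t0)
    with open(_out(cfg, "summary.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def analyze_simulation(sim, gap: int = 2000):
    """In-memory annotate + categorize + subdivide for a Simulation.

    Convenience path used for parameter-recovery experiments; mirrors the
    annotate and compare stages without file round-trips. Returns a dict
    with the assignment frames, gene-category frame, enhancer peak sets of
    commonly bound genes, and the peak subdivision.
    """
    cfg = sim.config
    index = GeneIndex(sim.genes)
    frames = {}
    for tissue, peaks in ((cfg.tissue_a, sim.peaks_a), (cfg.tissue_b, sim.peaks_b)):
        frames[tissue] = assignments_to_frame(assign_peaks_to_genes(peaks, index))
    categories = categorize_genes(
        frames[cfg.tissue_a], frames[cfg.tissue_b], cfg.tissue_a, cfg.tissue_b
    )
    common = set(categories[categories["category"] == "common"]["gene_id"])
    enhancer_values = {lab.value for lab in ENHANCER_LABELS}
    enhancer = {}
    for tissue, peaks in ((cfg.tissue_a, sim.peaks_a), (cfg.tissue_b, sim.peaks_b)):
        frame = frames[tissue]
        keep = set(
            frame[
                frame["gene_id"].isin(common) & frame["location"].isin(enhancer_values)
            ]["peak_id"]
        )
        enhancer[tissue] = [p for p in peaks if p.id in keep]
    subdivision = subdivide_common_peaks(
        enhancer[cfg.tissue_a],
        enhancer[cfg.tissue_b],
        gap=gap,
        tissue_a=cfg.tissue_a,
        tissue_b=cfg.tissue_b,
    )
    return {
        "assignments": frames,
        "categories": categories,
        "enhancer_peaks": enhancer,
        "subdivision": subdivision,
    }


def make_fixture(sim_config, outdir: str | Path, overwrite: bool = False) -> RunConfig:
    """Generate a synthetic fixture and a ready-to-run RunConfig for it."""
    from .simulate import simulate, write_fixture

    outdir = Path(outdir)
    sim = simulate(sim_config)
    paths = write_fixture(sim, outdir / "input", overwrite=overwrite)
    cfg = RunConfig(
        peaks=dict(paths["peaks"]),
        gtf=paths["genes_gtf"],
        fasta=paths["genome_fasta"],
        marks=dict(paths["marks"]),
        outdir=str(outdir / "output"),
        stage=sim_config.stage,
    )
    cfg.to_yaml(outdir / "run_config.yaml")
    return cfg
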