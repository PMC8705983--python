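"""Position weight matrices: scanning, enrichment testing and de novo
discovery.

Enrichment follows the AME-style sequence-level unit: a sequence either
contains at least one hit or it does not, and foreground vs background
presence is tested with a one-sided Fisher exact test, Bonferroni-corrected
across the motif set. Discovery is a k-mer-seeded, masking-based algorithm
in the spirit of STREME: exhaustive seed scoring by Fisher p of
sequence-level occurrence, PWM refinement from within-1-mismatch
occurrences, column extension by information content, then masking and
iteration.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC code for every non-empty subset of bases
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}

UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 (A=0..T=3, anything else = 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class PWM:
    """Per-position base-probability model of a binding motif."""

    name: str
    matrix: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if m.shape[0] < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if np.any(m < 0):
            raise ValueError("PWM entries must be non-negative")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(
                self.matrix > 0, np.log2(self.matrix / self.background), -np.inf
            )

    @property
    def max_score(self) -> float:
        """Highest achievable log-odds score (consensus on this background)."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @property
    def iupac(self) -> str:
        """IUPAC consensus: per column, bases with p >= 0.5 x column max."""
        out = []
        for col in self.matrix:
            keep = frozenset(BASES[i] for i in range(4) if col[i] >= 0.5 * col.max())
            out.append(_IUPAC[keep])
        return "".join(out)

    @property
    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (uniform background)."""
        from scipy.special import xlogy

        return 2.0 + (xlogy(self.matrix, self.matrix) / np.log(2)).sum(axis=1)

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name + "_rc",
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background,
            pseudocount=self.pseudocount,
        )


def pwm_from_counts(
    counts: np.ndarray,
    name: str = "motif",
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> PWM:
    """Build a PWM from a width x 4 count matrix with a per-cell pseudocount."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("count matrix must be width x 4")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if np.any(counts.sum(axis=1) == 0) and pseudocount == 0:
        raise ValueError("all-zero count column with zero pseudocount")
    padded = counts + pseudocount
    matrix = padded / padded.sum(axis=1, keepdims=True)
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    return PWM(name=name, matrix=matrix, background=bg, pseudocount=pseudocount)


def pwm_from_consensus(
    consensus: str, name: str = "motif", dominant: float = 0.91
) -> PWM:
    """Sharp PWM whose consensus is the given string (IUPAC 2-fold codes allowed)."""
    expand = {"W": "AT", "S": "CG", "R": "AG", "Y": "CT", "K": "GT", "M": "AC"}
    rows = []
    for ch in consensus.upper():
        bases = expand.get(ch, ch)
        col = np.full(4, (1.0 - dominant) / (4 - len(bases)) if len(bases) < 4 else 0.25)
        if len(bases) == 1:
            col[_BASE_INDEX[bases]] = dominant
        elif len(bases) < 4:
            # split the dominant mass slightly unevenly for a unique argmax
            col[_BASE_INDEX[bases[0]]] = dominant * 0.55
            col[_BASE_INDEX[bases[1]]] = dominant * 0.45
        rows.append(col / col.sum())
    return PWM(name=name, matrix=np.array(rows))


# ---------------------------------------------------------------------------
# Built-in motif stand-ins
# ---------------------------------------------------------------------------

def hox_classical_pwm() -> PWM:
    """Hox-like PWM built around the canonical T(A/T)AT(T/G)(A/G) core.

    The published matrices behind the original enrichment analysis are not
    public; this is a documented stand-in with the canonical core flanked by
    one moderately constrained column on each side. Consensus: TTAATGAA.
    """
    return pwm_from_consensus("TWATKR", name="hox_classical", dominant=0.95).widen_with(
        left=("T", 0.85), right=("A", 0.85)
    )


def hox_divergent_pwm() -> PWM:
    """Divergent Hox-like variant with an AT-rich tract; models the
    tissue-specific non-canonical motif scenario without cross-reacting
    with the classical scanner."""
    return pwm_from_consensus("TACTTTGA", name="hox_divergent", dominant=0.95)


def trl_gaga_pwm() -> PWM:
    """GAGA-factor-like (Trl) stand-in motif."""
    return pwm_from_consensus("GAGAGAGA", name="trl_gaga", dominant=0.88)


def _widen_with(self: PWM, left: tuple[str, float], right: tuple[str, float]) -> PWM:
    def col(base: str, p: float) -> np.ndarray:
        c = np.full(4, (1.0 - p) / 3)
        c[_BASE_INDEX[base]] = p
        return c

    matrix = np.vstack([col(*left), self.matrix, col(*right)])
    return PWM(name=self.name, matrix=matrix, background=self.background,
               pseudocount=self.pseudocount)


PWM.widen_with = _widen_with  # small helper kept off the public dataclass API


# ---------------------------------------------------------------------------
# MEME minimal format I/O
# ---------------------------------------------------------------------------

def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write motifs in MEME minimal format (version 4)."""
    bg = pwms[0].background if pwms else UNIFORM_BACKGROUND
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.5f}" for b, p in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 10000 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[PWM]:
    """Read motifs from a MEME minimal format file."""
    background = UNIFORM_BACKGROUND.copy()
    pwms: list[PWM] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freqs = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freqs.get(b, 0.25) for b in BASES])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            header = lines[i].strip()
            width = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(width):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            matrix = np.array(rows)
            matrix = np.clip(matrix, 1e-9, None)
            matrix = matrix / matrix.sum(axis=1, keepdims=True)
            pwms.append(PWM(name=name, matrix=matrix, background=background.copy()))
        i += 1
    return pwms


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # forward-strand coordinate of the window start
    strand: str
    score: float  # log-odds in bits


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N get -inf."""
    w = log_odds.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    lo = np.column_stack([log_odds, np.full(w, np.nan)])  # column 4 catches N
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    scores = lo[np.arange(w)[None, :], windows].sum(axis=1)
    scores[np.isnan(scores)] = -np.inf
    return scores


DEFAULT_THRESHOLD_FRACTION = 0.7


def scan(
    sequence: str,
    pwm: PWM,
    threshold_bits: float | None = None,
    sequence_id: str = "",
    both_strands: bool = True,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> list[MotifHit]:
    """Scan a sequence for PWM hits at or above a log-odds threshold.

    The default threshold is ``threshold_fraction`` (70%) of the PWM's
    maximum achievable score.
    Reverse-strand hits are reported in forward coordinates. Windows
    containing N are skipped.
    """
    if threshold_bits is None:
        threshold_bits = threshold_fraction * pwm.max_score
    codes = encode(sequence)
    w = pwm.width
    hits: list[MotifHit] = []
    fwd = _window_scores(codes, pwm.log_odds)
    for off in np.flatnonzero(fwd >= threshold_bits):
        hits.append(MotifHit(sequence_id, int(off), "+", float(fwd[off])))
    if both_strands:
        rev = _window_scores(codes, pwm.reverse_complement().log_odds)
        for off in np.flatnonzero(rev >= threshold_bits):
            hits.append(MotifHit(sequence_id, int(off), "-", float(rev[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def best_score(sequence: str, pwm: PWM) -> float:
    """Best log-odds score over both strands (-inf if no valid window)."""
    codes = encode(sequence)
    fwd = _window_scores(codes, pwm.log_odds)
    rev = _window_scores(codes, pwm.reverse_complement().log_odds)
    best = -np.inf
    if fwd.size:
        best = max(best, float(fwd.max()))
    if rev.size:
        best = max(best, float(rev.max()))
    return best


# ---------------------------------------------------------------------------
# Background shuffles
# ---------------------------------------------------------------------------

def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson Euler-path shuffle preserving dinucleotide counts."""
    if len(seq) < 3:
        return seq
    letters = sorted(set(seq))
    edges: dict[str, list[str]] = {a: [] for a in letters}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    # pick a random tree of "last edges" pointing toward the final vertex
    # (sequential edge sampling + connectivity check, standard construction)
    for _ in range(100):
        last_edge: dict[str, str] = {}
        ok = True
        for a in letters:
            if a == last:
                continue
            if not edges[a]:
                ok = False
                break
            last_edge[a] = edges[a][rng.integers(len(edges[a]))]
        if not ok:
            break
        # check every vertex reaches `last` via last_edge links
        def reaches(v: str) -> bool:
            seen = set()
            while v != last:
                if v in seen or v not in last_edge:
                    return False
                seen.add(v)
                v = last_edge[v]
            return True

        if all(reaches(a) for a in letters if a != last):
            out_edges = {}
            for a in letters:
                rest = list(edges[a])
                if a != last:
                    rest.remove(last_edge[a])
                rng.shuffle(rest)
                if a != last:
                    rest.append(last_edge[a])
                out_edges[a] = rest
            chunks = [seq[0]]
            pos = {a: 0 for a in letters}
            v = seq[0]
            for _ in range(len(seq) - 1):
                nxt = out_edges[v][pos[v]]
                pos[v] += 1
                chunks.append(nxt)
                v = nxt
            return "".join(chunks)
    return seq  # degenerate composition; identity is the only valid shuffle


def shuffle_background(
    sequences: Sequence[str], order: int = 2, seed: int = 0
) -> list[str]:
    """Composition-preserving shuffled background sequences.

    ``order=1`` permutes letters (mononucleotide-preserving); ``order=2``
    performs an Euler-path shuffle preserving all dinucleotide counts.
    Deterministic under ``seed``.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    rng = np.random.default_rng(seed)
    out = []
    for seq in sequences:
        if order == 2 and len(seq) < 3:
            warnings.warn("sequence shorter than 3; falling back to order-1 shuffle")
            order_here = 1
        else:
            order_here = order
        if order_here == 1:
            arr = np.array(list(seq))
            rng.shuffle(arr)
            out.append("".join(arr))
        else:
            out.append(_dinucleotide_shuffle(seq, rng))
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def _has_hit(sequences: Mapping[str, str], pwm: PWM, threshold: float) -> int:
    return sum(1 for s in sequences.values() if best_score(s, pwm) >= threshold)


def motif_enrichment(
    fg_sequences: Mapping[str, str] | Sequence[str],
    bg_sequences: Mapping[str, str] | Sequence[str],
    pwms: Sequence[PWM],
    threshold_bits: float | None = None,
    alpha: float = 0.05,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> pd.DataFrame:
    """AME-style sequence-level motif enrichment of foreground vs background.

    Per motif: 2x2 table of sequences with/without >= 1 hit in fg/bg, a
    one-sided Fisher exact p for foreground over-representation, and a
    Bonferroni-adjusted p across the motif set. Motifs with adjusted
    p >= ``alpha`` are flagged not enriched.
    """
    if not pwms:
        raise ValueError("empty motif list")
    if not fg_sequences or not bg_sequences:
        raise ValueError("foreground and background must be non-empty")
    fg = fg_sequences if isinstance(fg_sequences, Mapping) else {
        str(i): s for i, s in enumerate(fg_sequences)
    }
    bg = bg_sequences if isinstance(bg_sequences, Mapping) else {
        str(i): s for i, s in enumerate(bg_sequences)
    }
    rows = []
    for pwm in pwms:
        thr = (
            threshold_bits
            if threshold_bits is not None
            else threshold_fraction * pwm.max_score
        )
        fg_hit = _has_hit(fg, pwm, thr)
        bg_hit = _has_hit(bg, pwm, thr)
        table = [[fg_hit, len(fg) - fg_hit], [bg_hit, len(bg) - bg_hit]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        p_adj = min(1.0, p * len(pwms))
        rows.append(
            {
                "motif": pwm.name,
                "fg_hits": fg_hit,
                "fg_total": len(fg),
                "bg_hits": bg_hit,
                "bg_total": len(bg),
                "odds_ratio": odds,
                "p_value": p,
                "p_adjusted": p_adj,
                "enriched": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# De novo discovery (k-mer seeded, masking)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscoveredMotif:
    consensus: str  # IUPAC consensus of the refined PWM
    pwm: PWM
    seed: str
    p_value: float
    p_adjusted: float
    rank: int


def _canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _kmer_presence(sequences: Sequence[str], k: int) -> dict[str, int]:
    """Number of sequences containing each canonical k-mer (either strand)."""
    counts: dict[str, int] = {}
    for seq in sequences:
        seen: set[str] = set()
        su = seq.upper()
        for i in range(len(su) - k + 1):
            kmer = su[i : i + k]
            if "N" in kmer:
                continue
            seen.add(_canonical(kmer))
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _hamming_occurrences(
    sequences: Sequence[str], seed: str, max_mismatch: int = 1
) -> list[tuple[int, int, str, str]]:
    """(seq_idx, offset, strand, oriented window) within ``max_mismatch`` of seed."""
    k = len(seed)
    rc_seed = reverse_complement(seed)
    occs = []
    for idx, seq in enumerate(sequences):
        su = seq.upper()
        for i in range(len(su) - k + 1):
            window = su[i : i + k]
            if "N" in window:
                continue
            d_fwd = sum(a != b for a, b in zip(window, seed))
            if d_fwd <= max_mismatch:
                occs.append((idx, i, "+", window))
                continue
            d_rev = sum(a != b for a, b in zip(window, rc_seed))
            if d_rev <= max_mismatch:
                occs.append((idx, i, "-", reverse_complement(window)))
    return occs


def _column_counts(letters: Iterable[str]) -> np.ndarray:
    col = np.zeros(4)
    for ch in letters:
        if ch in _BASE_INDEX:
            col[_BASE_INDEX[ch]] += 1
    return col


def discover_motifs(
    fg_sequences: Sequence[str],
    bg_sequences: Sequence[str],
    k_min: int = 6,
    k_max: int = 10,
    n_motifs: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    max_extension: int = 4,
    ic_threshold: float = 0.3,
) -> list[DiscoveredMotif]:
    """k-mer-seeded de novo motif discovery with masking.

    Every canonical k-mer (k in [k_min, k_max]) is scored by a one-sided
    Fisher exact test of sequence-level occurrence in foreground vs
    background (Bonferroni-adjusted across the candidate seeds tested). The
    best seed's foreground occurrences within 1 mismatch are aligned into a
    PWM (pseudocount 0.5), extended by one flanking column per side while
    the new column's information content is >= ``ic_threshold`` bits, the
    occurrences are masked with N, and the search repeats until ``n_motifs``
    motifs are found or no seed reaches adjusted significance.
    """
    if len(fg_sequences) < 10:
        raise ValueError(
            f"foreground has {len(fg_sequences)} sequences; need >= 10 for any power"
        )
    del seed  # the algorithm is fully deterministic; kept for interface stability
    fg = [s.upper() for s in fg_sequences]
    bg = [s.upper() for s in bg_sequences]
    n_fg, n_bg = len(fg), len(bg)
    results: list[DiscoveredMotif] = []
    bg_cache: dict[int, dict[str, int]] = {}
    for rank in range(1, n_motifs + 1):
        best: tuple[float, str] | None = None
        n_candidates = 0
        for k in range(k_min, k_max + 1):
            fg_counts = _kmer_presence(fg, k)
            if k not in bg_cache:
                bg_cache[k] = _kmer_presence(bg, k)
            bg_counts = bg_cache[k]
            if not fg_counts:
                continue
            kmers = sorted(fg_counts)
            a = np.array([fg_counts[m] for m in kmers])
            b = np.array([bg_counts.get(m, 0) for m in kmers])
            n_candidates += len(kmers)
            # one-sided Fisher p == hypergeometric upper tail
            pvals = stats.hypergeom.sf(a - 1, n_fg + n_bg, a + b, n_fg)
            order = np.lexsort((np.array(kmers, dtype=object), pvals))
            i = order[0]
            if best is None or (pvals[i], kmers[i]) < best:
                best = (float(pvals[i]), kmers[i])
        if best is None:
            break
        p_value, seed_kmer = best
        p_adj = min(1.0, p_value * max(1, n_candidates))
        if p_adj >= alpha:
            break
        occs = _hamming_occurrences(fg, seed_kmer, max_mismatch=1)
        counts = np.array(
            [_column_counts(w[j] for _, _, _, w in occs) for j in range(len(seed_kmer))]
        )
        pwm_matrix_counts = counts
        left_ext = right_ext = 0
        for _ in range(max_extension):
            extended = False
            for side in ("left", "right"):
                letters = []
                k = len(seed_kmer)
                for idx, off, strand, _ in occs:
                    # seed-oriented flank position mapped back to the read strand
                    if side == "left":
                        pos = off - (left_ext + 1) if strand == "+" else off + k + left_ext
                    else:
                        pos = off + k + right_ext if strand == "+" else off - (right_ext + 1)
                    if 0 <= pos < len(fg[idx]):
                        ch = fg[idx][pos]
                        if strand == "-":
                            ch = reverse_complement(ch)
                        letters.append(ch)
                col = _column_counts(letters)
                if col.sum() < max(2, 0.5 * len(occs)):
                    continue
                probs = (col + 0.5) / (col + 0.5).sum()
                ic = 2.0 + float((probs * np.log2(probs)).sum())
                if ic >= ic_threshold:
                    if side == "left":
                        pwm_matrix_counts = np.vstack([col, pwm_matrix_counts])
                        left_ext += 1
                    else:
                        pwm_matrix_counts = np.vstack([pwm_matrix_counts, col])
                        right_ext += 1
                    extended = True
            if not extended:
                break
        pwm = pwm_from_counts(
            pwm_matrix_counts, name=f"discovered_{rank}", pseudocount=0.5
        )
        results.append(
            DiscoveredMotif(
                consensus=pwm.iupac,
                pwm=pwm,
                seed=seed_kmer,
                p_value=p_value,
                p_adjusted=p_adj,
                rank=rank,
            )
        )
        # mask the seed-region occurrences in the foreground
        k = len(seed_kmer)
        masked = list(fg)
        for idx, off, _, _ in occs:
            s = masked[idx]
            masked[idx] = s[:off] + "N" * k + s[off + k :]
        fg = masked
    return results


# ---------------------------------------------------------------------------
# Motif location distribution
# ---------------------------------------------------------------------------

def motif_location_distribution(
    hits: pd.DataFrame, labels: Mapping[str, object]
) -> pd.DataFrame:
    """Fraction of hits per location label, per motif.

    ``hits`` needs columns ``motif`` and ``peak_id``; ``labels`` maps peak
    ids to location labels. Fractions sum to 1 per motif; motifs with zero
    hits are omitted.
    """
    rows = []
    for motif, group in hits.groupby("motif"):
        labelled = [str(labels[p]) for p in group["peak_id"] if p in labels]
        if not labelled:
            continue
        frac = pd.Series(labelled).value_counts(normalize=True)
        for label, f in frac.items():
            rows.append({"motif": motif, "location": label, "fraction": f})
    return pd.DataFrame(rows, columns=["motif", "location", "fraction"])
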