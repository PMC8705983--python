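import collections
import math

import numpy as np
import pytest

import oracles
from crossbind.motifs import (
    PWM,
    discover_motifs,
    hox_classical_pwm,
    hox_divergent_pwm,
    motif_enrichment,
    motif_location_distribution,
    pwm_from_consensus,
    pwm_from_counts,
    read_meme,
    reverse_complement,
    scan,
    shuffle_background,
    write_meme,
)
from crossbind.simulate import random_sequences, _sample_instance


class TestPWMConstruction:
    def test_counts_without_pseudocount(self):
        pwm = pwm_from_counts(np.array([[10, 0, 0, 0]] * 4), pseudocount=0.0)
        assert np.allclose(pwm.matrix[0], [1, 0, 0, 0])

    def test_uniform_counts_give_uniform_columns(self):
        pwm = pwm_from_counts(np.full((5, 4), 7.0), pseudocount=0.5)
        assert np.allclose(pwm.matrix, 0.25)

    def test_columns_sum_to_one_for_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            counts = rng.integers(0, 50, size=(int(rng.integers(4, 12)), 4))
            if (counts.sum(axis=1) == 0).any():
                counts[counts.sum(axis=1) == 0, 0] = 1
            pwm = pwm_from_counts(counts, pseudocount=float(rng.random()) + 0.01)
            assert np.allclose(pwm.matrix.sum(axis=1), 1.0)

    def test_all_zero_column_rejected_without_pseudocount(self):
        with pytest.raises(ValueError):
            pwm_from_counts(np.array([[0, 0, 0, 0]] * 4), pseudocount=0.0)

    def test_consensus_and_iupac(self):
        pwm = pwm_from_consensus("TWAT", dominant=0.9)
        assert pwm.consensus == "TAAT"  # W splits 0.55/0.45 toward A
        assert pwm.iupac == "TWAT"

    def test_classical_standin_realizes_core(self):
        pwm = hox_classical_pwm()
        assert pwm.width == 8
        core = pwm.iupac[1:7]
        assert core == "TWATKR"  # T(A/T)AT(T/G)(A/G)


class TestMemeIO:
    def test_round_trip(self, tmp_path):
        pwms = [hox_classical_pwm(), hox_divergent_pwm()]
        path = tmp_path / "motifs.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert [p.name for p in back] == [p.name for p in pwms]
        for orig, rt in zip(pwms, back):
            assert np.allclose(orig.matrix, rt.matrix, atol=1e-5)

    def test_biopython_reads_our_meme_files(self, tmp_path):
        """Cross-check the minimal-format writer against Bio.motifs."""
        from Bio import motifs as bio_motifs

        path = tmp_path / "motifs.meme"
        write_meme([hox_classical_pwm()], path)
        with open(path) as fh:
            record = bio_motifs.parse(fh, "minimal")
        assert len(record) == 1
        theirs = record[0]
        ours = hox_classical_pwm()
        assert theirs.length == ours.width
        for j, base in enumerate("ACGT"):
            for i in range(ours.width):
                # Bio.motifs quantizes probabilities at 1/nsites on read
                assert theirs.pwm[base][i] == pytest.approx(
                    ours.matrix[i, j], abs=1e-3
                )


class TestScan:
    def test_consensus_scores_maximum(self):
        pwm = pwm_from_consensus("TTAATGGA", dominant=0.9)
        hits = scan(pwm.consensus, pwm, threshold_bits=0.0)
        top = max(hits, key=lambda h: h.score)
        expected = sum(math.log2(pwm.matrix[j].max() / 0.25) for j in range(8))
        assert top.score == pytest.approx(expected)
        assert top.offset == 0 and top.strand == "+"
        assert expected > 0

    def test_reverse_complement_flips_strand(self):
        pwm = pwm_from_consensus("TTAACGGA", dominant=0.9)
        seq = "ACGT" * 5 + pwm.consensus + "GGCC" * 5
        fwd_hits = scan(seq, pwm)
        rev_hits = scan(reverse_complement(seq), pwm)
        assert {(h.strand, round(h.score, 6)) for h in fwd_hits} == {
            ("+-"["+-".index(h.strand) ^ 1], round(h.score, 6)) for h in rev_hits
        }

    @pytest.mark.parametrize("seed", range(5))
    def test_hits_match_all_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pwm = pwm_from_consensus("TGATTTAT", dominant=0.8)
        seq = "".join(rng.choice(list("ACGTN"), size=200, p=[0.27, 0.2, 0.2, 0.27, 0.06]))
        threshold = 0.5 * pwm.max_score
        got = {(h.offset, h.strand, round(h.score, 9)) for h in scan(seq, pwm, threshold)}
        matrix = [list(row) for row in pwm.matrix]
        expected = set(oracles.scan_all_windows(seq, matrix, [0.25] * 4, threshold))
        assert got == expected

    def test_short_sequence_yields_no_hits(self):
        pwm = pwm_from_consensus("TTAATGGA")
        assert scan("ACG", pwm) == []

    def test_strand_symmetric_best_score(self):
        from crossbind.motifs import best_score

        rng = np.random.default_rng(3)
        pwm = hox_classical_pwm()
        for _ in range(20):
            seq = random_sequences(1, 80, rng)[0]
            assert best_score(seq, pwm) == pytest.approx(
                best_score(reverse_complement(seq), pwm)
            )


class TestShuffles:
    def test_homopolymer_unchanged(self):
        assert shuffle_background(["AAAA"], order=1, seed=0) == ["AAAA"]
        assert shuffle_background(["AAAA"], order=2, seed=0) == ["AAAA"]

    def test_mononucleotide_counts_preserved(self):
        rng = np.random.default_rng(1)
        seqs = random_sequences(20, 150, rng)
        for order in (1, 2):
            out = shuffle_background(seqs, order=order, seed=5)
            for s, o in zip(seqs, out):
                assert collections.Counter(s) == collections.Counter(o)

    def test_dinucleotide_counts_preserved_and_sequence_changed(self):
        rng = np.random.default_rng(2)
        seqs = random_sequences(30, 200, rng)
        out = shuffle_background(seqs, order=2, seed=7)
        changed = 0
        for s, o in zip(seqs, out):
            di = lambda x: collections.Counter(x[i : i + 2] for i in range(len(x) - 1))
            assert di(s) == di(o)
            changed += s != o
        assert changed >= 28  # all but degenerate cases actually shuffle

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        seqs = random_sequences(5, 100, rng)
        assert shuffle_background(seqs, 2, seed=9) == shuffle_background(seqs, 2, seed=9)
        assert shuffle_background(seqs, 2, seed=9) != shuffle_background(seqs, 2, seed=10)

    def test_short_sequence_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="order-1"):
            out = shuffle_background(["AC"], order=2, seed=0)
        assert sorted(out[0]) == ["A", "C"]

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            shuffle_background(["ACGT"], order=3, seed=0)


class TestEnrichment:
    def test_identical_sets_are_not_enriched(self):
        rng = np.random.default_rng(4)
        seqs = random_sequences(50, 120, rng)
        table = motif_enrichment(seqs, list(seqs), [hox_classical_pwm()])
        row = table.iloc[0]
        assert row.odds_ratio == pytest.approx(1.0)
        assert row.p_value >= 0.5
        assert not row.enriched

    def test_fisher_p_matches_log_gamma_tail_oracle(self):
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[80, 20], [10, 190]], alternative="greater")
        assert p == pytest.approx(oracles.fisher_one_sided(80, 20, 10, 190), rel=1e-9)

    def test_planted_motif_strongly_enriched(self):
        rng = np.random.default_rng(5)
        pwm = hox_classical_pwm()
        fg = []
        for i, s in enumerate(random_sequences(200, 150, rng)):
            if i < 160:  # 80% planting rate
                inst = pwm.consensus
                off = int(rng.integers(0, 150 - 8))
                s = s[:off] + inst + s[off + 8 :]
            fg.append(s)
        bg = random_sequences(200, 150, rng)
        table = motif_enrichment(fg, bg, [pwm])
        assert table.iloc[0].p_adjusted < 1e-6
        assert table.iloc[0].enriched

    def test_fisher_monotone_in_foreground_hits(self):
        from scipy.stats import fisher_exact

        last = 1.0
        for fg_hits in range(10, 60, 10):
            _, p = fisher_exact(
                [[fg_hits, 100 - fg_hits], [10, 90]], alternative="greater"
            )
            assert p <= last + 1e-12
            last = p

    def test_empty_motif_list_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment(["ACGT"], ["ACGT"], [])


class TestDiscovery:
    def test_planted_kmer_recovered_as_rank_one(self):
        rng = np.random.default_rng(6)
        plant = "TTAATGA"
        fg = []
        for i, s in enumerate(random_sequences(300, 150, rng)):
            if i < 210:  # 70% planting
                off = int(rng.integers(0, 150 - len(plant)))
                s = s[:off] + plant + s[off + len(plant) :]
            fg.append(s)
        bg = random_sequences(300, 150, rng)
        found = discover_motifs(fg, bg, seed=0)
        assert found
        top = found[0].pwm.consensus
        dist = min(
            sum(a != b for a, b in zip(top, plant)) if len(top) == len(plant) else 99,
            min(
                (
                    sum(a != b for a, b in zip(top[i : i + len(plant)], plant))
                    for i in range(len(top) - len(plant) + 1)
                ),
                default=99,
            ),
            min(
                (
                    sum(
                        a != b
                        for a, b in zip(
                            reverse_complement(top)[i : i + len(plant)], plant
                        )
                    )
                    for i in range(len(top) - len(plant) + 1)
                ),
                default=99,
            ),
        )
        assert dist <= 1

    def test_null_input_discovers_nothing(self):
        rng = np.random.default_rng(7)
        fg = random_sequences(200, 150, rng)
        bg = shuffle_background(fg, order=2, seed=1)
        assert discover_motifs(fg, bg, seed=0) == []

    def test_masking_prevents_rediscovery(self):
        rng = np.random.default_rng(8)
        plant = "TTCGAACG"
        fg = []
        for s in random_sequences(120, 120, rng):
            off = int(rng.integers(0, 120 - 8))
            fg.append(s[:off] + plant + s[off + 8 :])
        bg = random_sequences(120, 120, rng)
        found = discover_motifs(fg, bg, n_motifs=4, seed=0)
        consensi = [m.pwm.consensus for m in found]
        assert len(set(consensi)) == len(consensi)

    def test_tiny_foreground_refused(self):
        with pytest.raises(ValueError, match="power|>= 10|10"):
            discover_motifs(["ACGT"] * 5, ["ACGT"] * 5)


class TestLocationDistribution:
    def test_all_hits_in_introns(self):
        import pandas as pd

        hits = pd.DataFrame({"motif": ["m"] * 4, "peak_id": list("abcd")})
        labels = {p: "intron" for p in "abcd"}
        table = motif_location_distribution(hits, labels)
        assert table.iloc[0].fraction == 1.0 and table.iloc[0].location == "intron"

    def test_fractions_sum_to_one_and_match_tally(self):
        import pandas as pd

        rng = np.random.default_rng(9)
        labs = ["promoter", "intron", "intergenic", "other", "distal_enhancer"]
        peaks = {f"p{i}": labs[rng.integers(0, 5)] for i in range(100)}
        hits = pd.DataFrame(
            {
                "motif": [f"m{rng.integers(0, 3)}" for _ in range(300)],
                "peak_id": [f"p{rng.integers(0, 100)}" for _ in range(300)],
            }
        )
        table = motif_location_distribution(hits, peaks)
        for motif, group in table.groupby("motif"):
            assert group["fraction"].sum() == pytest.approx(1.0)
            # oracle: plain tally over this motif's hits
            sub = hits[hits["motif"] == motif]
            counts = collections.Counter(peaks[p] for p in sub["peak_id"])
            for _, row in group.iterrows():
                assert row.fraction == pytest.approx(
                    counts[row.location] / sum(counts.values())
                )
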