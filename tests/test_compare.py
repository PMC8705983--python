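import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_peak
from crossbind.compare import (
    binding_frequency,
    categorize_genes,
    category_percentages,
    occupancy_matrix,
    pca_scores,
    peak_count_histogram,
    round_half_up,
    sample_correlation,
    subdivide_common_peaks,
    tissue_specific_fraction,
)


def frame(pairs):
    return pd.DataFrame(
        [
            {"peak_id": p, "gene_id": g, "distance_to_tss": 0, "location": "intron"}
            for p, g in pairs
        ]
    )


class TestGeneCategories:
    def test_basic_three_way_split(self):
        a = frame([("p1", "g1"), ("p2", "g2")])
        b = frame([("q1", "g2"), ("q2", "g3")])
        cats = categorize_genes(a, b, "meso", "neuro")
        got = dict(zip(cats["gene_id"], cats["category"]))
        assert got == {
            "g1": "meso_specific",
            "g2": "common",
            "g3": "neuro_specific",
        }

    def test_published_count_percentages(self):
        """3552/2865/3596 bound genes give the printed 35/29/36% split."""
        pct = category_percentages({"common": 3552, "meso": 2865, "neuro": 3596})
        assert pct == {"common": 35, "meso": 29, "neuro": 36}

    def test_swap_symmetry(self):
        a = frame([("p1", "g1"), ("p2", "g2"), ("p3", "g4")])
        b = frame([("q1", "g2"), ("q2", "g3")])
        ab = categorize_genes(a, b, "A", "B")
        ba = categorize_genes(b, a, "B", "A")
        for cats, spec_a in ((ab, "A_specific"), (ba, "A_specific")):
            got = dict(zip(cats["gene_id"], cats["category"]))
            assert got["g2"] == "common"
        got_ab = dict(zip(ab["gene_id"], ab["category"]))
        got_ba = dict(zip(ba["gene_id"], ba["category"]))
        assert {g for g, c in got_ab.items() if c == "A_specific"} == {
            g for g, c in got_ba.items() if c == "A_specific"
        }

    def test_empty_tissue_warns(self):
        a = frame([("p1", "g1")])
        b = frame([])
        b = pd.DataFrame(columns=["peak_id", "gene_id", "distance_to_tss", "location"])
        with pytest.warns(UserWarning):
            cats = categorize_genes(a, b, "A", "B")
        assert list(cats["category"]) == ["A_specific"]

    def test_round_half_up(self):
        assert round_half_up(0.5) == 1
        assert round_half_up(1.49) == 1
        assert round_half_up(2.5) == 3


class TestBindingFrequency:
    def test_single_and_multi_classes(self):
        a = frame([("p1", "g1"), ("p2", "g2"), ("p3", "g2"), ("p4", "g2")])
        freq = binding_frequency(a, "meso")
        got = dict(zip(freq["gene_id"], zip(freq["n_peaks"], freq["binding_class"])))
        assert got == {"g1": (1, "singlePeak"), "g2": (3, "multiPeak")}

    def test_histogram_matches_brute_tally(self):
        rng = np.random.default_rng(0)
        pairs = [
            (f"p{i}", f"g{rng.integers(0, 20)}") for i in range(200)
        ]
        freq = binding_frequency(frame(pairs))
        hist = peak_count_histogram(freq)
        # oracle: plain dict tally
        per_gene: dict[str, set] = {}
        for p, g in pairs:
            per_gene.setdefault(g, set()).add(p)
        expected: dict[int, int] = {}
        for peaks in per_gene.values():
            expected[len(peaks)] = expected.get(len(peaks), 0) + 1
        assert hist.to_dict() == expected


class TestSubdivision:
    def test_overlapping_pair_is_shared(self):
        a = [make_peak("chr1", 1000, 1200, "a1")]
        b = [make_peak("chr1", 1100, 1300, "b1")]
        subs = {s.peak_id: s for s in subdivide_common_peaks(a, b)}
        assert subs["a1"].category == "shared_2kb"
        assert subs["a1"].partner_peak_id == "b1"
        assert subs["b1"].partner_peak_id == "a1"

    def test_distant_peak_is_tissue_specific(self):
        a = [make_peak("chr1", 1000, 1200, "a1")]
        b = [make_peak("chr1", 6500, 6700, "b1")]
        subs = {s.peak_id: s for s in subdivide_common_peaks(a, b, tissue_a="m", tissue_b="n")}
        assert subs["a1"].category == "m_only"
        assert subs["b1"].category == "n_only"
        assert tissue_specific_fraction(list(subs.values())) == 1.0

    def test_gap_boundary_inclusive(self):
        a = [make_peak("chr1", 0, 100, "a1")]
        b = [make_peak("chr1", 2100, 2200, "b1")]  # edge distance exactly 2000
        subs = {s.peak_id: s for s in subdivide_common_peaks(a, b)}
        assert subs["a1"].category == "shared_2kb"

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            subdivide_common_peaks([], [], gap=-1)

    def test_partition_and_symmetry_properties(self):
        rng = np.random.default_rng(5)
        a = [
            make_peak("chr1", int(s), int(s) + 150, f"a{i}")
            for i, s in enumerate(sorted(rng.integers(0, 40000, size=25)))
        ]
        b = [
            make_peak("chr1", int(s), int(s) + 150, f"b{i}")
            for i, s in enumerate(sorted(rng.integers(0, 40000, size=25)))
        ]
        subs = subdivide_common_peaks(a, b)
        assert len(subs) == 50  # every peak exactly once
        shared_a = [s for s in subs if s.category == "shared_2kb" and s.peak_id.startswith("a")]
        shared_b = [s for s in subs if s.category == "shared_2kb" and s.peak_id.startswith("b")]
        assert len(shared_a) == len(shared_b)
        # input order invariance
        rng.shuffle(a)
        rng.shuffle(b)
        again = subdivide_common_peaks(a, b)
        assert {(s.peak_id, s.category, s.partner_peak_id) for s in again} == {
            (s.peak_id, s.category, s.partner_peak_id) for s in subs
        }

    @pytest.mark.parametrize("seed", range(20))
    def test_optimal_matching_equals_exhaustive_oracle(self, seed):
        """The optimal method reproduces the exhaustive maximum-cardinality,
        minimum-distance matching on small random instances; greedy achieves
        the same cardinality except on dense pile-ups where a nearest pair
        can block two other feasible pairs."""
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        a = [
            make_peak("chr1", int(s), int(s) + 100, f"a{i}")
            for i, s in enumerate(rng.integers(0, 12000, size=na))
        ]
        b = [
            make_peak("chr1", int(s), int(s) + 100, f"b{i}")
            for i, s in enumerate(rng.integers(0, 12000, size=nb))
        ]
        dists = {}
        for i, pa in enumerate(a):
            for j, pb in enumerate(b):
                d = pa.interval.gap_to(pb.interval)
                if d is not None and d <= 2000:
                    dists[(i, j)] = float(d)
        best_pairs, best_total = oracles.min_weight_max_matching(dists, na, nb)

        optimal = subdivide_common_peaks(a, b, method="optimal")
        opt_shared = [s for s in optimal if s.category == "shared_2kb"]
        opt_total = sum(
            dists[(int(s.peak_id[1:]), int(s.partner_peak_id[1:]))]
            for s in opt_shared
            if s.peak_id.startswith("a")
        )
        assert len(opt_shared) // 2 == best_pairs
        assert opt_total == pytest.approx(best_total)

        greedy = subdivide_common_peaks(a, b)
        greedy_pairs = sum(s.category == "shared_2kb" for s in greedy) // 2
        assert greedy_pairs <= best_pairs

    def test_greedy_equals_optimal_when_partners_are_unambiguous(self):
        """With well-separated peak clusters (each peak has at most one
        candidate partner, the generator's regime) greedy and optimal agree."""
        a = [make_peak("chr1", i * 10000, i * 10000 + 200, f"a{i}") for i in range(6)]
        b = [
            make_peak("chr1", i * 10000 + 700, i * 10000 + 900, f"b{i}")
            for i in range(6)
        ]
        g = subdivide_common_peaks(a, b, method="greedy")
        o = subdivide_common_peaks(a, b, method="optimal")
        assert {(s.peak_id, s.category, s.partner_peak_id) for s in g} == {
            (s.peak_id, s.category, s.partner_peak_id) for s in o
        }


class TestOccupancy:
    def test_identical_sets_give_all_ones(self):
        peaks = [make_peak("chr1", 100, 200, "p1"), make_peak("chr1", 500, 600, "p2")]
        m = occupancy_matrix({"s1": peaks, "s2": list(peaks)})
        assert m.shape == (2, 2)
        assert (m.values == 1).all()

    def test_disjoint_sets_give_block_pattern(self):
        a = [make_peak("chr1", 100, 200, "p1")]
        b = [make_peak("chr1", 5000, 5100, "q1")]
        m = occupancy_matrix({"s1": a, "s2": b})
        assert m.values.sum(axis=1).tolist() == [1.0, 1.0]
        assert m.values.sum(axis=0).tolist() == [1.0, 1.0]

    def test_consensus_count_matches_sweep_line_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            sets = {}
            all_ivs = []
            for s in range(3):
                peaks = []
                for i in range(int(rng.integers(1, 20))):
                    start = int(rng.integers(0, 5000))
                    peaks.append(
                        make_peak(f"chr{rng.integers(1, 3)}", start, start + int(rng.integers(20, 400)), f"s{s}p{i}")
                    )
                sets[f"s{s}"] = peaks
                all_ivs += [p.interval for p in peaks]
            m = occupancy_matrix(sets)
            assert m.shape[0] == oracles.union_region_count(all_ivs)

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            occupancy_matrix({"a": [], "b": []})


class TestCorrelationAndPCA:
    def test_duplicate_and_complementary_columns(self):
        x = np.array([1.0, 0, 1, 0, 1])
        m = pd.DataFrame({"a": x, "b": x, "c": 1 - x})
        corr = sample_correlation(m)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_zero_variance_column_is_nan_not_zero(self):
        m = pd.DataFrame({"a": [1.0, 0, 1], "b": [0.5, 0.5, 0.5]})
        corr = sample_correlation(m)
        assert np.isnan(corr.loc["a", "b"]) and np.isnan(corr.loc["b", "b"])
        assert corr.loc["a", "a"] == 1.0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.random((40, 5)), columns=list("abcde"))
        corr = sample_correlation(m)
        for i in "abcde":
            for j in "abcde":
                x, y = m[i].to_numpy(), m[j].to_numpy()
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                assert corr.loc[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_identical_samples_have_identical_scores(self):
        rng = np.random.default_rng(3)
        col = rng.random(30)
        m = pd.DataFrame({"a": col, "b": col, "c": rng.random(30)})
        scores, _ = pca_scores(m, n_components=2)
        assert np.allclose(scores.loc["a"], scores.loc["b"])

    def test_explained_variance_sums_to_one_at_full_rank(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.random((50, 4)))
        _, explained = pca_scores(m, n_components=4)
        assert explained.sum() == pytest.approx(1.0)

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.random((60, 5)))
        scores, explained = pca_scores(m, n_components=3)
        X = m.to_numpy().T
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for k in range(3):
            proj = Xc @ v[:, k]
            assert np.allclose(np.abs(proj), np.abs(scores.iloc[:, k]), atol=1e-8)
            assert explained[k] == pytest.approx(w[k] / w.sum())

    def test_too_many_components_rejected(self):
        m = pd.DataFrame(np.random.default_rng(0).random((10, 3)))
        with pytest.raises(ValueError):
            pca_scores(m, n_components=4)
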