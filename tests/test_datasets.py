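"""Dataset builder: extraction, trimming, negative sampling, assembly,
splitting and the QC statistics, each against an independent oracle."""

import re

import numpy as np
import pytest

import splicevision as sv
from splicevision.datasets import (DatasetError, SamplingError,
                                   _heterogeneous_counts)


def _rng(seed=0):
    return np.random.Generator(np.random.PCG64(seed))


class TestExtractPositives:
    def test_toy_donor_window(self, toy_gene):
        out = sv.extract_positive_windows([toy_gene], "donor", flank=4)
        assert len(out) == 1
        e = out[0]
        assert e.window == "CGAGTAAG"
        assert e.window[3:5] == "GT"
        assert e.canonical and e.label == 1 and e.origin == "true_site"
        assert e.center_pos == 11

    def test_toy_acceptor_window(self, toy_gene):
        out = sv.extract_positive_windows([toy_gene], "acceptor", flank=4)
        assert len(out) == 1
        assert out[0].window == "TCTAGCCT"
        assert out[0].window[3:5] == "AG"
        assert out[0].center_pos == 19

    def test_single_exon_gene_yields_nothing(self):
        gene = sv.GeneRecord("one", "ACGT" * 30, [(1, 120)])
        assert sv.extract_positive_windows([gene], "donor", flank=4) == []

    def test_windows_overlapping_ends_discarded(self, toy_gene):
        # flank 20 would need 20 nt on each side of position 11: impossible
        assert sv.extract_positive_windows([toy_gene], "donor", flank=20) == []

    def test_windows_with_n_discarded(self):
        gene = sv.GeneRecord("n", "ACGACGACGN" + "GTAAGTCTAG" + "CCTACGTACG",
                             [(1, 10), (21, 30)])
        assert sv.extract_positive_windows([gene], "donor", flank=4) == []

    def test_canonical_flag_matches_regex_oracle(self, small_genes):
        for site in ("donor", "acceptor"):
            pattern = sv.datasets.CANONICAL_DINUCLEOTIDE[site]
            for e in sv.extract_positive_windows(small_genes, site, flank=30):
                L = len(e.window)
                assert e.canonical == bool(
                    re.match(pattern, e.window[L // 2 - 1:]))


class TestTrimWindow:
    def test_600_to_200_repositions_center(self, small_genes):
        examples = sv.extract_positive_windows(small_genes, "donor", flank=300)
        e600 = examples[0]
        e200 = sv.trim_window(e600, 200)
        assert len(e200.window) == 200
        # bases at old positions 301-302 now at positions 101-102
        assert e200.window[100:102] == e600.window[300:302]

    def test_identity_when_same_length(self, toy_gene):
        e = sv.extract_positive_windows([toy_gene], "donor", flank=4)[0]
        assert sv.trim_window(e, 8).window == e.window

    def test_index_arithmetic_on_8mer(self, toy_gene):
        e = sv.extract_positive_windows([toy_gene], "donor", flank=4)[0]
        t = sv.trim_window(e, 4)
        assert t.window == "AGTA"
        assert t.window[1:3] == "GT"  # central dinucleotide at L/2, L/2+1

    def test_enlarging_is_an_error(self, toy_gene):
        e = sv.extract_positive_windows([toy_gene], "donor", flank=4)[0]
        with pytest.raises(DatasetError):
            sv.trim_window(e, 12)


class TestSampleNegatives:
    def test_fp_windows_carry_central_gt(self, small_genes):
        out = sv.sample_negatives(small_genes, "donor", "fp_dinucleotide",
                                  50, set(), _rng(), flank=30)
        for e in out:
            assert e.window[29:31] == "GT"
            assert e.label == 0 and e.origin == "fp_dinucleotide"

    def test_count_zero_gives_empty(self, small_genes):
        assert sv.sample_negatives(small_genes, "donor", "fp_dinucleotide",
                                   0, set(), _rng()) == []

    def test_toy_fp_centers_match_regex_scan(self, toy_gene):
        """Exhaustive draw enumerates exactly the non-site GT occurrences a
        brute-force string scan finds (within window range)."""
        flank = 4
        seq = toy_gene.sequence
        true_center = toy_gene.donor_sites[0]
        expected = {m.start() + 1 for m in re.finditer("(?=GT)", seq)}
        expected -= {true_center}
        expected = {c for c in expected if flank <= c <= len(seq) - flank}
        got = sv.sample_negatives([toy_gene], "donor", "fp_dinucleotide",
                                  len(expected), set(), _rng(), flank=flank)
        assert {e.center_pos for e in got} == expected
        with pytest.raises(SamplingError):
            sv.sample_negatives([toy_gene], "donor", "fp_dinucleotide",
                                len(expected) + 1, set(), _rng(), flank=flank)

    def test_background_centers_lie_inside_their_interval(self, small_genes):
        for category in ("exon_bg", "intron_bg"):
            out = sv.sample_negatives(small_genes, "donor", category, 40,
                                      set(), _rng(3), flank=30)
            by_id = {g.gene_id: g for g in small_genes}
            for e in out:
                gene = by_id[e.gene_id]
                intervals = gene.exons if category == "exon_bg" else gene.introns
                assert any(s <= e.center_pos and e.center_pos + 1 <= t
                           for s, t in intervals)

    def test_annotated_sites_never_sampled(self, small_genes):
        annotated = {(g.gene_id, c) for g in small_genes for c in g.donor_sites}
        out = sv.sample_negatives(small_genes, "donor", "fp_dinucleotide",
                                  200, set(), _rng(4), flank=30)
        assert not ({(e.gene_id, e.center_pos) for e in out} & annotated)

    def test_sampling_without_replacement(self, small_genes):
        out = sv.sample_negatives(small_genes, "donor", "fp_dinucleotide",
                                  300, set(), _rng(5), flank=30)
        coords = [(e.gene_id, e.center_pos) for e in out]
        assert len(set(coords)) == len(coords)


class TestDeduplicate:
    def test_duplicates_removed_first_kept(self):
        def ex(w, gid):
            return sv.SpliceExample(w, 0, "donor", "exon_bg", False, gid, 10)
        a, b = ex("ACGTAA", "g1"), ex("ACGTAA", "g2")
        out = sv.deduplicate([a, b])
        assert out == [a]

    def test_unique_input_unchanged(self):
        def ex(w):
            return sv.SpliceExample(w, 0, "donor", "exon_bg", False, "g", 10)
        items = [ex("ACGTAA"), ex("AAGTAA"), ex("TTGTAA")]
        assert sv.deduplicate(items) == items

    def test_cardinality_against_set_oracle(self):
        rng = _rng(6)
        windows = ["".join(rng.choice(list("ACGT"), size=6)) for _ in range(100)]
        items = [sv.SpliceExample(w, 0, "donor", "exon_bg", False, "g", 10)
                 for w in windows]
        out = sv.deduplicate(items)
        assert len(out) == len(set(windows))


class TestHeterogeneousCounts:
    @pytest.mark.parametrize("n, expected", [
        (12000, (4000, 4000, 4000)),
        (11000, (3650, 3650, 3700)),   # intron / exon / FP
        (100, (33, 33, 34)),
        (3, (1, 1, 1)),
    ])
    def test_table_pattern(self, n, expected):
        assert _heterogeneous_counts(n) == expected

    def test_sums_to_n(self):
        for n in range(3, 400, 7):
            assert sum(_heterogeneous_counts(n)) == n


class TestAssemble:
    def test_ratio_and_mix(self, small_genes):
        positives = [sv.trim_window(e, 60) for e in
                     sv.extract_positive_windows(small_genes, "donor", flank=30)]
        spec = sv.DatasetSpec(name="GS_1", quality="confirmed_only", ratio=1,
                              negative_mix="heterogeneous", window_length=60,
                              seed=3)
        ds = sv.assemble_dataset(spec, positives, small_genes, flank=30)
        assert len(ds.negatives) == len(ds.positives)
        windows = [e.window for e in ds.examples]
        assert len(set(windows)) == len(windows)
        assert not any("N" in w for w in windows)
        from collections import Counter
        counts = Counter(e.origin for e in ds.negatives)
        third, _, fp = _heterogeneous_counts(len(ds.negatives))
        assert counts["intron_bg"] == third
        assert counts["exon_bg"] == third
        assert counts["fp_dinucleotide"] == fp

    def test_one_to_two_ratio(self, small_genes):
        positives = [sv.trim_window(e, 60) for e in
                     sv.extract_positive_windows(small_genes, "donor", flank=30)]
        positives = positives[:100]
        spec = sv.DatasetSpec(name="custom", quality="confirmed_only", ratio=2,
                              negative_mix="fp_only", window_length=60, seed=3)
        ds = sv.assemble_dataset(spec, positives, small_genes, flank=30)
        assert len(ds.negatives) == 2 * len(ds.positives)

    def test_replicates_share_positives_not_negatives(self, small_genes):
        positives = [sv.trim_window(e, 60) for e in
                     sv.extract_positive_windows(small_genes, "donor", flank=30)]
        specs = [sv.DatasetSpec(name="GS_1", quality="confirmed_only", ratio=1,
                                negative_mix="heterogeneous", window_length=60,
                                replicate=r, seed=3) for r in (1, 2)]
        ds1, ds2 = (sv.assemble_dataset(s, positives, small_genes, flank=30)
                    for s in specs)
        assert [e.window for e in ds1.positives] == [e.window for e in ds2.positives]
        assert ({e.center_pos for e in ds1.negatives}
                != {e.center_pos for e in ds2.negatives})

    def test_empty_positives_rejected(self, small_genes):
        spec = sv.DatasetSpec()
        with pytest.raises(DatasetError):
            sv.assemble_dataset(spec, [], small_genes)


class TestSplit:
    def _dummy_dataset(self, n_pos, n_neg):
        def ex(i, label):
            # unique 12-mer: base-4 encoding of i over the DNA alphabet
            digits = np.base_repr(i, base=4).zfill(12)
            window = "".join("ACGT"[int(d)] for d in digits)
            origin = "true_site" if label else "exon_bg"
            return sv.SpliceExample(window, label, "donor", origin,
                                    bool(label), f"g{i}", 10)
        pos = [ex(i, 1) for i in range(n_pos)]
        neg = [ex(i + n_pos, 0) for i in range(n_neg)]
        return sv.Dataset(spec=sv.DatasetSpec(window_length=12), positives=pos,
                          negatives=neg)

    def test_exact_arithmetic_1000(self):
        ds = self._dummy_dataset(1000, 1000)
        train, test = sv.split_train_test(ds, 0.8, seed=1)
        assert (len(train.positives), len(train.negatives)) == (800, 800)
        assert (len(test.positives), len(test.negatives)) == (200, 200)

    def test_arithmetic_11000(self):
        ds = self._dummy_dataset(11000, 11000)
        train, test = sv.split_train_test(ds, 0.8, seed=1)
        assert len(train.examples) == 17600
        assert len(test.examples) == 4400

    def test_same_seed_identical_partition(self):
        ds = self._dummy_dataset(50, 50)
        a = sv.split_train_test(ds, 0.8, seed=7)
        b = sv.split_train_test(ds, 0.8, seed=7)
        assert [e.window for e in a[0].examples] == [e.window for e in b[0].examples]

    def test_class_ratio_preserved_within_one(self):
        ds = self._dummy_dataset(333, 666)
        train, test = sv.split_train_test(ds, 0.8, seed=2)
        for part in (train, test):
            ratio = len(part.negatives) / len(part.positives)
            assert abs(ratio - 2.0) < 2.0 / len(part.positives) + 0.02

    def test_too_small_class_rejected(self):
        ds = self._dummy_dataset(4, 100)
        with pytest.raises(DatasetError):
            sv.split_train_test(ds, 0.8, seed=1)


class TestIdentity:
    @pytest.mark.parametrize("a, b, expected", [
        ("ACGT", "ACGT", 100.0),
        ("ACGT", "ACGA", 75.0),
        ("AAAA", "CCCC", 0.0),
    ])
    def test_percent_identity(self, a, b, expected):
        assert sv.percent_identity(a, b) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(DatasetError):
            sv.percent_identity("ACGT", "ACG")

    def test_two_identical_sequences(self):
        dist = sv.identity_distribution(["ACGT", "ACGT"])
        assert dist.bins[9] == 1.0
        assert dist.mean_of_means == 100.0

    def test_hand_computed_triple(self):
        # means: (75+0)/2=37.5, (75+25)/2=50, (0+25)/2=12.5
        dist = sv.identity_distribution(["AAAA", "AAAT", "TTTT"])
        expected = np.zeros(10)
        expected[[3, 5, 1]] = 1 / 3
        np.testing.assert_allclose(dist.bins, expected)

    def test_bins_sum_to_one(self):
        rng = _rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(30)]
        dist = sv.identity_distribution(seqs)
        assert abs(dist.bins.sum() - 1.0) < 1e-9

    def test_random_sequences_concentrate_near_25_percent(self):
        rng = _rng(9)
        seqs = ["".join(rng.choice(list("ACGT"), size=600)) for _ in range(40)]
        dist = sv.identity_distribution(seqs)
        assert dist.bins[2] > 0.9  # [20-30)% bin dominates

    def test_fewer_than_two_rejected(self):
        with pytest.raises(DatasetError):
            sv.identity_distribution(["ACGT"])


class TestFrequencyMatrix:
    def test_counts_for_repeated_dinucleotide(self):
        pfm = sv.position_frequency_matrix(["GT"] * 10)
        assert pfm.loc[1, "G"] == 10
        assert pfm.loc[2, "T"] == 10
        assert pfm.sum(axis=1).eq(10).all()

    def test_empty_input_rejected(self):
        with pytest.raises(DatasetError):
            sv.position_frequency_matrix([])

    def test_mixed_lengths_rejected(self):
        with pytest.raises(DatasetError):
            sv.position_frequency_matrix(["ACGT", "ACG"])

    def test_planted_motif_dominates_center(self, small_genes):
        examples = [e for e in sv.extract_positive_windows(small_genes, "donor",
                                                           flank=30)
                    if e.canonical]
        pfm = sv.position_frequency_matrix(examples)
        L = len(examples[0].window)
        assert pfm.loc[L // 2].idxmax() == "G"
        assert pfm.loc[L // 2 + 1].idxmax() == "T"


class TestRoundTrip:
    def test_dataset_tsv_roundtrip(self, small_genes, tmp_path):
        positives = [sv.trim_window(e, 60) for e in
                     sv.extract_positive_windows(small_genes, "donor", flank=30)]
        spec = sv.DatasetSpec(name="GS_0", quality="confirmed_only", ratio=1,
                              negative_mix="fp_only", window_length=60, seed=4)
        ds = sv.assemble_dataset(spec, positives, small_genes, flank=30)
        path = tmp_path / "ds.tsv"
        ds.to_tsv(path)
        loaded = sv.Dataset.from_tsv(path)
        assert [e.window for e in loaded.examples] == [e.window for e in ds.examples]
        assert [e.label for e in loaded.examples] == [e.label for e in ds.examples]
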