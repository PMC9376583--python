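import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnpscreen.barcodes import (
    BarcodeSet,
    PrimerSet,
    ScaffoldLayout,
    assemble_scaffold,
    barcode_space_size,
    generate_barcode_set,
    hamming,
    load_primer_set,
    read_barcode_fasta,
    write_barcode_fasta,
)


def brute_force_min_hamming(codes):
    return min(hamming(a, b) for a, b in itertools.combinations(codes, 2))


class TestBarcodeSpaceSize:
    @pytest.mark.parametrize("length,expected", [(8, 65536), (1, 4), (3, 64)])
    def test_known_sizes(self, length, expected):
        assert barcode_space_size(length) == expected

    @pytest.mark.parametrize("length", range(1, 7))
    def test_matches_explicit_enumeration(self, length):
        enumerated = sum(1 for _ in itertools.product("ACGT", repeat=length))
        assert barcode_space_size(length) == enumerated

    @pytest.mark.parametrize("bad", [0, -1, 2.5])
    def test_rejects_non_positive_or_fractional(self, bad):
        with pytest.raises(ValueError):
            barcode_space_size(bad)


class TestGenerateBarcodeSet:
    def test_min_distance_verified_by_all_pairs_scan(self):
        bset = generate_barcode_set(n=66, length=8, min_hamming=3, seed=42)
        assert len(bset) == 66
        true_min = brute_force_min_hamming(bset.barcodes)
        assert true_min >= 3
        assert bset.min_pairwise_hamming == true_min

    def test_maximally_distant_pair(self):
        bset = generate_barcode_set(n=2, length=8, min_hamming=8, seed=1)
        a, b = bset.barcodes
        assert hamming(a, b) == 8

    def test_infeasible_request_fails_explicitly(self):
        with pytest.raises(ValueError):
            generate_barcode_set(n=300, length=2, min_hamming=1, seed=1)

    def test_exhausted_search_never_returns_smaller_set(self):
        # 20 codes of length 3 at distance 3 exceed the sphere-packing bound
        with pytest.raises(ValueError, match="could not generate"):
            generate_barcode_set(n=20, length=3, min_hamming=3, seed=1,
                                 max_attempts=5000)

    def test_deterministic_per_seed(self):
        a = generate_barcode_set(n=20, length=8, min_hamming=3, seed=7)
        b = generate_barcode_set(n=20, length=8, min_hamming=3, seed=7)
        c = generate_barcode_set(n=20, length=8, min_hamming=3, seed=8)
        assert a.barcodes == b.barcodes
        assert a.barcodes != c.barcodes

    def test_per_position_diversity_ceiling(self):
        bset = generate_barcode_set(n=66, length=8, min_hamming=3, seed=3,
                                    diversity_ceiling=0.75)
        assert bset.per_position_base_counts.max() <= int(np.ceil(0.75 * 66))
        assert bset.per_position_base_counts.sum(axis=1).tolist() == [66] * 8

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(
        n=st.integers(2, 25),
        min_hamming=st.integers(1, 3),
        seed=st.integers(0, 10_000),
    )
    def test_reported_distance_matches_oracle(self, n, min_hamming, seed):
        bset = generate_barcode_set(n=n, length=8, min_hamming=min_hamming,
                                    seed=seed)
        assert bset.min_pairwise_hamming == brute_force_min_hamming(bset.barcodes)
        assert bset.min_pairwise_hamming >= min_hamming
        assert len(set(bset.barcodes)) == n


class TestBarcodeSetValidation:
    def test_rejects_duplicates(self):
        with pytest.raises(ValueError):
            BarcodeSet(barcodes=("ACGTACGT", "ACGTACGT"))

    def test_rejects_mixed_lengths_and_alphabet(self):
        with pytest.raises(ValueError):
            BarcodeSet(barcodes=("ACGT", "ACGTA"))
        with pytest.raises(ValueError):
            BarcodeSet(barcodes=("ACGN",))


class TestFastaRoundTrip:
    def test_exact_round_trip(self, tmp_path):
        bset = generate_barcode_set(n=12, length=8, min_hamming=3, seed=9)
        path = tmp_path / "barcodes.fasta"
        write_barcode_fasta(bset, path)
        loaded = read_barcode_fasta(path)
        assert loaded.barcodes == bset.barcodes
        assert loaded.ids == bset.ids
        assert loaded.min_pairwise_hamming == bset.min_pairwise_hamming


class TestPrimerSet:
    def test_distinct_stagger_lengths(self, primer_set):
        lengths = primer_set.stagger_lengths
        assert sorted(lengths["forward"]) == list(range(8))
        assert sorted(lengths["reverse"]) == list(range(8))

    def test_anchor_is_brute_force_longest_common_suffix(self, primer_set):
        def oracle(seqs):
            best = ""
            for k in range(1, min(len(s) for s in seqs) + 1):
                suffix = seqs[0][-k:]
                if all(s.endswith(suffix) for s in seqs):
                    best = suffix
            return best

        assert primer_set.fwd_anchor == oracle(list(primer_set.forward))
        assert primer_set.rvs_anchor == oracle(list(primer_set.reverse))
        assert len(primer_set.fwd_anchor) == 20
        assert all(f.endswith(primer_set.fwd_anchor) for f in primer_set.forward)
        assert all(r.endswith(primer_set.rvs_anchor) for r in primer_set.reverse)

    def test_identical_primers_rejected_for_duplicate_staggers(self):
        seq = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAGGCTCTC"
        with pytest.raises(ValueError, match="stagger"):
            PrimerSet(forward=(seq, seq), reverse=("ACGTACGT",))

    def test_whitespace_grouped_dialect(self, tmp_path, primer_set):
        table = tmp_path / "primers.txt"
        table.write_text(
            "FWD_1 TCG TCG GCA GCG TCA GAT GTG TAT AAG AGA CAG GCT CTC ATA CGA ACT CGT CC\n"
            "FWD_2 TCG TCG GCA GCG TCA GAT GTG TAT AAG AGA CAG TGC TCT CAT ACG AAC TCG TCC\n"
            "RVS_1 GTC TCG TGG GCT CGG AGA TGT GTA TAA GAG ACA GGT CTC TGC TCG ACT AAC CAC\n"
            "RVS_2 GTC TCG TGG GCT CGG AGA TGT GTA TAA GAG ACA GTG TCT CTG CTC GAC TAA CCA C\n"
        )
        ps = load_primer_set(table)
        assert ps.fwd_anchor == primer_set.fwd_anchor
        assert ps.rvs_anchor == primer_set.rvs_anchor


class TestScaffoldAssembly:
    def test_length_and_segment_cover(self, primer_set, layout):
        scaffold = assemble_scaffold("ACGTACGT", primer_set, layout)
        assert len(scaffold.sequence) == 91
        names = [name for name, _, _ in scaffold.segments]
        assert names == ["fwd_primer_region", "probe_site", "barcode8",
                         "umi7", "spacer", "rvs_primer_region"]
        # contiguous half-open cover of [0, 91)
        assert scaffold.segments[0][1] == 0
        assert scaffold.segments[-1][2] == 91

    def test_barcode_planted_verbatim(self, primer_set, layout):
        scaffold = assemble_scaffold("AAAAAAAA", primer_set, layout)
        assert scaffold.segment("barcode8") == "AAAAAAAA"
        assert scaffold.segment("umi7") == "NNNNNNN"
        assert len(scaffold.segment("barcode8")) == 8

    def test_primer_regions_match_anchors(self, primer_set, layout):
        from lnpscreen.barcodes import reverse_complement

        scaffold = assemble_scaffold("ACGTACGT", primer_set, layout)
        assert scaffold.segment("fwd_primer_region") == primer_set.fwd_anchor
        assert scaffold.segment("rvs_primer_region") == reverse_complement(
            primer_set.rvs_anchor
        )

    def test_scaffolds_identical_outside_variable_segments(self, primer_set, layout):
        s1 = assemble_scaffold("ACGTACGT", primer_set, layout)
        s2 = assemble_scaffold("TTTTCCCC", primer_set, layout)
        variable = set()
        for name, start, end in s1.segments:
            if name in ("barcode8", "umi7"):
                variable.update(range(start, end))
        diffs = {i for i, (a, b) in enumerate(zip(s1.sequence, s2.sequence))
                 if a != b}
        assert diffs <= variable

    def test_assembly_is_deterministic(self, primer_set, layout):
        a = assemble_scaffold("ACGTACGT", primer_set, layout)
        b = assemble_scaffold("ACGTACGT", primer_set, layout)
        assert a.sequence == b.sequence

    def test_layout_not_summing_to_total_is_config_error(self, primer_set):
        bad = ScaffoldLayout(total_length=90)
        with pytest.raises(ValueError, match="sum"):
            assemble_scaffold("ACGTACGT", primer_set, bad)

    def test_bad_barcode_rejected(self, primer_set, layout):
        with pytest.raises(ValueError):
            assemble_scaffold("ACGT", primer_set, layout)
        with pytest.raises(ValueError):
            assemble_scaffold("ACGTACGN", primer_set, layout)
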