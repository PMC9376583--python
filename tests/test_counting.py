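import pytest

from lnpscreen.barcodes import hamming, reverse_complement
from lnpscreen.counting import (
    CountParams,
    CountsTable,
    assign_barcode,
    count_reads,
    count_sample,
    extract_barcode_umi,
    locate_anchor,
    parse_fastq,
)
from lnpscreen.synthetic import SimParams, simulate_ground_truth, simulate_sample_reads

import pandas as pd


def naive_locate(read, primer_set, max_mismatch, window=None):
    """Sliding-window full-Hamming scan; leftmost best match."""
    anchor = primer_set.fwd_anchor
    if window is None:
        window = primer_set.max_fwd_stagger + len(primer_set.fwd_adapter) + len(anchor)
    best_pos, best_d = None, max_mismatch + 1
    for p in range(min(window, len(read)) - len(anchor) + 1):
        d = hamming(anchor, read[p:p + len(anchor)])
        if d < best_d:
            best_pos, best_d = p, d
    return None if best_pos is None else best_pos + len(anchor)


def naive_assign_read(read, bset, primer_set, layout, params):
    """Quadratic reference matcher: every read x every barcode, full Hamming."""
    for seq in (read, reverse_complement(read)):
        offset = naive_locate(seq, primer_set, params.anchor_max_mismatch,
                              params.search_window)
        if offset is None:
            continue
        extracted = extract_barcode_umi(seq, offset, layout)
        if extracted is None:
            continue
        observed, umi = extracted
        if len(observed) != bset.length:
            continue
        dists = [(hamming(observed, b), bid)
                 for b, bid in zip(bset.barcodes, bset.ids)]
        best = min(d for d, _ in dists)
        if best > params.barcode_max_mismatch:
            continue
        hits = [bid for d, bid in dists if d == best]
        if len(hits) == 1:
            return hits[0], umi
        return None
    return None


@pytest.fixture(scope="module")
def sim(screen, primer_set):
    truth = simulate_ground_truth(screen["pool"], ["kupffer"], SimParams(),
                                  seed=17, n_mice=1, depth=4000)
    return simulate_sample_reads(truth, "kupffer_m1", screen["scaffolds"],
                                 primer_set, seed=18)


@pytest.fixture(scope="module")
def clean_sim(screen, primer_set):
    truth = simulate_ground_truth(
        screen["pool"], ["kupffer"],
        SimParams(error_rate=0.0), seed=19, n_mice=1, depth=4000,
    )
    return simulate_sample_reads(truth, "kupffer_m1", screen["scaffolds"],
                                 primer_set, seed=20)


class TestLocateAnchor:
    def test_every_stagger_offset(self, screen, primer_set):
        scaffold = next(iter(screen["scaffolds"].values()))
        seq = scaffold.with_umi("ACGTACG")
        for stagger in primer_set.fwd_staggers:
            read = stagger + seq
            assert locate_anchor(read, primer_set) == (
                len(stagger) + len(primer_set.fwd_anchor)
            )

    def test_all_n_read_not_found(self, primer_set):
        assert locate_anchor("N" * 100, primer_set) is None

    def test_one_substitution_matches_oracle_offset(self, screen, primer_set):
        scaffold = next(iter(screen["scaffolds"].values()))
        seq = "GAT" + scaffold.with_umi("ACGTACG")  # stagger 3
        for pos in (3, 10, 22):  # inside the anchor
            base = seq[pos]
            sub = "A" if base != "A" else "C"
            mutated = seq[:pos] + sub + seq[pos + 1:]
            assert locate_anchor(mutated, primer_set, max_mismatch=1) == \
                naive_locate(mutated, primer_set, max_mismatch=1)

    def test_exact_matching_only_when_mismatch_zero(self, screen, primer_set):
        scaffold = next(iter(screen["scaffolds"].values()))
        seq = scaffold.with_umi("ACGTACG")
        mutated = "T" + seq[1:]
        assert locate_anchor(mutated, primer_set, max_mismatch=0) is None
        assert locate_anchor(mutated, primer_set, max_mismatch=1) is not None


class TestExtract:
    def test_round_trip_on_error_free_reads(self, clean_sim, screen,
                                            primer_set, layout):
        scaffolds = screen["scaffolds"]
        checked = 0
        for rid, seq in clean_sim.records[:1000]:
            _sample, _r, bid, umi = rid.rsplit(":", 3)
            offset = locate_anchor(seq, primer_set)
            observed, observed_umi = extract_barcode_umi(seq, offset, layout)
            assert observed == scaffolds[bid].segment("barcode8")
            assert observed_umi == umi
            checked += 1
        assert checked == 1000

    def test_truncated_read_returns_not_found(self, screen, primer_set, layout):
        scaffold = next(iter(screen["scaffolds"].values()))
        seq = scaffold.with_umi("ACGTACG")
        offset = locate_anchor(seq, primer_set)
        truncated = seq[:offset + layout.barcode_offset_from_anchor() + 5]
        assert extract_barcode_umi(truncated, offset, layout) is None


class TestAssign:
    def test_exact_member_wins(self, small_bset):
        for seq, bid in zip(small_bset.barcodes, small_bset.ids):
            assert assign_barcode(seq, small_bset) == bid

    def test_one_substitution_recovered_matches_oracle(self, small_bset):
        for seq, bid in zip(small_bset.barcodes, small_bset.ids):
            mutated = ("A" if seq[3] != "A" else "C").join([seq[:3], seq[4:]])
            dists = [hamming(mutated, b) for b in small_bset.barcodes]
            oracle = small_bset.ids[dists.index(min(dists))] \
                if min(dists) <= 1 and dists.count(min(dists)) == 1 else None
            assert assign_barcode(mutated, small_bset) == oracle == bid

    def test_distant_observation_unassigned(self, small_bset):
        # find a 2-substitution variant at distance >= 2 from every member
        # (oracle scan); it must come back unassigned
        import itertools

        found = False
        for seq in small_bset.barcodes:
            for i, j in itertools.combinations(range(len(seq)), 2):
                mutated = list(seq)
                mutated[i] = "A" if seq[i] != "A" else "C"
                mutated[j] = "A" if seq[j] != "A" else "C"
                mutated = "".join(mutated)
                if min(hamming(mutated, b) for b in small_bset.barcodes) >= 2:
                    assert assign_barcode(mutated, small_bset) is None
                    found = True
        assert found

    def test_low_distance_set_falls_back_to_exact_with_warning(self):
        from lnpscreen.barcodes import BarcodeSet

        tight = BarcodeSet(barcodes=("AAAAAAAA", "AAAAAAAT"))
        with pytest.warns(UserWarning, match="exact"):
            assert assign_barcode("AAAAAAAC", tight, max_mismatch=1) is None


class TestCountSample:
    def test_error_free_counts_match_simulator_truth_exactly(self, clean_sim,
                                                             screen, primer_set):
        table = count_reads((seq for _r, seq in clean_sim.records),
                            screen["bset"], primer_set)
        true_reads = clean_sim.true_read_counts
        for bid, expected in true_reads.items():
            assert table.counts.at[bid, "raw_reads"] == expected
        assert table.unassigned_reads == 0

    def test_error_free_umi_collapse_recovers_planted_molecules(self, clean_sim,
                                                                screen, primer_set):
        table = count_reads((seq for _r, seq in clean_sim.records),
                            screen["bset"], primer_set)
        true_umis = clean_sim.true_molecule_counts
        for bid, expected in true_umis.items():
            assert table.counts.at[bid, "distinct_umis"] == expected

    def test_count_conservation_with_errors(self, sim, screen, primer_set):
        table = count_reads((seq for _r, seq in sim.records),
                            screen["bset"], primer_set)
        assert (table.counts["raw_reads"].sum() + table.unassigned_reads
                == table.total_reads == len(sim.records))
        assert (table.counts["distinct_umis"] <= table.counts["raw_reads"]).all()

    def test_naive_quadratic_matcher_agrees(self, sim, screen, primer_set, layout):
        """Optimized counter vs reference quadratic matcher, read by read."""
        params = CountParams()
        from lnpscreen.counting import _process_read

        lookup = dict(zip(screen["bset"].barcodes, screen["bset"].ids))
        agree = 0
        for _rid, seq in sim.records[:2000]:
            fast = _process_read(seq, lookup, screen["bset"], primer_set,
                                 layout, params, params.barcode_max_mismatch)
            if fast is None and params.try_reverse_complement:
                fast = _process_read(reverse_complement(seq), lookup,
                                     screen["bset"], primer_set, layout,
                                     params, params.barcode_max_mismatch)
            naive = naive_assign_read(seq, screen["bset"], primer_set, layout,
                                      params)
            assert fast == naive
            agree += 1
        assert agree == 2000

    def test_raising_error_rate_never_raises_assigned_fraction(self, screen,
                                                               primer_set):
        fractions = []
        for err in (0.0, 0.01, 0.05):
            truth = simulate_ground_truth(
                screen["pool"], ["x"], SimParams(error_rate=err),
                seed=30, n_mice=1, depth=1500,
            )
            reads = simulate_sample_reads(truth, "x_m1", screen["scaffolds"],
                                          primer_set, seed=31)
            table = count_reads((s for _r, s in reads.records),
                                screen["bset"], primer_set)
            fractions.append(table.assigned_fraction)
        assert fractions[0] >= fractions[1] >= fractions[2]

    def test_empty_fastq_gives_zero_table(self, screen, primer_set, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        table = count_sample(path, screen["bset"], primer_set)
        assert table.total_reads == 0
        assert table.counts["raw_reads"].sum() == 0
        assert table.assigned_fraction == 0.0

    def test_malformed_fastq_reports_record_number(self, screen, primer_set,
                                                   tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\nOOPS\nIIII\n")
        with pytest.raises(ValueError, match="record"):
            count_sample(path, screen["bset"], primer_set)

    def test_reverse_complement_reads_recovered(self, clean_sim, screen,
                                                primer_set):
        rc = [reverse_complement(seq) for _r, seq in clean_sim.records[:200]]
        table = count_reads(rc, screen["bset"], primer_set)
        assert table.unassigned_reads == 0
        off = count_reads(
            rc, screen["bset"], primer_set,
            params=CountParams(try_reverse_complement=False),
        )
        assert off.unassigned_reads == 200

    def test_counts_table_tsv_round_trip(self, clean_sim, screen, primer_set,
                                         tmp_path):
        table = count_reads((s for _r, s in clean_sim.records),
                            screen["bset"], primer_set, sample_id="s1")
        path = tmp_path / "counts.tsv"
        table.write_tsv(path)
        loaded = CountsTable.read_tsv(path)
        assert loaded.sample_id == "s1"
        assert loaded.total_reads == table.total_reads
        pd.testing.assert_frame_equal(loaded.counts, table.counts)

    def test_conservation_enforced_at_construction(self, screen):
        df = pd.DataFrame({"raw_reads": [5], "distinct_umis": [2]},
                          index=pd.Index(["BC01"], name="barcode_id"))
        with pytest.raises(ValueError, match="conservation"):
            CountsTable("s", df, unassigned_reads=0, total_reads=99)
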