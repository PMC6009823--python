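"""Demultiplexing, family assignment, length filtering, classification."""

import numpy as np
import pytest

from spikequant.read_processing import (
    CountTable,
    DemuxScheme,
    ReadRecord,
    assign_family,
    assign_family_seq,
    demultiplex,
    length_filter,
    process_reads,
    read_fastq,
    synthetic_category,
    write_fastq,
)
from spikequant.simulate import simulate_run
from spikequant.spike_design import revcomp


def _sorted(df):
    return df.sort_index().loc[:, sorted(df.columns)]


class TestDemuxScheme:
    def test_duplicate_barcode_pairs_rejected(self, tmp_path):
        scheme = DemuxScheme(
            "A" * 12, "C" * 12, {("AAAA", "CCCC"): "s1", ("GGGG", "TTTT"): "s2"}
        )
        path = tmp_path / "scheme.tsv"
        scheme.to_tsv(path)
        text = path.read_text().splitlines()
        text.append(text[1])  # duplicate the first barcode pair
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(ValueError):
            DemuxScheme.from_tsv(path)

    def test_unequal_barcode_lengths_rejected(self):
        with pytest.raises(ValueError):
            DemuxScheme("A" * 12, "C" * 12, {("AAAA", "CCC"): "s1"})

    def test_tsv_round_trip(self, tmp_path):
        scheme = DemuxScheme(
            "ACACGACGCTCT", "GTGACTGGAGTT", {("AAAA", "CCCC"): "s1"}
        )
        scheme.to_tsv(tmp_path / "s.tsv")
        back = DemuxScheme.from_tsv(tmp_path / "s.tsv")
        assert back.barcode_map == scheme.barcode_map
        assert back.pad_forward == scheme.pad_forward


class TestDemultiplex:
    def test_simulated_counts_recovered_exactly(self, small_run):
        bins, unassigned = demultiplex(small_run.reads, small_run.scheme)
        assert not unassigned
        per_sample = {s: len(rs) for s, rs in bins.items()}
        expected = small_run.truth_counts.counts.sum(axis=0).to_dict()
        assert per_sample == expected

    def test_counts_conserved_with_foreign_reads(self, small_run):
        foreign = [ReadRecord("junk", "ACGT" * 30)]
        bins, unassigned = demultiplex(small_run.reads[:100] + foreign,
                                       small_run.scheme)
        assert sum(len(r) for r in bins.values()) + len(unassigned) == 101
        assert len(unassigned) == 1

    def test_empty_input(self, small_run):
        bins, unassigned = demultiplex([], small_run.scheme)
        assert not unassigned and all(len(v) == 0 for v in bins.values())

    def test_trims_barcodes_and_pads(self, small_run):
        bins, _ = demultiplex(small_run.reads[:50], small_run.scheme)
        overhead = 2 * (small_run.scheme.barcode_length + 12)
        raw_by_id = {r.identifier: r for r in small_run.reads[:50]}
        for reads in bins.values():
            for r in reads:
                assert len(r.sequence) == len(raw_by_id[r.identifier].sequence) - overhead


class TestAssignFamily:
    def test_spike_amplicons_map_to_own_family(self, spikes, primer_pairs):
        for fam, spike in spikes.items():
            got, insert = assign_family_seq(spike.amplicon, primer_pairs.values())
            assert got == fam
            assert insert == spike.stuffer

    def test_random_sequence_unassigned(self, primer_pairs):
        fam, _ = assign_family_seq("AT" * 150, primer_pairs.values())
        assert fam is None

    def test_one_mismatch_tolerated_in_budget(self, spikes, primer_pairs):
        amp = spikes["E"].amplicon
        mutated = "T" + amp[1:] if amp[0] != "T" else "A" + amp[1:]
        fam, _ = assign_family_seq(mutated, primer_pairs.values(), max_mismatches=1)
        assert fam == "E"
        fam0, _ = assign_family_seq(mutated, primer_pairs.values(), max_mismatches=0)
        assert fam0 is None

    def test_quality_trimmed_with_sequence(self, spikes, primer_pairs):
        amp = spikes["P"].amplicon
        read = ReadRecord("r", amp, "I" * len(amp))
        fam, trimmed = assign_family(read, primer_pairs.values())
        assert fam == "P"
        assert len(trimmed.quality) == len(trimmed.sequence)


class TestLengthFilter:
    def test_window_boundaries_inclusive(self):
        reads = {
            "P": [ReadRecord("a", "A" * 253), ReadRecord("b", "A" * 260),
                  ReadRecord("c", "A" * 252), ReadRecord("d", "A" * 255)]
        }
        kept, frac = length_filter(reads, {"P": (252, 254)})
        assert [r.identifier for r in kept["P"]] == ["a", "c"]
        assert frac["P"] == pytest.approx(0.5)

    def test_missing_window_raises(self):
        with pytest.raises(KeyError):
            length_filter({"X": [ReadRecord("a", "AC")]}, {"P": (1, 2)})

    def test_planted_off_length_retention(self):
        run = simulate_run(
            n_samples=2, depth_per_family=4000, seed=5, off_length_fraction=0.05
        )
        result = process_reads(
            run.reads, run.scheme, run.primer_pairs, run.spikes, run.references
        )
        for fam, n_planted in run.planted_off_length.items():
            n_family = int(
                run.truth_counts.counts.loc[
                    run.truth_counts.family == fam
                ].to_numpy().sum()
            )
            expected = 1 - n_planted / n_family
            assert result.retention[fam] == pytest.approx(expected, abs=1e-9)


class TestClassification:
    def test_round_trip_reproduces_latent_draw(self, small_run):
        result = process_reads(
            small_run.reads,
            small_run.scheme,
            small_run.primer_pairs,
            small_run.spikes,
            small_run.references,
        )
        assert result.n_unassigned == 0
        assert _sorted(result.count_table.counts).equals(
            _sorted(small_run.truth_counts.counts)
        )

    def test_conservation_through_all_stages(self, small_run):
        result = process_reads(
            small_run.reads,
            small_run.scheme,
            small_run.primer_pairs,
            small_run.spikes,
            small_run.references,
        )
        assert result.n_input == result.n_counted + result.n_unassigned

    def test_planted_substitution_still_classified(self, small_run):
        run = small_run
        ref = run.references[0]
        sample = run.scheme.samples[0]
        fbc, rbc = [p for p, s in run.scheme.barcode_map.items() if s == sample][0]
        amp = list(ref.amplicon)
        mid = len(amp) // 2
        amp[mid] = "A" if amp[mid] != "A" else "G"
        seq = (
            fbc + run.scheme.pad_forward + "".join(amp)
            + revcomp(run.scheme.pad_reverse) + revcomp(rbc)
        )
        result = process_reads(
            [ReadRecord("mut", seq)],
            run.scheme, run.primer_pairs, run.spikes, run.references,
        )
        assert result.count_table.counts.loc[ref.label, sample] == 1

    def test_exact_spike_read_goes_synthetic(self, small_run):
        syn = small_run.truth_counts.counts.loc[
            [synthetic_category(f) for f in small_run.primer_pairs]
        ]
        result = process_reads(
            small_run.reads, small_run.scheme, small_run.primer_pairs,
            small_run.spikes, small_run.references,
        )
        got = result.count_table.counts.loc[syn.index]
        assert _sorted(got).equals(_sorted(syn))

    def test_missing_references_raise(self, small_run):
        from spikequant.read_processing import classify_reads

        reads = {("S01", "P"): [ReadRecord("r", "ACGT" * 50)]}
        with pytest.raises(ValueError):
            classify_reads(reads, {}, [], small_run.primer_pairs)


class TestCountTable:
    def test_tsv_round_trip(self, small_run, tmp_path):
        path = tmp_path / "counts.tsv"
        small_run.truth_counts.to_tsv(path)
        back = CountTable.from_tsv(path)
        assert _sorted(back.counts).equals(_sorted(small_run.truth_counts.counts))
        assert back.family.sort_index().equals(
            small_run.truth_counts.family.sort_index()
        )

    def test_negative_counts_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            CountTable(
                pd.DataFrame({"s": [-1]}, index=["t"]),
                pd.Series({"t": "P"}),
            )

    def test_drop_singletons_keeps_synthetic(self):
        import pandas as pd

        counts = pd.DataFrame(
            {"s1": [1, 0, 5], "s2": [0, 1, 5]},
            index=["rare", synthetic_category("P"), "common"],
        )
        # "rare" has 1 read total -> dropped; synthetic kept regardless
        counts.loc[synthetic_category("P")] = [1, 0]
        table = CountTable(counts, pd.Series("P", index=counts.index))
        slim = table.drop_singletons()
        assert "rare" not in slim.categories
        assert synthetic_category("P") in slim.categories


class TestFastqIO:
    def test_fastq_round_trip(self, small_run, tmp_path):
        subset = small_run.reads[:200]
        path = tmp_path / "reads.fastq"
        write_fastq(subset, path)
        back = list(read_fastq(path))
        assert [r.sequence for r in back] == [r.sequence for r in subset]

    def test_gzip_supported(self, small_run, tmp_path):
        subset = small_run.reads[:10]
        path = tmp_path / "reads.fastq.gz"
        write_fastq(subset, path)
        assert [r.sequence for r in read_fastq(path)] == [
            r.sequence for r in subset
        ]
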