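"""Alignment and quantification: DP-oracle equivalence, hand-counted tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ggbe.quant import (
    QuantWindow,
    align_reads,
    conversion_frequency,
    genotype_table,
    indel_frequency,
    nucleotide_percentages,
)
from ggbe.synth import EditingProfile, simulate_reads

from conftest import edit_at, reads_from_seqs
from oracles import gotoh_score

dna = st.text(alphabet="ACGT", min_size=10, max_size=60)


class TestAlignReads:
    def test_identical_read_all_match(self, ref):
        al = align_reads(reads_from_seqs([ref.sequence]), ref)
        (ar,) = al
        assert ar.identity == 1.0
        assert not ar.has_indel
        assert "".join(ar.base_at) == ref.sequence

    def test_three_nt_deletion_at_cut(self, ref):
        c = ref.cut_index
        read = ref.sequence[: c - 1] + ref.sequence[c + 2:]
        al = align_reads(reads_from_seqs([read]), ref)
        (ar,) = al
        assert ar.deletions == [(c - 1, c + 2)]
        assert [ar.base_at[i] for i in range(c - 1, c + 2)] == ["-"] * 3
        start, end = QuantWindow().resolve(ref)
        assert ar.has_indel_overlapping(start, end)
        # score matches the exhaustive affine-gap DP
        assert ar.score == gotoh_score(ref.sequence, read)

    def test_insertion_recorded_at_junction(self, ref):
        c = ref.cut_index
        read = ref.sequence[: c + 1] + "AAAA" + ref.sequence[c + 1:]
        # avoid ambiguity with neighbouring A runs by checking the junction
        # only within one base
        (ar,) = align_reads(reads_from_seqs([read]), ref)
        assert len(ar.insertions) == 1
        junction, seq = ar.insertions[0]
        assert seq == "AAAA"
        assert abs(junction - c) <= 1
        assert not ar.deletions

    def test_junk_read_discarded(self, ref):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), size=len(ref.sequence)))
        al = align_reads(reads_from_seqs([ref.sequence, junk]), ref)
        assert len(al) == 1
        assert al.n_discarded == 1
        assert al.n_input == 2

    def test_empty_readset_rejected(self, ref):
        with pytest.raises(ValueError):
            align_reads(reads_from_seqs([]), ref)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(refseq=dna, readseq=dna)
    def test_score_equals_gotoh_oracle(self, refseq, readseq):
        al = align_reads(reads_from_seqs([readseq]), refseq)
        expected = gotoh_score(refseq, readseq)
        if len(al) == 1:
            assert al[0].score == expected
        else:  # read fell below the identity filter; oracle still bounds it
            assert al.n_discarded == 1


class TestQuantWindow:
    def test_default_resolves_to_protospacer(self, ref):
        assert QuantWindow().proto_interval() == (1, 20)
        start, end = QuantWindow().resolve(ref)
        s = ref.protospacer_start
        assert (start, end) == (s, s + 20)

    def test_minus_strand_same_region(self, ref_minus):
        start, end = QuantWindow().resolve(ref_minus)
        s = ref_minus.protospacer_start
        assert (start, end) == (s, s + 20)

    def test_rejects_zero_width(self):
        with pytest.raises(ValueError):
            QuantWindow(width=0)


class TestNucleotidePercentages:
    def test_unedited_reads_reference_fraction_one(self, ref):
        al = align_reads(reads_from_seqs([ref.sequence] * 100), ref)
        table = nucleotide_percentages(al, ref)
        for _, row in table.df.iterrows():
            assert row[row["ref_base"]] == 1.0
            assert row["denominator"] == 100

    def test_hand_counted_substitution_fraction(self, ref):
        edited = edit_at(ref, 6, "G")
        al = align_reads(
            reads_from_seqs([ref.sequence] * 70 + [edited] * 30), ref
        )
        table = nucleotide_percentages(al, ref)
        assert conversion_frequency(table, "C", "G", 6) == pytest.approx(30.0)
        assert conversion_frequency(table, "C", "T", 6) == 0.0

    def test_hand_counted_deletion_fraction(self, ref):
        i16 = ref.amplicon_index(16)
        deleted = ref.sequence[:i16] + ref.sequence[i16 + 3:]
        al = align_reads(
            reads_from_seqs([ref.sequence] * 90 + [deleted] * 10), ref
        )
        table = nucleotide_percentages(al, ref)
        for pos in (16, 17, 18):
            row = table.row_for_proto(pos)
            assert row["-"] == pytest.approx(0.10)
            assert row["denominator"] == 100  # deletions stay in the denominator

    def test_fractions_sum_to_one(self, ref):
        prof = EditingProfile(
            rates={(6, "C", "G"): 0.3, (5, "A", "G"): 0.2},
            indel_rate=0.1, seq_error_rate=0.01,
        )
        al = align_reads(simulate_reads(ref, prof, 400, seed=8), ref)
        table = nucleotide_percentages(al, ref)
        covered = table.df[table.df["denominator"] > 0]
        sums = covered[["A", "C", "G", "T", "N", "-"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_conversion_frequency_rejects_wrong_ref_base(self, ref):
        al = align_reads(reads_from_seqs([ref.sequence]), ref)
        table = nucleotide_percentages(al, ref)
        with pytest.raises(ValueError, match="not C"):
            conversion_frequency(table, "C", "G", 5)  # position 5 is A

    def test_minus_strand_labels_map_through(self, ref_minus):
        edited = edit_at(ref_minus, 6, "G")
        al = align_reads(
            reads_from_seqs([ref_minus.sequence] * 3 + [edited]), ref_minus
        )
        table = nucleotide_percentages(al, ref_minus)
        assert conversion_frequency(table, "C", "G", 6) == pytest.approx(25.0)


class TestIndelFrequency:
    def test_no_indels_zero(self, ref):
        al = align_reads(reads_from_seqs([ref.sequence] * 10), ref)
        assert indel_frequency(al, ref) == 0.0

    def test_deletion_outside_window_excluded(self, ref):
        # delete 3 nt near the amplicon start, far from the protospacer
        read = ref.sequence[:5] + ref.sequence[8:]
        al = align_reads(reads_from_seqs([ref.sequence] * 9 + [read]), ref)
        assert indel_frequency(al, ref) == 0.0
        assert al[9].has_indel  # ...but the indel itself was seen

    def test_simulated_rate_recovered(self, ref):
        from scipy.stats import binom
        n = 10_000
        prof = EditingProfile(indel_rate=0.1)
        al = align_reads(simulate_reads(ref, prof, n, seed=9), ref)
        pct = indel_frequency(al, ref)
        lo = binom.ppf(0.005, n, 0.1) / n * 100
        hi = binom.isf(0.005, n, 0.1) / n * 100
        assert lo <= pct <= hi


class TestGenotypeTable:
    def test_single_genotype_single_row(self, ref):
        allele = edit_at(ref, 6, "G")
        al = align_reads(reads_from_seqs([allele] * 50), ref)
        gt = genotype_table(al, ref)
        assert len(gt.df) == 1
        row = gt.df.iloc[0]
        assert row["frequency_pct"] == 100.0
        assert row["annotations"] == "C6>G"
        assert not row["has_indel"]

    def test_explicit_genotype_frequencies(self, ref):
        from scipy.stats import binom
        n = 10_000
        dual = list(ref.protospacer)
        dual[4], dual[5] = "G", "G"  # A5>G + C6>G
        prof = EditingProfile(
            genotypes=[(ref.protospacer, 0.6), ("".join(dual), 0.4)]
        )
        al = align_reads(simulate_reads(ref, prof, n, seed=10), ref)
        gt = genotype_table(al, ref)
        assert len(gt.df) == 2
        wt = gt.df[gt.df["allele"] == ref.protospacer]["count"].iloc[0]
        lo, hi = binom.ppf(0.005, n, 0.6), binom.isf(0.005, n, 0.6)
        assert lo <= wt <= hi
        dual_row = gt.df[gt.df["allele"] == "".join(dual)].iloc[0]
        assert dual_row["annotations"] == "A5>G,C6>G"

    def test_equal_counts_sorted_lexicographically(self, ref):
        a1 = edit_at(ref, 6, "G")
        a2 = edit_at(ref, 6, "T")
        al = align_reads(reads_from_seqs([a1] * 5 + [a2] * 5), ref)
        gt = genotype_table(al, ref)
        assert list(gt.df["count"]) == [5, 5]
        assert list(gt.df["allele"]) == sorted(gt.df["allele"])

    def test_counts_and_frequencies_consistent(self, ref):
        prof = EditingProfile(
            rates={(6, "C", "G"): 0.4}, indel_rate=0.1, seq_error_rate=0.005
        )
        al = align_reads(simulate_reads(ref, prof, 500, seed=11), ref)
        gt = genotype_table(al, ref)
        assert gt.df["count"].sum() == gt.total_classified
        assert gt.df["frequency_pct"].sum() == pytest.approx(100.0, abs=0.01)

    def test_aggregates_reproduce_percentage_table(self, ref):
        """Per-position aggregation of indel-free genotypes equals the
        nucleotide percentage table."""
        prof = EditingProfile(
            rates={(6, "C", "G"): 0.35, (5, "A", "G"): 0.15, (3, "C", "T"): 0.1}
        )
        al = align_reads(simulate_reads(ref, prof, 2_000, seed=12), ref)
        gt = genotype_table(al, ref)
        table = nucleotide_percentages(al, ref)
        for pos in (3, 5, 6):
            base_frac = {}
            for _, row in gt.df.iterrows():
                b = row["allele"][pos - 1]
                base_frac[b] = base_frac.get(b, 0.0) + row["frequency_pct"]
            trow = table.row_for_proto(pos)
            for b, pct in base_frac.items():
                assert trow[b] * 100 == pytest.approx(pct, abs=1e-9)

    def test_indel_allele_kept_as_gapped_sequence(self, ref):
        c = ref.cut_index
        read = ref.sequence[: c] + ref.sequence[c + 2:]  # 2-nt deletion
        al = align_reads(reads_from_seqs([read] * 4), ref)
        gt = genotype_table(al, ref)
        row = gt.df.iloc[0]
        assert row["has_indel"]
        assert "-" in row["allele"]
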