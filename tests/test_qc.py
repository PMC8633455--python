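"""Read-cleaning rules: boundaries, classification and accounting."""

import numpy as np

from mirwood import qc

A3 = "AGATCGGAAGAGCACACGTCT"
A5 = "GTTCAGAGTTCTACAGTCCGACGATC"
INSERT21 = "ACGTACGTACGTACGTACGTA"


def read(seq, qual=None, rid="r1"):
    return (rid, seq, qual if qual is not None else "I" * len(seq))


class TestSmallRNACleaning:
    def test_normal_read_is_trimmed_to_insert(self):
        out, rep = qc.clean_srna_reads([read(INSERT21 + A3)], A3, A5)
        assert rep.clean == 1
        assert out[0].seq == INSERT21
        assert len(out[0].qual) == 21

    def test_low_quality_boundary_two_bases_fail_one_passes(self):
        q_two = "5" + "I" * 20 + "5" + "I" * (len(A3) - 1)
        q_one = "5" + "I" * (20 + len(A3))
        seq = INSERT21 + A3
        _, rep = qc.clean_srna_reads([read(seq, q_two)], A3, A5)
        assert rep.removed_low_quality == 1
        _, rep = qc.clean_srna_reads([read(seq, q_one)], A3, A5)
        assert rep.clean == 1

    def test_phred_21_is_not_low_quality(self):
        # '6' encodes Phred 21: two of them must still pass
        q = "66" + "I" * (19 + len(A3))
        _, rep = qc.clean_srna_reads([read(INSERT21 + A3, q)], A3, A5)
        assert rep.clean == 1

    def test_n_base_removed_as_low_quality(self):
        seq = INSERT21[:-1] + "N" + A3
        _, rep = qc.clean_srna_reads([read(seq)], A3, A5)
        assert rep.removed_low_quality == 1

    def test_insert_length_boundary(self):
        for n, field in ((17, "removed_short"), (18, "clean")):
            seq = "ACGT" * 5 + "AC"
            seq = seq[:n] + A3
            _, rep = qc.clean_srna_reads([read(seq)], A3, A5)
            assert getattr(rep, field) == 1, n

    def test_malformed_record_dropped_and_counted(self):
        _, rep = qc.clean_srna_reads([read("ACGT", "II")], A3, A5)
        assert rep.malformed == 1 and rep.conserved()

    def test_report_conservation_on_random_batch(self, rng):
        reads = []
        for i in range(500):
            kind = rng.integers(0, 6)
            if kind == 0:
                reads.append(read(INSERT21 + A3, rid=f"r{i}"))
            elif kind == 1:
                reads.append(read(A5 + A3, rid=f"r{i}"))
            elif kind == 2:
                reads.append(read("A" * 20 + A3, rid=f"r{i}"))
            elif kind == 3:
                reads.append(read("".join(rng.choice(list("ACGT"), 25)), rid=f"r{i}"))
            elif kind == 4:
                reads.append(read("ACGTACGTACGT" + A3, rid=f"r{i}"))
            else:
                reads.append(read(INSERT21 + A3, "#" * (21 + len(A3)), rid=f"r{i}"))
        _, rep = qc.clean_srna_reads(reads, A3, A5)
        assert rep.total_raw == 500 and rep.conserved()

    def test_report_invariant_to_input_order(self, rng):
        reads = [read(INSERT21 + A3), read(A5 + A3), read("A" * 20 + A3),
                 read("ACGTACGT" + A3)] * 10
        _, rep1 = qc.clean_srna_reads(reads, A3, A5)
        perm = [reads[i] for i in rng.permutation(len(reads))]
        _, rep2 = qc.clean_srna_reads(perm, A3, A5)
        assert rep1.as_dict() == rep2.as_dict()

    def test_recleaning_with_adapter_reappended_removes_nothing(self):
        out, _ = qc.clean_srna_reads([read(INSERT21 + A3)], A3, A5)
        again = [(r.id, r.seq + A3, r.qual + "I" * len(A3)) for r in out]
        out2, rep2 = qc.clean_srna_reads(again, A3, A5)
        assert rep2.clean == len(out) and out2[0].seq == out[0].seq


class TestAdapterDetection:
    def test_insert_plus_three_prime_adapter(self):
        cls, insert = qc.detect_adapter(INSERT21 + A3[:10], A3, A5)
        assert cls == "3p_only" and insert == INSERT21

    def test_both_adapters_no_insert(self):
        assert qc.detect_adapter(A5 + A3, A3, A5) == ("both_no_insert", "")

    def test_five_prime_contamination(self):
        cls, _ = qc.detect_adapter(A5 + "ACGTACGTACGTACGT", A3, A5)
        assert cls == "5p_only"

    def test_polya_insert(self):
        cls, _ = qc.detect_adapter("A" * 20 + A3, A3, A5)
        assert cls == "polyA"

    def test_ninety_percent_a_is_polya(self):
        cls, _ = qc.detect_adapter("A" * 18 + "GG" + A3, A3, A5)
        assert cls == "polyA"  # 18/20 = 90%
        cls, _ = qc.detect_adapter("A" * 17 + "GGG" + A3, A3, A5)
        assert cls == "3p_only"

    def test_no_adapter(self):
        assert qc.detect_adapter("ACGTACGTACGTACGTACGTACGT", A3, A5)[0] == "none"

    def test_seed_with_one_extension_mismatch_still_found(self):
        mutated = A3[:10] + ("A" if A3[10] != "A" else "C") + A3[11:]
        cls, insert = qc.detect_adapter(INSERT21 + mutated, A3, A5)
        assert cls == "3p_only" and insert == INSERT21


class TestMRNACleaning:
    def pair(self, s1, q1=None, s2=None, q2=None):
        s2 = s2 if s2 is not None else s1
        return ("p1", s1, q1 or "I" * len(s1), s2, q2 or "I" * len(s2))

    def test_n_fraction_boundary(self):
        base = "ACGT" * 31 + "A"  # 125 nt
        bad = "N" * 13 + base[13:]
        good = "N" * 12 + base[12:]
        _, rep = qc.clean_mrna_reads([self.pair(bad)], "AGATCGGAAGAGC")
        assert rep.removed_low_quality == 1
        _, rep = qc.clean_mrna_reads([self.pair(good)], "AGATCGGAAGAGC")
        assert rep.clean == 1

    def test_post_trim_length_boundary(self):
        adapter = "AGATCGGAAGAGC"
        _, rep = qc.clean_mrna_reads([self.pair("ACGT" * 12 + "A" + adapter)], adapter)
        assert rep.removed_short == 1  # 49 nt after trimming
        _, rep = qc.clean_mrna_reads([self.pair("ACGT" * 13 + adapter)], adapter)
        assert rep.clean == 1

    def test_low_quality_fraction_boundary(self):
        seq = "ACGT" * 25
        q_51 = "5" * 51 + "I" * 49
        q_50 = "5" * 50 + "I" * 50
        _, rep = qc.clean_mrna_reads([self.pair(seq, q_51)], "AGATCGGAAGAGC")
        assert rep.removed_low_quality == 1
        _, rep = qc.clean_mrna_reads([self.pair(seq, q_50)], "AGATCGGAAGAGC")
        assert rep.clean == 1

    def test_pair_dropped_if_either_mate_fails(self):
        good = "ACGT" * 20
        short = "ACGT" * 10
        _, rep = qc.clean_mrna_reads([self.pair(good, s2=short)], "AGATCGGAAGAGC")
        assert rep.removed_short == 1 and rep.clean == 0
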