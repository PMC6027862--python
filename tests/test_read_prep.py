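"""FLNC triage, trimming, digital normalization and decoy filtering contracts."""

import pytest

from organsnap import (
    CHIMERIC,
    FLNC,
    NON_FULL_LENGTH,
    ReadOfInsert,
    TrimPolicy,
    classify_roi,
    decoy_filter,
    digital_normalize,
    reverse_complement,
    trim_pairs,
    trim_read,
)

A5 = "ACGTACGTCC"
A3 = "GGATCCTTAA"
INSERT = "TTGACCGATGGCTTGACAGTCCTGATCCGGTACGATTACAGGCTAGATCC"


def _roi(seq):
    return ReadOfInsert("r1", seq)


class TestClassifyRoi:
    def test_canonical_architecture_is_flnc_forward(self):
        cls = classify_roi(_roi(A5 + INSERT + "A" * 12 + A3), A5, A3)
        assert cls.category == FLNC
        assert cls.orientation == "forward"
        assert cls.adapter5_found and cls.adapter3_found and cls.polya_found
        assert cls.internal_adapter_count == 0

    def test_missing_polya_is_non_full_length(self):
        cls = classify_roi(_roi(A5 + INSERT + A3), A5, A3)
        assert cls.category == NON_FULL_LENGTH
        assert not cls.polya_found
        assert cls.adapter5_found and cls.adapter3_found

    def test_missing_adapter_is_non_full_length(self):
        cls = classify_roi(_roi(INSERT + "A" * 12 + A3), A5, A3)
        assert cls.category == NON_FULL_LENGTH
        assert not cls.adapter5_found

    def test_internal_adapter_copy_is_chimeric(self):
        insert2 = "CATTGGCCAATGCCGGTTAACGGCCATTAACCGGTTACAGGACT"
        cls = classify_roi(_roi(A5 + INSERT + A5 + insert2 + "A" * 12 + A3), A5, A3)
        assert cls.category == CHIMERIC
        assert cls.internal_adapter_count == 1

    def test_strand_flip_swaps_orientation_not_category(self):
        for seq, want in [
            (A5 + INSERT + "A" * 12 + A3, FLNC),
            (A5 + INSERT + A3, NON_FULL_LENGTH),
            (A5 + INSERT + A5 + INSERT + "A" * 12 + A3, CHIMERIC),
        ]:
            fwd = classify_roi(_roi(seq), A5, A3)
            rev = classify_roi(_roi(reverse_complement(seq)), A5, A3)
            assert fwd.category == rev.category == want
            if fwd.category == FLNC:
                assert (fwd.orientation, rev.orientation) == ("forward", "reverse")

    def test_adapter_tolerates_configured_mismatches(self):
        mutated = "T" + A5[1:]  # one substitution in the 5' adapter
        cls = classify_roi(_roi(mutated + INSERT + "A" * 12 + A3), A5, A3)
        assert cls.category == FLNC

    def test_adapter_longer_than_read_is_non_full_length(self):
        cls = classify_roi(_roi("ACGT"), A5, A3)
        assert cls.category == NON_FULL_LENGTH

    def test_polya_run_tolerates_one_non_a_per_ten(self):
        tail = "AAAAA" + "G" + "AAAAAA"  # 11 A's, 1 non-A
        cls = classify_roi(_roi(A5 + INSERT + tail + A3), A5, A3, min_polya=10)
        assert cls.polya_found


class TestTrim:
    def test_high_quality_read_unchanged(self):
        read = ReadOfInsert("r", "A" * 300, tuple([30] * 300))
        assert trim_read(read, TrimPolicy()) == read

    def test_low_quality_ends_removed(self):
        q = tuple([15] * 10 + [30] * 200 + [15] * 10)
        read = ReadOfInsert("r", "A" * 220, q)
        trimmed = trim_read(read, TrimPolicy())
        assert len(trimmed.sequence) == 200
        assert all(v >= 20 for v in trimmed.quality)

    def test_short_after_trim_dropped(self):
        q = tuple([15] * 10 + [30] * 100 + [15] * 10)
        assert trim_read(ReadOfInsert("r", "A" * 120, q), TrimPolicy()) is None

    def test_trimming_never_lengthens(self):
        q = tuple([15, 25] * 100)
        read = ReadOfInsert("r", "A" * 200, q)
        trimmed = trim_read(read, TrimPolicy())
        assert trimmed is None or len(trimmed.sequence) <= 200

    def test_pair_conservation(self):
        good = tuple([30] * 200)
        bad = tuple([10] * 200)
        pairs = []
        for i in range(6):  # both mates pass
            pairs.append(
                (ReadOfInsert(f"p{i}/1", "A" * 200, good), ReadOfInsert(f"p{i}/2", "A" * 200, good))
            )
        for i in range(6, 9):  # mate 2 drops
            pairs.append(
                (ReadOfInsert(f"p{i}/1", "A" * 200, good), ReadOfInsert(f"p{i}/2", "A" * 200, bad))
            )
        pairs.append(  # both drop
            (ReadOfInsert("p9/1", "A" * 200, bad), ReadOfInsert("p9/2", "A" * 200, bad))
        )
        kept, orphans, dropped = trim_pairs(pairs, TrimPolicy())
        assert (len(kept), len(orphans), dropped) == (6, 3, 5)
        assert 2 * len(kept) + len(orphans) + dropped == 20

    def test_unmatched_mate_ids_rejected(self):
        good = tuple([30] * 200)
        pairs = [(ReadOfInsert("a/1", "A" * 200, good), ReadOfInsert("b/2", "A" * 200, good))]
        with pytest.raises(ValueError, match="unmatched"):
            trim_pairs(pairs, TrimPolicy())


class TestDigitalNormalize:
    def test_fifty_identical_copies_cutoff_thirty_retains_thirty(self):
        seq = "ACGTTGCAGGCTTAGCATGCCAGT"
        reads = [(f"r{i}", seq) for i in range(50)]
        assert len(digital_normalize(reads, k=20, coverage_cutoff=30)) == 30

    def test_disjoint_kmer_reads_all_retained(self, rng):
        # random 25-mers essentially never share a 20-mer, so coverage stays 0
        bases = "ACGT"
        reads = []
        for i in range(40):
            reads.append((f"r{i}", "".join(bases[b] for b in rng.integers(0, 4, 25))))
        retained = digital_normalize(dict(reads).items(), k=20, coverage_cutoff=30)
        assert len(retained) == len(reads)

    def test_saturated_suffix_is_inert(self):
        seq = "ACGTTGCAGGCTTAGCATGCCAGT"
        base = [(f"r{i}", seq) for i in range(40)]
        more = base + [(f"x{i}", seq) for i in range(25)]
        assert digital_normalize(base, 20, 30) == digital_normalize(more, 20, 30)

    def test_read_shorter_than_k_rejected(self):
        with pytest.raises(ValueError, match="shorter than k"):
            digital_normalize([("tiny", "ACGT")], k=20, coverage_cutoff=30)


class TestDecoyFilter:
    DECOY = "ATGCCGGTTAACGGCCATTAACCGGTTACAGGACTTGACCGATGGCTTGACAGTC"

    def test_exact_substring_removed(self):
        mate = self.DECOY[5:45]
        pairs = [((("a/1"), mate), (("a/2"), "ACGT" * 10))]
        kept, removed = decoy_filter(pairs, self.DECOY, k=20, hit_fraction=0.5)
        assert removed == 1 and not kept

    def test_unrelated_pair_retained(self, rng):
        mate = "".join("ACGT"[b] for b in rng.integers(0, 4, 40))
        pairs = [(("a/1", mate), ("a/2", mate))]
        kept, removed = decoy_filter(pairs, self.DECOY, k=20, hit_fraction=0.5)
        assert removed == 0 and len(kept) == 1

    def test_half_overlap_boundary_inclusive(self):
        # mate = 19 decoy bases + 10 foreign bases: of its 20 10-mers exactly
        # the first 10 are decoy-derived, so the hit fraction is exactly 0.5
        decoy = "ATGCCGGTTAACGGCCATTAACCGGTTACA"
        mate = decoy[0:19] + "T" * 10
        from organsnap.clustering import reverse_complement as rc
        from organsnap.read_prep import _kmers

        index = set(_kmers(decoy, 10)) | set(_kmers(rc(decoy), 10))
        hits = sum(m in index for m in _kmers(mate, 10))
        assert hits == 10 and len(_kmers(mate, 10)) == 20
        pairs = [(("a/1", mate), ("a/2", "G" * 30))]
        kept, removed = decoy_filter(pairs, decoy, k=10, hit_fraction=0.5)
        assert removed == 1 and not kept
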