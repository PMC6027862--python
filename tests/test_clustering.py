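"""Identity definition, greedy clustering vs the brute-force oracle, chaining."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from organsnap import (
    ClusterSet,
    TranscriptRecord,
    chain,
    exhaustive_cluster,
    greedy_cluster,
    pairwise_identity,
    reference_identity,
    reverse_complement,
    semiglobal_distance,
)
from organsnap.clustering import mean_gc
from organsnap.io import read_clstr, write_clstr
from organsnap.synthetic_data import simulate_transcript_families

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _canon(cs: ClusterSet):
    return sorted(
        (c.representative, sorted((m.seq_id, round(m.identity, 9), m.strand) for m in c.members))
        for c in cs.clusters
    )


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_single_substitution(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGA") == pytest.approx(7 / 8)

    def test_reverse_complement_scores_one(self):
        s = "ATTGCCGGATCAGGAT"
        assert pairwise_identity(s, reverse_complement(s)) == 1.0

    def test_substring_scores_one(self):
        s = "ATTGCCGGATCAGGATTACGGACT"
        assert pairwise_identity(s[4:18], s) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    @given(a=dna, b=dna)
    def test_agrees_with_reference_dp_and_is_symmetric(self, a, b):
        fast = pairwise_identity(a, b)
        assert fast == pytest.approx(reference_identity(a, b))
        assert fast == pytest.approx(pairwise_identity(b, a))

    @given(a=dna)
    def test_reference_dp_substring_distance_zero(self, a):
        assert semiglobal_distance(a, "GG" + a + "TT") == 0


class TestGreedyCluster:
    def test_exact_duplicates_collapse(self):
        recs = [TranscriptRecord(f"s{i}", "ACGTACGTAA" * 6) for i in range(3)]
        out = greedy_cluster(recs, 1.0)
        assert out.n_clusters == 1
        assert len(out.clusters[0].members) == 3

    def test_threshold_separates_variants(self, rng):
        a = "".join("ACGT"[b] for b in rng.integers(0, 4, 600))
        b_arr = list(a)
        for p in rng.choice(600, size=30, replace=False):
            b_arr[p] = "ACGT"[(("ACGT".index(b_arr[p])) + 1) % 4]
        b = "".join(b_arr)
        c = "".join("ACGT"[x] for x in rng.integers(0, 4, 600))
        recs = [TranscriptRecord("A", a), TranscriptRecord("B", b), TranscriptRecord("C", c)]
        assert pairwise_identity(a, b) == pytest.approx(0.95, abs=0.002)
        at90 = greedy_cluster(recs, 0.90)
        assert sorted(len(c.members) for c in at90.clusters) == [1, 2]
        at100 = greedy_cluster(recs, 1.0)
        assert at100.n_clusters == 3

    def test_empty_input(self):
        assert greedy_cluster([], 0.9).n_clusters == 0

    def test_duplicate_ids_rejected(self):
        recs = [TranscriptRecord("x", "ACGTACGTAC"), TranscriptRecord("x", "ACGTACGTAC")]
        with pytest.raises(ValueError, match="duplicate"):
            greedy_cluster(recs, 0.9)

    def test_representative_is_longest_member(self):
        recs = [
            TranscriptRecord("short", "ACGTACGTACGT"),
            TranscriptRecord("long", "GG" + "ACGTACGTACGT" + "TT"),
        ]
        out = greedy_cluster(recs, 0.9)
        assert out.n_clusters == 1
        assert out.clusters[0].representative == "long"

    def test_partition_preserves_input_multiset(self):
        records = [
            TranscriptRecord(i, s) for i, s in simulate_transcript_families(seed=77)
        ]
        out = greedy_cluster(records, 0.9)
        assert sorted(out.member_ids()) == sorted(r.seq_id for r in records)

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_bruteforce_oracle_and_threshold_monotone(self, seed):
        records = [
            TranscriptRecord(i, s) for i, s in simulate_transcript_families(seed=seed)
        ][:30]
        counts = []
        for threshold in (1.0, 0.9, 0.8):
            fast = greedy_cluster(records, threshold)
            slow = exhaustive_cluster(records, threshold)
            assert _canon(fast) == _canon(slow)
            counts.append(fast.n_clusters)
        assert counts[0] >= counts[1] >= counts[2]

    def test_representative_gc_not_above_input_gc_with_utr_variants(self, rng):
        # UTR-bearing variants: longer, AT-rich extensions around a core
        records = []
        for i in range(20):
            core = "".join("ACGT"[b] for b in rng.integers(0, 4, 300))
            utr5 = "".join("AT"[b] for b in rng.integers(0, 2, 80))
            utr3 = "".join("AT"[b] for b in rng.integers(0, 2, 80))
            records.append(TranscriptRecord(f"g{i}_full", utr5 + core + utr3))
            records.append(TranscriptRecord(f"g{i}_cds", core))
        out = greedy_cluster(records, 0.9)
        by_id = {r.seq_id: r.sequence for r in records}
        rep_gc = mean_gc(by_id[rep] for rep in out.representatives())
        all_gc = mean_gc(r.sequence for r in records)
        assert rep_gc <= all_gc


class TestChain:
    def _stage(self, threshold, groups):
        from organsnap.clustering import Cluster, ClusterMember

        clusters = []
        for rep, members in groups:
            clusters.append(
                Cluster(rep, [ClusterMember(m, 1.0, "+", "x") for m in members])
            )
        return ClusterSet(threshold, clusters)

    def test_single_stage_valid(self):
        st1 = self._stage(1.0, [("a", ["a", "b"])])
        assert chain([st1]).backtrack() == {"a": ["a", "b"]}

    def test_two_stage_backtrack_reaches_leaves(self):
        st1 = self._stage(1.0, [("a", ["a", "b"]), ("c", ["c"]), ("d", ["d", "e"])])
        st2 = self._stage(0.9, [("a", ["a", "c"]), ("d", ["d"])])
        result = chain([st1, st2]).backtrack()
        assert result == {"a": ["a", "b", "c"], "d": ["d", "e"]}

    def test_missing_representative_named(self):
        st1 = self._stage(1.0, [("a", ["a"]), ("b", ["b"])])
        st2 = self._stage(0.9, [("a", ["a"])])
        with pytest.raises(ValueError, match="'b'"):
            chain([st1, st2])

    def test_total_reads_conserved_through_chain(self):
        st1 = self._stage(1.0, [("a", ["a", "b", "c"]), ("d", ["d"])])
        st2 = self._stage(0.9, [("a", ["a", "d"])])
        leaves = chain([st1, st2]).backtrack()
        assert sum(len(v) for v in leaves.values()) == 4


class TestClstrRoundTrip:
    def test_write_parse_identity(self, tmp_path):
        records = [
            TranscriptRecord(i, s, "bud") for i, s in simulate_transcript_families(seed=3)
        ]
        out = greedy_cluster(records, 0.9)
        lengths = {r.seq_id: len(r.sequence) for r in records}
        path = tmp_path / "stage.clstr"
        write_clstr(out, lengths, path)
        parsed, parsed_lengths = read_clstr(path)
        assert parsed_lengths == lengths
        assert [c.representative for c in parsed.clusters] == [
            c.representative for c in out.clusters
        ]
        for orig, re in zip(out.clusters, parsed.clusters):
            assert [(m.seq_id, m.strand) for m in orig.members] == [
                (m.seq_id, m.strand) for m in re.members
            ]
            for m_orig, m_re in zip(orig.members, re.members):
                assert m_re.identity == pytest.approx(m_orig.identity, abs=5e-5)
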