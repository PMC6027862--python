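"""The generator must honour its apportionment, architecture and determinism contracts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from organsnap import (
    DEFAULT_ADAPTER_3,
    DEFAULT_ADAPTER_5,
    GroundTruth,
    ReadArtifactRates,
    largest_remainder,
    simulate_catalog,
    simulate_long_reads,
    simulate_short_reads,
)
from organsnap.divergence import build_pileup
from organsnap.synthetic_data import ORGANS


class TestApportionment:
    @pytest.mark.parametrize(
        "n, props, expected",
        [
            (10, {1: 0.5, 2: 0.5}, {1: 5, 2: 5}),
            # rare positive categories keep one seat; rest by largest remainder
            (100, {1: 0.43, 2: 0.53, 3: 0.033, 4: 0.001}, {1: 43, 2: 53, 3: 3, 4: 1}),
            (7, {"a": 0.6, "b": 0.4}, {"a": 4, "b": 3}),
            (3, {"a": 1.0, "b": 0.0}, {"a": 3, "b": 0}),
        ],
    )
    def test_worked_examples(self, n, props, expected):
        assert largest_remainder(n, props) == expected

    @given(
        n=st.integers(4, 500),
        weights=st.lists(st.floats(0.001, 10.0), min_size=1, max_size=6),
    )
    def test_total_conserved_and_positive_categories_kept(self, n, weights):
        props = {i: w / sum(weights) for i, w in enumerate(weights)}
        counts = largest_remainder(n, props)
        assert sum(counts.values()) == n
        if n >= len(props):
            assert all(counts[k] >= 1 for k, p in props.items() if p > 0)

    def test_invalid_proportions_rejected_with_name(self):
        with pytest.raises(ValueError, match="haplotype_distribution"):
            simulate_catalog(10, haplotype_distribution={1: 0.7, 2: 0.7}, seed=0)
        with pytest.raises(ValueError, match="organ_category_distribution"):
            simulate_catalog(
                10, organ_category_distribution={("bud",): 0.5, ("root",): 0.1}, seed=0
            )


class TestCatalog:
    def test_haplotype_histogram_matches_apportionment_exactly(self):
        truth = simulate_catalog(10, haplotype_distribution={1: 0.5, 2: 0.5}, seed=7)
        assert truth.haplotype_histogram() == {1: 5, 2: 5, 3: 0, 4: 0}

    def test_organ_category_histogram_matches_apportionment(self):
        dist = {("bud",): 0.5, ("root", "leaf"): 0.3, ORGANS: 0.2}
        truth = simulate_catalog(20, organ_category_distribution=dist, seed=3)
        realized = {}
        for cat in truth.organ_categories().values():
            realized[cat] = realized.get(cat, 0) + 1
        assert realized == {("bud",): 10, ("root", "leaf"): 6, ORGANS: 4}

    def test_same_seed_identical_output(self):
        a = simulate_catalog(25, seed=7)
        b = simulate_catalog(25, seed=7)
        assert a.haplotype_sequences == b.haplotype_sequences
        assert a.genes == b.genes

    def test_haplotypes_differ_only_at_divergent_sites_and_are_distinct(self, small_truth):
        for g in small_truth.genes:
            haps = [
                small_truth.haplotype_sequences[(g.gene_id, h)] for h in range(g.n_haplotypes)
            ]
            assert len(set(haps)) == g.n_haplotypes
            for h in haps[1:]:
                diffs = [i for i, (x, y) in enumerate(zip(haps[0], h)) if x != y]
                assert set(diffs) <= set(g.divergent_site_positions)

    def test_adapters_absent_from_haplotypes(self, small_truth):
        for seq in small_truth.haplotype_sequences.values():
            assert DEFAULT_ADAPTER_5 not in seq
            assert DEFAULT_ADAPTER_3 not in seq


class TestLongReads:
    def test_zero_artifacts_reproduce_organ_profiles(self, small_truth):
        reads, sidecar = simulate_long_reads(small_truth, seed=5)
        assert (sidecar.artifact == "clean").all()
        profile = small_truth.profile_frame()
        for organ in ORGANS:
            counts = sidecar[sidecar.organ == organ].gene_id.value_counts()
            for g in small_truth.genes:
                assert counts.get(g.gene_id, 0) == profile.loc[g.gene_id, organ]

    def test_clean_read_architecture(self, small_truth):
        reads, sidecar = simulate_long_reads(small_truth, polya_length=20, seed=5)
        for organ, organ_reads in reads.items():
            for _, seq in organ_reads:
                assert seq.startswith(DEFAULT_ADAPTER_5)
                assert seq.endswith("A" * 20 + DEFAULT_ADAPTER_3)

    def test_forced_concatemer_contains_internal_adapter(self):
        truth = simulate_catalog(1, organ_category_distribution={("bud",): 1.0}, seed=9)
        reads, sidecar = simulate_long_reads(
            truth, artifact_rates=ReadArtifactRates(concatemer_fraction=1.0), seed=9
        )
        all_reads = [seq for organ in reads.values() for _, seq in organ]
        assert all_reads and all(seq.count(DEFAULT_ADAPTER_5) >= 2 for seq in all_reads)
        assert (sidecar.artifact == "concatemer").all()

    def test_reads_partition_across_haplotypes(self):
        truth = simulate_catalog(
            1,
            haplotype_distribution={2: 1.0},
            organ_category_distribution={("root",): 1.0},
            seed=2,
        )
        import dataclasses

        gene = dataclasses.replace(truth.genes[0], organ_profile={"root": 10})
        truth = GroundTruth([gene], truth.haplotype_sequences, truth.seed)
        reads, _ = simulate_long_reads(truth, seed=2)
        h0 = truth.haplotype_sequences[(gene.gene_id, 0)]
        h1 = truth.haplotype_sequences[(gene.gene_id, 1)]
        n0 = sum(h0 in seq for _, seq in reads["root"])
        n1 = sum(h1 in seq for _, seq in reads["root"])
        assert n0 == n1 == 5

    def test_adapter_inside_haplotype_rejected(self, small_truth):
        gene = small_truth.genes[0]
        poisoned = dict(small_truth.haplotype_sequences)
        seq = poisoned[(gene.gene_id, 0)]
        poisoned[(gene.gene_id, 0)] = seq[:50] + DEFAULT_ADAPTER_5 + seq[50:]
        bad = GroundTruth(small_truth.genes, poisoned, small_truth.seed)
        with pytest.raises(ValueError, match="adapter occurs inside"):
            simulate_long_reads(bad, seed=1)


class TestShortReads:
    def test_error_free_reads_are_exact_haplotype_substrings(self):
        truth = simulate_catalog(3, haplotype_distribution={1: 1.0}, seed=4)
        pairs, sams, _ = simulate_short_reads(truth, 10, 200, 0.0, seed=4)
        haps = {g.gene_id: truth.haplotype_sequences[(g.gene_id, 0)] for g in truth.genes}
        for rec in sams:
            assert rec.seq == haps[rec.rname][rec.pos - 1 : rec.pos - 1 + len(rec.seq)]

    def test_divergent_site_pileup_splits_by_haplotype(self):
        truth = simulate_catalog(1, haplotype_distribution={2: 1.0}, seed=6)
        gene = truth.genes[0]
        _, sams, _ = simulate_short_reads(truth, 30, 250, 0.0, seed=6)
        unigenes = {gene.gene_id: truth.haplotype_sequences[(gene.gene_id, 0)]}
        pile, _ = build_pileup(sams, unigenes)
        p = gene.divergent_site_positions[0]
        counts = sorted(pile[gene.gene_id][:, p], reverse=True)[:2]
        assert counts[0] > 0 and counts[1] > 0
        assert abs(counts[0] - counts[1]) <= 0.2 * max(counts)

    def test_site_depth_within_twenty_percent(self, small_truth):
        _, sams, _ = simulate_short_reads(small_truth, 30, 250, 0.0, seed=8)
        unigenes = {
            g.gene_id: small_truth.haplotype_sequences[(g.gene_id, 0)]
            for g in small_truth.genes
        }
        pile, _ = build_pileup(sams, unigenes)
        for g in small_truth.genes:
            expected = 30 * g.n_haplotypes
            for p in g.divergent_site_positions:
                depth = pile[g.gene_id][:, p].sum()
                assert abs(depth - expected) <= 0.2 * expected

    def test_same_seed_identical_reads(self, small_truth):
        a = simulate_short_reads(small_truth, 10, 250, 0.01, seed=3)
        b = simulate_short_reads(small_truth, 10, 250, 0.01, seed=3)
        assert a[0] == b[0] and a[1] == b[1]

    def test_preconditions(self, small_truth):
        with pytest.raises(ValueError, match="depth"):
            simulate_short_reads(small_truth, 0, 250, 0.0, seed=1)
        with pytest.raises(ValueError, match="read_length"):
            simulate_short_reads(small_truth, 10, 10_000, 0.0, seed=1)

    def test_artifact_rates_validation(self):
        with pytest.raises(ValueError):
            ReadArtifactRates(0.6, 0.6, 0.0)
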