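"""Divergent-site calling and distinguishable-haplotype counting.

Given ungapped short-read alignments to unigene references, this module
quantifies single-nucleotide divergence per sequence and asks the ploidy
question operationally: how many *distinguishable* allele/paralog copies of
each gene do the reads support?

The procedure:

1. pile up base counts per reference position (M-only CIGARs; anything else
   is skipped and reported);
2. call divergent sites — positions with adequate depth where at least two
   bases each clear an absolute count and a fractional threshold;
3. reduce every read overlapping a gene's divergent sites to its allele
   pattern over the sites it covers, merge patterns that are compatible
   sub-patterns of fuller ones, and count the supported distinct patterns,
   capped at four (no gene in the study system exceeded four copies).

Genes with zero divergent sites are homozygous (one copy).  Phasing by read
patterns rather than genotype likelihoods keeps the call directly testable
against simulated truth.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SamRecord

_BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}
_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _CODE[ord(_b)] = _i


@dataclass(frozen=True)
class PileupColumn:
    unigene_id: str
    position: int  # 0-based
    base_counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


@dataclass(frozen=True)
class DivergentSite:
    unigene_id: str
    position: int  # 0-based
    alleles: tuple[tuple[str, int], ...]  # (base, count), descending count
    depth: int


@dataclass(frozen=True)
class HaplotypeCall:
    unigene_id: str
    n_haplotypes: int
    n_sites: int
    n_patterns_observed: int
    min_pattern_support: int


@dataclass
class AlleleHistogram:
    counts: dict[object, int]

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts)


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


def build_pileup(
    alignments: Iterable[SamRecord], unigenes: Mapping[str, str]
) -> tuple[dict[str, np.ndarray], int]:
    """Base-count matrices (4 x length) per unigene from ungapped alignments.

    Input positions are 1-based (SAM); internally everything is 0-based.
    Records whose CIGAR is not a single M run are skipped; the count of
    skipped records is returned alongside.
    """
    pile: dict[str, np.ndarray] = {}
    skipped = 0
    for rec in alignments:
        cigar = rec.cigar
        if not cigar.endswith("M") or not cigar[:-1].isdigit():
            skipped += 1
            continue
        if rec.rname not in unigenes:
            skipped += 1
            continue
        length = len(unigenes[rec.rname])
        if rec.rname not in pile:
            pile[rec.rname] = np.zeros((4, length), dtype=np.int32)
        start = rec.pos - 1
        codes = _CODE[np.frombuffer(rec.seq.encode(), dtype=np.uint8)]
        positions = np.arange(start, start + len(codes))
        valid = (codes >= 0) & (positions < length)
        np.add.at(pile[rec.rname], (codes[valid], positions[valid]), 1)
    return pile, skipped


def iter_pileup_columns(pile: Mapping[str, np.ndarray]) -> Iterator[PileupColumn]:
    """Stream non-empty columns (depth 0 omitted) in reference order."""
    for rname in sorted(pile):
        counts = pile[rname]
        depths = counts.sum(axis=0)
        for pos in np.nonzero(depths)[0]:
            yield PileupColumn(
                unigene_id=rname,
                position=int(pos),
                base_counts={
                    b: int(counts[i, pos]) for i, b in enumerate(_BASE_ORDER) if counts[i, pos]
                },
            )


# ---------------------------------------------------------------------------
# divergent sites
# ---------------------------------------------------------------------------


def call_divergent_sites(
    pileups: Mapping[str, np.ndarray] | Iterable[PileupColumn],
    min_depth: int = 10,
    min_allele_fraction: float = 0.20,
    min_allele_count: int = 3,
) -> list[DivergentSite]:
    """Positions where at least two bases clear the depth/count/fraction gates."""
    if min(min_depth, min_allele_count) <= 0 or min_allele_fraction <= 0:
        raise ValueError("thresholds must be positive")
    if isinstance(pileups, Mapping):
        columns: Iterable[PileupColumn] = iter_pileup_columns(pileups)
    else:
        columns = pileups
    sites: list[DivergentSite] = []
    for col in columns:
        depth = col.depth
        if depth < min_depth:
            continue
        alleles = [
            (b, c)
            for b, c in col.base_counts.items()
            if c >= min_allele_count and c / depth >= min_allele_fraction
        ]
        if len(alleles) >= 2:
            alleles.sort(key=lambda bc: (-bc[1], bc[0]))
            sites.append(
                DivergentSite(col.unigene_id, col.position, tuple(alleles), depth)
            )
    return sites


# ---------------------------------------------------------------------------
# haplotype counting
# ---------------------------------------------------------------------------


def _read_patterns(
    sites: Sequence[DivergentSite], alignments: Iterable[SamRecord]
) -> tuple[Counter, int]:
    """Collapse reads to allele patterns over the divergent sites they span."""
    positions = [s.position for s in sites]
    pos_arr = np.asarray(positions)
    patterns: Counter = Counter()
    informative = 0
    for rec in alignments:
        cigar = rec.cigar
        if not cigar.endswith("M") or not cigar[:-1].isdigit():
            continue
        start = rec.pos - 1
        end = start + len(rec.seq)
        covered = np.nonzero((pos_arr >= start) & (pos_arr < end))[0]
        if covered.size == 0:
            continue
        pat = tuple((int(i), rec.seq[positions[i] - start]) for i in covered)
        patterns[pat] += 1
        informative += 1
    return patterns, informative


def _merge_patterns(patterns: Counter) -> list[tuple[tuple, int]]:
    """Merge compatible sub-patterns into fuller ones.

    Patterns are visited fullest-first (more sites, then higher support, then
    lexicographic); each is folded into the first established pattern whose
    alleles agree at every shared site and whose site set contains it,
    otherwise it becomes established itself.
    """
    order = sorted(patterns.items(), key=lambda kv: (-len(kv[0]), -kv[1], kv[0]))
    merged: list[tuple[dict[int, str], int]] = []
    for pat, support in order:
        sites = dict(pat)
        target = None
        for entry in merged:
            canon = entry[0]
            if all(i in canon and canon[i] == b for i, b in sites.items()):
                target = entry
                break
        if target is None:
            merged.append([sites, support])  # type: ignore[arg-type]
        else:
            target[1] += support  # type: ignore[index]
    return [(tuple(sorted(c.items())), s) for c, s in merged]


def count_haplotypes(
    sites: Sequence[DivergentSite],
    alignments: Iterable[SamRecord],
    cap: int = 4,
    min_pattern_support: int = 2,
    min_pattern_fraction: float = 0.05,
) -> HaplotypeCall:
    """Count distinguishable allele/paralog copies of one unigene.

    Distinct merged allele patterns supported by at least
    ``min_pattern_support`` reads and ``min_pattern_fraction`` of the gene's
    informative reads are counted, capped at ``cap``.  Zero divergent sites
    means a single (homozygous) copy.
    """
    unigene_ids = {s.unigene_id for s in sites}
    if len(unigene_ids) > 1:
        raise ValueError(f"sites span multiple unigenes: {sorted(unigene_ids)}")
    unigene_id = next(iter(unigene_ids)) if unigene_ids else ""
    if not sites:
        return HaplotypeCall(unigene_id, 1, 0, 0, min_pattern_support)
    patterns, informative = _read_patterns(sites, alignments)
    merged = _merge_patterns(patterns)
    floor = max(min_pattern_support, min_pattern_fraction * informative)
    qualified = sum(1 for _, support in merged if support >= floor)
    return HaplotypeCall(
        unigene_id=unigene_id,
        n_haplotypes=min(cap, max(1, qualified)),
        n_sites=len(sites),
        n_patterns_observed=len(merged),
        min_pattern_support=min_pattern_support,
    )


# ---------------------------------------------------------------------------
# per-transcriptome driver
# ---------------------------------------------------------------------------


def call_ploidy(
    alignments: Sequence[SamRecord],
    unigenes: Mapping[str, str],
    min_depth: int = 10,
    min_allele_fraction: float = 0.20,
    min_allele_count: int = 3,
    cap: int = 4,
    min_pattern_support: int = 2,
    min_pattern_fraction: float = 0.05,
) -> tuple[list[HaplotypeCall], list[DivergentSite], int]:
    """Site calling plus haplotype counting for every unigene with alignments."""
    pile, skipped = build_pileup(alignments, unigenes)
    sites = call_divergent_sites(pile, min_depth, min_allele_fraction, min_allele_count)
    sites_by_gene: dict[str, list[DivergentSite]] = defaultdict(list)
    for s in sites:
        sites_by_gene[s.unigene_id].append(s)
    reads_by_gene: dict[str, list[SamRecord]] = defaultdict(list)
    for rec in alignments:
        if rec.rname in sites_by_gene:
            reads_by_gene[rec.rname].append(rec)
    calls: list[HaplotypeCall] = []
    for rname in sorted(pile):
        gene_sites = sites_by_gene.get(rname, [])
        if gene_sites:
            calls.append(
                count_haplotypes(
                    gene_sites,
                    reads_by_gene[rname],
                    cap=cap,
                    min_pattern_support=min_pattern_support,
                    min_pattern_fraction=min_pattern_fraction,
                )
            )
        else:
            calls.append(HaplotypeCall(rname, 1, 0, 0, min_pattern_support))
    return calls, sites, skipped


def allele_histogram(calls: Iterable[HaplotypeCall]) -> AlleleHistogram:
    """Histogram of copy-number calls: homozygous / 2 / 3 / 4 genes."""
    counts: dict[object, int] = {"homozygous": 0, 2: 0, 3: 0, 4: 0}
    seen: set[str] = set()
    for call in calls:
        if call.unigene_id in seen:
            raise ValueError(f"duplicate call for unigene {call.unigene_id!r}")
        seen.add(call.unigene_id)
        key: object = "homozygous" if call.n_haplotypes == 1 else call.n_haplotypes
        counts[key] += 1
    return AlleleHistogram(counts=counts)


def sites_table(sites: Iterable[DivergentSite]) -> pd.DataFrame:
    rows = [
        {
            "unigene_id": s.unigene_id,
            "position": s.position,
            "alleles": ",".join(b for b, _ in s.alleles),
            "counts": ",".join(str(c) for _, c in s.alleles),
            "depth": s.depth,
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=["unigene_id", "position", "alleles", "counts", "depth"])


def calls_table(calls: Iterable[HaplotypeCall]) -> pd.DataFrame:
    rows = [
        {
            "unigene_id": c.unigene_id,
            "n_haplotypes": c.n_haplotypes,
            "n_sites": c.n_sites,
            "n_patterns_observed": c.n_patterns_observed,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["unigene_id", "n_haplotypes", "n_sites", "n_patterns_observed"])
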