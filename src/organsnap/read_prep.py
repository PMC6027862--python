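"""Long-read classification and short-read preprocessing.

The long-read side reproduces the full-length non-chimeric (FLNC) triage of
consensus reads of insert: a read is FLNC when the 5' adapter, a poly(A)
tail, and the 3' adapter are found in that order on one strand, with no
additional adapter copy inside; any internal adapter copy marks a chimeric
(concatemeric) molecule; anything else is non-full-length.

The short-read side covers end-quality trimming with a minimum-length gate,
pair bookkeeping (pairs / orphans / dropped), single-pass digital
normalization on the running median k-mer coverage, and decoy filtering by
exact k-mer sharing with a contaminant reference (the role chloroplast decoy
mapping plays in organelle removal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .clustering import reverse_complement

FLNC = "FLNC"
NON_FULL_LENGTH = "NON_FULL_LENGTH"
CHIMERIC = "CHIMERIC"


@dataclass(frozen=True)
class ReadOfInsert:
    read_id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.read_id!r}: quality length != sequence length")


@dataclass(frozen=True)
class ROIClassification:
    category: str
    orientation: str  # forward / reverse / unknown
    adapter5_found: bool
    adapter3_found: bool
    polya_found: bool
    internal_adapter_count: int


@dataclass(frozen=True)
class TrimPolicy:
    min_quality: int = 20
    min_length: int = 150
    k: int = 20
    coverage_cutoff: int = 30

    def __post_init__(self) -> None:
        if min(self.min_quality, self.min_length, self.k, self.coverage_cutoff) <= 0:
            raise ValueError("all trim-policy fields must be positive")


# ---------------------------------------------------------------------------
# FLNC classification
# ---------------------------------------------------------------------------


def _match_starts(seq: str, pattern: str, max_mm: int) -> np.ndarray:
    """Start positions where pattern matches seq with <= max_mm substitutions."""
    if len(seq) < len(pattern):
        return np.empty(0, dtype=int)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, len(p))
    return np.nonzero((windows != p).sum(axis=1) <= max_mm)[0]


def _polya_run(seq: str, end: int, min_polya: int) -> bool:
    """Poly(A) run of >= min_polya A's ending at ``end`` (1 non-A allowed per 10).

    The run is the best window ending at ``end`` whose non-A content stays
    within one per ten bases; its A count must reach ``min_polya``.
    """
    total = non_a = 0
    best = 0
    for i in range(end - 1, -1, -1):
        total += 1
        if seq[i] != "A":
            non_a += 1
            if non_a * 10 > total + 50:  # too degraded to recover
                break
        if non_a * 10 <= total:
            best = max(best, total - non_a)
    return best >= min_polya


def _classify_strand(
    seq: str, adapter5: str, adapter3: str, min_polya: int, max_mm: int
) -> tuple[bool, bool, bool, int, bool]:
    """(adapter5_found, adapter3_found, polya_found, internal_count, arrangement_ok)."""
    starts5 = _match_starts(seq, adapter5, max_mm)
    starts3 = _match_starts(seq, adapter3, max_mm)
    found5 = starts5.size > 0
    pos5_end = int(starts5[0]) + len(adapter5) if found5 else 0
    after3 = starts3[starts3 >= pos5_end] if found5 else starts3
    found3 = after3.size > 0
    pos3 = int(after3[-1]) if found3 else len(seq)
    polya = _polya_run(seq, pos3, min_polya) if found3 else False
    internal = max(0, starts5.size - (1 if found5 else 0)) + max(
        0, starts3.size - (1 if found3 else 0)
    )
    arrangement = found5 and found3 and polya
    return found5, found3, polya, internal, arrangement


def classify_roi(
    read: ReadOfInsert,
    adapter5: str,
    adapter3: str,
    min_polya: int = 10,
    max_adapter_mismatches: int = 2,
) -> ROIClassification:
    """Classify one read of insert as FLNC, non-full-length, or chimeric.

    Both strands are searched; the orientation is the strand on which the
    complete 5'-insert-polyA-3' arrangement is found (forward preferred on
    ties), ``unknown`` when neither strand shows it.  Any additional adapter
    copy beyond the terminal pair makes the read chimeric.
    """
    if not adapter5 or not adapter3:
        raise ValueError("adapters must be non-empty")
    if min_polya < 5:
        raise ValueError("min_polya must be >= 5")
    fwd = _classify_strand(read.sequence, adapter5, adapter3, min_polya, max_adapter_mismatches)
    rev = _classify_strand(
        reverse_complement(read.sequence), adapter5, adapter3, min_polya, max_adapter_mismatches
    )
    if fwd[4]:
        chosen, orientation = fwd, "forward"
    elif rev[4]:
        chosen, orientation = rev, "reverse"
    else:
        chosen = fwd if sum(fwd[:3]) >= sum(rev[:3]) else rev
        orientation = "unknown"
    found5, found3, polya, internal, arrangement = chosen
    if internal > 0:
        category = CHIMERIC
    elif arrangement:
        category = FLNC
    else:
        category = NON_FULL_LENGTH
    return ROIClassification(
        category=category,
        orientation=orientation,
        adapter5_found=found5,
        adapter3_found=found3,
        polya_found=polya,
        internal_adapter_count=internal,
    )


# ---------------------------------------------------------------------------
# quality trimming
# ---------------------------------------------------------------------------


def trim_read(read: ReadOfInsert, policy: TrimPolicy) -> ReadOfInsert | None:
    """End-trim bases below the quality floor; drop reads shorter than the gate.

    Only leading and trailing low-quality bases are removed — interior bases
    keep their coordinates.  Returns ``None`` for dropped reads.
    """
    if read.quality is None:
        raise ValueError(f"read {read.read_id!r} has no quality values")
    q = np.asarray(read.quality)
    good = np.nonzero(q >= policy.min_quality)[0]
    if good.size == 0:
        return None
    lo, hi = int(good[0]), int(good[-1]) + 1
    if hi - lo < policy.min_length:
        return None
    return ReadOfInsert(read.read_id, read.sequence[lo:hi], tuple(read.quality[lo:hi]))


def _pair_key(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def trim_pairs(
    pairs: Iterable[tuple[ReadOfInsert, ReadOfInsert]], policy: TrimPolicy
) -> tuple[list[tuple[ReadOfInsert, ReadOfInsert]], list[ReadOfInsert], int]:
    """Trim both mates; returns (surviving pairs, orphans, dropped-read count)."""
    kept: list[tuple[ReadOfInsert, ReadOfInsert]] = []
    orphans: list[ReadOfInsert] = []
    dropped = 0
    for r1, r2 in pairs:
        if _pair_key(r1.read_id) != _pair_key(r2.read_id):
            raise ValueError(f"unmatched mate ids: {r1.read_id!r} vs {r2.read_id!r}")
        t1, t2 = trim_read(r1, policy), trim_read(r2, policy)
        if t1 is not None and t2 is not None:
            kept.append((t1, t2))
        elif t1 is not None:
            orphans.append(t1)
            dropped += 1
        elif t2 is not None:
            orphans.append(t2)
            dropped += 1
        else:
            dropped += 2
    return kept, orphans, dropped


# ---------------------------------------------------------------------------
# digital normalization
# ---------------------------------------------------------------------------


def _kmers(seq: str, k: int) -> list[str]:
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def digital_normalize(
    reads: Iterable[tuple[str, str]], k: int = 20, coverage_cutoff: int = 30
) -> list[tuple[str, str]]:
    """Single-pass redundancy reduction on running median k-mer coverage.

    A read is retained iff the median abundance of its k-mers — counted over
    the reads retained so far — is below the cutoff; retained reads then
    update the table.  Order-dependent by design, like streaming
    normalization tools.
    """
    counts: dict[str, int] = {}
    retained: list[tuple[str, str]] = []
    for read_id, seq in reads:
        if len(seq) < k:
            raise ValueError(f"read {read_id!r} is shorter than k={k}")
        kmers = _kmers(seq, k)
        median = float(np.median([counts.get(m, 0) for m in kmers]))
        if median < coverage_cutoff:
            retained.append((read_id, seq))
            for m in kmers:
                counts[m] = counts.get(m, 0) + 1
    return retained


# ---------------------------------------------------------------------------
# decoy filtering
# ---------------------------------------------------------------------------


def decoy_filter(
    pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]],
    decoy_reference: str,
    k: int = 20,
    hit_fraction: float = 0.5,
) -> tuple[list[tuple[tuple[str, str], tuple[str, str]]], int]:
    """Remove pairs matching a contaminant reference by k-mer sharing.

    A pair is removed when at least ``hit_fraction`` of either mate's k-mers
    occur (on either strand) in the decoy's k-mer index; the boundary is
    inclusive.  Returns (retained pairs, number removed).
    """
    if not decoy_reference:
        raise ValueError("decoy reference must be non-empty")
    index = set(_kmers(decoy_reference, k)) | set(_kmers(reverse_complement(decoy_reference), k))

    def _hits(seq: str) -> float:
        kmers = _kmers(seq, k)
        if not kmers:
            return 0.0
        return sum(m in index for m in kmers) / len(kmers)

    kept = []
    removed = 0
    for pair in pairs:
        (id1, s1), (id2, s2) = pair
        if _hits(s1) >= hit_fraction or _hits(s2) >= hit_fraction:
            removed += 1
        else:
            kept.append(pair)
    return kept, removed
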