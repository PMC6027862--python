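"""Greedy incremental identity clustering with longest-sequence representatives.

The redundancy-reduction step of the pipeline mirrors the behaviour of
incremental nucleotide clusterers used for transcript collapse: sequences are
sorted longest-first and each one either joins the first existing cluster
whose representative it matches at or above the identity threshold, or founds
a new cluster.  Because the longest sequence of any group is processed first,
representatives are always the longest member — the property that lets a
reduced transcript set retain full-length, UTR-bearing variants.

Identity between two sequences is defined as ``1 - d / len(shorter)`` where
``d`` is the minimum edit distance of the shorter sequence aligned
semi-globally (end gaps free) against the longer, taken on the better of the
two strands.  Exact duplicates, substrings and reverse complements therefore
all score 1.0.

Two implementations are provided:

* :func:`greedy_cluster` — the production path (edlib band-limited distances,
  shared-word candidate prefilter).
* :func:`exhaustive_cluster` — an independent reference implementation used
  for validation: it computes every pairwise identity with a pure-numpy
  dynamic program (:func:`semiglobal_distance`) and applies the same
  longest-first, first-qualifying rule with no shortcuts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import edlib
import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptRecord:
    """One nucleotide sequence with its source library label."""

    seq_id: str
    sequence: str
    source_label: str = "merged"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.seq_id!r}")


class ClusterMember(NamedTuple):
    seq_id: str
    identity: float
    strand: str  # '+' or '-': strand on which the member matched the representative
    source_label: str


@dataclass
class Cluster:
    representative: str
    members: list[ClusterMember] = field(default_factory=list)


@dataclass
class ClusterSet:
    threshold: float
    clusters: list[Cluster] = field(default_factory=list)

    def representatives(self) -> list[str]:
        return [c.representative for c in self.clusters]

    def member_ids(self) -> list[str]:
        return [m.seq_id for c in self.clusters for m in c.members]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass
class ClusterChain:
    """Ordered reduction stages; stage i+1's inputs are stage i's representatives."""

    stages: list[ClusterSet]

    def backtrack(self) -> dict[str, list[str]]:
        """Map each final-stage representative to its original (stage-0 member) ids."""
        # expansion[stage][id] -> member ids of the cluster represented by id at that stage
        maps = []
        for stage in self.stages:
            maps.append({c.representative: [m.seq_id for m in c.members] for c in stage.clusters})
        out: dict[str, list[str]] = {}
        for rep in self.stages[-1].representatives():
            frontier = [rep]
            for level in range(len(self.stages) - 1, -1, -1):
                frontier = [leaf for node in frontier for leaf in maps[level][node]]
            out[rep] = frontier
        return out


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------


def _edlib_distance(query: str, target: str, k: int = -1) -> int:
    """Semi-global (end gaps free in target) edit distance; -1 if > k."""
    return edlib.align(query, target, mode="HW", task="distance", k=k)["editDistance"]


def _identity_strand(a: str, b: str, max_edits: int | None = None) -> tuple[float, str]:
    """Identity of the shorter sequence inside the longer, best strand.

    When ``max_edits`` is given, pairs beyond it report identity -1 (cheap
    band-limited rejection).
    """
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    k = -1 if max_edits is None else max_edits
    d_fwd = _edlib_distance(query, target, k)
    d_rev = _edlib_distance(reverse_complement(query), target, k)
    candidates = [(d, s) for d, s in ((d_fwd, "+"), (d_rev, "-")) if d >= 0]
    if not candidates:
        return -1.0, "+"
    d, strand = min(candidates)
    return 1.0 - d / len(query), strand


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of the shorter sequence matched in a free-end-gap alignment (best strand)."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    identity, _ = _identity_strand(a, b)
    return max(0.0, identity)


def semiglobal_distance(query: str, target: str) -> int:
    """Reference DP: minimum edit distance of query against any target window.

    End gaps in the target are free (query is aligned in full).  Independent
    of edlib; used by :func:`exhaustive_cluster` and validation tests.
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    n = len(t)
    ramp = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)  # row 0: leading target gap is free
    v = np.empty(n + 1, dtype=np.int32)
    for i in range(1, len(q) + 1):
        v[0] = i
        np.minimum(prev[:-1] + (t != q[i - 1]), prev[1:] + 1, out=v[1:])
        # horizontal moves cost 1 each: cur[j] = min_{j'<=j} v[j'] + (j - j')
        cur = np.minimum.accumulate(v - ramp) + ramp
        prev = cur
    return int(prev.min())


def reference_identity(a: str, b: str) -> float:
    """Identity computed with the numpy DP (both strands); oracle for pairwise_identity."""
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    d = min(
        semiglobal_distance(query, target),
        semiglobal_distance(reverse_complement(query), target),
    )
    return max(0.0, 1.0 - d / len(query))


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------


def _sorted_records(records: Sequence[TranscriptRecord]) -> list[TranscriptRecord]:
    seen: set[str] = set()
    for r in records:
        if r.seq_id in seen:
            raise ValueError(f"duplicate seq_id {r.seq_id!r} in clustering input")
        seen.add(r.seq_id)
    return sorted(records, key=lambda r: (-len(r.sequence), r.seq_id))


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _word_set(seq: str, k: int) -> frozenset[int]:
    """Forward-strand k-mers encoded as integers; empty if ambiguous bases present."""
    if len(seq) < k:
        return frozenset()
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        return frozenset()
    # convolution flips the kernel, so an ascending power ramp encodes each
    # window as sum(codes[j+i] * 4**(k-1-i)) — a positional base-4 word code
    kernel = 4 ** np.arange(k, dtype=np.int64)
    words = np.convolve(codes, kernel, mode="valid")
    return frozenset(words.tolist())


def _max_edits(threshold: float, shorter_len: int) -> int:
    return math.floor((1.0 - threshold) * shorter_len + 1e-9)


def greedy_cluster(
    records: Sequence[TranscriptRecord],
    threshold: float,
    word_size: int = 8,
) -> ClusterSet:
    """Longest-first incremental clustering at an identity threshold.

    Records are processed longest-first (ties: ascending seq_id) and each
    joins the *first* cluster, in founding order, whose representative matches
    at identity >= threshold; otherwise it founds a new cluster.

    The shared-word candidate prefilter is applied only when the pigeonhole
    bound guarantees that any qualifying pair must share an exact word of
    ``word_size`` (``ceil((m - e) / (e + 1)) >= word_size`` with ``e`` the
    edit budget at the threshold); otherwise every cluster is a candidate, so
    the prefilter can never change the result.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = _sorted_records(records)
    reps: list[TranscriptRecord] = []
    rep_words: list[frozenset[int]] = []
    out = ClusterSet(threshold=threshold)
    for rec in ordered:
        m = len(rec.sequence)
        e = _max_edits(threshold, m)
        guaranteed_word = math.ceil((m - e) / (e + 1))
        use_filter = guaranteed_word >= word_size
        if use_filter:
            words = _word_set(rec.sequence, word_size) | _word_set(
                reverse_complement(rec.sequence), word_size
            )
            use_filter = bool(words)
        placed = False
        for idx, rep in enumerate(reps):
            if use_filter and words.isdisjoint(rep_words[idx]):
                continue
            identity, strand = _identity_strand(rec.sequence, rep.sequence, max_edits=e)
            if identity >= threshold - 1e-12:
                out.clusters[idx].members.append(
                    ClusterMember(rec.seq_id, identity, strand, rec.source_label)
                )
                placed = True
                break
        if not placed:
            reps.append(rec)
            rep_words.append(_word_set(rec.sequence, word_size))
            out.clusters.append(
                Cluster(
                    representative=rec.seq_id,
                    members=[ClusterMember(rec.seq_id, 1.0, "+", rec.source_label)],
                )
            )
    return out


def exhaustive_cluster(records: Sequence[TranscriptRecord], threshold: float) -> ClusterSet:
    """Brute-force reference: all-pairs DP identities + the same longest-first rule."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = _sorted_records(records)
    out = ClusterSet(threshold=threshold)
    reps: list[TranscriptRecord] = []
    for rec in ordered:
        placed = False
        for idx, rep in enumerate(reps):
            d_fwd = semiglobal_distance(rec.sequence, rep.sequence)
            d_rev = semiglobal_distance(reverse_complement(rec.sequence), rep.sequence)
            d, strand = min((d_fwd, "+"), (d_rev, "-"))
            identity = 1.0 - d / len(rec.sequence)
            if identity >= threshold - 1e-12:
                out.clusters[idx].members.append(
                    ClusterMember(rec.seq_id, identity, strand, rec.source_label)
                )
                placed = True
                break
        if not placed:
            reps.append(rec)
            out.clusters.append(
                Cluster(rec.seq_id, [ClusterMember(rec.seq_id, 1.0, "+", rec.source_label)])
            )
    return out


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


def chain(stages: Sequence[ClusterSet]) -> ClusterChain:
    """Validate that consecutive stages nest and return the chain.

    Stage ``i+1``'s member ids must be exactly stage ``i``'s representatives.
    """
    if not stages:
        raise ValueError("chain requires at least one stage")
    for i in range(len(stages) - 1):
        reps = set(stages[i].representatives())
        inputs = set(stages[i + 1].member_ids())
        missing = reps - inputs
        extra = inputs - reps
        if missing or extra:
            offender = sorted(missing or extra)[0]
            kind = "missing from" if missing else "foreign to"
            raise ValueError(
                f"stage {i + 1} inputs do not match stage {i} representatives: "
                f"{offender!r} is {kind} stage {i + 1}"
            )
    return ClusterChain(stages=list(stages))


def combine_cluster_sets(sets: Iterable[ClusterSet], threshold: float) -> ClusterSet:
    """Union of disjoint cluster sets (e.g. the per-organ stage) as one stage."""
    clusters: list[Cluster] = []
    seen: set[str] = set()
    for cs in sets:
        for c in cs.clusters:
            for m in c.members:
                if m.seq_id in seen:
                    raise ValueError(f"seq_id {m.seq_id!r} present in more than one set")
                seen.add(m.seq_id)
            clusters.append(c)
    return ClusterSet(threshold=threshold, clusters=clusters)


def mean_gc(sequences: Iterable[str]) -> float:
    """Pooled GC fraction over unambiguous bases (helper for drift checks)."""
    gc = at = 0
    for s in sequences:
        u = s.upper()
        gc += u.count("G") + u.count("C")
        at += u.count("A") + u.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases")
    return gc / (gc + at)
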