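"""ORF finding and domain co-occurrence screening.

The resistance-gene (R-gene) screen applies the field's operational rule:
a transcript is a putative R-gene when a single open reading frame carries
both a nucleotide-binding domain (NB-ARC) and a leucine-rich-repeat (LRR)
domain.  Domain calls arrive as Pfam-scan-like tables produced elsewhere;
this module supplies the deterministic ORF decomposition the rule needs and
the co-occurrence logic itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .clustering import reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"

DEFAULT_NBARC_NAMES = frozenset({"NB-ARC"})


@dataclass(frozen=True)
class OrfSpan:
    unigene_id: str
    frame: int  # +1,+2,+3 forward; -1,-2,-3 reverse
    start: int  # 0-based half-open on the forward strand
    end: int
    aa_length: int  # codons before the stop

    @property
    def orf_key(self) -> tuple[int, int]:
        return (self.frame, self.start)


@dataclass(frozen=True)
class DomainHit:
    unigene_id: str
    orf_key: tuple[int, int]  # (frame, forward-strand start)
    domain_name: str
    aa_start: int  # 1-based inclusive
    aa_end: int
    score: float


def _frame_orfs(seq: str, offset: int) -> list[tuple[int, int, int]]:
    """(start, end, aa_length) spans, in frame coordinates on the given strand.

    A span runs from the first ATG after the previous stop to the stop codon
    inclusive.
    """
    orfs = []
    start = None
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon == START_CODON and start is None:
            start = i
        elif codon in STOP_CODONS:
            if start is not None:
                end = i + 3
                orfs.append((start, end, (end - start) // 3 - 1))
            start = None
    return orfs


def longest_orf(sequence: str, unigene_id: str = "", min_aa: int = 0) -> OrfSpan | None:
    """Longest start-to-stop span over all six frames.

    Coordinates are reported 0-based half-open on the forward strand; ties
    break toward the forward strand, then the lowest frame, then the lowest
    start.  Returns ``None`` when no ORF of at least ``min_aa`` codons (stop
    excluded) exists.
    """
    if len(sequence) < 3:
        raise ValueError("sequence must be at least one codon long")
    seq = sequence.upper()
    rc = reverse_complement(seq)
    n = len(seq)
    candidates: list[tuple[int, int, int, int, OrfSpan]] = []
    for strand, s in ((1, seq), (-1, rc)):
        for offset in range(3):
            frame = strand * (offset + 1)
            for start, end, aa in _frame_orfs(s, offset):
                if strand == 1:
                    fwd_start, fwd_end = start, end
                else:
                    fwd_start, fwd_end = n - end, n - start
                span = OrfSpan(unigene_id, frame, fwd_start, fwd_end, aa)
                strand_rank = 0 if strand == 1 else 1
                candidates.append((-aa, strand_rank, offset + 1, fwd_start, span))
    candidates = [c for c in candidates if c[4].aa_length >= max(min_aa, 1)]
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[:4])
    return candidates[0][4]


def _is_lrr(name: str, lrr_names: frozenset[str] | None) -> bool:
    if lrr_names is None:
        return name.startswith("LRR")
    return name in lrr_names


def rgene_screen(
    hits: Iterable[DomainHit],
    nbarc_names: frozenset[str] = DEFAULT_NBARC_NAMES,
    lrr_names: frozenset[str] | None = None,
) -> list[str]:
    """Unigenes with an NB-ARC and an LRR domain inside the *same* ORF.

    ``lrr_names=None`` uses the default family rule (any domain name
    beginning "LRR", covering LRR_1..LRR_9 and relatives); passing an
    explicit set restricts matching to exactly those names.  Output is
    sorted and unique, invariant to hit order and duplication.
    """
    if not nbarc_names:
        raise ValueError("nbarc_names must be non-empty")
    if lrr_names is not None and not lrr_names:
        raise ValueError("lrr_names must be non-empty (or None for the default rule)")
    per_orf: dict[tuple[str, tuple[int, int]], list[bool]] = {}
    for hit in hits:
        key = (hit.unigene_id, hit.orf_key)
        entry = per_orf.setdefault(key, [False, False])
        if hit.domain_name in nbarc_names:
            entry[0] = True
        if _is_lrr(hit.domain_name, lrr_names):
            entry[1] = True
    qualifying = {uid for (uid, _), (has_nb, has_lrr) in per_orf.items() if has_nb and has_lrr}
    return sorted(qualifying)


def term_select(table: Mapping[str, Iterable[str]] | pd.DataFrame, term: str) -> list[str]:
    """Unigene ids annotated with an exact (case-insensitive) term."""
    term_lower = term.lower()
    if isinstance(table, pd.DataFrame):
        mapping: dict[str, list[str]] = {}
        for uid, t in zip(table.iloc[:, 0], table.iloc[:, 1]):
            mapping.setdefault(str(uid), []).append(str(t))
    else:
        mapping = {u: list(ts) for u, ts in table.items()}
    return sorted(u for u, ts in mapping.items() if any(t.lower() == term_lower for t in ts))


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def read_domain_table(path: str | Path) -> list[DomainHit]:
    """Pfam-scan-like TSV: id, domain, aa_start, aa_end, score.

    The id column encodes the translated ORF as ``unigene|frame|start``
    (amino-acid coordinates in the table are 1-based, per the upstream
    convention).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    hits = []
    for _, row in df.iterrows():
        seq_id = str(row.iloc[0])
        try:
            unigene, frame, start = seq_id.rsplit("|", 2)
        except ValueError as exc:
            raise ValueError(f"id {seq_id!r} is not of the form unigene|frame|start") from exc
        hits.append(
            DomainHit(
                unigene_id=unigene,
                orf_key=(int(frame), int(start)),
                domain_name=str(row.iloc[1]),
                aa_start=int(row.iloc[2]),
                aa_end=int(row.iloc[3]),
                score=float(row.iloc[4]),
            )
        )
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    rows = [
        {
            "seq_id": f"{h.unigene_id}|{h.orf_key[0]}|{h.orf_key[1]}",
            "domain": h.domain_name,
            "aa_start": h.aa_start,
            "aa_end": h.aa_end,
            "score": h.score,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=["seq_id", "domain", "aa_start", "aa_end", "score"]).to_csv(
        path, sep="\t", index=False
    )
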