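"""Transcriptome summary statistics, genome-size arithmetic, BUSCO percentages.

Small, exactly-specified computations: N50 and pooled GC over a sequence
set; flow-cytometry genome size from sample/reference fluorescence peak
means against an external standard of known 2C DNA mass (sample 2C =
reference 2C x sample peak / reference peak, converted to base pairs at
0.978 x 10^9 bp per pg); and BUSCO category percentages with half-up
rounding at a chosen precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

PG_TO_BP = 0.978e9  # base pairs per picogram of (double-stranded) DNA


@dataclass(frozen=True)
class FlowSample:
    sample_peak_mean: float
    reference_peak_mean: float
    reference_2c_pg: float

    def __post_init__(self) -> None:
        if min(self.sample_peak_mean, self.reference_peak_mean, self.reference_2c_pg) <= 0:
            raise ValueError("flow-cytometry peaks and reference mass must be positive")


@dataclass(frozen=True)
class BuscoCounts:
    complete: int
    duplicated: int
    fragmented: int
    missing: int

    def __post_init__(self) -> None:
        if min(self.complete, self.duplicated, self.fragmented, self.missing) < 0:
            raise ValueError("BUSCO counts must be non-negative")
        if self.duplicated > self.complete:
            raise ValueError("duplicated BUSCOs are a subset of complete BUSCOs")

    @property
    def total(self) -> int:
        return self.complete + self.fragmented + self.missing


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L such that sequences >= L hold at least half the bases."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def gc_content(sequences: Iterable[str]) -> float:
    """Pooled GC percentage over all sequences; ambiguous bases excluded."""
    gc = at = 0
    for seq in sequences:
        u = seq.upper()
        gc += u.count("G") + u.count("C")
        at += u.count("A") + u.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases in input")
    return 100.0 * gc / (gc + at)


def genome_size_pg(sample: FlowSample) -> float:
    """2C DNA mass from the fluorescence-ratio equation against the standard."""
    return sample.reference_2c_pg * sample.sample_peak_mean / sample.reference_peak_mean


def pg_to_bp(pg: float) -> float:
    """Picograms of DNA to base pairs (0.978 x 10^9 bp/pg)."""
    if pg <= 0:
        raise ValueError("mass must be positive")
    return pg * PG_TO_BP


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def busco_percentages(counts: BuscoCounts, decimals: int = 1) -> dict[str, float]:
    """Complete / duplicated / fragmented / missing as percentages of the total.

    Duplicated is reported as a share of the same total (it is a subset of
    complete).  Values are rounded half-up to ``decimals``.
    """
    total = counts.total
    if total <= 0:
        raise ValueError("BUSCO total must be positive")
    return {
        "complete": _round_half_up(100.0 * counts.complete / total, decimals),
        "duplicated": _round_half_up(100.0 * counts.duplicated / total, decimals),
        "fragmented": _round_half_up(100.0 * counts.fragmented / total, decimals),
        "missing": _round_half_up(100.0 * counts.missing / total, decimals),
    }


def transcript_stats(sequences: Sequence[str]) -> dict[str, float]:
    """n, total length, N50, max length and pooled GC% of a sequence set."""
    if not sequences:
        raise ValueError("empty sequence set")
    lengths = [len(s) for s in sequences]
    return {
        "n": len(sequences),
        "total_length": sum(lengths),
        "n50": n50(lengths),
        "max_length": max(lengths),
        "gc_percent": gc_content(sequences),
    }
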