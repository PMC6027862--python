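"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA/FASTQ go through Biopython, SAM parsing through pysam; the ``.clstr``
cluster-file dialect (">Cluster N" headers, one member per line with the
representative starred) has no library support and is implemented here so
that cluster chains can be written, shipped, and re-read bit-exactly.

Coordinates are 0-based half-open everywhere inside the package; the SAM and
domain-table boundaries are the only places 1-based coordinates appear.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clustering import Cluster, ClusterMember, ClusterSet


def get_logger(stage: str) -> logging.Logger:
    """Stage-tagged logger writing to stderr; machine output goes to files only."""
    logger = logging.getLogger(f"organsnap.{stage}")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(f"[{stage}] %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return out


def write_fastq(records: Iterable[tuple[str, str, list[int]]], path: str | Path) -> None:
    seq_records = []
    for read_id, seq, quals in records:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        seq_records.append(rec)
    SeqIO.write(seq_records, str(path), "fastq")


# ---------------------------------------------------------------------------
# SAM subset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamRecord:
    """The alignment fields the pipeline consumes; ``pos`` is 1-based."""

    qname: str
    flag: int
    rname: str
    pos: int
    cigar: str
    seq: str


def write_sam(
    records: Iterable[SamRecord], ref_lengths: Mapping[str, int], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in ref_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in records:
            fh.write(
                f"{r.qname}\t{r.flag}\t{r.rname}\t{r.pos}\t60\t{r.cigar}\t*\t0\t0\t"
                f"{r.seq}\t*\n"
            )


def read_sam(path: str | Path) -> tuple[list[SamRecord], dict[str, int]]:
    records: list[SamRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        ref_lengths = dict(zip(fh.references, fh.lengths))
        for rec in fh:
            if rec.is_unmapped:
                continue
            records.append(
                SamRecord(
                    qname=rec.query_name,
                    flag=rec.flag,
                    rname=rec.reference_name,
                    pos=rec.reference_start + 1,
                    cigar=rec.cigarstring or "",
                    seq=rec.query_sequence or "",
                )
            )
    return records, ref_lengths


# ---------------------------------------------------------------------------
# .clstr dialect
# ---------------------------------------------------------------------------


def write_clstr(
    cluster_set: ClusterSet, lengths: Mapping[str, int], path: str | Path
) -> None:
    """Write the standard .clstr dialect; the representative line ends in '*'."""
    with open(path, "w") as fh:
        for i, cluster in enumerate(cluster_set.clusters):
            fh.write(f">Cluster {i}\n")
            for j, member in enumerate(cluster.members):
                line = f"{j}\t{lengths[member.seq_id]}nt, >{member.seq_id}... "
                if member.seq_id == cluster.representative:
                    line += "*"
                else:
                    line += f"at {member.strand}/{member.identity * 100:.2f}%"
                fh.write(line + "\n")


def read_clstr(
    path: str | Path, source_labels: Mapping[str, str] | None = None
) -> tuple[ClusterSet, dict[str, int]]:
    """Parse a .clstr file back into a ClusterSet plus member lengths.

    Source labels are not part of the dialect; pass a map to restore them.
    """
    labels = source_labels or {}
    clusters: list[Cluster] = []
    lengths: dict[str, int] = {}
    current: Cluster | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">Cluster"):
                current = Cluster(representative="", members=[])
                clusters.append(current)
                continue
            if current is None:
                raise ValueError(f"{path}:{lineno}: member line before any cluster header")
            try:
                _, rest = line.split("\t", 1)
                size_part, rest = rest.split("nt, >", 1)
                seq_id, tail = rest.split("... ", 1)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed member line: {line!r}") from exc
            lengths[seq_id] = int(size_part)
            if tail == "*":
                current.representative = seq_id
                current.members.append(
                    ClusterMember(seq_id, 1.0, "+", labels.get(seq_id, "merged"))
                )
            else:
                if not tail.startswith("at "):
                    raise ValueError(f"{path}:{lineno}: malformed identity field: {tail!r}")
                strand, pct = tail[3:].split("/")
                current.members.append(
                    ClusterMember(
                        seq_id,
                        float(pct.rstrip("%")) / 100.0,
                        strand,
                        labels.get(seq_id, "merged"),
                    )
                )
    for i, cluster in enumerate(clusters):
        if not cluster.representative:
            raise ValueError(f"{path}: cluster {i} has no representative line")
    return ClusterSet(threshold=float("nan"), clusters=clusters), lengths


# ---------------------------------------------------------------------------
# flat key=value config
# ---------------------------------------------------------------------------


def parse_config(path: str | Path) -> dict[str, str]:
    """Flat ``key=value`` file; '#' starts a comment, blank lines ignored."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def iter_fasta_lazy(path: str | Path) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()
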