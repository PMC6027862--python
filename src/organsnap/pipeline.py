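"""End-to-end pipeline driver: classify -> cluster -> chain -> snapshot.

Stage order mirrors the study design: per-organ read classification keeps
only full-length non-chimeric reads; each organ is collapsed at 100%
identity; the collapsed representatives are merged and reduced again at each
configured threshold (default 100% then 90%); the final representatives are
the unigene set, backtracked through the cluster chain to per-organ counts.

A run manifest records the configuration, input checksums and per-stage
record counts with conservation checks, so identical configuration and
inputs reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import clustering, organ_snapshot, read_prep, summary_stats
from .io import get_logger, parse_config, read_fasta, write_clstr, write_fasta
from .synthetic_data import DEFAULT_ADAPTER_3, DEFAULT_ADAPTER_5

_log = get_logger("pipeline")


@dataclass
class PipelineConfig:
    organs: tuple[str, ...] = organ_snapshot.ORGANS
    identity_thresholds: tuple[float, ...] = (1.0, 0.90)
    adapter5: str = DEFAULT_ADAPTER_5
    adapter3: str = DEFAULT_ADAPTER_3
    min_polya: int = 10
    max_adapter_mismatches: int = 2
    word_size: int = 8
    min_reads: int = 1  # presence threshold for upset categories
    seed: int = 0
    outdir: str = "organsnap_out"

    def __post_init__(self) -> None:
        if len(set(self.organs)) != len(self.organs):
            raise ValueError("organ labels must be unique")
        thresholds = tuple(self.identity_thresholds)
        if any(t2 >= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
            raise ValueError("identity thresholds must be strictly decreasing")
        self.identity_thresholds = thresholds

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = parse_config(path)
        kwargs: dict = {}
        if "organs" in raw:
            kwargs["organs"] = tuple(raw["organs"].split(","))
        if "identity_thresholds" in raw:
            kwargs["identity_thresholds"] = tuple(
                float(x) for x in raw["identity_thresholds"].split(",")
            )
        for key in ("adapter5", "adapter3", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("min_polya", "max_adapter_mismatches", "word_size", "min_reads", "seed"):
            if key in raw:
                kwargs[key] = int(raw[key])
        return cls(**kwargs)


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict[str, str]
    stage_counts: dict[str, int] = field(default_factory=dict)
    conservation_ok: bool = False
    version: str = "1.0.0"

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    organ_reads: Mapping[str, Sequence[tuple[str, str]]] | Mapping[str, str | Path],
    outdir: str | Path | None = None,
) -> dict:
    """Run the full long-read pipeline and write all outputs.

    ``organ_reads`` maps organ labels to either in-memory ``(id, seq)`` lists
    or FASTA paths.  Returns a dict with the matrix, tallies, chain, unigene
    records and manifest.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    reads: dict[str, list[tuple[str, str]]] = {}
    checksums: dict[str, str] = {}
    for organ in config.organs:
        source = organ_reads.get(organ, [])
        if isinstance(source, (str, Path)):
            reads[organ] = read_fasta(source)
        else:
            reads[organ] = list(source)
        checksums[organ] = _sha256("".join(f">{i}\n{s}\n" for i, s in reads[organ]))

    manifest = RunManifest(
        config={
            **{k: v for k, v in asdict(config).items()},
            "organs": list(config.organs),
            "identity_thresholds": list(config.identity_thresholds),
        },
        input_checksums=checksums,
    )

    # stage 1: FLNC classification per organ
    flnc: dict[str, list[tuple[str, str]]] = {}
    class_rows = []
    for organ in config.organs:
        flnc[organ] = []
        for read_id, seq in reads[organ]:
            cls = read_prep.classify_roi(
                read_prep.ReadOfInsert(read_id, seq),
                config.adapter5,
                config.adapter3,
                config.min_polya,
                config.max_adapter_mismatches,
            )
            class_rows.append(
                {
                    "read_id": read_id,
                    "organ": organ,
                    "category": cls.category,
                    "orientation": cls.orientation,
                    "adapter5_found": cls.adapter5_found,
                    "adapter3_found": cls.adapter3_found,
                    "polya_found": cls.polya_found,
                    "internal_adapter_count": cls.internal_adapter_count,
                }
            )
            if cls.category == read_prep.FLNC:
                flnc[organ].append((read_id, seq))
        manifest.stage_counts[f"reads_in_{organ}"] = len(reads[organ])
        manifest.stage_counts[f"flnc_{organ}"] = len(flnc[organ])
        _log.info("%s: %d reads, %d FLNC", organ, len(reads[organ]), len(flnc[organ]))
    pd.DataFrame(class_rows).to_csv(out / "roi_classification.tsv", sep="\t", index=False)

    sequences: dict[str, str] = {}
    organ_of_read: dict[str, str] = {}
    for organ in config.organs:
        for read_id, seq in flnc[organ]:
            sequences[read_id] = seq
            organ_of_read[read_id] = organ

    # stage 2: per-organ collapse at the first (highest) threshold
    first_threshold = config.identity_thresholds[0]
    per_organ_sets = []
    for organ in config.organs:
        records = [
            clustering.TranscriptRecord(read_id, seq, organ) for read_id, seq in flnc[organ]
        ]
        per_organ_sets.append(
            clustering.greedy_cluster(records, first_threshold, config.word_size)
        )
    stage0 = clustering.combine_cluster_sets(per_organ_sets, first_threshold)
    stages = [stage0]
    write_clstr(stage0, {i: len(sequences[i]) for i in stage0.member_ids()}, out / "stage0_per_organ.clstr")
    manifest.stage_counts["stage0_clusters"] = stage0.n_clusters

    # stage 3: merged reduction at every configured threshold
    for level, threshold in enumerate(config.identity_thresholds, start=1):
        prev_reps = stages[-1].representatives()
        records = [
            clustering.TranscriptRecord(rep, sequences[rep], "merged") for rep in prev_reps
        ]
        stage = clustering.greedy_cluster(records, threshold, config.word_size)
        stages.append(stage)
        write_clstr(
            stage,
            {i: len(sequences[i]) for i in stage.member_ids()},
            out / f"stage{level}_merged_{int(round(threshold * 100))}.clstr",
        )
        manifest.stage_counts[f"stage{level}_clusters"] = stage.n_clusters
        _log.info("merged @%.2f: %d clusters", threshold, stage.n_clusters)

    chain = clustering.chain(stages)

    # stage 4: backtrack and snapshot
    matrix = organ_snapshot.backtrack_counts(chain, organ_of_read, config.organs)
    tallies = organ_snapshot.upset_tally(matrix, config.min_reads)
    matrix.rename_axis("unigene").to_csv(out / "organ_counts.tsv", sep="\t")
    tallies.to_csv(out / "upset_tallies.tsv", sep="\t", index=False)

    unigenes = [(rep, sequences[rep]) for rep in sorted(chain.stages[-1].representatives())]
    write_fasta(unigenes, out / "unigenes.fasta")
    stats = summary_stats.transcript_stats([s for _, s in unigenes]) if unigenes else {}
    manifest.stage_counts["unigenes"] = len(unigenes)
    manifest.stage_counts["matrix_total_reads"] = int(matrix.to_numpy().sum())

    total_flnc = sum(manifest.stage_counts[f"flnc_{o}"] for o in config.organs)
    conserved = manifest.stage_counts["matrix_total_reads"] == total_flnc
    conserved &= len(stage0.member_ids()) == total_flnc
    manifest.conservation_ok = bool(conserved)
    if not conserved:
        raise RuntimeError("conservation check failed: backtracked reads != FLNC reads")
    manifest.write(out / "manifest.json")

    return {
        "matrix": matrix,
        "tallies": tallies,
        "chain": chain,
        "unigenes": unigenes,
        "stats": stats,
        "manifest": manifest,
        "classification": pd.DataFrame(class_rows),
    }
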