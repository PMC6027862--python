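"""Synthetic gene catalogs, long reads and short read pairs with known truth.

The generator emulates the statistical structure of an organ-resolved
long-read transcriptome study of a possibly paleo-duplicated outbreeding
plant: a catalog of genes carrying 1-4 distinguishable haplotypes
(alleles or diverged paralogs collapsing to one representative), paralog
families, organ-restricted expression over four organs (bud, root, leaf,
stem), full-length cDNA reads with the 5'adapter-insert-polyA-3'adapter
architecture plus truncated/concatemeric/tail-less artifacts, and paired
short reads with uniform substitution errors.

Category counts (haplotype multiplicity, organ-restriction pattern) are
apportioned deterministically from the requested proportions rather than
sampled, so downstream recovery tests can compare exact histograms.  The
default proportions reproduce the multiplicities and organ-restriction
pattern reported for the *S. sisymbriifolium* SMRT transcriptome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import reverse_complement
from .io import SamRecord

ORGANS: tuple[str, ...] = ("bud", "root", "leaf", "stem")

# Short synthetic adapters (not the commercial cDNA-kit primers): the
# classification logic, not the adapter identity, is what the pipeline tests.
DEFAULT_ADAPTER_5 = "TCAGACGATGCGTCAT"
DEFAULT_ADAPTER_3 = "GATCGGAAGAGCGTCG"

# Haplotype-multiplicity weights: 17,773 homozygous / 22,098 two- / 1,358
# three- / 44 four-copy genes, as observed in the study system.
_HAP_COUNTS = {1: 17773, 2: 22098, 3: 1358, 4: 44}
DEFAULT_HAPLOTYPE_PROPS: dict[int, float] = {
    k: v / sum(_HAP_COUNTS.values()) for k, v in _HAP_COUNTS.items()
}

# Organ-restriction pattern: single-organ counts and the all-four class as
# observed; the remaining mass (genes in >1 but <4 organs) split evenly over
# the ten intermediate subsets.
def _default_category_props() -> dict[tuple[str, ...], float]:
    singles = {("bud",): 8019, ("root",): 4957, ("leaf",): 5349, ("stem",): 4198}
    all_four = {ORGANS: 7212}
    rest_total = 11538
    subsets: list[tuple[str, ...]] = []
    for size in (2, 3):
        idx = range(len(ORGANS))
        from itertools import combinations

        for combo in combinations(idx, size):
            subsets.append(tuple(ORGANS[i] for i in combo))
    counts: dict[tuple[str, ...], float] = {**singles}
    for s in subsets:
        counts[s] = rest_total / len(subsets)
    counts.update(all_four)
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


DEFAULT_ORGAN_CATEGORY_PROPS = _default_category_props()


# ---------------------------------------------------------------------------
# apportionment
# ---------------------------------------------------------------------------


def largest_remainder(
    n: int, proportions: Mapping[Hashable, float], *, ensure_nonzero: bool = True
) -> dict[Hashable, int]:
    """Deterministic apportionment of ``n`` items over categories.

    Plain largest-remainder, with one refinement when ``ensure_nonzero`` is
    set and ``n`` is at least the number of positive categories: any positive
    category whose quota ``n*p`` falls below one is reserved a single seat,
    and the remaining seats are apportioned by largest remainder over the
    renormalized rest.  This keeps rare categories represented in small
    catalogs.  Ties in the fractional part break in key order.
    """
    keys = list(proportions)
    props = {k: float(proportions[k]) for k in keys}
    if any(p < 0 for p in props.values()):
        raise ValueError("proportions must be non-negative")
    total = sum(props.values())
    if total <= 0:
        raise ValueError("proportions must have positive mass")
    props = {k: p / total for k, p in props.items()}
    positive = [k for k in keys if props[k] > 0]
    result = {k: 0 for k in keys}
    if ensure_nonzero and n >= len(positive):
        reserved = [k for k in positive if n * props[k] < 1.0]
        if reserved:
            rest = {k: props[k] for k in positive if k not in reserved}
            sub = largest_remainder(n - len(reserved), rest, ensure_nonzero=True) if rest else {}
            for k in reserved:
                result[k] = 1
            for k, v in sub.items():
                result[k] = v
            return result
    quotas = {k: n * props[k] for k in keys}
    base = {k: math.floor(quotas[k]) for k in keys}
    leftover = n - sum(base.values())
    order = sorted(range(len(keys)), key=lambda i: (-(quotas[keys[i]] - base[keys[i]]), i))
    for i in order[:leftover]:
        base[keys[i]] += 1
    for k in keys:
        result[k] = base[k]
    return result


def _validate_proportions(name: str, proportions: Mapping[Hashable, float]) -> None:
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions sum to {total!r}, expected 1")
    if any(p < 0 for p in proportions.values()):
        raise ValueError(f"{name} contains negative proportions")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    length: int
    n_haplotypes: int
    family_id: str
    organ_profile: dict[str, int]
    divergent_site_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.n_haplotypes <= 4:
            raise ValueError(f"{self.gene_id}: n_haplotypes must be 1..4")
        pos = self.divergent_site_positions
        if list(pos) != sorted(set(pos)) or any(p >= self.length for p in pos):
            raise ValueError(f"{self.gene_id}: divergent sites must be increasing and < length")
        if any(v < 0 for v in self.organ_profile.values()):
            raise ValueError(f"{self.gene_id}: negative organ counts")
        if not any(v > 0 for v in self.organ_profile.values()):
            raise ValueError(f"{self.gene_id}: at least one organ count must be positive")


@dataclass(frozen=True)
class ReadArtifactRates:
    truncated_fraction: float = 0.0
    concatemer_fraction: float = 0.0
    missing_polya_fraction: float = 0.0

    def __post_init__(self) -> None:
        fracs = (self.truncated_fraction, self.concatemer_fraction, self.missing_polya_fraction)
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise ValueError("artifact fractions must lie in [0,1] and sum to at most 1")


@dataclass
class GroundTruth:
    genes: list[GeneSpec]
    haplotype_sequences: dict[tuple[str, int], str]
    seed: int

    def gene(self, gene_id: str) -> GeneSpec:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def haplotype_histogram(self) -> dict[int, int]:
        out = {1: 0, 2: 0, 3: 0, 4: 0}
        for g in self.genes:
            out[g.n_haplotypes] += 1
        return out

    def organ_categories(self) -> dict[str, tuple[str, ...]]:
        """Ground-truth upset category (organs with expected count > 0) per gene."""
        return {
            g.gene_id: tuple(o for o in ORGANS if g.organ_profile.get(o, 0) > 0)
            for g in self.genes
        }

    def profile_frame(self) -> pd.DataFrame:
        rows = {
            g.gene_id: [g.organ_profile.get(o, 0) for o in ORGANS] for g in self.genes
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(ORGANS)).sort_index()

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "family_id": g.family_id,
                    "n_haplotypes": g.n_haplotypes,
                    **{o: g.organ_profile.get(o, 0) for o in ORGANS},
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# catalog simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _find_approx(hay: np.ndarray, needle: str, max_mm: int) -> int:
    """First window of ``hay`` within ``max_mm`` mismatches of ``needle``, else -1."""
    pat = np.frombuffer(needle.encode(), dtype=np.uint8)
    if len(hay) < len(pat):
        return -1
    windows = np.lib.stride_tricks.sliding_window_view(hay, len(pat))
    mism = (windows != pat).sum(axis=1)
    hits = np.nonzero(mism <= max_mm)[0]
    return int(hits[0]) if hits.size else -1


def _break_window(
    seq: np.ndarray,
    hit: int,
    pattern: str,
    max_mm: int,
    rng: np.random.Generator,
    protected: set[int],
) -> list[tuple[int, int]]:
    """Force > max_mm mismatches between seq[hit:] and pattern in one pass.

    Picks max_mm + 1 spread positions and sets each to a base differing from
    both the current base and the pattern base there, so the window cannot
    keep matching after a single round.  Returns the (position, base) edits.
    """
    free = [p for p in range(hit, hit + len(pattern)) if p not in protected]
    step = max(1, len(free) // (max_mm + 1))
    chosen = free[::step][: max_mm + 1] or free[:1]
    edits = []
    for p in chosen:
        pat_base = ord(pattern[p - hit])
        choices = [b for b in _BASES if b != seq[p] and b != pat_base]
        new = choices[int(rng.integers(0, len(choices)))]
        seq[p] = new
        edits.append((p, int(new)))
    return edits


def _scrub_adapters(
    seq: np.ndarray,
    adapters: Sequence[str],
    rng: np.random.Generator,
    max_mm: int = 2,
    protected: Iterable[int] = (),
) -> np.ndarray:
    """Mutate bases until no adapter (either strand) occurs within max_mm mismatches."""
    patterns = []
    for a in adapters:
        patterns.extend([a, reverse_complement(a)])
    protected_set = set(protected)
    seq = seq.copy()
    for _ in range(500):
        clean = True
        for pat in patterns:
            pos = _find_approx(seq, pat, max_mm)
            if pos >= 0:
                _break_window(seq, pos, pat, max_mm, rng, protected_set)
                clean = False
                break
        if clean:
            return seq
    raise RuntimeError("could not scrub adapter-like subsequences from simulated gene")


def simulate_catalog(
    n_genes: int,
    haplotype_distribution: Mapping[int, float] | None = None,
    organ_category_distribution: Mapping[tuple[str, ...], float] | None = None,
    mean_length: int = 1800,
    seed: int = 0,
    *,
    reads_per_organ_mean: float = 3.0,
    min_length: int = 600,
    site_window: int = 120,
    n_sites_range: tuple[int, int] = (2, 5),
    paralog_pair_fraction: float = 0.10,
    adapters: tuple[str, str] = (DEFAULT_ADAPTER_5, DEFAULT_ADAPTER_3),
) -> GroundTruth:
    """Generate a gene catalog with known haplotypes and organ profiles.

    Haplotype multiplicities and organ-restriction categories are assigned by
    deterministic apportionment of the requested proportions; everything else
    (lengths, residues, site placement, per-organ depths) is drawn from the
    seeded generator.  Haplotypes of one gene differ by substitutions only, at
    the listed divergent sites, and every pair of haplotypes differs at the
    first site.  Sequences are scrubbed of (near-)occurrences of the adapter
    sequences on either strand so downstream read classification is exact.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if min_length < 530:
        raise ValueError(
            "min_length must be >= 530 so divergent sites stay in the evenly "
            "covered interior of default short-read layouts"
        )
    hap_dist = dict(haplotype_distribution or DEFAULT_HAPLOTYPE_PROPS)
    cat_dist = dict(organ_category_distribution or DEFAULT_ORGAN_CATEGORY_PROPS)
    _validate_proportions("haplotype_distribution", hap_dist)
    _validate_proportions("organ_category_distribution", cat_dist)
    if any(k not in (1, 2, 3, 4) for k in hap_dist):
        raise ValueError("haplotype_distribution keys must be in {1,2,3,4}")
    for cat in cat_dist:
        if not cat or any(o not in ORGANS for o in cat):
            raise ValueError(f"organ_category_distribution key {cat!r} is not a valid organ subset")

    rng = np.random.default_rng(seed)
    hap_counts = largest_remainder(n_genes, hap_dist)
    cat_counts = largest_remainder(n_genes, cat_dist)
    hap_assign = [k for k in sorted(hap_counts) for _ in range(hap_counts[k])]
    cat_assign = [k for k in cat_counts for _ in range(cat_counts[k])]
    rng.shuffle(hap_assign)
    rng.shuffle(cat_assign)

    lengths = rng.normal(mean_length, 0.2 * mean_length, size=n_genes)
    lengths = np.clip(lengths, min_length, 4 * mean_length).astype(int)

    # paralog families: pairs of genes ~20% diverged (well below clustering
    # thresholds, so they remain separate unigenes but share a family label)
    n_pairs = int(paralog_pair_fraction * n_genes / 2)
    pair_idx = rng.permutation(n_genes)[: 2 * n_pairs].reshape(-1, 2) if n_pairs else np.empty((0, 2), int)
    # the later-indexed gene of each pair derives from the earlier one
    partner_of = {max(int(a), int(b)): min(int(a), int(b)) for a, b in pair_idx}
    family_of: dict[int, str] = {}
    for fam, (a, b) in enumerate(pair_idx):
        family_of[int(a)] = family_of[int(b)] = f"fam{fam:05d}"

    genes: list[GeneSpec] = []
    hap_seqs: dict[tuple[str, int], str] = {}
    base_arrays: dict[int, np.ndarray] = {}
    margin = 260  # keeps divergent sites in the evenly covered interior of short-read layouts
    for i in range(n_genes):
        gene_id = f"g{i:05d}"
        length = int(lengths[i])
        n_hap = hap_assign[i]
        if i in partner_of:
            src = base_arrays[partner_of[i]]
            length = len(src)
            base = src.copy()
            n_sub = max(1, round(0.20 * length))
            subs = rng.choice(length, size=n_sub, replace=False)
            for p in subs:
                choices = [b for b in _BASES if b != base[p]]
                base[p] = choices[int(rng.integers(0, 3))]
        else:
            base = _random_seq(rng, length)
        base = _scrub_adapters(base, adapters, rng)
        base_arrays[i] = base

        if n_hap >= 2:
            lo, hi = n_sites_range
            n_sites = int(rng.integers(lo, hi + 1))
            window = min(site_window, length - 2 * margin - 1)
            start = int(rng.integers(margin, length - margin - window))
            positions = tuple(
                sorted(int(p) for p in rng.choice(window, size=min(n_sites, window), replace=False) + start)
            )
        else:
            positions = ()

        haps: list[np.ndarray] = [base.copy() for _ in range(n_hap)]
        if positions:
            first = positions[0]
            ref_idx = int(np.where(_BASES == base[first])[0][0])
            for h in range(1, n_hap):
                haps[h][first] = _BASES[(ref_idx + h) % 4]
            for p in positions[1:]:
                if n_hap > 1:
                    k = int(rng.integers(1, n_hap))  # proper non-empty subset size
                    carriers = rng.choice(n_hap, size=k, replace=False)
                    ref_idx = int(np.where(_BASES == base[p])[0][0])
                    alt = _BASES[(ref_idx + 1 + int(rng.integers(0, 3))) % 4]
                    for h in carriers:
                        haps[h][p] = alt
        # substitutions at sites must not have created adapter-like runs; fix by
        # mutating non-site positions identically across all haplotypes
        patterns = [p for a in adapters for p in (a, reverse_complement(a))]
        site_set = set(positions)
        for _ in range(200):
            hit = -1
            hit_pat = ""
            for arr in haps:
                for pat in patterns:
                    pos = _find_approx(arr, pat, 2)
                    if pos >= 0:
                        hit, hit_pat = pos, pat
                        break
                if hit >= 0:
                    break
            if hit < 0:
                break
            edits = _break_window(base, hit, hit_pat, 2, rng, site_set)
            for arr in haps:
                for p, new_base in edits:
                    arr[p] = new_base
        else:
            raise RuntimeError(f"could not scrub adapters from haplotypes of {gene_id}")

        category = cat_assign[i]
        profile = {
            o: int(1 + rng.poisson(max(0.0, reads_per_organ_mean - 1.0))) for o in category
        }
        genes.append(
            GeneSpec(
                gene_id=gene_id,
                length=length,
                n_haplotypes=n_hap,
                family_id=family_of.get(i, f"fam_single_{gene_id}"),
                organ_profile=profile,
                divergent_site_positions=positions,
            )
        )
        for h, arr in enumerate(haps):
            hap_seqs[(gene_id, h)] = arr.tobytes().decode()
    return GroundTruth(genes=genes, haplotype_sequences=hap_seqs, seed=seed)


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------


def simulate_long_reads(
    truth: GroundTruth,
    adapters: tuple[str, str] = (DEFAULT_ADAPTER_5, DEFAULT_ADAPTER_3),
    polya_length: int = 20,
    artifact_rates: ReadArtifactRates = ReadArtifactRates(),
    seed: int = 0,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Per-organ full-length cDNA reads plus a ground-truth sidecar table.

    Clean reads are ``5'adapter + haplotype insert + polyA + 3'adapter``; the
    organ profile counts are allocated round-robin over the gene's haplotypes.
    Artifact reads (truncated: 5' adapter and part of the insert lost;
    concatemer: a second adapter+insert block inside; missing-polyA) replace a
    deterministically apportioned fraction of each organ's reads and are
    flagged in the sidecar, so at zero artifact rates the clean per-organ
    counts equal the organ profiles exactly.
    """
    a5, a3 = adapters
    if not a5 or not a3:
        raise ValueError("adapter sequences must be non-empty")
    for (gene_id, h), seq in truth.haplotype_sequences.items():
        for pat in (a5, a3, reverse_complement(a5), reverse_complement(a3)):
            if pat in seq:
                raise ValueError(
                    f"adapter occurs inside haplotype {h} of {gene_id}; "
                    "chimera detection would be ambiguous"
                )
    rng = np.random.default_rng(seed)
    polya = "A" * polya_length
    reads: dict[str, list[tuple[str, str]]] = {o: [] for o in ORGANS}
    sidecar_rows = []
    all_gene_ids = [g.gene_id for g in truth.genes]
    for organ in ORGANS:
        plan: list[tuple[str, int]] = []  # (gene_id, haplotype)
        for g in truth.genes:
            count = g.organ_profile.get(organ, 0)
            for j in range(count):
                plan.append((g.gene_id, j % g.n_haplotypes))
        n = len(plan)
        if n == 0:
            continue
        rates = {
            "truncated": artifact_rates.truncated_fraction,
            "concatemer": artifact_rates.concatemer_fraction,
            "no_polya": artifact_rates.missing_polya_fraction,
        }
        rates["clean"] = 1.0 - sum(rates.values())
        counts = largest_remainder(n, rates, ensure_nonzero=False)
        labels = (
            ["truncated"] * counts["truncated"]
            + ["concatemer"] * counts["concatemer"]
            + ["no_polya"] * counts["no_polya"]
            + ["clean"] * counts["clean"]
        )
        order = rng.permutation(n)
        label_of = dict(zip(order.tolist(), labels))
        for idx, (gene_id, hap) in enumerate(plan):
            insert = truth.haplotype_sequences[(gene_id, hap)]
            label = label_of[idx]
            if label == "clean":
                seq = a5 + insert + polya + a3
            elif label == "no_polya":
                seq = a5 + insert + a3
            elif label == "truncated":
                cut = int(rng.integers(len(insert) // 10, max(len(insert) // 10 + 1, int(0.6 * len(insert)))))
                seq = insert[cut:] + polya + a3
            else:  # concatemer
                other_gene = all_gene_ids[int(rng.integers(0, len(all_gene_ids)))]
                other = truth.haplotype_sequences[(other_gene, 0)]
                seq = a5 + insert + a5 + other + polya + a3
            read_id = f"{organ}_r{idx:06d}"
            reads[organ].append((read_id, seq))
            sidecar_rows.append(
                {
                    "read_id": read_id,
                    "organ": organ,
                    "gene_id": gene_id,
                    "haplotype": hap,
                    "artifact": label,
                }
            )
    sidecar = pd.DataFrame(sidecar_rows, columns=["read_id", "organ", "gene_id", "haplotype", "artifact"])
    return reads, sidecar


# ---------------------------------------------------------------------------
# short reads
# ---------------------------------------------------------------------------


def simulate_short_reads(
    truth: GroundTruth,
    depth_per_haplotype: float = 30.0,
    read_length: int = 250,
    substitution_error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], list[SamRecord], dict[str, int]]:
    """Paired short reads from every haplotype plus their true alignments.

    Read starts are laid out evenly along each haplotype — mate 1 on an
    ascending grid over ``[0, L - read_length]``, mate 2 (reverse strand) on
    the mirrored grid — so realized depth at interior positions, in
    particular at every divergent site, stays within a few percent of the
    request, and every window narrower than a read is spanned by whole
    reads.  Returns ``(fastq_pairs, sam_records, reference_lengths)`` where
    each FASTQ pair is ``(pair_id, mate1_seq, mate2_seq)`` (mate 2
    reverse-complemented) and the SAM records hold both mates
    reference-oriented with M-only CIGARs and 1-based positions.
    """
    if depth_per_haplotype <= 0:
        raise ValueError("depth_per_haplotype must be positive")
    min_len = min(g.length for g in truth.genes)
    if read_length >= min_len:
        raise ValueError(f"read_length {read_length} must be < shortest gene length {min_len}")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str, str]] = []
    sams: list[SamRecord] = []
    ref_lengths = {g.gene_id: g.length for g in truth.genes}
    for g in truth.genes:
        length = g.length
        span = length - read_length
        # interior coverage of 2*n_pairs evenly spread reads is
        # 2 * n_pairs * read_length / span; solve for the requested depth
        n_pairs = max(2, round(depth_per_haplotype * span / (2 * read_length)))
        for h in range(g.n_haplotypes):
            hap = truth.haplotype_sequences[(g.gene_id, h)]
            for j in range(n_pairs):
                s1 = round(j * span / (n_pairs - 1)) if n_pairs > 1 else 0
                s2 = span - s1
                m1 = hap[s1 : s1 + read_length]
                m2_ref = hap[s2 : s2 + read_length]
                if substitution_error_rate > 0:
                    m1 = _mutate(m1, substitution_error_rate, rng)
                    m2_ref = _mutate(m2_ref, substitution_error_rate, rng)
                pair_id = f"{g.gene_id}_h{h}_p{j:04d}"
                pairs.append((pair_id, m1, reverse_complement(m2_ref)))
                sams.append(SamRecord(pair_id, 0, g.gene_id, s1 + 1, f"{read_length}M", m1))
                sams.append(
                    SamRecord(pair_id, 16, g.gene_id, s2 + 1, f"{read_length}M", m2_ref)
                )
    return pairs, sams, ref_lengths


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    positions = rng.choice(len(seq), size=n_err, replace=False)
    for p in positions:
        choices = [b for b in _BASES if b != arr[p]]
        arr[p] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def simulate_transcript_families(
    n_families: int = 4,
    members_range: tuple[int, int] = (1, 8),
    parent_length_range: tuple[int, int] = (150, 400),
    substitution_rate: float = 0.03,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Small family-structured sequence sets for clustering validation.

    Each family has a longest parent transcript plus members that are exact
    duplicates, lightly substituted variants (same length), substrings
    (UTR-trimmed fragments), or reverse-complemented copies.  Intra-family
    identities stay >= 0.9 and inter-family identities far below 0.8, so
    cluster counts are well defined at the 1.0 / 0.9 / 0.8 thresholds.
    Returns ``(seq_id, sequence)`` pairs; ids sort the parent first.
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    for f in range(n_families):
        length = int(rng.integers(*parent_length_range))
        parent = _random_seq(rng, length)
        parent_str = parent.tobytes().decode()
        records.append((f"f{f:02d}_m00", parent_str))
        n_members = int(rng.integers(members_range[0], members_range[1] + 1))
        for m in range(1, n_members):
            kind = rng.choice(["dup", "sub", "substr", "revcomp"])
            if kind == "dup":
                seq = parent_str
            elif kind == "revcomp":
                seq = reverse_complement(parent_str)
            elif kind == "substr":
                sub_len = int(rng.integers(int(0.6 * length), length))
                start = int(rng.integers(0, length - sub_len + 1))
                seq = parent_str[start : start + sub_len]
            else:
                n_sub = max(1, int(substitution_rate * length))
                arr = parent.copy()
                for p in rng.choice(length, size=n_sub, replace=False):
                    choices = [b for b in _BASES if b != arr[p]]
                    arr[p] = choices[int(rng.integers(0, 3))]
                seq = arr.tobytes().decode()
            records.append((f"f{f:02d}_m{m:02d}", seq))
    return records


def fastq_records(
    pairs: Iterable[tuple[str, str, str]], quality: int = 40
) -> tuple[list[tuple[str, str, list[int]]], list[tuple[str, str, list[int]]]]:
    """Split simulated pairs into mate-1 / mate-2 FASTQ record lists."""
    r1, r2 = [], []
    for pair_id, m1, m2 in pairs:
        r1.append((f"{pair_id}/1", m1, [quality] * len(m1)))
        r2.append((f"{pair_id}/2", m2, [quality] * len(m2)))
    return r1, r2
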