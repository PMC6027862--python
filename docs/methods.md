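# Methods

This note documents the models, rules and numerical choices behind
`organsnap`, and what the synthetic-data experiments do and do not show.

## The analysis, end to end

The pipeline assumes four separately sequenced organ cDNA pools (bud,
root, leaf, stem) of full-length-capable long reads. Stage order: per-read
FLNC classification → per-organ collapse at 100% identity → merge →
reduction at each configured threshold (default 100%, then 90%) →
backtracking of final unigenes to organ-labelled reads → snapshot tables.
Short-read data enter only the divergent-gene analysis, as ungapped
alignments to unigenes. All coordinates are 0-based half-open internally;
SAM and domain tables are the only 1-based boundaries. All randomness
flows from explicit integer seeds; reruns are byte-identical.

## FLNC classification

A read of insert is **FLNC** iff one strand shows the 5' adapter, then the
insert, then a poly(A) tail, then the 3' adapter, with no additional
adapter copy anywhere; any extra copy makes it **chimeric**; anything else
is **non-full-length**. Choices:

- Adapter matching is a sliding substitution-only comparison with at most
  `max_adapter_mismatches` (default 2) mismatches; no indels. This keeps
  detection O(n·|adapter|) and exactly testable.
- The poly(A) detector accepts the best window ending at the 3' adapter
  whose non-A content is at most one per ten bases and whose A count
  reaches `min_polya` (default 10). The windowed formulation lets an early
  non-A be absorbed when the full tail satisfies the ratio.
- Both strands are searched; orientation is the strand carrying the
  complete arrangement (forward preferred on ties), `unknown` otherwise.
  Reverse-complementing a read flips orientation, never category.
- An instrument-style minimum read quality is exposed only as an optional
  mean-quality threshold, off by default: it has no reproducible
  definition outside the original basecalling pipeline.

## Identity and clustering

**Identity** between sequences `a`, `b` is `1 − d/len(shorter)`, where `d`
is the minimum edit distance of the shorter aligned semi-globally (end
gaps free) against the longer, taken on the better of the two strands.
This is path-free (no ambiguity between co-optimal alignments), symmetric,
gives 1.0 for duplicates, substrings and reverse complements, and matches
the documented semantics of standard nucleotide clusterers. The production
path uses band-limited edlib distances; an independent pure-numpy dynamic
program (`semiglobal_distance`) backs the validation suite.

**Greedy clustering** processes records longest-first (ties broken by
ascending id so outputs are byte-stable) and joins each record to the
*first* cluster, in founding order, whose representative matches at or
above the threshold — the incremental first-fit dialect, not best-fit.
Representatives are therefore always the longest member, which is why
reduced sets drift toward longer, UTR-bearing (AT-richer) variants; the
test suite checks that directional GC effect explicitly.

The shared-word prefilter (word size 8, "must share ≥ 1 word") is applied
per record only when the pigeonhole bound `ceil((m − e)/(e + 1)) ≥ 8`
(`m` record length, `e` the edit budget at the threshold) guarantees that
any qualifying pair must share an exact 8-mer; otherwise every cluster is
a candidate. The filter is then provably lossless at every threshold, and
`greedy_cluster` equals the brute-force all-pairs implementation
(`exhaustive_cluster`) identically rather than approximately.

Greedy first-fit clustering is not mathematically monotone in the
threshold for arbitrary non-metric inputs. On family-structured inputs —
well-separated families whose members sit within the threshold of their
longest parent, which is what transcript collapse assumes — it is, and the
validation sets are generated that way (`simulate_transcript_families`:
duplicates, ≤ 3%-substituted variants, substrings, reverse complements of
a longest parent; inter-family identity far below 0.8).

**Chaining.** Consecutive stages must nest exactly (stage *i+1* inputs =
stage *i* representatives); violations abort with the offending id. Reads
are conserved through the chain — backtracked matrix totals equal the FLNC
read count, enforced at run time by the manifest.

## Expression snapshots

Presence of a unigene in an organ means at least one of that organ's reads
is reachable through the chain (`min_reads` exposed, default 1; long-read
depth is low and membership is the published semantics). Upset categories
are exclusive subsets of the four organs, all 15 reported including
zero-count ones. Snapshot heat values are raw membership counts;
normalization against a reference gene (ratio per organ, undefined organs
flagged rather than dropped) is a separate operation. Snapshots are
provisional profiles, not a substitute for replicated RNA-seq — no
differential-expression statistics are offered.

## Divergent-gene (ploidy) analysis

Pileups accept only all-M CIGARs; anything else is skipped and counted. A
**divergent site** needs depth ≥ `min_depth` (10) and ≥ 2 bases each with
count ≥ `min_allele_count` (3) and fraction ≥ `min_allele_fraction`
(0.20). The upstream study delegated calling to an external variant caller
at fixed ploidies without printing its filters, so these gates are this
package's choices, all exposed as configuration.

**Counting distinguishable copies.** Reads overlapping a gene's divergent
sites are reduced to allele patterns over the sites they cover; patterns
are merged fullest-first when one is a compatible sub-pattern of another
(same alleles wherever both are defined; ambiguous partial patterns fold
into the first established compatible pattern, which cannot change the
count). A merged pattern is counted when supported by at least
`min_pattern_support` reads (2) **and** `min_pattern_fraction` (0.05) of
the gene's informative reads; the fractional gate mirrors the
allele-fraction gate and keeps coincident sequencing errors (two identical
miscalls at one site) from fabricating a haplotype, which biases residual
errors toward under-counting. Calls are capped at 4 copies, mirroring the
escalation of defined ploidy settings in the source analysis; zero
divergent sites means homozygous. At a uniform 0.5% substitution error and
30× per-haplotype depth, recovery is ≥ 95% per gene with no over-counting
observed.

## R-gene screen

Six-frame longest-ORF decomposition: an ORF runs from the first ATG after
the previous stop to the stop codon inclusive; the longest span wins, with
ties broken toward the forward strand, lowest frame, lowest start. The
`min_aa` floor defaults to 0 (any complete ORF); screens may raise it. A
unigene qualifies as a putative R-gene when one `(frame, start)` ORF key
carries both an NB-ARC hit and an LRR hit. "Same ORF" is the literal key,
not merely the same strand. The default LRR rule accepts any domain name
beginning `LRR` (Pfam splits LRRs across families and the inventory is
database-version-dependent); an explicit name set restricts it. Published
R-gene counts depend on database versions and the real dataset, so they
are context, not validation targets here.

## Summary statistics

N50 is the smallest length whose descending cumulative sum reaches half
the total. GC is pooled over all sequences (not per-sequence averaged),
ambiguous bases excluded from numerator and denominator. Flow-cytometry
genome size is the fluorescence-ratio equation against an external
standard of known 2C mass, converted at 0.978 × 10⁹ bp/pg — the standard
constant and the only one consistent with the measured 4.73 pg ↔
4.63 × 10⁹ bp pair. BUSCO percentages are `100·count/total` with half-up
rounding (reproducing 93 / 30.2 / 2.2 / 4.8 from 889/289/21/46 over 956);
where a published table and its accompanying text disagree on
fragmented/missing, the text values are the self-consistent set and the
ones reproduced here.

## The synthetic-data generator

The generator emulates the study's statistical structure: genes with 1–4
distinguishable haplotypes, organ-restricted expression over four organs,
clean long reads with the full adapter architecture plus truncated /
concatemeric / tail-less artifacts, and evenly laid-out paired short reads
with uniform substitution errors.

- **Deterministic apportionment.** Haplotype-multiplicity and
  organ-category counts are apportioned from the requested proportions by
  largest remainder, not sampled, so recovery tests compare exact
  histograms. One refinement: a positive-proportion category whose quota
  falls below one seat is reserved a single seat before the remainder is
  apportioned — without it, rare classes (the 4-copy genes, ~0.1% of the
  default mix) would vanish from any desk-scale catalog.
- **Defaults as study conditions.** Haplotype weights 17,773 : 22,098 :
  1,358 : 44 and organ-category weights from the observed pattern (8,019
  bud-only, 4,957 root-only, 5,349 leaf-only, 4,198 stem-only, 7,212 in
  all four, the remaining 11,538 split evenly over the ten intermediate
  subsets). Mean transcript length 1,800 nt (clipped at 600), matching the
  reduced set's mean; reads per expressed organ 1 + Poisson(2), consistent
  with ~5–6 reads per unigene overall. Artifact rates default to zero;
  when set, artifact reads *replace* apportioned members of each organ's
  read list and are flagged in a ground-truth sidecar table, so FASTA
  headers stay format-clean and clean counts equal the organ profiles
  exactly at zero rates.
- **Haplotypes** differ by substitutions only, at 2–5 divergent sites
  placed inside a 120 nt window at least 260 nt from either end; every
  pair of haplotypes differs at the first site (so any read covering it is
  discriminating), and later sites carry alternative alleles on proper
  subsets. Substitution-only divergence matches the single-nucleotide
  framing of the analysis and keeps pileups ungapped.
- **Adapter hygiene.** Default adapters are short synthetic 16-mers, not
  the commercial primer sequences — the classification logic, not the
  adapter identity, is under test. Catalog sequences are scrubbed of
  near-occurrences (≤ 2 mismatches, either strand) of the configured
  adapters so classification on simulated data is exact by construction;
  `simulate_long_reads` still rejects any haplotype containing an adapter.
- **Short reads.** Mate-1 starts on an ascending even grid over
  `[0, L − read_length]`, mate 2 mirrored on the reverse strand. This
  forgoes a fragment-size distribution (explicitly out of scope) in
  exchange for two guarantees the divergence tests rely on: depth at every
  divergent site within a few percent of the request, and whole-read
  coverage of any window narrower than a read. Errors are uniform
  substitutions; no quality-score realism.

**What passing tests show — and don't.** Synthetic genes are unrelated
random sequences (paralog families at ~20% divergence excepted), so
clustering faces no borderline-identity continuum as real gene families
do; reads are full-length and error-free unless artifacts or substitution
errors are requested, so FLNC recovery rates here do not bound real-data
rates; and divergent sites are placed where even coverage is guaranteed,
so site discovery power on real, unevenly covered transcripts will be
lower. The experiments validate the *logic* — exact bookkeeping,
thresholds, conservation, recovery under the stated noise — not the
field performance of the original instruments.

## Problem sizes

The validation suite uses 200 family-structured sets of ≤ 30 sequences
for the clustering cross-check, a 500-gene catalog for the snapshot
round-trip, and a 240-gene catalog at 30× per-haplotype coverage for the
ploidy round-trip; `scripts/acceptance.py` uses 120 sets / 300 genes /
240 genes. These sizes make every rare class (4-copy genes, three-organ
categories) non-empty while keeping a full run in minutes on one CPU.

## Known limitations

- No consensus polishing, adapter discovery, or gapped adapter alignment.
- Decoy filtering is exact k-mer sharing, not alignment; its contract
  (contaminant pairs removed, boundary inclusive) is preserved, but
  diverged contaminants below the k-mer level pass.
- Digital normalization keeps exact k-mer counts in memory — appropriate
  at package scale; streaming sketches are out of scope.
- Phasing is read-pattern counting, not likelihood-based genotyping;
  haplotypes distinguishable only across sites farther apart than a read
  cannot be separated and are under-counted by design.
- The CLI holds no logic; every command is a veneer over one library
  operation, so library results and CLI results cannot diverge.
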