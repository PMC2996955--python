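# Methods

This note documents the models and numerical choices behind `flcdna`: what
each stage computes, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Alignment model

All pairwise alignment is local (Smith–Waterman) with affine gaps. The
default scoring is match +1, mismatch −2, gap open −5, gap extend −1,
where a gap of length *L* costs `open + (L−1)·extend` (the opening charge
includes the first gapped base). `N` never counts as a match on either
side. Transcript-scale alignment is delegated to Biopython's C
`PairwiseAligner`; an independently written brute-force DP in the test
suite pins the scores. Among co-optimal alignments the engine's first
enumeration is taken; it is deterministic for fixed inputs, which is all
downstream bookkeeping requires.

Hit acceptance requires identity ≥ 0.90 over ≥ 100 aligned (non-gap)
columns — chosen values, since no alignment-tool cutoffs were available
to adopt; both are keyword parameters everywhere. Best-hit ties break by
score, then longer aligned query span, then lexicographically smaller
target id, making target choice reproducible.

**Genome mapping.** Spliced alignment needs target-side gaps of hundreds
of bases at sub-linear cost, so the genome kernel (numba) adds a fourth
DP state: a target-consuming gap opened at a flat cost (default 24,
roughly the affine cost of a 20 nt gap) and extended free. Gaps realized
through either route are classified afterwards purely by length: target
gaps ≥ `min_intron` (default 30 nt) are introns and delimit exon-level
blocks; shorter gaps are indels and are absorbed into blocks. Windows for
the DP come from exact 13-mer seeds (seeds occurring > 50 times in the
genome are dropped as repeats); seeding only selects the window — scoring
inside it is the exact DP. Consequences worth knowing: an alignment never
jumps an intron to pick up fewer than ~24 matching bases, so a terminal
exon overlapped by only a few bases may be dropped, and splice junctions
that share sequence with the intron are placement-ambiguous within a few
bases. Recovery tests allow exactly these two tolerances and nothing else.

## Region categories

A gene model partitions its transcript into 5'UTR `[0, cds_start)`, CDS
`[cds_start, cds_end)` and 3'UTR `[cds_end, len)`, all half-open. A
mapped read's category is the set of regions its aligned target span
overlaps by ≥ 1 nt (the overlap threshold is a parameter; 1 nt is the
choice consistent with a per-base labeling oracle). Non-coding reference
hits are `NR_XR`. In the per-category summary each cDNA counts once (its
best hit); each gene also counts once, in the category of the union of
regions its member cDNAs cover, so both columns partition their totals.
Percentages divide by the distinct-gene total and round half away from
zero to one decimal — the convention that reproduces the published
percent column from the published counts.

## Consensus and identity

Clusters with ≥ 2 members are collapsed on reference columns: each
member's alignment places its bases on transcript coordinates, each
covered column takes the majority base, ties resolve toward the
reference-agreeing base and then alphabetically, and uncovered columns
are absent. Insertions relative to the reference are ignored — the
consensus is a reference-frame object. This replaces an unspecified
multiple-alignment step with a deterministic, testable operation; it
slightly favors the reference at divergent tied columns, which is
conservative for divergence estimates with two members (a planted variant
seen by both members always outvotes it). Identity is the fraction of
consensus columns agreeing with the reference, over the consensus's
category span, reported as a percent; a consensus with zero columns in
the requested span is excluded from means with a warning rather than
contributing 0.

## Triage cascade

Reference-set hit → `REFSEQ_MATCH`; else secondary-database hit →
`OTHER_DB_MATCH`; else genome mapping and ORF calling decide:
`GENOME_ORF` (hit + ORF), `ORF_ONLY` (no hit + ORF), `UNCLASSIFIED`
(neither). A transcript with a reference hit never reaches genome
mapping. `UNCLASSIFIED` exists deliberately — the pipeline does not force
every unknown into a candidate class. The ORF caller scans the three
forward frames only (the library is directional; a `both_strands` flag
exists), requires ATG..stop with no internal stop, ≥ `min_aa` amino
acids, and returns the longest ORF, leftmost on ties. `min_aa` defaults
to 40: the smallest published novel-candidate ORF is 44 aa, and a gate
slightly below it avoids misses at the observed edge while still
rejecting the bulk of spurious short ORFs.

## Indels and TE exonization

Every alignment gap shorter than `min_intron` is one indel event; target
gaps at or above it are introns, so each gap is counted exactly once as
indel xor intron. Before anchoring, gaps are left-normalized (VCF-style:
shifted 5' while the entering and departing bases match), making anchors
deterministic under alignment ambiguity; anchors are classified by the
region of their leftmost reference coordinate, with deletions spanning a
boundary taking the compound label. The summary counts *transcripts* per
region (a transcript with indels in k regions contributes once to each)
and also reports raw event counts, since published tallies are ambiguous
between the two readings; the functional-region total sums the five mRNA
region categories.

The TE screen takes a transcript's genome alignment and its (possibly
absent) reference-mRNA alignment. An exon-level block whose query
interval is covered < 20% by the mRNA alignment is "absent from the
reference mRNA"; absent blocks ≥ 30 nt whose genomic interval is covered
≥ 50% by one repeat family are called exonizations, species-specific when
the family carries the lineage flag in the repeat annotation (defaults:
AluYRa2, MER11B). The lineage-specific family list is an input — the
package does not re-derive primate phylogeny. In the pipeline, only reads
whose mRNA alignment leaves ≥ 50 nt of clean read unaligned are
genome-mapped for screening; a fully reference-concordant read cannot
carry a novel exon.

## Synthetic data generator

The generator emits a reference world and reads with a complete truth
ledger. Reference transcripts have uniform-length 5'UTRs (50–300 nt),
CDSs of 100–500 codons (ATG start, stop end, no internal stop) and
3'UTRs (100–900 nt); ~3.4% of genes are non-coding. The genome embeds
each transcript as 2–12 exons separated by ≥ 50 nt introns with
intergenic spacers, plus novel multi-exon loci absent from the mRNA set,
background TE copies, and — for TE genes — an intronic TE copy from which
a cassette exon (80–250 nt) is spliced into an alternative transcript.
All randomness flows from one seed; identical configs produce
byte-identical output files.

**Divergence is per gene, not per read.** Substitutions (region- or
category-specific rates) and short indels (Poisson, default 0.15
events/kb, geometric lengths capped at 20 nt) are planted once on each
gene's simulated rhesus transcript; all reads of the gene share them.
This is what makes consensus identity an estimator of the planted rate —
per-read errors would be voted away. Indels are planted only at sites
whose left-normalized position is unambiguous (no single-step shift
possible) and ≥ 10 nt apart, so truth positions are well-defined up to
the ±2 nt ambiguity window the recovery tests allow. Per-read sequencing
error is a separate knob (`seq_error="quality"` draws errors from the
Phred model) and is off in the library profile: post-cleaning Sanger
consensus data are dominated by species divergence, and leaving errors
off keeps the identity recovery criterion an unbiased rate check.

**Reads.** Qualities decay linearly (mean 40 → 10 along the raw read,
s.d. 4), which places the Q20 trim point at about 2/3 of the raw read;
the configured read-length distribution (normal 860 ± 160, clipped to
170–1174) therefore describes the intended *clean* length, and raw reads
are drawn 1.5× longer. Reads are single-strand (directional library),
5'-anchored with probability 0.2 and windowed otherwise; vector segments
(20–80 nt) are prepended with probability 0.15, 8.25% of reads are pure
vector, 1% host, and 10% come from novel sources split between
secondary-database transcripts, genome-backed novel loci and free
ORF-bearing transcripts in the published 66:60:61 proportion. Novel
transcripts carry 5'-proximal ORFs of 44–198 aa with long 3' trailers so
cleaning does not amputate the stop codon.

**Category-targeted mode.** The library profile must realize specific
per-category divergence rates (5UTR_CDS 4.9%, 5UTR_CDS_3UTR 4.1%, CDS
3.2%, CDS_3UTR 4.3%, 3UTR 6.7% — chosen so 100·(1−rate) equals the
published per-category identities), which requires knowing a gene's
category before planting divergence. In this mode each coding gene draws
a category from the published gene-count weights and its reads sample
spans realizing that category (each required region overlapped by ≥ 10
nt, single-region reads ≥ 150 nt). The trade-off: span sampling, not the
read-length distribution, then drives clean lengths, so profile-mode
clean reads average shorter than 860 nt; the default (non-targeted) mode
reproduces the length distribution but controls divergence only per
region. Three per-region rates cannot represent five per-category values,
so the two parameterizations coexist and the profile uses the
per-category override.

**What a green test does not establish.** The generator draws uniform
random sequence: no composition bias, no repeats inside transcripts
beyond the planted TEs, no chromatogram-shaped error model, no
polyA/polyT tails, and vector/host are random stand-ins rather than real
pUC/lambda/E. coli sequence. Recovery results therefore certify the
pipeline's bookkeeping and estimators on the stated statistical world,
not robustness to low-complexity sequence or systematic base-calling
artifacts.

## Cleaning details

Quality trimming returns the longest interval in which every length-`w`
window (default 10) has mean quality ≥ 20; an interval shorter than the
window is judged as a single whole-interval window (this also covers
window > read length). Ties break leftmost. The stage order is quality →
vector → host → length, a stated choice (the published account does not
order them). Vector screening aligns the read against the vector library
(hits ≥ 20 nt at ≥ 95% identity); terminal hits are trimmed together with
anything outside them, while a hit flanked by ≥ 50 nt of non-vector on
both sides marks a chimeric/multi-cloning-site read for removal, as does
a read reduced below the match threshold. Host screening removes reads
with a host alignment ≥ 95% identity over ≥ 100 nt or half the read. An
exact k-mer prescreen skips the DP for reads sharing no 12-mer with the
contaminant libraries; a real ≥ 20 nt near-exact match always shares one,
so the prescreen only skips alignments that could not have produced a
hit. The length filter is strict (> 100 bp survives, 100 bp does not).

## Known limitations

* The exact seed-free DP scales as O(query × target); the package is a
  desk-scale tool (thousands of reads × thousands of transcripts, toy
  genomes), not a BLAST replacement. Alignment statistics (E-values) are
  out of scope.
* Genome mapping assumes the transcript's locus fits in one seeded window
  (default cluster gap 10 kb); trans-spliced or giant-intron structures
  would be truncated.
* Consensus building is reference-anchored: reads of a gene with no
  reference alignment contribute nothing, and member insertions are
  invisible to the consensus.
* The exporter's published-table layout reports `matched_length =
  query_end − query_start`, adopted from the source table's arithmetic;
  it counts query-side gap columns inside the span.
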