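# Methods

`lncscape` re-implements the downstream arithmetic of a nanopore
direct-RNA-sequencing (DRS) lncRNA characterization workflow as a tested
library. Everything upstream — basecalling, alignment, transcript
assembly, the m6A caller, signal-level poly(A) estimation, and
quantification — is treated as an input producer; the package consumes
their tabular outputs.

## Coordinate model

All intervals are 0-based half-open (BED-like) internally; GTF/GFF3 are
1-based inclusive and converted only at the file boundary. A transcript
is an ordered tuple of non-overlapping exons on one chromosome and
strand, optionally with a CDS span. UTR lengths are always derived as
exonic-minus-CDS, never read from UTR features, so there is a single
source of truth. `transcript_coord_to_genomic` walks the exon chain
5'→3' (on the minus strand, transcript position 0 is the genomically
last exon base) and is a bijection between `[0, length)` and the exonic
base set.

## Class codes

A query transcript receives one code against the reference annotation:
`=` (identical ordered junction chain, same strand; for single-exon
pairs, mutual exonic overlap with no junctions on either side), `i`
(query inside a single same-strand intron), `y` (a reference inside a
query intron, same strand), `o` (same-strand exonic overlap, flagged
`j_like` when a junction is shared), `x` (opposite-strand exonic
overlap), `s` (query inside an opposite-strand intron), `p` (no span
overlap but within a run-on distance, same strand; default 2000 nt, the
convention of the comparison tools this emulates), and `u` (intergenic).

Several rules can hold simultaneously against different references, so
the result is resolved by the fixed precedence
`= > i > y > o > x > s > p > u`; ties within a code prefer the larger
exonic overlap (the nearer reference for `p`), then the smallest
reference id. This makes assignment independent of reference file
order. `x` is ranked before `s` purely for determinism; both map to the
antisense category downstream, so the choice never changes category
output. Queries with unknown strand return the sentinel code `.`
(unclassifiable) rather than raising, so data loss is visible in
reports. Junction matching is exact by design: a 1-nt shift is a
different junction, because fuzziness would silently change novel-lncRNA
counts.

Category mapping: `{s,x}` → antisense, `{p,u}` → intergenic, `{i}` →
intronic, `{y,o}` → overlapping; anything else (`=`, `.`) is counted as
unclassified and excluded from the proportion denominator. Reported
proportions therefore sum to 100% over the classified subset only,
which reproduces the behaviour of published category tables whose
counts do not sum to the full lncRNA tally.

## Novel lncRNA filter

A novel transcript (code ≠ `=`) is accepted as a lncRNA iff

1. spliced length strictly exceeds 200 nt ("exceeding" read literally);
2. its CPAT-style coding probability is below the cutoff (default
   0.325);
3. its CPC2-style label is `noncoding`;
4. it shares no splice junction with any protein-coding reference
   transcript.

Criteria are evaluated in that order and the first failure is reported
as the rejection reason. The filter is monotone: raising the length
floor or lowering the cutoff never admits new transcripts.

The cutoff can be trained from labelled scores by a two-graph ROC:
sensitivity(t) = fraction of coding examples with score ≥ t,
specificity(t) = fraction of non-coding examples with score < t,
swept over the observed scores plus {0, 1} (no interpolation — the
observed-value sweep is exactly reproducible). The default
`intersection` mode returns the smallest threshold minimizing
|sens − spec|, which for overlapping unimodal score distributions sits
at the equal-error-rate point, numerically close to the class-density
crossing; `max_mean` maximizes (sens+spec)/2 instead. Scores must be
oriented higher-is-more-coding; the trainer rejects inputs where the
coding class averages strictly below the non-coding class.

## m6A methylome

Sites arrive per library as (transcript, position of the central A,
5-mer, modification ratio `m_i` ∈ [0,1], supporting reads `r_i`). The
ratio column is treated as an opaque value in [0,1] (the upstream
caller does not document whether it is a probability or a
stoichiometry). Sites with fewer than 5 supporting reads are dropped;
a site is methylated iff `m_i > 0`, and a transcript is methylated iff
it carries ≥1 methylated site.

The transcript-level ratio is the read-weighted mean

    M = Σ(m_i · r_i) / Σ(r_i)

which is order-invariant, scale-invariant in the reads, and bounded by
[min m_i, max m_i]. Two summation universes are supported because the
upstream convention is genuinely ambiguous: `include_zero_sites=True`
(default, used in the pipeline's Fig-2-style summaries) runs the sum
over all candidate sites regardless of modification status;
`include_zero_sites=False` restricts to methylated sites. A transcript
with no qualifying site yields *no record*, never M = 0.

Across libraries, site identity is (transcript_id, position); kmers are
checked for consistency and pooling sums reads and takes the
read-weighted mean of per-library ratios. A per-library mode is
available where stage comparisons need library-level M values.

Metagene mapping. lncRNAs use full-length normalization
`position / (length − 1)` so both endpoints are attainable (a 1-nt
transcript maps to 0.5). mRNAs are segmented by the CDS span projected
onto transcript coordinates and mapped into fixed bands
5'UTR [0, 0.2), CDS [0.2, 0.7), 3'UTR [0.7, 1.0) — the 2:5:3
convention — with within-region fraction
`(pos − region_start) / region_length`. The first base of each region
lands exactly on its band boundary (0, 0.2, 0.7) and the bands are
half-open, so the last CDS base maps just under 0.7. A zero-length UTR
simply contributes no positions and the mapping degenerates to the
remaining bands. A `min_ratio` filter (0.4 in the highly-methylated
convention) reproduces the 3'UTR-shift analysis.

Density is `100 · n_methylated / transcript_length` (sites per 100 nt).
Motif usage tallies 5-mers over methylated DRACH sites (non-DRACH kmers
are excluded and counted), with the AAACH subfamily = `AAAC[ACT]`.

Genotype comparison is exact set algebra on site identities:
`wildtype_only = WT \ ∪mutants`, `shared_all = WT ∩ ∩mutants`,
`novel_in(g) = g \ WT`, plus the full membership-pattern tally so the
categories partition the union. Stage comparison of site sets is the
analogous two-way partition.

The differential modification of a transcript is
`mean(M, floral-bud libraries) − mean(M, seedling libraries)`;
transcripts missing either stage are excluded and counted.

## Poly(A)

Per-read tail estimates are averaged per transcript over QC-passing
reads pooled across libraries (per-library mode behind a flag); zero
passing reads yields no record. Tail lengths are reported to 0.01 nt.

Classification combines rRNA-depleted NGS and poly(A)-selected DRS
evidence: with NGS support (TPM strictly > 0.1 in ≥ 2 samples), zero
QC-passing DRS reads ⇒ `non_polyA`, ≥ 1 ⇒ `polyA`; without NGS support
the transcript is `undetermined` regardless of DRS. Proportions are
reported over the classified set. Input read tables are expected to be
pre-restricted to uniquely aligned reads; the package does not
re-examine alignments.

## Expression dynamics

CPM uses the column sum over the full quantified transcript universe of
each sample (standard CPM, not a subset denominator). A transcript is
moderately expressed in a sample when CPM strictly exceeds 0.1, and in
a stage when that holds in ≥ 1 sample of the stage. The stage statistic

    d = log2( (mean CPM floral bud + 0.1) / (mean CPM seedling + 0.1) )

uses 0.1 as a pseudo-CPM; d > 0.7 calls up-regulation in the floral
bud, d < −0.7 down-regulation. d is antisymmetric under swapping stage
labels and attenuates toward 0 as abundance approaches the
pseudo-count. The default analysis universe is the set expressed in
every sample of the matrix (the expressed-in-all-four-samples
convention), and is configurable.

Supporting statistics are library-grade: two-sided Mann–Whitney U with
tie correction, tie-aware Spearman correlation (undefined on constant
vectors, reported as NaN), and ordinary least squares for trend lines,
all via scipy. Two-sided tests are used throughout since the upstream
convention does not state sidedness. No multiple-testing correction is
applied, matching the reporting style this package emulates. The
methylation–expression coupling statistic is Spearman's ρ between d and
the differential modification, joined on transcripts carrying both.

## Synthetic data generator

The generator is first-class, tested code; it defines the study
conditions for every recovery test. One chromosome is divided into
20-kb slots, one planted unit per slot: a 3–5-exon protein-coding gene
(exons 150–400 nt, introns 400–900 nt, CDS trimmed 30 nt inside the
span), a reference lncRNA (single- or two-exon, 300–600 nt), or an
intergenic novel transcript. Novel transcripts are constructed
geometrically so that their class code is true by construction:
exon-overlapping on either strand (`o`/`x`), intron-contained on either
strand (`i`/`s`), a two-exon query whose intron swallows a dedicated
single-exon reference (`y`), a run-on placed 400 nt downstream (`p`),
isolated single-exon transcripts (`u`), junction-sharing coding
isoforms (rejected by the junction filter), and sub-200-nt transcripts
(rejected by the length filter). Slot margins keep unrelated units
farther apart than the run-on distance, so codes never interfere.

Default library design mirrors the stage comparison: two seedling and
two floral-bud wild-type DRS libraries, four methyltransferase-mutant
genotypes (vir/fip37/mtb/fio1), and four NGS samples per stage. Sites
are placed per transcript at Poisson rates of 1.0 (lncRNA) and 1.6
(mRNA) per 100 nt; per-transcript methylation levels are beta
distributed (lncRNA Beta(2, 10), mRNA Beta(2.5, 9.4)) with 10% of
candidate sites permanently unmodified, putting pooled transcript-level
medians in the 0.1–0.2 range with lncRNAs below mRNAs — emulating the
reported ordering of medians (0.16 vs 0.18). Observed per-library
ratios are binomial draws at the site's level, so read-depth-limited
noise behaves as in real calling; 10% of site rows are emitted with
fewer than 5 reads to exercise the support filter. Each wild-type
methylated site carries a planted "writer" class (independent /
MTA-complex / FIO1 / fragile) determining which mutant genotypes retain
it, plus per-mutant novel sites, so genotype partitions have exact
expectations.

Poly(A) tails are gamma distributed (lncRNA shape 4.5, scale 20 →
median ≈ 83.5 nt; mRNA scale 21.7 → ≈ 90.6 nt, emulating the reported
83.89/91.09 medians as design targets); 33% of lncRNAs are planted
non-poly(A) and emit no DRS reads anywhere (they remain present in NGS
TPM). A poly(A) transcript is guaranteed one QC-passing read in the
first library of a stage where it is expressed — in this generator,
polyadenylation *means* DRS visibility — so status-recovery misses come
only from NGS TPM support noise. Expression uses log-normal abundances,
planted Gaussian log2 fold-changes for both-stage lncRNAs, Poisson DRS
counts at 300k reads per library, and a planted linear coupling
(slope 0.08, noise 0.02) between log2 fold-change and the stage shift
of the methylation level, giving a strongly positive
methylation–expression correlation by construction.

The generator is deterministic: one `numpy` Generator seeded from the
config drives every draw, files are written in fixed order and format,
and identical seeds give byte-identical bundles.

What the generator does *not* emulate: genome sequence (kmers are drawn
directly, with an optional bias toward AAACH at weight 0.38, not read
from a FASTA), assembly artifacts, alignment ambiguity, batch effects,
overdispersed counts, or correlated site placement. Passing recovery
tests therefore demonstrates the correctness of the downstream
arithmetic under clean planted conditions, not robustness to upstream
noise on real libraries.

## Problem sizes

The default bundle is 60 coding genes, 30 reference lncRNAs, 65 planted
novel lncRNAs over seven class codes, 6 junction-sharing isoforms and 4
short rejects — small enough that the whole pipeline runs in about a
second while covering every code path. Recovery suites use dedicated
cohorts: a high-depth configuration (400 reads per site per library,
site rate 3 per 100 nt) for ratio recovery within ±0.02, and a
550-lncRNA coupled cohort so that ≥ 300 transcripts carry both a d value
and a methylation shift for the correlation check.

## Known limitations

- Single-exon `=` uses a permissive any-overlap rule; junction chains
  are undefined for unspliced transcripts and the upstream convention
  is not documented. The flag is visible in assignment evidence.
- A query whose span overlaps a reference while satisfying no
  structural rule (exotic interleaved geometry) falls through to `u`.
- The reference biotype vocabulary is mapped onto three classes
  (protein_coding / lncRNA / other); users of real annotations with
  richer vocabularies (e.g. novel_transcribed_region) must choose their
  own mapping before relying on the annotated-lncRNA set.
- The m6A module never lifts sites to genome space beyond the
  transcript-to-genome coordinate helper; multi-isoform site collapsing
  in genome space is out of scope.
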