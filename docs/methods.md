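# Methods

This note documents the models and procedures novostart implements, the
parameters that matter, the synthetic-data design, and the numerical and
design choices that were genuinely open.

## Coordinates and data model

All internal coordinates are 0-based, half-open, on the forward strand of
the reference; GFF3/VCF (1-based inclusive) and MAF reverse-strand starts
are converted once, at the I/O boundary. Transcript coordinates count
mature-transcript bases 5'→3', so position 0 of a minus-strand transcript
is its highest genomic coordinate. The genome↔transcript map is built per
transcript from its exon list and is a bijection onto the exonic bases
(checked exhaustively in the tests). Uniqueness of footprint mapping is
taken from the SAM NH tag (NH == 1), falling back to MAPQ > 3 when NH is
absent. Non-coding-RNA filtering is consumed as a precomputed BED blacklist
rather than rebuilt from rRNA/tRNA/snRNA databases.

## Start-gain SNV calling

A call requires, for a biallelic SNV and a transcript with a nonempty
5'UTR: (1) the SNV is exonic and upstream of the canonical start in
transcript coordinates; (2) substituting the alternate allele creates ATG
at one of the three triplets covering the variant base, the reference
triplet not being ATG — if more than one qualifies, the 5'-most in-frame
AUG is reported (scanning-model default); (3) the distance to the canonical
start is a multiple of 3; (4) no TAA/TAG/TGA in that frame strictly between
the two starts (both exclusive, matching the novel-CDS definition);
(5) the genomic position is outside the union of CDS intervals across all
annotated transcripts. Calls are per (SNV, transcript) pair with a
deduplicated per-SNV view for population summaries, because the rules are
transcript-relative but counts are reported per SNV.

Population conventions the upstream data leave open: missing genotypes are
excluded from both numerator and denominator of the allele frequency; an
individual "carries" a call if at least one haplotype has the alternate
allele (heterozygotes and homozygotes count equally in burden);
multiallelic VCF rows are split into biallelic records and indels skipped;
transcripts whose CDS starts at transcript base 0 simply yield no
candidates. Autosomes default to contigs 1–22 with or without a "chr"
prefix (configurable).

The occupancy-analysis filter keeps calls with ≥ 5 codons between the novel
and canonical starts, ≥ 3 carriers, and an autosomal contig. The
nonsense-mediated-decay rule computes `distance = last_junction_tpos −
stop_end_tpos` and predicts decay when the distance strictly exceeds 50 nt;
single-exon transcripts are never predicted targets.

## Fixed human-specific start codons

Pairwise blocks are reduced to one-to-one coverage: a block survives iff no
other block overlaps its span on either genome (equivalently, per-base
coverage is exactly 1 on both sides; the implementation is a sweep, the
tests check it against a brute-force coverage count). Divergent sites are
ungapped, N-free columns where human ≠ chimp; gorilla and orangutan alleles
are read through their own one-to-one maps. A candidate becomes a call when
the site is inside an annotated human start codon, the chimp ortholog is in
a chimp 5'UTR (any chimp transcript qualifies; its id is recorded), both
outgroups differ from the human allele, and the population VCF shows no
alternate allele at the site (absent, or present with all called genotypes
homozygous reference — sites with some missing genotypes still qualify).
A missing outgroup allele drops the candidate: polarization is impossible,
and the conservative choice avoids misassigning the mutation to the human
branch. Codons, not SNVs, are the unit at species level: sites divergent at
more than one of the three triplet positions merge into a single call with
all offsets recorded. The CUG-origin flag is the chimp orthologous triplet,
read in human-transcript orientation, equal to CTG; a partially aligned
triplet leaves the flag unknown and the call retained, so occupancy
analyses can run with and without CUG-origin codons. Every rejected site
carries a machine-readable reason code.

## Ribosome profiling

Retained reads are unique, off-blacklist, 26–32 nt. P-site offsets are the
fixed rule (11 for 26–29 nt, 12 for 30–32 nt, 0-based from the 5' end; on
the minus strand the 5' end is the rightmost base). Tracks are per-base
P-site counts × 10⁶/total, so each sample's track sums to exactly one
million RPM. Codon occupancy sums the anchor base and its two genomic
neighbours — the transcript-directional "nucleotide before the first" and
"second nucleotide" mirror each other across strands, so the same three
bases contribute either way. Metagene windows walk transcript coordinates
(splice-aware), since 5'UTR anchors can sit near junctions; positions
falling outside the transcript are excluded from means with bookkeeping
kept. Aggregation is mean over anchors within a sample, then mean over
samples, so deep samples do not dominate. Reads whose P-site lands in an
intron still contribute to the genomic track; transcript-space windows
simply never visit them.

Paired anchor classes (e.g. novel vs ancestral start) are compared with a
Wilcoxon signed-rank test whose null is exact for up to 25 non-zero
differences — computed by dynamic programming over doubled midranks, so
ties are handled exactly (the tests verify agreement with full
sign-assignment enumeration) — and a tie-corrected normal approximation
with continuity correction beyond. Zero differences are dropped; all-zero
input returns p = 1 with a warning. The carrier vs non-carrier comparison
is unpaired and uses the rank-sum test; the choice of test is exposed, as
the corresponding published comparison does not name one. Fold ratios are
ratios of group means, unweighted by expression.

## Codon branch models

The substitution model is the Goldman–Yang-style 61-sense-codon model:
`q_ij = π_j κ^[transition] ω^[nonsynonymous]` for pairs differing at one
position, zero otherwise, rows summing to zero, scaled so the expected
substitutions per codon per unit branch length is 1. The tree is the
unrooted 3-taxon star (human, chimpanzee, gorilla) — orangutan serves only
for polarization upstream. The likelihood is Felsenstein pruning: per
column, Σ over root states of π_r Π_branches P_b(r→observed), with
P_b = exp(Q_b t_b) from the symmetrized eigendecomposition of the
reversible Q (restricted to the support of π; zero-π codons are isolated
states, which is safe because any observed codon has positive F3×4
frequency). Columns are compressed to unique patterns.

Codon frequencies default to F3×4 from the fitted alignment, with a uniform
option used by simulation-calibration tests to avoid deliberate
misspecification. Fitting maximizes over κ, ω₀ (plus ω₁ with a foreground),
and three branch lengths, log-parameterized, L-BFGS-B with bounds
(κ ∈ [0.05, 50], ω ∈ [10⁻⁴, 50], t ∈ [10⁻⁶, 20]), from a default start plus
5 seeded random restarts (lnL tolerance 10⁻⁸). Stop-containing alignment
columns are dropped rather than erroring: the orthologs of a novel human
CDS need not be coding in the other genomes. Novel-CDS alignments are
concatenated when the source CDS is strictly longer than 15 nt (the
threshold is exposed; "longer than" is read as strict). The LRT statistic
is 2·ΔlnL against chi-squared with df = 1 (one extra ω); a statistic below
−10⁻⁴ raises an optimizer-failure error, and small negatives are clamped
to zero.

## Synthetic data

The generator builds gene cassettes in transcript orientation — flank,
5'UTR, planted start-codon motifs, simulated novel-CDS interior, main CDS,
intron (inside the CDS, in the 3'UTR for planted NMD targets, or absent),
3'UTR — as a 4-species alignment, assembles per-species genomes with
spacers, and emits FASTA/GFF3/VCF/MAF/SAM/BED plus a truth JSON. Background
sequence uses only C/G, so no AUG or stop codon can arise by accident;
planted motifs (ACG→ATG SNVs, in-frame TAA interruptions, reference ATGs,
overlapping-CDS transcripts) realize one distractor family per rejection
rule of each caller. Footprints are drawn from a per-transcript P-site
intensity (background 1 with 3-nt periodicity of amplitude 0.6, upstream
noise 0.05, anchor codons multiplied by their planted fold), and each
read's leftmost coordinate is back-computed from its sampled length via the
inverse offset rule, so re-running the P-site rule recovers the sampled
positions exactly on both strands and all seven lengths.

Defaults mirror the real study's design at toy scale: 62 genotyped
individuals; 10 true start-gain SNVs with novel-CDS median 48 nt whose
filter partition is 6 kept / 2 short / 1 under-carried / 1 on chrX, plus 3
distractors per rejection class; 26 fixed human-specific start codons with
novel-CDS lengths 3–186 nt (median 30), 16 analyzable at the 5-codon
threshold, 2 of CUG origin, 15 longer than 15 nt for concatenation (330
codons); carrier enrichment 4-fold and hSSC/hASC enrichment 4.9-fold;
codon evolution with κ = 2, t = 0.06 per branch, human ω = 0.36 against
background ω = 2.74. Sequencing depth (12 human samples at 40 000 retained
footprints, 5 chimp samples at 30 000) and the ~600 bp cassette scale are
the package's own choices to keep a full run in seconds while leaving
Monte-Carlo error well below the planted effects. Calibration experiments
(ω-recovery bias, LRT type-I error, null fold rejection rate) use 300–500
codon alignments at t = 0.1 and small in-memory footprint sets, sized so
the whole suite runs in about a minute.

What the generator does not emulate — and hence what passing tests do not
show about real data: alignment error and paralogy beyond simple overlap
conflicts, indel evolution beyond single planted gaps, sequencing error and
mapping bias, expression heterogeneity across genes, kozak-context effects
on initiation, and linkage between variants. Recovery of planted truth
demonstrates the machinery is correct, not that real-data error modes are
handled.

## Known limitations

- The fixation check sees only the supplied VCF; cohort-external variation
  is invisible.
- ω estimates on short concatenations (tens of substitutions) are noisy;
  at the default toy scale individual runs can miss the planted foreground/
  background ordering, which is why calibration uses replicate simulations.
- The exact signed-rank null is quadratic in total rank mass; beyond n = 25
  the normal approximation is used.
- Branch lengths and ω hitting optimizer bounds (e.g. ω₀ = 50 on
  near-saturated backgrounds) are reported as-is with convergence
  diagnostics rather than masked.
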