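# Methods notes

This note records the models, parameter choices and numerical decisions
behind the package, what the synthetic data do and do not emulate, and
the known limitations.

## Coordinate and format conventions

All coordinates are 0-based half-open in memory; GFF3 and VCF are
converted to/from their 1-based conventions only at the file boundary.
Alignments are plain-text SAM (read and written through pysam), phased
SNPs are VCF 4.2 with `GT` of `1|0`/`0|1`, 6mA calls are 6-column
stranded BED with one base per record, and gene/intron annotations are
flat GFF3 (`gene`/`CDS`/`intron` rows with `ID`/`Parent` attributes).

## Synthetic data: what is emulated

The generator reproduces the statistical structure the analyses rely
on, not the full complexity of real sequencing data.

**Diploid genome.** One random AT-rich reference (default 1 Mbp over 4
contigs; base frequencies A=T=0.35, C=G=0.15). Haplotype 1 equals the
reference; haplotype 2 carries heterozygous SNPs at rate 0.006/bp (the
~0.6% heterozygosity regime) and monoallelic indels at 5×10⁻⁴/bp, half
insertions, lengths 15 + Geometric(0.1) to give the downward-sloping
length profile above the 15 bp detection cutoff. A quarter of
insertions are built as TDR-bounded: the insert suffix duplicates the
3–10 bp of reference immediately left of the junction, and the
junction is placed so this repeat contains a TA dinucleotide (the
mobile-element integration signature). Optional "true IES" inserts go
onto *both* haplotypes of the MIC template only, so the MIC library
shows retention ≈ 1 and the MAC ≈ 0 at those loci.

**Reads.** Long reads (5 kbp) are substrings of the haplotype
sequences drawn alternately from both haplotypes at half the library
coverage each; CIGARs are derived from the known haplotype layout
rather than from a mapper, so alignment is exact by construction and
aligner artifacts (soft-clips, mismapping near repeats, chimeras) are
deliberately absent. Reads carry an integer `HP` tag; substitution
errors are optional and homopolymer-type errors are not modeled. An
adapter path exists for real data: alignments without tags can be
haplotagged internally from a phased VCF by majority vote over covered
SNPs (ties left untagged).

**Genes and coding sequence.** A gene is ATG + interior codons + 7
guard codons + UGA. Interior codon count is 60 + Geometric(mean 90)
(mean 150 codons): the floor reflects that real annotated gene sets
contain essentially no sub-200 bp ORF-only genes, and a pure geometric
tail would make them common. Codon usage combines standard eukaryotic
amino-acid frequencies (under the karyorelict code: UAA/UAG = Gln,
UGA = Trp) with position-specific GC (0.42/0.335/0.25 by codon
position, mean ≈ 0.35), which gives coding sequence both the observed
CDS/UTR GC contrast and its 3-base compositional periodicity. UGA
appears as Trp at 1% of coding codons — the value is not reported for
the organism and was fixed once as a typical ambiguous-code usage —
and never within the 21 nt guard. Intergenic/UTR sequence is i.i.d.
AT-rich at 18.6% GC.

**Transcripts and introns.** Transcript = CDS + exponential 3′-UTR
(mean 53 bp, AT-rich) + poly-A of 7 + Geometric(0.3). Genomic copies
carry introns drawn from an explicit categorical distribution on
16–40 bp: weight 0.55 at 16, exp(−(L−17)/3.2) above 17, and lengths
divisible by three down-weighted ×0.5 (3n depletion); this yields mode
17, mean ≈ 19, ~94% ≤ 25 bp. Spliced alignments support each intron
with configurable spliced/unspliced read counts (defaults 15/3).

**Chromatin.** Nucleosome arrays have 160 bp spacing with Gaussian
jitter (sd 10 bp). In MIC mode the array phase is random per contig
and independent of genes; in MAC mode arrays start at a fixed offset
(60 bp) downstream of each CDS start in the gene's own direction. The
offset is not reported in the source data and is an arbitrary fixed
choice; only its existence (phase coherence across genes), not its
value, matters to the analyses. Fragment template lengths are drawn
±30 bp beyond the nominal library windows (96–136 MAC, 126–166 MIC) so
template-length filtering is actually exercised.

**6mA.** Calls are placed at ApT dyads inside gene bodies with
probability `sixma_fraction_of_ApT × (1 − cos(2π(pos − anchor)/160))`,
i.e. peaking in linkers, anti-phase to nucleosome centers (the
qualitative alternate phase, implemented as a raised-cosine). A
hemimethylated dyad's methylated strand is the gene's sense strand
with odds 34:1; a `1 − hemi_fraction` share of dyads is methylated on
both strands (default hemi_fraction 1.0). MIC mode scales the call
probability by 2×10⁻⁴, matching the orders-of-magnitude MAC/MIC
contrast.

Because the generator emits exact alignments, error-free splices and
i.i.d. background sequence, passing tests demonstrate correctness of
the computations and their calibration under the assumed statistical
structure — not robustness to mapping artifacts, repeats, sequencing
error profiles, or model misspecification in real libraries.

## IES screen

Indel events are collected from CIGAR I/D operations (length ≥ 15 bp),
clustered per contig and type when junctions and lengths agree within
10 bp (standing in for fuzzy-length merging; junction and length of a
cluster are the support-weighted modes), and kept at ≥ 3 supporting
reads for insertions and ≥ 5 for deletions. A read counts as spanning
("without" the variant) only when it covers ≥ 15 bp on each side of
the junction. Retention is defined symmetrically for deletions (the
fraction of reads carrying the deletion). The Wilcoxon comparison
drops zero differences, uses the exact null for n ≤ 25 without ties
and a continuity-corrected normal approximation otherwise (scipy's
implementation behind the module's interface). Fisher's exact test for
haplotype concordance is two-sided with the standard
sum-of-less-probable-tables rule; concordance takes the better of the
two phase assignments, so it is ≥ 0.5 by construction. TDR detection
tests both junction sides and reports the longer match; the analytic
expectation uses the same two-sided-max rule so observed and expected
distributions are commensurable.

## Gene model

Durations are geometric (self-transitions) for CDS interior and
intergenic states; the guard is a fixed 7 codons. The "21 nt" guard is
interpreted as 7 whole codons. Emissions are order-0: a 64-codon table
for CDS (UGA mass = its Trp usage, with +1 pseudocounts), a 63-codon
renormalized table for the guard (UGA = 0), and single-base
frequencies for intergenic sequence. The start model is a bare ATG.
Training matches the geometric parameters to the mean interior-CDS and
intergenic lengths (q = m/(m+1)); the gene-start probability is split
equally between strands. Decoding is a single joint Viterbi path over
mirrored forward/reverse states, so opposite-strand overlaps are
impossible; arithmetic is in log space; ties break deterministically
toward the forward/earlier state. Genes always begin ATG, end UGA, and
contain no in-frame UGA within the guard, because the guard emission
assigns it probability zero. On genomes simulated from fitted
parameters, ≥ 90% of genes are recovered with exact boundaries; the
remaining disagreements are genuine maximum-likelihood ambiguities
(nearby in-frame start codons, stop placement past a coding UGA) of
the kind the ambiguous code makes unavoidable for any
composition-based decoder.

Intron annotation counts an unspliced read only when a contiguous
aligned block covers one base on each side of the intron; overlapping
accepted introns on one strand resolve to the better-supported one.
The intronless assembly splits contigs at N-runs and masked intervals,
drops pieces < 1 kbp, and records a strictly monotone block map;
lift-back splits CDS around excised introns and re-emits them as
features, and round-trips exactly on retained bases.

## Chromatin statistics

Midpoints use the forward-oriented mate: (leftmost + rightmost) // 2
(rounding down for even template lengths). The global phaseogram
counts downstream offsets 1..1000 only, unnormalized. The dominant
period is the autocorrelation argmax over 120–200 bp of the
mean-subtracted counts, reported only when the peak exceeds 0.2 of the
lag-0 autocorrelation — shot noise in aperiodic profiles stays well
below that at these window sizes, and genuinely periodic profiles sit
far above. Gene-anchored periodicity is quantified separately as the
relative spectral amplitude of the profile at its best period
(|Σ (c − mean)·e^{2πi·offset/T}| / Σ c): this measures phase-coherent
modulation, which distinguishes gene-phased MAC arrays from MIC arrays
that are periodic but independently phased per region (whose anchored
profile flattens while remaining locally periodic). The nucleosome–6mA
phase offset is computed from the complex phase of each anchored
profile at the shared dominant period; anti-phase means a lag near
half a period. The plus:minus 6mA ratio is computed in the gene's
sense frame over calls inside CDS, per the stated sense-strand
framing. ApT dyads pair a plus-strand call at i with a minus-strand
call at i+1 within a reference 5′-AT-3′ dinucleotide.

## Transcript statistics

The 3′-UTR excludes the stop codon (UTR begins after its third base).
Poly-A detection takes the longest terminal A-run (optionally allowing
mismatches); because UTRs are AT-rich, a trailing UTR adenosine is
occasionally absorbed into the tail — records whose annotated stop is
damaged by trimming are dropped as internally inconsistent. The
3n-depletion baseline for intron lengths is the mean of the two
flanking non-3n classes; reports with fewer than three length classes
are flagged degenerate rather than given a ratio.

## k-mer comparison

Counting is canonical (k odd, so no k-mer equals its reverse
complement) and in-memory, sized for tens of Mbp. "Combined frequency"
is the sum of the two libraries' frequencies. The joint matrix is
capped at 400 per axis with overflow pooled in the last bin. The
genome-size estimator is deliberately simple: the dominant multiplicity
peak above a minimum frequency (after width-3 smoothing of the
multiplicity histogram, so the peak is not set by shot noise) divides
the total k-mer mass above the cutoff. It is a coverage-peak heuristic,
not a mixture-model fit, and inherits that method's biases (no
heterozygosity or repeat modeling).

## Problem sizes used in tests and the acceptance script

Fixed once as desk-scale stand-ins for the genome-scale originals:
1 Mbp diploid at 40× per library for the retention screen; ~10⁴
midpoints for phaseogram periodicity; 500 training genes and 10⁴
decoded single-gene contigs for the gene model; 2 000 introns at 15
spliced / 3 unspliced reads for intron recovery; 1 000 replicate
candidate sets for the null calibration of the Wilcoxon comparison and
10⁶ random junctions for the TDR expectation check.

## Known limitations

- No aligner, error-profile or repeat realism in the generator (see
  above); results on real libraries depend on upstream mapping quality.
- The GHMM models CDS only (no UTR or promoter states), order-0
  emissions, geometric durations, bare-ATG starts.
- The k-mer size estimator is not a substitute for spectrum
  model-fitting when heterozygosity or repeat content matters.
- Deletion retention uses the symmetric definition; other conventions
  exist for the denominator.
- `classify_candidates` labels are heuristic summaries driven by the
  stated thresholds, not calibrated posterior probabilities.
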