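# Methods

`subfrac` quantifies how the two subgenomes of an allotetraploid diverge
after interspecific hybridization and whole-genome duplication, using a
diploid outgroup as reference. The motivating system is a frog
allotetraploid whose parental chromosome sets (L, long; S, short) remain
separate and recognizable, with an outgroup species T; everything below is
written for that L/S/T setting but applies to any triplet with resolvable
subgenomes.

## Deletion calling

Input is three pairwise whole-genome alignments (L-T, S-T, L-S) as
homology blocks. A deletion from subgenome X is called on the sister
subgenome, where the sequence survives:

1. **Candidates** — regions of the retained subgenome covered by
   reciprocal blocks to the outgroup but with zero reciprocal-block
   coverage to X. Sub-regions within 10 bp are merged; candidates
   overlapping assembly gaps (maximal N-runs >= 10 bp) for more than 25%
   of their length are removed.
2. **Flank evidence** — both 500-bp flanks of a candidate must contain a
   reciprocal block to X overlapping the flank by >= 50 bp (the 50-bp
   minimum guards against 1-bp anchors; configurable).
3. **Size filters** — the gap between the projected flank anchors on X
   must be at most 4 kb, and the retained span at least three times the
   gap. The anchor on each side is taken from the block nearest the
   candidate (ties broken by longer block).

The 4-kb bound is applied on the deleted genome and the 3x ratio compares
the retained span to that residual gap. This reading makes large clean
deletions callable (big retained span, tiny residual gap) and, just as
importantly, rejects sequence that is merely private or unalignable: for
such regions the "gap" on the sister genome is about the size of the
region itself, so the ratio fails. In the synthetic system this filter is
what separates implanted deletions (called with precision 1.0) from
implanted subgenome-specific zones.

## Randomization enrichment

Deleted base pairs overlapping a feature class are compared with the mean
of within-chromosome randomizations (default 1000; each deletion
relocated uniformly on its own chromosome, length preserved, overlaps
permitted). The p-value is the two-sided normal tail of
z = (obs - mean)/sd; direction is carried by log2(obs/expected).
Benjamini-Hochberg adjustment is applied across all feature x chromosome
tests, and the L-vs-S contrast per feature class is a Mann-Whitney U on
the per-chromosome log2 fold values (n = number of chromosomes). Feature
classes for a deleted copy use the sister homeolog's annotation projected
through the L-S alignment as a proxy for the pre-deletion state;
"intergenic" means >= 1 kb from any gene. Shuffled intervals may overlap
each other; a rejection-sampling non-overlapping mode exists but the
overlapping null is the default because overlap-free packing biases nulls
on dense chromosomes. Null calibration (deletions placed independently of
a feature) keeps the fraction of p < 0.05 near nominal (~0.04 at 200
replicates, 200 randomizations).

## NAHR signatures

Non-allelic homologous recombination between repeats on one chromosome
deletes the intervening sequence. Two statistics on retained regions:

* **Repeat length** — lengths of repeat elements overlapping retained
  regions versus repeats overlapping count/chromosome/size-matched random
  regions, summarized as a ratio of means with a Mann-Whitney p.
* **Flank similarity** — global-alignment identity (Needleman-Wunsch;
  match 1, mismatch -1, gap open -2, gap extend -1, pinned and recorded in
  output) between each region's left and right 1-kb flanks, versus random
  same-chromosome 1-kb pairs. Left-vs-right is the mechanistically
  motivated reading (the recombining repeat pair straddles the
  breakpoints); an each-vs-random mode is available. Identity values are
  scoring-dependent — random DNA pairs score ~0.52 under the defaults, so
  only contrasts are meaningful.

## Codon evolution and pseudogene dating

Ka/Ks uses Nei-Gojobori (1986) counting with Jukes-Cantor correction:
per-codon synonymous-site fractions averaged over both sequences,
multi-substitution codons averaged over minimal substitution paths (paths
through stops excluded unless unavoidable; changes creating stops counted
nonsynonymous), codons with gaps, ambiguity or stops in either sequence
excluded. The estimator is deliberately transparent and is verified
exhaustively against an independent path-enumeration oracle; it is
pluggable if a likelihood estimator is preferred.

The ancestor at the L/S split is reconstructed per column by Fitch
parsimony on ((L,S),T): child agreement wins, otherwise the outgroup
arbitrates, three-way disagreements become N and drop out of rate
counting. At these divergences (~0.2 synonymous substitutions/site) a
three-taxon ML reconstruction would be nearly identical. One consequence:
substitutions shared by L and S are assigned to neither branch, so
per-branch Ks against the Fitch ancestor is mildly underestimated
(~10-15% at default divergence); dating is robust to this because it uses
the ratio of rates on the same branch.

A unitary pseudogene is dated by a two-epoch mixture: the copy evolves
under its constrained ratio omega_f until losing constraint t My before
present, then neutrally, so omega_obs = (omega_f (T - t) + t)/T and

    t = T (omega_obs - omega_f) / (1 - omega_f),  clamped to [0, T].

omega_f is the functional homeolog's branch ratio (or the mean over extra
functional orthologs when supplied); T is the time since the subgenome
split, default 34 My with the hybridization marker at 17 My. Confidence
intervals come from resampling aligned codon columns with replacement
(default 1000; replicates with zero synonymous divergence dropped, CI
flagged unreliable if more than half drop). On synthetic pseudogenes with
loss times uniform on [0, 34] My at Ks ~ 0.2, the estimator's regression
slope is ~0.98, median absolute error ~4 My, and 95% CI coverage ~0.91.

## Gene loss

Four non-exclusive pseudogene features per copy: premature stop codons
(in-frame, strictly before the annotated terminal codon), coding sequence
at least 50% shorter than both the homeolog and the outgroup ortholog
(annotated CDS lengths), loss of >= 75% of the homeolog's
H3K4me3-decorated promoter (the peak overlapping the TSS, falling back to
TSS +/- 500 bp) after projection through the L-S alignment into deletions
or unaligned sequence, and frameshifts (alignment gap runs of length not
divisible by 3, each run reported). A likely pseudogene additionally must
be expressed at least tenfold below its homeolog with the homeolog
expressed (TPM >= 1 by default; a strict no-expression mode requires the
candidate below the floor). The exclusive partition gives deletion
features priority (truncation or promoter loss -> "deletion-driven"),
then single point features, then "multiple"; the priority is configurable.

Nonsense (protein-truncating) variants: SNPs inside annotated CDS passing
the depth post-filter (>= 10x with >= 4 alternative observations) whose
substituted codon — strand-aware, complemented on minus-strand genes —
becomes a stop strictly before the terminal codon. The implementation is
checked against a whole-CDS mutate-and-translate oracle on both strands.
Protein-complex retention classifies fully represented heterodimers by
copy status; the expected both-single fraction under independent loss is
q^2 with q either supplied or estimated from the classified dimers as
(one_single + 2 both_single)/(2 n).

## Regulatory landscape

A reference peak is conserved when its projection overlaps a target peak
by >= 1 bp (configurable). Subgenome-specific peaks have strictly zero
aligned bp to both the sister subgenome and the outgroup (relaxable).
Annotation enrichment of a peak subset against the full peak population
uses the hypergeometric upper tail computed in log space (reportable below
the float underflow limit), with a peak counted as overlapping an
annotation when more than 50% of the peak is covered; an annotation is
reported as enriched when it passes the p, fold and prevalence thresholds
together (defaults 1e-4, 2x, 15%). Active transcription uses a
mean + 2 SD background threshold per mark (both marks required, boundary
passes, scale-equivariant). The proximity test partitions genes by
TSS-to-nearest-enhancer distance (<= 5 kb, inclusive) and compares log-TPM
between groups by Mann-Whitney.

## Synthetic data generator

Each chromosome is built in a shared ancestral coordinate space. Backbone
sequence is common to the three genomes; the generator implants, with
non-overlapping padded placement:

* **Deletions** removed from L or S (defaults 150 and 300 on a 5 x 2-Mb
  system — a 2:1 S bias; sizes log-uniform 200-5000 bp). A configurable
  fraction (default 0.5) carries an NAHR signature: three identical copies
  of an 800-bp repeat family — one in each flank of the retained
  counterpart and one inside the lost segment — so that retained regions
  overlap long repeats *and* their flanks align to each other, the two
  statistics the NAHR module measures. Background repeats are exponential
  with mean 150 bp at 5% density.
* **Private zones** of novel per-genome sequence hosting subgenome-
  specific enhancer peaks; pairs involving the owner emit no blocks there.
* **Genes** (default 500, 300-1200 bp single-exon CDS, random strand)
  whose codon sequences evolve along ((L,S),T) under a Jukes-Cantor
  proposal process with an omega acceptance filter: proposals at the
  neutral rate (0.2/34 per site per My, giving branch Ks ~ 0.2),
  synonymous changes always accepted, nonsynonymous accepted with
  probability omega (Beta(2,8) per gene, mean 0.2) while constrained and
  always after the gene's loss-of-constraint time; premature stops are
  rejected under constraint. 20% of genes lose constraint on one branch
  (S-biased 2.3:1) at a time uniform on [0, 34] My. The split times are
  34 My (L/S) and 48 My (outgroup).
* **Expression** — bivariate log-normal homeolog TPM with correlation 0.60
  and a ~5.7% median L excess; relaxed copies are knocked down 1000x so
  both the tenfold and the no-expression pseudogene filters engage.
* **Peaks** — promoter (H3K4me3) peaks per gene and intergenic enhancer
  (p300) peaks on the outgroup, mirrored onto L and S with configured
  conservation probabilities (0.40 and 0.13); specific peaks sit in the
  private zones.
* **Variants** — single-sample VCFs with DP/AD fields; coding SNPs at
  3.5/kb plus stop-creating SNPs at 0.02/kb (matching ~2% of genes
  carrying a nonsense variant at typical CDS lengths).

Alignment blocks between every pair are emitted exactly (broken only at
deletions, zones and N-runs, identity measured from the sequences), with
mirrored rows so all blocks are reciprocal. Everything derives from one
seeded generator consumed in fixed order, so runs are byte-identical.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: alignment error and fragmented
homology, repeat-mediated misalignment, inversions and rearrangements,
CpG and context-dependent mutation bias, indel hotspots, intron structure,
chromatin-signal intensity (peaks are intervals with labels, not signal),
and read-level noise in variants or expression. Recovery results bound
algorithmic correctness, not robustness to those artifacts.

## Problem sizes and numerics

Default test and acceptance runs use the 10-Mb five-chromosome system
(450 implanted deletions, 500 genes), 200 randomizations or bootstrap
replicates where the analysis defaults to 1000, 200 genes for dating
recovery, and 200 replicates for null calibration — sizes chosen so the
whole suite re-runs in well under a minute while keeping Monte-Carlo
standard errors small relative to the tested tolerances. Mann-Whitney
switches from exhaustive enumeration to the tie-corrected normal
approximation above n + m = 14. Degenerate cases are explicit: zero-sd
randomization nulls are flagged with p in {0, 1}, empty projections are
valid results, JC corrections at p >= 0.75 flag the estimate undefined
rather than extrapolating, and ambiguous Fitch columns drop out of
counting rather than being guessed.

## Known limitations

Single-exon gene models in the generator (the classifiers accept any CDS
intervals); no inversion or rearrangement calling; parsimony rather than
ML ancestors; the NG86 estimator saturates near p = 0.75; promoter
definitions inherit H3K4me3 peak quality; the enrichment null is uniform
per chromosome with no GC or mappability matching.
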