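# Methods

This note documents the models, parameter choices and numerical decisions
behind `svlegacy`, stage by stage, and what the synthetic experiments do and
do not demonstrate about real data.

## Structural-event inference from three-genome alignments

A chromosome is represented as a `TripleAlignment`: three gapped rows
(ingroup A, ingroup B, outgroup) of equal column count with per-row
column-to-position maps.  Coordinates are 0-based half-open everywhere;
conversion to 1-based happens only at file boundaries (GFF3).

**Candidate extraction.**  An event region is the maximal run of columns in
which *any* row is gapped, kept when at least one row contains a run of
strictly more than `min_gap = 50` consecutive gaps.  Merging adjacent
gap-containing columns into one region avoids double-counting events whose
deletion and insertion components abut (the common case for repair-derived
indels).  Candidates whose 50-column flanks would run off the chromosome are
discarded and logged.

**Filters and polarization.**  Flank quality requires, in each flank
separately, strictly more than 90% of columns with the same non-gap base in
all three rows; three-way (rather than pairwise) agreement is required
because polarization relies on both ingroup–outgroup comparisons being
trustworthy.  Region identity between two rows is (matching non-gap columns)
/ (the larger ungapped length); two rows entirely gapped over a region are
identical by convention — they share the ancestral absence of sequence,
which is what routes outgroup-private insertions into the "ingroups
identical" discard.  Ingroup–ingroup identity ≥ 0.95 discards the candidate;
otherwise the event is assigned to the ingroup that does *not* match the
outgroup at > 0.95 (ties and double-matches are discarded as ambiguous).

**Gap coverage and classes.**  `g = L_der / (L_der + L_anc)` over the event
region; `g > 0.95` insertion, `g < 0.05` deletion, `0.49 ≤ g ≤ 0.51` dropped
as balanced artifacts, otherwise mixed.  Note that an event's *net* length
(|L_der − L_anc|) can be ≤ 50 while its longest gap run exceeds 50; such
mixed events are genuine >50 bp mutations and are emitted.  Genic context is
annotated on the reference (ingroup A) interval with precedence exon >
intron > intergenic; zero-length reference intervals (insertions) are
treated as 1 bp points.

## The d statistic

Contexts are `left flank (L) + allele + right flank (L)` on each genome.
Local alignment uses match +1 / mismatch −2 and blastn-style affine gaps
(a gap of length k costs 2 + 4k).  The second major alignment is found after
masking the first's footprint on the longer context, with two refinements
that the anchor geometry forces:

* **Edge margin.**  The mask is shrunk by `max(25, 10% of the footprint)` bp
  at each edge.  Slippage events re-use a short annealing site, so the two
  major alignments legitimately overlap there; a full-footprint mask would
  delete the anneal from the search space and collapse slippage (d > L) onto
  tandem (d = L).  A second alignment falling entirely inside the first's
  footprint is rejected and recomputed under the full mask.
* **Anchor trimming.**  Each alignment is trimmed back to its outermost run
  of ≥ 10 consecutive matched columns.  Optimal local alignments extend a
  few score-positive columns past the true homology boundary by chance;
  requiring a solid terminal match run removes those edges (a random 10-run
  has probability 4⁻¹⁰ per end) without touching genuine boundaries.

With the pair ordered along the longer context, `d` is the signed overlap of
their projections on the shorter context (half-open ends, so a perfect
tandem gives exactly `L` and abutting flank alignments give exactly 0).
Mechanism calls use tolerance `max(2 bp, 5% of L)`: tandem when `|d − L|`
is within tolerance, ectopic when `|d|` is, slippage-like when
`d > L +` tolerance, otherwise unclassified (including events with fewer
than two alignments above score 20).

**Breakpoint ambiguity.**  When an insert happens to begin with the same
bases as its right flank, the breakpoint — and therefore the exact d — is
not a well-defined quantity (the same degeneracy that makes un-normalized
VCF indel positions ambiguous).  The bundled reference constructions
(`svlegacy.constructs`) therefore resample up to 5 bases at each junction so
that planted events are breakpoint-unambiguous; real events with ambiguous
junctions can carry d values a few bp off their ideal anchor, which the
classification tolerance absorbs.

## TE families

Full-length element discovery uses infix (semi-global) edit-distance
alignment with a combined budget: an accepted hit may lose at most
`(1 − 0.95) + (1 − 0.97)` of the element length to mismatches, indels and
truncation.  Hits are harvested best-first with masking; a genomic interval
claimed by an earlier element is skipped, so results depend on element order
(documented, and exercised by a test).  Near-identical sequences are paired
when a global alignment matches ≥ 90% of *both* lengths; clusters are
connected components of the pair graph (a small Markov-clustering
implementation, inflation 2, is available as `method="mcl"` for chained
components).  Members are multiply aligned with mafft and summarized by a
majority-rule consensus: per-column plurality over {A, C, G, T, gap}, ties
broken by that fixed order, gap-plurality columns deleted.  The bundled toy
library (8 families, 1–12 kb, generated deterministically in code) exists to
exercise this machinery; it does not attempt to model real repeat
landscapes.

## Read-contiguity genotyping

The genotyper consumes an abstract `ReadEvidence` (sample, read intervals,
split/soft-clip flags), so tests need no BAM; a BAM adapter would map CIGAR
soft-clips and supplementary alignments onto the two flags.  Rules, in
order: split/soft-clipped reads removed; reference call when > 98% of the
interval is covered (or, under 20 bp, when a read spans the interval ± 5
bp); derived call when reference support fails *and* both 50 bp flanks carry
at least one read; otherwise missing.  The derived/missing distinction is a
documented reconstruction — contiguity logic states only the reference rule
— chosen so that loss of data (no flank coverage) is never read as a derived
allele.  The false-negative assessment downsamples a deep all-derived
sample to 22×/31×/40× and reports the fraction of loci called reference;
with hemizygous-like noise planted at 10% of loci the measured rate recovers
the planted parameter within binomial error.

## The breeding-cohort simulator

One simulator generation represents a ~4-year breeding *cycle*: a cross (or
a carried-forward line) followed by selfing to near-fixation.  Lines are
therefore fully inbred and haploid-coded.  Per cycle, parents are sampled
with probability ∝ fitness `w = Π (1 − s_class)^x · (1 + s_sweep)^x_sweep`;
a line is carried forward unchanged with probability `selfing_rate`
(cycle-level carryover, not per-meiosis selfing — rice selfs at ~99% per
meiosis, but most released varieties derive from deliberate crosses), else
two parents recombine with Poisson breakpoints at `recomb_rate` per bp,
which folds in the map expansion of the within-cycle selfing generations.
Generations map linearly onto release years (default 28 cycles over
1905–2013) and varieties are sampled evenly across cycles.

Founders are mosaics of K = 8 base haplotypes (segments ~10 kb).  With
founder LD enabled, sites within a 10 kb window share one random ranking of
the K bases, so carrier sets are nested and the population shows real
LD-block structure; with it disabled, every locus draws carriers
independently.  The sweep allele is *not* present at founding: it is
introgressed mid-course (default generation G/2, ≈ 1960) on a deliberately
novel local haplotype, mirroring how the semi-dwarf allele entered US
breeding in the late 1960s from foreign material.

**Experiment designs** (fixed in `svlegacy.experiments` and shared by the
analysis drivers, tests and acceptance checks):

* *Rate ordering*: N = 300 lines, 101 varieties, 80 loci per SV class,
  s_exonic = 0.12, s_intronic = 0.03, intergenic neutral; carryover 0.4,
  recombination 2×10⁻⁴/bp, founder LD off.  The s values spread the purge
  over the whole century (a strong s exhausts the decline within a few
  cycles and leaves nothing for the year regression to see), and founder LD
  is off because nested founding carrier sets make neutral loci hitchhike
  with selected neighbours — a real phenomenon, but one that would test
  linkage, not the rate statistic.
* *Sweep scan*: N = 500, 150 SNPs, carryover 0.95, recombination 10⁻⁵/bp,
  founder LD on, sweep s = 0.5.  Tight linkage preserves the block
  structure the scan needs.
* *Genotyping*: 40× (or 207× for the downsampling study) reads of 100 bp;
  derived carriers produce reads truncated at breakpoints (soft-clipped
  with probability 0.9, else split); SV loci are spaced ≥ 2 kb so read
  pools of neighbouring loci stay independent.

**Neutrality calibration.**  With all s = 0, per-variant year-regression
slopes pool to zero within Monte-Carlo error and frequency trajectories are
martingales — *before* any frequency filter.  Conditioning on a final
minor-allele frequency > 0.1 (as the selection analyses do) induces a known
ascertainment bias away from zero; neutrality is therefore asserted on the
unfiltered generator output.

## Selection analyses

Per-variant rate = OLS slope of the 0/1 allele on release year over non-NA
varieties (missing calls excluded, not imputed).  The LSD test pools the
error variance by one-way ANOVA, compares all class pairs with pooled-SE t
statistics, adjusts with Benjamini–Hochberg, and assigns letters by
insert-and-absorb on mean-ordered classes.  The burden regression counts
derived exonic-SV alleles per variety (missing = 0 by default, with the
informative-call count reported; a drop mode rescales instead) and fits OLS
per grain type and combined.  The block-score regression fits each block's
haplotype score (count of derived class alleles) on release year and then
regresses those coefficients on score variances, reporting a 95% CI.  Trio
analysis drops trios whose miscall/segregating ratio exceeds 0.35, then
variants segregating in fewer than 10 trios or with one allele never
inherited (common-parent miscall signature), and reports derived-inheritance
bias per variant.

## Haplotype blocks, sweep scan, H-scan, kinship

Panel preparation drops sites with > 10% heterozygous calls or ≥ 20 missing
calls (the missingness phrasing is ambiguous in the field description; the
stricter reading was implemented) and thins to ≥ 3 kb spacing.  LD pruning
follows plink's `--indep-pairwise 50 10 0.1` semantics: r² computed on
dosages over pairwise-complete cases, the later site of an offending pair
removed.  Block definition is a documented reconstruction (the original
tool's algorithm is unpublished): greedy left-to-right agglomeration while
the bp span stays ≤ 800 kb, the next site's r² with the block's last site is
≥ 0.5, and the number of haplotypes at frequency ≥ 0.02 stays ≤ 10;
sub-threshold haplotypes pool as "other".  Every site belongs to exactly one
block.

The sweep scan flags a block when any single haplotype's frequency
*increases* by ≥ 0.23 (inclusive) from an earlier to a later era, any era
pair; ≥ 2 such haplotypes in one block marks a candidate soft sweep.
Directional gain rather than absolute change is used because the threshold
is anchored on the semi-dwarf block's observed *rise*, and absolute change
would double-count the complementary decline of displaced haplotypes.  Era
boundaries are fixed at 1905–1961 / 1964–1986 / 1990–2013; varieties between
boundaries join the nearer era.

H-scan index: for each site, the mean over variety pairs of the bp length of
the maximal run of consecutive identical sites around the focal site;
missing calls break tracts and exclude the pair at that site; a single-site
tract has length 1 bp.  Centered-IBS kinship: dosages centered per site by
the mean derived frequency (missing values sit at the center), `K = WWᵀ /
Σ p(1−p)`.

## What the synthetic experiments do and do not show

The generator reproduces the *statistical structure* each stage assumes —
exact planted breakpoints, known mechanisms, known selection coefficients, a
planted sweep, era-stratified sampling — on a 100–400 kb toy genome with
drastically scaled-down population sizes.  Consequences: drift is far
stronger than in the real population, so the neutral sweep-scan null
(~0.15–0.25 of blocks flagged at Δ = 0.23) is much higher than the 3%
observed at real scale, and the planted sweep is assessed *against that
measured null*, not against the real-data percentage.  The simulator does
not model admixture among subpopulations, realistic repeat landscapes,
reference-mapping artifacts, or genotyping error beyond the stylized
hemizygous pattern.  Passing tests demonstrate correctness of the
algorithms and recoverability of planted signal under the stated designs —
not that real rice data would yield the same numbers.

## Problem sizes

Default experiment scales were chosen so the full test suite and analysis
drivers run on a laptop in minutes: 400 kb chromosomes with ~50 planted
events for inference round trips, 50 seeded cohorts for the ordering and
sweep experiments, 100–150 loci for genotyper calibration, and d-statistic
anchors up to L = 4.9 kb (the longest perfect tandem duplication the
mechanism analysis contemplates).
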