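# Methods

`orgrearr` analyses structural instability of small circular organellar
genomes (plant mitochondrial and chloroplast DNA) from short-read data.  It
implements three read-level assays — per-kilobase coverage stoichiometry,
soft-clip junction detection, and repeat-crossover quantification — together
with the models they rest on: exact repeat-pair discovery on a circle,
prediction of recombination products, and a ground-truthed simulator of
libraries containing substoichiometric recombination subgenomes (sublimons).

## Genome and repeat model

A genome is a circular string over {A,C,G,T,N}; every coordinate is
interpreted modulo its length, and all reported coordinates are 1-based
inclusive (internal arithmetic is 0-based half-open).  A repeat pair is two
non-overlapping intervals whose sequences are identical (direct) or reverse
complements (inverted), classed by length: large (>500 bp), intermediate
(50–500 bp), micro (<50 bp).  Large repeats support frequent reversible
recombination; intermediate-size repeats recombine rarely and asymmetrically,
which is the phenomenon the crossover assay quantifies.

`find_exact_repeats` reports **maximal** exact pairs (extendable in neither
direction) of at least `min_len` bases (floor 20, guarding against the
microhomology explosion).  Circularity is handled by indexing `min_len`-mers
of the doubled sequence and deduplicating modulo length; seed pairs are
extended with modular arithmetic.  Two boundary rules matter and are applied
identically by the implementation and by the independent brute-force oracle
used in tests (a numpy scan over all rotations and anti-diagonals):

* copies may be adjacent but never overlap (the repeat-pair invariant);
* a pair whose equality run would force the copies to overlap — a perfect
  tandem array of three or more periods, or a contiguous/overlapping
  palindrome — is not reported.  Such structures need an array model, not a
  pair model, and do not occur in the genomes this package targets.

Mismatch-tolerant ("degenerate") repeat families are out of scope; the
named organellar repeats are treated as exact for detection.

## Recombination products

For a direct pair with upstream flanks a (copy 1) and c (copy 2) and
downstream flanks b and d, a crossover between the copies excises the region
between them: one product circle is a repeat copy plus the segment from the
end of copy 1 to the start of copy 2 (its junction reads c–R–b, configuration
2/1), the other is a repeat copy plus the complementary segment (a–R–d,
configuration 1/2).  The circle lengths always sum to the parent length, and
concatenating the two circles reconstructs the parent up to rotation — both
are property-tested.  For an inverted pair the product is not a smaller
circle but the genome with the inter-copy segment reverse-complemented in
place ("flip-flop" isomerization); the operation is an involution.

## Read simulation

The simulator draws a paired-end library (defaults 2×150 bp, fragment length
normal(400, 50) truncated to [read length, 3×mean], substitution error rate
0.002, constant Q40 qualities) from a weighted mixture of molecules: the
master genome at weight 1 plus any combination of loop-out circles, remainder
circles, inversions (repeat-mediated or between explicit breakpoints) and
chimeric circles joining two breakpoints, each at a stated copy number per
master genome.  Fragments are assigned to molecules with probability
proportional to weight × length and start uniformly on each circle, so
`depth` is the mean per-base read coverage of the weighted mixture (equal to
master fold-coverage when nothing is planted).  The pair count is
`round(depth × Σ weight·length / (2 × read_length))`.  Reads carry a header
comment with their source molecule, fragment coordinates and strand, and a
`TruthSet` records the expected per-kb copy number (1 + Σ weights covering
the bin, partial bins pro-rated) and every planted junction.

The error model is substitution-only by design: the junction pipeline
discards indel-containing alignments, so indel simulation would exercise
nothing.  The generator does not emulate machine error profiles, GC bias,
optical duplicates, or nuclear insertions of organellar DNA (NUMTs) —
consequently, passing tests demonstrate correctness of the analysis logic
under idealized sequencing, not robustness to those real-data artifacts.

## Alignment

A deterministic seed-and-extend aligner keeps the pipeline self-contained on
genomes up to ~1 Mb: exact 31-mer seeds (shorter for short queries) are
looked up in an index of the doubled sequence, then extended ungapped in both
directions while the running mismatch rate stays ≤ 0.04; unextendable read
ends become soft clips (only M and S are ever emitted).  A placement needs an
aligned block of ≥ 30 bases; score is block length − 4×mismatches; score ties
mark the read non-unique and are resolved to the leftmost placement, or
uniformly with a seeded generator when coverage is being accumulated (the
analog of counting MAPQ-0 multi-mappers once at a random copy).  Positions
are reported modulo length, so origin-spanning placements are ordinary.

Because extension tolerates a running 4% mismatch rate, an anchor can slip a
few chance-matching bases past a chimeric junction before the cap bites;
breakpoints are therefore accurate to ±~4 bp, which the 1-kb binning of the
junction assay absorbs entirely.

SAM is written with @HD/@SQ headers, MAPQ 60 (unique) or 0 (tied), and read
back through pysam, so any external aligner's SAM can be substituted
bit-for-bit; uniqueness is then inferred from MAPQ > 0.

## Coverage stoichiometry

Aligned reference-consuming bases (M, D, N, =, X) are accumulated per 1-kb
bin; a position belongs to the bin labelled by its upper kilobase
(bin = ceil(pos/1000)) — the self-consistent reading of "rounded to the upper
kb" labelling; any consistent alternative shifts results by under one bin.
Bin depth is normalized to reads-per-million of the library.  The normalizer
is the total library read count by default; for simulated libraries, which
are purely organellar, sample/control comparisons instead use a common
nominal total (`normalize_total`), because the real assay's normalizer —
total genomic reads — is dominated by a nuclear background that organellar
amplification does not change.  Sample/control comparison uses per-bin
log2((s+ε)/(c+ε)) with ε the normalized depth of a single 150-bp read in one
bin, keeping empty bins finite.  Maximal sign-homogeneous runs of bins with
|log2| ≥ 1 (two-fold, configurable) become flagged regions; any repeat pair
with a copy boundary within one bin of a region boundary is attached as the
candidate mediator.  No significance testing or segmentation beyond threshold
runs is attempted.

## Junction detection

Mapped, uniquely anchored reads pass the clip filter iff their CIGAR contains
a soft clip of ≥ 20 nucleotides and no I, D or H operation; both clips of a
doubly clipped read are processed independently.  Each clip is remapped as an
independent segment that must align end-to-end within the mismatch cap;
partial placements are discarded, and clips with tied best placements (e.g.
repeat interiors) are dropped as non-unique, with drop counts reported.
Events are keyed by (anchor-breakpoint bin, clip junction-proximal-base bin,
relative strand) and supported by distinct reads (mates count separately).

**Detection envelope.**  A crossover junction across a repeat of length r is
clip-detectable only if a read can bridge the repeat plus the minimum anchor
and clip: r ≤ read_length − min_clip − min_anchor = 100 bp for 150-bp reads.
The 60-bp planted repeat is detected; the 249-bp one is invisible (its
junction-crossing reads align contiguously within one repeat context) — both
verified by test.  Coverage stoichiometry, which has no such limit, is the
complementary assay for longer repeats.

**Isomerization filtering and its degeneracy.**  In chloroplast-like genomes,
recombination between the two copies of the large inverted repeat merely
interconverts the two genome isomers and must not be reported as a
rearrangement.  The filter flags opposite-strand events whose two endpoints
both fall within one bin of the boundaries of one large inverted pair — a
deliberately broad rule (any boundary of either copy, not only the strictly
corresponding one), because repeat-copy ambiguity reflects event placements
between equivalent boundaries and the 1-kb resolution cannot distinguish
them.  A structural point documented here because it shapes what the filter
can see: the flip-flop isomer of a *large* inverted repeat is locally
sequence-identical to the master genome — every isomer read, including
boundary-spanning ones, aligns contiguously on one strand or the other, so a
correct aligner yields *no* soft-clipped reads from pure isomerization; and
for repeats short enough for reads to bridge, the clips fall inside the
repeat and are dropped as non-unique.  What the filter actually removes are
junctions *attributed* to the repeat boundaries — e.g. inversions breaking
just inside the single-copy regions, or placement artifacts of aligners that
split boundary reads.  The validation scenario therefore plants, alongside
the true flip-flop isomer (which correctly yields nothing), an
inverted-segment junction just inside the repeat boundaries: its events are
flagged and excluded, while junctions far from the repeat survive.

Event burden is summarized as junction-supporting reads per genome copy:
Σ support of retained events ÷ mean per-bin depth.  This operationalizes
"events per genome copy"; the normalization is isolated in a single function
so alternative readings can be swapped.

## Crossover quantification

The read-level analog of flanking-primer qPCR: a fragment is informative for
a direct pair iff one mate lies wholly inside an upstream flank (a or c) and
the other wholly inside a downstream flank (b or d), both uniquely and fully
aligned.  Flank identity gives the configuration (a→b = 1/1, c→d = 2/2,
a→d = 1/2, c→b = 2/1).  Flanks extend 2× read length (300 bp) from each copy
— with flanks equal to the read length, "wholly inside" would admit a single
fragment start position — and must not overlap any other repeat copy
(enforced).  Geometry requires fragments of at least r + 2×read length, so
for a 127-bp repeat with 400±50-bp fragments only the upper fragment-length
tail is informative; scenarios use deeper libraries (200–250×) for this assay.
Accumulation is reported per configuration as
log2(((x_s+½)/N_s)/((x_c+½)/N_c)) with N the informative-fragment count
(assay-local normalization, mirroring qPCR normalization to co-amplified
reference loci) and a Haldane ½ correction, since crossover products can be
wholly absent from the control.  The report is antisymmetric under swapping
sample and control.

## Validation scenarios and problem sizes

The seeded scenarios in `orgrearr.scenarios` fix the study conditions used by
the test suite and `scripts/acceptance.py`; sizes are desk-scale analogs of
organellar genomes chosen once:

| scenario | genome | planted | library |
|---|---|---|---|
| stoichiometry | 60 kb, 127-bp direct pair spanning 12 kb | loop-out at weight 7 (8× copy number) vs weight-0 control | 40× |
| junctions | 50 kb | three chimeric circles at weight 0.5; master-only control | 40×, error-free |
| isomerization | 60 kb, 2-kb inverted repeat | flip-flop isomer (w=1), near-boundary inversion (w=0.5), far inversion control (w=0.5) | 30×, error-free |
| crossover | 20 kb, 127-bp direct pair | loop-out only, weight 1 | 250× |
| demo pipeline | 100 kb, direct pairs 556/350/249/127/60 bp | loop-outs at weights 7 (127 bp) and 2 (60 bp), one chimera | 60× |

Scenario breakpoints are placed mid-bin so the ±4-bp anchor slip cannot move
an event across a bin boundary, and the amplified footprint of the
stoichiometry scenario is bin-aligned so its expected flagged-region mean is
exactly log2(8) = 3.

The monotonicity check of crossover accumulation uses four-fold-spaced
weights (0.5/2/8): at these library sizes the expected informative-fragment
counts for more closely spaced weights differ by less than Poisson noise, so
strict ordering would test the random number stream, not the method.

## Known limitations

* Exact repeats only; diverged repeat families are not detected.
* Ungapped alignment: reads over true indels soft-clip or go unmapped
  (harmless for the junction assay, which discards indel records anyway, but
  this aligner is not a general-purpose replacement for bwa/bowtie2 on real
  data — SAM ingestion exists for that).
* No nuclear-genome filtering: with real whole-genome libraries, nuclear
  copies of organellar DNA cross-map and should be removed upstream.
* Breakpoint resolution is the 1-kb bin; base-pair junction assembly and
  microhomology scoring are out of scope.
* Crossover quantification covers direct repeats; inverted-repeat crossovers
  have a different flank geometry and are not quantified.
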