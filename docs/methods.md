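# Methods

`mitescout` implements a complete desk-scale workflow for characterizing
miniature inverted-repeat transposable elements (MITEs): de novo structural
discovery, family clustering and superfamily classification, copy-number
estimation from assemblies and from read depth, genic-context statistics,
consensus-based insertion dating, neighbor-joining phylogenetics with
bootstrap, and in-silico insertion-polymorphism (MIP) genotyping. This note
records the models, the parameter choices that matter, and the numerical
decisions made where the design was genuinely open.

## The structural element model

A MITE is modeled as a short element (100–1,000 bp by default) bounded by a
terminal inverted repeat (TIR, ≥ 10 bp) and flanked by an exact target-site
duplication (TSD, 2–10 bp). The TSD arises mechanistically by duplication of
the insertion target, so it is required to be an exact direct repeat; the TIR
is allowed up to 10% internal mismatch (Hamming — no indels — and a reported
TIR always ends on a matching base pair). TSD length is the superfamily
signature: an 8 bp TSD marks the hAT superfamily; the remaining rules
(`TA` → Tc1/mariner, `TTA`/`TAA` → PIF/Harbinger, 9–11 bp → Mutator) are
editable defaults in the configuration, not assertions about any particular
genome. AT fraction is reported but never filtered on.

## Discovery

The structural scan seeds on exact 8-mer inverted-repeat matches at element-
compatible spacings, extends each seed pair outward base-exactly, and refines
the element boundary to the symmetric trim exposing the most credible TSD.
Two degeneracies make single-candidate boundary calls ambiguous and are
handled explicitly:

* a boundary shifted one base inward always retains the TSD interior as a
  shorter duplication, and a chance flank base extends the duplication past
  its true length one time in four per side;
* a boundary shifted symmetrically outward keeps the TIR register, gaining
  one chance "TIR" base pair per step with probability 1/4.

Final boundaries are therefore chosen by a joint score — TSD length plus
twice the exact TIR run — under which every systematic decoy exactly ties the
true boundary and the smaller-shift tie-break lands on the truth.

Structural candidates are clustered into families by single linkage, with an
edge when the best local alignment covers ≥ 80% of the shorter sequence at
≥ 80% identity. Local (not end-to-end) alignment is essential: a global
alignment free to gap aligns an LCS-like subsequence of two unrelated
same-composition sequences at deceptively high gap-excluded identity, while a
local alignment of unrelated sequences stays short and fails the coverage
bar. A shared-8-mer prefilter (at least 10% of the shorter sequence's 8-mers)
avoids aligning pairs that cannot clear the identity threshold.

TIRs erode with age, so the structural scan systematically misses older
copies. The full pipeline mirrors field practice (de novo discovery of
families, then a homology sweep for members): families with at least
`min_family_size` (3) structurally crisp members are retained — this size
filter, not a TSD filter, is what suppresses chance inverted repeats — and
the family consensus is swept across the genome for intact copies (≥ 80%
identity over ≥ 80% of the consensus, both strands, greedy non-overlapping).
The consensus is then refined over two further rounds: first rebuilt from
members extracted with 25 bp of flanking sequence (so that boundary
truncation inherited from the structural candidates cannot propagate — the
mutually unrelated flank pads vote down to junk that a subsequent trim to the
maximal exact TIR run removes), then rebuilt plainly from the boundary-
snapped members of the second sweep. In testing this converges on the exact
planted element for both a 25 bp-TIR and a 12 bp-TIR family.

Consensus building itself votes per column over a progressive multiple
alignment of the length-coherent core of the member set (members within 15%
of the median length; the longest member seeds the profile), dropping columns
carried by fewer than half the rows. Ties break in the fixed order
A < C < G < T.

## Alignment machinery

Pairwise dynamic programming (global, and local extension of exact-seed
clusters) uses affine gap scoring (match +2, mismatch −3, gap open −5, gap
extend −2; a gap of length L costs open + (L−1)·extend), values chosen to
behave like a megablast-style search on 80–100% identity hits. N and IUPAC
ambiguity codes never match anything, including themselves. `identity` is
computed over gap-free aligned columns; `coverage` is the aligned query span
over the query length, so a consensus searched against a genome is covered
relative to the consensus and a read mapped to a consensus relative to the
read. Seed lengths default to 12 for assembly search and 16 for read mapping
(sensitivity at 80% identity versus speed). Reverse-complement search runs
the seeded scan on both strands and reports minus-strand hits in forward
coordinates. The progressive multiple aligner adds sequences in descending
8-mer similarity to the first input, aligning each against the running
profile's majority consensus and projecting gaps into all rows; output rows
ungap exactly to the inputs.

## Copy number

Two estimators are deliberately kept distinct. Intact-copy counting applies
the ≥ 80% identity / ≥ 80% consensus-coverage rule to non-overlapping sweep
hits. Read-depth estimation maps each read to the consensus (best hit only)
and keeps it when identity exceeds 80% over more than 50% of the read length
— strict inequalities here, non-strict for intact copies, mirroring the
different conventions the two thresholds come from. Depth is averaged over
the central 80% of consensus positions because the termini systematically
under-recruit reads, then divided by haploid genome coverage (total read
bases / genome size) to give copies per haploid genome. Genome-specificity
tables report the fold difference between the highest-count genome and each
other genome, with an integer-floor display column.

## Genic context

Each element receives exactly one category with precedence exon > intron >
upstream/downstream (within a 2 kb window) > intergenic; upstream/downstream
are strand-aware relative to the transcription start/termination sites. The
full element interval decides overlap; the midpoint is used for TSS/TTS
distance binning (±5 kb window), each element contributing at most once per
anchor at its nearest TSS and nearest TTS. An element overlapping two genes
is classified against the larger overlap, ties preferring an exonic call.
Percentages round half away from zero, the convention that reproduces
printed contingency percentages such as 156/331 → 47%.

## Insertion dating

The repeat molecular clock: each copy accumulates substitutions after
insertion, so its Kimura 2-parameter distance k to the family consensus (a
proxy for the ancestral element) dates the insertion as T = k/(2r), with
r = 1.30 × 10⁻⁸ substitutions·site⁻¹·year⁻¹ by default (configurable). K2P
corrects transitions (P) and transversions (Q) separately:
k = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q). Sites with a gap or ambiguity in either
row are excluded pairwise — pairwise rather than complete deletion because
ragged MITE alignments would otherwise waste most sites. Distances outside
the formula's domain are flagged as saturated and excluded from histograms
(with the exclusion count reported), never capped, since capping would
silently distort the age distribution. Consensus construction for dating can
balance clade sizes: an equal-sized random sample per clade (seeded,
deterministic) avoids biasing the consensus toward the most numerous
subfamily.

## Phylogenetics

Neighbor joining uses the standard Q-criterion agglomeration with a
deterministic smallest-index tie-break; negative branch lengths are clamped
to zero with the deficit moved to the sister branch. On any additive matrix
the reconstruction reproduces the generating path metric to 10⁻⁹. Bootstrap
support resamples alignment columns (seeded), rebuilds the K2P matrix and NJ
tree per replicate, and reports the percentage of successful replicates
containing each internal bipartition of the full-data tree; a saturated
replicate is redrawn up to ten times, then skipped and counted. The default
of 1,000 replicates is configurable.

## In-silico MIP typing

A locus is the pair of 300 bp flanks around an element. Both flanks are
located in a target assembly (≥ 90% identity over ≥ 80% of the flank, unique
placement — a near-tied second hit makes the locus ambiguous, as a
multi-mapping primer pair would fail in the wet assay). With both flanks on
one sequence and strand, the gap between them is compared to the element
length: occupied within ±20%, empty at ≤ 50 bp (accommodating the retained
TSD), ambiguous otherwise. The ±20% and 50 bp windows are calibrated to
separate ~670 bp elements as a 2% agarose gel would, with coarse but
unambiguous resolution.

## The synthetic-data generator

The generator emulates the features the pipeline measures: i.i.d. background
DNA at a chosen GC (fixtures use 36%, a plant-nuclear-like composition),
non-overlapping gene models with 1–5 exons, and planted element families
with realistic geometries — the shipped defaults are 673 bp/25 bp TIR and
666 bp/12 bp TIR, both with 8 bp TSDs and 70–75% AT, the geometry of
high-copy plant hAT MITE families. Each copy draws an age T from a discrete
mixture (default: 10% new insertions, then a 1–3 Mya amplification burst),
converts it to divergence k = 2rT, and evolves the consensus under an exact
finite-time K2P process with transition rate twice each transversion rate
(a typical plant nuclear bias). Using exact transition probabilities rather
than a per-site Bernoulli at rate k means multiple hits are modeled and the
K2P estimator is consistent for the generated divergence; recovery tests are
therefore fair but not circular, since the estimator never sees the
generator's rate ratio. Insertion duplicates the target bases on both sides
of the copy and shifts every downstream coordinate, so gene models are
remapped and truth intervals are reported in final coordinates. The excision
operator inverts an insertion exactly (element plus one TSD copy removed),
reconstructing the empty allele for MIP round trips.

What the generator does not emulate: indel decay of old elements
(substitution-only evolution keeps TIR/TSD structure intact apart from point
mutations — the dating model is likewise substitution-only, but real old
elements also shrink), nested or tandem repeat structures, soft-masked or
ambiguous reference bases, sequencing-error profiles beyond i.i.d.
substitutions, and paired-end read structure. Passing tests therefore
demonstrate correctness of the algorithms under the structural model, not
performance on a real repeat landscape, where fragmented and nested copies
would reduce recall.

## Problem sizes and reproducibility

The shipped benchmarks use a 1 Mb genome with two families of 50 copies for
discovery, a 200 kb genome with 20 copies and 10× error-free reads for copy
number, cohorts of 100 × 670 bp elements per age point for clock recovery,
and 20 loci across two assemblies for MIP — sizes at which every published
contrast the package reproduces is measurable in minutes on one core. All
stochastic steps take seeds from the configuration (default 42); rerunning
any command with the same seed is byte-reproducible.

## Known limitations

* The discovery scan requires an exact 8-mer inverted-repeat seed; TIRs
  shorter than 8 bp or hyper-degenerate TIRs are invisible to the structural
  stage (though family members are still recovered by the homology sweep
  once any family member is found structurally).
* Single-linkage clustering can in principle chain two related families
  through intermediate copies; the local-alignment edge criterion makes this
  unlikely at the default 80/80 thresholds but does not forbid it.
* Read mapping is single-end, best-hit, quality-blind; copy-number estimates
  for families with close paralogous subfamilies will blur across them.
* E-value statistics are not implemented; the seeded search is thresholded
  on score, identity and coverage instead.
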