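# Methods

This note documents the models, conventions and numerical choices behind
`concerta`, in the order the pipeline applies them, together with the
design decisions that were genuinely open and the package's known
limitations.

## Coordinates and regions

Gene coordinates are 1-based and inclusive, with position 1 the first base
of the start codon, upstream positions negative, and **no position 0** —
the convention of promoter annotation in the genomics literature (a
promoter spanning −805..−1 is 805 bp).  Each `GeneRecord` stores the gene
coordinate of its first base, making coordinate ↔ string-offset conversion
an exact bijection; the CDS is the ordered concatenation of exon spans.
When a region file contains negative coordinates and no origin was set,
the sequence is assumed to begin at the 5'-most annotated position.

## Alignment

Coding sequences are aligned through their proteins and back-translated,
so frame is preserved by construction and degapping any row reproduces its
input CDS byte-for-byte (terminal stop codons, if present, are carried as
a final gap-padded codon column).  Pairwise alignment is global
Needleman–Wunsch with affine gaps (Gotoh), BLOSUM62, gap open 10, gap
extend 0.5; traceback ties are broken diagonal > up > left, so output is
deterministic.  More than two sequences are aligned progressively over a
UPGMA guide tree built from pairwise-alignment p-distances (adequate and
stable for the ≥90%-identical families this package targets; no iterative
refinement is attempted).  Profile–profile scores are mean substitution
scores over non-gap symbol pairs.  Nucleotide regions (promoters, introns,
3' ends) use match +1, mismatch −1, gap open 4, gap extend 0.5.  Whole
genes are aligned region by region and concatenated, which keeps dynamic
programming matrices small and prevents gaps from crossing annotated
boundaries.

**Percent identity** is computed over columns where both rows carry a
base; columns gapped in either row are excluded from numerator and
denominator (identity is then symmetric and a property of compared bases),
and N never matches anything.  Published identity figures rarely state
their denominator convention or aligner parameters, so comparisons to
printed tables carry a few tenths of a percentage point of convention
noise.

## Nei–Gojobori counting and the Z-test

Synonymous site counts use per-position renormalisation: at each codon
position the synonymous fraction is (synonymous single-base changes) /
(changes that do not create a stop codon), so every position contributes a
full site and S + N = 3 × codons compared.  Conventions for stop-adjacent
sites differ between published implementations; this one eliminates
mutations to termination codons from both numerator and denominator, which
can move fourth-decimal values relative to other software.  Difference
counts average the per-step synonymous/nonsynonymous labels over all
orderings of the differing positions (1, 2 or 6 pathways), excluding
pathways through stop codons; if every pathway is blocked, all pathways
are used with a logged warning.  Codon columns containing a gap, an
ambiguous base or a stop codon in either sequence of a pair are dropped
pairwise (the statistics are pairwise, so complete deletion across the
whole alignment would discard information for no benefit).

Distances are Jukes–Cantor corrected, d = −(3/4)·ln(1 − (4/3)p), defined
for p < 3/4; proportions at or beyond 3/4 raise a saturation error rather
than returning a number.  Standard errors come from B bootstrap
resamplings of codon columns (default B = 1000), resampled **jointly** for
the pair so that the variance of (dS − dN) respects the covariance of the
two distances; replicates that saturate are dropped with a warning.  The
purifying-selection test is one-tailed by default, Z = (dS − dN)/SE(dS −
dN) against the upper normal tail (H₁: dN < dS); a two-tailed variant is
available by flag.  Every result records B and the seed.

The windowed scan slides a window (default 60 codons, step 20) over the
pair's compared codons; windows with dS = 0 are flagged untestable rather
than reported as evidence.

Known limitation: unweighted site counting understates ω when transitions
are favoured (κ > 1), because transition-rich synonymous change inflates
dS relative to the counted synonymous sites.  The ω-recovery scenario
(`scenario_pair`) therefore generates without transition bias, validating
the estimator under its own assumptions; the family scenarios keep κ = 2
for realism, where the deep-pair ω estimates inherit a modest downward
bias (≈0.1 at ω = 1 in side experiments).  Transition/transversion-
weighted (modified) counting is deliberately out of scope.

## Gene-conversion scan

The alignment is condensed to polymorphic columns (≥2 distinct bases
across all sequences; columns containing any gap or N are dropped first,
since match/mismatch is undefined there).  With only two sequences every
variable column is a pairwise mismatch and the test degenerates; the scan
warns and proceeds.  For each pair, candidate fragments are maximal
scoring subsequences of the +1/−g match/mismatch vector over polymorphic
sites: with the default g = 0 these are maximal mismatch-free runs (score
= run length); with g > 0 the linear-time Ruzzo–Tompa algorithm returns
all maximal-scoring subsequences, allowing tracts to span the isolated
mismatches that accumulate after older conversion events.  A practical
guide: use g = 0 for recent, sharply bounded tracts, and g ≈ 2 when
converted pairs have measurable residual divergence (e.g. whole-gene
homogenisation followed by drift).

The null distribution jointly permutes the **order** of polymorphic
columns — site patterns stay intact across sequences, so base composition
and per-pair match densities are preserved exactly — and records, per
permutation, the best fragment score over *all* pairs.  The reported
`global_p = (1 + #{null ≥ score}) / (n_perm + 1)` is therefore family-wise
("BLAST-like" across the whole alignment); per-pair p-values are also
recorded but are not multiplicity-corrected.  Fragments at or below the
reporting threshold (default 0.05) are reported; multiple tracts per pair
are found by removing a reported fragment's sites and re-scanning that
pair against the same null until nothing significant remains.

Tract boundaries between informative sites are unidentifiable, so
fragment ends are extended halfway to the neighbouring polymorphic site
(rounded toward the fragment) and fully to the alignment ends for terminal
fragments; coordinates are then mapped into each gene's coordinate system.
Only within-alignment ("inner") fragments are sought; conversion with
sequences outside the alignment, donor direction, and unequal-crossover
breakpoints are out of scope — mechanism (conversion vs unequal crossover)
is reported as a note driven by declared genomic organisation (a tandem
head-to-tail flag), never inferred from sequence.

## Decision procedure

Orthology: each gene's 5' promoter (annotated region or, by default, the
1100 bp directly upstream of the start codon) is compared pairwise;
cross-species reciprocal best matches above an identity floor (default
50%) become orthologue pairs.  The floor is a declared convention — the
"no significant match" criterion in comparative studies is rarely
quantified — and reciprocal-best filtering does the real work.

Classification: concerted evolution is called when max(paralogue P_S) ≤
r × min(orthologue P_S).  The ratio threshold r = 0.5 encodes "much
lower"; observed ratios in clear concerted families sit near 0.2–0.3, so
0.5 is permissive without admitting purifying-selection-only patterns
(ratio ≈ 1).  Any contributing P_S at or above 0.4 — the lower edge of the
commonly cited 0.4–0.7 synonymous-saturation band — makes the verdict
`saturated_indeterminate`, since saturated synonymous distances cannot
support either reading.

Mosaic analysis: codon columns whose bases fall inside any significant
tract (global_p < 0.05 by default) for the pair are masked; surviving
codons form maximal contiguous segments, each tested separately plus one
pooled "combined" row (pooling codons, not averaging statistics — the
combined row is then a genuine estimate over the unconverted region).
Segments shorter than 10 codons are dropped: between adjacent tracts the
survivors are exactly the pair's own difference positions, which carry no
usable signal.  If no analysable segment remains the pair is flagged
whole-gene converted, the entire-gene homogenisation signal.

## Neighbour joining

Distances are amino-acid p-distances with pairwise deletion of gap
columns; p-distance (not Poisson/JTT) is the default because within-family
identities are high and the estimator is then essentially linear, exact
for topology on additive inputs, and fully deterministic.  Saitou–Nei
agglomeration breaks Q-matrix ties by the smallest (i, j) index pair;
negative branch lengths are clamped to zero with a warning (the standard
practical convention).  Bootstrap supports resample alignment columns with
replacement and report the percentage of replicate trees containing each
internal bipartition of the point-estimate tree.  Likelihood and Bayesian
inference are out of scope.

## Simulator

The generator produces exactly the structure the analyses assume: a gene
laid out as promoter (1100 bp) — exon1 — intron1 — exon2 — intron2 —
exon3 — 3' end (introns 70 bp, 3' end 200 bp; exons split ~50/147/rest
codons, in frame), evolving on an event script of duplications,
speciations and conversion events on a two-species tree.  Each nucleotide
site proposes substitutions as a Poisson process (rate μ per site per unit
time), targets drawn with transition bias κ (default 2); in coding
sequence a proposal is rejected if it creates a stop, accepted if
synonymous, and accepted with probability ω if nonsynonymous — ω is
therefore exactly the nonsynonymous relative fixation probability, and
the realized acceptance-rate ratio converges to it.  Neutral regions
accept everything.  Conversion events overwrite the recipient tract with
the donor's current sequence.  All draws flow through one seeded
generator; the event log, true tracts, true tree and realized counts are
returned as ground truth.

What it does **not** emulate: indels (alignment is exercised separately
with engineered gap fixtures), rate heterogeneity among sites, codon-usage
bias, recombination other than scripted conversion, and copy-number
change.  Passing tests therefore demonstrate the statistics behave
correctly under the model's assumptions — clean alignments, uniform rates
— not robustness to misalignment or rate variation in real data.

Calibration (measured once, in side experiments at divergences 0.05–0.25):
corrected synonymous divergence accrues at ≈0.91 per unit of μ × separation
time at κ = 2, and ≈0.94 at κ = 1.  The canned scenarios use these
constants.  `scenario_vtg` (the study family: ancient duplication at
t = 0, speciation 0.110 before the present, whole-gene conversion — tract
−101 to the 3' end, sparing the distal promoter — 0.028 before the
present, ω = 0.5, 1500 codons) yields paralogue P_S ≈ 0.05, orthologue
P_S ≈ 0.19, orthologue promoter identity ≈ 80% with paralogue promoters
near the noise floor, so promoter-based orthology and the P_S contrast
both resolve.  `scenario_conversion` places a 300-bp tract between
paralogues at 10% background divergence; `scenario_pair` produces a single
pair at a chosen expected dS (default 0.2).

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage child seeds from one master seed via `numpy.random.SeedSequence`,
so identical config + seed gives byte-identical outputs, single-threaded
by contract.  The test suite and the acceptance script run the simulator
at the scenario sizes above (1500-codon genes; 400–800 codons for the
replicated null/detection studies, 20 replicates for recovery and recall,
100 conversion-free families for false-positive control, B = 1000
bootstrap replicates and 1000 permutations) — sizes chosen so each
statistic's sampling error is small against the effects being measured.
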