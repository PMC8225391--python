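# Methods

## Motif model and scanning

A motif is a position probability matrix over A/C/G/T with a 0-order
background model.  The scoring matrix is log2-odds in bits; before taking
odds the probabilities are smoothed with a background-weighted pseudocount
(default 0.1): with a known site count *n* the smoothed probability is
`(p·n + c·bg)/(n + c)`, otherwise `(p + c·bg)/(1 + c)`.  The background
defaults to the motif file's background line (uniform when absent) and can
be replaced by the 0-order composition of the reference genome.

Match p-values are exact under the background model.  The matrix is
discretized onto an integer lattice of `granularity` bins (default 1000)
spanning the achievable score range; the per-position score distributions
are convolved under the background letter probabilities; and the tail sum
maps every achievable lattice score to `P(random word scores ≥ s)`.
Windows are scored *with the same discretized matrix*, which has two
consequences worth stating plainly:

* reported scores are lattice scores (discretization error below
  `width · range / granularity` bits, i.e. ~0.1 bits at the defaults), and
* score → p-value is exactly monotone, and the scanner agrees *exactly*
  with exhaustive enumeration over all `4^width` words (the unit and
  acceptance suites verify this for widths 3–6).

Both strands are scanned; the minus strand scores the reverse-complemented
matrix, whose score distribution under a strand-symmetric background is
identical, so one p-value table serves both strands (for a non-symmetric
background this is an approximation, as in standard scanners).  Windows
containing any non-ACGT letter are skipped entirely rather than scored
with a neutral letter, avoiding threshold-dependent artifacts at assembly
gaps.  Hits are ordered by start, then + before −.  The default match
threshold is p ≤ 1e-4.

## Gene models and compartments

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the boundary.  For multi-transcript genes the exon union
defines introns and the most 5′ transcript start defines the TSS —
maximizing the searched regulatory space consistently.  Non-coding genes
are ignored both as assignment anchors and as intergenic boundaries.

The upstream interval runs 5′ from the TSS to the nearer of the closest
protein-coding gene body and the configured maximum distance (`None` =
full intergenic stretch), clipped to the sequence.  Divergently
transcribed neighbors both receive the full shared interval, and a hit in
it is counted upstream of **both** genes — a shared promoter region can
plausibly serve both.  The downstream interval is defined symmetrically;
downstream and exonic assignments are annotated in the outputs but never
scored.  Within a gene body, a hit overlapping any exon base is exonic
(the more gene-proximal, conservative non-scoring label); intronic
assignment requires full containment in one intron, and upstream
assignment full containment in the upstream interval.

## Cross-species features

Each reference gene with at least one scoring (upstream or intronic) match
in at least one panel species becomes a candidate target gene.  Its
feature vector over an S-species panel has `6·S + 2` entries: per species
the upstream/intronic match counts and maximum and mean match scores
(zeros when the species has no ortholog or no matches — a deliberate dense
encoding that conflates the two), plus two conservation counts, the number
of species with ≥ 1 upstream (resp. intronic) match.  Features depend only
on counts and scores, never on match coordinates: conservation is
alignment-free.

## Ranking

Training pairs the validated targets with an equal-sized uniform draw
(without replacement) of other candidate genes.  There are no true
negatives — some "random" genes will be real targets — but the two samples
differ in their feature distributions, which is all the classifier needs.
Features are standardized with training-row statistics only.  The default
classifier is a Gaussian process with a constant × RBF kernel (unit
initial length-scale, optimized by marginal likelihood); logistic
regression and random forest are available for comparison.

Candidates are ranked by posterior probability of the target label.
Posteriors are rounded to 10 decimals before ranking so that tie structure
(and hence ranks) is invariant to row order and to batch-level float
noise; ties share the mean of their ranks.  The normalized rank maps rank
r in a G-row table to `1 + 99·(G − r)/(G − 1)` — 100 for the best
candidate, 1 for the worst, 100 for a single-row table.  With tied
extremes the tie group maps to its mean-rank value rather than the
endpoint, a direct consequence of the tie rule.

Cross-validation repeats (default 10×) the cycle: fresh negative draw,
shuffle, half/half split (odd row counts put the extra row in training),
train on each half and validate on the other.  Per fold it reports recall
of validation positives at a 0.5 posterior threshold and the rank-sums Z
comparing validation-positive against validation-negative posteriors
(rank-sums is invariant to monotone transforms, so using posteriors rather
than integer ranks changes nothing except tie handling).

## Battery statistics

*Enrichment*: hypergeometric upper tail `P(X ≥ n_with)` with population =
protein-coding genes in the reference annotation, successes = the
candidate set, draws = the battery.  *Rank*: two-sided Wilcoxon rank-sums
comparing the normalized ranks of motif-bearing battery genes against the
genome-wide candidate ranking, with a direction guard — significance for
classification additionally requires the battery median normalized rank to
exceed the genome median, so a significantly *worse*-ranked battery can
never be called coordinated.  A battery with no motif-bearing genes gets
rank p = 1 with a flag.

Benjamini–Hochberg correction (α = 0.05) is applied separately to the
enrichment family and to the rank family across all (motif, battery) pairs
in a run; the conservative separate-family reading keeps the two tests'
calibration independent.  Classification: coordinated ⇔ both adjusted
p < 0.05 (with direction); piecemeal ⇔ only the rank test passes; other
otherwise, with a diagnostic subcase column separating
"enriched-but-not-ranked" from "neither".

*Cofactors* (pairwise only; larger combinations are read off the pairwise
table): the joint count `|battery ∩ candidates₁ ∩ candidates₂|` is tested
against a hypergeometric null whose success count is
`K = round(N·p₁·p₂)` — nearest-integer rounding keeps the null mean
closest to the independence expectation.  `K = 0` with a positive
observation reports the smallest representable tail with a degeneracy
flag.  The jointly hit genes are rank-tested once per motif; joint rank
significance requires both.  BH families: co-enrichment p-values as one
family, the pooled per-motif rank p-values as another.  The three-way call
combines the co-tests with the two individual signature categories.

Two calibration facts, verified by simulation in the test suite:

* The enrichment and co-enrichment tests are discrete and exact, hence
  conservative: raw p-values are sub-uniform.  Uniformity is therefore
  verified on randomization-smoothed p-values
  (`P(X > obs) + U·P(X = obs)`, exactly Uniform(0,1) iff the test is
  exact) while reported p-values remain the conservative tails.
* The independence product `p₁·p₂` ignores gene-level covariates.  With
  heterogeneous region lengths, genes with longer regulatory regions are
  likelier candidates for *both* motifs, making the co-enrichment null
  mildly anti-conservative on real-like genomes.  This is inherent to the
  product-of-marginals expectation; the calibration fixtures therefore use
  homogeneous region lengths to isolate the test's own sampling null, and
  the caveat should be kept in mind when interpreting borderline
  co-enrichment calls.

## Synthetic worlds

The generator emulates the study design, not sequence evolution: every
species carries the same ordered orthologous gene set; gene structures are
re-drawn per species (1–3 exons of 100–300 bp, introns 60–200 bp,
intergenic stretches 300–800 bp, uniform); sequence is i.i.d. from the
background.  A configurable fraction of reference genes (default 2.5% of
2000 genes = 50) are true targets; each target's ortholog independently
receives one planted site per motif — upstream or in a random intron,
orientation randomized — with probability `conservation_prob` (default
0.9).  Site fidelity follows `signal_strength`: per column the consensus
letter with probability 0.95/0.85/0.70 (high/medium/low), otherwise a draw
from the column's off-consensus distribution.  The bundled demo motifs are
width-12 with 0.97-probability consensus columns, so at p ≤ 1e-4 the
scanner accepts up to two mismatches and recovers ~98% of high-fidelity
planted sites.

Planted sites never overlap each other or exon boundaries, and genes are
laid on the + strand by default (`strand_mode="random"` is available), so
every planted site maps unambiguously to its intended target gene —
divergent shared promoters would otherwise blur the truth labels.  Strand
handling of the scanner and assigner is exercised by randomized site
orientation and by dedicated fixtures instead.  Identical configurations
give byte-identical outputs.

What the generator does **not** model — phylogenetic correlation between
species, indels and alignment ambiguity, operons, non-coding genes,
GC/repeat structure, ortholog-map errors — bounds what passing tests show:
they validate the statistical machinery and its calibration under the
stated generative assumptions, not performance on real genome panels.

## Problem sizes and numerical choices

The test and acceptance fixtures use desk-scale versions of the study
design, chosen so every check runs on one CPU in minutes: the high-signal
recovery world is 8 species × 2000 genes with 50 planted targets
(conservation 0.9); null calibration pools 100 random batteries (sizes
100–250, spanning realistic battery sizes) from each of ten signal-free
worlds — 2 species × 4000 genes for the single-motif tests, and larger
16000-gene worlds for co-enrichment, where the realized joint-candidate
count must pin down the independence product tightly.  Under the null the
rank-test calibration is classifier-independent (battery members are a
uniform subset of a fixed ranking), so those fixtures use the fast
logistic classifier.  Scan thresholds are 1e-4 for signal runs and 1e-3
for null calibration, where a denser candidate set gives the discrete
tests a finer support.

Degenerate inputs are defined rather than left to chance: sequences
shorter than the motif scan to an empty hit list; an empty candidate table
ranks to an empty list and exits the CLI with a distinct "zero candidates"
status; a single-row table gets normalized rank 100; empty battery rank
lists give p = 1 with a flag; a zero-range score matrix yields p = 1
everywhere.  All randomness flows through explicit integer seeds.

## Known limitations

Beyond the generator's simplifications: zeros conflate "no ortholog" with
"no matches"; the SR-similarity curation filter consumes a precomputed
score table rather than computing domain similarity; motif matches are
counted per motif independently, so overlapping matches of two motifs are
not de-duplicated in the cofactor analysis; and the ranking model assumes
the validated-target feature distribution transfers to novel TFs' motifs.
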