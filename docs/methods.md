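# Methods

`mitoirg4` analyses organelle genomes for two co-occurring structural
features — G-quadruplex-forming sequence motifs (G4DNA) and a large
two-arm inverted repeat (IR) — and provides the statistics used to relate
them: compartment enrichment tests, exonic-DNA fractions, IR-vs-SC motif
densities, a phylogenetic paired t-test across species, and GC-skew
profiles. A synthetic-genome generator with complete ground truth stands in
for sequenced strains so that every stage of the pipeline is testable
end-to-end.

## G4 motif scanning (`g4scan`)

Per-base scores follow the run-based scheme: a G inside a run of k
consecutive G's scores +min(k, 4), a C in a run of k C's scores
−min(k, 4), and A/T/N score 0. A window of width `w` (default 25 nt) slides
with step 1; a window is a hit when |mean per-base score| ≥ `s`. The two
conventional parameter sets are strict (`s = 1.7`) and relaxed (`s = 1.2`).
Overlapping or adjacent same-sign hit windows merge into maximal regions; a
sign change terminates a region, because a G-rich and a C-rich tract are
distinct candidate quadruplexes (one per strand). The region score is the
signed mean of its peak window — stable under region extension and
consistent with the threshold's per-window semantics — with the first peak
kept on ties.

Overlap elimination: motifs are visited in priority order (descending
|score|, ties by smaller start) and a motif is dropped when its overlap
with any already-retained motif exceeds half its own length (strictly
greater than; an exactly-half overlap survives). The order is configurable
(`position` priority keeps earlier motifs instead); the choice changes
which representative of an overlapping cluster survives, not the cluster
count. Densities are motifs per kilobase.

Circular genomes are scanned linearly by default, matching scans of
linearized deposited records; `circular=True` in `ScanParams` wraps the
window `w − 1` bases past the origin, with run scoring computed in rotated
context so runs crossing the origin are exact.

## Inverted-repeat detection (`ir_detect`)

Finished genomes contain the IR as two near-identical inverted copies, so
detection is self-comparison: exact k-mer seeds (k = 21) between the
sequence and its reverse complement are grouped by anti-diagonal (an
ungapped inverted match keeps the sum of paired coordinates constant),
clustered, and extended outward base by base. Mismatches are absorbed while
the running identity of the arm stays at or above `min_identity` (default
0.99) and no mismatch streak exceeds 10; trailing mismatches are trimmed so
an arm always ends on a matching base. Ungapped extension suffices because
ongoing homologous recombination homogenises the two copies; indels between
arms are out of scope. Circular genomes are searched over all rotations by
doubling the sequence, with duplicate candidates collapsed modulo the
genome length. Among candidates the longest arm pair wins, then the highest
identity, then the smallest start; a palindrome spanning the whole genome
is rejected explicitly since the single-copy regions would be empty.

The depth-based detector reproduces the assembly-time signal instead: a
collapsed IR shows a two-fold coverage plateau. The track is normalised by
its median, smoothed with a 201-bp sliding median, and maximal runs with
normalised depth in [1.75, 2.5] and length ≥ 2 kb are reported. It serves
as an independent check on simulated depth; it is not the primary detector
for finished sequences.

Partition labels the four regions IR copy 1/copy 2, SC1, SC2. SC1 is the
single-copy region containing cox1 when annotation is available (the
convention the comparative literature uses), otherwise the longer region,
with the fallback logged. The border report lists the nearest flanking gene
on each side of all four IR/SC junctions and flags genes that partially
overlap an arm. Intervals use wrap notation (start in [0, L), end may
exceed L) so the four regions tile the circle exactly once:
2·arm + |SC1| + |SC2| = L is asserted in tests.

## Compartments and enrichment (`compartment_stats`)

The exon compartment is the union of exons of the conserved protein-coding
genes (cox1–3, nad1–6, nad4L, atp6, atp8, atp9, cob, rps3) plus the full
spans of the two rRNA subunits rns and rnl (large, functional transcripts);
nad4L's membership is configurable and on by default. tRNAs are not
exonic under this definition. Introns of those genes form the intron
compartment; everything else is intergenic. Base-level priority is
exon > intron > intergenic, so overlapping annotations cannot double-count
and the three compartments always tile the genome (asserted on every run).

Motifs are assigned to the compartment of their midpoint base — a
deterministic rule that is unbiased for short motifs straddling a boundary.
Expected counts are proportional to compartment length; the goodness-of-fit
test is Pearson's χ² without continuity correction, df = retained
compartments − 1, with a warning (not an automatic exact test) when any
expected count is below 5.

Exonic fractions are reported as percent of bases in one IR arm and in
SC1 ∪ SC2 that are exonic. IR motif density counts motifs with midpoint in
arm 1 only, divided by one arm length, so homogenised duplicates are not
double-counted; counting both copies (`ir_copies=2`) is a pure scale
convention that cannot change the direction of the IR-vs-SC comparison.

## Phylogenetic paired t-test (`phylo_stats`)

Per-species paired differences d = x − y are modelled as multivariate
normal with mean μ·1 and covariance σ²·V(λ), where V is the
Brownian-motion covariance of a rooted tree with branch lengths (entries =
shared root-to-MRCA path length) and Pagel's λ ∈ [0, 1] scales the
off-diagonals. λ is profiled by bounded 1-D maximisation of the likelihood
(tolerance 1e-8, boundary values checked); μ and σ² follow in closed form
by GLS. Trees without branch lengths are rejected unless Grafen heights are
requested explicitly. Nearly singular covariances (duplicate zero-length
tips) receive a 1e-10 jitter with a warning.

Point estimates are maximum likelihood. For inference, the plug-in Wald
test — t = μ̂/SE at λ = λ̂ — is badly anticonservative in small samples:
on 12-tip trees simulated with strong phylogenetic signal it rejects a true
null about three times too often, because λ̂ frequently collapses to 0 and
the resulting SE ignores the correlation actually present (hessian-based
and REML variants measured similarly inflated). The package therefore
reports, by default, the supremum over λ ∈ [0, 1] of the exact fixed-λ
GLS t-test p-value: for every fixed λ the t statistic (unbiased GLS
variance) is exactly Student-t under the null, so the supremum is a valid
p-value whatever the true λ, at the cost of conservatism when the true λ is
far from the extremes. The reported `t_stat` is the t at the λ attaining
that supremum, so `p == 2·T.sf(|t|, df)` always holds; the plug-in
construction remains available as `p_method="plugin"` for comparability
with the R implementation this test mirrors.

Degrees of freedom: n − 2 (one each for μ and λ). On a star tree the
off-diagonal covariances vanish, λ drops out of the likelihood, df = n − 1,
and the procedure collapses exactly — estimate, statistic and p — onto the
classical paired t-test. The df is overridable.

## GC skew (`gc_skew`)

Per-window skew is (G − C)/(G + C) on the forward strand — the sign
convention is stated because tools differ — over non-overlapping windows
(default 1 kb; step configurable). Windows with no G or C get skew 0 with a
warning. The cumulative curve is the running sum of window skews; its
global extrema (first occurrence on ties) are the classical candidates for
replication origin and terminus. Extrema are reported, not asserted to be
origins: in frequently rearranged genomes the signal is typically
inconclusive, and origin calling is explicitly a non-goal.

## Synthetic genomes (`synthetic_data`)

The generator emulates the structure the analysis assumes: circular
genomes of 40–250 kb; a planted two-arm IR (arm 2 the reverse complement
of arm 1, optionally with a controlled substitution rate); conserved genes
with exon/intron structure and the two rRNA subunits, with genes inside the
arm mirrored into the second copy (flipped strand) as in real finished
genomes; G-rich motif templates — default (GGGT)×7, validated at
construction to clear the strict threshold — planted at controlled per-kb
rates either per region (IR vs SC) or per compartment; Poisson depth tracks
with a two-fold plateau over arm 1 of a collapsed assembly (arm 2's
coordinates absent, as a collapsed assembly would show); and paired species
traits evolving on a pure-birth tree under Brownian motion with a
tree-structured paired difference.

Default study conditions: 150 kb genome, 35 kb arms, GC 0.35, motif
densities 1.0/kb inside the IR vs 0.4/kb outside, depth mean 100× — the
regime of mid-sized IR-bearing fungal mitochondrial genomes. The cohort
scripts draw genome sizes uniformly from 100–200 kb and arms from 20–50 kb.

Two generator choices make ground truth exact rather than approximate.
First, background sequence is i.i.d. at the requested GC content with G/C
runs capped at two bases, so the maximal background window mean is about
1.3 and strict-threshold hits can only come from planted templates; planted
motif counts are therefore exact, not approximate, and test assertions use
equality. Second, twelve forced-mismatch bases (A/T, chosen against the
inverted-pair base) flank each arm end: without them, chance matches in the
background extend a detected arm a few bases past the planted boundary with
high probability, and "exact recovery" would be ill-posed. With walls, the
planted arm end is the unique maximal extension endpoint. Planted
substitutions inside mismatched arms avoid mirrored motif copies so the
motif truth list stays exact.

One integer seed drives everything through NumPy's `SeedSequence`; repeated
calls with the same spec and seed are bit-identical. The pure-birth tree
generator completes the final exponential waiting interval after the n-th
speciation so terminal branches are strictly positive and the Brownian
covariance is positive definite.

What the generator does not emulate — and what passing tests therefore do
not show about real data: realistic intron/homing-endonuclease sequence,
tRNA genes, plasmid insertions, compositional heterogeneity along the
genome, G4 motifs of irregular run structure, read-level sequencing error,
or IR copies diverged by indels. Results on real genomes depend on
annotation quality (the conserved-gene alias table covers common naming
variants but not arbitrary ones) and on the deposited record's topology
flag.

## Problem sizes in the shipped checks

The test suite and acceptance script run cohorts of 9–20 genomes of
100–200 kb, 1,000-table χ² comparisons, 1,000 null replicates and 200
effect replicates for the phylogenetic test, and 100 random 2-kb sequences
for the scanner oracle — sizes chosen to exercise every code path at full
realism while keeping a complete run in the low minutes on one core.

## Known limitations

- The IR finder assumes exactly one dominant inverted duplication; nested
  or multiple IRs return only the best-scoring pair, and direct (tandem)
  repeats are out of scope.
- The sup-λ p-value is conservative at intermediate true λ (measured
  rejection well below nominal in that regime); power is traded for
  finite-sample validity.
- GenBank ingest maps multi-segment CDS locations to exons/introns but does
  not interpret trans-splicing or fuzzy coordinates.
- The χ² enrichment test is per-genome; no correction across species is
  applied (by design, matching the per-species reporting convention).
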