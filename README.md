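# mitoirg4

Analysis pipeline for two co-occurring structural features of organelle
(mitochondrial) genomes: **G-quadruplex-forming motifs (G4DNA)** and a
**large two-arm inverted repeat (IR)** — plus the statistics that relate
them. Some fungal mitochondrial genomes carry an inverted duplication
spanning up to half the molecule together with an unusually high density of
G4 motifs; because G4 structures promote double-stranded breaks and IRs
support recombination-mediated repair, where and how strongly the two
features co-occur is a question about genome stability and replication.
This package is for researchers who have assembled organelle genomes (or
want fully controlled synthetic ones) and need the detection and testing
machinery for that question.

## What it computes

- **G4 scanning** — run-based per-base scores (+min(k,4) per G in a k-run,
  mirrored negative for C), averaged over sliding windows of `w = 25` nt; a
  window is a hit when |mean| ≥ `s` (strict 1.7, relaxed 1.2). Same-sign
  hit windows merge into maximal regions; motifs overlapping a
  previously-kept motif by more than 50% of their length are eliminated.
  Densities are reported per kb.
- **IR detection** — seed-and-extend self-comparison of a finished
  sequence against its reverse complement (k-mer seeds on anti-diagonals,
  mismatch-tolerant ungapped extension, identity ≥ 0.99), plus an
  independent read-depth detector for the 2× coverage plateau a collapsed
  IR leaves in an assembly. The genome is partitioned into IR copies and
  single-copy regions SC1/SC2 (SC1 = the one containing *cox1*), with
  border-gene reports.
- **Compartment statistics** — exon/intron/intergenic partition (exons of
  the conserved genes *cox1–3, nad1–6, nad4L, atp6, atp8, atp9, cob, rps3*
  plus the rRNA subunits *rns*/*rnl*), observed-vs-expected motif counts
  with a χ² goodness-of-fit test, percent exonic DNA in IR vs SC, and
  IR-vs-SC motif densities.
- **Phylogenetic paired t-test** — per-species paired differences
  d = x − y modelled as MVN(μ·1, σ²·V(λ)) with Brownian tree covariance V
  and Pagel's λ; ML estimates with a finite-sample-valid p-value
  (supremum over λ of the exact fixed-λ GLS t-test; reduces exactly to the
  classical paired t-test on star trees).
- **GC skew** — per-window (G−C)/(G+C) and its cumulative curve, whose
  extrema are classical replication-origin candidates.
- **Synthetic genomes** — circular genomes with planted IR, genes, motif
  densities, depth tracks and tree-evolving paired traits, all with exact
  ground truth (see `docs/methods.md`).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
nine-species cohort (genomes 100–200 kb, IR arms 20–50 kb, planted motif
densities 1.0/kb inside the IR vs 0.4/kb outside) and write tables under
`results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_g4_and_ir.py
python analysis/03_enrichment.py
python analysis/04_phylo_test.py
python analysis/05_gc_skew.py
```

`02_g4_and_ir.py` prints:

```
IR recovered exactly in 9/9 species; density_IR > density_SC in 9/9
```

and its table (`results/g4_ir_summary.tsv`) shows, per species, that the
strict scan finds exactly the planted motifs and that single-arm IR
densities sit at the planted 1.0/kb against 0.4/kb outside, e.g.

```
species  motifs_strict  motifs_planted  ir_arm_bp  ir_exact  density_ir_per_kb  density_sc_per_kb
sp1      105            105             36496      True      0.986              0.397
sp2      117            117             44217      True      0.995              0.405
```

`04_phylo_test.py` then tests that IR-vs-SC difference across the related
species while accounting for their shared history:

```
mean IR-SC density difference 0.601/kb (lambda=0.00, t=69.71, df=7, p=3.29e-11)
```

i.e. the mean paired difference μ̂ ≈ 0.60 motifs/kb recovers the planted
0.6/kb gap, and the null of equal densities is firmly rejected.
`03_enrichment.py` reports the compartment χ² per species (planted
exon-free motif placement is detected as exon depletion in 9/9 species)
and the exonic percentages in IR vs SC.

For a single genome from the shell, the same steps are exposed as a CLI:

```sh
mitoirg4 simulate --seed 7 --out scratch/demo
mitoirg4 scan  --fasta scratch/demo/genome.fasta --threshold 1.7 --bed scratch/demo/g4.bed
mitoirg4 ir    --fasta scratch/demo/genome.fasta --gff scratch/demo/features.gff3
mitoirg4 skew  --fasta scratch/demo/genome.fasta --window 1000
```

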