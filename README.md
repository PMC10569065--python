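# mosaicscan

Detecting horizontally transferred allele blocks inside a bacterial gene
cluster, and quantifying the phenotypes that go with them.

Some loci are *mosaics*: their flanking genes follow the species phylogeny
while an internal segment was swapped between lineages by recombination, so
that segment carries a divergent, discrete allele pair. The motivating case
is the *app* oligopeptide-permease operon of the *Bacillus subtilis* group,
where an internal *appA*+*appB* block exists as two deeply diverged alleles
that differ measurably in how avidly they import signalling peptides.
`mosaicscan` provides, as a plain Python library:

1. **A sliding-window phylogenetic incongruence scan.** Windows of 500 bp
   every 50 bp across an aligned locus; a Jukes–Cantor + neighbor-joining
   tree per window; branch-length-aware comparison of window trees with the
   K tree score (find the scale factor `K* = Σ b_ref·b_comp / Σ b_comp²`
   over the union of bipartitions, score `√Σ (K*·b_comp − b_ref)²`);
   all-pairs window similarity matrix; contiguity-constrained segmentation;
   congruent / incongruent / mixed region calls against a reference
   (species) tree with breakpoint positions; hierarchical clustering of
   strains into alleles over the incongruent region.
2. **An erf dose-response model of peptide import.**
   `Y(c) = Emin + (Emax − Emin)·(1 + erf(log10(c/K)/n))/2`, with
   half-maximal concentration K, fitted by multi-start least squares; fold
   comparison of K between genotypes with log-scale error propagation, and
   the 10×-over-background ON-cell readout.
3. **Geometric fold-change statistics** for replicate efficiencies:
   `ratio = 10^(mean log10 a − mean log10 b)`, logarithmic standard error
   `√(s_a²/n_a + s_b²/n_b)`, geometric ±1 SE interval `ratio·10^(±SE)`, and
   a Welch t-test on the log10 values.
4. **A synthetic-data generator** producing every input with known ground
   truth: mosaic alignments evolved under Jukes–Cantor along discordant
   species/donor trees, noisy dose-response tables, and log-normal
   replicate efficiencies — so the whole pipeline is testable end to end.

## Worked example

`python examples/mosaic_scan.py` simulates a 24-strain, 5800 bp operon in
which a 2500 bp internal block (boundaries at 2800 and 5300 bp) follows a
two-allele donor tree 0.3 substitutions/site deep, then scans it:

```
segment calls (status by window vote):
  [    0,  2900)  congruent    flagged   0%  mean z   0.27
  [ 2450,  5650)  incongruent  flagged 100%  mean z  21.88
  [ 5200,  5800)  congruent    flagged   0%  mean z   4.84
breakpoints (bp): [2675, 5425]
```

The scan recovers a single incongruent region whose breakpoints land within
125 bp of the true recombination boundaries, and splits the 24 strains into
two allele clusters that match the simulated partition exactly. The other
examples (`dose_response_fit.py`, `sporulation_fold_change.py`,
`export_files.py`) fit the import curves for two permease alleles and
recover their ~5-fold K ratio, estimate a 30-fold sporulation-efficiency
change with its geometric error interval, and demonstrate the plain-text
file interfaces (aligned FASTA, Newick, TSV).

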