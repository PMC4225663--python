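# biasdiag

Diagnostics for systematic bias in phylogenomic supermatrices: did a
clade emerge because of genuine signal, or because of compositional
artifacts and structured missing data?

Given a concatenated amino-acid supermatrix and a fixed (rooted or
outgroup-rootable) tree, the package provides:

- **Parsimony apomorphy mapping** — Fitch/Hartigan minimum-change
  counting and an ACCTRAN-resolved ancestral-state reconstruction on
  the fixed topology; extraction of the alignment columns whose state
  changes on a focal clade's stem branch, and their positional
  distribution along the alignment (with a KS uniformity diagnostic).
- **Node-based compositional chi-square test** — does the reconstructed
  ancestral sequence of a clade deviate in amino-acid composition, at
  that clade's apomorphy columns, from the pooled composition of all
  sequences in the subset (terminals plus the two reconstructed
  ancestral rows)?  A significant focal node paired with a
  non-significant deeper ancestor flags a composition-driven grouping.
- **Compositional ordination** — pairwise compositional distances
  (half the sum of squared residue-count differences) and non-metric
  multidimensional scaling (SMACOF with isotonic regression, Kruskal
  stress-1, multiple seeded restarts).
- **Missing-data analytics** — coverage accounting, the inclusive
  >=50%-taxon-coverage position filter, the gene admission rule
  (>=100 columns, >=25 taxa), shared-missing overlap matrices with
  UPGMA clustering and heat maps, and binary presence/absence parsimony
  mapping of missingness onto the tree.
- **Synthetic benchmarks** — Yule trees, nonstationary F81-style
  sequence simulation with a planted clade-specific frequency shift
  (parameterized by total-variation distance), gene-block dropout
  missingness, and machine-readable truth records, so every diagnostic
  has a recovery test without external downloads.

## Command line

```sh
biasdiag simulate --preset planted_shift --seed 7 --outdir bench/
biasdiag coverage --aln bench/alignment.fasta
biasdiag filter --aln bench/alignment.fasta --min-frac 0.5 --out reduced.fasta
biasdiag overlap --aln bench/alignment.fasta --heatmap overlap.png
biasdiag missing-tree --aln bench/alignment.fasta --tree bench/tree.nwk --out annotated.nwk
biasdiag clades --tree bench/tree.nwk --tips t001,t002,t003
biasdiag apomorphies --aln bench/alignment.fasta --tree bench/tree.nwk \
    --clade-tips t001,t002,t003 --out apomorphies.tsv --plot apomorphies.png
biasdiag comp-test --aln bench/alignment.fasta --tree bench/tree.nwk \
    --clade-tips t001,t002,t003 --json-out report.json
biasdiag nmds --aln bench/alignment.fasta --seed 1 --out coords.tsv --plot nmds.png
biasdiag convert --aln bench/alignment.fasta --out bench/alignment.phy --out-format phylip
```

Alignments are read in FASTA, relaxed PHYLIP, or NEXUS; `-`, `?` and
`X` (and the ambiguity codes B/Z/J/U/O, with a warning) are treated as
missing.  Trees are Newick, optionally with support labels and branch
lengths; use `--outgroup a,b` on commands that need a rooted tree.

## Notes on conventions

- The chi-square test follows the TREE-PUZZLE convention: each sequence
  is tested against the pooled composition of the whole subset (itself
  included) with df fixed at 19; states with zero expectation are
  dropped from the sum.  P-values are raw (no multiple-testing
  correction) and printed as percentages in CLI output.
- ACCTRAN ambiguity that survives the accelerated-transformation
  criterion is resolved by a deterministic seeded draw in the
  node-based test pipeline (`tie_break="random"`); a fixed alphabetical
  order is available but couples tie resolution to residue identity and
  measurably biases the composition test.
- Column indices in all reports are 1-based; gene boundary files are
  half-open 0-based.
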