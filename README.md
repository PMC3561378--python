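# chromexpr

Does the 3D folding of a genome line up with which genes are expressed
together?  `chromexpr` is a Python library for answering that question at
single-gene resolution in small eukaryotic genomes (budding yeast being the
motivating case): it integrates genome-wide chromosome-conformation-capture
contact data (4C/Hi-C fragment-pair counts) with a large gene-expression
compendium and quantifies whether spatially linked genes are co-expressed
and whether functionally related gene sets are enriched in mutual contacts.

## What it computes

Given a contact list (`chrom_a pos_a chrom_b pos_b count`), a GFF3 gene
annotation with chromosome lengths and centromeres, a genes × samples
expression matrix, and a flat GO-slim-style gene-set collection:

1. **Contact → gene mapping.** A gene is assigned to a contact locus if it
   lies within an offset *d* (default 500 bp) of the locus, measured to the
   gene boundary or, optionally, its 5′ end.  Every gene at one end is
   paired with every gene at the other end; only inter-chromosomal (trans)
   pairs are kept, excluding *cis* sequence-proximity effects.  Repeated
   support collapses to one link with frequency `max` (default) or `sum`
   of the supporting count frequencies *f*.
2. **Linked vs background co-expression.**  Expression is sample-mean
   normalized; co-expression of a pair (*g₁*, *g₂*) is the Pearson
   correlation *r* of their profiles.  The statistic is
   E[r | linked] − E[r | all trans pairs], with a two-sample
   Kolmogorov–Smirnov test, plus the curve of E[r | f ≥ f₀] against the
   count threshold f₀, an assignment-offset sweep, a 5′-anchored window
   profile, chromosome-pair link-density regression (one-tailed *t* on
   *r*·√((n−2)/(1−r²))), expression-rank link-enrichment bins,
   centromere–telomere arm-position bins, and a pair-exclusion sensitivity
   analysis.
3. **Matrix normalization.**  The contact map as a symmetric locus matrix,
   normalized three ways — linear (M<sub>ij</sub>/(Σ<sub>i</sub>·Σ<sub>j</sub>)), Euclidean
   (row/column 2-norms), and SCN (iterative column/row unit-norm
   scaling to a fixed point) — with top-N strongest-link selection to show
   the co-expression signal is normalization-robust.
4. **Monte-Carlo gene-set enrichment.**  For each gene set, the number of
   links joining two members, compared with size-matched random gene
   groups: ratio observed/expected, Z-score, and a calibrated empirical
   p-value.
5. **Contact networks.**  Per gene set, the undirected link graph
   (isolated genes included) with edges-per-node, component structure, and
   deterministic edge-list/DOT export.
6. **Resampling significance.**  A random-link null ensemble (spread of
   the genome-wide mean at the observed link count) and a without-
   replacement 50% bootstrap of the measured links.
7. **Synthetic data.**  A generator that plants all of the above —
   co-expression modules with a target latent correlation, module-biased
   contacts with truncated-Poisson counts (optionally count-stratified by
   correlation strength), restriction-site loci, dubious (contact-depleted)
   genes, and enriched/null gene sets — with exported ground truth, so the
   entire pipeline is testable without external data.

## Worked example

```bash
python examples/02_linked_coexpression.py
```

```
mean correlation, linked pairs:      0.2969  (n=168)
mean correlation, all trans pairs:   -0.0021  (n=112500)
KS statistic 0.975, p = 3.63e-270

count-frequency threshold curve (f=0 is the genome-wide background):
 min_count  mean_correlation  n_pairs
         0         -0.002076   112500
         1          0.296926      168
         5          0.298666      162
        10          0.297708       86
```

The generator planted contacts only on gene pairs sharing a latent factor
with pairwise correlation 0.3; the pipeline maps the contacts back to gene
links and recovers a mean linked correlation of 0.297 against a genome-wide
trans background of ≈0, with a decisive KS separation — the full
detection chain working end to end.  The other `examples/` scripts walk
through mapping, normalization robustness, gene-set enrichment, contact
networks, and resampling significance the same way.

The same analyses are scriptable from a shell:

```bash
chromexpr --seed 1 --out-dir out simulate --out data
chromexpr --seed 1 --out-dir out map    --contacts data/contacts.tsv \
    --gff3 data/genes.gff3 --chrom-sizes data/chrom_sizes.tsv
chromexpr --seed 1 --out-dir out coexpr --links out/links.tsv \
    --expr data/expression.tsv --gff3 data/genes.gff3 \
    --chrom-sizes data/chrom_sizes.tsv
```

Each stage writes TSV outputs plus a JSON manifest recording the
configuration, seed, and input checksums.

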