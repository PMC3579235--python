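# sagescape

Digital gene expression (SuperSAGE) analysis for ecological
transcriptomics: from raw 26-bp tag reads to permutational multivariate
statistics, negative-binomial exact-test differential expression and
GO-term enrichment — plus a synthetic-study generator that emulates the
full experimental design so every stage can be exercised and tested
without any external data.

## The problem

SuperSAGE quantifies transcripts by counting short sequence tags: the
type-III restriction enzyme EcoP15I releases a 26-bp tag anchored at the
3'-most NlaIII site (`CATG`) of each transcript, so each gene contributes
one (or, with splice variants, a few) distinct tags and expression is
measured by tag counts rather than hybridization intensity or
length-normalized read coverage.  The package targets the kind of study
this protocol was built for: 24 head-kidney libraries from lake and
river three-spined stickleback ecotypes (2 populations x 2 families x 3
parasite-exposure treatments x 2 sexes), asking whether the two
populations mount different transcriptome-wide immune responses.

## What the pipeline does

1. **Tag processing** — each read is `8-bp random barcode + 26-bp tag`.
   PCR duplicates are removed by the barcode ("TrueQuant", functionally a
   UMI scheme): a tag's count is the number of *distinct* barcodes seen
   with it.  One-off neighbours of highly abundant tags are absorbed as
   likely sequencing artifacts, tags with non-ACGT bases are dropped, and
   a tag must occur in ≥ 7 of the 24 libraries to be retained (this
   removes family-private alleles and powerless singletons).
2. **Reference consensus** — cDNA reads from the study fish are aligned
   (ungapped) to backbone transcripts and well-supported SNPs are
   rewritten as IUPAC ambiguity codes, so that both alleles of a
   polymorphic tag pay the same one-mismatch cost.
3. **Mapping and counting** — a tag scores a gene if it matches the
   forward strand of one of its transcripts with ≤ 1 mismatch, uniquely
   across genes (splice variants collapse).  Counts are normalized to
   1 000 000 tags per library (CPM).
4. **Multivariate statistics** — Pearson correlation distance
   (d = 1 − r) between libraries; PerMANOVA (sequential sums of squares
   from the Gower-centered distance matrix; terms treatment, population,
   family-within-population, sex; free permutations, default 999) and
   nonmetric MDS (Kruskal stress-1) for ordination.
5. **Differential expression** — conditional-likelihood NB dispersion
   estimation, exact conditional test per gene between treatment groups
   within each population, Benjamini–Hochberg FDR, Fig-2-style
   classification into population-specific / shared up- and
   down-regulated sets, and a 2x2 chi-squared contrast of the up/down
   pattern between populations.
6. **Enrichment** — true-path propagation of GO annotations, per-term
   one-sided hypergeometric (Fisher) over-representation of up-regulated
   sets (terms with < 5 annotated genes excluded), and second-order GO
   profiles (proportion of a gene set under each child of the ontology
   root).

The model behind the count stages is NB(μ, φ) with Var = μ + φμ²; at
φ = 0 the exact test reduces to the exact binomial test, and the
PerMANOVA pseudo-F reduces to the classical ANOVA F for Euclidean
distances with one factor — both identities are enforced in the test
suite against independent oracles.

## Worked example

```sh
sagescape demo --seed 1 --out-dir demo_out
```

simulates the 24-library study (300 genes, immune gene set up-regulated
4-fold in exposed lake fish, a second set down-regulated in exposed
river fish), writes every stage's TSV outputs plus a run manifest to
`demo_out/`, and prints:

```
demo complete; outputs in demo_out
NMDS stress: 0.220
chi-squared control_to_once: chi2=21.1 p=4.28e-06
```

The NMDS stress is the two-dimensional stress-1 of the ordination of the
24 libraries.  The chi-squared line is the contrast of up- versus
down-regulated counts among population-specific genes for the
control → once-exposed transition: the simulated antagonistic regulation
(lake up, river down) is recovered as a strongly significant 2x2
association.  `demo_out/permanova_overall.tsv` holds the Table-2-style
term tests (F, df, permutation P), `de_*.tsv` the per-gene DE tables,
and `enrichment_lake_up_control_to_once.tsv` shows the immune term
(GO:0002376) strongly over-represented in the lake-only-up set.

Every stage is also available as a library call (see the module
docstrings under `src/sagescape/`) and as individual subcommands
(`simulate`, `extract`, `filter`, `stats-permanova`, `stats-nmds`, `de`,
`enrich`, `run-all`).

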