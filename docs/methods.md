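# Methods

This note records the models, algorithmic choices and limitations behind
each stage, in the spirit of a statistical software manual: what is
computed, under which assumptions, and which decisions were genuinely
open.

## Count model

Tag counts for gene *g* in library *i* are modelled as negative binomial,
NB(μ_gi, φ), parameterized by mean and dispersion with
Var = μ + φμ².  φ = 0 is the Poisson limit.  The synthetic generator,
the dispersion estimator and the exact test all share this
parameterization, so parameter-recovery tests are meaningful end to end.
The real tag-count dispersion of the emulated study is not published;
the generator default (φ = 0.2) is a typical bulk-expression value for
outbred vertebrate samples and is config-exposed, not asserted as the
study's value.

## Synthetic study generator

The generator emulates the design, not the biology: 24 libraries =
2 populations x 2 families x 3 treatments (control / once exposed /
twice exposed) x 2 sexes, one male and one female per cell.  Effects are
multiplicative fold changes applied to designated gene sets in chosen
(population, treatment) cells; an effect tied to the control→once
transition persists in twice-exposed fish so it does not masquerade as a
reversal on the second transition.  The default demo scenario places a
4-fold up-regulation on an immune-annotated gene set in exposed lake
fish and a 4-fold down-regulation on a second set in exposed river fish,
reproducing the antagonistic up/down pattern the pipeline's 2x2
chi-squared contrast is designed to detect.

Transcripts are random sequences with a single planted `CATG` anchor
~30 bp from the 3' end and splice variants sharing their 3' region, so
each gene has one well-defined tag; a configurable fraction of genes
carries no anchor anywhere and is undetectable by design (these genes
receive expression but produce no reads).  Reads are
`barcode (8 nt) + tag (26 nt)`; the tag includes the 4-base anchor plus
the following 22 bases, taken at the 3'-most `CATG` (the SAGE
convention).  PCR duplication replicates (barcode, tag) pairs with
geometric copy numbers; substitution errors are applied per base after
duplication.  No adapters, no quality-score model, no indels — the
emulation covers exactly what the extraction and deduplication stages
consume, so passing tests demonstrate correctness of the counting logic,
not robustness to real base-calling noise.

The returned ground truth is the *realized* number of distinct barcodes
per tag.  Two molecules of one tag can draw the same 8-mer barcode
(birthday collisions); the deduplicated count then undercounts molecules
— exactly as the real barcoding protocol does — and the ground truth
records the collided value so the round-trip identity is exact.

The toy ontology is a single-root DAG whose second level includes an
immune-system term (GO:0002376) with innate (GO:0045087) and adaptive
(GO:0002250) children plus generic metabolic/cellular/stimulus/
developmental branches; extra terms attach below at random (acyclic by
construction, occasional double parents to exercise DAG closure).

## Reference consensus

The cDNA aligner is deliberately minimal: seeded by shared k-mers
(k = 12 default), ungapped, best (transcript, offset) by seed count then
identity.  Reads under the identity floor (0.9 default) or tying across
genes are discarded; ties among one gene's transcripts go to the longest
transcript.  Ungapped alignment suffices because the consumer is a
26-bp substitution-tolerant tag matcher; indel realignment would add
complexity without changing tag-level behaviour at this scale.
Consensus calling rewrites a position as the IUPAC code covering the
backbone base and every alternative base with count ≥ 2 and frequency
≥ 0.2 (both config-exposed; the thresholds that produced the original
study's consensus bases are not published).

## Tag matching

A tag scores a transcript at the minimum substitution distance over all
forward-strand offsets; hits with ≤ 1 mismatch (the literal reading of
"fewer than two") are collected, splice variants collapse to genes, and
multi-gene hits are ambiguous (excluded from counting, fraction logged).
Reference IUPAC codes cost one mismatch for **every** tag base — even
bases the code covers.  This mirrors treating ambiguity codes as unknown
Ns: both alleles of a polymorphic site have the same mismatch count and
the same likelihood of scoring the gene, which is the property that
matters; IUPAC-aware matching would instead favour the allele matching
the code.  Matching uses a pigeonhole index (tag split into
max_mismatch + 1 chunks; any window within budget matches one chunk
exactly), verified in tests to be identical to the exhaustive scan.

Normalization is counts-per-million over *assigned* tags: each library
column is scaled to exactly 1 000 000.  Whether the original totals were
taken pre- or post-assignment is unstated; assigned totals are the
self-consistent choice for a matrix of assigned counts.

## PerMANOVA

Squared distances are Gower-centered (G = −½ J D² J); sequential
(Type I) sums of squares are read off as tr((H_k − H_{k−1}) G) with hat
matrices of the cumulative dummy-coded design in the order given
(treatment, population, family, sex for the full model).  Family labels
are unique within populations, so plain dummy coding after the
population term yields the nested degrees of freedom (2 for family,
giving the 2/17, 1/17, 2/17, 1/17 pattern on the full 24-library design
and 1/3, 2/3, 1/3 within a treatment group of 8).  P-values use free
permutation of library labels with the add-one correction,
P = (#{F* ≥ F} + 1)/(n_perm + 1); restricted/strata permutation is out
of scope.  The distance is d = 1 − r (not halved, not absolute);
a `halved` variant would simply rescale all SS and leave F and P
unchanged, so no flag is provided.

Degenerate designs are rejected: a term adding no rank (confounded) or a
saturated model (no residual df) raises with the term named.

## NMDS

Kruskal stress-1 with primary tie handling, minimized by SMACOF with
isotonic regression (scikit-learn's nonmetric `smacof`), multi-started
from a classical-scaling configuration plus random starts (20 by
default); the best configuration is returned and the run is fully
seeded.  With a perfect low-dimensional embedding the classical start
already reaches stress ≈ 0.

## Differential expression

Library sizes are equalized exactly (rescaled to the mean total and
rounded) rather than quantile-adjusted — upstream normalization already
fixes relative totals, so the quantile machinery of the package family
this engine follows would be a no-op up to rounding.  Dispersion is
estimated by conditional maximum likelihood on the equalized counts
within groups (the design's population x treatment cells): the common
value maximizes the genes-summed conditional log-likelihood (grid plus
bounded refinement); tagwise values maximize each gene's likelihood plus
`shrinkage_weight` times the genes-average likelihood, recovering the
common value as the weight grows.

The exact test conditions on a gene's combined total z: the group-A
total under the null follows a Polya-type conditional law (sums of iid
NB are NB; the success probability cancels), and the two-sided p sums
the probabilities of all outcomes no more likely than the observed one
(a doubled-smaller-tail mode is available).  φ = 0 reduces exactly to
the binomial test.  Log2 fold changes are moderated with a 0.125
pseudo-count per library.  Zero-total genes are defined, not errors:
p = 1, log2FC = 0.

Caveat: with strongly asymmetric regulation (many genes changed in one
direction only), total-count equalization absorbs part of the fold
change into the library sizes — an inherent property of total-count
normalization, which the study design shares.  The power harness
therefore simulates composition-balanced effects when measuring
per-gene detection power.

The Fig-2-style classification marks a gene population-specific when it
is significant (BH-FDR < α, default 0.05) in exactly one population and
not significant in the other, and shared when significant in the same
direction in both.  The up/down contrast between populations is the
Pearson chi-squared on the 2x2 table of population-specific counts
without continuity correction.  The Mann–Whitney U companion (parasite
loads) uses exact enumeration for pooled n ≤ 12 without ties and the
tie-corrected normal approximation otherwise.

## Enrichment

Annotations are closed upward before testing (true-path rule).  The
universe is the set of annotated genes; per term, the one-sided
upper-tail hypergeometric p is computed for the observed overlap, and
terms with fewer than 5 annotated universe genes (counted after
propagation) are omitted entirely.  This is the classic per-term Fisher
test; elim/weight-style DAG decorrelation is deliberately out of scope.
Raw p-values are primary (mirroring how such tables are reported), with
a BH column alongside.  Second-order profiles report, for each direct
child of the root, the proportion of a gene set annotated under it via
closure; proportions may sum to more than 1.

## Pipeline and problem sizes

The orchestrated run synthesizes (or loads) inputs, executes all stages,
writes TSVs per stage plus a JSON manifest of parameters, input hashes
and per-stage record counts, and is deterministic given the config.
Defaults for the synthetic demo — 300 genes, mean length 400, baseline
mean 20 tags/gene/library, φ = 0.2, 30-gene immune and river-down sets
at |log2FC| = 2 — keep a laptop-scale single-CPU run around a quarter of
a minute while leaving all effects comfortably detectable; the
calibration and recovery test harnesses use 200 null datasets for the
permutation test and 20 seeds x 2000 genes for the exact test, sizes at
which the binomial check bands are a few parts per thousand wide.

## Known limitations

- Barcode collisions undercount high-abundance tags (no collision
  correction, as in the real protocol).
- The artifact absorber is a transparent Hamming-1 count-ratio rule
  (threshold 100x, config-exposed); the originally cited reduction
  method's parameters are not public, so equivalence is not claimed.
- Reverse-strand (antisense) tag hits are never counted ("correct
  orientation" is read as sense only).
- No TMM or other composition-robust normalization; no GLM/QL framework;
  no trended dispersion.
- The filter order (N-filter, per-library artifact reduction, then the
  ≥ 7-library occurrence filter) is a documented choice; the original
  order is unstated.
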