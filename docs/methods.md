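# Methods

## Problem and model

`moipred` classifies nonsynonymous single-nucleotide variants (nsSNVs) into
three classes — benign, dominant (disease-causing in one copy) and
recessive (disease-causing only in two copies) — using a random forest over
a fixed catalogue of annotation features.  The three class probabilities
are reported per variant and sum to one; pathogenicity is derived from the
class call.  The package contains the full training, evaluation and
feature-importance protocol plus a synthetic-data generator, so every claim
the test suite makes is computable offline.

## Annotation features

The default catalogue has 79 features in six families (the count is
configurable through `AnnotationConfig`: population tags, ethnicity tags,
tissue count and extra numeric columns):

* **Evolutionary** — per-site conservation score and constrained-element
  membership; gene-level dN/dS against two outgroups (dimensionless ratios,
  ≥ 0; values ≪ 1 indicate purifying selection).
* **Allele frequency / constraint** — per-dataset and per-population
  alternate-allele frequencies in [0, 1]; the gene-level pLI score in
  [0, 1] (probability of loss-of-function intolerance, a haploinsufficiency
  proxy).
* **Functional** — flags for protein domains (PFAM/SMART/SCOP-style,
  signal peptide, transmembrane), six post-translational-modification
  types, disordered regions, validated miRNA binding sites, and a numeric
  splice score consumed from a per-site table.
* **Network** — unweighted shortest-path distance in a protein-interaction
  graph to the nearest known dominant and recessive disease gene (0 if the
  gene itself is listed; missing when unreachable or absent — a distance is
  never invented); centralities in metabolic/genetic/signaling networks;
  mean expression in 25 tissues and its Shannon entropy.
* **Gene/transcript** — coding length, longest-isoform flag, whether the
  variant hits all (full) or only some (partial) isoforms, segmental
  duplication / pseudogene / paralog flags.
* **Polymorphism summaries** — synonymous and nonsynonymous SNP density
  (count / coding length), mean conservation of each SNP class, percent of
  each class inside constrained elements, percent of the CDS covered by
  constrained elements, and per-ethnicity average heterozygosity.

Average heterozygosity uses the kernel 2pq (p = minor, q = reference allele
frequency); the per-transcript statistic is Σ 2pᵢqᵢ / l over the SNP list
with l the coding length, which makes it additive over disjoint SNP sets
and comparable across transcripts.  Tissue-specificity entropy normalizes
the expression vector to proportions and returns −Σ p_t log₂ p_t (bits);
base 2 is a convention that affects scale, not ranking.  An all-zero
expression vector has no defined distribution and is reported missing.

Consequence calling translates the affected codon with the standard codon
table, respecting strand; it is validated against a brute-force oracle that
translates the entire CDS before and after each substitution.  Genomic
intervals are half-open 0-based internally (VCF positions converted on
ingest); protein intervals are half-open over 1-based residue indices.
Multi-allelic VCF records are decomposed into biallelic substitutions;
indels and MNVs are out of scope.

## Training protocol

Training pools are class-labelled annotation records grouped by gene.  To
limit over-representation of heavily mutated genes, the sampler draws
min(k, n_gene) variants per gene uniformly at random, restricted to
longest-transcript records: k = 1 for benign and recessive, k = 2 for the
dominant class under the default (haploinsufficiency-focused) rule; an
"all dominant" rule with k = 1 everywhere is provided.  Descriptive
features are encoded to −1/+1 (two-level categories to a single column,
wider ones to one column per level); numerics pass through unscaled
(forests are invariant to monotone rescaling).

Missing values are imputed with a weighted average of the three classes'
means.  The default weighting is each class's share of the rows observing
the feature — equivalently the pooled mean over observed rows; an
equal-class-weight switch exists.  Fills are fitted inside each training
fold (or once on the training set for final models) and reused verbatim at
prediction time, so observed values are never altered and no label
information leaks from held-out data.

The forest uses 500 trees and ⌊√p⌋ candidate features per split (both
configurable); class probability is the fraction of trees voting for the
class, which satisfies the sum-to-one output contract exactly.  Argmax
ties are broken dominant > recessive > benign (preferring the more
actionable call) and logged.  Pathogenicity is "pathogenic" iff the class
call is not benign; a switch derives it from dominant + recessive > 0.5
instead.

Evaluation is stratified 10-fold cross-validation, repeated 40 times by
default; each repeat re-draws both the per-gene variant selection (when
pools are supplied) and the fold assignment.  Per repeat, every row is
scored exactly once out-of-fold; reported are per-class precision and
recall (pooled over folds and fold-averaged — both, since either
aggregation is defensible), and the multiclass AUC as the Hand–Till
average over unordered class pairs of the two-class rank-sum AUCs (for two
classes this is the ordinary AUC; the implementation is cross-checked in
tests against an independent one-vs-one reference).  Permutation
importance follows the classical out-of-bag recipe: per tree, the error on
its out-of-bag rows is measured before and after permuting one feature;
the per-tree differences are averaged and divided by their standard
deviation (zero SD with nonzero mean reports the unnormalized mean; a
constant feature reports 0).

## Synthetic-data generator

The generator emulates the statistical structure of the training data, not
its biology.  It builds a random genome with multi-exon genes on both
strands (valid start/stop, no internal stops; ~40% of genes get an
exon-skipped second isoform whose middle exon length is a multiple of 3),
resource tables for every family above, and pools of genuine nonsynonymous
variants.  Default pool shapes are 292/119/409 genes contributing
1024/598/2413 candidate variants for benign/dominant/recessive — the
composition used for the per-gene-sampler checks.

A single separation parameter δ scales every class-dependent shift:
allele frequencies (benign common: logit-normal with mean −6 + 1.2δ for
benign), per-site conservation (pathogenic sites ~N(δ, 1) vs N(0, 1)),
pLI (dominant genes: logit-normal mean −2 + 1.3δ), dN/dS (benign genes
shifted up on the log scale), constrained-element and domain coverage
fractions (weakly shifted), and network attachment: fixture genes attach
to a random node of their class's hub star with probability 1 − e^(−δ),
uniformly otherwise, so shortest-path features carry class signal only for
δ > 0.  At δ = 0 every class-conditional distribution is identical by
construction.  Missingness is a single per-value withholding rate
(default 0.05) applied to site rows, gene-table cells and network
membership.

What the generator does **not** emulate: realistic allele-frequency
spectra, linkage, mutational signatures, correlated features within a
family, shared domains across paralogous genes, or label noise.  Passing
recovery tests therefore demonstrates that the pipeline's machinery is
correct and unbiased — not that real-data accuracy would match.

## Study sizes and numerical choices

* The parameter-recovery experiment uses 300 genes per class with two
  candidate variants each and **one variant sampled per gene** (n = 900),
  10-fold CV, 5 repeats, 500 trees.  One-per-gene is deliberate: with two
  sampled variants per dominant gene, the twin rows share all ~40
  gene-level features, and the forest re-identifies genes across folds
  (measured AUC ≈ 0.80 at δ = 0).  That leakage is a structural property
  of duplicating genes in training, not a defect, but it would mask the
  null; with one variant per gene the measured δ = 0 AUC is ≈ 0.51 and the
  δ = 3 AUC ≈ 1.00 with per-class precision ≥ 0.97.
* The importance study uses 5 signal and 20 noise features at n = 600
  (200 per class), δ = 3, over 20 seeds.
* The score-sum contract is checked over 10,000 pipeline predictions.
* One user seed drives named, independently re-derivable substreams
  (`numpy` SeedSequence spawn keys) for reference, pools, resources, CV
  repeats and permutation draws; scikit-learn seeds are drawn below 2³¹.
* Degenerate cases: precision/recall with a zero denominator report an
  explicit undefined marker; a rank-sum comparison where all values tie is
  rejected as degenerate; inheritance accuracy over an all-benign truth set
  reports 0/0 undefined; resource lookups for absent keys return missing,
  never a default number.

## Known limitations

* The consequence caller handles single-base substitutions in CDS only; no
  splice-region, UTR or indel consequences (splice effects enter only via
  the consumed splice-score table).
* Gene identity is by case-sensitive symbol; no alias resolution.
* Probabilities are vote fractions, not calibrated posteriors.
* The 99-feature identity of a production annotation run depends on which
  resource tables are supplied; the default synthetic catalogue has 79
  columns and is configurable rather than fixed.
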