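# Methods

## Background model for per-codon missense expectation

The model separates *mutational process* from *position*. The process is
summarized by the 96-channel trinucleotide spectrum: each SNV is assigned
to one of 6 substitution classes × 16 flank combinations after collapsing
purine-reference changes onto the pyrimidine strand, so classification is
strand-symmetric and a gene's coding-strand sequence suffices. Channel
order is fixed (class major — C>A, C>G, C>T, T>A, T>C, T>G — then 5′ and
3′ flank in A,C,G,T order) so outputs are comparable across runs.

**Cohort spectrum.** Samples with fewer than 50 SNVs are excluded; each
remaining sample's channel counts are normalized to proportions and the
cohort spectrum is their arithmetic mean. Equal sample weighting keeps
hypermutators from dominating; a pooled-count estimator is available
(`pooled=True`) for the alternative reading. The spectrum is computed
from all SNVs by default; a `missense_only` switch restricts it, since
the observed/predicted gene-level comparison concerns missense variants
while the process estimate need not.

**Gene renormalization.** The exome-wide spectrum reflects the exome's
trinucleotide composition. To obtain the channel distribution local to a
gene, each channel is reweighted by the ratio of the gene's to the
exome's frequency of the channel's source context, then renormalized to
sum to 1. Channels whose context is absent from the gene get probability
exactly 0. The operation is invariant to rescaling either composition,
so single-strand versus both-strand context counting cancels.

**Per-codon expectation.** `P(missense at p | i)` is realized as
`m[p,i] / N[c(i)]`: conditional on a type-*i* mutation occurring in the
gene, it lands uniformly among the gene's `N[c(i)]` sites carrying the
channel's source context, and `m[p,i]` of those (site, alt) outcomes are
missense in codon *p*. This is the reading under which the conditional
probabilities over all positions and consequences sum to one, and it
makes two formulations provably identical: the channel-sum form
`Σ_i P_i^gene · m[p,i]/N[c(i)]` and a direct site-rate form in which each
gene site mutates at rate `P_i^exome / f_exome[c(i)]`. The test suite
checks this equivalence to < 1e−10 relative error on random instances.
Consequences come from the standard codon table; changes to a stop are
nonsense and excluded, as are synonymous changes and (for a trailing
reference stop codon) stop-lost changes. Contexts at codon boundaries use
the one-base flanks stored in the gene model; splice-junction genomic
context is not modelled.

**Normalization and ranking.** The predicted profile is scaled so its sum
equals the observed missense total (which therefore makes the comparison
shape-only). Residues are ranked by observed/predicted ratio with ties
broken by observed count then position; `observed/0` is reported as an
infinite-excess sentinel, `0/0` as 0. The per-position Poisson upper-tail
p-value in the report is a descriptive convenience: the expectation model
itself makes no formal hotspot test, and the report flags the p-value as
auxiliary.

## Cohort stratification

A tumour is *CTNNB1*-activated if it has a missense mutation at residue
32, 33, 34, 35, 36, 37, 41, 45, 335, 383 or 387, or an in-frame indel
whose residue range intersects 23–71 (inclusive intersection — the
weakest reading of "at hotspots"). Copy gain is GISTIC ≥ +1. Expression
is analysed as log2(RSEM + 1), transformed at load with pseudo-count 1;
contrasts use a two-sided equal-variance Student's t-test by default with
a Welch option. Mismatch-repair-deficient (or otherwise excluded) samples
are an input flag/list, not computed. The co-occurrence proportion's
denominator (number of non-excluded activated tumours) is always reported
alongside the proportion. A loader for cBioPortal study files
(`cbioportal_cooccurrence`) applies the same rules to
`data_mutations.txt` / `data_cna.txt` matrices.

## Zonation clusters and enrichment

Gene profiles over the nine lobule layers (L1 central vein … L9 portal
node) are filtered to genes with non-zero expression, scaled row-wise to
unit-sum fractions (shape, not magnitude, defines zonation), and
clustered with complete-linkage agglomerative clustering on Euclidean
distances, cutting the tree at k = 4. The row representation was an open
choice; fractions were chosen because zonation archetypes differ in shape
while absolute expression spans orders of magnitude, and the clustering
is then invariant to uniform rescaling. Cluster labels Z1…Z4 are ordered
by the centroid's centre of mass along the lobule axis (Z1 most
pericentral).

Enrichment of a gene set in per-gene statistics uses ES = mean statistic
of set members — the simplest score consistent with normalizing to "the
mean enrichment of random samples" — with a null of `n_perm` random
same-size gene samples drawn without replacement from the scored
universe. NES = ES / mean(null ES); the two-sided p-value is
`(1 + #{|null − mean(null)| ≥ |ES − mean(null)|}) / (n_perm + 1)` (add-one
so p > 0); Benjamini–Hochberg runs across the sets scored in one call.
The permutation unit is genes; sample-label permutation is out of scope.
A tolerance of `1e−12·(1+|ES|)` in the two-sided comparison makes exact
mathematical ties (e.g. the set equal to the whole universe, where every
null sample is a permutation of the set) count as ties despite float
summation-order noise; it is negligible for continuous statistics. When
the null mean is zero the NES is reported as undefined rather than
divided through.

## Synthetic data

The generators define the conditions under which the analyses are
validated. One integer seed drives named substreams, so each generator is
independently reproducible and all outputs are byte-identical across
runs.

- **Sequences.** The exome surrogate is 10 kb of i.i.d. uniform bases;
  the focal gene is 100 codons drawn uniformly from the 61 sense codons
  (stop draws are redrawn individually — distributionally identical to
  rejection of whole genes, but with acceptance probability independent
  of gene length), plus one random flank base on each side.
- **Catalogues.** 100 samples × 200 SNVs; each SNV picks a (site, alt)
  outcome with probability proportional to the channel rate of its
  context, across exome and gene; duplicates within a sample are
  collapsed. The default rate vector is signature-like rather than flat:
  transition-dominant class weights with C>T at CpG ×8 (clock-like
  deamination), A[T>C] ×8 (the liver-specific peak) and G[C>A] ×3
  (aflatoxin-like). Concentration matters: real spectra are spiky, and
  the sampling error of spectrum estimates scales with Σ√p. An optional
  hotspot multiplies all rates in one codon by `hotspot_fold` (default
  none; 20× in recovery experiments). Gene records carry the consequence
  and residue computed by translation; positions are 1-based in the named
  sequence, which for the gene is the flanked CDS.
- **Cohorts.** 500 tumours; activation Bernoulli(0.3) realized as a
  hotspot missense record; gain Bernoulli(0.8) given activation
  (matching the reported ~80% co-occurrence regime) and Bernoulli(0.3)
  otherwise; GISTIC +1/+2 split 70/30 given gain; expression baseline 10
  on the log2 scale with a +1 gain effect and Gaussian noise sd 0.5,
  back-transformed to RSEM.
- **Layers.** Four archetypes (pericentral-declining, periportal-rising,
  mid-lobular peak, flat) × 25 genes, amplitude 100, Gaussian noise sd
  10% of amplitude, clipped at zero.

What the generators do **not** emulate: real exome composition and gene
structure (introns, splice sites, replication timing, expression-coupled
repair), indels and multi-nucleotide events, copy-number segments,
between-sample spectrum heterogeneity (all samples share one process),
and correlated noise across lobule layers. Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
generative model, not robustness to these real-data complications.

## Problem sizes and numerics

Simulation-based checks use 100 samples × 200 SNVs for spectrum
recovery, 100 replicates × 5,000 gene mutations for hotspot recovery,
500-tumour cohorts, and 200–500 seeds × 200 permutations for enrichment
calibration — sizes at which the targeted properties are comfortably
resolvable while a full run stays interactive. Spectra are validated to
sum to 1 within 1e−12; conservation after observed-total normalization
holds to 1e−9; the two profile formulations agree to 1e−10 relative.
Degenerate inputs fail loudly: empty cohorts, all-zero predicted
profiles, compositions lacking a needed context, and GISTIC calls outside
−2…2 each raise a typed error mapped to a distinct CLI exit code.

## Known limitations

- Protein residue numbering is taken from the input catalogue; no
  transcript mapping is performed, so records numbered on a different
  transcript will mis-align.
- The expectation model considers single-nucleotide missense changes
  only; selection (dN/dS), indels and covariate-adjusted background
  rates are out of scope.
- The auxiliary Poisson p-values assume independent Poisson counts per
  residue and are not calibrated for the normalization step; they are for
  triage, not inference.
- The enrichment score is a set-mean; rank-based (KS-style) enrichment
  statistics are deliberately not reimplemented.
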