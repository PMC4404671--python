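# Methods

This note documents the statistical models behind `tomatopop`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
panel can and cannot demonstrate.

## Data model

Genotypes are diploid biallelic calls stored as the dosage of the first
(reference/design) allele, 0/1/2, with a distinct missing sentinel (−1);
missing is never coded as 0. Marker metadata (chromosome, genetic-map
position in cM, allele pair) is carried alongside the call matrix.
Classification is a strict three-level nesting (species ⊃ group ⊃ subgroup)
plus a per-accession mixture flag; flagged accessions carry no labels below
the level at which they were flagged and are excluded from all group
statistics.

## Merging and strand harmonization

Laboratories call Illumina array SNPs against different strand conventions,
so the same marker can arrive as A/G in one dataset and T/C in another. The
first dataset carrying a marker anchors its orientation; other datasets are
relabelled when their pair is the element-wise complement (dosages
untouched — a strand flip changes labels, not which allele was counted) and
dosage-recoded d → 2−d when the pair order is swapped. A/T and C/G pairs
equal their own complement; for those the orientation is chosen by
allele-frequency concordance with the anchor dataset, and the marker is
dropped when the two orientations are nearly equally plausible (margin
between the two frequency mismatches < 0.2). The margin rule is this
package's own operationalization — array-merging scripts in the literature
resolve these markers but rarely document how — and it is deliberately
conservative: a frequency near 0.5 gives no evidence either way, and such a
marker should not survive.

Replicate QC computes the mean pairwise Kosman–Leonard distance inside each
set of repeated samples of one accession; groups above a configurable
threshold (default 0.05) are flagged as inconsistent, and one seeded-random
representative per accession is retained for analysis.

## Marker selection

Three sequential stages, in the order narrated above: missingness (strictly
greater than 0.10 removed), major-allele frequency (strictly greater than
0.95 removed, computed on the whole collection because selection precedes
classification), and greedy per-chromosome thinning at 0.1 cM (scan in map
order, keep a marker iff ≥ 0.1 cM from the last kept; ties at identical
positions keep the first in input order). Greedy scanning is not the only
possible thinning rule, but it is deterministic, auditable and guarantees
the adjacency invariant that tests assert directly. Rarefaction and LD use
the pre-thinning ("all-polymorphic") set: thinning biases allele counts and
removes exactly the short-range pairs LD decay needs.

## Distances

Kosman–Leonard dissimilarity for codominant diploid markers: per locus
d = |x−y|/2 (one minus the shared-allele fraction), averaged over
pairwise-complete loci. Missing-data handling is pairwise-complete because
the alternative (imputation) would leak information across accessions. The
full-matrix implementation reduces the computation to six dosage-indicator
matrix products, so an 866 × 866 matrix over ~4,000 markers takes seconds.

## Diversity

Per locus within a group: H_e = 2p(1−p) with p from non-missing calls,
H_o = fraction heterozygous; group values are unweighted means over loci
with data, P95 the fraction of such loci with major-allele frequency
< 0.95. The plain (uncorrected) H_e estimator is the default — magnitudes
of published array-panel tables are consistent with it — and the
2N/(2N−1) bias-corrected variant sits behind the `unbiased` flag. H and
P95 are computed over all retained loci, with P95 reported separately,
rather than restricting H to the P95-polymorphic subset; both readings of
the usual table caption are defensible, and this one keeps H comparable
across groups with different polymorphism rates. Groups under 5 members
and mixture groups are excluded.

## Differentiation

Jost's D per locus uses the Nei–Chesser small-sample estimators built on
the harmonic mean ñ of per-group sample sizes:

    h_s = mean_k 2 p_k q_k                H_S = ñ/(ñ−1) (h_s − H_o/2ñ)
    h_t = 2 p̄ q̄,  p̄ = mean_k p_k          H_T = h_t + H_S/(ñn) − H_o/(2ñn)
    D   = [(H_T − H_S)/(1 − H_S)] · n/(n−1)

The multi-locus D_est is the arithmetic mean of per-locus D over loci
polymorphic in the pooled sample (harmonic-mean aggregation is available
behind a flag). F_ST is Weir–Cockerham θ as the ratio of sums Σa/Σ(a+b+c)
of the among-group / among-individual / within-individual variance
components; θ was preferred over an AMOVA formulation because it has a
citable closed form and agrees closely on biallelic diploid data. Negative
estimates are reported as computed; they are clamped at zero only where a
differentiation matrix feeds tree building. Significance uses
label permutations holding group sizes fixed and the add-one estimator
p = (1 + #{perm ≥ obs})/(n_perm+1), which cannot return 0 and has lower
bound 1/(n_perm+1).

Neighbor joining is the standard Saitou–Nei agglomeration (Q-criterion,
lowest-index tie-break, negative branch lengths clamped to zero and
counted); on additive matrices it is exact, which the tests check against
enumerated path lengths, and its topologies are cross-checked against
scikit-bio's independent implementation. Bootstrap support resamples loci
with replacement, rebuilds the pairwise D_est matrix and tree, and reports
the percentage of replicates containing each bipartition of the
point-estimate tree.

## PCA and classification

PCA standardizes each marker to (x − μ)/√(p(1−p)) with p = μ/2, sets
missing entries to zero after centring, drops monomorphic markers and
eigendecomposes the accession covariance; score signs are fixed
deterministically. The hierarchical classification runs k-means (k from
config, default 3/3/2 clusters per level, 2 leading PCs) inside each parent
cluster. The mixture rule makes the usual visual call operational: an
accession whose nearest-to-second-nearest centroid distance ratio exceeds
0.8 sits between clusters and is flagged. This threshold is a design
choice, not an estimate; published mixture calls made by expert inspection
cannot be reproduced exactly, and external label files can be injected at
any level to use a published classification verbatim.

## Rarefaction

E[K(g)] per locus is the sum over alleles of the hypergeometric presence
probability 1 − C(N−Nᵢ, g)/C(N, g); private richness multiplies the focal
presence probability by the absence probabilities in every other
population. g counts allele copies (2 per diploid); loci where any
population has fewer than g copies are dropped listwise so curves are
comparable. Binomial coefficients are computed as exact Python integers and
combined in rational arithmetic, so the identities E[K(1)] = 1 and
E[K(N)] = observed allele count hold exactly and no overflow is possible at
any realistic N. Note that private richness is legitimately large at very
small g — absence from a 2-copy draw is likely even for a shared allele —
and only becomes a useful private-variation measure at moderate g; both the
per-locus mean and a normalized variant are emitted.

## LD decay

r² is the squared Pearson correlation of unphased dosage vectors over
pairwise-complete accessions (the composite/Rogers–Huff convention, what
TASSEL computes on genotypes), for all within-chromosome pairs, with pairs
under 4 complete observations or monomorphic in the subset skipped. Decay
curves are tricube-weighted local-linear (LOESS) fits of r² on cM distance,
span 0.3 by default (exposed — no canonical value exists), clipped to
[0, 1]. A per-chromosome pair subsample cap (seeded) bounds output size on
dense maps.

## Isolation by distance

Geographic distances use the haversine formula with R = 6371 km. Climatic
distances standardize the climate variables, rotate to principal components
and take Euclidean distances on the full score space — equal to distances
on the standardized variables (orthogonal rotation), with truncation
available. The Mantel test correlates upper triangles and permutes one
matrix's rows/columns simultaneously; the default alternative is one-sided
positive, matching the directional isolation-by-distance hypothesis, with
a two-sided option because ecologically meaningful negative correlations do
occur in scattered, recently dispersed groups.

## Trait loci

Six cloned fruit loci (fw2.2, fw3.2, lc, fas, ovate, sun) with
ancestral/derived/heterozygous/missing calls. Because counting conventions
differ, both the carrier frequency (heterozygote counts as carrying the
derived allele) and the allele-count frequency (heterozygote = ½) are
reported; the exact Clopper–Pearson interval from Beta quantiles accompanies
the carrier frequency, with exact boundaries at k = 0 and k = n.

## Synthetic panel

The generator draws ancestral frequencies p₀ ~ U(0.05, 0.95) and lets them
drift down the hierarchy under Balding–Nichols,
p' ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so E[p'] = p and Var[p'] = F·p(1−p) and
every estimator has a known expectation in the generating F. Defaults
emulate a three-species tomato panel: ~866 accessions (SP 112, SLC 221,
SLL 492, plus 5% admixed individuals who draw each locus's parental
subgroup 50/50 from two random subgroups), 7,700 SNPs on 12 chromosomes of
100 cM, species-level F of 0.10/0.20/0.30 so diversity orders
SP > SLC > SLL, per-marker missing rates Beta-distributed with mean 3% and
concentration 35 (placing ~3% of markers above the 10% QC cut, as in real
array panels), group-centroid geography in and beyond the Andes, climate
variables linear in latitude/longitude plus noise, and derived trait-allele
frequencies of 0.02/0.35/0.90 for SP/SLC/SLL.

What the panel does *not* emulate: recombination-driven LD (markers are
conditionally independent given subgroup frequencies, so within-group LD is
background-level and LD-decay curves on synthetic data mainly exercise the
machinery), ascertainment bias of array SNP selection (synthetic H_e runs
higher than typical array-panel tables), selfing/inbreeding (genotypes are
Hardy–Weinberg within subgroups, so synthetic H_o is not depressed the way
a selfer's is), and continuous spatial clines (geography is group-level, so
isolation by distance appears between and around group centroids rather
than as a smooth gradient). Passing tests therefore demonstrate estimator
correctness and pipeline behaviour under the stated drift model, not
performance on every feature of real array data.

## Problem sizes and reproducibility

Default analysis sizes (866 × 7,700 simulation; 1,000 permutations and
bootstraps in the pipeline configuration) run in minutes on one core; the
test suite and the acceptance script use the same code paths at reduced
permutation counts and marker numbers, chosen so the whole suite completes
in about two minutes while leaving every statistical check at its stated
tolerance. All randomness flows through explicit `numpy` generator seeds —
simulation, representative choice, permutation tests, bootstraps, k-means —
and the pipeline manifest records parameters, seeds and SHA-256 hashes of
every artifact, so a rerun with the same seed is verifiably bit-identical.

## Known limitations

- The mixture-detection threshold and the A/T–C/G margin rule are design
  choices; both are exposed in configuration and documented above.
- D_est aggregation over loci (arithmetic mean of per-locus D) follows one
  of several published conventions; the harmonic alternative is available.
- The VCF reader handles biallelic SNPs only and reports skipped records;
  indels and multiallelic sites are out of scope.
- No imputation, phasing, model-based ancestry (ADMIXTURE-style), split
  networks or Bayesian species trees; those belong to other tools.
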