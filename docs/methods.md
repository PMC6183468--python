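# Methods

This note documents the models, estimators and numerical choices behind
`flounderscape`, and what the synthetic data can and cannot certify.

## The scientific setting

The package analyses panels of unlinked bi-allelic SNPs sampled from a
high-gene-flow coastal species along a one-dimensional seascape with a
biogeographic break (canonically Cape Hatteras for the U.S. east
coast).  Three questions drive the design: is the species one
population or several (PCA, F_ST, individual isolation by distance)?
how much dispersal crosses the break (coalescent ABC on the joint site
frequency spectrum)?  and which loci track environmental gradients
despite panmixia (Bayes-factor and redundancy-analysis genome scans)?

## Two-deme structured coalescent

**Model.**  Two demes of diploid effective sizes N1 and N2 exchange
migrants with per-generation, per-individual probability *m* (the
"dispersal" parameter, in [0, 0.5]); backward in time each lineage
migrates at rate *m*, symmetrically.  Within deme *i* each pair of
lineages coalesces at rate 1/(4 N_i) per generation.  Each unlinked
locus is an independent genealogy carrying exactly one mutation placed
uniformly on its total branch length (infinite-sites with a single
segregating site, appropriate for one-SNP-per-contig panels).  Diploid
genotypes pair consecutive sampled lineages within a deme.

**Sampling algorithm.**  Event-by-event simulation enumerates every
migration event, whose expected count grows like m x total branch
length (~ 4 N m log k) and becomes prohibitive at large N x m.  The
simulator instead uses exact Poisson thinning: candidate coalescence
times are proposed at the configuration-free bound
lam_max = k(k-1)/4 x max(1/N1, 1/N2); between proposals each lineage's
deme evolves as an independent symmetric two-state Markov chain with
closed-form flip probability (1 - exp(-2 m dt))/2, realized as a
binomial count plus a uniformly chosen subset; a proposal is accepted
with probability (actual rate)/(lam_max).  This samples the identical
law (verified against an event-by-event reference and against an
independent coalescent implementation in the test suite) at O(k^2)
cost per genealogy, independent of N and m.

**Degenerate inputs.**  Lineages isolated in different demes with
m = 0 have zero total event rate and raise a no-coalescence error
immediately; a configurable `max_time` (default 1e9 generations)
guards the near-isolated case.  MAF-rejected loci are re-simulated
with an attempt budget of 1000 x n_loci; exhausting it raises an error
carrying the realized acceptance rate.

## Synthetic study generator

The generator emulates the structure of a coastwise ddRAD survey:

* 232 diploids, 135 north and 97 south of the break, clustered into
  trawl-like sites (22 north, 15 south) along a ~1,900 km polyline
  approximating the shelf from Cape Canaveral to southern New England;
* 1,137 unlinked SNPs with sample MAF >= 0.05 (rejection-resampled)
  and 0.5% uniformly random missing genotypes;
* four environmental variables per individual — distance along the
  coast (km, deterministic in position), capture depth (m), bottom
  temperature (degC, falling ~8 degC across the span) and bottom
  salinity (psu, freshening ~3 psu northward) — as linear gradients in
  coastline position plus site-level Gaussian noise with exchangeable
  correlation 0.3;
* neutral loci draw genotypes binomially from one shared frequency
  p0 ~ U(0.1, 0.9) (ideal panmixia); clinal loci (default 10) from
  logistic(logit(p0) + 2 x standardized bottom temperature).

What this does **not** emulate: linkage, drift-induced background
differentiation between demes (neutral loci are exactly panmictic, so
study-level F_ST reflects only the clinal minority and sampling noise),
sequencing-error genotypes, site-specific depth pathologies (read
depths are i.i.d. Poisson), or real bathymetry.  Passing scan tests on
these data therefore certify detector calibration and power under
clean conditions, not robustness to demographic confounding — the
covariance correction is exercised, but against a nearly identity
background.

## Filtering cascade

The cascade follows a standard ddRAD recipe for FreeBayes-style calls,
in a fixed logged order: call rate >= 50% and minor allele count >= 3
(discovery screens); genotypes on fewer than 3 reads recoded missing;
individuals with > 77% missing dropped; call rate >= 95%, MAF >= 0.05
and mean depth >= 20; mean heterozygote allele balance >= 0.25;
QUAL/total depth >= 0.2; mapping-quality ratio of alternate to
reference reads inside (0.25, 1.75); sites with total depth above the
across-site mean + 1 SD removed when QUAL < 2 x depth; and finally only
the lower 95% of the mean-depth distribution kept, with the realized
cutoff reported.  Thresholds phrased "at least / of X" are inclusive.
The minor allele is defined globally and recomputed after each stage.
Rules whose source field is absent in the VCF are skipped with a
warning.  "Mean depth" rules use the per-individual mean at a site;
the high-depth/quality rule uses the site total, matching the
FreeBayes QUAL scale.

## Isolation by distance

Rousset's individual distance a-hat = (Q_w - Q_r)/(1 - Q_w) uses gene
identities in state with within-individual allele frequencies
{0, 1/2, 1}; Q_r is averaged over pairwise-complete loci and Q_w is by
default the global mean within-individual homozygosity (the SPAGEDI
convention), with a pair-local option.  Geographic distance is the
law-of-cosines great circle (Earth radius 6,378.137 km) or a
least-cost path over an 8-connected passability raster (e.g. shelf
cells no deeper than 200 m), with edge weights equal to great-circle
lengths between cell centres and snapping of query points to the
nearest passable cell.  The Mantel statistic is the Pearson
correlation of lower-triangle entries; the permutation p is
(1 + exceedances)/(n_perm + 1), one-sided positive by default because
isolation by distance predicts a positive slope.

## ABC on the joint SFS

The observed matrix is reduced to complete-data loci and folded into
the joint minor-allele SFS (pooled-sample minor allele; exact 50/50
ties stay with the alternate allele).  The ascertainment cutoff is
inferred as the smallest pooled MAF present in the observed spectrum
unless supplied.  Simulated panels are drawn at the observed sample
sizes with the same MAF rejection, so each already contains exactly
the observed locus count and the downsampling step is the identity (a
hypergeometric downsampler is provided and tested for spectra
simulated in excess).  Spectra are restricted to cells passing the
structural MAF mask, centred on the pilot mean and projected onto PCA
axes fitted to the pilot batch; with all components retained the
projection is an isometry on the reference table, so acceptance
reproduces raw-space rejection exactly (tested).  Rejection keeps
round(accept_frac x n) smallest Euclidean distances, ties broken by
simulation index.  Posterior modes are Gaussian-KDE maxima (Silverman
bandwidth) over accepted draws, deme sizes on the log10 scale;
credible intervals are equal-tailed 2.5/97.5% quantiles.

Survey-scale settings (100,000 simulations, 10,000-component pilot,
0.5% acceptance) are configurable but the package's defaults for
tests, examples and the acceptance script are scaled down (2,000-5,000
simulations, 200 loci, 20+20 diploids, prior log-uniform (100, 20,000)
for sizes and uniform (0, 0.5) for dispersal), sizes a single CPU
completes in minutes.  A caveat the scaled study makes explicit: once
8 N m >> 1 the joint SFS saturates, so the posterior for dispersal is
one-sided — it excludes low dispersal but cannot rank two already-
panmictic dispersal values (e.g. 0.01 vs 0.40 at N = 5,000).

## Environment scans

**Grouping and standardization.**  Individuals are grouped by latitude
between ordered breaks (an individual exactly on a break joins the
northern side); environmental variables are averaged within groups and
then z-scored across the group means (population SD), giving exactly
mean 0 / SD 1 across groups.

**Covariance model.**  With p_l the group-frequency vector of locus l
and pbar_l its across-group mean, x_l = (p_l - pbar_l)/sqrt(pbar_l (1 -
pbar_l)); the background model is Omega = (1/L) sum x_l x_l' + ridge I,
estimated on HWE-passing loci (exact test, alpha = 0.01).  The ridge
(default 1e-3, small against typical diagonal entries of ~1/(2 n_g))
guarantees positive definiteness.  This closed-form moment estimator
replaces an MCMC covariance estimate: it is deterministic and testable,
and the Bayes factor below conditions on it the same way.  Note the
centering constraint sum_g x_lg = 0 builds an anti-correlation of
-1/(P-1) into off-diagonals even for independent groups.

**Bayes factor.**  In the standardized-frequency model the null is
x_l ~ N(0, Omega) — Omega *is* the residual covariance; there is no
free variance scale.  Whitening by Omega^(-1/2) (symmetric square
root) reduces the alternative to a known-variance regression of the
whitened x_l on the whitened standardized environment beyond a
whitened intercept (flat prior, shared by both models).  With a
Gaussian g-prior on the slope the marginal-likelihood ratio is closed
form:

    BF = (1 + g)^(-1/2) x exp( g/(1+g) x z^2 / 2 ),

where z is the environmental signal amplitude in whitened
(background-SD) units.  BF is invariant to allele relabeling
(x -> -x).  The default g = 100 says a selected locus may plausibly
swing ~10 background SDs per environmental SD — large effects over a
near-panmictic background — and, at the conventional BF > 3 cutoff,
implies a null exceedance of |z| > 2.6, i.e. under 1% per variable.  A
profiled-variance (R^2-based) alternative was rejected because with
five groups its null exceedance is fixed near 5.6% regardless of g,
which contradicts how rarely a covariance-aware scan flags neutral
loci.  A quadrature oracle for the marginal likelihood backs the
closed form in the tests.

**Permutation nulls for BF.**  Environmental values are permuted
across individuals, re-averaged and re-standardized over the original
groups (default 10 permutations), yielding the expected BF > 3 count,
a two-sample Kolmogorov-Smirnov comparison of observed vs pooled
permuted BF distributions, and a one-sided binomial exact test of the
observed exceedance count against the permuted exceedance proportion.

**RDA.**  Individual allele frequencies (dosage/2, missing values
mean-interpolated, centred per locus, unscaled) are regressed on the
per-individual standardized environment matrix; Yhat = X(X'X)^-1 X'Y
is decomposed by SVD (computed in the predictor column space, so each
permutation costs one small QR + SVD).  Locus scores are right
singular vectors scaled by singular values; outliers lie beyond +/- 3
SD of the mean score on any of the first three constrained axes
(z-scored per axis, so score scaling conventions are immaterial).
Outliers are confirmed by per-locus OLS on each variable at p < 0.001
(two-sided slope test).  The permutation null permutes environment
rows jointly (10,000 permutations at survey scale; 500 in the scaled
defaults) and reports empirical p-values
(1 + exceedances)/(n_perm + 1) for the outlier count and the
significant-association count.  Because the association count is a
small integer tied at zero under the null, its permutation p is
conservatively super-uniform rather than exactly uniform; the
outlier-count p is uniform in the usual sense.  Non-linear (GAM)
confirmation of associations is out of scope; the linear regression is
the primary rule.

## Numerical conventions

* Genotype dosages are int8 with -1 as the missing marker.
* HWE exact test: two-sided conditional test summing configurations no
  more probable than observed (no mid-p), computed in log space with a
  1 + 1e-12 tie guard; monomorphic sites return p = 1.
* Weir-Cockerham theta: ratio of summed variance components across
  loci; loci monomorphic overall, or with an empty group, are skipped.
* PCA: mean-imputation of missing dosages, column centering, no
  scaling, SVD.
* All stochastic stages consume a single seeded generator per run;
  kernel seeds derived from it stay below 2^31.  Reruns with the same
  config and seed are byte-identical (hashes in the run manifest).

## Known limitations

* The coalescent model has exactly two demes, constant sizes,
  symmetric migration and no recombination, growth or selection.
* The scan's covariance correction is exercised against an essentially
  identity background in the synthetic study; power/FPR numbers do not
  transfer to strongly structured populations.
* Least-cost distances depend on raster resolution; paths are
  restricted to the 8-connected lattice, which overestimates lengths
  by up to ~8% relative to free-angle paths.
* BayEnv-style run-to-run MCMC variability has no analogue here: the
  covariance estimator and BF are deterministic, so "median BF over
  runs" collapses to the single computed value.
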