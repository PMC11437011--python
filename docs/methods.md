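# Methods

This note documents the models, conventions and design choices behind
`seascape_biogeo`, in the order the pipeline runs.

## Repeated rarefaction

Rarefaction draws, for each sample, a subsample of exactly `depth` reads
without replacement — a multivariate hypergeometric draw over the sample's
read pool. "Without replacement" is the standard reading of rarefying;
sampling with replacement (multinomial) would inflate the variance of
retained counts. Samples whose library size is below the depth are dropped
once, identically across all ensemble members, with a logged warning; they
are never resampled up. The ensemble consists of `ensemble_size` independent
rarefactions of the same table (default 1000; the test-suite and the
acceptance script run 50–100 members to stay desk-scale while leaving the
estimator unchanged). Percentile bands across members use the nearest-rank
convention, which is reproducible without interpolation ambiguity. For a
strongly skewed statistic at small ensemble sizes the nearest-rank 5th
percentile can exceed the mean; this is reported as a warning, not an error.

Every stage derives its random generator from a single base seed through
`derive_seed(base_seed, stage_name, *indices)` (CRC-32 of the stage name
mixed into a `numpy` `SeedSequence`). Member *i* of the ensemble uses
`(base_seed, "rarefy", i)`; surrogate draws for taxon *t* in member *m* use
`(base_seed, "affinity", m, t)`, so per-taxon results are independent of
iteration order. Identical config + seed reproduces every output table byte
for byte.

## Seascape classification

Features are per-sample temperature (°C), salinity (PSU) and DIN (µM).
DIN spans orders of magnitude and is strictly positive, so it is
log₁₀(x + 10⁻³)-transformed by default (config-visible); all three features
are then z-scored with the sample standard deviation (ddof = 1). Constants
are stored so held-out samples can be projected into the training space.

The SOM is a classical online Kohonen map: codebook initialized from random
data rows; per step, one random sample is presented, its best-matching unit
(BMU) found by Euclidean distance, and all nodes updated with a Gaussian
neighborhood. Radius decays exponentially from half the grid diagonal to one
node and the learning rate from 0.5 to 1% of itself over `100·n_samples`
steps. Defaults (grid 10×10, steps, rates) are exposed in the config; they
were chosen as conventional values for a three-feature map, not fitted to
any dataset. The codebook is clustered with Ward linkage (Euclidean) cut at
k = 3; each sample inherits its BMU's cluster, BMU ties broken by lowest
node index.

For k = 3 the clusters are named by centroid rules that encode the
qualitative contrasts of the three Southern California Current surface water
masses: lowest salinity → PSUW; of the remaining two, warmer → ENPCW and
DIN-richer → PEW. If both rules select the same cluster, or centroids tie,
names are withheld and numeric labels stand.

A known propagation property: the SOM sheet must span the gaps between
well-separated environmental clusters, and occasionally a "bridge" node that
still wins one or two samples is merged by Ward into the wrong seascape.
On the default synthetic spec this leaves 0–4 of 450 samples mislabeled in
roughly half of random seeds (ARI 0.97–1.0) even though a nearest-centroid
oracle makes no errors. Because presence-based classification is absolute —
an endemic found in even one mislabeled sample stops being endemic — such
label noise demotes the affected habitat's endemics to generalists. Recovery
experiments for the ensemble classifier therefore use the generator's true
habitat labels, isolating the classifier; habitat-label recovery is measured
separately (ARI against truth). Users of real data should treat samples near
seascape boundaries with the same caution.

## Singleton screen

Occurrence statistics are ensemble statistics, so singleton status is
computed on the rarefied ensemble, not the raw table. Rule `max` (default)
flags an ASV whose sample occurrence is ≤ 1 in **every** member — the
strictest reading of "found at most in only one sample"; rule `mean` flags
mean occurrence ≤ 1. Filtering is idempotent under `max`. The filter is
applied before classification and affinity testing; the relative-abundance
denominator remains the rarefaction depth, so retained taxa keep the
proportions they had before filtering.

The Gaussian-mixture diagnostic fits univariate mixtures to log₁₀ mean reads
per ASV by EM with 20 seeded restarts per component count, convergence when
the log-likelihood gain drops below 10⁻⁸ (max 500 iterations), and discards
restarts whose component sd collapses below 10⁻⁶. BIC is reported as
`(3k − 1)·ln n − 2·logL` (k means, k sds, k − 1 free weights; lower is
better) — stated explicitly because mixture-BIC sign conventions vary. The
diagnostic justifies the filter (the largest BIC gain occurring at 1 → 2
components indicates a distinct low-read mode) but never changes the filter
set.

## Biogeographic classification

Presence requires ≥ 1 read post-rarefaction; no minimum-count or
minimum-prevalence threshold is applied. Endemic requires the *same* single
habitat in every counted member — a taxon whose single habitat switches
between members is a generalist (a relaxed mode accepting any single habitat
per member is available). Cosmopolitan requires all k habitats in every
counted member. Members where a taxon is entirely absent after rarefaction
are skipped by default: an unobserved taxon carries no presence evidence in
that member. A strict mode instead treats absence as breaking both endemism
and cosmopolitanism. Ubiquity (≥ 1 read in every sample of every member) is
reported as a flag on cosmopolitans, not a fourth category. The three
categories always partition the analyzed set.

## Habitat affinity

For one taxon in one equal-depth member, per-sample relative abundance is
`count / depth`. Habitat means are unweighted means of these proportions
within each habitat; the overall mean is across all samples. The null model
resamples the taxon's N per-sample proportions with replacement across all
samples (labels fixed) B times and recomputes each habitat mean; the
p-value is the fraction of surrogate means strictly greater than the actual
mean. Only overabundance is tested. Ensemble significance is the mean p̄_h
over contributing members, thresholded at α (default 0.05). No
multiple-testing correction is applied across habitats or taxa; the
per-ASV table carries everything needed for a user-side FDR pass.

Degenerate-case conventions:

- **Constant taxon.** A taxon with identical proportions in every sample
  ties every surrogate mean; the strict inequality would yield p = 0
  spuriously, so a zero-variance guard reports p = 1 for all habitats.
- **Absent member.** A taxon with zero reads in a member would likewise
  score p = 0 everywhere; the default policy skips the member (and counts
  it), with `p1` and `error` policies available.
- **Weighted-mean identity.** Σ_h n_h μ̄_h = N μ̄_overall holds exactly in
  real arithmetic, so at most two of three habitat means can strictly exceed
  the overall mean and the affinity count is ≤ 2. The comparison is asserted
  on every run with a 10⁻⁹ relative tolerance absorbing float rounding.

**Known conservativeness.** The surrogate pool contains the tested habitat's
own samples, so the surrogate habitat mean is positively correlated with the
observed one; for iid data the large-sample probability of p < α is
Φ(z_α·√(1 − n_h/N)) — about 0.022 instead of 0.05 when a habitat holds a
third of the samples. Averaging p across ensemble members compounds this:
when between-sample variation is pure sequencing noise (the generator's
no-overdispersion default), deep subsampling re-randomizes most of that
noise per member, de-correlating member p-values and shrinking their mean
toward 0.5. With libraries ≫ depth the realized Type-I rate can fall below
0.005. The test is therefore conservative — significant affinities are
trustworthy, but weak true affinities will be missed, and the rate of
nominal-α exceedances should not be interpreted as a calibrated error rate.

## Synthetic communities

The generator emulates a ~450-sample regional survey from three water
masses. Environmental envelopes (defaults): PSUW T 12 ± 1 °C, S 32.8 ± 0.12,
DIN 10^(log₁₀0.3 ± 0.25) µM; ENPCW 19 ± 1, 33.6 ± 0.12, ~0.2 µM; PEW
13 ± 1, 33.5 ± 0.12, ~4 µM — qualitatively fresh/cool/poor vs
warm/salty/poor vs cool/salty/rich. DIN is lognormal because concentrations
are positive and right-skewed. A pairwise-separability check warns (or, in
strict mode, fails) when two habitats are closer than a stated margin in
every feature.

Default taxa: 5,000 total — 1,000 endemics, 750 generalists, 750
cosmopolitans (each split into no-affinity and ×10-enriched variants) and
2,500 random-rare taxa, matching the observation that most marine ASVs are
rare and unstructured. Structured baselines are lognormal (σ = 1.5 on the
natural-log scale, a typical microbiome abundance spread); random-rare taxa
get equal tiny support everywhere (0.005 × the median structured weight),
which at the default depth makes them appear in ~1–3 samples — the rare
biosphere. Library sizes are lognormal (median 30,000, σ = 0.35). The
spurious-singleton error mode injects `rate × n_taxa` artifact ASVs with
1–10 reads in one random sample each, carved out of the sample's library so
column sums still equal the drawn library sizes.

Within-habitat abundance is homogeneous across samples (no overdispersion)
by default: each sample's counts are one multinomial draw from its habitat's
normalized latent profile. Real communities are overdispersed (patchiness,
temporal succession, compositional interactions), so passing recovery tests
here demonstrates correctness of the machinery, not performance on real
data; the affinity test in particular becomes more conservative, not less,
as libraries grow relative to depth (see above). Sequences, chimeras, primer
bias and temporal autocorrelation are not simulated.

## Global overlap

Region sets are matched by exact identifier or exact uppercase full-length
sequence equality; primer-region harmonization and fuzzy/OTU-level matching
are out of scope, so cross-pipeline overlaps are lower bounds. Sets are
deduplicated on load, making percentages invariant to duplicate entries.
The richness-vs-overlap relationship is an ordinary least-squares fit
(statsmodels) of percent overlap on region richness, overall and per
biogeographic category.

## Problem sizes used by the tests and the acceptance script

Recovery and calibration experiments run at 3 × 150 samples, 5,000 taxa,
depth 10,000, 50–100 ensemble members, B = 200 surrogates — sizes chosen so
the full suite completes on a laptop-class single core while keeping every
estimator identical to the full-scale configuration (which is a pure config
change: `ensemble_size: 1000`, `surrogate_count: 1000`).
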