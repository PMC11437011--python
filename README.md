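# seascape-biogeo

Quantifying endemic, generalist and cosmopolitan distributions — and habitat
affinity — in a regional marine microbiome from amplicon (ASV) count tables.

Pelagic habitats are not fixed places: a water mass is a parcel of ocean with
internally consistent temperature, salinity and nutrient properties whose
geographic position moves seasonally and interannually. This package
classifies each sample into such a habitat (seascape) from its in-situ
environment, then asks, for every amplicon sequence variant (ASV), whether it
is restricted to one habitat (endemic), found in all of them (cosmopolitan),
or something in between (generalist) — and whether it is significantly more
abundant in particular habitats than random placement would produce (habitat
affinity). It is intended for microbial ecologists working with
ASV-by-sample read-count tables plus per-sample temperature / salinity /
dissolved-inorganic-nitrogen (DIN) metadata.

## Method

1. **Repeated rarefaction.** Each sample is subsampled without replacement
   (multivariate hypergeometric) to a common depth *d*. Because one
   rarefaction randomly discards rare taxa, the subsampling is repeated *M*
   times (default 1000) and every downstream statistic is a mean (with 5/95
   percentile bands) across the ensemble members.
2. **Seascape classification.** A self-organizing map is trained on z-scored
   (T, S, log₁₀ DIN); its codebook is clustered hierarchically (Ward) into
   *k* = 3 seascapes, and each sample inherits the cluster of its
   best-matching node. For *k* = 3 the clusters are named by centroid rules
   after the Southern California Current water masses (PSUW fresh/cool/
   nutrient-poor, ENPCW warm/salty/nutrient-poor, PEW cool/salty/
   nutrient-rich).
3. **Singleton screen.** ASVs occurring in at most one sample (per ensemble
   member, rule `max`; or on ensemble average, rule `mean`) are removed. A
   univariate Gaussian-mixture/BIC diagnostic on log₁₀ mean reads documents
   the low-read singleton mode but never changes the filter.
4. **Biogeographic classification.** Per member, an ASV's presence set is the
   set of habitats holding ≥ 1 read of it. Endemic = same single habitat in
   every member; cosmopolitan = all habitats in every member; generalist =
   anything else. Ubiquity (≥ 1 read in every sample of every member) is a
   flag on top.
5. **Habitat affinity (bootstrap null).** Per member and taxon, with per-
   sample relative abundances x₁…x_N (denominator = rarefaction depth) and
   habitat means μ̄_h, B surrogate datasets resample (x_i) with replacement
   across all N samples, labels fixed, giving B null habitat means, and

       p_h = #{ surrogate μ̄_h* > μ̄_h } / B.

   Ensemble significance is the mean p̄_h across members; affinity set =
   {h : p̄_h < α}. Because Σ_h n_h μ̄_h = N μ̄_overall, at most two of three
   habitat means can exceed the overall mean, so the affinity count is 0, 1
   or 2.

A synthetic-community generator (three environmental habitats, planted
endemic/generalist/cosmopolitan taxa with optional enrichment, a large
random rare fraction, lognormal library sizes, and a spurious-singleton
error mode) makes every stage testable against known ground truth.

## Worked example

```python
import numpy as np
import seascape_biogeo as sb

spec = sb.SyntheticSpec(
    n_samples_per_habitat={h: 40 for h in sb.HABITATS},
    n_taxa={"endemic": 60, "endemic_affinity": 60, "generalist": 60,
            "generalist_affinity": 30, "cosmopolitan": 60,
            "cosmopolitan_affinity": 30, "random_rare": 300},
    library_mu=float(np.log(5000)), seed=42)
counts, env, truth_labels, truth, lib = sb.generate_community(spec)

cfg = sb.PipelineConfig(rarefaction_depth=2000, ensemble_size=50,
                        surrogate_count=200, base_seed=42)
result = sb.run_pipeline(counts, env, cfg)
print(result.category_summary.to_string(index=False))
```

prints

```
    category  count   percent
     endemic    106 23.660714
  generalist    252 56.250000
cosmopolitan     90 20.089286
```

i.e. of the 448 ASVs surviving the singleton screen, 23.7% were seen in
exactly one habitat in every ensemble member, 20.1% in all three habitats in
every member, and the rest are generalists (the planted random-rare taxa
land here: too sporadic to be consistently endemic or cosmopolitan). One
planted PSUW-endemic taxon with enrichment looks like this:

```python
row = result.affinity.table.set_index("asv_id").loc["endemic_affinity_00003"]
```

```
mu_PSUW       0.00423
mu_ENPCW      0.00000
mu_PEW        0.00000
mu_overall    0.00142
p_PSUW        0.00000
p_ENPCW       1.00000
p_PEW         1.00000
affinity_set: PSUW
```

Its mean relative abundance is 0.42% inside PSUW and zero elsewhere; no
surrogate ever beat the observed PSUW mean (p̄ = 0), so the pipeline reports
a single-habitat affinity — exactly the planted structure.

The same pipeline is scriptable from the shell:

```bash
seascape-biogeo --seed 42 --out-dir sim simulate --n-per-habitat 40 --taxa-scale 0.1
seascape-biogeo --config config.yaml --out-dir results run-all
```

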