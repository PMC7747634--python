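# bodysize-assembly

Quantify how the balance between stochastic (dispersal, drift) and
deterministic (environmental selection) community assembly scales with
organism body size, from rarefied sample × OTU count tables.

The package is aimed at microbial ecologists analysing amplicon surveys
of soil (or any spatially structured) communities that span organism
groups of very different propagule sizes — bacteria, fungi, protists,
nematodes. It implements the full analysis chain:

- **β-null deviation (NDV)** — observed pairwise Bray-Curtis minus its
  expectation under a randomization that preserves each sample's
  richness and read total (OTUs drawn by occurrence, reads by
  abundance; 999 nulls by default). NDV ≈ 0 → stochastic assembly,
  NDV → ±1 → deterministic.
- **Distance-decay relationship (DDR)** — `log10 S = a + b·log10 D`
  with S = 1 − Bray-Curtis and D the haversine distance (km); the
  halving-distance `d_H = 10^((log10(S0/2) − a)/b)` with initial
  similarity S0 at 1 km.
- **Sloan neutral model** — dispersal rate m fitted by least squares of
  per-OTU occurrence frequencies to
  `Freq_i = 1 − I(1/N | N·m·p_i, N·m·(1−p_i))` (regularized incomplete
  beta), with Wilson 95% bands, generalized R², and a bootstrap AIC
  comparison against binomial subsampling.
- **OMI niche breadth** — squared distance between each OTU's
  abundance-weighted mean position in standardized environmental space
  and the study-area centroid; low OMI = wide niche.
- **Variation partitioning** — Hellinger-transformed RDA with
  forward-selected environmental variables and Moran's eigenvector maps
  (classical PCNM), Ezekiel-adjusted pure/shared/residual fractions and
  permutation tests.
- **Body-size scaling** — OLS of every assembly metric on log10 body
  size, ANOVA + Tukey group contrasts, and a batch harness pooling NDVs
  across many studies by ecosystem.

A synthetic-study generator (`bodysize_assembly.synth`) produces
landscapes, metacommunities and Moran-type local communities with
tunable, body-size-coupled dispersal and selection, so every estimator
can be tested against known ground truth.

## Worked example

Simulate a 5-group, 20-site study with dispersal decreasing and
selection strengthening along the body-size ladder, then run the whole
pipeline:

```sh
bodysize-assembly simulate demo --n-sites 20 --n-otus 60 --depth 1000 \
    --n-groups 5 --seed 11
bodysize-assembly pipeline demo --out-dir demo_out --reps 199 \
    --n-perm 99 --seed 11
```

which prints (abridged):

```text
       size_um  mean_ndv       m  mean_omi  ddr_slope        d_h
grp01    0.400     0.023   1.000     0.135     -0.110  69588.420
grp02    2.758     0.070   0.444     0.311     -0.193   6032.371
grp03   19.016     0.106   0.101     0.700     -0.310   1749.298
grp04  131.112     0.163   0.030     0.718     -1.154    615.376
grp05  904.000     0.179   0.007     0.903     -1.672    457.952

  response     slope  r_squared  p_value  n
  mean_ndv  0.048141   0.979713 0.001234  5
         m -0.286187   0.813498 0.036314  5
  mean_omi  0.231769   0.933113 0.007495  5
 ddr_slope -0.487013   0.874665 0.019592  5
```

Reading the output: as body size grows from 0.4 µm to 904 µm, the mean
null deviation rises (0.02 → 0.18: assembly becomes more
deterministic), the fitted dispersal rate falls (1.0 → 0.007), niche
marginality (OMI) rises, the distance-decay slope steepens (−0.11 →
−1.67) and the halving-distance shortens (≈70,000 km → ≈460 km:
communities of large organisms turn over in space far faster). The
scaling table confirms the four sign patterns (positive NDV and OMI
slopes, negative m and DDR slopes against log10 size), matching the
coupling built into the simulation.

Every stage is also available separately (`ddr`, `ndv`, `neutral`,
`omi`, `varpart`, `meta`) and as plain library calls; see the module
docstrings under `src/bodysize_assembly/`.

## Input formats

- Count table: TSV, samples as rows, OTUs as columns (BIOM classic
  dense text also accepted).
- Metadata CSV: `sample_id, latitude, longitude`, then numeric
  environmental columns (e.g. pH, MAT, MAP).
- Taxon map TSV: `otu_id, group`; body sizes CSV: `group, size_um`.

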