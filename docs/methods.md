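# Methods

This note documents the models and procedures implemented in
`bodysize_assembly`, the choices made where the design was genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Scientific setting

Soil organisms spanning four orders of magnitude in body size —
bacteria (~0.4 µm propagules) through fungi, protists and nematodes
(~900 µm) — are hypothesised to assemble under different balances of
stochastic forces (dispersal, ecological drift) and deterministic
forces (environmental selection): the smaller the organism, the larger
its populations and dispersal ability, hence the more stochastic its
community assembly. The package quantifies that balance per organism
group from a rarefied sample × OTU count table, sample coordinates and
environmental covariates, then regresses each assembly metric on log10
body size.

## Metrics and models

**β-null deviation (NDV).** For each unordered sample pair, NDV =
observed Bray-Curtis dissimilarity − mean Bray-Curtis over null
reassemblies of the table (999 replicates by default). Each null
replicate preserves, per sample, the observed richness R_j and read
total N_j: R_j distinct OTUs are drawn with probability proportional to
each OTU's occurrence (number of samples occupied), each selected OTU
is seeded with one read, and the remaining N_j − R_j reads are
distributed multinomially with probabilities proportional to the
selected OTUs' total abundances, renormalized over the selected set.
The one-read seeding guarantees exact richness preservation; weighted
OTU selection uses the exponential-clock construction (keys Exp(1)/w,
smallest R_j kept), which is exactly successive weighted sampling
without replacement. NDV ≈ 0 indicates assembly indistinguishable from
stochastic reassembly; NDV near ±1 indicates deterministic structure.
Group-level NDV is computed on each group's own sub-table (samples with
zero group reads dropped), with occurrence/abundance weights from that
sub-table.

*Calibration caveat (measured by our own tests).* Under pure
multinomial sampling noise the signed mean NDV is not exactly zero:
when per-sample richness does not saturate the OTU pool, null
assemblies occasionally omit dominant OTUs, inflating the null
expectation and biasing NDV negative. With a lognormal metacommunity
(shape σ_log = 1.5, our default) at S = 200 OTUs and 2000 reads the
bias is ≈ −0.07; it shrinks to ≈ −0.004 for near-even pools (σ_log =
0.8) and grows to ≈ −0.13 at σ_log = 2. Small |NDV| values should
therefore be read against this floor. Relatedly, NDV is hump-shaped in
selection strength: under extreme filtering sites approach
monodominance and the null expectation rises too, so NDV falls again.
The monotonicity tests use niche breadths σ ≥ 2 (environment units on a
0–10 gradient), the informative regime.

**Distance-decay relationship (DDR).** Similarity S = 1 − Bray-Curtis
is regressed on geographic distance D (haversine, Earth radius
6371 km) on log10–log10 axes over all unordered pairs: log10 S = a +
b·log10 D. Pairs with S ≤ 0 or D < 1 km are excluded (log undefined;
1 km is the floor at which the initial similarity S0 = 10^a is
defined). The halving-distance d_H = 10^((log10(S0/2) − a)/b) is the
distance at which similarity falls to S0/2; with S0 = 10^a it reduces
to 10^(−log10 2 / b). Significance is the two-sided t test on the OLS
slope; all pairs enter the regression (pairwise pseudo-replication is
accepted deliberately, as is conventional for DDR slopes — the p-values
are optimistic and should be read as descriptive).

**Sloan neutral model.** Occurrence frequency of OTU i across local
communities of size N is predicted from its mean relative abundance p_i
and a dispersal rate m as Freq_i = 1 − I(1/N | N·m·p_i, N·m·(1−p_i)),
with I the regularized incomplete beta function (the beta CDF at the
one-individual detection threshold; the CDF is the only reading that
yields probabilities). m is estimated by bounded scalar least squares
with multi-start brackets (the objective flattens toward m → 1); fit
quality is the generalized R² = 1 − SSerr/SStotal, which can be
negative and is not clipped. Wilson score 95% intervals around the
predicted frequencies partition OTUs into above/within/below the
neutral band. A binomial subsampling null (Freq = 1 − (1−p)^N) is
compared by Gaussian-likelihood AIC (n·ln(SSerr/n) + 2k, k = 1 vs 0)
over bootstrap replicates resampling OTUs with replacement (1000 by
default), refitting m in each replicate.

*Estimator bias at large m (measured).* By detailed balance, the
one-death-one-birth Moran community with immigration probability m has
exact stationary occupancy beta-binomial with scale N·m/(1−m); Sloan's
formula uses scale N·m (the small-m diffusion approximation). Fitting
the model to exactly stationary Moran data therefore recovers m
inflated by roughly 1/(1−m) plus a detection-threshold discreteness
term: ≈ +13% at m = 0.02, ≈ +45% at m = 0.1, ≈ +100% at m = 0.3. Rank
order across dispersal levels is preserved essentially always, and
fitted m should be interpreted as an effective dispersal index rather
than an unbiased rate outside the small-m regime.

For a group's sub-table of an evenly rarefied whole-community table the
row sums are unequal; the fit then uses N = mean group reads per sample
and p_i = mean of per-sample relative abundances, the convention of
standard neutral-model fitting scripts.

**OMI niche analysis.** Environmental variables are centered and
scaled to population (divide-by-n) standard deviation 1; an optional
full-rank PCA rotation is available and leaves OMI unchanged (it is an
orthogonal rotation). Each OTU's niche position is its
abundance-weighted mean site coordinate; OMI is the squared Euclidean
distance to the unweighted site centroid (the origin), so every site
counts equally regardless of richness. Low OMI = wide niche breadth.
Group summaries report the unweighted mean over member OTUs (headline)
and the abundance-weighted mean. OMI magnitudes are
convention-dependent (they scale with the number of environmental
axes), so analyses should compare OMIs only within one standardization.

**Variation partitioning.** Counts are Hellinger-transformed; spatial
predictors are Moran's eigenvector maps built by the classical PCNM
recipe (truncate the distance matrix at the longest minimum-spanning-
tree edge, replace beyond-threshold distances by 4× the threshold,
double-center, keep positive-eigenvalue eigenvectors scaled by √λ; the
construction reproduces R vegan's `pcnm` to numerical precision, which
is frozen as a test oracle). Duplicate coordinates are jittered by
1e−6 km with a warning. Predictors enter by forward selection with the
double stopping criterion: a permutation pre-test of the global model
gates any selection (without it, testing the best of q candidates
inflates type I error), then candidates are added while their
residual-permutation p ≤ α and the cumulative adjusted R² stays below
the global model's. Fractions use Ezekiel-adjusted R² of the env-only,
spatial-only and joint redundancy models: pure_env = R²adj(both) −
R²adj(spatial), pure_spatial symmetric, shared the complement within
R²adj(both), residual = 1 − R²adj(both); unadjusted fractions sum to 1
exactly by construction. Pure fractions are tested by partial RDA with
Freedman-Lane residual permutation; negative adjusted fractions are
reported as-is.

**Scaling layer.** Per-group metrics (mean NDV, m, mean OMI, DDR slope,
d_H, S0, Chao1, richness) are regressed on log10 body size by OLS with
two-sided t p-values; group contrasts use one-way ANOVA with Tukey HSD
and a compact letter display. A batch harness pools group-level NDVs
over many study directories with optional kingdom/ecosystem labels for
stratified scaling fits. Missing metrics propagate as missing, never
zero.

## Synthetic studies and ground truth

`synth.generate_study` emulates the post-processing products of a
large-transect soil survey: by default 45 evenly spaced sites along a
4165 km north-south transect, one environmental covariate built as a
linear trend over (0, 10) plus Gaussian noise with an exponential
spatial correlation kernel (length 800 km, sd 10% of the range), and
per group a lognormal metacommunity (σ_log = 1.5, 100 OTUs) with
per-OTU environmental optima uniform over the gradient. Each site runs
a Moran-type local community of N = 2000 individuals for 50
generations (N×50 one-death-one-birth steps from a multinomial start):
a death is replaced with probability m by an immigrant from the
niche-weighted metacommunity (Gaussian filtering with breadth σ), else
by a local offspring. Selection thus acts on immigration; drift acts
through the zero-sum update. Communities are simulated at the target
depth, so tables are born evenly rarefied.

The size-coupled ladder encodes the smaller-is-more-stochastic
hypothesis as ground truth: six groups log-spaced over 0.4–904 µm with
dispersal m log-interpolated 0.7 → 0.04 and niche breadth σ 5 → 1.2.
The dispersal range is chosen by matching N·m — the quantity that
controls drift — between the emulated survey (N ≈ 27,000 reads,
fitted m ~ 0.01–0.1) and the scaled-down communities (N = 2000), giving
N·m ≈ 80–1400; pushing m lower at this N would put the largest groups
into the monodominance regime where NDV turns non-monotone (see the
calibration caveat above). An uncoupled variant (identical m and σ
across the ladder) provides the null for the scaling regressions.

Equilibration: the Moran process relaxes toward stationarity at rate m
per generation, so recovery experiments at small m run ⌈3/m_min⌉ = 150
generations (uniformly across dispersal levels); pipeline-level studies
use the 50-generation default, adequate for their m ≥ 0.04.

What the generator does not emulate: spatially explicit dispersal
kernels between neighbouring sites (immigration always draws from the
regional pool), speciation/diversification, multi-variable
environmental trade-offs, sequencing error, or compositional artifacts
of PCR. Passing the end-to-end tests shows the estimators recover the
encoded dispersal/selection gradients under this idealized model — not
that real paddy-soil communities assemble this way.

## Numerical choices and degenerate inputs

- Rarefaction is multivariate hypergeometric (without replacement),
  one master seed with per-sample substreams; undersampled samples are
  reported by name rather than silently dropped.
- Chao1 switches to the bias-corrected form S + F1(F1−1)/(2(F2+1))
  when no doubletons are observed.
- All randomness flows through numpy's PCG64 generators seeded from
  explicit integers; fixed seeds reproduce results bit-identically.
- DDR declines to report d_H when b ≥ 0 (returns NaN with a warning);
  halving-distance inputs are validated (b < 0, S0 ∈ (0, 1]).
- predicted_frequency handles p = 0 → 0 and p = 1 → 1 explicitly
  (degenerate beta limits).
- Forward selection drops constant candidates; MEM construction
  requires ≥ 4 sites; variation partitioning accepts an empty block on
  one side (its R² is 0) but not both.
- Problem sizes in the test-suite simulations (tens of sites, hundreds
  of OTUs, hundreds of null replicates) are scaled-down study designs
  chosen to keep each calibration well-resolved relative to its
  assertion margin.

## Known limitations

- The NDV calibration floor and hump (above) mean signed NDV is a
  relative, not absolute, stochasticity scale.
- Fitted dispersal rates are effective indices, biased upward outside
  the small-m regime (above).
- DDR p-values ignore pairwise non-independence (no Mantel correction
  by default).
- OMI is reported without its permutation significance test or the
  Tol/Rtol decomposition of the full ordination method.
- Scaling regressions treat groups as independent points; no
  phylogenetic comparative correction is applied.
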