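# Methods

`tempopg` infers demographic history from a pair of population samples of
the *same* (meta)population taken two points in time apart — typically a
museum/archive ("historic") sample and a modern resurvey — and then asks
which SNPs moved in frequency between the two time points more than the
fitted demography allows. This note records the models, the numerical
choices, and what the synthetic data used in tests do and do not emulate.

## The temporal joint SFS and its binned summary

For each time period, diploid individuals are pooled across sampling
localities into one metapopulation sample; the joint (2D) site frequency
spectrum `X[i, j]` counts SNPs with derived-allele count `i` among the
`n1` historic chromosomes and `j` among the `n2` modern chromosomes. Over
~90 generations allele frequencies barely decorrelate, so virtually all
mass hugs the `i/n1 = j/n2` diagonal; drift intensity (deme size), and
changes in connectivity or size, control how mass spreads off the diagonal
and along it. Counts are haploid chromosome counts; diploids contribute 2.

Raw joint spectra are high-dimensional and dominated by near-empty cells,
which makes them poor direct targets for simulation-based fitting. They
are therefore reduced to band sums:

* the spectrum is made square by hypergeometric projection of each axis to
  `min(n1, n2)` (expected down-sampling; mass-conserving, fractional
  entries allowed),
* optionally folded to minor-allele classes (the default: folding is
  robust to polarization error from outgroup misassignment and ancient-DNA
  damage),
* then partitioned twice into parallel bands of width `2w + 1`: by
  diagonal offset `d = i − j` and by anti-diagonal position
  `s = i + j − n`. Band index is `round(offset / (2w+1))` with ties away
  from zero — unreachable for integer offsets and odd widths, so the
  partition is deterministic. The default half-width is `w = 2`.

The summary vector is the concatenation (diagonal family first, bands in
ascending index order) of both band-sum vectors. Each family is an exact
partition, so each family's bins sum to the spectrum mass — the invariant
the tests enforce to 1e−9. The binning function is pluggable
(`SummaryPipeline.binner`) because "categories on either side of the
diagonal" admits more than one tiling; the parallel-band partition is the
default.

Diversity statistics (S, Watterson's θ_W, pairwise θ_π, Tajima's D) use
the standard SFS formulas; θ_W and θ_π are fold-invariant, so folded
spectra may be passed padded with zeros above n/2.

## Demographic model catalog

Populations are modeled as finite island metapopulations: `d` demes of
equal effective size `Ne_mod` (diploid individuals, at the present)
exchanging migrants at per-pair, per-generation rate `m` (symmetric by
default; an optional pairwise mode draws one rate per unordered deme
pair). The catalog crosses

* deme-size trajectory: constant; bottleneck declining into the present at
  intrinsic rate `r_shrink` from 90 generations ago; historic exponential
  expansion at rate `r_grow` ending `t_grow_stop` generations ago; or
  expansion followed by the bottleneck; with
* a migration-rate change (from `m_hist` to `m_mod`) at the historic
  sampling time, yes/no,

giving eight topologies with stable one-letter ids (E/F constant, A/B
bottleneck, C/D expansion, H/G expansion-then-bottleneck; the second
letter of each pair carries the migration change). Bottleneck onset and
migration change are pinned at the historic sampling time (90 generations
by default, one generation per year) — the natural changepoint for a
century-scale contrast. Expansion histories carry no drawn start time:
going backward in time the size decays exponentially from `t_grow_stop`
and is floored at 10 individuals by a final constant epoch, keeping every
history inside a [10, 1e6] individuals envelope.

Default priors (all config-overridable, and deliberately documented as
placeholders rather than anyone's fitted values): `Ne_mod`
log-uniform[1e2, 5e4]; migration rates log-uniform[1e−5, 1e−1];
`r_shrink` uniform[1e−4, 0.03] (a 90-generation bottleneck then changes
size at most ~15-fold); `r_grow` uniform[1e−4, 0.02]; `t_grow_stop`
uniform[90, 5000] generations.

## Simulation with serial sampling

The coalescent engine is msprime behind `simulate_snp_table`; the
translation of forward-time histories into backward-time epochs, the
serial sampling (lineages drawn at time 0 and at `t_hist_sample`), and all
downstream processing are implemented here. Loci are independent msprime
replicates (default genome: 1,000 × 1 kb at μ = 1e−8 /bp/gen, no
recombination within loci; every scale is configurable and the tests use
smaller genomes, stated below). Mutations follow an infinite-sites binary
model, so every site is biallelic with known ancestral state; sites
monomorphic across the union of both period samples are dropped, exactly
matching the SNP ascertainment of observed data.

Matched filtering reproduces the ascertainment effect of removing
deamination-prone SNP classes (C/T and G/A in either orientation — the
damage classes of hydrolytically deaminated cytosines in old DNA) from
simulated data that carry no nucleotide identities: by default simulated
SNPs are thinned by an independent Bernoulli draw with the excluded-class
fraction measured on the observed table before filtering; alternatively
sites can be assigned substitution types from a configurable distribution
and filtered through the identical class rule as the observed data.

`SummaryPipeline` freezes the whole chain (sampling design, genome,
thinning probability, projection, folding, bin width) so reference-table
rows and the observed summary are guaranteed identical treatment; its
configuration is stored beside every reference table.

An independent Wright–Fisher forward simulator (`wf_forward_oracle`,
binomial drift, island migration, hypergeometric sampling without
replacement at both time points, optional Poisson mutation influx with
burn-in from scratch) exists purely as a cross-check of the coalescent
path at desk scales (Ne ≤ 5,000). Its `n_sites` initialization seeds each
deme independently from the single-population equilibrium law P(x) ∝ 1/x —
an initial condition, not the joint multi-deme equilibrium; comparisons
that need true equilibrium use the burn-in path. Note that the mean
ratio-of-sums Hudson F_ST between the two time points of a constant-size
population is substantially below the textbook drift figure t/(2Ne):
union-polymorphism ascertainment and mutations arising inside the window
both dilute it. The coalescent and forward engines agree on it to within
Monte-Carlo error, which is the meaningful check.

## Rejection ABC

Summaries are standardized dimension-wise by median/MAD computed over the
pooled multi-model reference table (constant dimensions get unit scale),
distances are Euclidean, and the posterior sample is the ε-fraction of
closest rows (default ε = 0.008, the tolerance used at full 25,000-row
scale; small reference tables need proportionally larger ε so that tens
of rows are accepted). Model posterior probabilities are the model shares
of the globally accepted rows, with equal prior row counts enforced.
Local-linear regression adjustment (Epanechnikov weights within the
acceptance radius, strictly positive parameters adjusted on log scale) is
available behind a flag; the plain rejection sample is the default.

The "best-fit history" is operationalized as the reference row minimizing
the standardized distance to the observed summary, with ties broken to
the lowest row index — deterministic, and the natural analogue of a
maximum-likelihood point under a simulation-based likelihood; the
regression-adjusted posterior mode would be the alternative and can be
derived from the adjusted sample.

Cross-validation holds out reference rows as pseudo-observed datasets
(removing one row from every model to keep prior counts equal) and tallies
the argmax-model confusion matrix.

### Goodness of fit and its known caveat

`gof_fit` simulates R replicate bin vectors under the best-fit history,
records the Euclidean distances from the observed bins to every replicate
(D_obs) and from one seed-designated pseudo-observed replicate to the
remaining R−1 (D_pseudo), and reports Weitzman's coefficient of
overlapping (OVL: shared histogram breaks spanning the pooled range,
Freedman–Diaconis width with at least 10 bins, summed bin-wise minimum of
the two probability mass functions) plus the two-sample KS statistic and
p-value (scipy's exact method at small samples, asymptotic otherwise).

Caveat: both distance samples are conditioned on a single random center
(the observed dataset, respectively the pseudo-observed replicate). The
center's own distance from the cloud mean shifts its entire distance
sample as a block by roughly 0.6 within-sample standard deviations on
average — independent of data size or summary dimension — so under a
perfectly fitting history the two-sample KS p-value is *not* uniform and
rejects far more often than its nominal level, increasingly so for large
R. The OVL (typically ~0.5–0.8 under the null, near 0 under gross
misfit) is the robust part of the diagnostic; treat the KS p-value as a
descriptive contrast between candidate models rather than a calibrated
test of fit.

## Selection scan

Per-site temporal F_ST uses Hudson's estimator on allele counts
(numerator `(p̂1−p̂2)² − p̂1(1−p̂1)/(n1−1) − p̂2(1−p̂2)/(n2−1)`, denominator
`p̂1(1−p̂2) + p̂2(1−p̂1)`), with a two-population Weir–Cockerham variant
available; global F_ST is the ratio of summed numerators to summed
denominators with a percentile bootstrap CI over sites. Working on counts
rather than genotype likelihoods is this package's principal deliberate
simplification: with degraded samples a genotype-likelihood pipeline
shrinks frequency-estimation noise that count-based estimators retain, so
count-based null F_ST means run somewhat higher at the same sample sizes.

The neutral fit follows the OutFLANK logic: model F_ST ~ (F̄/df)·χ²(df)
and estimate both F̄ and the effective degrees of freedom by maximizing a
two-sided truncated likelihood on the trimmed bulk (default trims 5% of
each tail, pooled expected heterozygosity ≥ 0.1, non-positive values
excluded as carrying no shape information). Fitting and p-values use the
*uncorrected* estimator (no finite-sample terms), which is non-negative
as the χ² model requires; q-values are Benjamini–Hochberg over the tested
sites and outliers are sites with q below the configured FDR (default
0.01). Fitting df empirically rather than fixing it at (number of
populations − 1) absorbs the effect of demographic structure on the null
F_ST distribution.

The simulation null (`null_fst_scan`) replays the full matched pipeline
under the best ABC-fitted history, pools per-site null F_ST values across
all replicates and sites, and assigns each observed site the add-one
upper-tail empirical p-value `(1 + #{null ≥ obs}) / (1 + N_pool)`.
Pooling across sites is what resolves p-values far below 1/n_sims.
Because allele-count F_ST values are heavily tied (many sites share a
count configuration), these default p-values are valid but conservative —
stochastically larger than uniform. `tie_break="random"` breaks ties
uniformly at random, the standard construction for discrete nulls, and is
exactly calibrated; calibration checks use it, reported results keep the
conservative default.

Elevation-band frequencies pool group counts into `floor(elev/width)`
bands (default 100 m), and OLS of per-band mean derived-allele frequency
on the band midpoint gives R² and p (reported missing with fewer than two
occupied bands).

## The synthetic study design

The packaged scenarios emulate the study design the framework targets:
a 4-deme island metapopulation, deme size 1,500, per-pair migration 0.01
declining threefold at the historic sampling time, 90 generations (= 90
years) between samples, 52 historic and 48 modern diploids, 1 Mb of
sequence (400 × 2.5 kb loci) at μ = 1e−8, and a transition-biased (Ts:Tv
= 2:1) substitution-type distribution so that the deamination-class
filter removes a realistic ~50% of SNPs. The `one_outlier` scenario adds
a single site binomially sampled at frequency 0.2 (historic) and 0.65
(modern) — the magnitude of shift a strongly selected standing variant
can reach over ~90 generations; the pooled sample frequencies are hit
exactly (largest-remainder allocation of counts across demes), so the
injected signal is a controlled stimulus rather than one more random
draw. What the generator does *not* emulate:
genotyping error and coverage heterogeneity, linkage within loci beyond
the shared genealogy, missing data, spatially heterogeneous deme sizes,
and polarization error — so passing tests demonstrate correctness of the
inference machinery under the stated model, not robustness to those
real-data complications.

Test problem sizes (all deliberate reductions of the full-scale method,
chosen to keep the default suite fast): simulator calibration uses 1 Mb
single-deme genomes with 100–200 replicates; ABC parameter recovery uses
a 4-deme design with 16 diploids per period, 100 kb genomes, a
2,000-row reference table and 50 pseudo-observed datasets with narrowed
priors (Ne log-U[2e2, 5e3], m log-U[1e−3, 1e−1]) spanning the true values
(Ne = 1,500, m: 0.01 → 1/300); the scan calibration/power tests use the
fitted-history conditions of the contrast that motivates the scan — 10
demes of 1,350 individuals, threefold migration decline, 50 diploids per
period and ~10⁴ SNPs on four 750-kb chromosomes recombining at 1e−8 (an
exome's SNPs sit on thousands of loosely linked contigs; long
non-recombining loci would instead make the trimmed χ² fit unstable) —
with 50 replicate datasets.

## Numerical choices

* Band-index rounding: ties away from zero (unreachable; documented for
  determinism). Folding keeps exactly one representative of each
  boundary-cell pair and never double-counts the self-symmetric cell.
* MAD standardization: zero MADs replaced by unit scale.
* χ² fit: Nelder–Mead on (log df, log F̄) from moment-matched starting
  values, df clamped to [0.05, 50] only at initialization; non-convergence
  raises with diagnostics rather than returning a partial fit.
* Degenerate inputs raise informative errors: non-square spectra sent to
  binning, upward projection, folding a folded spectrum, empty bootstrap
  tables, all-identical F_ST values, epsilon outside (0, 1].
* All randomness flows through numpy Generators seeded from explicit
  integers; nested seeds derive via SeedSequence so reference tables are
  bit-reproducible row-by-row and resumable.

## Known limitations

* Count-based F_ST (see above) — the scan's power at a given sample size
  is somewhat below a genotype-likelihood implementation's.
* Rectangular spectra are squared by projection before binning; an exact
  unequal-sample-size binning is not implemented (the ABC remains valid
  because observed and simulated data receive identical treatment).
* The GOF KS p-value is anti-conservative by construction (caveat above).
* Single-population/divergence-free topologies only: no admixture from
  other species, no stepping-stone geometry.
* The forward oracle is a validation tool, not a production simulator;
  it is restricted to Ne ≤ 5,000.
* At the reduced scale the reproduction script uses for its ABC stage
  (16 diploids per period, 200 kb), the posterior for the recent
  migration contrast is prior-dominated: the reported migration-decline
  factor hovers near the prior median rather than the simulated
  threefold drop, and the constant-versus-declining-migration posterior
  sits near 0.5. Resolving that contrast needs the full-scale design
  (tens of thousands of simulations of megabase genomes), which is
  exactly why the parameter-recovery test checks credible-interval
  coverage rather than point recovery.
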