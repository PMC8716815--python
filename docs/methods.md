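# Methods

This note records the models implemented, the numerical and design
choices made where the methodology was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Preprocessing

Input is a taxa × samples integer count table with per-sample metadata
(site ∈ {control, radiation}, tissue ∈ {aerial, root}, season,
replicate). Filtering removes taxa with dataset-wide total count below
3 (singletons and doubletons) and taxa whose dataset-wide relative
abundance (taxon total / grand total) is below 0.001; both thresholds
are interpreted at the whole-dataset level, computed before
rarefaction, and filtering precedes rarefaction. Rarefaction is a
single multivariate-hypergeometric draw per sample (subsampling reads
without replacement) to a common depth — by default the minimum sample
sum; samples below the depth are dropped with a warning rather than
padded. Taxa left with zero counts are re-dropped after rarefaction.

## Hill-number diversity

`hill_number` implements the effective number of taxa for q = 0
(richness), q = 1 (exp of Shannon entropy, natural log — the Hill
definition is base-free after exponentiation) and q = 2 (inverse
Simpson concentration). Seasonal curves work on incidence data, with
the replicate samples of a group as sampling units.

*Interpolation* is defined as the expectation of the Hill number under
hypergeometric subsampling of units. For q = 0 this has the standard
closed form through expected incidence-frequency counts. For q = 1, 2
the frequency-count plug-in has a Jensen gap, so when the number of
subsets C(T, t) is at most 20,000 the expectation is computed exactly
by enumeration (the study-scale designs with ≤ 10 units always hit
this path); larger designs fall back to the plug-in.

*Extrapolation* for q = 0 uses the Chao2 estimator of undetected taxa
with its geometric approach to the asymptote. For q = 1, 2 the curve
approaches asymptotic estimates — exp of a singleton/doubleton
bias-corrected Shannon entropy of the incidence frequencies, and a
bias-corrected inverse Simpson — along the same geometric form; with
no singletons the curve stays flat at the observed value. Uncertainty
is a percentile band from resampling sampling units with replacement
(200 replicates by default); analytic variance formulas are not used.

## Composition tests

Bray–Curtis dissimilarity is computed on rarefied counts (not relative
abundances; rarefaction already equalises depths). One-factor PERMANOVA
partitions squared distances (SS_total = Σ d²/N; within-group sums
normalised by group size); R² = SS_between/SS_total; p-values come from
seeded label permutations with p = (1 + #{F* ≥ F})/(n_perm + 1), 999
permutations by default. ANOSIM ranks all pairwise distances (average
ties) and uses R = (mean between-rank − mean within-rank)/(M/2).
Both are implemented in-package so the permutation stream is explicit
and reproducible; the scikit-bio implementations serve as independent
oracles in the test suite. No strata or multi-factor designs: the
factors of interest (site, season) are tested separately.

NMDS minimises Kruskal stress-1 by SMACOF majorization alternated with
isotonic regression of configuration distances on the input
dissimilarities. Tied dissimilarities share a fitted disparity
(secondary tie treatment). Defaults: 20 random starts, ≤ 200
iterations per start, convergence when the stress decrease falls below
1e-6 (or stress < 1e-4, an essentially perfect fit); the recorded
stress trajectory is non-increasing and the best start is returned,
with a warning flag if unconverged.

## Sloan neutral community model

Predicted occupancy of a taxon with mean relative abundance p is
`1 − B(d; Nm·p, Nm·(1−p))`, the survival function of the beta
approximation to the local abundance distribution, evaluated at the
detection limit d = 1/depth (one read at the rarefied depth). Nm is
fitted by nonlinear least squares of observed occupancy on this curve,
via bounded scalar search on log Nm ∈ [0, log 10⁷] with 5 restarts
(SSE tolerance 1e-8); R² = 1 − SSE/SST about the mean occupancy and
may be negative on pathological data. Per-taxon 95% Wilson score
binomial bands are placed around the predicted occupancy at the
group's sample count; occupancy above/below the band labels the taxon
*above*/*below*, read as candidate plant selection / dispersal
limitation. Deviation direction is assessed on occupancy only.
Bootstrap intervals for Nm and R² resample taxa with replacement
(1,000 replicates by default; bootstrap refits use a single looser
search, the point fit keeps the multistart). Cross-season persistence
counts, per taxon and direction, the seasons whose fit carries that
label (taxa missing from a season count as non-deviating); a count
equal to the number of seasons (4) flags the taxon persistent.

**Known limitation — threshold-detection bias.** The step detection
1[x > 1/depth] underlying the beta survival function is an
approximation to the true sampling detection probability
1 − (1 − x)^depth. Fitting the approximation to communities whose
counts really are multinomial draws (as in the synthetic generator)
overestimates Nm by roughly 20% at Nm = 500 and depth 10⁴, stably
across pool shapes; fitting the exact Dirichlet-multinomial expected
occupancy instead recovers Nm within a few percent. The package keeps
the field-standard threshold form — its occupancy *labels* are driven
by the band around the fitted curve and are insensitive to this bias —
but absolute Nm values should be read as the conventional estimator's
output, not as unbiased migration estimates.

## Raup–Crick index

Samples are reduced to presence/absence. For each pair, null samples
of the two observed richnesses are drawn without replacement from the
regional pool — all taxa of the analysis table, with selection
probability proportional to occurrence frequency by default (a
uniform null is available for sensitivity analysis); draws use the
Gumbel-top-k trick for vectorised weighted sampling. With SS the
number of shared taxa, `RCI = 2·[#(SS* < SS) + ½·#(SS* = SS)]/n_reps − 1`
(ties at half weight), with 999 replicates by default. The stochastic
fraction is the proportion of (optionally within-group, e.g.
within-season) pairs with |RCI| < 0.95. The pool is scoped to the
table passed in — per site × tissue, pooled over seasons, in the
pipeline — and pool scope is a parameter. Abundance-weighted
Raup–Crick and phylogenetic nulls are out of scope.

## Co-occurrence networks

Within each site × tissue × season slice (n = 5 replicates), all
unordered taxon pairs are tested by Spearman correlation of abundance
vectors; zero-variance taxa are skipped. Edges require |ρ| > 0.8 and
p < 0.01. `spearman_test` provides an exact two-sided p by full
enumeration of the n! rank permutations for n ≤ 9 without ties, and a
t-approximation otherwise. The network stage defaults to the
t-approximation: on tied count data that is what cor.test-style
testing falls back to, and at n = 5 the exact two-sided p for a
perfect correlation is 2/120 ≈ 0.017, which would make the p < 0.01
gate unreachable even for |ρ| = 1 — under the t-approximation the gate
is passable exactly at |ρ| = 1, making the edge criterion coherent at
this design's replication.

Edge identity across seasons is the unordered taxon pair plus the
correlation sign (a positive and a negative association are different
relationships; a flag relaxes this). Associations present in ≥ 2 of
the 4 seasonal networks form the combined persistence network, whose
nodes are exactly the endpoints of kept edges; the kept ratio (edges
in ≥ 2 seasons vs ≥ 1 season) is reported. Kingdoms (bacteria/fungi)
are networked separately per site × tissue by default.

Properties: edge density uses the ordered-pair denominator
E/(V(V−1)) — the convention that reproduces the published reference
densities from their own node/edge counts, locked in by a regression
test; transitivity is the global clustering coefficient; diameter is
the longest finite shortest path over connected pairs; centralizations
are Freeman-style Σ(c_max − c_i) normalised by the star-graph maximum
for closeness ((V−1)(V−2)/(2V−3), closeness over reachable pairs),
eigenvector (V−1, centralities scaled to max 1) and unnormalised
betweenness ((V−1)²(V−2)/2) — conventions verified against
python-igraph on connected graphs. Network structural dissimilarity is
the Jaccard distance on edge-identity sets (the published comparison's
reference method is not identifiable, so this transparent set-based
distance is the package's stated choice), and panels of networks are
ordinated by NMDS on that distance. Nodes can be annotated as rare
when their group-level mean relative abundance is below 0.005.

## Synthetic study generator

The generator emulates the target survey design: 2 sites × 2
tissues × 4 seasons × 5 replicates, 300 taxa, 7,500 reads per sample.
The metacommunity pool is lognormal (μ = 0, σ = 1.5 — a realistic
rank-abundance skew for amplicon surveys; a log-series option exists),
with seasonal pools drifting by 10% multiplicative lognormal jitter
(clipped at 3σ) so season is a mild, not dominant, factor. Local
communities are Dirichlet(Nm·p) compositions with multinomial counts
at depth — the exact finite counterpart of the Sloan beta
approximation, with Nm = 500 by default, so estimator tests are
internally consistent up to the detection-threshold bias noted above.

Planted ground truth, applied in the order: limited zeroing → pair
rewrite → selected injection → exact renormalisation to depth (using
only unplanted taxa):

* *selected taxa* (8, drawn from the rare pool tail) are forced
  present in every sample with a floor of 9 reads — high enough to
  survive the dataset-wide 0.001 relative-abundance filter and to keep
  occupancy at 1 through rarefaction, low enough that their neutral
  predicted occupancy stays clearly below 1;
* *limited taxa* (8, from the abundant head) are zeroed in 60% of each
  group's samples, putting their occupancy below the band around a
  predicted occupancy near 1;
* *correlated pairs* (8 pairs from rare taxa, matching the observation
  that persistently networked endophytes are rare) have their counts
  rewritten in active seasons as monotone transforms of a shared
  latent sample factor (distinct values 10–50, so Spearman ρ is
  exactly ±1), and are zeroed outside their active seasons: planted
  pair taxa are seasonal specialists, which makes the manifest's
  "active seasons" an exact description — sparse background counts
  would otherwise fake perfect tied-rank correlations in off seasons.
  Five pairs are active in ≥ 2 seasons (recoverable by the combined
  network), three in exactly one (must be excluded).

Every planted truth is written to a manifest for recovery scoring.

**What the synthetic tests do not show.** The generator has no
compositional covariance beyond the planted pairs, no phylogenetic or
taxonomic structure, no cross-kingdom coupling, no sequencing-error or
chimera artefacts, and seasonal drift is memoryless. Passing recovery
tests therefore demonstrates the pipeline's statistical machinery and
bookkeeping, not robustness to the full messiness of real amplicon
data.

## Pipeline and reproducibility

The pipeline runs load/simulate → filter → rarefy → diversity → beta
tests → NCM + persistence → Raup–Crick → networks, writing TSV/JSON
artefacts and a summary index. Every stochastic stage derives its seed
from the global seed and the stage name by SHA-256 hashing (seeds
< 2³¹), so adding a stage never perturbs another stage's stream and
identical configurations are bit-identical. Network edges apply the
raw p < 0.01 gate with no multiple-testing correction by default
(matching the convention the thresholds come from); a
Benjamini–Hochberg flag is available. Problem sizes in the test suite
(e.g. 50 recovery runs, 1,000 calibration simulations, 20 recovery
seeds) are chosen to give stable rates at desk scale.
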