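# Methods

This note records the models, conventions and numerical choices behind
`macrogd`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Record filtering

A specimen record survives filtering iff, after trimming leading and
trailing gap runs, its non-gap length lies in [400, 800] (removal bounds
are strict: ">800" and "<400"), it carries coordinates inside valid
WGS84 ranges, and it does not belong to a listed invasive taxon observed
on ≥ 2 continents in the data.  `N` counts as a base for length purposes
(it is an ambiguous base, not a gap); only `-` is a gap character.  The
rules are conjunctive, so the retained set is order-independent; for the
per-rule counts in the filter report, a record is attributed to the first
matching rule in the order too_long → too_short → ungeoreferenced →
invasive → duplicate_record.  Invasiveness requires both list membership
(species name or OTU id) and multi-continent presence because many listed
taxa are invasive only outside their native continent; continent labels
come from the record metadata.

## Gridding

The Behrmann projection (cylindrical equal-area, standard parallel 30°)
is computed in closed form on the authalic sphere (R = 6 371 007.181 m):
x = Rλcos30°, y = R sinφ/cos30°.  Cell sizes 96.5, 193 and 385.9 km are
1°, 2° and 4° of longitude at 30°N.  Cells are half-open
[x0, x0+w) × [y0, y0+w) squares anchored at projected (0, 0), so cell
boundaries pass through the equator and prime meridian; a point on a
shared edge belongs to the +x/+y cell.  The anchor and the edge
convention are not dictated by anything upstream — results for points
exactly on cell boundaries depend on them, which is why they are fixed
and documented.  A cell's continent (used for stratified splitting) is
the majority continent of its records.

## Diversity metrics

Nucleotide diversity is the mean over unordered sequence pairs of
(mismatches / comparable sites), where a site is comparable for a pair
only if both sequences carry A/C/G/T there (pairwise deletion; ambiguity
codes never count as match or mismatch).  Each pair is normalized by its
own comparable-site count because trimmed barcode fragments differ in
coverage; a pair with zero comparable sites is excluded from the pair
count and logged.  Accumulation uses `math.fsum`, so the result is the
correctly rounded mean regardless of pair enumeration order.  A single
sequence carries no observable diversity (π := 0 where a collapsed sample
has one haplotype).

Per cell, OTUs need ≥ 3 copies (`min_copies`) and cells ≥ `min_otus`
OTUs (menu: 10, 25, 50, 100, 150, 200; the pipeline default is 10,
matched to the desk-scale synthetic worlds — on a global barcode
compilation the threshold-sweep tool exists precisely to pick this value
by prediction bias/precision).

GDM is the arithmetic mean of per-OTU π, reported raw and square-root
transformed; the transform is applied for all downstream statistics
because raw GDM is strongly zero-skewed.  GDE is exp(H)/N with H the
Shannon entropy of the normalized proportions p_i = π_i/Σπ_j and N the
OTU richness.  Normalizing to proportions is the Hill-number reading: it
is the only convention under which exp(H) ≤ N, hence GDE ∈ (0, 1], and
richness correction is meaningful.  A literal variant that applies the
entropy to raw π values (not bounded by 1) is available via
`literal_evenness` for comparison; no claim is made about which variant
any previously deposited table used.  Zero-π OTUs contribute p = 0 with
0·ln 0 := 0 — they reduce GDE through N but not through H.  A cell whose
OTUs are all monomorphic has undefined evenness and returns NaN with a
flag; downstream statistics drop such cells with a logged count rather
than inventing a value.

## Spatially corrected statistics

The modified t-test estimates each variable's spatial covariance matrix
from distance-class autocovariances (13 equal-count classes of the
pairwise distance distribution by default, config-exposed) and derives
the effective sample size

  M̂ = 1 + tr(BΣ̂x)·tr(BΣ̂y) / tr(BΣ̂x B Σ̂y),   B = I − J/n,

which equals n exactly for white noise and shrinks under autocorrelation;
F = (M̂−2)r²/(1−r²) is referred to F(1, M̂−2) with fractional dof.  If the
denominator trace degenerates (≤ 0), the correction falls back to M̂ = n.
Simulation behavior: iid nulls give mean dof ≈ 95 at n = 100 and nominal
α; two independent fields with exponential covariance (range 400 over a
1000-unit domain) give naive Pearson rejection > 0.4 while the corrected
test stays near 0.05.

Moran's I uses row-standardized k-nearest weights (k = 8 default; inverse
distance or a user matrix are alternatives — the weight scheme is a free
choice and is config-exposed) with a one-sided (greater) permutation
p-value (1 + #{I* ≥ I})/(B + 1).  Latitude tests regress the response on
absolute latitude (linear) and squared latitude (quadratic) through the
modified t-test; a subtropical hump symmetric about the equator yields a
negative quadratic correlation.

## Environmental model

Eleven-plus named predictors (temperature/precipitation extremes and
seasonality, habitat heterogeneity, human modification, and four
glacial-cycle climate-stability metrics) are pruned at |r| > 0.75 by
greedy removal of the lower-priority member of the worst pair, then
z-scored with training-set moments (sample sd, ddof = 1 — the convention
of R's `scale`).  The train/test split is 75/25 stratified by continent
with round-half-up training counts per stratum; single-cell strata go to
training with a warning.  The freeze indicator is MTCM ≤ 0 °C.

The regression model is

  y_i = α + x_i'β + w(s_i) + ε_i,  ε ~ N(0, σ²),

with w a knot-based predictive-process Gaussian field, exponential
correlation exp(−d/ρ), scaled by a heavy-tail mixture:
w | λ ~ GP(0, λ·s²·C) and λ ~ InvGamma(ν/2, ν/2), so the field is
marginally multivariate-t with ν degrees of freedom — regional outliers
inflate λ rather than distorting β.  Priors: β ~ N(0, 0.1), α ~ N(0, 5),
σ and s half-Normal(0, 1), log ρ normal around the log median inter-knot
distance (sd 1), ν − 2 ~ Gamma(2, 0.1).  These scales assume a response
of magnitude ~1 or less (sqrt-GDM, GDE) and standardized predictors.

Inference exploits the model's conditional structure: (α, β, knot values)
are jointly Gaussian given the five hyperparameters and are integrated
out analytically; the hyperparameters (log ρ, log τ, log σ, log(ν−2),
log λ, with τ = s√λ the effective field scale, a reparameterization that
removes a likelihood ridge) are sampled with an affine-invariant ensemble
sampler using differential-evolution moves (20 walkers × 1600 steps, 700
burn-in by default).  Per retained hyperparameter draw, (α, β, w) and
hence Bayesian R² = var(α+Xβ+w)/(var(α+Xβ+w)+σ²) are drawn exactly from
the conditional Gaussian.  Convergence is monitored with rank-normalized
split R-hat and bulk ESS over walkers; fits with max R-hat > 1.05 are
flagged and prediction refuses them unless explicitly overridden.

Knots default to 40 k-means centers of the training coordinates.  With
substantially fewer knots than field degrees of freedom the low-rank
approximation under-represents the field and the unexplained variance
leaks into σ (a known predictive-process artifact; at 25 knots on the
validation worlds σ̂ inflated ~70%); 40 knots keeps that leak small at a
few hundred cells while the likelihood stays O(n³ + nm²) per evaluation.

Variable selection is a forward search on K-fold (K = 5) cross-validated
expected log predictive density under a conjugate Gaussian ridge with the
same slope prior, the fold assignment fixed for the whole search so every
gain is a paired comparison, and the plug-in residual scale iterated to a
fixed point (a one-pass estimate over-shrinks strong slopes and makes
duplicated predictors look informative).  The search stops when the best
gain falls below 2 nats — about one parameter's worth of overfit — so
pure-noise candidates terminate it.  This is a cross-validation stand-in
for reference-model projection selection: same goal (the smallest model
with near-full predictive power), different search.

Prior–posterior overlap is ∫min(prior pdf, posterior KDE) per parameter,
in percent; parameters with low overlap are data-identified.  Predictions
at new cells krige the field from the knot values per posterior draw and
are summarized by median and 95% highest-density interval; residual noise
is excluded from map predictions by default (the map shows the mean
surface).  Test-set bias/precision is the OLS slope/intercept plus R² and
RMSE of observed against predicted — slope near 1 and intercept near 0
indicate unbiased prediction, and this is the criterion the threshold
sweep reports per minimum-OTU threshold.

## MESS masking

For each variable, with f the percentage of reference values strictly
below the candidate value: f = 0 → 100(v−min)/(max−min); 0 < f ≤ 50 → 2f;
50 < f < 100 → 2(100−f); f = 100 → 100(max−v)/(max−min).  The surface
value is the minimum over variables and cells with MESS < 0 (outside the
training range in at least one variable) are masked in map columns while
remaining in tables with a flag.  Ties count as "below" at half weight
only if `tie_half_weight` is enabled (reference implementations differ;
off by default).  A degenerate reference (min = max) scores 0 at the
constant and goes negative away from it with the zero range replaced by
1.0 in the out-of-range branches.  S is piecewise linear in v with steps
of 2·(100/n) at reference points — continuity across the formula branches
holds up to that empirical-f granularity.

## Coalescent simulator and the duplicate-allele experiment

The simulator is Hudson's single-population algorithm: coalescence times
Exp(k(k−1)/2) in units of Ne generations, mutations Poisson per site
along branches, Jukes–Cantor substitution on a finite sequence.  A site
hit m times transitions with the exact m-step JC kernel
(stay-probability 1/4 + (3/4)(−1/3)^m), so multiple hits need no
per-mutation loop.  Expected pairwise diversity is θ = 2·Ne·μ per site,
less the JC multiple-hit deficit of order θ² — at the calibration values
(θ ≤ 0.01, L = 500, 2000 replicates) that deficit is within the
Monte-Carlo 3-SE band, which is exactly what the calibration test
asserts.  Finite sites rather than infinite sites is deliberate:
diversity is computed from sequence mismatches exactly as for real data,
and saturation at high θ is part of the model.  The simulator never emits
gaps or ambiguity codes.

The duplicate-allele experiment asks how much diversity estimates move if
duplicate haplotypes are dropped before computing π (as some repository
submissions do).  Defaults: 10 samples, L = 600, μ = 5×10⁻⁴ per site per
generation, 200 replicates, Ne ∈ {10³, 10⁴, 10⁵, 10⁶}.  μ is chosen from
the closed-form marginal P(a sampled pair is identical) = 1/(1+θ_locus):
at Ne = 10³ (θ_locus = 600) roughly 7% of replicates contain a duplicate
haplotype — the biased regime — while at Ne ≥ 10⁵ (θ_locus ≥ 6×10⁴) the
expected number of duplicate-containing replicates across the whole
experiment is ≤ 0.15, so the bias is structurally zero there.  The
per-site mutation rate is far above any real mitochondrial rate; it is a
scaling device that walks the experiment across the duplicate-rich to
duplicate-free regimes within a practical Ne grid, and only the
θ-structure matters for the question.  Note one subtlety: the inequality
GD_unique ≥ GD_all holds in expectation and almost always, but it is not
a per-replicate theorem — GD_all is the copy-weighted mean over haplotype
pairs and GD_unique the unweighted mean, so a duplicated haplotype lying
unusually far from the rest of the sample can make the unique-only value
smaller.  At the default settings this occurs in roughly one replicate in
two hundred at the smallest Ne.

## Synthetic worlds

`generate_world` emits a BOLD-schema table, per-OTU-per-cell alignments,
an environment table and a truth record.  Environments are independent
unit-variance Gaussian fields with exponential covariance (range 600 km
by default) over cell centroids, de-standardized to physical-looking
units; MTCM straddles 0 °C so both freeze classes occur.  The planted
cell target on the sqrt-GDM scale is intercept (0.15) + slopes on
standardized predictors (+0.03 MTWM, −0.02 precipitation seasonality,
+0.02 temperature trend) + a spatial field (sd 0.01) + iid noise
(sd 0.01), floored at 0.02; per-OTU θ scatters around the squared target
with a mean-one log-normal multiplier (log-sd 0.6).  Records are placed
uniformly inside their cell and assigned orders with barcode-survey
prevalence weights (Diptera 34%, Lepidoptera 32%, Hymenoptera 17%, …).
Default world size (6×6 cells × 30 OTUs × 5 copies) is a desk-scale
stand-in for a global compilation — three orders of magnitude smaller,
chosen so a full pipeline run with regression completes in seconds while
every structural feature (filters, gridding, thresholds, planted slopes,
freeze classes, continents) is exercised.

What the generator does *not* emulate: real BOLD sampling is wildly
uneven across space and taxa (the generator is balanced per cell);
alignments are emitted gap-free, so pairwise deletion is exercised by
unit fixtures rather than by the world; OTU boundaries are exact (no BIN
splitting/lumping); environments are independent fields, not a
correlated climate system (collinearity pruning is exercised separately);
and per-OTU θ is drawn around the cell target rather than emerging from
range dynamics.  Passing end-to-end tests therefore demonstrates
correctness of the computation chain on data with known structure, not
robustness to every pathology of real barcode compilations.

`simulate_cell_world` skips the sequence layer for regression
experiments: standardized iid predictors, a planted spatial field and iid
noise.  The recovery experiments use slopes (0.5, −0.3, 0) at 200 cells
with field sd 0.25 (range 800 km over a 4000 km domain) and noise sd 0.1.
The noise share is deliberately small: a cell-level diversity summary
averages tens to thousands of OTUs, so its iid sampling error is a minor
variance component relative to spatially structured environmental and
historical effects — and with a regularizing N(0, 0.1) slope prior,
planted slopes five prior-sd from zero are recovered without the prior
shrinkage dominating only when the likelihood is this informative.

## Determinism and problem sizes

Every stochastic component takes a seed; worlds spawn per-purpose
sub-streams from one master `SeedSequence`, the pipeline derives stage
seeds from its config seed, and repeated runs are byte-identical at the
CSV level.  Test-suite and validation problem sizes (200-cell regression
worlds, 10 replicates, 300–500 simulation nulls, 2000 coalescent
calibration replicates) were chosen as the smallest sizes at which the
targeted effects are resolved with comfortable Monte-Carlo margins.
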