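# Methods

## The model

`edith` infers reach-resolved taxon distributions in a river catchment from
eDNA metabarcoding read counts measured in water samples. The chain of
reasoning is: organisms shed DNA in proportion to their local density; the
DNA is advected downstream and depleted (degradation plus deposition,
lumped) with first-order kinetics; a water sample therefore integrates the
shedding of the whole upstream network, weighted by decay in transit and
diluted by discharge.

The spatial unit is the *reach*: a stream segment from a source or
confluence to the next confluence or the outlet, treated as a node of a
rooted tree with edges following flow. For a sampling site on reach *j*,
the expected read number is

    N̂_j = (1 / Q_j) Σ_{i ∈ γ(j)} A_S,i · exp(−L_ij / (v_ij τ)) · p0' · exp(βᵀX(i))

where γ(j) is the set of reaches draining to *j* (including *j*), A_S,i =
L_i·w_i is the source area of reach *i* (length times width), L_ij and v_ij
are the along-stream path length and the travel-time-consistent mean
velocity from *i* to *j* (both endpoints included; v_ij = ΣL_k / Σ(L_k/v_k)),
τ is the decay time, Q_j the discharge at *j*, X(i) the z-scored covariate
vector of reach *i*, β the covariate effects, and p0' an effective
production rate that absorbs the unknown read-conversion constant. Because
that constant is unidentifiable, the package reports *relative* density
k·p_i ∝ p0'·exp(βᵀX(i)), never absolute density.

Replicate read counts at a site are modelled as geometric on {0, 1, 2, …}
with mean N̂_j (success probability 1/(1+N̂_j)): a one-parameter, zero-mode
count law with tails fat enough to accommodate the occasional very large
read number typical of metabarcoding data.

Detection probability of reach *i* treats it as unplugged from the network:
N̂_U,i = p'_i·(A_S,i/q_i)·exp(−L_i/(v_i τ)) with q_i the locally contributed
discharge, and P_D,i = N̂_U,i/(1+N̂_U,i), the chance of a nonzero geometric
count. Presence is called at P_D,i ≥ 2/3 (inclusive), and summing presence
maps over taxa gives richness.

## Network construction and hydraulics

Networks come either from a reach table or from a DEM (ESRI ASCII). The
raster pipeline is: priority-flood depression filling with an epsilon
gradient (fills pits to their spill level and drains flats toward their
outlet in one pass), D8 steepest-descent directions (drop per unit
distance; ties resolved by the fixed scan order E, SE, S, SW, W, NW, N,
NE), flow accumulation, and channelization of cells above an accumulation
threshold (800 cells ≈ 0.5 km² on a 25-m grid is a typical choice).
Reach length is measured along the pixel path (cardinal steps = cell size,
diagonal = cell size·√2), including the step into the downstream reach's
first cell; the confluence pixel belongs to the downstream (stem) reach,
and the outlet reach counts its outlet cell so every reach has positive
length. Drainage area is the accumulation at the reach's most downstream
cell times the cell area.

Hydraulic variables follow power laws of drainage area fitted by ordinary
least squares in log–log space (the standard estimator of downstream
hydraulic geometry). The bundled default laws are Q = 0.072·A^1.056,
w = 1.586·A^0.526, D = 0.073·A^0.463 (A in km², SI units), and rectangular
cross-sections give v = Q/(D·w) = 0.623·A^0.067. Local discharge is
q_i = Q_i − Σ upstream Q; a sub-linear Q law can make this negative at
confluences, in which case q is clamped to zero, flagged per reach, and a
warning emitted (conservation Q_i = Σ_{k∈γ(i)} q_k then holds only
approximately at the flagged reaches). Station inclusion in the fits is
caller-controlled (the CLI exposes `--exclude-station`) rather than
hard-coded, since which gauges are trustworthy is a data judgment.

## Covariates

Covariates are `local`, `upstream` (averaged over γ(i)), or `geographic`
0/1 cluster dummies. Upstream averaging at reach granularity weights each
reach by its locally contributed drainage area (the limit of averaging the
underlying raster over the upstream catchment); an unweighted mean is also
available since raster-level sources differ in convention. Z-scoring uses
the population standard deviation (any consistent convention works; this
one is fixed for reproducibility) and stores per-column statistics so new
reaches can be transformed identically. The collinearity screen (max |r|
and VIFs with one dummy removed, since a full dummy set is exactly
collinear) is advisory: it reports, it never drops columns from the fit.
VIFs are computed from per-column regressions on all remaining columns;
singular designs report infinite VIF instead of crashing.

## Calibration

Priors: β ~ N(0, 9·I); ln τ ~ N(9, 0.5) with τ in seconds (mean 2.55 h,
sd 1.36 h); p0' uniform on (0, 10⁶) in expected-read units — effectively
flat but proper; the fit flags a posterior piling against the bound.

The sampler is a single adaptive Metropolis chain in (β, ln p0', ln τ) —
the positive parameters are proposed on the log scale, with the Jacobian
added to the target so the posterior is over natural-scale parameters.
Proposal covariance: diagonal (0.1 × prior scale)² until adaptation starts
(after max(10·d, 100) iterations), then s_d·(Σ̂ + 10⁻⁹·diag(scale²)) with
s_d = 2.38²/d and Σ̂ the recursively updated empirical covariance of the
whole history. Two standard safeguards are built in: 5% of proposals always
use the fixed initial kernel (so a collapsed adapted covariance cannot
freeze the chain), and a Robbins–Monro update of a global log-scale factor
(step (t−t₀)^−0.6, target acceptance 0.234) runs during burn-in only, so
adaptation diminishes and the retained chain targets the exact posterior.
Default chain lengths are burn 5000 / keep 10000; cross-validation refits
use burn 1000 / keep 5000. Chains are initialized overdispersed
(β ~ N(0, 0.5²), ln p0' ~ N(0, 1), ln τ ~ N(9, 0.5²), re-drawn until the
posterior is finite) and are bit-reproducible given a seed. A chain that
accepts no move after burn-in raises an error rather than returning
garbage.

Summaries are medians and 95% equal-tailed intervals; a covariate effect is
*positive* (*negative*) when its whole interval lies above (below) zero,
otherwise non-significant. Prediction maps use posterior-median parameters.

The site-level forward evaluation inside the likelihood uses the exact
factorisation exp(−L_ij/(v_ij τ)) = exp(−(t_out(i) − t_out(j) + t_j)/τ),
with t_out the travel time to the outlet, which turns each evaluation into
a masked matrix–vector product with no per-iteration graph traversal. The
O(n) downstream-accumulation recursion and a brute-force enumeration over
all source–site paths are kept as independent routes; the test suite
requires all three to agree to 10⁻¹⁰ relative.

## Goodness of fit

Because the geometric law has no classical GOF test for triplets, a
bootstrap test on ordered Pearson residuals is used. For site *j* with
prediction N̂_j and R replicates: s_j = sqrt(Σ_o (N_jo − N̂_j)²) — note the
deviations are taken from the *predicted* mean with no R−1 factor — and
r_jo = (N_jo − N̂_j)/s_j. H bootstrap replicate sets are drawn from
Geom(mean N̂_j); their ordered residuals give per-rank medians r̃_o^(50);
d_j = Σ_o (r_(o) − r̃_o^(50))² is compared against the bootstrap
distribution of the same statistic, and p = (1 + #{d̃ ≥ d_j})/(1 + H), so
p ∈ [1/(1+H), 1]. Degenerate sites with s_j = 0 (every replicate equal to
the predicted mean — in practice all-zero data with N̂_j ≈ 0) are trivially
consistent: p = 1, flagged. H defaults to 10⁵; the tests use 2·10³, which
is ample for a 5% threshold. The per-taxon summary is the fraction of sites
with p > 0.05.

## Cross-validation

To quantify the effect of calibration sample size, the model is refit on
subsets of sites. Subsets preserve the stream-order distribution of the
full site set: the number of *excluded* sites per order is fixed by
D'Hondt highest-quotients allocation (ties to the larger stratum, then the
lower index), and excluded sites are drawn uniformly within each order,
seeded. Calibration size is ceil(fraction·n) — e.g. 49, 37 and 25 of 61
sites at fractions 0.8, 0.6, 0.4. Losses are reported as (complete-model
value − subset-model value)·100, so positive means degradation, separately
on all sites, the calibration subset and the validation subset (= all
sites not used for fitting); by construction the all-sites loss equals the
subset-size-weighted average of the other two, and the suite asserts the
identity exactly. A degenerate fraction of 1.0 reuses the complete model
and yields zero loss.

## Synthetic test bed

The generators produce data with exactly the statistical structure the
model assumes, so end-to-end recovery is a meaningful check of the
machinery rather than of nature. Tree-mode networks are random recursive
trees with lognormal reach lengths (median 0.78 km, log-sd 0.8, matching
the scale of a mid-size pre-alpine catchment discretization) and lognormal
local areas (median 0.5 km², the channelization threshold); DEM mode runs
the full raster pipeline on an inclined plane with smoothed noise.
Covariates are Gaussian fields smoothed along the tree (4 rounds of
neighbor blending by default; 0 rounds gives i.i.d. fields). Sites are
placed stream-order proportionally via D'Hondt. Reads are geometric draws
with the forward-model mean.

The default scenario is 150 reaches, 40 sites, 6 covariates, 3 replicates,
with planted effects +2/−2 on two covariates, τ = 5400 s and p0' = 2·10⁻⁴.
That p0' makes expected reads span roughly 0.5–100 across sites with
~20–35% zero counts: informative but noisy data, chosen once as a realistic
operating point for metabarcoding counts. A full
simulate–calibrate–evaluate cycle at this scale runs in a few seconds, so
the recovery study uses 20 independent replicates.

What the generators do *not* emulate: PCR amplification bias, chimeras,
tag jumping, replicate-level overdispersion beyond the geometric law,
covariate measurement error, or model misspecification of any kind.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not field validity.

## Numerical choices and degenerate inputs

- All-nodata grids, empty channel sets, cyclic flow fields, unknown
  downstream ids and negative counts raise typed errors early.
- Zero local discharge makes detection probability undefined: NaN, warned,
  and excluded from presence (treated as absent).
- N̂ = 0 with positive observed reads gets a large finite log-likelihood
  sentinel (−10¹²) instead of −inf/NaN so the sampler can always compare
  states.
- Seeds: every stochastic stage takes an explicit seed; derived seeds are
  drawn below 2³¹. Same seed ⇒ bit-identical chains, splits and reads.
- Tolerances: forward-model route agreement 10⁻¹⁰ relative; discharge
  conservation 10⁻⁹ relative; z-scoring round-trip 10⁻¹².

## Known limitations

- D8 routing only; no multiple-flow-direction or vector-hydrography
  support.
- The decay time lumps degradation and deposition; it is a characteristic
  residence time of detectable eDNA, not a biochemical rate.
- Absolute densities are unidentifiable (unknown read-conversion constant);
  only relative densities and detection probabilities are reported.
- Single-chain inference with acceptance-rate diagnostics; no multi-chain
  convergence statistics.
- The geometric read model is the abstraction boundary: sequencing
  mechanics are out of scope.
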