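# edith

**eDNA transport and Bayesian taxon-distribution modelling on river
networks.**

Environmental DNA (eDNA) metabarcoding of river water detects many taxa at
once, but a water sample is not a local measurement: it integrates DNA shed
across the entire upstream catchment, decayed in transit and diluted by
streamflow. `edith` inverts that integration. Given per-site, per-replicate
read counts for a taxon, a reach-discretized river network with hydraulic
geometry, and per-reach environmental covariates, it infers where the taxon
actually lives — producing catchment-wide, reach-resolved maps of relative
density, detection probability, presence and (across taxa) richness. It is
aimed at freshwater ecologists and biomonitoring practitioners who want to
turn point eDNA samples into spatially continuous biodiversity patterns.

## The model

For a sample at reach *j*, the expected read number couples a
species-distribution model with hydrological transport and first-order
decay:

```
N̂_j = (1 / Q_j) · Σ_{i ∈ γ(j)}  A_S,i · exp(−L_ij / (v_ij τ)) · p0′ · exp(βᵀ X(i))
```

- γ(j) — reaches draining to *j*, including *j* itself
- A_S,i = L_i·w_i — eDNA source area of reach *i* (m²)
- L_ij, v_ij — along-stream path length and travel-time-consistent mean
  velocity from *i* to *j*
- τ — eDNA decay time (s); half-life = ln(2)·τ
- β, X(i) — covariate effects and z-scored covariates (exponential link)
- p0′ — effective production rate (absorbs the read-conversion constant)
- Q_j — discharge at *j* (dilution)

Replicate read counts are geometric with mean N̂_j (zero mode, fat tails).
The posterior of (β, p0′, τ) is sampled per taxon with an Adaptive
Metropolis chain under β ~ N(0, 9 I), ln τ ~ N(9, 0.5) (mean 2.55 h) and a
flat prior on p0′. Detection probability of a reach treats it as unplugged
from the network, P_D = N̂_U/(1+N̂_U), and presence is called at
P_D ≥ 2/3. A bootstrap goodness-of-fit test checks the geometric law site
by site, and stream-order-stratified cross-validation (D'Hondt allocation)
quantifies how performance degrades with fewer calibration sites.

Hydraulics come from drainage-area power laws (defaults
Q = 0.072 A^1.056, w = 1.586 A^0.526, D = 0.073 A^0.463, hence
v = 0.623 A^0.067); networks are built from a DEM (D8 routing, accumulation
threshold) or loaded from a reach table. See `docs/methods.md` for the full
account.

## Worked example

```python
import numpy as np
from edith import (ChainSettings, ModelParams, calibrate, place_sites,
                   simulate_reads, synthetic_covariates, synthetic_network)

net = synthetic_network(150, seed=10)          # 150-reach river network
X = synthetic_covariates(net, 6, seed=11)      # 6 z-scored covariate fields
sites = place_sites(net, 40, seed=12)          # 40 stream-order-balanced sites

truth = ModelParams(beta=np.array([2.0, -2.0, 0, 0, 0, 0]),
                    p0_prime=2e-4, tau=5400.0)
reads = simulate_reads(net, X, truth, sites, seed=13)  # geometric triplets

post = calibrate(net, X, reads, settings=ChainSettings(5000, 10000), seed=14)
print(post.summary().round(3))
```

This is `examples/03_calibrate_and_recover.py`; it prints

```
parameter   median   ci_low   ci_high          effect
    cov_0    2.433    2.074     2.760        positive
    cov_1   -2.065   -2.406    -1.697        negative
    cov_2   -0.220   -0.494     0.064 non-significant
    ...
      tau 7418.475 3975.378 19260.915
true tau = 5400 s; posterior median 7418 s, 95% CI [3975, 19261] s
```

The two planted covariate effects (+2 and −2) are recovered with the right
signs and credible intervals excluding zero, and the 95% interval for the
decay time τ brackets the true 5400 s. The other scripts in `examples/`
walk through network extraction from a DEM, forward prediction and richness
mapping, and goodness of fit plus cross-validation; each prints a few lines
and states what they mean.

A thin CLI mirrors the library for shell pipelines:

```
edith simulate --n-reaches 150 --n-sites 40 --seed 1 --out-prefix syn
edith calibrate --network syn_network.csv --covariates syn_covariates.csv \
      --kinds syn_covariates.yaml --reads syn_reads.csv --taxon taxon \
      --out-chain chain.csv --out-summary summary.csv
edith predict --network syn_network.csv --covariates syn_covariates.csv \
      --kinds syn_covariates.yaml --summary summary.csv --out maps.csv
```

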