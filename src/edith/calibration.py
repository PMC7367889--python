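"""Bayesian calibration of (beta, p0', tau) with an Adaptive Metropolis sampler.

Observed read numbers per site and replicate are modelled as geometric on
{0, 1, 2, ...} with mean equal to the model-predicted expected read number
N_hat_j (success probability 1/(1+N_hat_j)): a one-parameter, zero-mode,
fat-tailed count distribution.  Priors: beta ~ N(0, 9 I); ln(tau) ~ N(9, 0.5)
with tau in seconds (prior mean 2.55 h, sd 1.36 h); p0' uniform on
(0, upper bound).  The sampler is a single Haario-style adaptive Metropolis
chain with p0' and tau proposed on the log scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CovariateMatrix
from .forward import ModelParams, SiteReadModel
from .network import RiverNetwork

__all__ = [
    "TaxonReads",
    "Priors",
    "ChainSettings",
    "PosteriorResult",
    "ConvergenceError",
    "log_likelihood",
    "log_prior",
    "adaptive_metropolis",
    "summarize_posterior",
    "calibrate",
]

#: finite stand-in for log(0) likelihood so the sampler can always compare
LOG_ZERO = -1e12


class ConvergenceError(RuntimeError):
    """The chain accepted no moves after burn-in."""


@dataclass
class TaxonReads:
    """Read-count replicates for one taxon: |S| sites x R replicates."""

    site_ids: list[str]
    counts: np.ndarray
    taxon: str = "taxon"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.site_ids):
            raise ValueError("counts must be a sites-by-replicates matrix")
        if np.any(self.counts < 0):
            raise ValueError("read counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("read counts must be integers")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[1]


@dataclass
class Priors:
    """Prior hyperparameters (tau in seconds)."""

    beta_sd: float = 3.0            # N(0, 9) per component
    tau_log_mean: float = 9.0
    tau_log_sd: float = 0.5
    p0_upper: float = 1e6           # uniform (0, p0_upper)

    def __post_init__(self) -> None:
        if min(self.beta_sd, self.tau_log_sd, self.p0_upper) <= 0:
            raise ValueError("prior scales must be positive")

    def tau_mean_seconds(self) -> float:
        return float(np.exp(self.tau_log_mean + self.tau_log_sd**2 / 2))

    def tau_sd_seconds(self) -> float:
        return self.tau_mean_seconds() * float(
            np.sqrt(np.exp(self.tau_log_sd**2) - 1.0))


@dataclass
class ChainSettings:
    """Length and adaptation settings of the Metropolis chain."""

    n_burn: int = 5000
    n_keep: int = 10000
    adapt_start: int | None = None     # default max(10 * dim, 100)
    scale: float | None = None         # default 2.38^2 / dim
    epsilon: float = 1e-9
    init_step: float = 0.1             # initial proposal sd = init_step * scale


#: chain lengths used for the reduced cross-validation fits
CV_SETTINGS = ChainSettings(n_burn=1000, n_keep=5000)


def log_likelihood(reads: TaxonReads, n_hat: np.ndarray) -> float:
    """Geometric log likelihood of the site-replicate count matrix.

    Per site: R * log(1/(1+N_hat)) + (sum of counts) * log(N_hat/(1+N_hat)).
    A site with N_hat = 0 but positive observed counts has zero likelihood;
    a large negative sentinel is returned instead of -inf/NaN.
    """
    n_hat = np.asarray(n_hat, dtype=float)
    if n_hat.shape != (len(reads.site_ids),):
        raise ValueError("one prediction per calibration site required")
    if np.any(n_hat < 0) or np.any(~np.isfinite(n_hat)):
        return LOG_ZERO
    R = reads.n_replicates
    totals = reads.counts.sum(axis=1)
    zero = n_hat == 0
    if np.any(zero & (totals > 0)):
        return LOG_ZERO
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = -R * np.log1p(n_hat) + totals * (np.log(n_hat) - np.log1p(n_hat))
    ll[zero & (totals == 0)] = 0.0
    out = float(ll.sum())
    return out if np.isfinite(out) else LOG_ZERO


def log_prior(params: ModelParams, priors: Priors) -> float:
    """Sum of component log prior densities; -inf outside the support."""
    if not (0.0 < params.p0_prime < priors.p0_upper) or params.tau <= 0:
        return -np.inf
    lp = -0.5 * float(params.beta @ params.beta) / priors.beta_sd**2
    lp -= params.beta.size * np.log(priors.beta_sd * np.sqrt(2 * np.pi))
    z = (np.log(params.tau) - priors.tau_log_mean) / priors.tau_log_sd
    lp += (-0.5 * z * z - np.log(params.tau * priors.tau_log_sd
                                 * np.sqrt(2 * np.pi)))
    lp -= np.log(priors.p0_upper)
    return float(lp)


def adaptive_metropolis(
    log_posterior,
    init: np.ndarray,
    n_burn: int,
    n_keep: int,
    seed: int,
    init_scales: np.ndarray | None = None,
    settings: ChainSettings | None = None,
):
    """Single-chain Haario-style Adaptive Metropolis in R^d.

    The proposal covariance starts diagonal at (init_step * init_scales)^2,
    and after ``adapt_start`` iterations (default 10 d) switches to
    s_d * (empirical covariance + epsilon I) with s_d = 2.38^2 / d, the
    empirical covariance being updated recursively over the whole history.

    Returns ``(samples, acceptance_rate)`` where samples has shape
    (n_keep, d).  Identical seeds give bit-identical chains.
    """
    settings = settings or ChainSettings(n_burn=n_burn, n_keep=n_keep)
    rng = np.random.default_rng(seed)
    x = np.asarray(init, dtype=float).copy()
    d = x.size
    lp = float(log_posterior(x))
    if not np.isfinite(lp):
        raise ValueError("log posterior not finite at the initial state")
    scales = (np.ones(d) if init_scales is None
              else np.asarray(init_scales, dtype=float))
    C0 = np.diag((settings.init_step * scales) ** 2)
    # regularization floor keeps the adapted proposal from collapsing when
    # the early chain history has near-zero variance
    reg = settings.epsilon * np.diag(scales**2)
    sd = settings.scale if settings.scale is not None else 2.38**2 / d
    adapt_start = (settings.adapt_start if settings.adapt_start is not None
                   else max(10 * d, 100))
    mean = x.copy()
    cov = np.zeros((d, d))
    n_total = n_burn + n_keep
    samples = np.empty((n_keep, d))
    accepted_after_burn = 0
    n_seen = 1
    log_s = 0.0  # Robbins-Monro global scale, adapted during burn-in only
    target_acc = 0.234
    for t in range(n_total):
        # 5% of proposals always come from the fixed initial kernel, the
        # standard safeguard against the adapted covariance collapsing
        if t < adapt_start or rng.uniform() < 0.05:
            prop_cov = C0
        else:
            prop_cov = np.exp(log_s) * sd * (cov + reg)
        try:
            step = rng.multivariate_normal(np.zeros(d), prop_cov,
                                           method="cholesky")
        except np.linalg.LinAlgError:
            step = rng.multivariate_normal(np.zeros(d), prop_cov)
        cand = x + step
        lp_cand = float(log_posterior(cand))
        acc_prob = min(1.0, np.exp(min(lp_cand - lp, 0.0)))
        if np.log(rng.uniform()) < lp_cand - lp:
            x = cand
            lp = lp_cand
            if t >= n_burn:
                accepted_after_burn += 1
        if adapt_start <= t < n_burn:
            gamma = (t - adapt_start + 1) ** -0.6
            log_s += gamma * (acc_prob - target_acc)
        # recursive empirical moments over the whole history
        n_seen += 1
        delta = x - mean
        mean += delta / n_seen
        cov += (np.outer(delta, x - mean) - cov) / n_seen
        if t >= n_burn:
            samples[t - n_burn] = x
    if n_keep > 0 and accepted_after_burn == 0:
        raise ConvergenceError("no accepted moves after burn-in")
    return samples, accepted_after_burn / max(n_keep, 1)


@dataclass
class PosteriorResult:
    """Retained chain plus summaries for one taxon fit.

    ``chain`` columns are the natural-scale parameters in ``param_names``
    order (beta components, then p0_prime, then tau).
    """

    param_names: list[str]
    chain: np.ndarray
    burn_in: int
    acceptance_rate: float
    medians: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    effect_class: dict[str, str]
    taxon: str = "taxon"
    p0_at_bound: bool = False

    @property
    def median_params(self) -> ModelParams:
        n_beta = len(self.param_names) - 2
        return ModelParams(
            beta=self.medians[:n_beta],
            p0_prime=float(self.medians[n_beta]),
            tau=float(self.medians[n_beta + 1]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.chain, columns=self.param_names)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "median": self.medians,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "effect": [self.effect_class.get(p, "") for p in self.param_names],
            }
        )


def summarize_posterior(
    chain: np.ndarray, param_names: list[str], beta_names: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, str]]:
    """Medians, 95% equal-tailed intervals and covariate-effect classes.

    A covariate effect is positive (negative) when the whole 95% interval
    lies above (below) zero, otherwise non-significant.
    """
    if chain.size == 0:
        raise ValueError("empty chain")
    medians = np.median(chain, axis=0)
    ci_low = np.percentile(chain, 2.5, axis=0)
    ci_high = np.percentile(chain, 97.5, axis=0)
    effect: dict[str, str] = {}
    for name in beta_names:
        k = param_names.index(name)
        if ci_low[k] > 0:
            effect[name] = "positive"
        elif ci_high[k] < 0:
            effect[name] = "negative"
        else:
            effect[name] = "non-significant"
    return medians, ci_low, ci_high, effect


def _initial_state(n_beta: int, rng: np.random.Generator) -> np.ndarray:
    """Overdispersed random start: beta ~ N(0, 0.25), ln tau ~ N(9, 0.25),
    ln p0' ~ N(0, 1)."""
    beta = rng.normal(0.0, 0.5, size=n_beta)
    log_p0 = rng.normal(0.0, 1.0)
    log_tau = rng.normal(9.0, 0.5)
    return np.concatenate([beta, [log_p0, log_tau]])


def calibrate(
    net: RiverNetwork,
    X: CovariateMatrix | np.ndarray,
    reads: TaxonReads,
    priors: Priors | None = None,
    settings: ChainSettings | None = None,
    seed: int = 0,
) -> PosteriorResult:
    """Fit the taxon model by Adaptive Metropolis on (beta, ln p0', ln tau).

    Positivity-constrained parameters are proposed on the log scale; the
    corresponding Jacobian terms are included in the target so the posterior
    is over the natural-scale parameters.
    """
    priors = priors or Priors()
    settings = settings or ChainSettings()
    model = SiteReadModel(net, X, reads.site_ids)
    n_beta = model.X.shape[1]
    beta_names = [f"beta_{k}" for k in range(n_beta)]
    if isinstance(X, CovariateMatrix):
        beta_names = list(X.names)
    param_names = beta_names + ["p0_prime", "tau"]

    def log_post(theta: np.ndarray) -> float:
        beta = theta[:n_beta]
        log_p0, log_tau = theta[n_beta], theta[n_beta + 1]
        if log_p0 > 700 or log_tau > 700:
            return LOG_ZERO
        p0 = np.exp(log_p0)
        tau = np.exp(log_tau)
        params = ModelParams(beta=beta, p0_prime=p0, tau=tau)
        lp = log_prior(params, priors)
        if not np.isfinite(lp):
            return LOG_ZERO
        n_hat = model.expected(beta, p0, tau)
        # + log Jacobian of the log transforms
        return log_likelihood(reads, n_hat) + lp + log_p0 + log_tau

    rng = np.random.default_rng(seed)
    init = _initial_state(n_beta, rng)
    for _ in range(100):
        if np.isfinite(log_post(init)) and log_post(init) > LOG_ZERO / 2:
            break
        init = _initial_state(n_beta, rng)
    scales = np.concatenate([np.full(n_beta, priors.beta_sd),
                             [1.0, priors.tau_log_sd]])
    samples, acc = adaptive_metropolis(
        log_post,
        init,
        settings.n_burn,
        settings.n_keep,
        seed=int(rng.integers(2**31 - 1)),
        init_scales=scales,
        settings=settings,
    )
    chain = samples.copy()
    chain[:, n_beta] = np.exp(samples[:, n_beta])      # p0_prime
    chain[:, n_beta + 1] = np.exp(samples[:, n_beta + 1])  # tau
    medians, lo, hi, effect = summarize_posterior(chain, param_names, beta_names)
    p0_at_bound = bool(hi[n_beta] > 0.99 * priors.p0_upper)
    return PosteriorResult(
        param_names=param_names,
        chain=chain,
        burn_in=settings.n_burn,
        acceptance_rate=acc,
        medians=medians,
        ci_low=lo,
        ci_high=hi,
        effect_class=effect,
        taxon=reads.taxon,
        p0_at_bound=p0_at_bound,
    )
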