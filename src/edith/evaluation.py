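"""Model evaluation: bootstrap goodness of fit, accuracy, cross-validation.

The goodness-of-fit test asks, site by site, whether the observed replicate
read counts are consistent with a geometric distribution whose mean is the
model-predicted expected read number; it is a bootstrap test on ordered
Pearson residuals.  Cross-validation refits the model on stream-order
stratified subsets of sites (proportionality enforced by D'Hondt allocation)
and reports losses of goodness of fit and accuracy relative to the
complete model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import (
    ChainSettings,
    Priors,
    TaxonReads,
    calibrate,
)
from .covariates import CovariateMatrix
from .forward import (
    PRESENCE_THRESHOLD,
    SiteReadModel,
    detection_probability,
    presence_map,
    unconnected_expected_reads,
)
from .network import RiverNetwork

__all__ = [
    "GofResult",
    "ConfusionCounts",
    "CrossValResult",
    "gof_test",
    "gof_test_sites",
    "accuracy_vs_reference",
    "edna_presence_rule",
    "ks_two_sample",
    "dhondt_allocation",
    "stratified_subsample",
    "cross_validate",
]


# -- goodness of fit ------------------------------------------------------


def _geometric_triplets(rng: np.random.Generator, mean: float,
                        size: tuple[int, int]) -> np.ndarray:
    """Geometric draws on {0, 1, ...} with the given mean."""
    p = 1.0 / (1.0 + mean)
    return rng.geometric(p, size=size) - 1


def gof_test(
    triplet: np.ndarray,
    n_hat: float,
    H: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Bootstrap p-value for 'the replicates are Geom with mean n_hat'.

    The sample standard deviation is taken around the *predicted* mean with
    no n-1 correction, s_j = sqrt(sum_o (N_jo - N_hat)^2); Pearson residuals
    are ordered and compared, through their squared deviation d_j from the
    bootstrap medians of ordered residuals, against the same statistic on H
    bootstrap replicate sets; p = (1 + #{d_tilde >= d_j}) / (1 + H).

    Degenerate data with s_j = 0 (every replicate equal to the predicted
    mean) are trivially consistent and return p = 1.
    """
    obs = np.asarray(triplet, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need at least two replicates")
    if np.any(obs < 0):
        raise ValueError("read counts must be non-negative")
    if not n_hat > 0:
        raise ValueError("n_hat must be positive")
    R = obs.size
    s = math.sqrt(float(((obs - n_hat) ** 2).sum()))
    if s == 0.0:
        return 1.0
    r_obs = np.sort((obs - n_hat) / s)
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = _geometric_triplets(rng, n_hat, (H, R)).astype(float)
    s_boot = np.sqrt(((draws - n_hat) ** 2).sum(axis=1))
    ok = s_boot > 0
    resid = np.zeros_like(draws)
    resid[ok] = (draws[ok] - n_hat) / s_boot[ok, None]
    resid.sort(axis=1)
    r50 = np.median(resid, axis=0)
    d_obs = float(((r_obs - r50) ** 2).sum())
    d_boot = ((resid - r50) ** 2).sum(axis=1)
    return float((1 + int((d_boot >= d_obs).sum())) / (1 + H))


@dataclass
class GofResult:
    """Per-site goodness-of-fit outcomes for one taxon."""

    site_ids: list[str]
    p_values: np.ndarray
    degenerate: np.ndarray  # sites where s_j = 0 (p = 1 by convention)
    alpha: float = 0.05

    @property
    def fraction_not_rejected(self) -> float:
        return float((self.p_values > self.alpha).mean())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_id": self.site_ids, "p_gof": self.p_values,
             "degenerate": self.degenerate}
        )


def gof_test_sites(
    reads: TaxonReads,
    n_hat: np.ndarray,
    H: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> GofResult:
    """Run :func:`gof_test` for every calibration site of one taxon.

    Sites where the predicted mean is not positive are treated as
    degenerate: consistent (p = 1) when all replicates are zero, otherwise
    maximally inconsistent (p at the lower attainable bound).
    """
    n_hat = np.asarray(n_hat, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(reads.site_ids)
    p = np.ones(n)
    degenerate = np.zeros(n, dtype=bool)
    for j in range(n):
        obs = reads.counts[j]
        if not n_hat[j] > 0:
            degenerate[j] = True
            p[j] = 1.0 if obs.sum() == 0 else 1.0 / (1 + H)
            continue
        s = math.sqrt(float(((obs - n_hat[j]) ** 2).sum()))
        if s == 0.0:
            degenerate[j] = True
            p[j] = 1.0
            continue
        p[j] = gof_test(obs, float(n_hat[j]), H=H, rng=rng)
    return GofResult(site_ids=list(reads.site_ids), p_values=p,
                     degenerate=degenerate, alpha=alpha)


# -- accuracy vs reference ------------------------------------------------


@dataclass
class ConfusionCounts:
    """Presence/absence confusion between model and reference sampling."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.total

    @property
    def accuracy_fp_ok(self) -> float:
        """Accuracy when false positives count as plausible (the reference
        method may simply have missed the taxon)."""
        return (self.TP + self.TN + self.FP) / self.total


def accuracy_vs_reference(
    model_presence: np.ndarray, reference_presence: np.ndarray
) -> ConfusionCounts:
    m = np.asarray(model_presence, dtype=bool)
    r = np.asarray(reference_presence, dtype=bool)
    if m.shape != r.shape:
        raise ValueError("model and reference cover different site sets")
    return ConfusionCounts(
        TP=int((m & r).sum()),
        TN=int((~m & ~r).sum()),
        FP=int((m & ~r).sum()),
        FN=int((~m & r).sum()),
    )


def edna_presence_rule(triplet: np.ndarray) -> bool:
    """Raw-data presence call: at least 2 of 3 replicates with nonzero reads
    (generalized to >= ceil(2R/3) nonzero for R replicates)."""
    obs = np.asarray(triplet)
    need = math.ceil(2 * obs.size / 3)
    return bool((obs > 0).sum() >= need)


# -- distribution comparison ---------------------------------------------


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


# -- stratified subsampling -----------------------------------------------


def dhondt_allocation(stratum_counts, n_total: int) -> np.ndarray:
    """Highest-quotients (D'Hondt) proportional allocation.

    Seats are awarded to the largest quotients count/1, count/2, ...; ties
    go first to the larger stratum, then to the lower stratum index.
    """
    counts = np.asarray(stratum_counts, dtype=np.int64)
    if n_total < 0 or np.any(counts < 0):
        raise ValueError("counts and n_total must be non-negative")
    if counts.sum() == 0:
        raise ValueError("at least one stratum must be non-empty")
    alloc = np.zeros(counts.size, dtype=np.int64)
    for _ in range(n_total):
        quotients = counts / (alloc + 1)
        best = max(range(counts.size),
                   key=lambda s: (quotients[s], counts[s], -s))
        alloc[best] += 1
    return alloc


def stratified_subsample(
    site_ids: list[str],
    stream_orders: np.ndarray,
    fraction: float,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Split sites into calibration/validation keeping the calibration
    subset's stream-order distribution proportional to the full set's.

    The calibration size is ceil(fraction * n); the number of *excluded*
    sites per stream order is set by D'Hondt allocation on the stream-order
    counts, and excluded sites are drawn uniformly within each order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    orders = np.asarray(stream_orders)
    if orders.shape != (len(site_ids),):
        raise ValueError("one stream order per site required")
    n = len(site_ids)
    n_cal = math.ceil(fraction * n)
    n_excl = n - n_cal
    levels, counts = np.unique(orders, return_counts=True)
    alloc = dhondt_allocation(counts, n_excl)
    if np.any(alloc > counts):
        raise ValueError("stratum allocation exceeds stratum size")
    rng = np.random.default_rng(seed)
    excluded: list[str] = []
    for level, k in zip(levels, alloc):
        members = [site_ids[i] for i in np.flatnonzero(orders == level)]
        pick = rng.choice(len(members), size=int(k), replace=False)
        excluded.extend(members[i] for i in sorted(pick))
    excluded_set = set(excluded)
    calibration = [s for s in site_ids if s not in excluded_set]
    validation = [s for s in site_ids if s in excluded_set]
    return calibration, validation


# -- cross-validation -----------------------------------------------------


@dataclass
class CrossValResult:
    """Per-simulation losses and a per-group summary (percent vs the
    complete model; positive = degradation)."""

    per_simulation: pd.DataFrame
    per_group: pd.DataFrame


def _gof_fraction(p_values: dict[str, float], subset: list[str],
                  alpha: float) -> float:
    if not subset:
        return float("nan")
    return float(np.mean([p_values[s] > alpha for s in subset]))


def cross_validate(
    net: RiverNetwork,
    X: CovariateMatrix | np.ndarray,
    reads_by_taxon: dict[str, TaxonReads],
    site_orders: dict[str, int],
    fractions=(0.8, 0.6, 0.4),
    n_reps: int = 3,
    settings: ChainSettings | None = None,
    cm_settings: ChainSettings | None = None,
    priors: Priors | None = None,
    H: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    reference: dict[str, dict[str, bool]] | None = None,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> CrossValResult:
    """Stratified cross-validation against the complete model (CM).

    For each subset fraction and repetition, the model is refit per taxon on
    the calibration sites only, goodness of fit is re-evaluated on all
    sites, and losses (CM minus subset model, in percent) are reported on
    the full site set, the calibration subset and the validation subset.
    By construction loss on all sites equals the subset-size-weighted
    average of the calibration and validation losses.
    """
    settings = settings or ChainSettings(n_burn=1000, n_keep=5000)
    cm_settings = cm_settings or settings
    priors = priors or Priors()
    rng = np.random.default_rng(seed)

    def fit_and_gof(reads: TaxonReads, site_subset: list[str], fit_seed: int):
        sub = TaxonReads(
            site_ids=site_subset,
            counts=reads.counts[[reads.site_ids.index(s) for s in site_subset]],
            taxon=reads.taxon,
        )
        chain_settings = cm_settings if len(site_subset) == len(reads.site_ids) \
            else settings
        post = calibrate(net, X, sub, priors=priors, settings=chain_settings,
                         seed=fit_seed)
        params = post.median_params
        model = SiteReadModel(net, X, reads.site_ids)
        n_hat = model.expected(params.beta, params.p0_prime, params.tau)
        gof = gof_test_sites(reads, n_hat, H=H,
                             seed=fit_seed + 1, alpha=alpha)
        pvals = dict(zip(reads.site_ids, gof.p_values))
        acc = float("nan")
        if reference is not None and reads.taxon in reference:
            n_u = unconnected_expected_reads(net, X, params)
            p_d = detection_probability(n_u)
            pres = presence_map(p_d, presence_threshold)
            ref = reference[reads.taxon]
            common = [s for s in reads.site_ids if s in ref]
            model_pres = np.array(
                [pres[net.index(s)] for s in common], dtype=bool)
            ref_pres = np.array([ref[s] for s in common], dtype=bool)
            acc = accuracy_vs_reference(model_pres, ref_pres).accuracy
        return pvals, acc

    site_ids = None
    cm: dict[str, tuple[dict[str, float], float]] = {}
    for taxon, reads in reads_by_taxon.items():
        if site_ids is None:
            site_ids = list(reads.site_ids)
        cm[taxon] = fit_and_gof(reads, list(reads.site_ids),
                                int(rng.integers(2**31 - 1)))
    orders = np.array([site_orders[s] for s in site_ids])

    rows = []
    for gi, fraction in enumerate(fractions):
        for rep in range(n_reps):
            split_seed = int(rng.integers(2**31 - 1))
            calib, valid = stratified_subsample(site_ids, orders, fraction,
                                                seed=split_seed)
            for taxon, reads in reads_by_taxon.items():
                fit_seed = int(rng.integers(2**31 - 1))
                if not valid:  # degenerate full-set "subset" is the CM itself
                    pvals, acc = cm[taxon]
                else:
                    pvals, acc = fit_and_gof(reads, calib, fit_seed)
                cm_pvals, cm_acc = cm[taxon]
                row = {
                    "group": f"AS{gi + 1}",
                    "fraction": fraction,
                    "rep": rep,
                    "taxon": taxon,
                    "n_calibration": len(calib),
                    "n_validation": len(valid),
                }
                for label, subset in (("all", site_ids),
                                      ("calibration", calib),
                                      ("validation", valid)):
                    loss = (_gof_fraction(cm_pvals, subset, alpha)
                            - _gof_fraction(pvals, subset, alpha)) * 100.0
                    row[f"loss_gof_{label}"] = loss
                row["loss_accuracy"] = (cm_acc - acc) * 100.0 \
                    if np.isfinite(acc) else float("nan")
                rows.append(row)
    per_sim = pd.DataFrame(rows)
    per_group = (
        per_sim.groupby("group")[
            ["loss_gof_all", "loss_gof_calibration", "loss_gof_validation",
             "loss_accuracy"]
        ]
        .mean()
        .reset_index()
    )
    return CrossValResult(per_simulation=per_sim, per_group=per_group)
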