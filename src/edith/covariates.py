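"""Per-reach design matrix: upstream averaging, dummies, scaling, screening.

Covariates come in three kinds: ``local`` (value at the reach), ``upstream``
(averaged over the whole catchment draining to the reach, as appropriate for
e.g. geology governing water chemistry) and ``geographic`` 0/1 cluster
indicators that let the model express spatial patterns uncorrelated with any
environmental layer.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import RiverNetwork

__all__ = [
    "CovariateMatrix",
    "CollinearityReport",
    "upstream_average",
    "geographic_dummies",
    "z_normalize",
    "collinearity_screen",
]

KINDS = ("local", "upstream", "geographic")


@dataclass
class CovariateMatrix:
    """Reaches-by-covariates table with per-column kind and scaling stats.

    ``stats`` maps each z-scored column to its (mean, sd) so the identical
    transform can be applied to new reaches or inverted.
    """

    values: pd.DataFrame
    kinds: dict[str, str]
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.values.columns:
            kind = self.kinds.get(name)
            if kind not in KINDS:
                raise ValueError(f"covariate {name!r} has invalid kind {kind!r}")

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def dummy_columns(self) -> list[str]:
        return [n for n in self.names if self.kinds[n] == "geographic"]


def upstream_average(
    net: RiverNetwork, local_values: np.ndarray, weights: str = "area"
) -> np.ndarray:
    """Average a per-reach field over gamma(i) for every reach i.

    ``weights="area"`` weights each reach by its locally contributed drainage
    area (the reach-granularity surrogate of averaging the underlying raster
    over the upstream catchment); ``weights="equal"`` is a plain mean over
    the upstream reach set.
    """
    x = np.asarray(local_values, dtype=float)
    if x.shape != (len(net),):
        raise ValueError("need exactly one local value per reach")
    if np.any(~np.isfinite(x)):
        raise ValueError("local values contain missing entries")
    if weights == "area":
        w = net.local_area_km2()
        w = np.maximum(w, 0.0)
        if not w.any():
            w = np.ones(len(net))
    elif weights == "equal":
        w = np.ones(len(net))
    else:
        raise ValueError("weights must be 'area' or 'equal'")
    num = w * x
    den = w.copy()
    num_acc = num.copy()
    den_acc = den.copy()
    for k in net.topo_order:
        d = net.downstream[k]
        if d >= 0:
            num_acc[d] += num_acc[k]
            den_acc[d] += den_acc[k]
    return num_acc / den_acc


def geographic_dummies(cluster_assignment: list[str | None]) -> pd.DataFrame:
    """One 0/1 indicator column per cluster; rows sum to one."""
    if any(c is None for c in cluster_assignment):
        raise ValueError("every reach must be assigned to a cluster")
    s = pd.Series(cluster_assignment, dtype="object")
    dummies = pd.get_dummies(s).astype(float)
    dummies.columns = [str(c) for c in dummies.columns]
    return dummies


def z_normalize(X: CovariateMatrix) -> CovariateMatrix:
    """Z-score non-dummy columns in place of a copy (population sd).

    Stores (mean, sd) per column so the transform can be reapplied or
    inverted; geographic indicator columns are left on their 0/1 scale.
    """
    values = X.values.copy()
    stats: dict[str, tuple[float, float]] = {}
    for name in values.columns:
        if X.kinds[name] == "geographic":
            continue
        col = values[name].to_numpy(dtype=float)
        mean = float(col.mean())
        sd = float(col.std())  # population convention (ddof=0)
        if sd == 0.0:
            raise ValueError(f"covariate {name!r} has zero variance")
        values[name] = (col - mean) / sd
        stats[name] = (mean, sd)
    return CovariateMatrix(values=values, kinds=dict(X.kinds), stats=stats)


def denormalize(X: CovariateMatrix) -> CovariateMatrix:
    """Invert :func:`z_normalize` using the stored statistics."""
    values = X.values.copy()
    for name, (mean, sd) in X.stats.items():
        values[name] = values[name] * sd + mean
    return CovariateMatrix(values=values, kinds=dict(X.kinds), stats={})


def apply_normalization(X: CovariateMatrix, new: pd.DataFrame) -> pd.DataFrame:
    """Apply X's stored z-scoring statistics to a table of new reaches."""
    out = new.copy()
    for name, (mean, sd) in X.stats.items():
        out[name] = (out[name] - mean) / sd
    return out


@dataclass
class CollinearityReport:
    """Advisory multicollinearity screen of a design matrix."""

    max_abs_corr: float
    corr: pd.DataFrame
    vif: dict[str, float]
    dropped: str

    def passes(self, corr_limit: float = 0.80, vif_limit: float = 10.0) -> bool:
        return self.max_abs_corr < corr_limit and all(
            v < vif_limit for v in self.vif.values()
        )


def collinearity_screen(X: CovariateMatrix, drop: str) -> CollinearityReport:
    """Pairwise correlations and variance inflation factors on the matrix
    with one geographic dummy removed.

    A full set of cluster indicators is exactly collinear (each is a linear
    combination of the others), so one dummy is removed for screening only;
    the dropped column stays in the matrix used for fitting.  A singular
    reduced matrix yields infinite VIFs rather than an error.
    """
    if drop not in X.names:
        raise ValueError(f"unknown covariate {drop!r}")
    reduced = X.values.drop(columns=[drop])
    M = reduced.to_numpy(dtype=float)
    corr = reduced.corr()
    off = corr.to_numpy().copy()
    np.fill_diagonal(off, 0.0)
    vif: dict[str, float] = {}
    n = M.shape[0]
    for j, name in enumerate(reduced.columns):
        y = M[:, j]
        others = np.column_stack([np.delete(M, j, axis=1), np.ones(n)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_res = float((resid**2).sum())
        if ss_tot == 0.0 or ss_res <= 1e-12 * max(ss_tot, 1.0):
            vif[name] = np.inf
        else:
            vif[name] = 1.0 / (ss_res / ss_tot)
    return CollinearityReport(
        max_abs_corr=float(np.nanmax(np.abs(off))) if off.size else 0.0,
        corr=corr,
        vif=vif,
        dropped=drop,
    )
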