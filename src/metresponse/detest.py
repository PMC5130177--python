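"""Count normalization and negative-binomial differential testing.

The model is the standard one for sequencing count data: feature counts are
NB-distributed with mean ``size_factor * condition_mean`` and variance
``m + alpha * m**2``.  Size factors come from median-of-ratios normalization,
per-feature dispersions from a method-of-moments estimate shrunk halfway to
the across-feature mean, and each contrast is a Wald test on the log2 ratio
of NB maximum-likelihood condition means at fixed dispersion.  The same
engine runs on gene counts and on peak counts.

The variance-stabilizing transform feeding the clustering stage is a shifted
log of normalized counts (``log2(count/sf + c)``), a deliberately simple
approximation to regularized-log shrinkage: downstream clustering needs the
stabilization, not the exact shrinkage estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .simulate import SampleDesign

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-4


class NormalizationError(ValueError):
    """No feature has positive counts in every sample."""


def _as_matrix(counts: pd.DataFrame) -> np.ndarray:
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, the factor is the median over features (restricted to
    features positive in all samples) of count_ij / geomean_i(count).
    """
    arr = _as_matrix(counts)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no feature has positive counts in all samples; cannot normalize"
        )
    logc = np.log(arr[positive])
    log_ratio = logc - logc.mean(axis=1, keepdims=True)
    log_sf = np.median(log_ratio, axis=0)
    log_sf -= log_sf.mean()  # geometric mean exactly 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    design: SampleDesign,
    size_factors: pd.Series,
    floor: float = DISPERSION_FLOOR,
    shrinkage: float = 0.5,
) -> pd.Series:
    """Per-feature NB dispersion by method of moments with trend shrinkage.

    Within-condition residual variance of normalized counts gives
    ``alpha_raw = max(floor, (s2 - mbar) / mbar**2)``; the final estimate is
    shrunk toward the across-feature mean of the raw estimates with weight
    ``shrinkage``.  All-zero features are set to the floor and flagged via
    the returned series' zero-variance handling downstream.
    """
    arr = _as_matrix(counts)
    sf = size_factors.reindex(counts.columns).to_numpy()
    norm = arr / sf

    cond = design.table.reindex(counts.columns)["condition"]
    ss = np.zeros(arr.shape[0])
    df = 0
    for _, idx in cond.groupby(cond).groups.items():
        cols = [counts.columns.get_loc(s) for s in idx]
        if len(cols) < 2:
            raise ValueError("each condition needs >= 2 replicates")
        sub = norm[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += len(cols) - 1
    s2 = ss / df
    mbar = norm.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mbar) / mbar**2
    raw = np.where(mbar > 0, np.maximum(floor, raw), floor)
    trend = raw[mbar > 0].mean() if (mbar > 0).any() else floor
    alpha = (1.0 - shrinkage) * raw + shrinkage * trend
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _fit_nb_group_means(
    y: np.ndarray, sf: np.ndarray, alpha: np.ndarray, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NB MLE of the group mean at fixed dispersion.

    Solves, per feature, sum_j y_j - sum_j (y_j + 1/a)*a*sf_j*mu/(1+a*sf_j*mu)
    = 0 by damped Newton.  Returns (mu_hat, fisher_info_logmu); groups with
    all-zero counts return mu_hat = 0 and info computed at a half-count floor.
    """
    tot = y.sum(axis=1)
    mu = np.maximum(tot / sf.sum(), 1e-12)
    a = alpha[:, None]
    sfv = sf[None, :]
    for _ in range(100):
        denom = 1.0 + a * sfv * mu[:, None]
        g = tot - ((y + 1.0 / a) * (a * sfv * mu[:, None]) / denom).sum(axis=1)
        gp = -((y + 1.0 / a) * (a * sfv) / denom**2).sum(axis=1)
        step = g / gp
        new = mu - step
        new = np.where(new <= 0, mu / 2.0, new)
        if np.max(np.abs(new - mu) / np.maximum(mu, 1e-12)) < tol:
            mu = new
            break
        mu = new
    mu = np.where(tot == 0, 0.0, mu)
    mu_info = np.where(mu > 0, mu, 0.5 / sf.sum())  # half-count floor for SE
    info = (sfv * mu_info[:, None] / (1.0 + a * sfv * mu_info[:, None])).sum(axis=1)
    return mu, info


def test_differential(
    counts: pd.DataFrame,
    design: SampleDesign,
    size_factors: pd.Series,
    dispersion: pd.Series,
    contrast: tuple[str, str] = ("MET", "NT"),
) -> pd.DataFrame:
    """Per-feature NB Wald test of `contrast[0]` versus reference `contrast[1]`.

    Returns a frame with baseMean, log2FoldChange, lfcSE, stat, pvalue, padj
    and an ``untestable`` flag (both groups all zero).
    """
    cond_name, ref_name = contrast
    cond_col = design.table.reindex(counts.columns)["condition"]
    for name in contrast:
        if name not in set(cond_col):
            raise ValueError(f"condition {name!r} not present in design")

    sf = size_factors.reindex(counts.columns).to_numpy()
    alpha = dispersion.reindex(counts.index).to_numpy()
    arr = _as_matrix(counts)
    base_mean = (arr / sf).mean(axis=1)

    sel_c = (cond_col == cond_name).to_numpy()
    sel_r = (cond_col == ref_name).to_numpy()
    mu_c, info_c = _fit_nb_group_means(arr[:, sel_c], sf[sel_c], alpha)
    mu_r, info_r = _fit_nb_group_means(arr[:, sel_r], sf[sel_r], alpha)

    both_zero = (mu_c == 0) & (mu_r == 0)
    floor_c = np.where(mu_c > 0, mu_c, 0.5 / sf[sel_c].sum())
    floor_r = np.where(mu_r > 0, mu_r, 0.5 / sf[sel_r].sum())
    lfc = np.log2(floor_c / floor_r)
    se = np.sqrt(1.0 / info_c + 1.0 / info_r) / LN2
    stat = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(stat))

    lfc[both_zero] = 0.0
    stat[both_zero] = 0.0
    p[both_zero] = 1.0

    res = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": p,
            "untestable": both_zero,
        },
        index=counts.index,
    )
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def transform_regularized_log(
    counts: pd.DataFrame, size_factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Shifted-log variance-stabilizing transform: log2(count/sf + c)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    arr = _as_matrix(counts)
    sf = size_factors.reindex(counts.columns).to_numpy()
    return pd.DataFrame(
        np.log2(arr / sf + pseudocount), index=counts.index, columns=counts.columns
    )


class NBDifferentialTester(BaseEstimator):
    """Estimator wrapper around the NB testing engine.

    ``fit(counts, design)`` computes size factors, dispersions and one result
    frame per configured contrast; ``transform(counts)`` applies the
    shifted-log transform with the fitted size factors.  The significant set
    feeding the clustering stage is defined by ``significance_contrasts``
    (default: the treated-vs-untreated contrast alone, the criterion that
    defines the responsive gene set); pass ``None`` to take the union over
    all computed contrasts instead — the union inflates the realized FDR of
    the combined list, so it is not the default.
    """

    def __init__(
        self,
        contrasts: tuple[tuple[str, str], ...] = (("MET", "NT"), ("METCC", "NT")),
        significance_contrasts: tuple[tuple[str, str], ...] | None = (("MET", "NT"),),
        fdr: float = 0.05,
        dispersion_floor: float = DISPERSION_FLOOR,
        shrinkage: float = 0.5,
        pseudocount: float = 1.0,
        min_base_mean: float = 1.0,
    ):
        self.contrasts = contrasts
        self.significance_contrasts = significance_contrasts
        self.fdr = fdr
        self.dispersion_floor = dispersion_floor
        self.shrinkage = shrinkage
        self.pseudocount = pseudocount
        self.min_base_mean = min_base_mean

    def fit(self, counts: pd.DataFrame, design: SampleDesign):
        self.size_factors_ = estimate_size_factors(counts)
        self.dispersions_ = estimate_dispersion(
            counts, design, self.size_factors_,
            floor=self.dispersion_floor, shrinkage=self.shrinkage,
        )
        self.results_ = {}
        for contrast in self.contrasts:
            self.results_[contrast] = test_differential(
                counts, design, self.size_factors_, self.dispersions_, contrast
            )
        self.expressed_ = next(iter(self.results_.values()))["baseMean"] >= self.min_base_mean
        which = self.significance_contrasts or tuple(self.results_)
        missing = [c for c in which if tuple(c) not in self.results_]
        if missing:
            raise ValueError(f"significance contrasts not computed: {missing}")
        sig = None
        for contrast in which:
            res = self.results_[tuple(contrast)]
            hit = (res["padj"] <= self.fdr) & ~res["untestable"]
            sig = hit if sig is None else (sig | hit)
        self.significant_ = sig & self.expressed_
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        return transform_regularized_log(
            counts, self.size_factors_, pseudocount=self.pseudocount
        )

    @property
    def significant_features_(self) -> pd.Index:
        return self.significant_.index[self.significant_]
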