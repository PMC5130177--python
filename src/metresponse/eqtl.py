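"""Per-cohort additive-model cis-eQTL regression and weighted meta-analysis.

Each cohort fits ordinary least squares of expression on intercept + allele
dosage + cohort-specific covariates; the dosage t statistic (beta / se, with
residual df = n - #covariates - 2) is the per-study association.  Studies
are combined with the sample-size-weighted statistic

    t_meta = (sum_i w_i t_i) / sqrt(sum_i w_i**2),   w_i = sqrt(n_i - #cov_i - 1)

referred to the standard normal for two-sided p-values.  Cis candidate
pairs keep a variant when its position falls within [gene_start - flank,
gene_end + flank] with inclusive bounds (default flank 100 kb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import CohortData

DEFAULT_CIS_FLANK = 100_000
_TINY = np.nextafter(0.0, 1.0)


@dataclass
class StudyAssociation:
    cohort_id: str
    variant_id: str
    gene_id: str
    beta: float
    se: float
    t: float
    df: int
    n: int
    n_covariates: int
    degenerate: bool = False


@dataclass
class MetaAssociation:
    variant_id: str
    gene_id: str
    weights: np.ndarray
    t_meta: float

    @property
    def p_meta(self) -> float:
        return meta_pvalue(self)


def cis_pairs(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = DEFAULT_CIS_FLANK,
) -> pd.DataFrame:
    """Variant-gene pairs with the variant inside the flanked gene span.

    ``variants`` needs columns chrom/pos (index variant_id); ``genes`` needs
    chrom/start/end (index gene_id).  Bounds are inclusive on both sides.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    rows = []
    for gene_id, g in genes.iterrows():
        lo, hi = g["start"] - flank, g["end"] + flank
        hit = variants[
            (variants["chrom"] == g["chrom"])
            & (variants["pos"] >= lo)
            & (variants["pos"] <= hi)
        ]
        rows.extend((v, gene_id) for v in hit.index)
    return pd.DataFrame(rows, columns=["variant_id", "gene_id"])


def fit_additive_model(
    cohort: CohortData, variant_id: str, gene_id: str
) -> StudyAssociation:
    """OLS of expression on intercept + dosage + covariates; t on the dosage term."""
    g = cohort.dosage[variant_id]
    y = cohort.expression[gene_id]
    X = pd.concat([g.rename("dosage"), cohort.covariates], axis=1)
    X = sm.add_constant(X, prepend=True)
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[keep], y.loc[keep]
    n = len(y)
    ncov = cohort.covariates.shape[1]
    df = n - ncov - 2
    if df < 1:
        raise ValueError(f"residual df = {df} < 1 for {variant_id}/{gene_id}")

    rank = np.linalg.matrix_rank(X.to_numpy())
    degenerate = rank < X.shape[1]
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params["dosage"])
    se = float(fit.bse["dosage"])
    if fit.ssr <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2):
        degenerate = True
    t = beta / se if se > 0 else np.inf * np.sign(beta)
    return StudyAssociation(
        cohort_id=cohort.cohort_id,
        variant_id=variant_id,
        gene_id=gene_id,
        beta=beta,
        se=se,
        t=float(t),
        df=df,
        n=n,
        n_covariates=ncov,
        degenerate=degenerate,
    )


def meta_combine(assocs: list[StudyAssociation]) -> MetaAssociation:
    """Weighted-Z combination of per-study t statistics.

    w_i = sqrt(n_i - #covariates_i - 1); order of the input list does not
    change the result.  Degenerate (rank-deficient / zero-residual) studies
    should be excluded by the caller before combining.
    """
    if not assocs:
        raise ValueError("need at least one study association")
    vg = {(a.variant_id, a.gene_id) for a in assocs}
    if len(vg) != 1:
        raise ValueError(f"inconsistent variant/gene across studies: {sorted(vg)}")
    w = np.array([a.n - a.n_covariates - 1 for a in assocs], dtype=float)
    if (w <= 0).any():
        raise ValueError("every study needs n - #covariates - 1 > 0")
    w = np.sqrt(w)
    t = np.array([a.t for a in assocs], dtype=float)
    t_meta = float((w * t).sum() / np.sqrt((w**2).sum()))
    variant_id, gene_id = next(iter(vg))
    return MetaAssociation(
        variant_id=variant_id, gene_id=gene_id, weights=w, t_meta=t_meta
    )


def meta_pvalue(meta: MetaAssociation) -> float:
    """Two-sided normal p-value, guarded against underflow to exactly 0."""
    if not np.isfinite(meta.t_meta):
        raise ValueError("t_meta must be finite")
    p = 2.0 * stats.norm.sf(abs(meta.t_meta))
    return float(max(p, _TINY))


def meta_scan(
    cohorts: list[CohortData], pairs: pd.DataFrame
) -> pd.DataFrame:
    """Fit every cohort for every pair and combine; returns the meta table."""
    rows = []
    for variant_id, gene_id in pairs.itertuples(index=False):
        assocs = [
            a
            for c in cohorts
            if variant_id in c.dosage.columns and gene_id in c.expression.columns
            for a in [fit_additive_model(c, variant_id, gene_id)]
            if not a.degenerate
        ]
        if not assocs:
            continue
        meta = meta_combine(assocs)
        rows.append(
            {
                "variant_id": variant_id,
                "gene_id": gene_id,
                "n_studies": len(assocs),
                "t_meta": meta.t_meta,
                "p_meta": meta.p_meta,
            }
        )
    return pd.DataFrame(rows)
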