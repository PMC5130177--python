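"""Permutation tests for peak-set overlap enrichment or depletion.

The observed statistic is the fraction of query peaks overlapping a target
region set (promoters of a foreground gene set, or a designated peak
subset).  The null resamples the *set* — |foreground| genes drawn without
replacement from the background universe (or |designated| peaks from the
reference set) — recomputing the fraction each time; peak coordinates are
never shuffled along the genome.  Empirical p-values use the add-one rule

    p = (1 + #{null >= observed}) / (n_perm + 1)        (enrichment)
    p = (1 + #{null <= observed}) / (n_perm + 1)        (depletion)

so p is never 0 and is bounded below by 1/(n_perm + 1).  The direction is
declared a priori.  Default n_perm is 2000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import define_promoters, intersect_intervals, sort_intervals


@dataclass
class OverlapStatistic:
    n_query: int
    n_overlapping: int

    @property
    def fraction(self) -> float:
        return self.n_overlapping / self.n_query


@dataclass
class PermutationResult:
    observed: OverlapStatistic
    n_permutations: int
    null_fractions: np.ndarray
    empirical_p: float
    direction: str
    seed: int


def overlap_fraction(query: pd.DataFrame, targets: pd.DataFrame) -> OverlapStatistic:
    """Fraction of query intervals overlapping >= 1 target by >= 1 base."""
    if len(query) == 0:
        raise ValueError("empty query set")
    if len(targets) == 0:
        return OverlapStatistic(n_query=len(query), n_overlapping=0)
    flags, _ = intersect_intervals(query, targets)
    return OverlapStatistic(n_query=len(query), n_overlapping=int(flags.sum()))


def _empirical_p(null: np.ndarray, observed: float, direction: str) -> float:
    if direction == "enrichment":
        extreme = int((null >= observed).sum())
    elif direction == "depletion":
        extreme = int((null <= observed).sum())
    else:
        raise ValueError("direction must be 'enrichment' or 'depletion'")
    return (1 + extreme) / (len(null) + 1)


def _incidence_by_group(
    query: pd.DataFrame, targets: pd.DataFrame, group_ids: np.ndarray
) -> dict:
    """Map group id -> indices of query intervals hitting that group's targets."""
    _, pairs = intersect_intervals(query, targets)
    hits: dict = {g: [] for g in np.unique(group_ids)}
    # intersect sorts both sides; recover group via the sorted target order
    t_sorted = sort_intervals(targets)
    order = sort_intervals(targets.assign(_g=group_ids))["_g"].to_numpy()
    del t_sorted
    for a_i, b_i in pairs.itertuples(index=False):
        hits[order[b_i]].append(a_i)
    return {g: np.unique(v).astype(int) for g, v in hits.items()}


def _set_resampling_test(
    n_query: int,
    hits_by_group: dict,
    foreground: list,
    background: list,
    n_perm: int,
    seed: int,
    direction: str,
) -> PermutationResult:
    rng = np.random.default_rng(seed)
    # dense boolean incidence (groups x query peaks): fast resampling
    bg = list(background)
    index = {g: i for i, g in enumerate(bg)}
    H = np.zeros((len(bg), n_query), dtype=bool)
    for g, rows in hits_by_group.items():
        if g in index:
            H[index[g], rows] = True
    fg_idx = np.array([index[g] for g in foreground], dtype=int)
    observed = OverlapStatistic(
        n_query=n_query, n_overlapping=int(H[fg_idx].any(axis=0).sum())
    )

    k = len(foreground)
    null = np.empty(n_perm)
    for t in range(n_perm):
        sample = rng.choice(len(bg), size=k, replace=False)
        null[t] = H[sample].any(axis=0).sum() / n_query
    p = _empirical_p(null, observed.fraction, direction)
    return PermutationResult(
        observed=observed,
        n_permutations=n_perm,
        null_fractions=null,
        empirical_p=p,
        direction=direction,
        seed=seed,
    )


def permutation_test_gene_sets(
    peaks: pd.DataFrame,
    foreground_genes: list,
    background_genes: list,
    gene_models: pd.DataFrame,
    upstream: int = 1000,
    downstream: int = 500,
    n_perm: int = 2000,
    seed: int = 0,
    direction: str = "enrichment",
) -> PermutationResult:
    """Overlap of peaks with foreground-gene promoters vs a background null.

    Foreground must be a strict subset of the background universe (all genes
    expressed well enough to be testable).  The null draws |foreground|
    genes from the background without replacement and recomputes the peak
    overlap fraction with the sampled promoters.
    """
    fg = list(foreground_genes)
    bg = list(background_genes)
    if not set(fg) <= set(bg):
        raise ValueError("foreground genes must be a subset of the background")
    missing = set(bg) - set(gene_models.index)
    if missing:
        raise ValueError(f"background genes absent from gene models: {sorted(missing)[:5]}")
    promoters = define_promoters(gene_models.loc[bg], upstream, downstream)
    hits = _incidence_by_group(
        peaks, promoters, promoters["name"].to_numpy()
    )
    return _set_resampling_test(
        len(peaks), hits, fg, bg, n_perm, seed, direction
    )


def permutation_test_peak_sets(
    query_peaks: pd.DataFrame,
    designated: pd.DataFrame,
    reference: pd.DataFrame,
    n_perm: int = 2000,
    seed: int = 0,
    direction: str = "enrichment",
) -> PermutationResult:
    """Overlap of query peaks with a designated peak subset vs all reference.

    Same resampling scheme with peak identities in place of genes; supports
    the depletion direction (e.g. shared peaks underrepresented among the
    differential set).  ``designated`` and ``reference`` must carry a
    ``name`` column with designated names a subset of reference names.
    """
    for df, lab in ((designated, "designated"), (reference, "reference")):
        if "name" not in df.columns:
            raise ValueError(f"{lab} set needs a 'name' column")
    des = list(designated["name"])
    ref = list(reference["name"])
    if not set(des) <= set(ref):
        raise ValueError("designated peaks must be a subset of the reference set")
    hits = _incidence_by_group(
        query_peaks, reference, reference["name"].to_numpy()
    )
    return _set_resampling_test(
        len(query_peaks), hits, des, ref, n_perm, seed, direction
    )
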