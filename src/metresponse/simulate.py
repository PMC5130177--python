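"""Synthetic data with the statistical structure the pipeline assumes.

Everything here is driven by a single :class:`SimulationConfig` whose seed
fully determines all outputs.  The generator plants known response patterns
(negative-binomial counts whose condition means follow one of the four
AMPK-dependence patterns or stay flat), condition-specific peak landscapes
with a known sharing structure, coverage tracks, and multi-cohort
genotype/expression data with additive genetic effects — plus the
ground-truth tables that tests compare against.

Planted patterns use full/zero reversion: AMPK-dependent features return to
the untreated mean under the combined inhibitor treatment, AMPK-independent
features keep the treated mean.  Pattern assignment is deterministic by
feature index so truth tables realize the configured fractions exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("NT", "MET", "METCC")

PATTERNS = (
    "MET_UP_AMPK_DEP",
    "MET_UP_AMPK_INDEP",
    "MET_DOWN_AMPK_DEP",
    "MET_DOWN_AMPK_INDEP",
    "NULL",
)

# Default planted fractions loosely mirror the observed DE-cluster balance in
# hepatocyte metformin response (up/AMPK-dependent dominant among responders).
_DEFAULT_FRACTIONS = {
    "MET_UP_AMPK_DEP": 0.15,
    "MET_UP_AMPK_INDEP": 0.05,
    "MET_DOWN_AMPK_DEP": 0.04,
    "MET_DOWN_AMPK_INDEP": 0.06,
    "NULL": 0.70,
}


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


class GenerationError(RuntimeError):
    """Raised when a requested landscape cannot be packed into the genome."""


@dataclass
class SimulationConfig:
    """All knobs for the synthetic study, with study-design defaults.

    ``n_replicates_per_condition`` defaults to 3 (cultures treated in
    triplicate); ``cohort_sizes`` default to four liver cohorts totalling
    1,180 samples.
    """

    seed: int = 0
    n_features: int = 1000
    n_replicates_per_condition: int = 3
    planted_pattern_fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    base_mean_log_range: tuple[float, float] = (1.0, 3.0)  # log10 of NB mean
    dispersion: float = 0.05
    effect_log2fc: float = 2.0
    genome_length: int = 2_000_000
    n_peaks: int = 200
    peak_width_range: tuple[int, int] = (300, 800)
    peak_partition: dict[str, int] | None = None
    n_cohorts: int = 4
    cohort_sizes: tuple[int, ...] = (200, 300, 300, 380)
    maf: float = 0.3
    genetic_beta: float = 0.5
    n_covariates_per_cohort: tuple[int, ...] = (2, 3, 4, 5)
    noise_sd: float = 1.0
    n_eqtl_pairs: int = 100
    size_factor_log_range: tuple[float, float] = (0.7, 1.4)

    def __post_init__(self) -> None:
        fr = self.planted_pattern_fractions
        unknown = set(fr) - set(PATTERNS)
        if unknown:
            raise ConfigurationError(f"unknown pattern labels: {sorted(unknown)}")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"pattern fractions sum to {total}, expected 1")
        if any(v < 0 for v in fr.values()):
            raise ConfigurationError("pattern fractions must be non-negative")
        for name in ("n_features", "n_replicates_per_condition", "n_peaks", "n_cohorts"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not (0 < self.maf <= 0.5):
            raise ConfigurationError("maf must lie in (0, 0.5]")
        if len(self.cohort_sizes) != self.n_cohorts:
            raise ConfigurationError("cohort_sizes length must equal n_cohorts")
        if len(self.n_covariates_per_cohort) != self.n_cohorts:
            raise ConfigurationError("n_covariates_per_cohort length must equal n_cohorts")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class SampleDesign:
    """Sample sheet: condition and replicate index per sample."""

    table: pd.DataFrame  # index sample_id; columns condition, replicate

    @property
    def conditions(self) -> pd.Series:
        return self.table["condition"]


@dataclass
class PlantedTruth:
    """Ground truth for planted effects; one row per simulated feature/variant."""

    features: pd.DataFrame | None = None
    peaks: pd.DataFrame | None = None
    variants: pd.DataFrame | None = None


@dataclass
class CohortData:
    """One eQTL cohort: dosage, expression and covariates sharing a sample axis."""

    cohort_id: str
    dosage: pd.DataFrame      # samples x variants, values in {0,1,2}
    expression: pd.DataFrame  # samples x genes
    covariates: pd.DataFrame  # samples x covariates

    @property
    def n(self) -> int:
        return len(self.dosage)


def _stream_rng(seed: int, stream_index: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence([seed, stream_index]))


def _assign_patterns(config: SimulationConfig) -> list[str]:
    """Deterministic assignment by index: exact planted counts."""
    n = config.n_features
    labels: list[str] = []
    fracs = [config.planted_pattern_fractions.get(p, 0.0) for p in PATTERNS]
    cum = np.round(np.cumsum(fracs) * n).astype(int)
    start = 0
    for pattern, stop in zip(PATTERNS, cum):
        labels.extend([pattern] * (stop - start))
        start = stop
    labels.extend(["NULL"] * (n - len(labels)))
    return labels[:n]


def _condition_means(base: float, pattern: str, lfc: float) -> tuple[float, float, float]:
    up = base * 2.0**lfc
    down = base * 2.0**-lfc
    if pattern == "MET_UP_AMPK_DEP":
        return base, up, base
    if pattern == "MET_UP_AMPK_INDEP":
        return base, up, up
    if pattern == "MET_DOWN_AMPK_DEP":
        return base, down, base
    if pattern == "MET_DOWN_AMPK_INDEP":
        return base, down, down
    return base, base, base


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws parameterized by mean m and dispersion alpha (var = m + alpha m^2)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 1e-8:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_count_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SampleDesign, PlantedTruth]:
    """NB gene counts across NT / MET / METCC with planted response patterns.

    Returns the counts (features x samples), the sample design, and the truth
    table (pattern, true log2 fold changes of each contrast vs NT, base mean).
    """
    rng = _stream_rng(config.seed, 1)
    n = config.n_features
    reps = config.n_replicates_per_condition
    patterns = _assign_patterns(config)

    lo, hi = config.base_mean_log_range
    base_means = 10.0 ** rng.uniform(lo, hi, size=n)

    sample_ids, cond_labels, rep_idx = [], [], []
    for cond in CONDITIONS:
        for r in range(1, reps + 1):
            sample_ids.append(f"{cond}_{r}")
            cond_labels.append(cond)
            rep_idx.append(r)
    design = SampleDesign(
        pd.DataFrame(
            {"condition": cond_labels, "replicate": rep_idx},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    sf_lo, sf_hi = config.size_factor_log_range
    size_factors = np.exp(rng.uniform(np.log(sf_lo), np.log(sf_hi), size=len(sample_ids)))

    mu = np.empty((n, len(sample_ids)))
    truth_rows = []
    for i, (pattern, base) in enumerate(zip(patterns, base_means)):
        m_nt, m_met, m_metcc = _condition_means(base, pattern, config.effect_log2fc)
        per_cond = {"NT": m_nt, "MET": m_met, "METCC": m_metcc}
        mu[i] = [per_cond[c] * s for c, s in zip(cond_labels, size_factors)]
        truth_rows.append(
            {
                "feature_id": f"gene_{i:05d}",
                "pattern": pattern,
                "base_mean": base,
                "true_lfc_MET": np.log2(m_met / m_nt),
                "true_lfc_METCC": np.log2(m_metcc / m_nt),
            }
        )

    counts = _nb_draw(rng, mu, config.dispersion)
    feature_ids = [r["feature_id"] for r in truth_rows]
    counts_df = pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"),
                             columns=sample_ids)
    truth = PlantedTruth(features=pd.DataFrame(truth_rows).set_index("feature_id"))
    return counts_df, design, truth


def _default_peak_partition(config: SimulationConfig) -> dict[str, int]:
    n = config.n_peaks
    shared_all = int(round(0.5 * n))
    per_unique = int(round(0.1 * n))
    remaining = n - shared_all - 3 * per_unique
    pairs = ["NT+MET", "NT+METCC", "MET+METCC"]
    part = {"NT+MET+METCC": shared_all}
    for i, p in enumerate(pairs):
        part[p] = remaining // 3 + (1 if i < remaining % 3 else 0)
    for c in CONDITIONS:
        part[c] = per_unique
    return part


def simulate_peak_landscape(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, PlantedTruth]:
    """Condition-specific peak sets with a known sharing structure.

    Peaks are non-overlapping loci on a single synthetic contig; each locus is
    assigned a membership combination (e.g. present in NT and MET only).  Peak
    counts are NB draws with an elevated mean where the peak is present.
    Returns per-condition interval sets (BED-style frames), a peak count
    matrix over the union loci, and the truth table of memberships.
    """
    rng = _stream_rng(config.seed, 2)
    partition = config.peak_partition or _default_peak_partition(config)
    unknown = [k for k in partition if not set(k.split("+")) <= set(CONDITIONS)]
    if unknown:
        raise ConfigurationError(f"bad partition keys: {unknown}")
    n_total = sum(partition.values())

    w_lo, w_hi = config.peak_width_range
    widths = rng.integers(w_lo, w_hi + 1, size=n_total)
    gaps_needed = config.genome_length - int(widths.sum())
    if gaps_needed < 2 * (n_total + 1):
        raise GenerationError(
            f"cannot pack {n_total} peaks of total width {int(widths.sum())} "
            f"into genome of length {config.genome_length}"
        )
    # random positive inter-peak gaps that never overshoot the genome
    gap_weights = rng.dirichlet(np.ones(n_total + 1))
    gaps = 1 + np.floor(gap_weights * (gaps_needed - (n_total + 1))).astype(int)
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], widths[:-1]]))
    ends = starts + widths

    membership_labels: list[str] = []
    for combo, count in partition.items():
        membership_labels.extend([combo] * count)
    order = rng.permutation(n_total)  # shuffle loci over combos
    membership_labels = [membership_labels[i] for i in order]

    peak_ids = [f"peak_{i:05d}" for i in range(n_total)]
    truth_df = pd.DataFrame(
        {
            "peak_id": peak_ids,
            "chrom": "chrS",
            "start": starts,
            "end": ends,
            "membership": membership_labels,
        }
    ).set_index("peak_id")

    per_condition: dict[str, pd.DataFrame] = {}
    for cond in CONDITIONS:
        mask = [cond in m.split("+") for m in membership_labels]
        sub = truth_df.loc[mask, ["chrom", "start", "end"]].reset_index()
        sub = sub.rename(columns={"peak_id": "name"})[["chrom", "start", "end", "name"]]
        per_condition[cond] = sub.reset_index(drop=True)

    reps = config.n_replicates_per_condition
    sample_ids = [f"{c}_{r}" for c in CONDITIONS for r in range(1, reps + 1)]
    cond_of = [c for c in CONDITIONS for _ in range(reps)]
    present_mean, absent_mean = 100.0, 5.0
    mu = np.empty((n_total, len(sample_ids)))
    for i, m in enumerate(membership_labels):
        present = set(m.split("+"))
        mu[i] = [present_mean if c in present else absent_mean for c in cond_of]
    counts = _nb_draw(rng, mu, config.dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(peak_ids, name="feature_id"),
                             columns=sample_ids)
    return per_condition, counts_df, PlantedTruth(peaks=truth_df)


def simulate_coverage_track(
    intervals: pd.DataFrame,
    genome_length: int,
    peak_height: float = 10.0,
    background: float = 1.0,
    chrom: str = "chrS",
) -> pd.DataFrame:
    """Piecewise-constant bedGraph-style coverage: background plus box signal."""
    edges = sorted(
        {0, genome_length}
        | set(intervals["start"].astype(int))
        | set(intervals["end"].astype(int))
    )
    rows = []
    iv = intervals.sort_values("start")
    for s, e in zip(edges[:-1], edges[1:]):
        inside = ((iv["start"] <= s) & (iv["end"] >= e)).any()
        rows.append((chrom, s, e, background + (peak_height if inside else 0.0)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def simulate_eqtl_cohorts(
    config: SimulationConfig,
) -> tuple[list[CohortData], PlantedTruth]:
    """Multi-cohort genotype/expression data with additive genetic effects.

    Per cohort: dosages ~ Binomial(2, maf); expression = intercept +
    beta * dosage + covariate effects + N(0, noise_sd); covariates standard
    normal.  One variant-gene pair per simulated feature index.
    """
    rng = _stream_rng(config.seed, 3)
    n_pairs = config.n_eqtl_pairs
    variant_ids = [f"var_{k:05d}" for k in range(n_pairs)]
    gene_ids = [f"egene_{k:05d}" for k in range(n_pairs)]

    cohorts: list[CohortData] = []
    truth_rows = []
    for ci in range(config.n_cohorts):
        n = config.cohort_sizes[ci]
        ncov = config.n_covariates_per_cohort[ci]
        sample_idx = pd.Index([f"c{ci+1}_s{j:04d}" for j in range(n)], name="sample_id")
        dosage = rng.binomial(2, config.maf, size=(n, n_pairs)).astype(float)
        cov = rng.standard_normal((n, ncov))
        gamma = rng.normal(0.0, 0.5, size=(ncov, 1))
        cov_effect = cov @ gamma
        noise = rng.normal(0.0, config.noise_sd, size=(n, n_pairs))
        expr = 1.0 + config.genetic_beta * dosage + cov_effect + noise
        cohorts.append(
            CohortData(
                cohort_id=f"cohort_{ci+1}",
                dosage=pd.DataFrame(dosage, index=sample_idx, columns=variant_ids),
                expression=pd.DataFrame(expr, index=sample_idx, columns=gene_ids),
                covariates=pd.DataFrame(
                    cov, index=sample_idx, columns=[f"cov{j+1}" for j in range(ncov)]
                ),
            )
        )
        for v in variant_ids:
            truth_rows.append(
                {"variant_id": v, "cohort_id": f"cohort_{ci+1}",
                 "true_beta": config.genetic_beta}
            )
    truth = PlantedTruth(variants=pd.DataFrame(truth_rows))
    return cohorts, truth


def simulate_enrichment_fixture(
    seed: int,
    n_reference: int = 400,
    n_designated: int = 100,
    n_query: int = 150,
    enrichment: float = 2.0,
    genome_length: int = 5_000_000,
    peak_width: int = 500,
) -> dict:
    """Query peaks preferentially overlapping a designated peak subset.

    Each query peak is placed inside one reference peak, drawn with probability
    proportional to ``enrichment`` for designated peaks and 1 for the rest
    (``enrichment=1`` gives the null).  Used by the permutation-test power and
    calibration checks and by the pipeline's enrichment demo stage.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    spacing = genome_length // (n_reference + 1)
    if spacing <= peak_width:
        raise GenerationError("genome too small for requested reference peaks")
    starts = np.arange(1, n_reference + 1) * spacing
    reference = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": starts,
            "end": starts + peak_width,
            "name": [f"ref_{i:05d}" for i in range(n_reference)],
        }
    )
    designated_idx = rng.choice(n_reference, size=n_designated, replace=False)
    designated = reference.iloc[np.sort(designated_idx)].reset_index(drop=True)

    weights = np.ones(n_reference)
    weights[designated_idx] = enrichment
    weights /= weights.sum()
    host = rng.choice(n_reference, size=n_query, p=weights)
    q_start = reference["start"].to_numpy()[host] + rng.integers(
        0, peak_width // 2, size=n_query
    )
    query = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": q_start,
            "end": q_start + peak_width // 4,
            "name": [f"query_{i:05d}" for i in range(n_query)],
        }
    ).sort_values(["start"]).reset_index(drop=True)
    return {
        "reference": reference,
        "designated": designated,
        "query": query,
        "designated_names": set(designated["name"]),
    }


def write_run_inputs(
    config: SimulationConfig,
    outdir: str | Path,
) -> dict[str, str]:
    """Write all simulated inputs plus truth tables and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    counts, design, truth = simulate_count_experiment(config)
    counts_path = outdir / "counts.tsv"
    counts.to_csv(counts_path, sep="\t")
    design_path = outdir / "samples.csv"
    design.table.to_csv(design_path)
    truth_path = outdir / "truth_features.tsv"
    truth.features.to_csv(truth_path, sep="\t")
    paths.update(counts=str(counts_path), samples=str(design_path),
                 truth_features=str(truth_path))

    peak_sets, peak_counts, peak_truth = simulate_peak_landscape(config)
    for cond, df in peak_sets.items():
        p = outdir / f"peaks_{cond}.bed"
        df.to_csv(p, sep="\t", header=False, index=False)
        paths[f"peaks_{cond}"] = str(p)
    pc_path = outdir / "peak_counts.tsv"
    peak_counts.to_csv(pc_path, sep="\t")
    pt_path = outdir / "truth_peaks.tsv"
    peak_truth.peaks.to_csv(pt_path, sep="\t")
    paths.update(peak_counts=str(pc_path), truth_peaks=str(pt_path))

    cohorts, eq_truth = simulate_eqtl_cohorts(config)
    for c in cohorts:
        for kind, df in (("dosage", c.dosage), ("expression", c.expression),
                         ("covariates", c.covariates)):
            p = outdir / f"{c.cohort_id}_{kind}.tsv"
            df.to_csv(p, sep="\t")
            paths[f"{c.cohort_id}_{kind}"] = str(p)
    vt_path = outdir / "truth_variants.tsv"
    eq_truth.variants.to_csv(vt_path, sep="\t", index=False)
    paths["truth_variants"] = str(vt_path)

    # manifest stores paths relative to its own directory so identical
    # configs produce byte-identical manifests anywhere on disk
    manifest = {
        "config": config.to_dict(),
        "outputs": {k: str(Path(v).name) for k, v in paths.items()},
    }
    man_path = outdir / "run_manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    paths["manifest"] = str(man_path)
    return paths
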