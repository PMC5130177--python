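"""End-to-end orchestration: simulate -> DE -> cluster/classify -> peak
interval ops -> permutation enrichment -> eQTL meta, driven by one config.

Every stage writes plain-text outputs under the run directory, and the run
manifest records the config, derived per-stage seeds and sha256 hashes of
every output, so a run is regenerable from the manifest alone.  Re-running
with an identical config reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detest, enrichment, eqtl, intervals, simulate
from .clustering import ResponseClusterer
from .simulate import SampleDesign, SimulationConfig

log = logging.getLogger("metresponse")


class PipelineError(RuntimeError):
    """Stage-tagged failure; completed outputs are preserved."""


@dataclass
class RunConfig:
    """Single config for a full synthetic-study run."""

    seed: int = 0
    outdir: str = "metresponse_run"
    # stage toggles
    stages: tuple[str, ...] = ("simulate", "de", "cluster", "peaks", "enrich", "eqtl")
    # differential testing
    fdr: float = 0.05
    min_base_mean: float = 1.0
    pseudocount: float = 1.0
    # clustering
    n_gene_clusters: int = 10
    n_peak_clusters: int = 4
    delta: float = 0.5
    rho_threshold: float = 0.5
    # enrichment
    n_perm: int = 2000
    # eQTL
    cis_flank: int = 100_000
    # simulation knobs forwarded to SimulationConfig
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown fields {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (stage toggling keeps each stable)."""
    names = ("simulate", "de", "cluster", "peaks", "enrich", "eqtl")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for name, child in zip(names, children)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    outputs: dict[str, str] = {}
    results: dict = {}

    sim_cfg = SimulationConfig(seed=seeds["simulate"], **config.simulation)

    def record(name: str, path: Path) -> None:
        outputs[name] = str(path)

    counts = design = None
    if "simulate" in config.stages:
        log.info("stage simulate: seed=%d", seeds["simulate"])
        paths = simulate.write_run_inputs(sim_cfg, outdir / "inputs")
        outputs.update({f"inputs/{k}": v for k, v in paths.items()})
        counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
        design = SampleDesign(pd.read_csv(paths["samples"], index_col=0))

    tester = None
    if "de" in config.stages:
        if counts is None:
            counts_path = outdir / "inputs" / "counts.tsv"
            if not counts_path.exists():
                raise PipelineError("de: missing input 'counts' (run simulate first)")
            counts = pd.read_csv(counts_path, sep="\t", index_col=0)
            design = SampleDesign(
                pd.read_csv(outdir / "inputs" / "samples.csv", index_col=0)
            )
        log.info("stage de: %d features", len(counts))
        tester = detest.NBDifferentialTester(
            fdr=config.fdr,
            pseudocount=config.pseudocount,
            min_base_mean=config.min_base_mean,
        ).fit(counts, design)
        for contrast, res in tester.results_.items():
            path = outdir / f"de_{contrast[0]}_vs_{contrast[1]}.tsv"
            with open(path, "w") as fh:
                fh.write(f"# contrast: {contrast[0]} vs {contrast[1]}\n")
                res.to_csv(fh, sep="\t")
            record(f"de_{contrast[0]}_vs_{contrast[1]}", path)
        rlog = tester.transform(counts)
        rlog_path = outdir / "rlog_matrix.tsv"
        rlog.to_csv(rlog_path, sep="\t")
        record("rlog_matrix", rlog_path)
        results["n_significant"] = int(tester.significant_.sum())

    if "cluster" in config.stages:
        if tester is None:
            raise PipelineError("cluster: requires the de stage")
        sig = tester.significant_features_
        if len(sig) < config.n_gene_clusters:
            raise PipelineError(
                f"cluster: only {len(sig)} significant features for "
                f"K={config.n_gene_clusters}"
            )
        log.info("stage cluster: %d significant features", len(sig))
        rlog = tester.transform(counts)
        clusterer = ResponseClusterer(
            n_clusters=config.n_gene_clusters,
            delta=config.delta,
            rho_threshold=config.rho_threshold,
        ).fit(rlog, design, features=sig)
        assign = pd.DataFrame(
            {
                "cluster": clusterer.labels_,
                "response_label": clusterer.feature_labels_,
            }
        )
        a_path = outdir / "cluster_assignments.tsv"
        assign.to_csv(a_path, sep="\t")
        record("cluster_assignments", a_path)
        s_path = outdir / "cluster_summary.tsv"
        clusterer.summary().to_csv(s_path, sep="\t")
        record("cluster_summary", s_path)
        results["cluster_sizes"] = (
            clusterer.labels_.value_counts().sort_index().to_dict()
        )

    if "peaks" in config.stages:
        log.info("stage peaks: venn partition of condition peak sets")
        peak_sets, _, peak_truth = simulate.simulate_peak_landscape(sim_cfg)
        counts_by_label, union = intervals.condition_overlap_partition(peak_sets)
        v_path = outdir / "peak_venn.tsv"
        pd.Series(counts_by_label, name="n_intervals").rename_axis("label").to_csv(
            v_path, sep="\t"
        )
        record("peak_venn", v_path)
        u_path = outdir / "peak_union_labeled.bed"
        union.rename(columns={"label": "name"}).pipe(
            intervals.write_bed, u_path
        )
        record("peak_union_labeled", u_path)
        results["peak_venn"] = counts_by_label

    if "enrich" in config.stages:
        log.info("stage enrich: permutation test, n_perm=%d", config.n_perm)
        fixture = simulate.simulate_enrichment_fixture(seeds["enrich"])
        res = enrichment.permutation_test_peak_sets(
            fixture["query"],
            fixture["designated"],
            fixture["reference"],
            n_perm=config.n_perm,
            seed=seeds["enrich"],
            direction="enrichment",
        )
        e_path = outdir / "enrichment_result.tsv"
        pd.DataFrame(
            [
                {
                    "observed_fraction": res.observed.fraction,
                    "n_query": res.observed.n_query,
                    "n_perm": res.n_permutations,
                    "empirical_p": res.empirical_p,
                    "direction": res.direction,
                    "seed": res.seed,
                }
            ]
        ).to_csv(e_path, sep="\t", index=False)
        record("enrichment_result", e_path)
        results["enrichment_p"] = res.empirical_p

    if "eqtl" in config.stages:
        log.info("stage eqtl: %d cohorts", sim_cfg.n_cohorts)
        cohorts, _ = simulate.simulate_eqtl_cohorts(sim_cfg)
        pairs = pd.DataFrame(
            {
                "variant_id": cohorts[0].dosage.columns,
                "gene_id": cohorts[0].expression.columns,
            }
        )
        study_rows = []
        for c in cohorts:
            for v, g in pairs.itertuples(index=False):
                a = eqtl.fit_additive_model(c, v, g)
                study_rows.append(dataclasses.asdict(a))
        st_path = outdir / "eqtl_per_study.tsv"
        pd.DataFrame(study_rows).to_csv(st_path, sep="\t", index=False)
        record("eqtl_per_study", st_path)
        meta = eqtl.meta_scan(cohorts, pairs)
        m_path = outdir / "eqtl_meta.tsv"
        meta.to_csv(m_path, sep="\t", index=False)
        record("eqtl_meta", m_path)
        results["eqtl_min_p"] = float(meta["p_meta"].min())

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "outputs": outputs,
        "hashes": {k: _sha256(Path(v)) for k, v in outputs.items()},
        "results": results,
    }
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
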