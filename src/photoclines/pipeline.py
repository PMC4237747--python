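"""Config-driven end-to-end runs: simulate -> scan -> enrich -> fst -> dind -> rsb.

Each enabled stage reads the outputs of its dependencies, writes per-stage
TSVs under the output directory and contributes to a JSON run report holding
the gate values, seeds, per-stage counts and (for synthetic runs) the
truth-label recall, so a run is fully reproducible from its report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from photoclines import core_data, differentiation, enrichment, env_scan, haplostats
from photoclines.synthdata import (
    SimulationConfig,
    make_populations,
    simulate_frequencies,
    simulate_genotype_counts,
    simulate_haplotypes,
    write_haplotypes_vcf,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "scan", "enrich", "fst", "dind", "rsb")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; YAML-serializable."""

    out_dir: str = "pipeline_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    reps: int = 1000
    rank_gate: float = 0.95
    p_gate: float = 0.05
    ld_threshold: float = 0.4
    ehhs_floor: float = 0.05
    snps_per_gene: int = 10
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        for name in ("rank_gate", "p_gate", "ld_threshold", "ehhs_floor"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["simulation"]["latitude_range"] = list(self.simulation.latitude_range)
        return d


def _synthetic_genes(table: core_data.FrequencyTable, snps_per_gene: int):
    """Tile consecutive SNPs into gene windows for the synthetic pipeline."""
    genes = []
    snps = table.snps
    for g, start in enumerate(range(0, len(snps), snps_per_gene)):
        chunk = snps[start : start + snps_per_gene]
        genes.append(
            core_data.GeneAnnotation(
                gene_id=f"gene{g:05d}",
                chrom=chunk[0].chrom,
                tx_start=chunk[0].pos,
                tx_end=chunk[-1].pos,
                strand="+",
            )
        )
    return genes


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in config.stages]
    report: dict = {"config": config.to_dict(), "stages": {}}

    if "simulate" not in stages:
        raise ValueError("pipeline currently starts from the simulate stage")
    sim = config.simulation
    populations, env = make_populations(sim)
    table, truth = simulate_frequencies(sim, populations, env)
    core_data.write_populations(populations, out / "populations.tsv")
    env.write(out / "environment.tsv")
    core_data.write_frequency_table(table, out / "frequencies.tsv")
    pd.DataFrame({"snp_id": table.snp_ids, "selected": truth}).to_csv(
        out / "truth_labels.tsv", sep="\t", index=False
    )
    sweep_site = None
    panels = {}
    if {"dind", "rsb"} & set(stages):
        n_sites = int(round(sim.region_length_kb * sim.mutation_density))
        sweep_site = n_sites // 2
        swept_pop, neutral_pop = populations[-1].id, populations[0].id
        panels[swept_pop] = simulate_haplotypes(sim, swept_pop, [sweep_site])
        panels[neutral_pop] = simulate_haplotypes(sim, neutral_pop, [])
        for pid, panel in panels.items():
            write_haplotypes_vcf(panel, out / f"haplotypes_{pid}.vcf")
    report["stages"]["simulate"] = {
        "n_populations": len(populations),
        "n_snps": len(table.snps),
        "n_selected": int(truth.sum()),
        "sweep_site": sweep_site,
    }

    results = None
    gene_map = None
    if "scan" in stages:
        results = env_scan.scan(table, env, "delta_photoperiod")
        env_scan.maf_binned_rank(results)
        env_scan.call_significant(results, n_tests=len(results))
        genes = _synthetic_genes(table, config.snps_per_gene)
        core_data.write_gene_annotations(genes, out / "genes.tsv")
        gene_map = core_data.assign_snps_to_genes(table.snps, genes)
        top = env_scan.top_snp_per_gene(
            results, gene_map, {s.id: s.pos for s in table.snps}
        )
        pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in results],
                "tau": [r.tau for r in results],
                "p_value": [r.p_value for r in results],
                "maf": [r.maf for r in results],
                "tau_rank": [r.tau_rank for r in results],
                "significant": [r.significant for r in results],
            }
        ).to_csv(out / "scan.tsv", sep="\t", index=False)
        sig = {r.snp_id for r in results if r.significant}
        sel = set(np.array(table.snp_ids)[truth])
        recall = len(sig & sel) / len(sel) if sel else float("nan")
        report["stages"]["scan"] = {
            "n_significant": len(sig),
            "n_genes_with_signal": len(top),
            "truth_recall": recall,
        }

    if "enrich" in stages:
        if results is None or gene_map is None:
            raise ValueError("enrich stage requires the scan stage")
        by_id = {r.snp_id: r for r in results}
        universe = {
            g: [by_id[s] for s in snp_ids] for g, snp_ids in gene_map.items()
        }
        sel_ids = set(np.array(table.snp_ids)[truth])
        target_genes = sorted(
            g for g, snp_ids in gene_map.items() if sel_ids & set(snp_ids)
        )
        if target_genes:
            observed = enrichment._count_significant_genes(target_genes, universe)
            res = enrichment.gene_set_resample(
                universe, m=len(target_genes), observed_n=observed,
                reps=config.reps, seed=config.seed,
            )
            report["stages"]["enrich"] = {
                "m_genes": len(target_genes),
                "observed": res.observed,
                "empirical_p": res.empirical_p,
            }
        else:
            report["stages"]["enrich"] = {"m_genes": 0, "note": "no clinal genes"}

    if "fst" in stages:
        gcounts = simulate_genotype_counts(table, sim)
        pair = (populations[0].id, populations[-1].id)
        mafs = core_data.average_maf_all(table)
        matrix = differentiation.pairwise_fst_matrix(
            gcounts, table.population_ids, table.snp_ids, mafs, pairs=[pair]
        )
        ranked, _ = differentiation.maf_binned_fst_rank(matrix[pair])
        n_high, n_low = differentiation.count_extreme(
            ranked, config.rank_gate, 1 - config.rank_gate
        )
        pd.DataFrame(
            {
                "pop1": pair[0],
                "pop2": pair[1],
                "snp_id": [r.snp_id for r in ranked],
                "theta": [r.theta for r in ranked],
                "fst_rank": [r.fst_rank for r in ranked],
            }
        ).to_csv(out / "fst.tsv", sep="\t", index=False)
        report["stages"]["fst"] = {"pair": list(pair), "n_high": n_high, "n_low": n_low}

    if "dind" in stages:
        swept = panels[populations[-1].id]
        batch = haplostats.dind_batch(swept)
        # empirical null: pooled neutral panels, emulating a large random
        # background SNP set
        background = []
        for k in range(10):
            bg_panel = simulate_haplotypes(sim, f"background{k:02d}", [])
            background.extend(haplostats.dind_batch(bg_panel))
        background, cap = haplostats.apply_dind_cap(background)
        batch, _ = haplostats.apply_dind_cap(batch, cap=cap)
        batch, daf_floor = haplostats.dind_significance(
            batch, background, gate=config.rank_gate, cap=cap
        )
        focal = batch[sweep_site]
        pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in batch],
                "daf": [r.daf for r in batch],
                "i_pi_a": [r.i_pi_a for r in batch],
                "i_pi_d": [r.i_pi_d for r in batch],
                "dind": [r.dind for r in batch],
                "significant": [r.significant for r in batch],
            }
        ).to_csv(out / "dind.tsv", sep="\t", index=False)
        report["stages"]["dind"] = {
            "sweep_dind": focal.dind,
            "sweep_significant": focal.significant,
            "daf_floor": daf_floor,
        }

    if "rsb" in stages:
        swept = panels[populations[-1].id]
        neutral = panels[populations[0].id]
        focal_id = swept.snp_ids[sweep_site]
        rsb = haplostats.lnrsb(swept, neutral, [focal_id], gate=config.rank_gate)
        pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in rsb],
                "lnrsb": [r.lnrsb for r in rsb],
                "lnrsb_rank": [r.lnrsb_rank for r in rsb],
                "significant": [r.significant for r in rsb],
            }
        ).to_csv(out / "rsb.tsv", sep="\t", index=False)
        focal_res = next((r for r in rsb if r.snp_id == focal_id), None)
        report["stages"]["rsb"] = {
            "n_region_snps": len(rsb),
            "sweep_lnrsb": None if focal_res is None else focal_res.lnrsb,
            "sweep_significant": None if focal_res is None else focal_res.significant,
        }

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
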