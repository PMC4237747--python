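"""Worked-example fixtures: the published per-SNP summary tables.

Two tables ship with the package as TSV fixtures: 84 top SNPs from five
circadian-related gene sets (core pacemaker, RNAi screen hits, mouse
circadian/sleep mutants, human Mendelian sleep disturbance, melanopsin
signaling) and 18 GWAS risk variants that correlate with Δphotoperiod.  Each
row carries the Kendall p-value, the MAF-binned tau percentile rank, F_ST
percentile ranks for two population pairs and lnRsb percentile ranks for two
population contrasts.  ``table_filters`` recomputes the headline summary
counts from the raw rows using the published rank gates, so the gate logic
can be exercised against known-answer data without any genotype download.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["SummaryTableFixture", "load_tables", "table_filters"]

N_TABLE1_ROWS = 84
N_TABLE2_ROWS = 18
CORE_SET_N_TESTS = 175  # SNPs analyzed in the core circadian set

# Ranks are printed to finite precision; a printed 0.950 sits at the gate, so
# the high-tail gates are applied inclusively at the printed value.
FST_HIGH_GATE = 0.95
FST_LOW_GATE = 0.05
LNRSB_GATE = 0.95


@dataclass
class SummaryTableFixture:
    """Parsed rows of the two published summary tables."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    strict: bool = True  # False permits partial tables (e.g. toy subsets)

    def __post_init__(self) -> None:
        if not self.strict:
            return
        if len(self.table1) != N_TABLE1_ROWS:
            raise ValueError(f"table1 must have {N_TABLE1_ROWS} rows, got {len(self.table1)}")
        if len(self.table2) != N_TABLE2_ROWS:
            raise ValueError(f"table2 must have {N_TABLE2_ROWS} rows, got {len(self.table2)}")
        need1 = {"snp_id", "gene", "gene_set", "kendall_p", "tau_rank",
                 "fst_rank_biaka_orcadian", "fst_rank_biaka_maya",
                 "lnrsb_rank_ceph", "lnrsb_rank_chbjpt", "annotation"}
        need2 = {"snp_id", "genes", "disease", "risk_allele",
                 "risk_decreases_with_delta", "kendall_p", "tau_rank"}
        if miss := need1 - set(self.table1.columns):
            raise ValueError(f"table1 missing columns {sorted(miss)}")
        if miss := need2 - set(self.table2.columns):
            raise ValueError(f"table2 missing columns {sorted(miss)}")
        for df in (self.table1, self.table2):
            if df["snp_id"].duplicated().any():
                raise ValueError("duplicate SNP ids in fixture")


def load_tables() -> SummaryTableFixture:
    """Load the packaged table fixtures."""
    pkg = resources.files("photoclines") / "data"
    with resources.as_file(pkg / "table1_selected_snps.tsv") as p:
        t1 = pd.read_csv(p, sep="\t")
    with resources.as_file(pkg / "table2_gwas_snps.tsv") as p:
        t2 = pd.read_csv(p, sep="\t")
    return SummaryTableFixture(table1=t1, table2=t2)


def table_filters(fixture: SummaryTableFixture) -> dict[str, int]:
    """Recompute the headline counts from the fixture rows.

    All counts are derived from the raw per-row values and the published
    gates, not transcribed: missense annotations, per-pair F_ST tail counts,
    per-contrast lnRsb counts, the Bonferroni-surviving core-set genes
    (p < 0.05/175), disease-subset sizes and risk-allele directions.
    """
    t1, t2 = fixture.table1, fixture.table2
    scz_bpd = t2[t2["disease"].str.contains("SCZ|BPD")]
    counts = {
        "table1_n_snps": len(t1),
        "missense_count": int(t1["annotation"].str.startswith("missense").sum()),
        "fst_high_biaka_orcadian": int(
            (t1["fst_rank_biaka_orcadian"] >= FST_HIGH_GATE).sum()
        ),
        "fst_low_biaka_maya": int((t1["fst_rank_biaka_maya"] < FST_LOW_GATE).sum()),
        "lnrsb_sig_ceph": int((t1["lnrsb_rank_ceph"] >= LNRSB_GATE).sum()),
        "lnrsb_sig_chbjpt": int((t1["lnrsb_rank_chbjpt"] >= LNRSB_GATE).sum()),
        "core_genes_bonferroni": int(
            (
                t1.loc[t1["gene_set"] == "core_circadian", "kendall_p"]
                < 0.05 / CORE_SET_N_TESTS
            ).sum()
        ),
        "table2_n_snps": len(t2),
        "scz_bpd_count": len(scz_bpd),
        "scz_bpd_risk_decreasing": int(
            (scz_bpd["risk_decreases_with_delta"] == "Yes").sum()
        ),
        "mdd_depression_count": int(
            t2["disease"].isin(["MDD", "Depression"]).sum()
        ),
        "asd_count": int((t2["disease"] == "Asperger").sum()),
        "rls_count": int((t2["disease"] == "RLS").sum()),
    }
    for gene_set, group in t1.groupby("gene_set"):
        counts[f"set_{gene_set}_genes"] = group["gene"].nunique()
    return counts
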