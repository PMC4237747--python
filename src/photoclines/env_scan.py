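"""Environmental-correlation selection scan.

Each SNP's per-population allele frequency is rank-correlated (Kendall tau-b)
with an environmental covariate, typically Δphotoperiod.  Demography affects
the whole genome, so raw tau values are converted to empirical percentile
ranks within 1%-wide bins of the average minor allele frequency: a SNP that
ranks high among MAF-matched SNPs is more likely to carry a locus-specific
(selective) signal on top of the genome-wide demographic one.  A SNP is
called significant when its Bonferroni-corrected p-value is below 0.05 AND
its |tau| percentile rank exceeds 0.95.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from photoclines.core_data import FrequencyTable, average_maf_all
from photoclines.photoperiod import EnvironmentTable

logger = logging.getLogger(__name__)

__all__ = [
    "ScanResult",
    "kendall_tau",
    "scan",
    "maf_binned_rank",
    "call_significant",
    "top_snp_per_gene",
    "sample_matched_controls",
    "normalized_daf_profile",
    "mid_rank_percentile",
]

RANK_GATE = 0.95
P_GATE = 0.05
MAF_BIN_WIDTH = 0.01


@dataclass
class ScanResult:
    """Per-SNP outcome of the correlation scan."""

    snp_id: str
    tau: float
    p_value: float
    maf: float
    tau_rank: float | None = None
    significant: bool | None = None
    note: str = ""

    @property
    def evaluable(self) -> bool:
        return math.isfinite(self.tau)


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b with its tie-adjusted two-sided asymptotic p-value.

    Pairs with a missing value in either vector are dropped first; at least
    three complete pairs and non-constant vectors are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def scan(
    table: FrequencyTable, env: EnvironmentTable, variable: str = "delta_photoperiod"
) -> list[ScanResult]:
    """Correlate every SNP's allele_b frequency with an environmental variable.

    SNPs that cannot be tested (fewer than 3 complete populations, or a
    constant frequency vector) are returned with tau = NaN and a note rather
    than dropped, so downstream bookkeeping sees every input SNP.
    """
    env_values = env.values(variable)  # KeyError if absent
    shared = [p for p in table.population_ids if p in env_values.index]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} populations shared between table and environment"
        )
    cols = [table.population_ids.index(p) for p in shared]
    envv = env_values.loc[shared].to_numpy(dtype=float)
    mafs = average_maf_all(table)
    results = []
    for i, snp in enumerate(table.snps):
        row = table.freq[i, cols]
        try:
            tau, p = kendall_tau(row, envv)
            note = ""
        except ValueError as exc:
            tau, p, note = float("nan"), float("nan"), str(exc)
        results.append(
            ScanResult(snp_id=snp.id, tau=tau, p_value=p, maf=float(mafs[i]), note=note)
        )
    return results


def mid_rank_percentile(values: np.ndarray) -> np.ndarray:
    """Mid-rank percentile: (strictly below + half ties) / n, in [0, 1]."""
    values = np.asarray(values, dtype=float)
    n = values.size
    order = np.argsort(values, kind="mergesort")
    sorted_v = values[order]
    below = np.searchsorted(sorted_v, values, side="left")
    upto = np.searchsorted(sorted_v, values, side="right")
    return (below + 0.5 * (upto - below)) / n


def maf_binned_rank(
    results: list[ScanResult], bin_width: float = MAF_BIN_WIDTH
) -> list[ScanResult]:
    """Fill ``tau_rank``: the mid-rank percentile of |tau| among SNPs whose
    average MAF falls in the same right-open ``bin_width`` bin."""
    evaluable = [r for r in results if r.evaluable]
    bins = {}
    for r in evaluable:
        bins.setdefault(int(r.maf / bin_width), []).append(r)
    for key, members in bins.items():
        if len(members) == 1:
            logger.warning("MAF bin %d has a single SNP; rank set to 0.5", key)
            members[0].tau_rank = 0.5
            continue
        ranks = mid_rank_percentile(np.abs([m.tau for m in members]))
        for m, rk in zip(members, ranks):
            m.tau_rank = float(rk)
    return results


def call_significant(results: list[ScanResult], n_tests: int) -> list[ScanResult]:
    """Dual gate: Bonferroni-corrected p < 0.05 AND tau rank > 0.95."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = P_GATE / n_tests
    for r in results:
        if not r.evaluable or r.tau_rank is None:
            r.significant = False
            continue
        r.significant = bool(r.p_value < threshold and r.tau_rank > RANK_GATE)
    return results


def top_snp_per_gene(
    results: list[ScanResult],
    gene_map: dict[str, list[str]],
    positions: dict[str, int] | None = None,
) -> dict[str, ScanResult]:
    """For each gene with at least one significant SNP, its strongest SNP.

    Strength is the tau percentile rank; ties break on smaller p-value, then
    on genomic position (ascending, when given), then on SNP id, so the
    choice is deterministic.
    """
    by_id = {r.snp_id: r for r in results}
    out: dict[str, ScanResult] = {}
    for gene_id, snp_ids in gene_map.items():
        sig = [by_id[s] for s in snp_ids if s in by_id and by_id[s].significant]
        if not sig:
            continue
        out[gene_id] = min(
            sig,
            key=lambda r: (
                -(r.tau_rank or 0.0),
                r.p_value,
                positions.get(r.snp_id, 0) if positions else 0,
                r.snp_id,
            ),
        )
    return out


def sample_matched_controls(
    panel_results: list[ScanResult],
    targets: list[str],
    k_per_target: int = 10,
    seed: int | np.random.Generator = 0,
    maf_tolerance: float = 0.01,
) -> list[str]:
    """Sample k control SNPs per target with average MAF within ±tolerance.

    Controls are drawn without replacement across the whole selection and
    never include target SNPs; same seed, same selection.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target_set = set(targets)
    by_id = {r.snp_id: r for r in panel_results}
    pool = [r for r in panel_results if r.snp_id not in target_set]
    taken: set[str] = set()
    controls: list[str] = []
    for t in targets:
        maf = by_id[t].maf
        candidates = [
            r.snp_id for r in pool
            if abs(r.maf - maf) <= maf_tolerance and r.snp_id not in taken
        ]
        if len(candidates) < k_per_target:
            raise ValueError(
                f"target {t}: only {len(candidates)} MAF-matched candidates "
                f"for {k_per_target} controls"
            )
        chosen = rng.choice(len(candidates), size=k_per_target, replace=False)
        for c in chosen:
            taken.add(candidates[c])
            controls.append(candidates[c])
    return controls


def normalized_daf_profile(
    table: FrequencyTable,
    env: EnvironmentTable | None = None,
    areas: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Per-SNP z-scored derived allele frequencies across populations.

    Each SNP's derived frequencies are centered to mean 0 and scaled to unit
    standard deviation over its non-missing populations; a SNP with zero
    variance yields an all-zero profile (flagged via a log warning).
    Population columns are ordered by geographic area (when ``areas`` maps
    population id -> area label) and by increasing Δphotoperiod within area
    (when ``env`` is given).

    Returns (matrix [n_snps x n_pops], snp_ids, ordered population_ids).
    """
    daf = table.derived_freq()
    pops = list(table.population_ids)
    if env is not None:
        delta = env.values("delta_photoperiod")
        area_of = (areas or {}).get
        pops = sorted(pops, key=lambda p: (str(area_of(p, "")), float(delta.get(p, 0.0))))
    cols = [table.population_ids.index(p) for p in pops]
    daf = daf[:, cols]
    out = np.full_like(daf, np.nan)
    for i in range(daf.shape[0]):
        row = daf[i]
        valid = ~np.isnan(row)
        sd = row[valid].std()
        if sd <= 1e-12:  # numerically constant across populations
            logger.warning("SNP %s: zero variance, flat profile", table.snps[i].id)
            out[i, valid] = 0.0
        else:
            out[i, valid] = (row[valid] - row[valid].mean()) / sd
    return out, table.snp_ids, pops
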