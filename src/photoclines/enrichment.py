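"""Resampling-based enrichment of selection signals in gene and SNP sets.

The observed count of genes (or SNPs) carrying at least one significant
signal is compared with the counts obtained in seeded random resamples of
equal-sized sets from the panel universe; the Bonferroni correction is
re-applied inside every resample with that sample's own SNP count, exactly as
for the observed set.  Empirical p-values use the (count+1)/(reps+1)
estimator so they are never zero.  A simpler excess test against a fixed
null rate (default 5%, the rank-gate expectation) is provided as a Fisher
exact test with a one-sided binomial cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from photoclines.env_scan import RANK_GATE, P_GATE, ScanResult

__all__ = [
    "ResampleResult",
    "gene_set_resample",
    "snp_matched_gene_resample",
    "snp_set_resample",
    "excess_test",
]


@dataclass(frozen=True)
class ResampleResult:
    """Outcome of a resampling test."""

    observed: int
    reps: int
    count_ge: int

    def __post_init__(self) -> None:
        if not 0 <= self.count_ge <= self.reps:
            raise ValueError("count_ge outside [0, reps]")

    @property
    def empirical_p(self) -> float:
        return (self.count_ge + 1) / (self.reps + 1)


def _is_significant(r: ScanResult, p_threshold: float) -> bool:
    return (
        r.evaluable
        and r.tau_rank is not None
        and r.p_value < p_threshold
        and r.tau_rank > RANK_GATE
    )


def _count_significant_genes(
    gene_ids: list[str], universe: dict[str, list[ScanResult]]
) -> int:
    """Genes with >= 1 significant SNP, Bonferroni over this sample's SNPs."""
    n_snps = sum(len(universe[g]) for g in gene_ids)
    threshold = P_GATE / max(n_snps, 1)
    return sum(
        any(_is_significant(r, threshold) for r in universe[g]) for g in gene_ids
    )


def gene_set_resample(
    universe: dict[str, list[ScanResult]],
    m: int,
    observed_n: int,
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> ResampleResult:
    """Empirical probability of >= observed_n genes with a significant SNP in
    a random draw of ``m`` genes from ``universe``.

    ``universe`` maps gene id -> scan results of its SNPs (every gene must
    have at least one).  Each resample draws m genes without replacement and
    applies the Bonferroni correction with that resample's total SNP count.
    """
    genes = sorted(universe)
    if m > len(genes):
        raise ValueError(f"m={m} exceeds universe size {len(genes)}")
    if any(len(universe[g]) == 0 for g in genes):
        raise ValueError("every universe gene needs >= 1 scan result")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count_ge = 0
    for _ in range(reps):
        sample = [genes[i] for i in rng.choice(len(genes), size=m, replace=False)]
        if _count_significant_genes(sample, universe) >= observed_n:
            count_ge += 1
    return ResampleResult(observed=observed_n, reps=reps, count_ge=count_ge)


def snp_matched_gene_resample(
    universe: dict[str, list[ScanResult]],
    target_set: list[str],
    observed_n: int | None = None,
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
    target_counts: dict[str, int] | None = None,
) -> ResampleResult:
    """Like :func:`gene_set_resample`, but each resampled gene is matched to
    one target gene's SNP count (exact count when available, else the nearest
    count within a factor-of-two window).

    ``target_counts`` lets a target gene outside ``universe`` declare its SNP
    count; such targets also require an explicit ``observed_n``.
    """
    genes = sorted(universe)
    if len(target_set) > len(genes):
        raise ValueError("target set larger than universe")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_count: dict[int, list[str]] = {}
    for g in genes:
        by_count.setdefault(len(universe[g]), []).append(g)
    counts_sorted = sorted(by_count)

    def count_of(g: str) -> int:
        if target_counts and g in target_counts:
            return target_counts[g]
        return len(universe[g])

    if observed_n is None:
        observed_n = _count_significant_genes(list(target_set), universe)

    def candidates_for(count: int) -> list[str]:
        if count in by_count:
            return by_count[count]
        in_window = [
            c for c in counts_sorted if count / 2 <= c <= count * 2
        ]
        if not in_window:
            return []
        nearest = min(in_window, key=lambda c: abs(c - count))
        return by_count[nearest]

    pools = []
    for g in target_set:
        pool = candidates_for(count_of(g))
        if not pool:
            raise ValueError(f"no SNP-count match within x2 window for gene {g}")
        pools.append(pool)

    count_ge = 0
    for _ in range(reps):
        sample: list[str] = []
        used: set[str] = set()
        for pool in pools:
            free = [g for g in pool if g not in used] or pool
            pick = free[rng.integers(len(free))]
            used.add(pick)
            sample.append(pick)
        if _count_significant_genes(sample, universe) >= observed_n:
            count_ge += 1
    return ResampleResult(observed=observed_n, reps=reps, count_ge=count_ge)


def snp_set_resample(
    pool: list[ScanResult],
    k: int,
    observed_n: int,
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
    match_maf: bool = False,
    observed_set: list[str] | None = None,
    maf_tolerance: float = 0.01,
) -> ResampleResult:
    """Empirical probability of >= observed_n significant SNPs among k drawn
    from ``pool`` (each pool entry carries its precomputed significance).

    With ``match_maf`` the resampled SNPs are frequency-matched: each draw
    takes one SNP within ±maf_tolerance of one observed SNP's average MAF
    (``observed_set`` then supplies the observed SNP ids, |set| = k).
    """
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flags = np.array([bool(r.significant) for r in pool])
    if match_maf:
        if observed_set is None or len(observed_set) != k:
            raise ValueError("match_maf requires observed_set of length k")
        by_id = {r.snp_id: r for r in pool}
        mafs = np.array([r.maf for r in pool])
        pools = []
        for snp_id in observed_set:
            cand = np.flatnonzero(np.abs(mafs - by_id[snp_id].maf) <= maf_tolerance)
            if cand.size == 0:
                raise ValueError(f"no MAF match for SNP {snp_id}")
            pools.append(cand)
        count_ge = 0
        for _ in range(reps):
            used: set[int] = set()
            n_sig = 0
            for cand in pools:
                free = [i for i in cand if i not in used] or list(cand)
                pick = free[rng.integers(len(free))]
                used.add(pick)
                n_sig += flags[pick]
            if n_sig >= observed_n:
                count_ge += 1
    else:
        count_ge = 0
        for _ in range(reps):
            idx = rng.choice(len(pool), size=k, replace=False)
            if int(flags[idx].sum()) >= observed_n:
                count_ge += 1
    return ResampleResult(observed=observed_n, reps=reps, count_ge=count_ge)


def excess_test(
    observed_sig: int, total: int, null_rate: float = 0.05
) -> dict[str, float]:
    """Excess of significant counts over a fixed null rate.

    Two-sided Fisher exact test on [[observed, total-observed],
    [expected, total-expected]] with expected = round(null_rate * total),
    plus a one-sided binomial tail as a cross-check.
    """
    if not 0 <= observed_sig <= total:
        raise ValueError("observed_sig outside [0, total]")
    expected = int(round(null_rate * total))
    table = [[observed_sig, total - observed_sig], [expected, total - expected]]
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    binom_p = float(stats.binomtest(observed_sig, total, null_rate,
                                    alternative="greater").pvalue)
    return {
        "observed": float(observed_sig),
        "expected": float(expected),
        "fisher_p": fisher_p,
        "binomial_p": binom_p,
    }
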