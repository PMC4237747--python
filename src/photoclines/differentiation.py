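"""Pairwise population differentiation (Weir-Cockerham F_ST) with MAF-binned
empirical percentile ranks.

The estimator is Weir & Cockerham's (1984) theta for two populations at a
biallelic site, built from the among-population (a), among-individual (b) and
within-individual (c) variance components with observed heterozygosity.
Negative estimates are kept as-is: clamping would distort the low tail, and
the scan's "below the 0.05 percentile" analysis lives in that tail.  Because
F_ST depends on allele frequency, per-pair values are ranked within 50
equal-width average-MAF classes on [0, 0.5].
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from photoclines.env_scan import mid_rank_percentile

logger = logging.getLogger(__name__)

__all__ = [
    "FstResult",
    "wc_fst",
    "wc_fst_components",
    "pairwise_fst_matrix",
    "maf_binned_fst_rank",
    "count_extreme",
]

N_MAF_CLASSES = 50


@dataclass
class FstResult:
    """Per-SNP, per-population-pair Weir-Cockerham theta."""

    snp_id: str
    pop_pair: tuple[str, str]
    theta: float  # NaN when undefined (monomorphic across both populations)
    maf: float
    fst_rank: float | None = None


def wc_fst_components(counts_pop1, counts_pop2) -> tuple[float, float, float]:
    """Weir-Cockerham variance components (a, b, c) for one biallelic site:
    among-population, among-individual-within-population and within-
    individual, from two (hom_ref, het, hom_alt) genotype counts.

    Per-site theta is a/(a+b+c); a multi-locus estimate sums each component
    over loci before taking the ratio.
    """
    counts = np.asarray([counts_pop1, counts_pop2], dtype=float)
    if counts.shape != (2, 3):
        raise ValueError("each population needs (hom_ref, het, hom_alt) counts")
    n = counts.sum(axis=1)  # individuals per population
    if np.any(n < 2):
        raise ValueError("need >= 2 genotyped individuals per population")
    p = (2 * counts[:, 2] + counts[:, 1]) / (2 * n)  # alt-allele frequency
    h = counts[:, 1] / n  # observed heterozygosity
    r = 2
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def wc_fst(counts_pop1, counts_pop2) -> float:
    """Weir-Cockerham theta from two (hom_ref, het, hom_alt) genotype counts.

    Returns NaN (flagged by the caller) when the site is monomorphic across
    both populations; negative estimates are returned as-is.
    """
    counts = np.asarray([counts_pop1, counts_pop2], dtype=float)
    n = counts.sum(axis=1)
    if np.any(n < 2):
        raise ValueError("need >= 2 genotyped individuals per population")
    p = (2 * counts[:, 2] + counts[:, 1]) / (2 * n)
    if p[0] in (0.0, 1.0) and p[1] == p[0]:
        return float("nan")
    a, b, c = wc_fst_components(counts_pop1, counts_pop2)
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return float(a / denom)


def pairwise_fst_matrix(
    genotype_counts: np.ndarray,
    population_ids: list[str],
    snp_ids: list[str],
    mafs: np.ndarray,
    pairs: list[tuple[str, str]] | None = None,
    min_individuals: int = 2,
) -> dict[tuple[str, str], list[FstResult]]:
    """Per-SNP theta for every (or the given) unordered population pair.

    ``genotype_counts`` has shape (n_snps, n_pops, 3) with per-population
    (hom_ref, het, hom_alt) counts.  Pairs where either population has fewer
    than ``min_individuals`` genotyped at a SNP are flagged missing.
    """
    genotype_counts = np.asarray(genotype_counts, dtype=float)
    n_snps, n_pops, _ = genotype_counts.shape
    if n_pops < 2:
        raise ValueError("need >= 2 populations")
    if pairs is None:
        pairs = list(itertools.combinations(population_ids, 2))
    idx = {p: k for k, p in enumerate(population_ids)}
    out: dict[tuple[str, str], list[FstResult]] = {}
    for p1, p2 in pairs:
        results = []
        for i in range(n_snps):
            c1, c2 = genotype_counts[i, idx[p1]], genotype_counts[i, idx[p2]]
            if c1.sum() < min_individuals or c2.sum() < min_individuals:
                logger.warning("pair (%s,%s) SNP %s: too few individuals",
                               p1, p2, snp_ids[i])
                theta = float("nan")
            else:
                theta = wc_fst(c1, c2)
            results.append(
                FstResult(snp_id=snp_ids[i], pop_pair=(p1, p2), theta=theta,
                          maf=float(mafs[i]))
            )
        out[(p1, p2)] = results
    return out


def maf_binned_fst_rank(
    results: list[FstResult], n_classes: int = N_MAF_CLASSES
) -> tuple[list[FstResult], dict[int, float]]:
    """Fill ``fst_rank`` within ``n_classes`` equal-width MAF classes on
    [0, 0.5]; also return each class's 95th percentile of theta.

    Returns (results, {class index -> 95th percentile}).
    """
    width = 0.5 / n_classes
    evaluable = [r for r in results if np.isfinite(r.theta)]
    classes: dict[int, list[FstResult]] = {}
    for r in evaluable:
        k = min(int(r.maf / width), n_classes - 1)
        classes.setdefault(k, []).append(r)
    percentiles: dict[int, float] = {}
    for k, members in sorted(classes.items()):
        thetas = np.array([m.theta for m in members])
        percentiles[k] = float(np.percentile(thetas, 95))
        if len(members) == 1:
            logger.warning("MAF class %d has a single SNP; rank set to 0.5", k)
            members[0].fst_rank = 0.5
            continue
        ranks = mid_rank_percentile(thetas)
        for m, rk in zip(members, ranks):
            m.fst_rank = float(rk)
    return results, percentiles


def count_extreme(
    results: list[FstResult], hi_gate: float = 0.95, lo_gate: float = 0.05
) -> tuple[int, int]:
    """(n with rank > hi_gate, n with rank < lo_gate) over ranked results."""
    ranks = [r.fst_rank for r in results if r.fst_rank is not None]
    n_high = sum(rk > hi_gate for rk in ranks)
    n_low = sum(rk < lo_gate for rk in ranks)
    return n_high, n_low
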