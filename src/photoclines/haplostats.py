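"""Haplotype-based positive-selection statistics: DIND and EHHS/iES/lnRsb.

DIND (derived intra-allelic nucleotide diversity) contrasts the mean pairwise
haplotype diversity among carriers of the ancestral allele (iπ_A) with that
among derived-allele carriers (iπ_D) over a fixed window of flanking variants
(20 per side).  A sweep on the derived allele leaves derived carriers on a
long shared haplotype, so iπ_D collapses and the ratio iπ_A/iπ_D blows up;
ratios with iπ_D = 0 are set to the dataset's maximum finite value plus 20.
Significance is empirical: above the 95th percentile of a background
DIND-vs-DAF distribution binned into 100 derived-allele-frequency classes;
low-DAF classes where the background itself is dominated by iπ_D = 0 are not
evaluable, which yields an empirical DAF floor for the test.

EHHS is the probability that two haplotypes drawn without replacement are
identical over the interval from a focal SNP out to a given site, normalized
to 1 at the focal site and followed outward until it decays below 0.05.  Its
integral over physical position (iES) measures how far homozygosity extends;
lnRsb = ln(iES_pop1/iES_pop2), median-centered over all SNPs in the analyzed
regions, picks up population-specific extension, with empirical mid-rank
percentiles supplying significance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from photoclines.core_data import HaplotypePanel
from photoclines.env_scan import mid_rank_percentile

logger = logging.getLogger(__name__)

__all__ = [
    "DindResult",
    "RsbResult",
    "window_pairwise_diversity",
    "dind",
    "dind_batch",
    "apply_dind_cap",
    "dind_significance",
    "haplotype_homozygosity",
    "ehhs",
    "ies",
    "lnrsb",
]

DIND_FLANK = 20          # flanking variants per side
DIND_CAP_OFFSET = 20.0   # added to the dataset maximum when i_pi_D = 0
EHHS_FLOOR = 0.05
N_DAF_CLASSES = 100
REGION_HALFWIDTH = 100_000  # bp each side for lnRsb regions


@dataclass
class DindResult:
    snp_id: str
    daf: float
    i_pi_a: float
    i_pi_d: float
    dind: float  # inf until the dataset cap is applied; NaN when not computable
    significant: bool | None = None  # None = not evaluable
    note: str = ""


@dataclass
class RsbResult:
    snp_id: str
    ies_pop1: float
    ies_pop2: float
    lnrsb_raw: float
    lnrsb: float | None = None       # median-centered
    lnrsb_rank: float | None = None  # mid-rank percentile in the pooled set
    significant: bool | None = None


def window_pairwise_diversity(
    panel: HaplotypePanel, haplotype_subset, site_window
) -> float:
    """Mean pairwise difference count among a haplotype subset over a window.

    ``site_window`` is a sequence of site indices; ``haplotype_subset`` a
    sequence of haplotype row indices (>= 2 required).
    """
    rows = np.asarray(haplotype_subset, dtype=int)
    if rows.size < 2:
        raise ValueError("need >= 2 haplotypes")
    sub = panel.alleles[np.ix_(rows, np.asarray(site_window, dtype=int))]
    m = rows.size
    c = sub.sum(axis=0, dtype=np.int64)
    total_diffs = (c * (m - c)).sum()  # per site: derived x ancestral pairs
    return float(total_diffs / (m * (m - 1) / 2))


def _flank_window(panel: HaplotypePanel, focal: int, flank: int) -> np.ndarray:
    lo = max(focal - flank, 0)
    hi = min(focal + flank, panel.n_sites - 1)
    got = (focal - lo) + (hi - focal)
    if got < 2 * flank:
        logger.debug(
            "SNP at site %d: window truncated to %d of %d flanking variants",
            focal, got, 2 * flank,
        )
    window = np.r_[lo:focal, focal + 1 : hi + 1]
    return window


def dind(panel: HaplotypePanel, focal_snp: int, flank: int = DIND_FLANK) -> DindResult:
    """DIND at one site: iπ_A/iπ_D over ``flank`` variants each side.

    The focal site must be polarized (panel coding is 0 = ancestral).  With
    fewer than two carriers of either allele the result is flagged not
    computable (NaN).  iπ_D = 0 yields +inf; apply :func:`apply_dind_cap`
    over the full batch to replace it with (dataset max + 20).
    """
    alleles = panel.alleles[:, focal_snp]
    snp_id = panel.snp_ids[focal_snp] if panel.snp_ids else str(focal_snp)
    derived = np.flatnonzero(alleles == 1)
    ancestral = np.flatnonzero(alleles == 0)
    daf = derived.size / alleles.size
    if derived.size < 2 or ancestral.size < 2:
        return DindResult(snp_id, daf, math.nan, math.nan, math.nan,
                          note="fewer than 2 carriers of one allele")
    window = _flank_window(panel, focal_snp, flank)
    i_pi_a = window_pairwise_diversity(panel, ancestral, window)
    i_pi_d = window_pairwise_diversity(panel, derived, window)
    value = math.inf if i_pi_d == 0 else i_pi_a / i_pi_d
    return DindResult(snp_id, daf, i_pi_a, i_pi_d, value)


def dind_batch(
    panel: HaplotypePanel, sites=None, flank: int = DIND_FLANK
) -> list[DindResult]:
    if sites is None:
        sites = range(panel.n_sites)
    return [dind(panel, s, flank) for s in sites]


def apply_dind_cap(
    results: list[DindResult], cap: float | None = None
) -> tuple[list[DindResult], float]:
    """Replace infinite DIND values by dataset-max finite DIND + 20.

    Returns (results, cap value used).  ``cap`` may be supplied to reuse the
    cap of a background dataset for a foreground batch.
    """
    if cap is None:
        finite = [r.dind for r in results if math.isfinite(r.dind)]
        top = max(finite) if finite else 0.0
        cap = top + DIND_CAP_OFFSET
    for r in results:
        if math.isinf(r.dind):
            r.dind = cap
    return results, cap


def dind_significance(
    results: list[DindResult],
    background: list[DindResult],
    n_daf_classes: int = N_DAF_CLASSES,
    gate: float = 0.95,
    cap: float | None = None,
    min_class_size: int = 20,
) -> tuple[list[DindResult], float | None]:
    """Empirical DIND significance against a background distribution.

    The background (DIND, DAF) pairs are binned into ``n_daf_classes``
    equal-width DAF classes; a focal SNP is significant when its DIND exceeds
    its class's ``gate`` quantile.  Classes whose quantile is itself a capped
    value (the background there is dominated by iπ_D = 0) or that hold fewer
    than two background values are not evaluable; the lowest DAF at which a
    class is evaluable is returned as the empirical DAF floor.

    Classes with fewer than ``min_class_size`` background values are also
    marked not evaluable: a 95th percentile from a handful of values carries
    no 5%-tail meaning.  The background should be large relative to
    ``n_daf_classes`` (the emulated design used 20,000 panel SNPs).
    """
    bg = [b for b in background if math.isfinite(b.dind)]
    if not bg:
        raise ValueError("empty background")
    if cap is None:
        cap = max(b.dind for b in bg)  # capped values are the batch maximum
    width = 1.0 / n_daf_classes
    classes: dict[int, list[float]] = {}
    for b in bg:
        k = min(int(b.daf / width), n_daf_classes - 1)
        classes.setdefault(k, []).append(b.dind)
    thresholds: dict[int, float] = {}
    for k, values in classes.items():
        if len(values) < max(min_class_size, 2):
            continue
        q = float(np.percentile(values, 100 * gate))
        if q >= cap:  # the tail is made of iπ_D = 0 caps: not evaluable
            continue
        thresholds[k] = q
    daf_floor = min((k * width for k in thresholds), default=None)
    for r in results:
        if not math.isfinite(r.dind):
            r.significant = None
            continue
        k = min(int(r.daf / width), n_daf_classes - 1)
        if k not in thresholds:
            r.significant = None
            r.note = (r.note + "; " if r.note else "") + "DAF class not evaluable"
            continue
        r.significant = bool(r.dind > thresholds[k])
    return results, daf_floor


def haplotype_homozygosity(alleles: np.ndarray) -> float:
    """Probability two haplotypes drawn without replacement are identical
    over the given (n_haplotypes x n_sites) matrix:
    sum n_h (n_h - 1) / (n (n - 1)) over distinct haplotype classes."""
    n = alleles.shape[0]
    _, counts = np.unique(alleles, axis=0, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehhs(
    panel: HaplotypePanel, focal_snp: int, direction: int,
    floor: float = EHHS_FLOOR,
) -> list[tuple[int, float]]:
    """EHHS curve from the focal site outward in one direction (+1 / -1).

    Each point is (position, homozygosity of the interval focal..site divided
    by the focal-site homozygosity).  The curve starts at (focal position, 1)
    and stops once the value drops below ``floor`` (the crossing point is
    kept) or the data ends.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    if panel.n_haplotypes < 4:
        raise ValueError("need >= 4 haplotypes")
    h0 = haplotype_homozygosity(panel.alleles[:, [focal_snp]])
    if h0 == 0:
        raise ValueError("focal-site homozygosity is zero")
    curve = [(int(panel.positions[focal_snp]), 1.0)]
    site = focal_snp + direction
    while 0 <= site < panel.n_sites:
        lo, hi = sorted((focal_snp, site))
        h = haplotype_homozygosity(panel.alleles[:, lo : hi + 1])
        value = h / h0
        curve.append((int(panel.positions[site]), value))
        if value < floor:
            break
        site += direction
    return curve


def ies(curve_left: list[tuple[int, float]], curve_right: list[tuple[int, float]]) -> float:
    """Trapezoid integral (bp x homozygosity) of a two-sided EHHS curve.

    ``curve_left`` and ``curve_right`` both start at the focal site; the
    focal point is counted once.
    """
    points = list(reversed(curve_left)) + curve_right[1:]
    if len(points) < 2:
        raise ValueError("single-point curve: iES undefined")
    pos = np.array([p for p, _ in points], dtype=float)
    val = np.array([v for _, v in points], dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("curve positions not increasing")
    return float(np.trapezoid(val, pos))


def _ies_at(panel: HaplotypePanel, site: int) -> float:
    left = ehhs(panel, site, -1)
    right = ehhs(panel, site, +1)
    return ies(left, right)


def lnrsb(
    panel_pop1: HaplotypePanel,
    panel_pop2: HaplotypePanel,
    snp_set: list[str],
    region_halfwidth: int = REGION_HALFWIDTH,
    gate: float = 0.95,
) -> list[RsbResult]:
    """lnRsb for all SNPs in regions around the selected variants.

    Both panels must share positions and SNP ids.  For every SNP within
    ``region_halfwidth`` of a selected variant, lnrsb_raw =
    ln(iES_pop1/iES_pop2); the pooled values are median-centered and given
    mid-rank percentiles, with significance at rank >= ``gate`` (upper tail:
    extended homozygosity in pop1 relative to pop2).
    """
    if panel_pop1.snp_ids is None or panel_pop1.snp_ids != panel_pop2.snp_ids:
        raise ValueError("panels must share SNP ids")
    if not np.array_equal(panel_pop1.positions, panel_pop2.positions):
        raise ValueError("panels must share positions")
    positions = panel_pop1.positions
    region_sites: set[int] = set()
    for snp_id in snp_set:
        focal = panel_pop1.site_index(snp_id)
        center = positions[focal]
        lo = np.searchsorted(positions, center - region_halfwidth, side="left")
        hi = np.searchsorted(positions, center + region_halfwidth, side="right")
        region_sites.update(range(int(lo), int(hi)))
    results: list[RsbResult] = []
    for site in sorted(region_sites):
        snp_id = panel_pop1.snp_ids[site]
        try:
            i1 = _ies_at(panel_pop1, site)
            i2 = _ies_at(panel_pop2, site)
        except ValueError as exc:
            logger.warning("SNP %s skipped: %s", snp_id, exc)
            continue
        if i1 <= 0 or i2 <= 0:
            logger.warning("SNP %s skipped: non-positive iES", snp_id)
            continue
        results.append(RsbResult(snp_id, i1, i2, math.log(i1 / i2)))
    if not results:
        return results
    raw = np.array([r.lnrsb_raw for r in results])
    centered = raw - np.median(raw)
    ranks = mid_rank_percentile(centered)
    for r, c, rk in zip(results, centered, ranks):
        r.lnrsb = float(c)
        r.lnrsb_rank = float(rk)
        r.significant = bool(rk >= gate)
    return results
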