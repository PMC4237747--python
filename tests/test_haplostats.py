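"""DIND and EHHS/iES/lnRsb haplotype selection statistics."""

import itertools
import math

import numpy as np
import pytest

from photoclines.core_data import HaplotypePanel
from photoclines.haplostats import (
    apply_dind_cap,
    dind,
    dind_batch,
    dind_significance,
    ehhs,
    haplotype_homozygosity,
    ies,
    lnrsb,
    window_pairwise_diversity,
)
from photoclines.synthdata import SimulationConfig, simulate_haplotypes


def _panel(alleles, positions=None, ids=True):
    alleles = np.asarray(alleles, dtype=np.int8)
    n_sites = alleles.shape[1]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    return HaplotypePanel(
        population_id="p", chrom="1", positions=positions, alleles=alleles,
        snp_ids=[f"s{i}" for i in range(n_sites)] if ids else None,
    )


def brute_force_pi(alleles, rows, cols):
    pairs = list(itertools.combinations(rows, 2))
    total = sum(
        int((alleles[i, cols] != alleles[j, cols]).sum()) for i, j in pairs
    )
    return total / len(pairs)


class TestWindowPairwiseDiversity:
    def test_identical_haplotypes_give_zero(self):
        panel = _panel(np.tile([0, 1, 0, 1], (4, 1)))
        assert window_pairwise_diversity(panel, [0, 1, 2, 3], range(4)) == 0.0

    def test_single_pair_counts_differences(self):
        a = np.zeros((4, 40), dtype=int)
        a[1, [3, 17, 29]] = 1
        panel = _panel(a)
        assert window_pairwise_diversity(panel, [0, 1], range(40)) == 3.0

    def test_matches_exhaustive_pair_count(self, rng):
        a = rng.integers(0, 2, (6, 30))
        panel = _panel(a)
        rows, cols = [0, 2, 3, 5], list(range(5, 25))
        assert window_pairwise_diversity(panel, rows, cols) == pytest.approx(
            brute_force_pi(a, rows, cols), abs=1e-12
        )

    def test_subset_too_small_rejected(self):
        panel = _panel(np.zeros((4, 10)))
        with pytest.raises(ValueError, match=">= 2"):
            window_pairwise_diversity(panel, [0], range(10))


class TestDind:
    def test_equal_diversity_gives_one(self, rng):
        background = rng.integers(0, 2, (8, 41))
        background[:4] = background[4:]  # ancestral rows mirror derived rows
        background[:, 20] = [0, 0, 0, 0, 1, 1, 1, 1]
        panel = _panel(background)
        res = dind(panel, 20)
        assert res.dind == pytest.approx(1.0)

    def test_swept_fixture_hits_cap(self, rng):
        a = rng.integers(0, 2, (10, 41))
        a[5:] = a[5]          # derived carriers identical
        a[:, 20] = [0] * 5 + [1] * 5
        results = [dind(_panel(a), 20)]
        assert math.isinf(results[0].dind)
        results, cap = apply_dind_cap(results + [dind(_panel(a), 19)])
        assert results[0].dind == cap

    def test_matches_brute_force_ratio(self, rng):
        a = rng.integers(0, 2, (6, 41))
        a[:, 20] = [0, 0, 0, 1, 1, 1]
        res = dind(_panel(a), 20)
        window = [c for c in range(41) if c != 20]
        expected = (
            brute_force_pi(a, [0, 1, 2], window)
            / brute_force_pi(a, [3, 4, 5], window)
        )
        assert res.dind == pytest.approx(expected, abs=1e-12)

    def test_few_carriers_flagged(self):
        a = np.zeros((6, 41), dtype=int)
        a[0, 20] = 1  # single derived carrier
        res = dind(_panel(a), 20)
        assert math.isnan(res.dind)
        assert "carriers" in res.note

    def test_invariant_to_monomorphic_within_class_sites(self, rng):
        """Inserting a site that is monomorphic within each allele class
        (widening the flank so the original sites stay in the window) leaves
        both intra-allelic diversities, hence DIND, unchanged."""
        a = rng.integers(0, 2, (8, 41))
        a[:, 20] = [0] * 4 + [1] * 4
        base = dind(_panel(a), 20, flank=20).dind
        extra = np.where(a[:, 20] == 1, 1, 0).reshape(-1, 1)
        b = np.hstack([extra, a])  # focal moves to 21
        assert dind(_panel(b), 21, flank=21).dind == pytest.approx(base, abs=1e-12)


class TestDindSignificance:
    def _background(self, rng, n=3000):
        return apply_dind_cap([
            dind_result for dind_result in (
                _fake_dind(f"b{i}", daf=float(rng.uniform(0.05, 0.95)),
                           value=float(rng.lognormal(0, 0.5)))
                for i in range(n)
            )
        ])

    def test_value_above_entire_class_is_significant(self, rng):
        background, cap = self._background(rng)
        focal = _fake_dind("f", daf=0.5, value=1e6)
        results, _ = dind_significance([focal], background, cap=cap)
        assert results[0].significant is True

    def test_low_daf_class_not_evaluable(self, rng):
        background, cap = self._background(rng)
        focal = _fake_dind("f", daf=0.001, value=5.0)  # no background below 0.05
        results, floor = dind_significance([focal], background, cap=cap)
        assert results[0].significant is None
        assert floor is not None and floor > 0.001

    def test_neutral_type_one_error_near_five_percent(self, rng):
        background, cap = self._background(rng, n=5000)
        probes = [
            _fake_dind(f"p{i}", daf=float(rng.uniform(0.1, 0.9)),
                       value=float(rng.lognormal(0, 0.5)))
            for i in range(1000)
        ]
        results, _ = dind_significance(probes, background, cap=cap)
        rate = np.mean([r.significant for r in results if r.significant is not None])
        assert rate == pytest.approx(0.05, abs=0.03)

    def test_empty_background_errors(self):
        with pytest.raises(ValueError, match="empty"):
            dind_significance([_fake_dind("f", 0.5, 1.0)], [])


def _fake_dind(snp_id, daf, value):
    from photoclines.haplostats import DindResult

    return DindResult(snp_id, daf, 1.0, 1.0, value)


def brute_force_ehhs(alleles, focal, site):
    """Identical-pair fraction over the interval, normalized at the focal."""
    lo, hi = sorted((focal, site))
    n = alleles.shape[0]

    def hom(cols):
        pairs = list(itertools.combinations(range(n), 2))
        same = sum(np.array_equal(alleles[i, cols], alleles[j, cols])
                   for i, j in pairs)
        return same / len(pairs)

    return hom(list(range(lo, hi + 1))) / hom([focal])


class TestEhhs:
    def test_normalized_to_one_at_focal(self, rng):
        a = rng.integers(0, 2, (6, 11))
        curve = ehhs(_panel(a), 5, +1)
        assert curve[0] == (6000, 1.0)

    def test_identical_haplotypes_stay_at_one(self):
        a = np.tile([0, 1, 1, 0, 1], (5, 1))
        curve = ehhs(_panel(a), 2, +1)
        assert [v for _, v in curve] == [1.0, 1.0, 1.0]

    def test_matches_brute_force_identical_pair_fraction(self, rng):
        a = rng.integers(0, 2, (8, 15))
        a[:, 7] = [0, 0, 0, 0, 1, 1, 1, 1]  # keep focal homozygosity positive
        panel = _panel(a)
        for direction in (+1, -1):
            curve = ehhs(panel, 7, direction, floor=0.0)
            for k, (_, value) in enumerate(curve[1:], start=1):
                site = 7 + direction * k
                assert value == pytest.approx(
                    brute_force_ehhs(a, 7, site), abs=1e-10
                )

    def test_non_increasing_and_bounded(self, rng):
        a = rng.integers(0, 2, (10, 31))
        curve = ehhs(_panel(a), 15, +1, floor=0.0)
        values = [v for _, v in curve]
        assert all(0.0 <= v <= 1.0 + 1e-12 for v in values)
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))

    def test_truncates_below_floor(self, rng):
        a = rng.integers(0, 2, (20, 41))
        curve = ehhs(_panel(a), 20, +1, floor=0.05)
        assert all(v >= 0.05 for _, v in curve[:-1])


class TestIes:
    def test_rectangle(self):
        left = [(10_000, 1.0), (5_000, 1.0), (0, 1.0)]
        right = [(10_000, 1.0), (15_000, 1.0), (20_000, 1.0)]
        assert ies(left, right) == pytest.approx(20_000.0)

    def test_triangle_decay(self):
        left = [(1_000, 1.0), (0, 0.0)]
        right = [(1_000, 1.0), (2_000, 0.0)]
        assert ies(left, right) == pytest.approx(1_000.0)

    def test_matches_fine_riemann_sum(self):
        xs = np.linspace(0, 5_000, 21)
        values = np.exp(-xs / 2_000)
        right = list(zip((5_000 + xs).astype(int), values))
        left = list(zip((5_000 - xs).astype(int), values))
        fine_x = np.linspace(0, 5_000, 200_001)
        fine = 2 * np.trapezoid(
            np.interp(fine_x, xs, values), fine_x
        )
        assert ies(left, right) == pytest.approx(fine, rel=0.01)

    def test_single_point_curve_rejected(self):
        with pytest.raises(ValueError, match="single-point"):
            ies([(0, 1.0)], [(0, 1.0)])


class TestLnRsb:
    def _two_panels(self, rng, sweep=False):
        cfg = SimulationConfig(seed=17, n_haplotypes=60, region_length_kb=200)
        n_sites = int(round(cfg.region_length_kb * cfg.mutation_density))
        focal = n_sites // 2
        p1 = simulate_haplotypes(cfg, "a", [focal] if sweep else [])
        p2 = simulate_haplotypes(cfg, "b", [])
        return p1, p2, p1.snp_ids[focal]

    def test_identical_panels_give_zero_raw_lnrsb(self, rng):
        p1, _, focal = self._two_panels(rng)
        results = lnrsb(p1, p1, [focal], region_halfwidth=20_000)
        assert all(r.lnrsb_raw == pytest.approx(0.0, abs=1e-12) for r in results)

    def test_centered_median_is_zero(self, rng):
        p1, p2, focal = self._two_panels(rng, sweep=True)
        results = lnrsb(p1, p2, [focal], region_halfwidth=50_000)
        assert np.median([r.lnrsb for r in results]) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_under_population_swap(self, rng):
        p1, p2, focal = self._two_panels(rng, sweep=True)
        fwd = lnrsb(p1, p2, [focal], region_halfwidth=30_000)
        rev = lnrsb(p2, p1, [focal], region_halfwidth=30_000)
        for a, b in zip(fwd, rev):
            assert a.lnrsb_raw == pytest.approx(-b.lnrsb_raw, abs=1e-12)
            assert a.lnrsb_rank == pytest.approx(1.0 - b.lnrsb_rank, abs=1e-9)

    def test_planted_sweep_scores_in_upper_tail(self, rng):
        p1, p2, focal = self._two_panels(rng, sweep=True)
        results = lnrsb(p1, p2, [focal], region_halfwidth=100_000)
        focal_res = next(r for r in results if r.snp_id == focal)
        assert focal_res.lnrsb_rank > 0.9

    def test_mismatched_panels_rejected(self, rng):
        cfg = SimulationConfig(seed=1, region_length_kb=50)
        p1 = simulate_haplotypes(cfg, "a", [])
        cfg2 = SimulationConfig(seed=1, region_length_kb=60)
        p2 = simulate_haplotypes(cfg2, "b", [])
        with pytest.raises(ValueError, match="share"):
            lnrsb(p1, p2, [p1.snp_ids[0]])


def test_haplotype_homozygosity_counts_identical_pairs(rng):
    a = rng.integers(0, 2, (6, 4))
    pairs = list(itertools.combinations(range(6), 2))
    expected = np.mean([np.array_equal(a[i], a[j]) for i, j in pairs])
    assert haplotype_homozygosity(a) == pytest.approx(expected, abs=1e-12)
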