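"""Exact and binned IEQ, bin factors, bin assignment, volume shares."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from isletquant import (
    BinningScheme,
    assign_bin,
    batch_from_diameters,
    bin_factor,
    ieq_binned,
    ieq_exact,
    ieq_exact_total,
    volume_share_by_class,
)


class TestIeqExact:
    @pytest.mark.parametrize(
        "d,expected", [(150, 1.0), (75, 0.125), (300, 8.0), (50, (1 / 3) ** 3)]
    )
    def test_reference_values(self, d, expected):
        assert ieq_exact(d) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ieq_exact(0)


class TestBinFactor:
    def test_midpoint_values(self):
        assert bin_factor(50, 100, "midpoint") == pytest.approx(0.125)
        assert bin_factor(100, 200, "midpoint") == pytest.approx(1.0)

    @given(
        lo=st.floats(20.0, 300.0),
        width=st.floats(1.0, 100.0),
    )
    def test_mean_volume_matches_numeric_integration(self, lo, width):
        # independent oracle: average (d/150)³ over a uniform diameter
        hi = lo + width
        oracle, _ = integrate.quad(lambda d: (d / 150.0) ** 3 / width, lo, hi)
        assert bin_factor(lo, hi, "mean_volume") == pytest.approx(oracle, rel=1e-9)

    def test_mean_volume_reference(self):
        assert bin_factor(50, 100, "mean_volume") == pytest.approx(0.138889, abs=1e-6)

    @given(lo=st.floats(20.0, 300.0), width=st.floats(0.5, 100.0))
    def test_mean_volume_at_least_midpoint(self, lo, width):
        # cubic convexity (Jensen): uniform-average volume >= midpoint volume
        hi = lo + width
        assert bin_factor(lo, hi, "mean_volume") >= bin_factor(lo, hi, "midpoint")

    def test_rejects_invalid_interval(self):
        with pytest.raises(ValueError):
            bin_factor(100, 100)
        with pytest.raises(ValueError):
            bin_factor(0, 50)


class TestAssignBin:
    def test_interval_membership(self, scheme):
        assert assign_bin(120, scheme) == "100-150"
        assert assign_bin(50, scheme) == "50-100"  # half-open boundary
        assert assign_bin(99.999, scheme) == "50-100"
        assert assign_bin(400, scheme) == ">350"
        assert assign_bin(350, scheme) == ">350"

    def test_sub50_handling(self, scheme):
        assert assign_bin(40, scheme) == "excluded"
        sub = BinningScheme(include_sub50=True)
        assert assign_bin(40, sub) == "20-50"
        assert assign_bin(10, sub) == "excluded"  # below the 20 μm floor

    def test_rejects_nonpositive(self, scheme):
        with pytest.raises(ValueError):
            assign_bin(0, scheme)


class TestIeqBinned:
    def test_single_islet(self, scheme):
        res = ieq_binned(batch_from_diameters([175.0]), scheme)
        assert res.total_ieq == pytest.approx((175 / 150) ** 3, rel=1e-9)
        assert res.total_ieq == pytest.approx(1.588, abs=1e-3)

    def test_ten_small_islets(self, scheme):
        res = ieq_binned(batch_from_diameters([75.0] * 10), scheme)
        assert res.total_ieq == pytest.approx(1.25)
        assert res.n_included == 10

    def test_all_sub50_excluded(self, scheme):
        res = ieq_binned(batch_from_diameters([30.0, 45.0, 25.0]), scheme)
        assert res.total_ieq == 0.0
        assert res.n_excluded == 3

    def test_empty_batch_rejected(self, scheme):
        with pytest.raises(ValueError):
            ieq_binned(batch_from_diameters([]), scheme)

    def test_totals_consistent_with_per_bin(self, scheme, rng):
        batch = batch_from_diameters(rng.uniform(20, 400, 500))
        res = ieq_binned(batch, BinningScheme(include_sub50=True))
        assert res.total_ieq == pytest.approx(sum(b.ieq for b in res.per_bin.values()))
        assert res.n_included + res.n_excluded == len(batch)

    def test_custom_factor_table(self, scheme):
        batch = batch_from_diameters([75.0] * 4)
        res = ieq_binned(batch, scheme, custom_factors={"50-100": 0.2})
        assert res.total_ieq == pytest.approx(0.8)

    @given(st.lists(st.floats(21.0, 399.0), min_size=1, max_size=30))
    def test_permutation_invariance_and_additivity(self, ds):
        s = BinningScheme(include_sub50=True)
        total = ieq_binned(batch_from_diameters(ds), s).total_ieq
        rev = ieq_binned(batch_from_diameters(ds[::-1]), s).total_ieq
        assert rev == pytest.approx(total, rel=1e-12)
        if len(ds) > 1:
            parts = (
                ieq_binned(batch_from_diameters(ds[:1]), s).total_ieq
                + ieq_binned(batch_from_diameters(ds[1:]), s).total_ieq
            )
            assert parts == pytest.approx(total, rel=1e-12)

    def test_excluding_sub50_never_increases_total(self, rng):
        batch = batch_from_diameters(rng.uniform(20, 200, 300))
        with_sub = ieq_binned(batch, BinningScheme(include_sub50=True)).total_ieq
        without = ieq_binned(batch, BinningScheme(include_sub50=False)).total_ieq
        assert without <= with_sub


class TestRefinementConvergence:
    def test_midpoint_gap_shrinks_monotonically_on_uniform_batch(self):
        # per-bin midpoint bias is O(width²) for uniform within-bin diameters,
        # so halving the bins must shrink the gap
        batch = batch_from_diameters(np.linspace(50, 350, 1000, endpoint=False))
        exact = ieq_exact_total(batch)
        gaps = []
        for splits in (1, 2, 4):  # 50 → 25 → 12.5 μm bins
            s = BinningScheme(factor_dialect="midpoint").refined(splits)
            gaps.append(abs(ieq_binned(batch, s).total_ieq - exact) / exact)
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-3

    def test_mean_volume_dialect_is_unbiased_on_uniform_batch(self):
        # the mean-volume factor is the exact average IEQ of a uniform bin, so
        # even 50 μm bins are already at the grid-resolution floor
        batch = batch_from_diameters(np.linspace(50, 350, 1000, endpoint=False))
        exact = ieq_exact_total(batch)
        mid = ieq_binned(batch, BinningScheme(factor_dialect="midpoint")).total_ieq
        mv = ieq_binned(batch, BinningScheme(factor_dialect="mean_volume")).total_ieq
        assert abs(mv - exact) < abs(mid - exact) / 5
        assert abs(mv - exact) / exact < 1e-3

    @pytest.mark.parametrize("dialect", ["midpoint", "mean_volume"])
    def test_fine_bins_converge_for_random_batch(self, dialect, rng):
        batch = batch_from_diameters(rng.uniform(50, 350, 1000))
        exact = ieq_exact_total(batch)
        coarse = abs(ieq_binned(batch, BinningScheme(factor_dialect=dialect)).total_ieq - exact)
        fine = abs(
            ieq_binned(batch, BinningScheme(factor_dialect=dialect).refined(64)).total_ieq - exact
        )
        assert fine < coarse
        assert fine / exact < 1e-3


class TestVolumeShare:
    def test_degenerate_shares(self):
        assert volume_share_by_class(batch_from_diameters([30, 40]), 50) == 1.0
        assert volume_share_by_class(batch_from_diameters([100, 200]), 50) == 0.0

    def test_two_islet_share(self):
        share = volume_share_by_class(batch_from_diameters([50.0, 150.0]), 50)
        assert share == pytest.approx((50 / 150) ** 3 / (1 + (50 / 150) ** 3), rel=1e-9)
        assert share == pytest.approx(0.0357, abs=1e-4)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            volume_share_by_class(batch_from_diameters([]), 50)
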