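"""Ground-truth generator: size distributions, shapes, technician, aliquots."""

import numpy as np
import pytest

import isletquant as iq
from isletquant import BinningScheme, ShapeModel, TechnicianModel
from isletquant.ieq import EXCLUDED, ieq_binned, ieq_exact_total
from isletquant.species import ProfileError, get_profile, lognormal_params
from isletquant.synth import (
    calibrate_technician,
    dissociation_experiment,
    sample_prep,
    sample_shapes,
    simulate_aliquot,
    simulate_technician_binning,
)


class TestSpeciesRegistry:
    def test_known_species_present(self):
        reg = iq.species_registry()
        assert {"human", "rat", "mouse", "adult_pig", "canine"} <= set(reg)
        assert reg["human"].mean_d == 108.0
        assert reg["rat"].sd_d == 5.0

    def test_goat_profile_cannot_be_sampled(self):
        # the published goat entry carries a range but no usable mean/sd
        with pytest.raises(ProfileError):
            sample_prep("goat", 10, seed=0)

    def test_lognormal_moment_match(self):
        mu, sigma = lognormal_params(108.0, 6.0)
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(108.0)
        var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
        assert np.sqrt(var) == pytest.approx(6.0)


class TestSamplePrep:
    def test_determinism(self):
        p1 = sample_prep("rat", 100, seed=42)
        p2 = sample_prep("rat", 100, seed=42)
        np.testing.assert_array_equal(p1.diameters, p2.diameters)
        np.testing.assert_array_equal(p1.perimeters, p2.perimeters)
        np.testing.assert_array_equal(p1.cells, p2.cells)

    def test_single_islet_prep_valid(self):
        prep = sample_prep("rat", 1, seed=0)
        batch = prep.to_batch()
        assert len(batch) == 1
        assert batch[0].shape.a >= batch[0].shape.b >= batch[0].shape.c > 0

    def test_human_mean_diameter(self):
        prep = sample_prep("human", 10_000, seed=11)
        assert prep.diameters.mean() == pytest.approx(108.0, abs=2.0)

    def test_moment_convergence_large_n(self):
        prep = sample_prep("human", 100_000, seed=12)
        assert prep.diameters.mean() == pytest.approx(108.0, rel=0.01)
        assert prep.diameters.std() == pytest.approx(6.0, rel=0.01)

    def test_axis_ratio_mean(self):
        prep = sample_prep("rat", 5000, seed=13)
        assert (prep.b / prep.a).mean() == pytest.approx(0.82, abs=0.02)
        assert (prep.c / prep.a).mean() == pytest.approx(0.70, abs=0.02)

    def test_mean_of_axes_equals_diameter(self):
        prep = sample_prep("rat", 200, seed=14)
        np.testing.assert_allclose((prep.a + prep.b + prep.c) / 3, prep.diameters)

    def test_purity_validated(self):
        with pytest.raises(ValueError):
            sample_prep("rat", 10, purity=0.0, seed=0)


class TestCircularityTargeting:
    @pytest.mark.parametrize("size_class,target", [("small", 0.801), ("large", 0.740)])
    def test_class_means_hit_targets(self, size_class, target):
        model = ShapeModel()
        rng = np.random.default_rng(99)
        lo, hi = (30, model.size_cutoff) if size_class == "small" else (model.size_cutoff, 350)
        d = rng.uniform(lo, hi, 1000)
        a, b, c, area, peri = sample_shapes(d, model, rng)
        circ = np.minimum(1.0, 4 * np.pi * area / peri**2)
        assert circ.mean() == pytest.approx(target, abs=0.01)

    def test_unreachable_target_rejected(self):
        model = ShapeModel(circ_small=0.999)
        with pytest.raises(ValueError):
            model.roughness_magnitude("small")


class TestTechnician:
    def test_zero_probabilities_are_identity(self, rat_prep, scheme):
        labels = simulate_technician_binning(rat_prep, scheme, TechnicianModel(0, 0, seed=1))
        expected = [iq.assign_bin(float(d), scheme) for d in rat_prep.diameters]
        assert labels == expected

    def test_forced_upshift_increases_ieq(self, rat_prep, scheme):
        labels = simulate_technician_binning(rat_prep, scheme, TechnicianModel(1.0, 0.0, seed=1))
        batch = rat_prep.to_batch()
        shifted = ieq_binned(batch, scheme, assigned_bins=labels).total_ieq
        assert shifted > ieq_binned(batch, scheme).total_ieq
        # every non-top islet moved exactly one bin up
        order = scheme.labels()
        for d, lab in zip(rat_prep.diameters, labels):
            true = iq.assign_bin(float(d), scheme)
            if true != EXCLUDED and true != order[-1]:
                assert order.index(lab) == order.index(true) + 1

    def test_upshift_fraction_matches_probability(self, scheme):
        prep = sample_prep("rat", 10_000, seed=15)
        tech = TechnicianModel(p_upbin=0.3, p_downbin=0.0, seed=77)
        labels = simulate_technician_binning(prep, scheme, tech)
        order = scheme.labels()
        true = [iq.assign_bin(float(d), scheme) for d in prep.diameters]
        shifted = sum(
            1
            for t, lab in zip(true, labels)
            if t != EXCLUDED and t != order[-1] and lab != t
        )
        eligible = sum(1 for t in true if t != EXCLUDED and t != order[-1])
        assert shifted / eligible == pytest.approx(0.30, abs=0.02)

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            TechnicianModel(0.7, 0.5)

    def test_calibrated_default_overestimates_half_the_time(self, rat_prep, scheme):
        tech = calibrate_technician(rat_prep, scheme)
        batch = rat_prep.to_batch()
        truth = ieq_binned(batch, scheme).total_ieq
        over = 0
        for rep in range(200):
            labels = simulate_technician_binning(
                rat_prep, scheme, tech, rng=np.random.default_rng(3000 + rep)
            )
            over += ieq_binned(batch, scheme, assigned_bins=labels).total_ieq > truth
        assert over / 200 == pytest.approx(0.50, abs=0.05)


class TestAliquot:
    def test_unbiased_at_zero_settling_bias(self, rat_prep):
        truth = ieq_exact_total(rat_prep.to_batch())
        frac = 0.1
        ests = []
        for s in range(500):
            sub = simulate_aliquot(rat_prep, frac, settling_bias=0.0, seed=s)
            ests.append(ieq_exact_total(sub.to_batch()) / frac)
        ests = np.array(ests)
        ci = 3 * ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - truth) < ci

    def test_settling_bias_enriches_large_islets(self, rat_prep):
        means = [
            simulate_aliquot(rat_prep, 0.2, settling_bias=4.0, seed=s).diameters.mean()
            for s in range(50)
        ]
        assert np.mean(means) > rat_prep.diameters.mean()

    def test_full_fraction_limit(self, rat_prep):
        sub = simulate_aliquot(rat_prep, 0.999, seed=1)
        assert sub.n == rat_prep.n
        np.testing.assert_array_equal(np.sort(sub.diameters), np.sort(rat_prep.diameters))

    def test_fraction_validation(self, rat_prep):
        for bad in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                simulate_aliquot(rat_prep, bad)


class TestEndToEndFlawDemo:
    def test_binned_density_below_actual(self, rat_prep, scheme):
        # the binning-induced density underestimation, end to end: staff
        # over-estimate diameters while binning, so the assigned category
        # diameter exceeds the measured one and apparent density drops
        tech = TechnicianModel(p_upbin=0.3, p_downbin=0.05)
        records = dissociation_experiment(
            rat_prep, scheme, tech, rng=np.random.default_rng(5)
        )
        actual, _ = iq.density_per_micron(records, "actual")
        binned, _ = iq.density_per_micron(records, "binned")
        assert binned < actual
        assert iq.percent_underestimation(actual, binned) > 0
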