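"""4PL fitting, LOD, cross-reactivity, unit conversions and Scatchard K_a."""

import numpy as np
import pytest

from maturelib.binding import (
    AssayConfig,
    DegenerateDataError,
    DoseResponseDataset,
    FourPLFit,
    ScatchardDataset,
    convert_units,
    cross_reactivity,
    fit_4pl,
    fold_improvement,
    lod,
    scatchard_ka,
)
from maturelib.fixtures import (
    DoseResponseConfig,
    ScatchardConfig,
    generate_doseresponse,
    generate_scatchard,
)


class TestFit4PL:
    def test_noiseless_wild_type_curve_recovers_midpoint(self):
        data = generate_doseresponse(DoseResponseConfig(midpoint=706.0, cv=0.0))
        fit = fit_4pl(data)
        assert fit.converged
        assert fit.midpoint == pytest.approx(706.0, rel=1e-3)
        assert fit.slope == pytest.approx(1.0, rel=1e-3)

    @pytest.mark.parametrize("slope", [0.5, 1.0, 2.0, 3.0])
    def test_noiseless_recovery_across_slopes(self, slope):
        data = generate_doseresponse(
            DoseResponseConfig(midpoint=29.4, slope=slope, dose_min=0.1,
                               dose_max=10_000.0, cv=0.0)
        )
        fit = fit_4pl(data)
        assert fit.midpoint == pytest.approx(29.4, rel=1e-3)

    def test_noisy_recovery_unbiased_within_5_percent(self):
        """3% multiplicative noise, 4 replicates, 100 seeded replicates.

        Individual fits scatter (free top/bottom soak up noise) but the mean
        recovered midpoint stays within 5% of the generating value.
        """
        recovered = []
        for seed in range(100):
            data = generate_doseresponse(
                DoseResponseConfig(midpoint=29.4, cv=0.03, dose_min=1.0,
                                   dose_max=3000.0, seed=seed)
            )
            fit = fit_4pl(data)
            assert fit.converged
            recovered.append(fit.midpoint)
        assert np.mean(recovered) == pytest.approx(29.4, rel=0.05)

    def test_response_at_midpoint_is_half_maximal(self):
        fit = FourPLFit(top=100.0, bottom=0.0, midpoint=37.5, slope=1.0,
                        residual_rms=0.0, converged=True)
        assert fit.predict(37.5) == pytest.approx(50.0)
        assert fit.invert(50.0) == pytest.approx(37.5)

    def test_all_equal_responses_rejected(self):
        data = DoseResponseDataset(
            doses=np.array([0.0, 1.0, 10.0, 100.0, 1000.0]),
            responses=np.full(5, 1.2),
        )
        with pytest.raises(DegenerateDataError):
            fit_4pl(data)

    def test_needs_four_distinct_nonzero_doses(self):
        with pytest.raises(ValueError):
            DoseResponseDataset(
                doses=np.array([0.0, 1.0, 10.0, 100.0]),
                responses=np.array([1.0, 0.9, 0.5, 0.1]),
            )

    def test_raw_responses_need_zero_dose_anchor(self):
        with pytest.raises(ValueError):
            DoseResponseDataset(
                doses=np.array([1.0, 10.0, 100.0, 1000.0]),
                responses=np.array([1.0, 0.9, 0.5, 0.1]),
            )


class TestLod:
    def fitted(self, midpoint=29.4):
        return FourPLFit(top=100.0, bottom=0.0, midpoint=midpoint, slope=1.0,
                         residual_rms=0.0, converged=True)

    def dataset_with_b0(self, b0_values):
        doses = np.array([1.0, 10.0, 100.0, 1000.0])
        fit = self.fitted()
        responses = np.asarray(fit.predict(doses))
        return DoseResponseDataset(
            doses=np.concatenate([np.zeros(len(b0_values)), doses]),
            responses=np.concatenate([np.asarray(b0_values, float), responses]),
            normalized=True,
        )

    def b0_with_exact_sd(self, sd, n=10, mean=100.0):
        base = np.linspace(-1.0, 1.0, n)
        standardized = (base - base.mean()) / base.std(ddof=1)
        return mean + sd * standardized

    def test_rule_inverts_to_configured_dose(self):
        """B0 dispersion chosen so mean - 2 SD lands exactly on 3.9 pg/assay."""
        fit = self.fitted(midpoint=29.4)
        target_pct = float(fit.predict(3.9))
        sd = (100.0 - target_pct) / 2.0
        data = self.dataset_with_b0(self.b0_with_exact_sd(sd))
        result = lod(data, fit)
        assert result.defined
        assert result.dose == pytest.approx(3.9, rel=1e-9)

    def test_zero_variance_b0_gives_zero_lod(self):
        data = self.dataset_with_b0(np.full(10, 100.0))
        result = lod(data, self.fitted())
        assert result.defined
        assert result.dose == 0.0

    def test_monotone_in_b0_sd(self):
        fit = self.fitted()
        lods = []
        for sd in (2.0, 5.0, 10.0, 20.0):
            data = self.dataset_with_b0(self.b0_with_exact_sd(sd))
            lods.append(lod(data, fit).dose)
        assert lods == sorted(lods)

    def test_threshold_below_bottom_flagged_undefined(self):
        fit = FourPLFit(top=100.0, bottom=60.0, midpoint=10.0, slope=1.0,
                        residual_rms=0.0, converged=True)
        data = self.dataset_with_b0(self.b0_with_exact_sd(30.0))
        result = lod(data, fit)
        assert not result.defined
        assert result.dose is None

    def test_needs_two_b0_replicates(self):
        data = self.dataset_with_b0([100.0])
        with pytest.raises(ValueError):
            lod(data, self.fitted())


class TestCrossReactivity:
    def test_equal_midpoints_give_100(self):
        assert cross_reactivity(3.5, 3.5) == 100.0

    def test_double_analog_midpoint_gives_50(self):
        assert cross_reactivity(10.0, 20.0) == 50.0

    def test_prednisone_scale_example(self):
        # analyte 706 vs analog 90,513 -> 0.78%
        assert cross_reactivity(706.0, 90_513.0) == pytest.approx(0.78, abs=0.005)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            cross_reactivity(0.0, 1.0)


class TestConvertUnits:
    def test_worked_example_10_pg_per_assay(self):
        conv = convert_units(10.0)
        assert conv.pg_per_ml == pytest.approx(66.7, abs=0.05)
        assert conv.pmol_per_l == pytest.approx(184.0, abs=0.5)

    def test_serum_equivalent_of_lod(self):
        conv = convert_units(10.2)
        assert conv.serum_ng_per_ml == pytest.approx(2.0, abs=0.05)

    def test_zero_amount_gives_zeros(self):
        conv = convert_units(0.0)
        assert (conv.pg_per_ml, conv.pmol_per_l, conv.serum_ng_per_ml) == (0, 0, 0)

    def test_linearity(self):
        one, five = convert_units(1.0), convert_units(5.0)
        assert five.pg_per_ml == pytest.approx(5 * one.pg_per_ml)
        assert five.serum_ng_per_ml == pytest.approx(5 * one.serum_ng_per_ml)

    def test_round_trip_pg_ml_to_pmol_l(self):
        config = AssayConfig()
        conv = convert_units(123.4, config)
        assert conv.pmol_per_l * config.analyte_molar_mass / 1000.0 == pytest.approx(
            conv.pg_per_ml
        )

    def test_standard_volume_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            AssayConfig(total_volume_ul=50.0, standard_volume_ul=150.0)


class TestScatchard:
    def test_noiseless_wild_type_ka_recovered(self):
        data = generate_scatchard(ScatchardConfig(ka=3.6e8, cv=0.0))
        result = scatchard_ka(data)
        assert result.valid
        assert result.ka == pytest.approx(3.6e8, rel=1e-3)

    def test_noisy_high_affinity_recovery_within_10_percent(self):
        """2% noise, 6 points: K_a = 1.1e10 recovered within 10% per seed."""
        for seed in range(100):
            data = generate_scatchard(
                ScatchardConfig(ka=1.1e10, cv=0.02, n_points=6, seed=seed)
            )
            result = scatchard_ka(data)
            assert result.valid
            assert result.ka == pytest.approx(1.1e10, rel=0.10)

    def test_sites_total_recovered(self):
        config = ScatchardConfig(ka=3.6e8, sites_total=2e-9, cv=0.0)
        result = scatchard_ka(generate_scatchard(config))
        assert result.sites_total == pytest.approx(2e-9, rel=1e-6)

    def test_flat_ratio_flagged_invalid(self):
        data = ScatchardDataset(
            bound=np.array([1.0, 2.0, 3.0]), free=np.array([1.0, 2.0, 3.0])
        )
        result = scatchard_ka(data)
        assert not result.valid
        assert np.isnan(result.ka)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            ScatchardDataset(bound=np.array([1.0, 2.0]), free=np.array([1.0, 2.0]))


class TestFoldImprovement:
    def test_headline_ka_folds(self):
        assert fold_improvement(1.1e10, 3.6e8).display == 31
        assert fold_improvement(0.62e10, 3.6e8).display == 17

    def test_midpoint_sensitivity_fold(self):
        result = fold_improvement(706.0, 29.4)
        assert result.ratio == pytest.approx(24.0, abs=0.05)
        assert result.display == 24

    def test_equal_inputs_give_unity(self):
        assert fold_improvement(5.0, 5.0).ratio == 1.0

    def test_display_rounds_half_away_from_zero(self):
        assert fold_improvement(3.5, 1.0).display == 4
        assert fold_improvement(2.49, 1.0).display == 2

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            fold_improvement(-1.0, 2.0)
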