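"""Explant assay quantification: tissue volume, interval rates, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivdmet.assay import (
    AssayConstants,
    CultureWell,
    InvalidMeasurementError,
    RateResult,
    aggregate_by_animal,
    compute_tissue_volume,
    interval_rates,
    quantify_cohort,
    rates_to_frame,
    steady_state_rates,
)
from ivdmet.synth import (
    DEFAULT_TREATMENTS,
    AssayDesign,
    cohort_to_frames,
    default_ground_truth,
    generate_cohort,
)


def make_well(glucose, lactate, times=None, v_tissue=0.1, media=0.6, region="NP"):
    """Well with wet/buoyant weights chosen to give the requested volume."""
    times = times if times is not None else tuple(range(len(glucose)))
    return CultureWell(
        animal_id="A01",
        region=region,
        treatment="control",
        wet_weight=0.05 + 1.07 * v_tissue,
        buoyant_weight=0.05,
        media_volume=media,
        times=tuple(float(t) for t in times),
        glucose_series=tuple(glucose),
        lactate_series=tuple(lactate),
        well_id="w1",
    )


class TestTissueVolume:
    @pytest.mark.parametrize(
        "wet, buoyant, rho, expected",
        [
            (0.107, 0.0, 1.07, 0.1),
            (0.05, 0.05, 1.07, 0.0),
            (0.0535, 0.0107, 1.07, 0.04),
        ],
    )
    def test_archimedes(self, wet, buoyant, rho, expected):
        assert compute_tissue_volume(wet, buoyant, rho) == pytest.approx(expected)

    def test_buoyant_exceeding_wet_names_the_well(self):
        with pytest.raises(InvalidMeasurementError, match="w9"):
            compute_tissue_volume(0.05, 0.06, 1.07, well_id="w9")


class TestIntervalRates:
    def test_glucose_drop_rate(self):
        # 0.1 mM drop over 1 h in 0.6 mL against 0.4 million cells -> 150
        constants = AssayConstants(rho_cell={"NP": 4.0})
        well = make_well([5.5, 5.4], [0.0, 0.0], v_tissue=0.1, media=0.6)
        (_, gcr, lpr), = interval_rates(well, constants)
        assert gcr == pytest.approx(150.0)
        assert lpr == pytest.approx(0.0)

    def test_lactate_rise_rate(self):
        # 0.05 mM rise over 1 h in 0.8 mL against 1.0 million cells -> 40
        constants = AssayConstants(rho_cell={"NP": 10.0})
        well = make_well([5.5, 5.5], [0.10, 0.15], v_tissue=0.1, media=0.8)
        (_, gcr, lpr), = interval_rates(well, constants)
        assert lpr == pytest.approx(40.0)
        assert gcr == pytest.approx(0.0)

    def test_flat_series_gives_zero_rates(self):
        well = make_well([5.5] * 6, [0.9] * 6)
        for _, gcr, lpr in interval_rates(well):
            assert gcr == 0.0 and lpr == 0.0

    def test_needs_two_time_points(self):
        well = make_well([5.5], [0.9])
        with pytest.raises(ValueError):
            interval_rates(well)

    def test_zero_tissue_volume_rejected(self):
        well = CultureWell(
            "A01", "NP", "control", 0.05, 0.05, 0.6,
            (0.0, 1.0), (5.5, 5.4), (0.0, 0.1), well_id="wz",
        )
        with pytest.raises(InvalidMeasurementError):
            interval_rates(well)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        scale=st.floats(min_value=0.25, max_value=4.0),
        drops=st.lists(
            st.floats(min_value=0.0, max_value=0.3), min_size=3, max_size=6
        ),
    )
    def test_scale_invariance(self, scale, drops):
        """Doubling media volume and cell count leaves the rates unchanged."""
        glucose = 5.5 - np.cumsum([0.0] + drops)
        lactate = np.cumsum([0.0] + drops)
        base = make_well(glucose, lactate, v_tissue=0.1, media=0.6)
        scaled = make_well(glucose, lactate, v_tissue=0.1 * scale, media=0.6 * scale)
        r0 = interval_rates(base)
        r1 = interval_rates(scaled)
        for (t0, g0, l0), (t1, g1, l1) in zip(r0, r1):
            assert g1 == pytest.approx(g0, rel=1e-12)
            assert l1 == pytest.approx(l0, rel=1e-12)

    def test_sign_convention(self):
        """Falling glucose and rising lactate both yield positive rates."""
        well = make_well([5.5, 5.3, 5.2, 5.0], [0.0, 0.1, 0.3, 0.4])
        for _, gcr, lpr in interval_rates(well):
            assert gcr > 0 and lpr > 0


class TestSteadyStateRates:
    def test_window_uses_three_hourly_intervals(self):
        well = make_well([5.5, 5.4, 5.3, 5.2, 5.1, 5.0], [0, 0.1, 0.2, 0.3, 0.4, 0.5])
        res = steady_state_rates(well)
        assert res.n_intervals == 3

    def test_constant_rate_roundtrip(self):
        """Noiseless constant-rate series recovers the generating rates."""
        constants = AssayConstants(rho_cell={"NP": 4.0})
        # truth gcr*=100, lpr*=150 against 0.4 Mcells in 0.6 mL
        slope_g = 100 * 0.4 / (1000 * 0.6)  # mM/h
        slope_l = 150 * 0.4 / (1000 * 0.6)
        t = np.arange(6.0)
        well = make_well(5.5 - slope_g * t, slope_l * t, v_tissue=0.1, media=0.6)
        res = steady_state_rates(well, constants)
        assert res.gcr == pytest.approx(100.0, rel=1e-12)
        assert res.lpr == pytest.approx(150.0, rel=1e-12)
        assert res.ratio == pytest.approx(1.5, rel=1e-12)

    def test_equal_rates_give_unit_ratio(self):
        constants = AssayConstants(rho_cell={"NP": 4.0})
        t = np.arange(6.0)
        well = make_well(5.5 - 0.05 * t, 0.05 * t, v_tissue=0.1, media=0.6)
        res = steady_state_rates(well, constants)
        assert res.ratio == pytest.approx(1.0)

    def test_nonpositive_gcr_flags_ratio_undefined(self):
        well = make_well([5.5] * 6, np.arange(6.0) * 0.05)
        res = steady_state_rates(well)
        assert not res.ratio_defined and np.isnan(res.ratio)
        assert res.lpr > 0

    def test_no_interval_in_window_errors(self):
        well = make_well([5.5, 5.4], [0.0, 0.1], times=(0.0, 1.0))
        with pytest.raises(ValueError, match="window"):
            steady_state_rates(well)

    def test_regression_matches_interval_mean_on_linear_series(self):
        t = np.arange(6.0)
        well = make_well(5.5 - 0.08 * t, 0.12 * t)
        a = steady_state_rates(well, method="interval_mean")
        b = steady_state_rates(well, method="regression")
        assert b.gcr == pytest.approx(a.gcr, rel=1e-9)
        assert b.lpr == pytest.approx(a.lpr, rel=1e-9)


class TestAggregation:
    @staticmethod
    def res(gcr, lpr, ratio, animal="A01", region="NP", well="w"):
        return RateResult(animal, region, "control", gcr, lpr, ratio, 3, well)

    def test_duplicate_well_means(self):
        out = aggregate_by_animal(
            [self.res(100, 150, 1.5, well="w1"), self.res(120, 150, 1.25, well="w2")]
        )
        assert len(out) == 1
        row = out.iloc[0]
        assert row.gcr_nmol_per_Mcells_h == pytest.approx(110.0)
        assert row.lpr_nmol_per_Mcells_h == pytest.approx(150.0)
        # mean of ratios, not ratio of means
        assert row.ratio_lpr_gcr == pytest.approx(1.375)

    def test_single_replicate_passthrough(self):
        out = aggregate_by_animal([self.res(80, 90, 1.125)])
        assert out.iloc[0].gcr_nmol_per_Mcells_h == pytest.approx(80.0)
        assert out.iloc[0].n_wells == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_by_animal([])

    def test_replicate_means_recover_truth_under_noise(self):
        """Mean over many noisy replicates approaches the generating rate."""
        design = AssayDesign(
            n_animals=10, regions=("NP",),
            treatments={"control": DEFAULT_TREATMENTS["control"]},
            replicates=3, noise_sd_mM=0.02, seed=11,
        )
        wells, truth = generate_cohort(design, default_ground_truth())
        results = [steady_state_rates(w) for w in wells]
        df = rates_to_frame(results)
        est = df.gcr_nmol_per_Mcells_h
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 149.13) < 3 * se + 1e-9


class TestCsvInterface:
    def test_cohort_roundtrip_through_tables(self, tmp_path):
        design = AssayDesign(n_animals=2, replicates=2, noise_sd_mM=0.0, seed=3)
        wells, truth = generate_cohort(design)
        meas, meta = cohort_to_frames(wells)
        mpath, wpath = tmp_path / "meas.csv", tmp_path / "wells.csv"
        meas.to_csv(mpath, index=False)
        meta.to_csv(wpath, index=False)
        per_well, per_animal = quantify_cohort(mpath, wpath)
        merged = per_well.merge(truth, on="well_id")
        assert np.allclose(
            merged.gcr_nmol_per_Mcells_h, merged.true_gcr, rtol=1e-9, atol=1e-9
        )
        assert set(per_animal.columns) >= {
            "animal_id", "region", "treatment", "gcr_nmol_per_Mcells_h"
        }

    def test_missing_measurements_error(self):
        meta = pd.DataFrame(
            [{"well_id": "w1", "animal_id": "A01", "region": "NP",
              "treatment": "control", "wet_weight_g": 0.157,
              "buoyant_weight_g": 0.05, "media_volume_mL": 0.6}]
        )
        meas = pd.DataFrame(
            [{"well_id": "other", "time_h": 0.0, "glucose_mM": 5.5, "lactate_mM": 0.0}]
        )
        with pytest.raises(ValueError, match="w1"):
            quantify_cohort(meas, meta)
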