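"""Staged constrained fitting: replicate selection, stages, full pipeline."""

import numpy as np
import pytest

from phantomgel import (
    FitConfig,
    FitStageError,
    MeasurementRecord,
    fit_agarose_only,
    fit_full,
    fit_mixing_model,
    fit_salt_only,
    fit_water,
    read_measurements,
    select_fit_measurements,
    write_measurements,
)
from phantomgel.synthetic_data import DesignSpec, generate_measurements


def rec(sample_id="s", salt="none", N=0.0, G=0.0, field=0.064, temp=20.0,
        t1=None, t2=None):
    return MeasurementRecord(sample_id=sample_id, salt=salt, salt_conc=N,
                             agarose_conc=G, field_T=field, temperature_C=temp,
                             t1_s=t1, t2_s=t2)


def from_rates(c, G, N):
    return 1.0 / (c[0] + c[1] * G + c[2] * G**2 + c[3] * N + c[4] * N**2
                  + c[5] * G * N + c[6] * G**2 * N + c[7] * G * N**2
                  + c[8] * G**2 * N**2)


class TestMeasurementRecord:
    def test_needs_at_least_one_time(self):
        with pytest.raises(ValueError):
            rec()

    def test_rejects_nonpositive_time(self):
        with pytest.raises(ValueError):
            rec(t1=-1.0)

    def test_salt_none_requires_zero_concentration(self):
        with pytest.raises(ValueError):
            rec(salt="none", N=1.0, t1=1.0)


class TestSelectFitMeasurements:
    def test_nearest_temperature_wins(self):
        records = [rec("a", temp=18, t1=1.0), rec("b", temp=25, t1=2.0)]
        out = select_fit_measurements(records)
        assert len(out) == 1 and out[0].t1_s == 1.0

    def test_same_temperature_replicates_averaged_in_time_domain(self):
        records = [rec("a", t1=1.0), rec("b", t1=1.2)]
        out = select_fit_measurements(records)
        assert len(out) == 1
        assert out[0].t1_s == pytest.approx(1.1, abs=1e-12)

    def test_equidistant_temperatures_both_retained_and_averaged(self):
        records = [rec("a", temp=19, t1=1.0), rec("b", temp=21, t1=3.0)]
        out = select_fit_measurements(records)
        assert len(out) == 1
        assert out[0].t1_s == pytest.approx(2.0, abs=1e-12)

    def test_rate_domain_averaging_option(self):
        records = [rec("a", t1=1.0), rec("b", t1=2.0)]
        out = select_fit_measurements(records, FitConfig(average_domain="rate"))
        # harmonic mean of times = 1 / mean(1/1, 1/2)
        assert out[0].t1_s == pytest.approx(1 / np.mean([1.0, 0.5]), abs=1e-12)

    def test_one_record_per_composition(self):
        records = [rec("a", G=1, t1=1.0), rec("b", G=1, t1=1.2),
                   rec("c", G=2, t1=0.5), rec("w", t1=2.5)]
        out = select_fit_measurements(records)
        assert sorted(r.composition for r in out) == [(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)]

    def test_empty_input_gives_empty_output(self):
        assert select_fit_measurements([]) == []

    def test_multiple_fields_rejected(self):
        with pytest.raises(ValueError, match="field"):
            select_fit_measurements([rec("a", field=0.064, t1=1.0),
                                     rec("b", field=0.55, t1=1.0)])


class TestFitWater:
    def test_single_record_reciprocal(self):
        assert fit_water([rec(t1=2.5)]) == pytest.approx(0.4, abs=1e-14)

    def test_mean_of_rates(self):
        got = fit_water([rec("a", t1=2.0), rec("b", t1=2.5)])
        assert got == pytest.approx(0.45, abs=1e-14)

    def test_no_water_record_raises_with_guidance(self):
        with pytest.raises(FitStageError, match="intercept"):
            fit_water([rec(G=1.0, t1=1.0)])


class TestSingleComponentStages:
    def test_agarose_only_noiseless_recovery(self):
        c1, c2, c3 = 0.4, 1.0, 0.05
        records = [rec(f"g{g}", G=g, t1=1 / (c1 + c2 * g + c3 * g**2))
                   for g in (0.5, 1, 2, 4)]
        got = fit_agarose_only(records, c1)
        assert got == pytest.approx((1.0, 0.05), abs=1e-6)

    def test_flat_response_gives_zeros(self):
        records = [rec(f"g{g}", G=g, t1=1 / 0.4) for g in (0.5, 1, 2, 4)]
        assert fit_agarose_only(records, 0.4) == (0.0, 0.0)

    def test_subthreshold_coefficient_zeroed(self):
        # quadratic term of 5e-5 is below the zeroing threshold
        c1, c2, c3 = 0.4, 1.0, 5e-5
        records = [rec(f"g{g}", G=g, t1=1 / (c1 + c2 * g + c3 * g**2))
                   for g in (0.5, 1, 2, 4)]
        got = fit_agarose_only(records, c1)
        assert got[1] == 0.0

    def test_salt_only_noiseless_recovery(self):
        c1, c4, c5 = 0.4, 0.55, 0.001
        records = [rec(f"n{n}", salt="NiCl2", N=n, t1=1 / (c1 + c4 * n + c5 * n**2))
                   for n in (1, 5, 10, 20)]
        assert fit_salt_only(records, c1) == pytest.approx((0.55, 0.001), rel=1e-6)

    def test_underdetermined_raises(self):
        with pytest.raises(FitStageError, match="distinct"):
            fit_agarose_only([rec(G=1.0, t1=1.0)], 0.4)


class TestFitFull:
    TRUTH = (0.4, 1.0, 0.05, 0.55, 0.001, 0.3, 0.02, 0.01, 0.005)

    def _grid_records(self, c, levels=(0.5, 1, 2, 4)):
        return [rec(f"m{g}-{n}", salt="NiCl2", N=n, G=g, t1=from_rates(c, g, n))
                for g in levels for n in levels]

    def test_noiseless_recovery_of_all_nine(self):
        got = fit_full(self._grid_records(self.TRUTH), self.TRUTH[:5])
        assert tuple(got) == pytest.approx(self.TRUTH, abs=1e-6)

    def test_additive_data_gives_zero_interactions(self):
        c = (0.4, 1.0, 0.05, 0.55, 0.001, 0, 0, 0, 0)
        got = fit_full(self._grid_records(c), c[:5])
        assert tuple(got)[5:] == (0.0, 0.0, 0.0, 0.0)

    def test_no_mixed_records_returns_additive_model(self):
        got = fit_full([rec(G=1.0, t1=0.7)], self.TRUTH[:5])
        assert tuple(got)[5:] == (0.0, 0.0, 0.0, 0.0)
        assert tuple(got)[:5] == self.TRUTH[:5]

    def test_fixed_part_never_changes(self):
        got = fit_full(self._grid_records(self.TRUTH), self.TRUTH[:5])
        assert tuple(got)[:5] == self.TRUTH[:5]


class TestFitMixingModel:
    def test_closed_loop_noiseless_recovery(self, published_models):
        truth = published_models[("NiCl2", 0.064)]
        records = generate_measurements(truth, DesignSpec(noise_sigma=0.0))
        refit = fit_mixing_model(records, "NiCl2", 0.064)
        for kind in ("T1", "T2"):
            got = refit.coeffs(kind).coefficients
            want = truth.coeffs(kind).coefficients
            assert got == pytest.approx(want, abs=1e-4)

    def test_water_only_dataset(self):
        records = [rec("w", t1=2.5, t2=2.0)]
        model = fit_mixing_model(records, "NiCl2", 0.064)
        assert model.t1_coeffs[0] == pytest.approx(0.4)
        assert tuple(model.t1_coeffs)[1:] == (0.0,) * 8

    def test_idempotent(self, synthetic_truth):
        records = generate_measurements(
            synthetic_truth, DesignSpec(noise_sigma=0.02, seed=3))
        a = fit_mixing_model(records, "NiCl2", 0.064)
        b = fit_mixing_model(records, "NiCl2", 0.064)
        assert a.t1_coeffs == b.t1_coeffs and a.t2_coeffs == b.t2_coeffs

    def test_time_domain_loss_also_recovers_noiseless_truth(self, synthetic_truth):
        records = generate_measurements(synthetic_truth, DesignSpec(noise_sigma=0.0))
        refit = fit_mixing_model(records, "NiCl2", 0.064,
                                 FitConfig(loss_domain="time"))
        assert tuple(refit.t1_coeffs) == pytest.approx(
            tuple(synthetic_truth.t1_coeffs), abs=1e-6)

    def test_error_shrinks_with_more_design_points(self, synthetic_truth):
        """Noise-limited coefficient error decreases on a larger design."""
        def worst_err(design):
            refit = fit_mixing_model(
                generate_measurements(synthetic_truth, design), "NiCl2", 0.064)
            return max(abs(f - t)
                       for kind in ("T1", "T2")
                       for t, f in zip(synthetic_truth.coeffs(kind),
                                       refit.coeffs(kind)))
        small = DesignSpec(agarose_levels=(1.0, 4.0), salt_levels=(1.0, 5.0),
                           noise_sigma=0.02, replicates=1, seed=11)
        large = DesignSpec(agarose_levels=(0.5, 1.0, 1.5, 2.0, 3.0, 4.0),
                           salt_levels=(0.5, 1.0, 2.0, 4.0, 7.0, 10.0),
                           noise_sigma=0.02, replicates=12, seed=11)
        assert worst_err(large) < worst_err(small)


class TestMeasurementTableIO:
    def test_round_trip(self, tmp_path, synthetic_truth):
        records = generate_measurements(synthetic_truth, DesignSpec(seed=5))
        path = tmp_path / "meas.csv"
        write_measurements(records, path)
        again = read_measurements(path)
        assert len(again) == len(records)
        assert again[0].t1_s == pytest.approx(records[0].t1_s, rel=1e-12)

    def test_negative_time_rejected_at_read(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sample_id,salt,salt_conc,agarose_conc,field_T,temperature_C,t1_s,t2_s\n"
            "x,NiCl2,1.0,1.0,0.064,20,-0.5,0.1\n")
        with pytest.raises(ValueError):
            read_measurements(path)

    def test_missing_value_becomes_none(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text(
            "sample_id,salt,salt_conc,agarose_conc,field_T,temperature_C,t1_s,t2_s\n"
            "x,NiCl2,1.0,1.0,0.064,20,0.5,\n")
        (record,) = read_measurements(path)
        assert record.t2_s is None and record.t1_s == 0.5
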