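"""Closed-form assay statistics and dose-response fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import speceff as se
from speceff.bioassay import (
    CHLOROGENIC_ACID_CALIBRATION,
    DoseResponseData,
    four_pl,
)

finite = st.floats(0.01, 10.0)


class TestRadicalScavenging:
    def test_sample_equals_blank_gives_zero(self):
        assert se.radical_scavenging(0.8, 0.8) == pytest.approx(0.0)

    def test_fully_bleached_sample_gives_hundred(self):
        assert se.radical_scavenging(0.8, 0.0) == pytest.approx(100.0)

    def test_direct_arithmetic(self):
        assert se.radical_scavenging(0.8, 0.2) == pytest.approx(75.0)

    def test_zero_blank_rejected(self):
        with pytest.raises(ZeroDivisionError):
            se.radical_scavenging(0.0, 0.2)

    @given(a=finite, b=finite)
    def test_algebraic_identity(self, a, b):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert se.radical_scavenging(a, b) == pytest.approx(
                100 * (1 - b / a)
            )

    def test_out_of_range_reported_with_warning(self):
        with pytest.warns(UserWarning):
            value = se.radical_scavenging(0.5, 0.8)
        assert value == pytest.approx(100 * (1 - 0.8 / 0.5))


class TestEnzymeInhibition:
    def test_full_inhibition_limit(self):
        assert se.enzyme_inhibition(0.3, 0.3, 0.8) == pytest.approx(100.0)

    def test_no_inhibition_limit(self):
        assert se.enzyme_inhibition(0.9, 0.1, 0.8) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        assert se.enzyme_inhibition(0.5, 0.1, 0.8) == pytest.approx(50.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ZeroDivisionError):
            se.enzyme_inhibition(0.5, 0.1, 0.0)

    @given(a_s=finite, a_n=finite, a_c=finite)
    def test_algebraic_identity(self, a_s, a_n, a_c):
        expected = (1 - (a_s - a_n) / a_c) * 100
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert se.enzyme_inhibition(a_s, a_n, a_c) == pytest.approx(expected)


class TestCAAUnit:
    def _kin(self, sa, ca):
        t = np.arange(0, 61, 5.0)
        return se.CAAKinetics(t, np.full(t.shape, sa), np.full(t.shape, ca))

    def test_sample_equals_control_gives_zero(self):
        kin = self._kin(2.0, 2.0)
        assert se.caa_unit(kin) == pytest.approx(0.0)

    def test_fully_quenched_sample_gives_one(self):
        kin = self._kin(0.0, 2.0)
        assert se.caa_unit(kin) == pytest.approx(1.0)

    def test_constant_curves_half_ratio(self):
        kin = self._kin(1.0, 2.0)
        assert se.caa_unit(kin) == pytest.approx(0.5)

    @given(scale=st.floats(0.01, 100.0))
    def test_joint_rescaling_invariance(self, scale):
        t = np.arange(0, 61, 5.0)
        sa = 10 + t
        ca = 30 + 2 * t
        base = se.caa_unit(se.CAAKinetics(t, sa, ca))
        scaled = se.caa_unit(se.CAAKinetics(t, sa * scale, ca * scale))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_control_area_rejected(self):
        with pytest.raises(ValueError):
            se.caa_unit(self._kin(1.0, 0.0))

    def test_synthetic_kinetics_round_trip(self):
        kin = se.synthetic.simulate_caa_kinetics(caa_unit_true=0.37)
        assert se.caa_unit(kin) == pytest.approx(0.37, abs=1e-12)


class TestCalibration:
    def test_absorbance_at_intercept_maps_to_zero(self):
        line = se.CalibrationLine(2.0, 0.5)
        assert se.apply_calibration(0.5, line) == pytest.approx(0.0)

    def test_printed_standard_curve_inversion(self):
        # y = 1.323 x - 0.0869 evaluated at x = 1 gives y = 1.2361
        conc = se.apply_calibration(1.2361, CHLOROGENIC_ACID_CALIBRATION)
        assert conc == pytest.approx(1.000, abs=1e-9)

    def test_simple_inversion(self):
        assert se.apply_calibration(4.0, se.CalibrationLine(2.0, 0.0)) == 2.0

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            se.CalibrationLine(0.0, 1.0)


class TestFitDoseResponse:
    def test_noiseless_round_trip_recovers_all_parameters(self):
        data = se.simulate_dose_response(2.0, hill=1.0, floor=0, ceiling=100)
        fit = se.fit_dose_response(data)
        assert fit.converged
        assert fit.ec50 == pytest.approx(2.0, abs=1e-6)
        assert fit.hill == pytest.approx(1.0, abs=1e-5)
        assert fit.floor == pytest.approx(0.0, abs=1e-5)
        assert fit.ceiling == pytest.approx(100.0, abs=1e-5)

    def test_midpoint_identity_at_fitted_ec50(self):
        data = se.simulate_dose_response(1.3, hill=1.8, floor=5, ceiling=95,
                                         noise_sd=1.0, seed=4)
        fit = se.fit_dose_response(data)
        mid = four_pl(fit.ec50, fit.floor, fit.ceiling, fit.ec50, fit.hill)
        assert mid == pytest.approx((fit.floor + fit.ceiling) / 2)

    def test_noisy_recovery_is_accurate(self):
        doses = np.repeat(2.0 * 2.0 ** np.arange(-3.5, 4.5), 3)
        errs = []
        for seed in range(100):
            data = se.simulate_dose_response(2.0, doses=doses, noise_sd=2.0,
                                             seed=seed)
            errs.append(abs(se.fit_dose_response(data).ec50 - 2.0) / 2.0)
        assert np.median(errs) < 0.05

    def test_fewer_than_four_doses_rejected(self):
        data = DoseResponseData(np.array([1, 2, 4.0]), np.array([10, 50, 90.0]))
        with pytest.raises(ValueError):
            se.fit_dose_response(data)

    def test_interpolation_mode_crossing(self):
        data = se.simulate_dose_response(2.0, hill=1.0, floor=0, ceiling=100)
        fit = se.fit_dose_response(data, method="interpolate")
        assert fit.ec50 == pytest.approx(2.0, rel=0.1)
        assert np.isnan(fit.hill)


class TestBuildActivityMatrix:
    def _results(self, n=16):
        rng = np.random.default_rng(0)
        return {
            f"S{i}": {
                "dpph_ec50": float(rng.uniform(1, 5)),
                "abts_ec50": float(rng.uniform(1, 5)),
                "frap": float(rng.uniform(10, 30)),
                "caa_unit": float(rng.uniform(0, 1)),
                "glucosidase_inhibition": float(rng.uniform(20, 90)),
                "lipase_inhibition": float(rng.uniform(20, 90)),
            }
            for i in range(n)
        }

    def test_shape(self):
        Y = se.build_activity_matrix(self._results())
        assert Y.shape == (16, 6)

    def test_missing_endpoint_names_sample_and_endpoint(self):
        results = self._results(3)
        del results["S1"]["frap"]
        with pytest.raises(ValueError, match="S1:frap"):
            se.build_activity_matrix(results)

    def test_reciprocal_harmonisation_of_ec50(self):
        results = self._results(4)
        Y = se.build_activity_matrix(results, harmonise="reciprocal")
        for sid in Y.index:
            assert Y.loc[sid, "dpph_ec50"] == pytest.approx(
                1.0 / results[sid]["dpph_ec50"]
            )
            assert Y.loc[sid, "frap"] == pytest.approx(results[sid]["frap"])


class TestAssayWells:
    def _wells_csv(self, tmp_path):
        import pandas as pd

        rows = []
        for _ in range(3):
            rows.append(("", "blank", 0.0, 0.8))
        for sid, reading in [("S1", 0.2), ("S1", 0.2), ("S2", 0.4)]:
            rows.append((sid, "sample", 1.0, reading))
        df = pd.DataFrame(rows, columns=["sample_id", "role",
                                         "concentration", "reading"])
        path = tmp_path / "wells.csv"
        df.to_csv(path, index=False)
        return path

    def test_scavenging_from_wells(self, tmp_path):
        from speceff.bioassay import read_assay_wells, scavenging_from_wells

        wells = read_assay_wells(self._wells_csv(tmp_path))
        out = scavenging_from_wells(wells)
        s1 = out.loc[out["sample_id"] == "S1", "scavenging_pct"].iloc[0]
        s2 = out.loc[out["sample_id"] == "S2", "scavenging_pct"].iloc[0]
        assert s1 == pytest.approx(75.0)
        assert s2 == pytest.approx(50.0)

    def test_missing_columns_rejected(self, tmp_path):
        import pandas as pd

        from speceff.bioassay import read_assay_wells

        path = tmp_path / "bad.csv"
        pd.DataFrame({"sample_id": ["a"], "reading": [1.0]}).to_csv(path)
        with pytest.raises(ValueError, match="missing columns"):
            read_assay_wells(path)
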