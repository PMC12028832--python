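"""Derived per-subject metrics: Hadlock EFW, MoM, extrapolation, CPR."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalgp.curves import CurveSet, GestationalAge, ReferenceCurve
from fetalgp.io import records
from fetalgp.metrics import (
    BiometryScan,
    DopplerScan,
    HADLOCK4_COEFFS,
    assess,
    assess_cohort,
    doppler_moms,
    efw_mom,
    expected_fw_3t,
    hadlock4_efw,
    pct_expected_fw,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False, allow_infinity=False)


def _const_curve(value: float, name: str = "EFW") -> ReferenceCurve:
    return ReferenceCurve(name, lambda g: np.full_like(np.asarray(g, float), value),
                          log_sd=0.11, valid_range=(16.0, 42.0))


class TestHadlock4:
    def test_intercept_only(self):
        assert hadlock4_efw(0, 0, 0, 0) == pytest.approx(10 ** 1.3596, rel=1e-12)

    def test_matches_exact_rational_exponent(self):
        # oracle: assemble the exponent in exact rational arithmetic
        bpd, hc, ac, fl = Fraction(88, 10), Fraction(32), Fraction(33), Fraction(7)
        c = {k: Fraction(str(v)) for k, v in HADLOCK4_COEFFS.items()}
        exponent = (c["intercept"] + c["hc"] * hc + c["ac"] * ac + c["fl"] * fl
                    + c["bpd_ac"] * bpd * ac + c["ac_fl"] * ac * fl)
        expected = 10.0 ** float(exponent)
        assert hadlock4_efw(8.8, 32.0, 33.0, 7.0) == pytest.approx(expected, rel=1e-12)

    def test_log_linear_in_fl_without_interactions(self):
        # with AC = 0 the AC*FL interaction vanishes; doubling FL scales by 10^(0.174*dFL)
        ratio = hadlock4_efw(0, 0, 0, 6.0) / hadlock4_efw(0, 0, 0, 3.0)
        assert ratio == pytest.approx(10 ** (0.174 * 3.0), rel=1e-12)

    def test_missing_field_named(self):
        with pytest.raises(ValueError, match="fl"):
            hadlock4_efw(8.8, 32.0, 33.0, None)

    def test_scan_requires_biometry_or_efw(self):
        with pytest.raises(ValueError, match="missing"):
            BiometryScan(ga=GestationalAge(20.0), bpd=4.7, hc=17.5)


class TestEfwMom:
    def test_median_gives_unity_and_doubling(self, curves):
        med = float(curves.efw.median(20.0))
        assert efw_mom(med, 20.0, curves.efw) == pytest.approx(1.0, rel=1e-12)
        assert efw_mom(2 * med, 20.0, curves.efw) == pytest.approx(2.0, rel=1e-12)

    def test_direct_division_oracle(self):
        curve = _const_curve(373.5)
        assert efw_mom(362.3, 20.0, curve) == pytest.approx(362.3 / 373.5, rel=1e-12)
        assert efw_mom(362.3, 20.0, curve) == pytest.approx(0.97, abs=5e-4)

    def test_nonpositive_efw_rejected(self, curves):
        with pytest.raises(ValueError):
            efw_mom(-5.0, 20.0, curves.efw)


class TestExpectedWeight:
    def test_median_start_lands_on_median(self, curves):
        efw20 = float(curves.efw.median(20.0))
        assert expected_fw_3t(efw20, 20.0, 39.0, curves.efw) == pytest.approx(
            float(curves.efw.median(39.0)), rel=1e-12
        )

    def test_linearity_in_efw20(self, curves):
        base = expected_fw_3t(400.0, 20.0, 39.0, curves.efw)
        assert expected_fw_3t(1.7 * 400.0, 20.0, 39.0, curves.efw) == pytest.approx(
            1.7 * base, rel=1e-12
        )

    def test_two_step_oracle(self, curves):
        # independent divide-then-multiply composition
        expected = (400.0 / float(curves.efw.median(20.0))) * float(curves.efw.median(39.0))
        assert expected_fw_3t(400.0, 20.0, 39.0, curves.efw) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("ga20,ga3t", [(18.5, 39.0), (20.0, 29.0), (20.0, 41.5)])
    def test_window_validation(self, curves, ga20, ga3t):
        with pytest.raises(ValueError, match="window"):
            expected_fw_3t(400.0, ga20, ga3t, curves.efw)
        # overridable for stress-testing outside the windows
        assert expected_fw_3t(400.0, ga20, ga3t, curves.efw, enforce_windows=False) > 0

    def test_unit_invariance_of_percentage(self, curves):
        """MoM cancels the median curve's scale: grams vs kg give the same %."""
        kg_curve = ReferenceCurve(
            "EFW", lambda g: np.asarray(curves.efw.median_fn(g)) / 1000.0,
            log_sd=0.11, valid_range=curves.efw.valid_range, monotone="increasing",
        )
        efw20_g, efw3t_g = 400.0, 3100.0
        pct_g = pct_expected_fw(efw3t_g, expected_fw_3t(efw20_g, 20.0, 39.0, curves.efw))
        pct_kg = pct_expected_fw(
            efw3t_g / 1000.0, expected_fw_3t(efw20_g / 1000.0, 20.0, 39.0, kg_curve)
        )
        assert pct_g == pytest.approx(pct_kg, rel=1e-12)


class TestPctExpected:
    @pytest.mark.parametrize("k,expected", [(1.25, 125.0), (0.75, 75.0), (1.0, 100.0)])
    def test_worked_ratios(self, k, expected):
        assert pct_expected_fw(k * 3000.0, 3000.0) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=positive, b=positive)
    def test_printed_form_equals_simplification(self, a, b):
        printed = 100.0 + ((a - b) / b) * 100.0
        assert pct_expected_fw(a, b) == pytest.approx(printed, rel=1e-12)

    def test_nonpositive_expected_weight(self):
        with pytest.raises(ValueError):
            pct_expected_fw(3000.0, 0.0)


class TestDopplerMoms:
    def test_equal_pis_give_unit_cpr(self, curves):
        scan = DopplerScan(GestationalAge(38.0), ua_pi=1.1, mca_pi=1.1)
        assert doppler_moms(scan, curves.ua, curves.mca, curves.cpr).cpr == pytest.approx(1.0)

    def test_values_on_medians_give_unit_moms(self, curves):
        ga = GestationalAge(36.0)
        scan = DopplerScan(ga, ua_pi=float(curves.ua.median(ga)),
                           mca_pi=float(curves.mca.median(ga)))
        dm = doppler_moms(scan, curves.ua, curves.mca, curves.cpr)
        for v in (dm.ua_pi_mom, dm.mca_pi_mom, dm.cpr_mom):
            assert v == pytest.approx(1.0, rel=1e-12)

    def test_division_oracle(self, curves):
        ga = GestationalAge(38.0)
        scan = DopplerScan(ga, ua_pi=0.9, mca_pi=1.6)
        dm = doppler_moms(scan, curves.ua, curves.mca, curves.cpr)
        assert dm.ua_pi_mom == pytest.approx(0.9 / float(curves.ua.median(ga)), rel=1e-12)
        assert dm.mca_pi_mom == pytest.approx(1.6 / float(curves.mca.median(ga)), rel=1e-12)
        assert dm.cpr == pytest.approx(1.6 / 0.9, rel=1e-12)
        # ratio-of-medians default: CPR MoM = MCA MoM / UA MoM
        assert dm.cpr_mom == pytest.approx(dm.mca_pi_mom / dm.ua_pi_mom, rel=1e-9)

    def test_implausible_pi_rejected(self):
        with pytest.raises(ValueError):
            DopplerScan(GestationalAge(38.0), ua_pi=5.5, mca_pi=1.6)


class TestAssess:
    def test_all_median_record(self, curves, default_cohort):
        rec = records(default_cohort)[0]
        ga20, ga3t = rec.scan20.ga, rec.scan3t.ga
        from dataclasses import replace

        on_median = replace(
            rec,
            scan20=BiometryScan(ga20, efw_grams=float(curves.efw.median(ga20))),
            scan3t=BiometryScan(ga3t, efw_grams=float(curves.efw.median(ga3t))),
            doppler3t=DopplerScan(ga3t, ua_pi=float(curves.ua.median(ga3t)),
                                  mca_pi=float(curves.mca.median(ga3t))),
        )
        a = assess(on_median, curves, enforce_windows=False)
        assert a.efw20_mom == pytest.approx(1.0, rel=1e-12)
        assert a.pct_exfw3t == pytest.approx(100.0, rel=1e-12)
        assert a.efwc_local == pytest.approx(50.0, abs=1e-9)
        assert a.efwc_intergrowth == pytest.approx(50.0, abs=1e-9)
        for mom in (a.ua_pi_mom, a.mca_pi_mom, a.cpr_mom):
            assert mom == pytest.approx(1.0, rel=1e-12)

    def test_recomposition_oracle(self, curves, default_cohort):
        for rec in records(default_cohort)[:20]:
            a = assess(rec, curves, enforce_windows=False)
            assert a.pct_exfw3t == pytest.approx(
                100.0 * a.efw3t_grams / a.exfw3t_grams, rel=1e-12
            )
            assert a.cpr == pytest.approx(
                rec.doppler3t.mca_pi / rec.doppler3t.ua_pi, rel=1e-9
            )

    def test_vectorised_matches_scalar(self, curves, default_cohort, assessed):
        recs = records(default_cohort)
        for i in (0, 100, 500):
            a = assess(recs[i], curves, enforce_windows=False)
            row = assessed.iloc[i]
            assert row["pct_exfw3t"] == pytest.approx(a.pct_exfw3t, rel=1e-9)
            assert row["mca_pi_mom"] == pytest.approx(a.mca_pi_mom, rel=1e-9)
            assert row["efwc_local"] == pytest.approx(a.efwc_local, rel=1e-9)

    def test_missing_scan_listed(self, curves):
        class Stub:
            subject_id = 1
            scan20 = None
            scan3t = None
            doppler3t = None

        with pytest.raises(ValueError, match="scan20"):
            assess(Stub(), curves)

    def test_below_expectation_magnitude(self, curves):
        """A fetus reaching 89.9% of its expected weight scores pct ~ 89.9."""
        exfw = expected_fw_3t(380.0, 20.0, 39.0, curves.efw)
        assert pct_expected_fw(0.899 * exfw, exfw) == pytest.approx(89.9, rel=1e-12)
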