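"""Kinetic calculus: Michaelis–Menten fits, Ko inference, derived columns.

Reference values come from the measured columns of the characterization
table of ancestral and extant RuBisCOs (carboxylation turnover Vc,
Michaelis constants Kc and Ko, specificity factor tau) and the
air-equilibrated dissolved O2 constant of 260 uM.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import paleorubisco as pr
from paleorubisco.kinetics import KineticsError

# enzyme -> (Vc, Kc, Ko, tau, expected Kc_air, expected Vc/Kc_air)
TABLE_ROWS = {
    "ancestral_form_1A": (4.77, 113.0, 2010.0, 54.7, 127.6, 37.4),
    "ancestral_form_1B": (4.72, 120.0, 641.0, 49.6, 168.7, 28.0),
    "prochlorococcus_form_1A": (6.58, 309.0, 1400.0, 59.9, 366.4, 18.0),
    "synechococcus_form_1B": (9.78, 152.0, 1231.0, 50.3, 184.1, 53.1),
    "wheat": (2.92, 10.9, 341.0, 100.0, 19.2, 152.0),
}


class TestFitMM:
    def test_noiseless_exact_recovery(self):
        S = np.array([5.0, 25.0, 60.0, 150.0, 300.0, 550.0])
        v = 4.72 * S / (120.0 + S)
        vmax, km, ssq = pr.fit_mm(S, v)
        assert vmax == pytest.approx(4.72, abs=1e-8)
        assert km == pytest.approx(120.0, abs=1e-6)
        assert ssq < 1e-16

    def test_saturating_substrate_gives_mean_rate(self):
        S = np.array([1e8, 2e8, 5e8])
        v = 4.72 * S / (120.0 + S)
        vmax, _, _ = pr.fit_mm(S, v)
        assert vmax == pytest.approx(v.mean(), rel=1e-6)

    def test_noisy_recovery_within_five_percent(self):
        # 2% multiplicative noise; median |Km error| < 5% across seeds
        S = np.array([5.0, 25.0, 60.0, 150.0, 300.0, 550.0])
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            v = 4.72 * S / (120.0 + S) * np.exp(rng.normal(0, 0.02, S.size))
            _, km, _ = pr.fit_mm(S, v)
            errors.append(abs(km - 120.0) / 120.0)
        assert np.median(errors) < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(KineticsError):
            pr.fit_mm([100.0, 100.0], [1.0, 1.0])
        with pytest.raises(KineticsError):
            pr.fit_mm([5.0, 50.0], [0.0, 0.0])


class TestKcAtO2:
    def test_zero_o2_returns_kc_unchanged(self):
        assert pr.kc_at_o2(120.0, 641.0, 0.0) == 120.0

    @pytest.mark.parametrize(
        "kc,ko,expected",
        [(10.9, 341.0, 19.2), (113.0, 2010.0, 127.6)],
    )
    def test_published_air_values(self, kc, ko, expected):
        assert pr.kc_at_o2(kc, ko, 260.0) == pytest.approx(expected, abs=0.05)

    def test_monotone_in_o2_and_ko(self):
        assert pr.kc_at_o2(100, 500, 300) > pr.kc_at_o2(100, 500, 200)
        assert pr.kc_at_o2(100, 500, 300) > pr.kc_at_o2(100, 800, 300)

    @given(
        kc=st.floats(1.0, 500.0),
        ko=st.floats(50.0, 5000.0),
        o2=st.floats(0.0, 2000.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_never_below_kc(self, kc, ko, o2):
        assert pr.kc_at_o2(kc, ko, o2) >= kc

    def test_nonpositive_ko_rejected(self):
        with pytest.raises(KineticsError):
            pr.kc_at_o2(120.0, 0.0, 260.0)


class TestInferKo:
    def test_exact_series_recovery(self):
        series = [(o2, pr.kc_at_o2(120.0, 641.0, o2)) for o2 in (0, 260, 530, 1325)]
        kc, ko, r2 = pr.infer_ko(series)
        assert kc == pytest.approx(120.0, abs=1e-8)
        assert ko == pytest.approx(641.0, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        series = [(0.0, 100.0), (500.0, 150.0)]
        kc, ko, r2 = pr.infer_ko(series)
        assert (kc, r2) == (pytest.approx(100.0), pytest.approx(1.0))
        assert ko == pytest.approx(1000.0)

    def test_no_inhibition_detected(self):
        with pytest.raises(KineticsError, match="no O2 inhibition"):
            pr.infer_ko([(0.0, 100.0), (500.0, 90.0)])

    def test_noisy_series_median_error_under_15_percent(self):
        o2 = np.array([0.0, 260.0, 742.9, 1238.1])
        errors = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            kc_app = pr.kc_at_o2(120.0, 641.0, 0) * (1 + o2 / 641.0)
            noisy = kc_app * np.exp(rng.normal(0, 0.05, o2.size))
            _, ko, _ = pr.infer_ko(list(zip(o2, noisy)))
            errors.append(abs(ko - 641.0) / 641.0)
        assert np.median(errors) < 0.15


class TestDeriveVo:
    @pytest.mark.parametrize(
        "vc,kc,ko,tau,expected,tol",
        [
            (2.92, 10.9, 341.0, 100.0, 0.91, 0.005),
            (4.72, 120.0, 641.0, 49.6, 0.51, 0.005),
        ],
    )
    def test_published_vo_values(self, vc, kc, ko, tau, expected, tol):
        assert pr.derive_vo(vc, kc, ko, tau) == pytest.approx(expected, abs=tol)

    def test_vo_vanishes_as_tau_grows(self):
        assert pr.derive_vo(4.72, 120.0, 641.0, 1e12) < 1e-10

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(KineticsError, match="tau"):
            pr.derive_vo(1.0, 1.0, 1.0, 0.0)

    @given(
        vc=st.floats(0.1, 20.0),
        kc=st.floats(1.0, 500.0),
        ko=st.floats(50.0, 5000.0),
        tau=st.floats(1.0, 300.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_tau_round_trip(self, vc, kc, ko, tau):
        vo = pr.derive_vo(vc, kc, ko, tau)
        assert (vc / kc) / (vo / ko) == pytest.approx(tau, rel=1e-10)


class TestEfficiencyAir:
    @pytest.mark.parametrize("enzyme", sorted(TABLE_ROWS))
    def test_published_derived_columns(self, enzyme):
        vc, kc, ko, tau, kc_air, vc_over = TABLE_ROWS[enzyme]
        params = pr.KineticParams(enzyme, Vc=vc, Kc=kc, Ko=ko, tau=tau)
        out = pr.efficiency_air(params)
        assert out.Kc_air == pytest.approx(kc_air, abs=0.05)
        # the table prints Vc/Kc_air to 3 s.f. (or fewer)
        assert out.Vc_over_Kc_air == pytest.approx(vc_over, rel=0.005)

    def test_infinite_ko_limit_leaves_kc(self):
        params = pr.KineticParams("x", Vc=5.0, Kc=100.0, Ko=1e15)
        out = pr.efficiency_air(params)
        assert out.Kc_air == pytest.approx(100.0, rel=1e-9)

    def test_unset_fields_named_in_error(self):
        with pytest.raises(KineticsError, match="Ko"):
            pr.efficiency_air(pr.KineticParams("x", Vc=1.0, Kc=1.0))

    def test_invariant_vc_over_kc_air_consistent(self):
        out = pr.efficiency_air(pr.KineticParams("x", Vc=4.72, Kc=120.0, Ko=641.0))
        assert out.Vc_over_Kc_air == pytest.approx(
            out.Vc / (out.Kc_air / 1000.0), rel=1e-6
        )
        assert out.Kc_air >= out.Kc


class TestNormalizeTau:
    def test_reference_maps_to_exactly_100(self):
        assert pr.normalize_tau([87.3], 87.3) == [100.0]

    def test_linear_scaling(self):
        assert pr.normalize_tau([43.65, 87.3], 87.3) == [50.0, 100.0]

    def test_zero_reference_rejected(self):
        with pytest.raises(KineticsError):
            pr.normalize_tau([50.0], 0.0)


class TestFitTradeoff:
    def test_exact_power_law_recovery(self):
        vc = np.array([1.0, 2.0, 5.0, 10.0])
        tau = 200.0 * vc**-0.5
        a, b, resid = pr.fit_tradeoff(list(zip(vc, tau)))
        assert a == pytest.approx(200.0, rel=1e-8)
        assert b == pytest.approx(-0.5, abs=1e-10)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_extant_enzymes_show_inverse_relationship(self):
        pts = [
            (TABLE_ROWS[e][0], TABLE_ROWS[e][3])
            for e in ("wheat", "synechococcus_form_1B", "prochlorococcus_form_1A")
        ]
        _, b, _ = pr.fit_tradeoff(pts)
        assert b < 0

    def test_duplicated_point_is_degenerate(self):
        with pytest.raises(KineticsError, match="degenerate|>=3"):
            pr.fit_tradeoff([(2.0, 50.0)] * 3)

    def test_too_few_points_rejected(self):
        with pytest.raises(KineticsError):
            pr.fit_tradeoff([(1.0, 10.0), (2.0, 5.0)])


class TestDeriveTable:
    def test_full_table_reproduction(self):
        import pandas as pd

        measured = pd.DataFrame(
            [
                {"enzyme": e, "Vc": r[0], "Kc": r[1], "Ko": r[2], "tau": r[3]}
                for e, r in TABLE_ROWS.items()
            ]
        )
        out = pr.derive_table(
            measured, derive_vo_for=["wheat", "ancestral_form_1B"]
        ).set_index("enzyme")
        for e, r in TABLE_ROWS.items():
            assert out.loc[e, "Kc_air"] == pytest.approx(r[4], abs=0.05)
            assert out.loc[e, "Vc_over_Kc_air"] == pytest.approx(r[5], rel=0.005)
        assert out.loc["wheat", "Vo"] == pytest.approx(0.91, abs=0.005)
        assert out.loc["ancestral_form_1B", "Vo"] == pytest.approx(0.5, abs=0.01)

    def test_empty_table_rejected(self):
        import pandas as pd

        with pytest.raises(KineticsError, match="empty"):
            pr.derive_table(pd.DataFrame(columns=["enzyme", "Vc", "Kc", "Ko"]))

    def test_missing_columns_named(self):
        import pandas as pd

        with pytest.raises(KineticsError, match="Ko"):
            pr.derive_table(pd.DataFrame([{"enzyme": "x", "Vc": 1.0, "Kc": 2.0}]))
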