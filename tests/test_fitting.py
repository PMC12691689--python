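"""Nonlinear fits, ratio-based specificity, occupancy deconvolution, kcat."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from alarmokin import (
    DeconvolutionError,
    FitFailureError,
    InvalidParameterError,
    NucleotideSpecies,
    deconvolve_km,
    donor_saturation,
    fit_dual_saturation,
    fit_michaelis_menten,
    kcat_from_rate,
    scale_kcats,
    specificity_from_ratio,
)

S = NucleotideSpecies


class TestMichaelisMentenFit:
    def test_exact_hyperbola_recovery(self):
        s = np.array([30, 60, 125, 250, 500, 1000], dtype=float)
        v = 110 * s / (82 + s)
        km, vmax = fit_michaelis_menten(s, v)
        assert km.value == pytest.approx(82, rel=1e-8)
        assert vmax.value == pytest.approx(110, rel=1e-8)

    def test_half_saturation_identity(self):
        s = np.array([20.5, 41, 82, 164, 328, 656], dtype=float)
        v = 110 * s / (82 + s)
        km, vmax = fit_michaelis_menten(s, v)
        # the fitted curve passes through (Km, Vmax/2)
        v_at_km = vmax.value * km.value / (km.value + km.value)
        assert v_at_km == pytest.approx(vmax.value / 2, rel=1e-12)
        assert vmax.value * 82 / (km.value + 82) == pytest.approx(55.0, rel=1e-6)

    def test_all_zero_velocities_fail(self):
        with pytest.raises(FitFailureError):
            fit_michaelis_menten([10, 100, 1000], [0, 0, 0])

    def test_single_concentration_fails(self):
        with pytest.raises(FitFailureError):
            fit_michaelis_menten([100, 100, 100], [1, 1.1, 0.9])

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(11)
        s = np.repeat(np.geomspace(30, 1000, 6), 2)
        v = 110 * s / (82 + s) * np.exp(rng.normal(0, np.log1p(0.05), s.size))
        km, vmax = fit_michaelis_menten(s, v)
        assert abs(km.value - 82) < 3 * km.se
        assert abs(vmax.value - 110) < 3 * vmax.se


class TestDualSaturationFit:
    def test_exact_recovery_with_fixed_donor_km(self):
        s = np.geomspace(500, 10000, 7)
        v = 114 * s / (1400 + s) * s / (82 + s)
        km_a, vmax = fit_dual_saturation(s, v, km_donor_uM=82)
        assert km_a.value == pytest.approx(1400, rel=1e-8)
        assert vmax.value == pytest.approx(114, rel=1e-8)

    def test_zero_donor_km_reduces_to_plain_hyperbola(self):
        s = np.geomspace(500, 10000, 7)
        v = 114 * s / (1400 + s)
        km_a, vmax = fit_dual_saturation(s, v, km_donor_uM=0.0)
        km_mm, vmax_mm = fit_michaelis_menten(s, v)
        assert km_a.value == pytest.approx(km_mm.value, rel=1e-6)
        assert vmax.value == pytest.approx(vmax_mm.value, rel=1e-6)

    def test_velocity_at_km_is_half_vmax_times_donor_sat(self):
        s = np.array([350, 700, 1400, 2800, 5600, 11200], dtype=float)
        v = 114 * s / (1400 + s) * s / (82 + s)
        km_a, vmax = fit_dual_saturation(s, v, km_donor_uM=82)
        v_at_km = (
            vmax.value * 0.5 * donor_saturation(km_a.value, 82)
        )
        assert v_at_km == pytest.approx(
            114 * 1400 / 2800 * 1400 / 1482, rel=1e-6
        )


class TestSpecificityFromRatio:
    def test_reference_ratio(self):
        out = specificity_from_ratio(
            v_x=2.0, v_pppApp=1.0, conc_x_uM=500, conc_atp_uM=5000,
            vmax_pppApp=114, km_acceptor_atp_uM=1400,
        )
        assert out == pytest.approx(2 * (114 / 1400) * 10, rel=1e-12)

    def test_zero_velocity_gives_zero(self):
        assert specificity_from_ratio(0.0, 1.0, 500, 5000, 114, 1400) == 0.0

    def test_self_ratio_identity(self):
        out = specificity_from_ratio(5.0, 5.0, 5000, 5000, 114, 1400)
        assert out == pytest.approx(114 / 1400, rel=1e-12)

    def test_zero_reference_velocity_rejected(self):
        with pytest.raises(ZeroDivisionError):
            specificity_from_ratio(1.0, 0.0, 500, 5000, 114, 1400)


class TestDeconvolveKm:
    def test_two_acceptor_roundtrip(self):
        # forward-simulated pppApp velocity at {ATP 5 mM, GMP 0.5 mM}, Km_GMP=50
        d = 1 + 5000 / 1400 + 500 / 50
        v = 114 * (5000 / 1400) / d * (5000 / 5082)
        theta_apo, theta_atp, theta_x, km = deconvolve_km(
            v, 5000, 500, 114, 82, 1400
        )
        assert theta_apo == pytest.approx(1 / d, rel=1e-9)
        assert theta_atp == pytest.approx((5000 / 1400) / d, rel=1e-9)
        assert theta_x == pytest.approx(10 / d, rel=1e-9)
        assert km == pytest.approx(50.0, rel=1e-9)

    def test_velocity_above_saturation_bound_errors(self):
        v_max_possible = 114 * donor_saturation(5000, 82)
        with pytest.raises(DeconvolutionError):
            deconvolve_km(v_max_possible * 1.01, 5000, 500, 114, 82, 1400)

    def test_inconsistent_occupancy_errors_with_thetas(self):
        # velocity implying theta_ATP + theta_apo > 1 (competitor seemingly absent)
        v = 114 * (5000 / 1400) / (1 + 5000 / 1400) * (5000 / 5082)
        with pytest.raises(DeconvolutionError) as exc:
            deconvolve_km(v * 1.0000001, 5000, 500, 114, 82, 1400)
        assert np.isfinite(exc.value.theta_atp)

    @given(
        km_d=st.floats(5, 500),
        km_atp=st.floats(200, 5000),
        km_x=st.floats(5, 5000),
        vmax=st.floats(10, 500),
        atp=st.floats(100, 20000),
        cx=st.floats(10, 20000),
    )
    def test_algebraic_inverse_property(self, km_d, km_atp, km_x, vmax, atp, cx):
        """Eq-chain identity: forward velocity -> occupancies -> exact Km."""
        d = 1 + atp / km_atp + cx / km_x
        v = vmax * (atp / km_atp) / d * atp / (km_d + atp)
        theta_apo, theta_atp, theta_x, km = deconvolve_km(
            v, atp, cx, vmax, km_d, km_atp
        )
        assert km == pytest.approx(km_x, rel=1e-9)
        assert theta_apo + theta_atp + theta_x == pytest.approx(1.0, abs=1e-12)


class TestKcat:
    def test_printed_worked_example(self):
        kcat = kcat_from_rate(23, 0.30, 5000, 82, 1400)
        assert kcat == pytest.approx(1.0e5, rel=0.02)

    def test_zero_velocity(self):
        assert kcat_from_rate(0.0, 0.30, 5000, 82, 1400) == 0.0

    def test_saturating_limit_is_identity(self):
        raw = 23 / (0.30 / 1000)
        assert kcat_from_rate(23, 0.30, 1e12, 82, 1400) == pytest.approx(raw, rel=1e-6)

    def test_zero_enzyme_rejected(self):
        with pytest.raises(InvalidParameterError):
            kcat_from_rate(23, 0.0, 5000, 82, 1400)


class TestScaleKcats:
    def test_vmax_proportionality(self):
        out = scale_kcats(1.0e5, {S.ATP: 114.0, S.GTP: 110.0})
        assert out[S.GTP] == pytest.approx(1.0e5 * 110 / 114, rel=1e-12)
        assert out[S.GTP] == pytest.approx(9.65e4, rel=0.01)

    def test_identity_and_zero_rows(self):
        out = scale_kcats(2.0, {S.ATP: 114.0, S.ADP: 114.0, S.GMP: 0.0})
        assert out[S.ADP] == 2.0
        assert out[S.GMP] == 0.0

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            scale_kcats(1.0, {S.GTP: 10.0})

    @given(vals=st.lists(st.floats(0, 500), min_size=1, max_size=5))
    def test_monotone_in_vmax(self, vals):
        table = {S.ATP: 100.0}
        table.update({sp: v for sp, v in zip([S.ADP, S.AMP, S.GMP, S.GTP, S.GDP], vals)})
        out = scale_kcats(7.0, table)
        ordered = sorted(table, key=table.get)
        kcats = [out[sp] for sp in ordered]
        assert kcats == sorted(kcats)
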