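"""Single-site ITC model: dilution, equilibrium, heats, fits, thermodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import equilibrium_complex_um, stepwise_itc_heats
from nlsbind.itc_binding import (
    FitFailure, ItcIsotherm, ItcProtocol, cell_concentrations,
    complex_concentration, fit_isotherm, injection_heats, kd_from_ka,
    molar_ratios, thermodynamic_profile,
)
from nlsbind.presets import ITC_PRESETS
from nlsbind.synthetic_data import NoiseSpec, simulate_itc


class TestCellConcentrations:
    def test_first_injection_closed_form(self, protocol):
        lt, pt = cell_concentrations(protocol, 1)
        assert lt == pytest.approx(0.9985, abs=1e-4)
        assert pt == pytest.approx(9.9001, abs=1e-4)

    def test_last_injection_closed_form(self, protocol):
        lt, pt = cell_concentrations(protocol, 19)
        assert pt == pytest.approx(10 * (1 - 2 / 200.3) ** 19, rel=1e-12)
        assert lt == pytest.approx(100 * (1 - (1 - 2 / 200.3) ** 19),
                                   rel=1e-12)
        assert lt == pytest.approx(17.36, abs=0.01)
        assert lt / pt == pytest.approx(2.10, abs=0.01)

    def test_out_of_range_rejected(self, protocol):
        with pytest.raises(ValueError, match="range"):
            cell_concentrations(protocol, 0)
        with pytest.raises(ValueError, match="range"):
            cell_concentrations(protocol, 20)

    def test_dilution_monotonicity(self, protocol):
        lts, pts = zip(*(cell_concentrations(protocol, j)
                         for j in range(1, 20)))
        assert np.all(np.diff(lts) > 0)
        assert np.all(np.diff(pts) < 0)

    def test_molar_ratio_strictly_increasing(self, protocol):
        assert np.all(np.diff(molar_ratios(protocol)) > 0)


class TestComplexConcentration:
    def test_no_ligand(self):
        assert complex_concentration(10.0, 0.0, 1e5) == 0.0

    def test_tight_binding_limit(self):
        assert complex_concentration(10.0, 5.0, 1e12) \
            == pytest.approx(5.0, rel=1e-5)
        assert complex_concentration(10.0, 50.0, 1e12, n=0.85) \
            == pytest.approx(8.5, rel=1e-5)

    def test_quadratic_vs_mass_balance_oracle(self):
        pl = complex_concentration(10.0, 5.0, 1e5, 1.0)
        assert pl == pytest.approx(2.192, abs=1e-3)
        assert pl == pytest.approx(equilibrium_complex_um(10.0, 5.0, 1e5),
                                   abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(pt=st.floats(min_value=0.1, max_value=100),
           lt=st.floats(min_value=0.0, max_value=100),
           log_ka=st.floats(min_value=2, max_value=9),
           n=st.floats(min_value=0.5, max_value=1.5))
    def test_mass_conservation(self, pt, lt, log_ka, n):
        pl = complex_concentration(pt, lt, 10 ** log_ka, n)
        assert -1e-9 <= pl <= min(n * pt, lt) + 1e-9

    def test_nonpositive_ka_rejected(self):
        with pytest.raises(ValueError):
            complex_concentration(10.0, 5.0, 0.0)


class TestInjectionHeats:
    def test_athermal_returns_background(self, protocol):
        q = injection_heats(protocol, 1e5, 0.0, 0.85, qd_kcal_mol=0.7)
        assert q == pytest.approx(np.full(19, 0.7))

    def test_tight_binding_first_injection_equals_dh(self, protocol):
        q = injection_heats(protocol, 1e12, 27.7, 1.0, 0.0)
        assert q[0] == pytest.approx(27.7, rel=1e-6)

    def test_ka_to_zero_gives_background(self, protocol):
        q = injection_heats(protocol, 1e-6, 27.7, 1.0, qd_kcal_mol=0.5)
        assert q == pytest.approx(np.full(19, 0.5), abs=1e-4)

    def test_tight_binding_step_at_n(self, protocol):
        q = injection_heats(protocol, 1e12, 20.0, 0.85, qd_kcal_mol=0.3)
        mr = molar_ratios(protocol)
        assert np.all(q[mr < 0.8] > 19.0)       # plateau ~ dH + Qd
        assert np.all(q[mr > 0.95] < 1.0)       # post-step ~ Qd

    def test_full_curve_matches_stepwise_oracle(self, protocol):
        q = injection_heats(protocol, 1e5, 27.7, 0.85, 0.5)
        oracle = stepwise_itc_heats(protocol, 1e5, 27.7, 0.85, 0.5)
        assert np.max(np.abs(q - oracle)) < 1e-8

    def test_oracle_equivalence_over_random_draws(self, protocol):
        # 1,000 seeded random parameter draws vs the brute-force simulator
        rng = np.random.default_rng(12345)
        worst = 0.0
        for _ in range(1000):
            ka = 10 ** rng.uniform(3.0, 7.0)
            dh = rng.uniform(-40.0, 40.0)
            n = rng.uniform(0.5, 1.5)
            qd = rng.uniform(-1.0, 1.0)
            q = injection_heats(protocol, ka, dh, n, qd)
            oracle = stepwise_itc_heats(protocol, ka, dh, n, qd)
            worst = max(worst, float(np.max(np.abs(q - oracle))))
        assert worst < 1e-8


class TestFitIsotherm:
    @pytest.mark.parametrize(
        "preset", ITC_PRESETS, ids=lambda p: f"{p.peptide}-{p.importin}")
    def test_noiseless_recovery_all_presets(self, protocol, preset):
        iso = simulate_itc(protocol, preset.ka_m, preset.dh_kcal_mol,
                           preset.n, qd_kcal_mol=0.5)
        fit = fit_isotherm(iso, protocol)
        assert abs(fit.ka_m - preset.ka_m) / preset.ka_m < 1e-3
        assert abs(fit.dh_kcal_mol - preset.dh_kcal_mol) \
            / abs(preset.dh_kcal_mol) < 1e-3
        assert abs(fit.n - preset.n) / preset.n < 1e-3
        assert abs(fit.qd_kcal_mol - 0.5) < 1e-3

    def test_noisy_kd_recovery_at_well_conditioned_design(self, protocol):
        # c = Ka*[P]*n ~ 6 (the truncated-importin cells): with 0.3
        # kcal/mol heat noise the Kd comes back within the 30%
        # experimental repeatability
        ka, dh, n = 7.0e5, 15.9, 0.87
        errors = []
        for rep in range(40):
            iso = simulate_itc(protocol, ka, dh, n, qd_kcal_mol=0.5,
                               noise=NoiseSpec(sigma=0.3, seed=5000 + rep))
            fit = fit_isotherm(iso, protocol)
            errors.append(abs(fit.kd_um - kd_from_ka(ka)) / kd_from_ka(ka))
        assert np.median(errors) < 0.30

    def test_low_c_degenerate_realization_fails_with_diagnostic(
            self, protocol):
        # at c ~ 1 with (Ka, dH, n, Qd) all free, noise can make the
        # weak-binding ridge (huge dH, tiny n) the global optimum; such
        # realizations must fail with the degeneracy diagnostic instead
        # of reporting a meaningless Kd
        iso = simulate_itc(protocol, 1e5, 27.7, 0.85, qd_kcal_mol=0.5,
                           noise=NoiseSpec(sigma=0.3, seed=777 + 82))
        with pytest.raises(FitFailure, match="degenerate"):
            fit_isotherm(iso, protocol)

    def test_all_zero_heats_fail(self, protocol):
        iso = ItcIsotherm(molar_ratios(protocol), np.zeros(19))
        with pytest.raises(FitFailure):
            fit_isotherm(iso, protocol)

    def test_too_few_injections_rejected(self):
        proto = ItcProtocol(injection_volumes_ul=(2.0,) * 5)
        iso = simulate_itc(proto, 1e5, 27.7)
        with pytest.raises(ValueError, match="8"):
            fit_isotherm(iso, proto)


class TestDerivedQuantities:
    @pytest.mark.parametrize("ka,kd_2sf", [
        (7.6e4, 13.0), (1.6e5, 6.3), (1e6, 1.0),
    ])
    def test_kd_from_ka(self, ka, kd_2sf):
        from nlsbind.report import round_sig
        assert round_sig(kd_from_ka(ka), 2) == pytest.approx(kd_2sf)

    def test_nonpositive_ka_rejected(self):
        with pytest.raises(ValueError):
            kd_from_ka(-1.0)

    def test_unit_ka_gives_zero_dg(self):
        assert thermodynamic_profile(1.0, 5.0).dg_kcal_mol == 0.0

    def test_dg_closed_form(self):
        prof = thermodynamic_profile(1e5, 27.7, 298.15)
        assert prof.dg_kcal_mol == pytest.approx(-6.82, abs=0.01)

    def test_entropically_driven_verdict(self):
        prof = thermodynamic_profile(1e5, 27.7, 298.15)
        assert prof.minus_tds_kcal_mol == pytest.approx(-34.5, abs=0.05)
        assert prof.entropically_driven
        # dG = dH + (-TdS) to float rounding
        assert prof.dg_kcal_mol == pytest.approx(
            prof.dh_kcal_mol + prof.minus_tds_kcal_mol, rel=1e-14)

    def test_enthalpically_driven_not_flagged(self):
        prof = thermodynamic_profile(1e5, -5.0, 298.15)
        assert not prof.entropically_driven


class TestProtocolValidation:
    def test_overfilled_cell_rejected(self):
        with pytest.raises(ValueError, match="V0"):
            ItcProtocol(cell_volume_ul=30.0)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            ItcProtocol(injection_volumes_ul=(2.0, -1.0))
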