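"""Drift-corrected sensorgram models, fits, and pseudo-first-order rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlsbind.bli_kinetics import (
    FitFailure, Sensorgram, SensorgramSchedule, association_model,
    dissociation_model, fit_association, fit_dissociation, kd_from_rates,
    pseudo_first_order,
)
from nlsbind.synthetic_data import NoiseSpec, simulate_bli


class TestModels:
    @settings(deadline=None, derandomize=True)
    @given(req=st.floats(min_value=-5, max_value=5),
           kobs=st.floats(min_value=1e-3, max_value=1.0),
           drift=st.floats(min_value=-0.01, max_value=0.01))
    def test_association_zero_at_t0(self, req, kobs, drift):
        assert association_model(np.array([180.0]), req, kobs, drift)[0] \
            == 0.0

    @settings(deadline=None, derandomize=True)
    @given(r1=st.floats(min_value=-5, max_value=5),
           koff=st.floats(min_value=0.0, max_value=1.0),
           drift=st.floats(min_value=-0.01, max_value=0.01))
    def test_dissociation_equals_r1_at_t0(self, r1, koff, drift):
        assert dissociation_model(np.array([300.0]), r1, koff, drift)[0] \
            == pytest.approx(r1)

    def test_association_one_time_constant(self):
        kobs = 0.129
        r = association_model(np.array([180.0 + 1 / kobs]), 1.0, kobs, 0.0)
        assert r[0] == pytest.approx(1 - np.exp(-1), rel=1e-12)

    def test_association_plateau(self):
        r = association_model(np.array([180.0 + 500.0]), 0.8, 0.1, 0.0)
        assert r[0] == pytest.approx(0.8, rel=1e-9)

    def test_dissociation_half_life(self):
        koff = 0.09
        r = dissociation_model(np.array([300.0 + np.log(2) / koff]),
                               1.0, koff, 0.0)
        assert r[0] == pytest.approx(0.5, rel=1e-12)

    def test_dissociation_no_decay_constant(self):
        t = np.array([300.0, 350.0, 420.0])
        assert dissociation_model(t, 0.7, 0.0, 0.0) \
            == pytest.approx([0.7, 0.7, 0.7])

    def test_before_t0_rejected(self):
        with pytest.raises(ValueError):
            association_model(np.array([100.0]), 1.0, 0.1, 0.0)
        with pytest.raises(ValueError):
            dissociation_model(np.array([100.0]), 1.0, 0.1, 0.0)


class TestSchedule:
    def test_default_matches_experiment(self):
        sched = SensorgramSchedule()
        assert sched.start("association") == 180.0
        assert sched.start("dissociation") == 300.0
        assert sched.total_duration == 420.0

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            SensorgramSchedule(segments=(("baseline1", 0.0, 30.0),
                                         ("association", 50.0, 120.0)))


class TestSegmentFits:
    def test_noiseless_association_roundtrip(self):
        traces = simulate_bli(0.039, 0.09, rmax=1.0,
                              concentrations_um=(1.0,))
        fit = fit_association(traces[0])
        assert abs(fit.kobs - 0.129) / 0.129 < 1e-6
        kd = 0.09 / 0.039
        req = 1.0 / (1.0 + kd)
        assert abs(fit.req - req) / req < 1e-6
        assert abs(fit.drift) < 1e-9

    def test_noiseless_dissociation_roundtrip(self):
        traces = simulate_bli(0.039, 0.09, concentrations_um=(5.0,))
        fit = fit_dissociation(traces[0])
        assert abs(fit.koff - 0.09) / 0.09 < 1e-6

    def test_drift_recovered(self):
        traces = simulate_bli(0.039, 0.09, concentrations_um=(5.0,),
                              association_drift=5e-4,
                              dissociation_drift=2e-4)
        assert fit_association(traces[0]).drift \
            == pytest.approx(5e-4, rel=1e-5)
        assert fit_dissociation(traces[0]).drift \
            == pytest.approx(2e-4, rel=1e-4)

    def test_pure_noise_segment_fails(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 420.5, 0.5)
        r = rng.normal(0.0, 0.01, t.shape)
        trace = Sensorgram(t, r, concentration_um=5.0)
        with pytest.raises(FitFailure):
            fit_association(trace)

    def test_short_segment_rejected(self):
        t = np.arange(0.0, 421.0, 15.0)
        trace = Sensorgram(t, np.zeros_like(t), concentration_um=5.0)
        with pytest.raises(FitFailure, match="20"):
            fit_dissociation(trace)


class TestPseudoFirstOrder:
    def test_exact_line_recovered(self):
        c = np.array([1.0, 2.0, 5.0, 10.0])
        kobs = 0.039 * c + 0.09
        assert kobs == pytest.approx([0.129, 0.168, 0.285, 0.48])
        kon, koff, s_kon, s_koff = pseudo_first_order(kobs, c)
        assert kon == pytest.approx(0.039, abs=1e-12)
        assert koff == pytest.approx(0.09, abs=1e-12)
        assert s_kon == pytest.approx(0.0, abs=1e-8)

    def test_rank_deficiency_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            pseudo_first_order(np.array([0.1, 0.1, 0.2]),
                               np.array([1.0, 1.0, 1.0]))

    def test_zero_slope_downstream_error(self):
        c = np.array([1.0, 2.0, 5.0])
        kon, koff, *_ = pseudo_first_order(np.full(3, 0.09), c)
        assert kon == pytest.approx(0.0, abs=1e-15)
        with pytest.raises(ValueError):
            kd_from_rates(kon, koff)


class TestKdFromRates:
    @pytest.mark.parametrize("kon,koff,kd_2sf", [
        (0.039, 0.09, 2.3),
        (0.05, 0.06, 1.2),
        (0.03, 0.06, 2.0),
        (0.038, 0.09, 2.4),
    ])
    def test_published_rate_pairs(self, kon, koff, kd_2sf):
        from nlsbind.report import round_sig
        res = kd_from_rates(kon, koff)
        assert round_sig(res.kd_um, 2) == pytest.approx(kd_2sf)

    def test_zero_koff_gives_zero_kd(self):
        assert kd_from_rates(0.06, 0.0).kd_um == 0.0

    def test_stored_kd_is_exact_ratio(self):
        res = kd_from_rates(0.0371, 0.0912, 0.003, 0.01)
        assert res.kd_um == res.koff / res.kon

    def test_propagated_error_quadrature(self):
        res = kd_from_rates(0.039, 0.09, 0.003, 0.01)
        expect = (0.09 / 0.039) * np.hypot(0.003 / 0.039, 0.01 / 0.09)
        assert res.sigma_kd_um == pytest.approx(expect)

    def test_two_state_assumption_recorded(self):
        assert kd_from_rates(0.039, 0.09).two_state_assumed


class TestEndToEnd:
    def test_noisy_drifted_recovery_within_10pct(self):
        # 20 seeded replicates at 1-10 uM, 1% noise, per-segment drift
        kon_true, koff_true = 0.039, 0.09
        kons, koffs = [], []
        for rep in range(20):
            traces = simulate_bli(
                kon_true, koff_true, rmax=1.0,
                concentrations_um=(1.0, 2.0, 5.0, 10.0),
                association_drift=2e-4, dissociation_drift=1e-4,
                noise=NoiseSpec(sigma=0.01, seed=9000 + rep))
            kobs = [fit_association(tr).kobs for tr in traces]
            conc = [tr.concentration_um for tr in traces]
            kon, koff, *_ = pseudo_first_order(np.array(kobs),
                                               np.array(conc))
            kons.append(kon)
            koffs.append(koff)
        assert abs(np.median(kons) - kon_true) / kon_true < 0.10
        assert abs(np.median(koffs) - koff_true) / koff_true < 0.10
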