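"""Tests of event application and piecewise integration."""

import numpy as np
import pytest

from isletchip import (ChipConfig, ModelParameters, SystemState,
                       apply_media_exchange, apply_sampling,
                       predict_with_dose_uncertainty, simulate_protocol,
                       standard_protocol)
from isletchip.protocol import (MediaExchangeEvent, SamplingEvent,
                                single_dose_protocol)

REACTIONS_OFF = dict(E_G0=0, S_I0=0, sigma_max=0, CL_I_spheroids=0, EGP=0)


def make_state(config, G_l=10.0, G_p=10.0, I_l=0.0, I_p=0.0, **kw):
    defaults = dict(t=0.0,
                    NG_liver=G_l * config.V_m_liver,
                    NG_pancreas=G_p * config.V_m_pancreas,
                    NI_liver=I_l * config.V_m_liver,
                    NI_pancreas=I_p * config.V_m_pancreas,
                    G_slow=G_p, V_beta=8.8e-9,
                    V_m_liver_now=config.V_m_liver,
                    V_m_pancreas_now=config.V_m_pancreas)
    defaults.update(kw)
    return SystemState(**defaults)


class TestMediaExchange:
    def test_sets_amounts_from_fresh_concentrations(self, config):
        state = make_state(config, G_l=3.0, G_p=4.0, I_l=50.0, I_p=80.0,
                           G_int=7.3)
        new = apply_media_exchange(state, MediaExchangeEvent(10.0, 11.0),
                                   config)
        assert new.NG_liver == pytest.approx(3.3e-3)
        assert new.NI_liver == 0.0 and new.NI_pancreas == 0.0
        assert new.G_int == 7.3  # slow variables continuous
        assert new.V_beta == state.V_beta

    def test_offsets_and_floor(self, config):
        ev = MediaExchangeEvent(10.0, 11.0, dG=0.5, dI=-3.0)
        new = apply_media_exchange(make_state(config), ev, config)
        assert new.G_liver == pytest.approx(11.5)
        assert new.I_liver == 0.0  # insulin floored at zero

    def test_negative_glucose_rejected(self, config):
        ev = MediaExchangeEvent(10.0, 2.8, dG=-3.0)
        with pytest.raises(ValueError):
            apply_media_exchange(make_state(config), ev, config)

    def test_volume_reset(self, config):
        state = make_state(config, V_m_liver_now=2.7e-4,
                           V_m_pancreas_now=2.7e-4)
        new = apply_media_exchange(state, MediaExchangeEvent(10.0, 5.5),
                                   config)
        assert new.V_m_liver_now == config.V_m_liver


class TestSampling:
    def test_proportional_removal_preserves_concentration(self, config):
        state = make_state(config, G_l=10.0)
        ev = SamplingEvent(time=1.0, volume_per_compartment=1.5e-5)
        new, _ = apply_sampling(state, ev, config)
        assert state.NG_liver - new.NG_liver == pytest.approx(1.5e-4)
        assert new.G_liver == pytest.approx(10.0)

    def test_pooled_measurement_is_mean(self, config):
        state = make_state(config, G_l=11.0, G_p=9.0)
        ev = SamplingEvent(time=1.0, volume_per_compartment=1.5e-5)
        _, ms = apply_sampling(state, ev, config)
        glucose = next(m for m in ms if m.observable == "glucose")
        assert glucose.compartment == "pooled"
        assert glucose.value == pytest.approx(10.0)
        assert len(ms) == 2

    def test_per_compartment_emits_four_records(self, config):
        ev = SamplingEvent(time=1.0, volume_per_compartment=1.5e-5,
                           pooled=False)
        _, ms = apply_sampling(make_state(config), ev, config)
        assert len(ms) == 4
        assert {(m.observable, m.compartment) for m in ms} == {
            ("glucose", "liver"), ("glucose", "pancreas"),
            ("insulin", "liver"), ("insulin", "pancreas")}

    def test_excessive_removal_rejected(self, config):
        ev = SamplingEvent(time=1.0, volume_per_compartment=4e-4)
        with pytest.raises(ValueError):
            apply_sampling(make_state(config), ev, config)

    def test_volume_tracking_off_keeps_amounts(self, config):
        state = make_state(config)
        ev = SamplingEvent(time=1.0, volume_per_compartment=1.5e-5)
        new, _ = apply_sampling(state, ev, config, track_volumes=False)
        assert new.NG_liver == state.NG_liver
        assert new.V_m_liver_now == state.V_m_liver_now


class TestIntegration:
    def test_conservation_with_reactions_off(self, config):
        p = ModelParameters(**REACTIONS_OFF)
        proto = standard_protocol("hyper", gtt_days=(1,), config=config)
        traj, _ = simulate_protocol(p, None, config, proto,
                                    track_volumes=False)
        # between-event windows conserve total amounts
        seg = (traj.times > 24.01) & (traj.times < 71.99)
        total = traj.column("NG_liver")[seg] + traj.column("NG_pancreas")[seg]
        assert np.ptp(total) / total[0] < 1e-6

    def test_two_compartment_mixing_matches_closed_form(self, config):
        p = ModelParameters(**REACTIONS_OFF)
        proto = single_dose_protocol(11.0, 6.0, sample_every=0.5)
        traj, _ = simulate_protocol(p, None, config, proto,
                                    track_volumes=False)
        # perturb via an asymmetric start: simulate a fresh state by hand
        # using the kernel path below instead; here assert equal start stays
        assert np.allclose(traj.G_liver, traj.G_pancreas)

    def test_mixing_rate_equals_2Q_over_V(self, config):
        from isletchip._kernel import pack_params
        from isletchip.simulate import _segment_adaptive

        p = pack_params(ModelParameters(**REACTIONS_OFF), config)
        V = config.V_m_liver
        y = np.array([11.0 * V, 5.5 * V, 0, 0, 0, 5.5, 0.0])
        grid = np.linspace(0.0, 3.0, 31)
        states, _ = _segment_adaptive(y, 0.0, 3.0, p, V, V, grid, 1e-10)
        diff = (states[:, 0] - states[:, 1]) / V
        rate = -np.polyfit(grid, np.log(np.abs(diff)), 1)[0]
        assert rate == pytest.approx(2 * config.Q / V, rel=1e-4)
        assert rate == pytest.approx(1.973, abs=2e-3)

    def test_pooled_glucose_decreasing_between_exchanges(self, hyper_run):
        traj, _ = hyper_run
        seg = (traj.times > 24.01) & (traj.times < 71.99)
        g = traj.G_pooled[seg]
        assert np.all(np.diff(g) < 1e-9)

    def test_event_commutation_zero_volume_sample(self, config, params):
        proto = standard_protocol("hyper", gtt_days=(1,), config=config)
        extra = SamplingEvent(time=40.0, volume_per_compartment=0.0)
        events = tuple(sorted(proto.events + (extra,),
                              key=lambda e: (e.time, e.order)))
        proto2 = proto.__class__(regime=proto.regime, events=events,
                                 duration=proto.duration)
        t1, _ = simulate_protocol(params, None, config, proto)
        t2, _ = simulate_protocol(params, None, config, proto2)
        common = np.intersect1d(t1.times, t2.times)
        i1 = np.searchsorted(t1.times, common)
        i2 = np.searchsorted(t2.times, common)
        assert np.allclose(t1.states[i1], t2.states[i2], rtol=1e-7, atol=1e-12)

    def test_positivity_along_trajectory(self, hyper_run):
        traj, _ = hyper_run
        assert (traj.states >= 0).all()

    def test_slow_variables_continuous_across_events(self, hyper_run):
        traj, _ = hyper_run
        dup = np.where(np.diff(traj.times) == 0.0)[0]
        assert len(dup) > 0
        for i in dup:
            assert np.allclose(traj.states[i, 4:7], traj.states[i + 1, 4:7])

    def test_large_alpha_keeps_secretion_flat(self, config, params):
        p = params.replace(alpha=1e12)
        proto = standard_protocol("hyper", gtt_days=(1,), config=config)
        traj, _ = simulate_protocol(p, None, config, proto)
        assert traj.sigma.min() >= 0.999 * p.sigma_max

    def test_insulin_non_decreasing_in_sigma_max(self, config, params):
        proto = standard_protocol("hyper", gtt_days=(1,), config=config)
        values = []
        for scale in (0.5, 1.0, 2.0):
            _, ms = simulate_protocol(params.replace(sigma_max=scale * 6e6),
                                      None, config, proto, method="fixed")
            values.append(max(m.value for m in ms if m.observable == "insulin"))
        assert values[0] < values[1] < values[2]


class TestDoseUncertainty:
    def test_zero_halfwidth_collapses_band(self, config, params):
        proto = standard_protocol("hypo", gtt_days=(13,), config=config)
        band = predict_with_dose_uncertainty(params, None, config, proto,
                                             0.0, n_grid=3, method="fixed")
        assert np.allclose(band.lo["glucose"], band.hi["glucose"])

    def test_band_contains_nominal_and_grows_with_halfwidth(self, config,
                                                            params):
        proto = standard_protocol("hypo", gtt_days=(13,), config=config)
        widths = []
        for h in (0.4, 0.85):
            band = predict_with_dose_uncertainty(params, None, config, proto,
                                                 h, n_grid=3, method="fixed")
            assert np.all(band.lo["glucose"] <= band.nominal["glucose"] + 1e-12)
            assert np.all(band.nominal["glucose"] <= band.hi["glucose"] + 1e-12)
            widths.append(band.hi["glucose"] - band.lo["glucose"])
        assert np.all(widths[1] >= widths[0] - 1e-12)
        table = band.measurement_table
        assert {"lo", "hi", "nominal"} <= set(table.columns)
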