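"""Spike detection and the 25-feature extraction."""

import numpy as np
import pytest

import vtasst as v
from vtasst.features import FeatureError, _isis, spikes_by_sweep

DT = 0.1


def _one_ap_trace(
    thr_t=220.0,
    thr_v=-31.0,
    peak_v=64.0,
    halfwidth=1.0,
    ahp=26.0,
    decay=2.2,
    base=-51.0,
    total_ms=400.0,
):
    """Piecewise-linear single-AP trace; anchors on the sample grid."""
    n = int(round(total_ms / DT))
    t = np.arange(n) * DT
    vtr = np.full(n, base)
    t_r = 0.3
    t_f = 2 * halfwidth - t_r
    anchors_t = [0, thr_t - 5, thr_t, thr_t + t_r, thr_t + t_r + t_f, thr_t + t_r + decay]
    anchors_v = [base, base, thr_v, peak_v, thr_v, thr_v - ahp]
    vtr = np.interp(t, anchors_t, anchors_v)
    # recovery back to baseline
    rec_end = thr_t + t_r + decay + 10.0
    mask = t > thr_t + t_r + decay
    vtr[mask] = np.interp(t[mask], [thr_t + t_r + decay, rec_end], [thr_v - ahp, base])
    vtr[t > rec_end] = base
    return vtr


class TestDetectSpikes:
    def test_flat_trace_yields_nothing(self):
        assert v.detect_spikes(np.full(5000, -70.0), DT) == []

    def test_subthreshold_ramp_yields_nothing(self):
        # 9 mV/ms rise never crosses the 10 mV/ms detection slope
        t = np.arange(0, 50, DT)
        assert v.detect_spikes(-70.0 + 9.0 * t, DT) == []

    def test_threshold_at_derivative_crossing(self):
        """Threshold localized to the dV/dt crossing of a constructed AP.

        Oracle: a dense finite-difference scan of the closed-form template
        puts the first 10 mV/ms crossing at the 220.0 ms anchor.
        """
        trace = _one_ap_trace(thr_t=220.0)
        dense_t = np.arange(210.0, 230.0, 0.001)
        dense_v = np.interp(dense_t, np.arange(trace.size) * DT, trace)
        dvdt = np.diff(dense_v) / 0.001
        oracle = dense_t[np.argmax(dvdt > 10.0)]
        events = v.detect_spikes(trace, DT)
        assert len(events) == 1
        assert events[0].threshold_time == pytest.approx(oracle, abs=DT)
        assert events[0].peak_v == pytest.approx(64.0)

    def test_small_wiggles_rejected(self):
        trace = _one_ap_trace(peak_v=-16.0)  # only 15 mV above threshold
        assert v.detect_spikes(trace, DT) == []

    def test_count_invariant_to_appended_baseline(self):
        trace = _one_ap_trace()
        longer = np.concatenate([trace, np.full(3000, trace[-1])])
        n0 = len(v.detect_spikes(trace, DT, search_end=trace.size))
        n1 = len(v.detect_spikes(longer, DT, search_end=trace.size))
        assert n0 == n1 == 1

    def test_halfwidth_by_level_crossing_oracle(self):
        """Half-width 1.00 ms at the half-amplitude level (+16.5 mV).

        Oracle: numeric level-crossing scan on a dense re-sampling of the
        same template.
        """
        trace = _one_ap_trace(thr_v=-31.0, peak_v=64.0, halfwidth=1.0)
        ev = v.detect_spikes(trace, DT)[0]
        level = -31.0 + (64.0 + 31.0) / 2
        dense_t = np.arange(215.0, 228.0, 0.0005)
        dense_v = np.interp(dense_t, np.arange(trace.size) * DT, trace)
        above = dense_v >= level
        t_up = dense_t[np.argmax(above)]
        t_dn = dense_t[np.argmax(above) + np.argmax(~above[np.argmax(above):])]
        assert t_dn - t_up == pytest.approx(1.0, abs=0.01)
        assert ev.halfwidth == pytest.approx(1.0, abs=0.02)


class TestPassive:
    def test_input_resistance_exact_linear_case(self):
        """Steady responses -78/-74/-70/-66 mV at -100/-50/0/+50 pA give a
        0.08 mV/pA slope, i.e. 80 MOhm."""
        n = int(round(1000.0 / DT))
        currents = np.array([-100.0, -50.0, 0.0, 50.0])
        vss = np.array([-78.0, -74.0, -70.0, -66.0])
        voltages = np.full((4, n), -70.0)
        i0, i1 = int(100 / DT), int(900 / DT)
        for k in range(4):
            voltages[k, i0:i1] = vss[k]
        ladder = v.SweepLadder("lin", DT, currents, voltages, 100.0, 800.0)
        _, rin, _, _ = v.passive_properties(ladder, spikes=[[], [], [], []])
        assert rin == pytest.approx(80.0)

    def test_sag_ratio_definition(self):
        """-100 pA sweep with trough -85.0 mV and late steady mean -81.6 mV
        has sag 0.96 by the ratio definition."""
        n = int(round(1000.0 / DT))
        i0, i1 = int(100 / DT), int(900 / DT)
        voltages = np.full((2, n), -70.0)
        voltages[0, i0:i1] = -85.0
        voltages[0, i1 - int(50 / DT): i1] = -81.6
        ladder = v.SweepLadder(
            "sag", DT, np.array([-100.0, -90.0]), voltages, 100.0, 800.0
        )
        _, _, sag, _ = v.passive_properties(ladder, spikes=[[], []])
        assert sag == pytest.approx(-81.6 / -85.0, abs=1e-3)
        assert sag == pytest.approx(0.96, abs=1e-3)

    def test_tau_recovered_from_exponential_relaxation(self):
        """Closed-form RC relaxation with tau = 15 ms is fit to +-0.1 ms."""
        tmpl = v.DEFAULT_SUBTYPES["ADP"].template
        ladder, truth = v.synth_trace_ladder(tmpl, seed=0, noise_sd=0.0)
        _, _, _, tau = v.passive_properties(ladder)
        assert tau == pytest.approx(15.0, abs=0.1)

    def test_too_few_quiet_sweeps_is_an_error(self):
        ladder, _ = v.synth_trace_ladder(v.DEFAULT_SUBTYPES["ADP"], seed=0, noise_sd=0)
        fake_spikes = [[None]] * (ladder.n_sweeps - 1) + [[]]
        with pytest.raises(FeatureError, match="spike-free"):
            v.passive_properties(ladder, spikes=fake_spikes)


class TestRheobaseBlock:
    def test_rheobase_is_lowest_spiking_current(self, adp_ladder_noiseless):
        ladder, truth = adp_ladder_noiseless
        fv = v.rheobase_features(ladder, spikes_by_sweep(ladder))
        assert fv.rheobase_current == truth.rheobase_current == 20.0

    def test_adp_amplitude_from_constructed_trough_and_bump(self):
        """AHP trough at -60.0 mV followed by a bump peaking at -46.2 mV
        gives an afterdepolarization of 13.8 mV."""
        tmpl = v.TraceTemplate(
            rmp=-70.0, tau=15.0, rin=800.0, sag_ratio=0.96, capacitance_pf=13.0,
            rheobase=18.0, saturating_current=207.0,
            threshold=-31.0, amplitude=95.0, halfwidth=1.0, ahp_amp=29.0, decay=2.2,
            amplitude_sat=80.0, halfwidth_sat=1.9, ahp_amp_sat=20.0, decay_sat=4.0,
            adp_amp=13.8, adp_latency=20.0,
            latency_rheo=218.0, latency_sat=24.8, count_rheo=2, count_sat=21,
            fmax_init=108.0, fmax_ss=25.6, isi_rheo=250.0,
        )
        ladder, _ = v.synth_trace_ladder(tmpl, seed=0, noise_sd=0.0)
        ev = spikes_by_sweep(ladder)[np.argmax(ladder.currents == 20.0)][0]
        assert ev.ahp_v == pytest.approx(-60.0, abs=0.1)
        assert ev.adp_v == pytest.approx(-46.2, abs=0.1)
        assert ev.adp_amplitude == pytest.approx(13.8, abs=0.1)

    def test_no_rheobase_error_for_subthreshold_ladder(self):
        n = int(round(1000.0 / DT))
        ladder = v.SweepLadder(
            "quiet", DT, np.array([-100.0, 0.0]), np.full((2, n), -70.0), 100.0, 800.0
        )
        with pytest.raises(FeatureError, match="no_rheobase"):
            v.extract_features(ladder)


class TestSaturatedBlock:
    def test_fmax_from_isi_arithmetic(self):
        """ISIs [5,6,7,...] give fmax_init = 200 Hz; last four ISIs
        [38,40,42,40] give fmax_ss = 25 Hz and adaptation 0.125."""
        isis = np.array([5.0, 6.0, 7.0, 38.0, 40.0, 42.0, 40.0])
        early = isis[:2]
        assert 1000.0 / early.min() == pytest.approx(200.0)
        late = isis[-4:]
        assert 1000.0 / late.mean() == pytest.approx(25.0)
        assert (1000.0 / late.mean()) / (1000.0 / early.min()) == pytest.approx(0.125)
        # the extractor applies the same formulas to detected spike trains
        ladder, truth = v.synth_trace_ladder(
            v.DEFAULT_SUBTYPES["HFF"], seed=0, noise_sd=0.0
        )
        fv = v.extract_features(ladder)
        assert fv.fmax_init == pytest.approx(truth.fmax_init, rel=1e-6)
        assert fv.fmax_ss == pytest.approx(truth.fmax_ss, rel=1e-6)

    def test_delayed_first_spike_latency(self, delayed_ladder_noiseless):
        """A constructed Delayed-type sweep with its first threshold
        crossing 279 ms after step onset reports that latency."""
        ladder, truth = delayed_ladder_noiseless
        fv = v.extract_features(ladder)
        assert truth.first_spike_latency_sat == 279.0
        assert fv.first_spike_latency_sat == pytest.approx(279.0, abs=0.1)

    def test_saturated_tie_breaks_to_lowest_current(self):
        ladder, truth = v.synth_trace_ladder(
            v.DEFAULT_SUBTYPES["ADP"], seed=0, noise_sd=0.0
        )
        spikes = spikes_by_sweep(ladder)
        counts = np.array([len(s) for s in spikes])
        ties = ladder.currents[counts == counts.max()]
        fv = v.saturation_features(ladder, spikes)
        assert fv.saturating_current == ties.min()


class TestExtractFeatures:
    def test_hff_initial_rate_recovered(self):
        """An HFF-type ladder built with a 129 Hz initial maximal rate is
        recovered within 2%."""
        tmpl = v.DEFAULT_SUBTYPES["HFF"].template
        ladder, truth = v.synth_trace_ladder(tmpl, seed=0, noise_sd=0.2)
        fv = v.extract_features(ladder)
        assert truth.fmax_init == pytest.approx(129.0, rel=0.01)
        assert fv.fmax_init == pytest.approx(truth.fmax_init, rel=0.02)

    def test_adaptation_ratio_identity(self, adp_ladder_noiseless):
        ladder, _ = adp_ladder_noiseless
        fv = v.extract_features(ladder)
        assert fv.adaptation_ratio == fv.fmax_ss / fv.fmax_init

    def test_isi_count_matches_spike_count(self, adp_ladder_noiseless):
        ladder, _ = adp_ladder_noiseless
        for events in spikes_by_sweep(ladder):
            if events:
                assert _isis(events).size == len(events) - 1

    def test_determinism(self, adp_ladder_noiseless):
        ladder, _ = adp_ladder_noiseless
        a = v.extract_features(ladder).as_series()
        b = v.extract_features(ladder).as_series()
        assert (a == b).all()

    def test_translation_invariance(self):
        """Adding a constant to all voltages shifts rmp and thresholds by
        that constant and leaves widths, latencies, rates and counts
        unchanged."""
        tmpl = v.DEFAULT_SUBTYPES["ADP"].template
        ladder, _ = v.synth_trace_ladder(tmpl, seed=0, noise_sd=0.0)
        shifted = v.SweepLadder(
            cell_id="shifted",
            dt=ladder.dt,
            currents=ladder.currents.copy(),
            voltages=ladder.voltages + 7.0,
            step_onset=ladder.step_onset,
            step_duration=ladder.step_duration,
            capacitance_pf=ladder.capacitance_pf,
        )
        a = v.extract_features(ladder)
        b = v.extract_features(shifted)
        assert b.rmp == pytest.approx(a.rmp + 7.0, abs=1e-9)
        assert b.ap_threshold == pytest.approx(a.ap_threshold + 7.0, abs=1e-9)
        for f in (
            "ap_halfwidth", "ap_amplitude", "ahp_amplitude", "adp_amplitude",
            "first_spike_latency_rheo", "first_spike_latency_sat",
            "fmax_init", "fmax_ss", "spike_count_rheo", "spike_count_sat",
            "input_resistance",
        ):
            assert getattr(b, f) == pytest.approx(getattr(a, f), abs=1e-9), f
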