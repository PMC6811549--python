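"""Current-clamp feature extraction: worked examples with exact
constructions, ground-truth recovery on simulations, and the chirp
impedance estimator against closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinequant.data import Sweep
from spinequant.intrinsic import (detect_aps, impedance_profile,
                                  input_resistance, rheobase_and_fi,
                                  sag_and_rebound)
from spinequant.resonance import design_resonant_membrane, simulate_chirp
from spinequant.simulate import NeuronParams, StimulusSpec, simulate

FS = 20_000.0
DT = 1.0 / FS


def step_sweep(amp_pa, trace_during, baseline=-60.0, pre_s=0.1, post_s=0.2):
    """Current-clamp sweep with an explicit voltage course during the step."""
    n_pre, n_post = int(pre_s * FS), int(post_s * FS)
    v = np.concatenate([np.full(n_pre, baseline), trace_during,
                        np.full(n_post, baseline)])
    i = np.zeros_like(v)
    i[n_pre:n_pre + len(trace_during)] = amp_pa
    return Sweep(dt=DT, samples=v, stimulus=i, mode="current_clamp")


def sag_trace(baseline, peak_defl, steady_defl, dur_s=0.5):
    """Step response hitting an exact early peak and an exactly constant
    steady tail (last 150 ms)."""
    n = int(dur_s * FS)
    v = np.empty(n)
    n_peak = int(0.15 * FS)
    v[:n_peak] = baseline + peak_defl
    n_ramp = int(0.1 * FS)
    v[n_peak:n_peak + n_ramp] = np.linspace(baseline + peak_defl,
                                            baseline + steady_defl, n_ramp)
    v[n_peak + n_ramp:] = baseline + steady_defl
    return v


class TestInputResistance:
    def test_two_point_exact_line(self):
        sweeps = [step_sweep(-25.0, np.full(int(0.5 * FS), -62.5)),
                  step_sweep(-50.0, np.full(int(0.5 * FS), -65.0))]
        assert input_resistance(sweeps) == pytest.approx(100.0)

    def test_single_smallest_step_variant(self):
        sw = step_sweep(-25.0, np.full(int(0.5 * FS), -62.5))
        assert input_resistance([sw]) == pytest.approx(100.0)

    def test_recovers_simulated_ground_truth(self):
        p = NeuronParams(cm=100.0, g_leak=1000.0 / 150.0, g_hcn_max=0.0)
        sweeps = simulate(p, [], StimulusSpec.step_family(
            [-25.0, -50.0, -75.0]))
        assert input_resistance(sweeps) == pytest.approx(150.0, abs=1.0)

    def test_too_few_steps_raises(self):
        with pytest.raises(ValueError):
            input_resistance([step_sweep(-25.0,
                                         np.full(int(0.5 * FS), -62.5)),
                              step_sweep(-25.0,
                                         np.full(int(0.5 * FS), -62.5))][0:0]
                             or [])


class TestDetectAPs:
    def test_flat_trace_no_events(self):
        sw = Sweep(dt=DT, samples=np.full(2000, -60.0),
                   stimulus=np.zeros(2000))
        assert detect_aps(sw) == []

    def test_subthreshold_epsp_respects_dvdt_criterion(self):
        # 10 mV EPSP rising over 20 ms: dV/dt = 0.5 mV/ms << 20 mV/ms
        t = np.arange(4000) * DT * 1000.0
        v = -60.0 + 10.0 * np.clip(t - 50.0, 0, 20.0) / 20.0
        sw = Sweep(dt=DT, samples=v, stimulus=np.zeros_like(v))
        assert detect_aps(sw) == []

    def test_count_matches_simulator_spike_markers(self):
        p = NeuronParams()
        sw = simulate(p, [], StimulusSpec.step_family([125.0]))[0]
        n_true = len(sw.marker_times("spike"))
        assert n_true > 0
        assert len(detect_aps(sw)) == n_true

    def test_ap_parameters_sane(self):
        p = NeuronParams()
        sw = simulate(p, [], StimulusSpec.step_family([100.0]))[0]
        aps = detect_aps(sw)
        for ap in aps:
            assert ap.peak_mv > 0 > ap.threshold_mv
            assert ap.amplitude_mv > 40.0


class TestRheobase:
    def test_first_firing_step_is_rheobase(self):
        p = NeuronParams()
        sweeps = simulate(p, [], StimulusSpec.step_family(
            np.arange(25.0, 126.0, 25.0)))
        rheo, censored, fi = rheobase_and_fi(sweeps)
        firing = sorted(a for a, n in fi.items() if n > 0)
        assert rheo == firing[0] and not censored

    def test_censored_when_nothing_fires(self):
        p = NeuronParams(spike_threshold=100.0)  # unreachable
        sweeps = simulate(p, [], StimulusSpec.step_family([25.0, 50.0]))
        rheo, censored, _ = rheobase_and_fi(sweeps)
        assert censored and rheo == 50.0

    def test_lower_leak_lowers_rheobase(self):
        rheos = []
        for gl in (4.0, 3.0, 2.0):
            p = NeuronParams(g_leak=gl, g_hcn_max=0.0)
            sweeps = simulate(p, [], StimulusSpec.step_family(
                np.arange(5.0, 126.0, 5.0)))
            rheos.append(rheobase_and_fi(sweeps)[0])
        assert rheos[0] >= rheos[1] >= rheos[2]
        assert rheos[0] > rheos[2]


class TestSagRebound:
    def test_constructed_sweep_gives_exact_sag(self):
        """Peak deflection 20 mV, steady 17.82 mV -> sag 10.9 %."""
        v = sag_trace(-60.0, -20.0, -20.0 * (1 - 0.109))
        sag, _, _ = sag_and_rebound([step_sweep(-100.0, v)])
        assert sag[-100.0] == pytest.approx(10.9)

    def test_monotone_exponential_zero_sag(self):
        t = np.arange(int(0.5 * FS)) * DT * 1000.0
        v = -60.0 - 20.0 * (1 - np.exp(-t / 10.0))  # settles in ~50 ms
        sag, _, _ = sag_and_rebound([step_sweep(-100.0, v)])
        assert sag[-100.0] == pytest.approx(0.0, abs=0.05)

    def test_rebound_points_on_line_recover_slope(self):
        """Rebound/steady pairs placed exactly on a -0.11 mV/mV line."""
        sweeps = []
        for amp, steady_defl in [(-25.0, -5.0), (-50.0, -10.0),
                                 (-75.0, -15.0), (-100.0, -20.0)]:
            v = sag_trace(-60.0, steady_defl - 1.0, steady_defl)
            sw = step_sweep(amp, v)
            reb = -0.11 * steady_defl
            i_off = np.flatnonzero(sw.stimulus != 0)[-1] + 1
            sw.samples[i_off + 10] = -60.0 + reb  # exact rebound peak
            sweeps.append(sw)
        _, slope, _ = sag_and_rebound(sweeps)
        assert slope == pytest.approx(-0.11)

    @given(offset=st.floats(-30.0, 30.0))
    @settings(max_examples=20, deadline=None)
    def test_sag_invariant_to_baseline_shift(self, offset):
        v = sag_trace(-60.0, -20.0, -17.0)
        sw = step_sweep(-100.0, v)
        sag0, _, _ = sag_and_rebound([sw])
        sw_shift = Sweep(dt=sw.dt, samples=sw.samples + offset,
                         stimulus=sw.stimulus, mode=sw.mode)
        sag1, _, _ = sag_and_rebound([sw_shift])
        assert sag1[-100.0] == pytest.approx(sag0[-100.0], abs=1e-9)

    def test_too_short_step_raises(self):
        v = np.full(int(0.2 * FS), -80.0)  # 200-ms step: windows don't fit
        with pytest.raises(ValueError):
            sag_and_rebound([step_sweep(-100.0, v)])


class TestImpedance:
    def test_pure_rc_matches_analytic_low_pass(self):
        """R = 100 MOhm, C = 100 pF: |Z(f)| = R/sqrt(1+(2 pi f R C)^2)
        within 2 %; peak at the lowest frequency with Q = 1."""
        p = NeuronParams(cm=100.0, g_leak=10.0, g_hcn_max=0.0,
                         compartments=1)
        sw = simulate(p, [], StimulusSpec.chirp())[0]
        freqs, z, f_res, q = impedance_profile(sw)
        rc = 100e6 * 100e-12
        analytic = 100.0 / np.sqrt(1 + (2 * np.pi * freqs * rc) ** 2)
        sel = (freqs > 0.3) & (freqs < 15.0)
        assert np.max(np.abs(z[sel] / analytic[sel] - 1)) < 0.02
        assert f_res == pytest.approx(0.2, abs=0.05)
        assert q == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("f_star, c_pf", [(0.8, 400.0), (1.1, 400.0),
                                              (2.5, 150.0)])
    def test_resonant_membrane_peak_recovered(self, f_star, c_pf):
        """Chirp + FFT pipeline recovers an analytically placed peak
        within 0.1 Hz."""
        mem = design_resonant_membrane(f_star, c_pf=c_pf)
        assert mem.peak_frequency() == pytest.approx(f_star, abs=0.01)
        sw = simulate_chirp(mem)
        _, _, f_res, q = impedance_profile(sw)
        assert f_res == pytest.approx(f_star, abs=0.1)
        assert q > 1.0

    def test_non_chirp_stimulus_rejected(self):
        n = int(20.0 * FS)
        i = np.zeros(n)
        i[n // 4:n // 2] = 50.0  # a step, not a chirp
        sw = Sweep(dt=DT, samples=np.full(n, -60.0), stimulus=i,
                   mode="current_clamp")
        with pytest.raises(ValueError, match="chirp"):
            impedance_profile(sw)

    def test_fft_matches_steady_state_sine_ratio(self):
        """Chirp-based |Z| agrees with single-sine steady-state amplitude
        ratios at 0.5, 2 and 8 Hz within 3 % (noiseless, passive)."""
        p = NeuronParams(cm=100.0, g_leak=10.0, g_hcn_max=0.0,
                         compartments=1)
        chirp = simulate(p, [], StimulusSpec.chirp())[0]
        freqs, z, _, _ = impedance_profile(chirp)
        for f0 in (0.5, 2.0, 8.0):
            spec = StimulusSpec("chirp", dict(f0=f0, f1=f0, amplitude=50.0,
                                              duration=6.0, holding=0.0))
            sine = simulate(p, [], spec)[0]
            # last two cycles: steady state
            n_cyc = int(round(2 / f0 / sine.dt))
            v = sine.samples[-n_cyc:]
            i = sine.stimulus[-n_cyc:]
            ratio = (np.ptp(v) / 2) / (np.ptp(i) / 2) * 1000.0
            j = int(np.argmin(np.abs(freqs - f0)))
            assert z[j] == pytest.approx(ratio, rel=0.03)
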