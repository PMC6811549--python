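"""Conductance-based point-neuron simulator for synthetic cohorts.

The model is one or two compartments (soma + lumped dendrite joined by a
coupling conductance), with leak, a first-order HCN conductance
(dm/dt = (m_inf(V) - m)/tau(V), m_inf(V) = 1/(1 + exp((V - V1/2)/k))),
bi-exponential AMPA/NMDA synapses with a voltage-dependent magnesium block
1/(1 + [Mg]*scale*exp(-slope*V)), and a stereotyped-threshold spike
mechanism in current clamp.  Voltage clamp is modelled through a series
resistance, which yields a physical capacitive transient and records the
pipette current.

Integration is exponential Euler on the gating variable and forward Euler
on the voltages at dt = 0.025 ms, decimated to the 20 kHz output rate.
Identical (params, stimulus, seed) yield bit-identical sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from numba import njit

from .data import Sweep, CURRENT_CLAMP, VOLTAGE_CLAMP

# Standard constants (configurable per-call; recorded here, not buried)
E_HCN_MV = -30.0
MG_MM = 1.0
MG_SLOPE_PER_MV = 0.062
MG_SCALE = 1.0 / 3.57

DT_MS_DEFAULT = 0.025
OUTPUT_HZ = 20_000.0


@dataclass
class NeuronParams:
    """Ground-truth biophysical parameters of a simulated cell.

    Conductances in nS, capacitances in pF, voltages in mV, times in ms.
    ``compartments=2`` adds a lumped dendrite (``cm_dend``, ``g_leak_dend``)
    coupled to the soma by ``g_c``; synapses then attach to the dendrite,
    giving a shared driving force and hence sublinear summation.
    """

    cm: float = 150.0
    g_leak: float = 3.0
    e_leak: float = -65.0
    g_hcn_max: float = 4.0
    hcn_v12: float = -86.0
    hcn_k: float = 10.0          # slope, > 0
    hcn_tau_min: float = 900.0   # ms, hyperpolarised limit
    hcn_tau_max: float = 1100.0  # ms, depolarised limit
    hcn_tau_v12: float = -90.0
    hcn_tau_k: float = 12.0
    e_hcn: float = E_HCN_MV
    compartments: int = 1
    g_c: float = 2.5
    cm_dend: float = 10.0
    g_leak_dend: float = 0.3
    # spike mechanism (current clamp only)
    spike_threshold: float = -45.0
    spike_reset: float = -55.0
    spike_refractory_ms: float = 2.0
    # voltage clamp residual access resistance (after compensation)
    series_mohm: float = 2.0

    def __post_init__(self) -> None:
        if self.cm <= 0 or self.hcn_k <= 0:
            raise ValueError("cm and hcn_k must be positive")
        for g in (self.g_leak, self.g_hcn_max, self.g_c, self.g_leak_dend):
            if g < 0:
                raise ValueError("conductances must be non-negative")
        if self.compartments not in (1, 2):
            raise ValueError("compartments must be 1 or 2")


@dataclass
class SynapseSpec:
    """One spine's synaptic conductances (nS) and kinetics (ms).

    A silent spine has ``g_ampa == 0`` and ``g_nmda > 0``.  ``n_contacts``
    models multi-innervated spines: the conductances are per contact and
    are multiplied by the contact count at activation.
    """

    spine_id: str = "s0"
    g_ampa: float = 0.1
    g_nmda: float = 0.1
    ampa_rise: float = 0.2
    ampa_decay: float = 2.5
    nmda_rise: float = 3.0
    nmda_decay: float = 90.0
    e_syn: float = 0.0
    n_contacts: int = 1

    def __post_init__(self) -> None:
        if self.g_ampa < 0 or self.g_nmda < 0:
            raise ValueError("synaptic conductances must be non-negative")
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")

    @property
    def silent(self) -> bool:
        return self.g_ampa == 0.0 and self.g_nmda > 0.0


@dataclass
class StimulusSpec:
    """Protocol description; one spec expands to one or more sweeps."""

    kind: str
    params: dict = field(default_factory=dict)

    # -- constructors for the recording protocols ------------------------
    @classmethod
    def step_family(cls, amplitudes_pa, duration_s=0.5, pre_s=0.1, post_s=0.4,
                    holding_pa=0.0):
        """Square current steps (-125..+125 pA, 25 pA, 500 ms by default)."""
        return cls("step_family", dict(
            amplitudes=list(amplitudes_pa), duration=duration_s,
            pre=pre_s, post=post_s, holding=holding_pa))

    @classmethod
    def chirp(cls, f0_hz=0.2, f1_hz=20.0, amplitude_pa=50.0, duration_s=20.0,
              holding_pa=0.0):
        """Linear subthreshold chirp (0.2-20 Hz, 50 pA, 20 s)."""
        return cls("chirp", dict(f0=f0_hz, f1=f1_hz, amplitude=amplitude_pa,
                                 duration=duration_s, holding=holding_pa))

    @classmethod
    def vstep_family(cls, holding_mv=-50.0, v_min_mv=-120.0, dv_mv=-10.0,
                     duration_s=5.0, pre_s=0.5, post_s=0.5):
        """Voltage-clamp hyperpolarising steps from -50 mV (-10 mV, 5 s)."""
        steps = list(np.arange(holding_mv + dv_mv, v_min_mv + dv_mv / 2, dv_mv))
        return cls("vstep_family", dict(
            holding=holding_mv, steps=steps, duration=duration_s,
            pre=pre_s, post=post_s))

    @classmethod
    def uncaging(cls, schedule, duration_s, holding=0.0):
        """Uncaging schedule: list of (spine_index, time_s) pairs."""
        return cls("uncaging", dict(schedule=list(schedule),
                                    duration=duration_s, holding=holding))

    @classmethod
    def train(cls, freq_hz, n_stim=5, start_s=0.1, duration_s=None,
              holding=0.0):
        """Stimulus train activating all synapses at each pulse time."""
        if duration_s is None:
            duration_s = start_s + n_stim / freq_hz + 0.3
        return cls("train", dict(freq=freq_hz, n_stim=n_stim, start=start_s,
                                 duration=duration_s, holding=holding))


def apply_drug(params: NeuronParams, drug: str, *, block: float = 1.0,
               forskolin_shift_mv: float = 6.0) -> NeuronParams:
    """Return params under a pharmacological manipulation.

    ``"ZD"`` (ZD-7288, 20 uM) scales the maximal HCN conductance by
    (1 - block), default full block.  ``"forskolin"`` (50 uM) shifts the
    HCN half-activation depolarised by ``forskolin_shift_mv`` (the default
    +6 mV normalises the knockout activation curve onto the wild-type one;
    the cAMP->V1/2 mapping is a free parameter of the model).
    """
    if drug == "ZD":
        return replace(params, g_hcn_max=params.g_hcn_max * (1.0 - block))
    if drug == "forskolin":
        return replace(params, hcn_v12=params.hcn_v12 + forskolin_shift_mv)
    raise ValueError(f"unknown drug {drug!r}")


# ---------------------------------------------------------------------------
# Integration kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _integrate(dt, n, istim, vcmd, is_vclamp,
               cm, gl, el, ghcn, v12, k, ehcn,
               tau_min, tau_max, tau_v12, tau_k,
               two_comp, cm_d, gl_d, gc,
               g_ampa_t, g_nmda_t, esyn, mgfac, mgslope,
               spikes_on, vthr, spike_shape, vreset, refr_steps,
               rs_mohm, v0):
    """Fixed-step integration; returns (recorded, vdend, spike_idx, status).

    ``recorded`` is soma voltage (mV) in current clamp or pipette current
    (pA) in voltage clamp.  status 0 = ok, 1 = unstable (|V| > 200 mV).
    """
    rec = np.empty(n)
    vd_out = np.empty(n if two_comp else 1)
    spk = np.empty(n // max(refr_steps, 1) + 1, dtype=np.int64)
    nspk = 0
    vs = v0
    vd = v0
    minf0 = 1.0 / (1.0 + math.exp((vs - v12) / k))
    m = minf0
    in_spike = -1
    refr_until = -1
    shape_len = spike_shape.shape[0]
    for i in range(n):
        # synaptic current on the synaptic compartment (dend if 2-comp)
        vloc = vd if two_comp else vs
        blk = 1.0 / (1.0 + mgfac * math.exp(-mgslope * vloc))
        isyn = g_ampa_t[i] * (vloc - esyn) + g_nmda_t[i] * blk * (vloc - esyn)

        minf = 1.0 / (1.0 + math.exp((vs - v12) / k))
        tau = tau_min + (tau_max - tau_min) / (
            1.0 + math.exp(-(vs - tau_v12) / tau_k))
        m = minf + (m - minf) * math.exp(-dt / tau)

        ihcn = ghcn * m * (vs - ehcn)

        if is_vclamp:
            ip = (vcmd[i] - vs) / rs_mohm * 1000.0  # mV/MOhm -> nA -> pA
            dv = (-gl * (vs - el) - ihcn + ip) * dt / cm
            if two_comp:
                dv += (-gc * (vs - vd)) * dt / cm
                dvd = (-gl_d * (vd - el) - isyn - gc * (vd - vs)) * dt / cm_d
                vd += dvd
            else:
                dv += (-isyn) * dt / cm
            vs += dv
            rec[i] = ip
        else:
            if in_spike >= 0:
                vs = spike_shape[in_spike]
                in_spike += 1
                if in_spike >= shape_len:
                    in_spike = -1
                    vs = vreset
                    refr_until = i + refr_steps
            else:
                dv = (-gl * (vs - el) - ihcn + istim[i]) * dt / cm
                if two_comp:
                    dv += (-gc * (vs - vd)) * dt / cm
                    dvd = (-gl_d * (vd - el) - isyn
                           - gc * (vd - vs)) * dt / cm_d
                    vd += dvd
                else:
                    dv += (-isyn) * dt / cm
                vs += dv
                if spikes_on and vs >= vthr and i > refr_until:
                    spk[nspk] = i
                    nspk += 1
                    in_spike = 0
            rec[i] = vs
        if two_comp:
            vd_out[i] = vd
        if abs(vs) > 200.0 or (two_comp and abs(vd) > 200.0):
            return rec, vd_out, spk[:nspk], 1
    return rec, vd_out, spk[:nspk], 0


def _spike_waveform(dt_ms: float, threshold: float, reset: float) -> np.ndarray:
    """Stereotyped AP shape pasted at threshold crossing: 0.35 ms rise to
    +35 mV (upstroke ~230 V/s, crossing 0 mV) then 1.0 ms fall to reset."""
    n_up = max(int(round(0.35 / dt_ms)), 2)
    n_down = max(int(round(1.0 / dt_ms)), 2)
    up = np.linspace(threshold, 35.0, n_up + 1)[1:]
    down = np.linspace(35.0, reset, n_down + 1)[1:]
    return np.concatenate([up, down])


def _syn_kernel(t_ms: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unit-peak bi-exponential conductance waveform."""
    if decay <= rise:
        raise ValueError("decay must exceed rise time constant")
    g = np.exp(-t_ms / decay) - np.exp(-t_ms / rise)
    tpk = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-tpk / decay) - np.exp(-tpk / rise)
    return g / peak


def _conductance_traces(n, dt_ms, synapses, events):
    """Summed AMPA and NMDA conductance traces for (syn_index, onset_s) events."""
    g_ampa = np.zeros(n)
    g_nmda = np.zeros(n)
    for idx, t_on in events:
        syn = synapses[idx]
        i0 = int(round(t_on * 1000.0 / dt_ms))
        if i0 >= n:
            continue
        span = n - i0
        t = np.arange(span) * dt_ms
        scale = syn.n_contacts
        if syn.g_ampa > 0:
            g_ampa[i0:] += syn.g_ampa * scale * _syn_kernel(
                t, syn.ampa_rise, syn.ampa_decay)
        if syn.g_nmda > 0:
            g_nmda[i0:] += syn.g_nmda * scale * _syn_kernel(
                t, syn.nmda_rise, syn.nmda_decay)
    return g_ampa, g_nmda


class UnstableIntegration(RuntimeError):
    pass


def _run_one(params, synapses, events, istim_or_vcmd, mode, dt_ms,
             holding, markers, rng, noise_sd, mg_mm, v0=None):
    n = len(istim_or_vcmd)
    g_ampa_t, g_nmda_t = _conductance_traces(n, dt_ms, synapses, events)
    is_vclamp = mode == VOLTAGE_CLAMP
    two_comp = params.compartments == 2
    if v0 is None:
        # start at the steady state of the initial command/bias so the
        # pre-stimulus baseline is flat
        v0 = (istim_or_vcmd[0] if is_vclamp
              else resting_potential(params, istim_or_vcmd[0]))
    shape = _spike_waveform(dt_ms, params.spike_threshold, params.spike_reset)
    refr_steps = int(round(params.spike_refractory_ms / dt_ms))
    zeros = np.zeros(0)
    rec, vd, spk_idx, status = _integrate(
        dt_ms, n,
        istim_or_vcmd if not is_vclamp else zeros,
        istim_or_vcmd if is_vclamp else zeros,
        is_vclamp,
        params.cm, params.g_leak, params.e_leak,
        params.g_hcn_max, params.hcn_v12, params.hcn_k, params.e_hcn,
        params.hcn_tau_min, params.hcn_tau_max,
        params.hcn_tau_v12, params.hcn_tau_k,
        two_comp, params.cm_dend, params.g_leak_dend, params.g_c,
        g_ampa_t, g_nmda_t, 0.0 if not synapses else synapses[0].e_syn,
        mg_mm * MG_SCALE, MG_SLOPE_PER_MV,
        not is_vclamp, params.spike_threshold, shape, params.spike_reset,
        refr_steps, params.series_mohm, float(v0))
    if status != 0:
        raise UnstableIntegration(
            f"voltage exceeded 200 mV (mode={mode}); check parameters")
    # decimate to the 20 kHz output rate
    step = max(int(round(1000.0 / OUTPUT_HZ / dt_ms)), 1)
    rec_out = rec[::step].copy()
    stim_out = istim_or_vcmd[::step].copy()
    if noise_sd and noise_sd > 0:
        rec_out = rec_out + rng.normal(0.0, noise_sd, len(rec_out))
    all_markers = list(markers)
    for si in spk_idx:
        all_markers.append(("spike", si * dt_ms / 1000.0))
    all_markers.sort(key=lambda x: x[1])
    return Sweep(dt=1.0 / OUTPUT_HZ, samples=rec_out, stimulus=stim_out,
                 mode=mode, markers=all_markers, holding=holding)


def simulate(params: NeuronParams,
             synapses: list[SynapseSpec],
             stim: StimulusSpec,
             mode: str = CURRENT_CLAMP,
             dt_ms: float = DT_MS_DEFAULT,
             seed: int | None = None,
             noise_sd: float | None = None,
             mg_mm: float = MG_MM) -> list[Sweep]:
    """Run one protocol and return its sweeps (20 kHz output).

    ``noise_sd`` is additive Gaussian noise on the recorded channel (mV in
    current clamp, pA in voltage clamp); default 0 (noiseless).  ``seed``
    controls the noise stream; identical inputs give bit-identical output.
    """
    if dt_ms > 0.05:
        raise ValueError("dt_ms must be <= 0.05 ms")
    rng = np.random.default_rng(seed)
    sweeps: list[Sweep] = []
    p = stim.params
    nps = lambda secs: int(round(secs * 1000.0 / dt_ms))

    if stim.kind == "step_family":
        for amp in p["amplitudes"]:
            n = nps(p["pre"] + p["duration"] + p["post"])
            i_arr = np.full(n, float(p["holding"]))
            i0, i1 = nps(p["pre"]), nps(p["pre"] + p["duration"])
            i_arr[i0:i1] += amp
            sweeps.append(_run_one(
                params, synapses, [], i_arr, CURRENT_CLAMP, dt_ms,
                p["holding"], [("step_on", p["pre"]),
                               ("step_off", p["pre"] + p["duration"])],
                rng, noise_sd, mg_mm))
    elif stim.kind == "chirp":
        n = nps(p["duration"])
        t = np.arange(n) * dt_ms / 1000.0
        f0, f1, T = p["f0"], p["f1"], p["duration"]
        i_arr = p["holding"] + p["amplitude"] * np.sin(
            2 * np.pi * (f0 * t + (f1 - f0) * t * t / (2 * T)))
        sweeps.append(_run_one(params, synapses, [], i_arr, CURRENT_CLAMP,
                               dt_ms, p["holding"], [], rng, noise_sd, mg_mm))
    elif stim.kind == "vstep_family":
        for v_step in p["steps"]:
            n = nps(p["pre"] + p["duration"] + p["post"])
            v_arr = np.full(n, float(p["holding"]))
            i0, i1 = nps(p["pre"]), nps(p["pre"] + p["duration"])
            v_arr[i0:i1] = v_step
            sweeps.append(_run_one(
                params, synapses, [], v_arr, VOLTAGE_CLAMP, dt_ms,
                p["holding"], [("step_on", p["pre"]),
                               ("step_off", p["pre"] + p["duration"])],
                rng, noise_sd, mg_mm))
    elif stim.kind == "uncaging":
        n = nps(p["duration"])
        if mode == VOLTAGE_CLAMP:
            arr = np.full(n, float(p["holding"]))
        else:
            arr = np.full(n, float(p["holding"]))
        events = [(idx, t_on) for idx, t_on in p["schedule"]]
        markers = [(f"uncage:{synapses[idx].spine_id}", t_on)
                   for idx, t_on in events]
        sweeps.append(_run_one(params, synapses, events, arr, mode, dt_ms,
                               p["holding"], markers, rng, noise_sd, mg_mm))
    elif stim.kind == "train":
        n = nps(p["duration"])
        arr = np.full(n, float(p["holding"]))
        times = [p["start"] + j / p["freq"] for j in range(p["n_stim"])]
        events = [(idx, t_on) for t_on in times
                  for idx in range(len(synapses))]
        markers = [("stim", t_on) for t_on in times]
        sweeps.append(_run_one(params, synapses, events, arr, mode, dt_ms,
                               p["holding"], markers, rng, noise_sd, mg_mm))
    else:
        raise ValueError(f"unknown stimulus kind {stim.kind!r}")
    return sweeps


def params_dict(params: NeuronParams) -> dict:
    return asdict(params)


def hcn_minf(v_mv: float, params: NeuronParams) -> float:
    return 1.0 / (1.0 + math.exp((v_mv - params.hcn_v12) / params.hcn_k))


def _g_dend_eff(params: NeuronParams) -> float:
    """Series combination of coupling and dendritic leak seen from the soma."""
    if params.compartments != 2:
        return 0.0
    return params.g_c * params.g_leak_dend / (params.g_c + params.g_leak_dend)


def resting_potential(params: NeuronParams, bias_pa: float = 0.0) -> float:
    """Steady-state somatic voltage under a constant bias current."""
    from scipy.optimize import brentq

    gd = _g_dend_eff(params)

    def net(v):
        i = -params.g_leak * (v - params.e_leak) + bias_pa
        i -= gd * (v - params.e_leak)
        i -= params.g_hcn_max * hcn_minf(v, params) * (v - params.e_hcn)
        return i

    return brentq(net, -150.0, 50.0)


def holding_bias_for(params: NeuronParams, v_target_mv: float) -> float:
    """Bias current (pA) holding the soma at ``v_target_mv`` at steady state."""
    i = (params.g_leak + _g_dend_eff(params)) * (v_target_mv - params.e_leak)
    i += params.g_hcn_max * hcn_minf(v_target_mv, params) * (
        v_target_mv - params.e_hcn)
    return i
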