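"""Current-clamp feature extraction: passive properties, excitability,
sag/rebound, and chirp resonance.

Conventions (fixed here, knobs where the protocol leaves them open):

* steady state of a 500-ms step = mean of its final 100 ms;
* sag peak = most negative voltage in the first 200 ms of the step, sag %
  = 100 * (peak - steady) / peak with both deflections measured from the
  pre-step baseline;
* rebound = peak post-release depolarisation (within 200 ms) relative to
  the pre-step baseline; the rebound slope is the least-squares slope of
  rebound against steady-state deflection across steps;
* AP onset = first sample with dV/dt > 20 V/s followed by a 0 mV crossing,
  2 ms refractory;
* impedance |Z(f)| = smoothed cross-spectral ratio restricted to the chirp
  band, Gaussian kernel in log-frequency (sigma = 0.05 decade); resonant
  frequency = argmax, Q = |Z(f_res)| / |Z(f_min)|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Sweep

AP_DVDT_MV_PER_MS = 20.0  # 20 V/s
AP_REFRACTORY_MS = 2.0


@dataclass
class APParams:
    time_s: float
    threshold_mv: float
    peak_mv: float
    amplitude_mv: float
    half_width_ms: float | None


@dataclass
class IntrinsicProfile:
    """Per-cell intrinsic feature summary."""

    r_input_mohm: float | None = None
    rheobase_pa: float | None = None
    rheobase_censored: bool = False
    fi_curve: dict[float, int] = field(default_factory=dict)
    sag_pct: float | None = None
    sag_per_step: dict[float, float] = field(default_factory=dict)
    rebound_slope: float | None = None
    f_res_hz: float | None = None
    q_factor: float | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _step_window(sweep: Sweep) -> tuple[int, int]:
    """Step on/off sample indices, from markers or the stimulus trace."""
    on = sweep.marker_times("step_on")
    off = sweep.marker_times("step_off")
    if on and off:
        return int(round(on[0] / sweep.dt)), int(round(off[0] / sweep.dt))
    stim = sweep.stimulus
    base = stim[0]
    dev = np.flatnonzero(np.abs(stim - base) > 1e-9)
    if dev.size == 0:
        raise ValueError("sweep has no stimulus step")
    return int(dev[0]), int(dev[-1]) + 1

def _step_amplitude(sweep: Sweep) -> float:
    i0, i1 = _step_window(sweep)
    return float(np.mean(sweep.stimulus[i0:i1]) - sweep.stimulus[0])


def _ms(sweep: Sweep, ms: float) -> int:
    return int(round(ms / 1000.0 / sweep.dt))


# ---------------------------------------------------------------------------
# action potentials
# ---------------------------------------------------------------------------

def detect_aps(sweep: Sweep,
               dvdt_thresh: float = AP_DVDT_MV_PER_MS,
               refractory_ms: float = AP_REFRACTORY_MS) -> list[APParams]:
    """Detect APs by the dV/dt-threshold-plus-overshoot criterion."""
    v = sweep.samples
    dt_ms = sweep.dt * 1000.0
    dvdt = np.diff(v) / dt_ms
    cand = np.flatnonzero(dvdt > dvdt_thresh)
    refr = max(int(round(refractory_ms / dt_ms)), 1)
    look = max(int(round(3.0 / dt_ms)), 2)  # overshoot window 3 ms
    out: list[APParams] = []
    last = -refr - 1
    for i in cand:
        if i <= last + refr:
            continue
        seg = v[i:i + look]
        if seg.size == 0 or seg.max() < 0.0:
            continue
        ipk = i + int(np.argmax(seg))
        thr = v[i]
        amp = v[ipk] - thr
        half = thr + amp / 2.0
        hw = None
        above = np.flatnonzero(v[i:min(ipk + look, len(v))] >= half)
        if above.size >= 2:
            hw = (above[-1] - above[0]) * dt_ms
        out.append(APParams(time_s=i * sweep.dt, threshold_mv=thr,
                            peak_mv=float(v[ipk]), amplitude_mv=float(amp),
                            half_width_ms=hw))
        last = ipk
    return out


# ---------------------------------------------------------------------------
# passive properties and excitability
# ---------------------------------------------------------------------------

def input_resistance(step_sweeps: list[Sweep],
                     steady_ms: float = 100.0) -> float:
    """Input resistance (MOhm) from the steady-state V-I relation of
    subthreshold hyperpolarising steps (least-squares slope).

    Sweeps containing APs are excluded; fewer than 2 usable steps raise.
    A single-step variant is supported via a one-point ratio when exactly
    one sweep is passed explicitly.
    """
    pts = []
    for sw in step_sweeps:
        amp = _step_amplitude(sw)
        if amp >= 0:
            continue
        if detect_aps(sw):
            continue
        i0, i1 = _step_window(sw)
        base = float(np.mean(sw.samples[:i0])) if i0 > 0 else sw.samples[0]
        steady = float(np.mean(sw.samples[i1 - _ms(sw, steady_ms):i1]))
        pts.append((amp, steady - base))
    if len(step_sweeps) == 1 and len(pts) == 1:
        di, dv = pts[0]
        return dv / di * 1000.0  # mV/pA -> MOhm
    if len(pts) < 2:
        raise ValueError(f"need >=2 usable hyperpolarising steps, got {len(pts)}")
    di = np.array([p[0] for p in pts])
    dv = np.array([p[1] for p in pts])
    slope = np.polyfit(di, dv, 1)[0]
    return float(slope * 1000.0)


def rheobase_and_fi(step_sweeps: list[Sweep]) -> tuple[float, bool, dict]:
    """Rheobase (smallest depolarising step evoking >=1 AP) and F-I curve.

    Returns (rheobase_pa, censored, fi_curve); censored=True means no step
    fired and the rheobase is reported at the largest amplitude tested.
    """
    fi: dict[float, int] = {}
    for sw in step_sweeps:
        amp = _step_amplitude(sw)
        if amp <= 0:
            continue
        i0, i1 = _step_window(sw)
        aps = [a for a in detect_aps(sw)
               if i0 * sw.dt <= a.time_s < i1 * sw.dt]
        fi[round(amp, 6)] = len(aps)
    if not fi:
        raise ValueError("no depolarising steps found")
    firing = sorted(a for a, n in fi.items() if n > 0)
    if firing:
        return firing[0], False, fi
    return max(fi), True, fi


# ---------------------------------------------------------------------------
# sag and rebound
# ---------------------------------------------------------------------------

def sag_and_rebound(step_sweeps: list[Sweep],
                    peak_window_ms: float = 200.0,
                    steady_ms: float = 100.0,
                    rebound_window_ms: float = 200.0,
                    baseline_ms: float = 100.0):
    """Sag percentage per hyperpolarising step and the rebound slope.

    Returns (sag_per_step, rebound_slope, pairs) where sag_per_step maps
    step amplitude (pA) to sag %, and pairs are the (steady-state
    deflection, rebound) points the slope is fitted to.  Depolarising
    steps are ignored; too-short steps raise.
    """
    sag_per_step: dict[float, float] = {}
    pairs: list[tuple[float, float]] = []
    for sw in step_sweeps:
        amp = _step_amplitude(sw)
        if amp >= 0:
            continue
        i0, i1 = _step_window(sw)
        if (i1 - i0) * sw.dt * 1000.0 < peak_window_ms + steady_ms:
            raise ValueError("step too short for sag windows")
        nb = _ms(sw, baseline_ms)
        base = float(np.mean(sw.samples[max(i0 - nb, 0):i0])) if i0 else sw.samples[0]
        peak_v = float(np.min(sw.samples[i0:i0 + _ms(sw, peak_window_ms)]))
        steady_v = float(np.mean(sw.samples[i1 - _ms(sw, steady_ms):i1]))
        peak_defl = peak_v - base      # negative
        steady_defl = steady_v - base  # negative
        if peak_defl >= 0:
            continue
        # passive charging still under way at the window edge can give a
        # slightly negative raw value; sag is floored at 0 by definition
        sag = max(100.0 * (peak_defl - steady_defl) / peak_defl, 0.0)
        sag_per_step[round(amp, 6)] = sag
        # rebound: peak depolarisation after release, relative to baseline
        ir = i1 + _ms(sw, rebound_window_ms)
        reb = float(np.max(sw.samples[i1:ir])) - base
        pairs.append((steady_defl, reb))
    if not sag_per_step:
        raise ValueError("no usable hyperpolarising steps")
    slope = None
    if len(pairs) >= 2:
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        slope = float(np.polyfit(x, y, 1)[0])
    return sag_per_step, slope, pairs


# ---------------------------------------------------------------------------
# chirp impedance
# ---------------------------------------------------------------------------

def _check_chirp(stimulus: np.ndarray, dt: float, f0: float, f1: float) -> None:
    """Spectral-occupancy check: most non-DC stimulus energy must lie in
    the analysed band, spread across it rather than concentrated."""
    spec = np.abs(np.fft.rfft(stimulus - np.mean(stimulus))) ** 2
    freqs = np.fft.rfftfreq(len(stimulus), dt)
    band = (freqs >= f0) & (freqs <= f1)
    total = spec[1:].sum()
    if total == 0 or spec[band].sum() / total < 0.7:
        raise ValueError("stimulus is not a chirp over the analysed band")
    # energy spread: at least half of 8 log-spaced sub-bands occupied
    edges = np.logspace(np.log10(f0), np.log10(f1), 9)
    occupied = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (freqs >= lo) & (freqs < hi)
        if spec[sel].sum() > 0.005 * total:
            occupied += 1
    if occupied < 4:
        raise ValueError("stimulus energy not spread across the chirp band")


def impedance_profile(sweep: Sweep, f_min: float = 0.2, f_max: float = 20.0,
                      sigma_decades: float = 0.05, pad_factor: int = 4):
    """Impedance magnitude profile from a subthreshold chirp sweep.

    Returns (freqs_hz, z_mohm, f_res_hz, q).  The estimate is the
    cross-spectral ratio |<V I*>| / <|I|^2> with Gaussian smoothing in
    log-frequency, which suppresses the onset transient that biases the
    raw FFT amplitude ratio.  Q is |Z(f_res)| / |Z(f_min)|, >= 1 by
    construction.
    """
    if sweep.mode != "current_clamp":
        raise ValueError("impedance profile requires a current-clamp sweep")
    v = sweep.samples - np.mean(sweep.samples)
    i = sweep.stimulus - np.mean(sweep.stimulus)
    _check_chirp(i, sweep.dt, f_min, f_max)
    n = pad_factor * len(v)
    vf = np.fft.rfft(v, n)
    if_ = np.fft.rfft(i, n)
    freqs = np.fft.rfftfreq(n, sweep.dt)
    sel = (freqs >= f_min) & (freqs <= f_max)
    num = vf[sel] * np.conj(if_[sel])
    den = np.abs(if_[sel]) ** 2
    fr = freqs[sel]
    logf = np.log10(fr)
    z = np.empty(len(fr))
    # Gaussian smoothing in log-frequency; truncated at 4 sigma for speed
    for j in range(len(fr)):
        lo = np.searchsorted(logf, logf[j] - 4 * sigma_decades)
        hi = np.searchsorted(logf, logf[j] + 4 * sigma_decades)
        w = np.exp(-0.5 * ((logf[lo:hi] - logf[j]) / sigma_decades) ** 2)
        z[j] = np.abs(np.sum(w * num[lo:hi])) / np.sum(w * den[lo:hi])
    z_mohm = z * 1000.0  # mV/pA -> GOhm -> MOhm x1000
    i_res = int(np.argmax(z_mohm))
    f_res = float(fr[i_res])
    q = float(z_mohm[i_res] / z_mohm[0])
    return fr, z_mohm, f_res, q


# ---------------------------------------------------------------------------
# per-cell profile
# ---------------------------------------------------------------------------

def intrinsic_profile(step_sweeps: list[Sweep],
                      chirp_sweep: Sweep | None = None,
                      sag_sweeps: list[Sweep] | None = None) -> IntrinsicProfile:
    """Convenience wrapper extracting the full intrinsic feature set."""
    prof = IntrinsicProfile()
    try:
        prof.r_input_mohm = input_resistance(step_sweeps)
    except ValueError:
        pass
    try:
        rheo, cens, fi = rheobase_and_fi(step_sweeps)
        prof.rheobase_pa, prof.rheobase_censored, prof.fi_curve = rheo, cens, fi
    except ValueError:
        pass
    try:
        sag, slope, _ = sag_and_rebound(sag_sweeps or step_sweeps)
        prof.sag_per_step = sag
        prof.sag_pct = sag[min(sag)]  # largest hyperpolarisation
        prof.rebound_slope = slope
    except ValueError:
        pass
    if chirp_sweep is not None:
        _, _, prof.f_res_hz, prof.q_factor = impedance_profile(chirp_sweep)
    return prof
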