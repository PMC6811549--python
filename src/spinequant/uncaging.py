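"""Single-spine uEPSC/uEPSP quantification, silent-spine classification,
NMDA/AMPA ratios, multi-spine summation and spike-threshold analysis.

Measurement windows follow the uncaging protocol: AMPA-receptor currents
are read over the first 10 ms after photolysis (0.5-ms average around the
extremum), NMDA-receptor currents as the 20-50 ms post-photolysis mean at
+40 mV, and uEPSP peaks over the 20 ms after the (first) photolysis
stimulus.  Spines are classified against a noise floor of 3x the SD of
the 5-ms pre-event baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .data import Sweep
from .intrinsic import detect_aps

NOISE_FLOOR_SD = 3.0
BASELINE_MS = 5.0


@dataclass
class SpineResult:
    spine_id: str
    ampa_amp_pa: float | None = None   # at -70 mV
    nmda_amp_pa: float | None = None   # at +40 mV
    uepsp_amp_mv: float | None = None
    distance_um: float | None = None
    call: str = "unclassified"         # responsive / silent / unresponsive
    ratio: float | None = None


@dataclass
class EnsembleResult:
    counts: list[int] = field(default_factory=list)
    observed_mv: list[float] = field(default_factory=list)
    expected_mv: list[float] = field(default_factory=list)
    normalized: list[float] = field(default_factory=list)
    ap_fired: list[bool] = field(default_factory=list)
    spines_to_ap: int | None = None
    ap_censored: bool = False
    normalized_slope: float | None = None
    linearity_slope: float | None = None


@dataclass
class TrainResult:
    frequency_hz: float
    p_spike: float
    n_trials: int


# ---------------------------------------------------------------------------
# amplitude measurement
# ---------------------------------------------------------------------------

def _window(sweep: Sweep, t0_s: float, ms0: float, ms1: float) -> np.ndarray:
    i0 = int(round((t0_s + ms0 / 1000.0) / sweep.dt))
    i1 = int(round((t0_s + ms1 / 1000.0) / sweep.dt))
    return sweep.samples[i0:i1]


def baseline_stats(sweep: Sweep, t_event_s: float,
                   baseline_ms: float = BASELINE_MS) -> tuple[float, float]:
    """Mean and SD of the pre-event baseline."""
    seg = _window(sweep, t_event_s, -baseline_ms, 0.0)
    if seg.size == 0:
        raise ValueError("no baseline available before the event marker")
    return float(np.mean(seg)), float(np.std(seg))


def measure_uepsc(sweep: Sweep, uncage_time_s: float,
                  receptor: str = "ampa",
                  peak_avg_ms: float = 0.5) -> float:
    """uEPSC amplitude (pA, magnitude) for one photolysis event.

    ``receptor="ampa"``: extremum within 0-10 ms post-event, averaged over
    a 0.5-ms window centred on it.  ``receptor="nmda"``: mean over
    20-50 ms post-event (after full AMPA-current decay).
    """
    if uncage_time_s + 0.010 >= sweep.duration:
        raise ValueError("event marker within 10 ms of sweep end")
    base, _ = baseline_stats(sweep, uncage_time_s)
    if receptor == "ampa":
        seg = _window(sweep, uncage_time_s, 0.0, 10.0)
        ipk = int(np.argmax(np.abs(seg - base)))
        half = max(int(round(peak_avg_ms / 1000.0 / sweep.dt / 2)), 1)
        lo = max(ipk - half, 0)
        peak = float(np.mean(seg[lo:ipk + half + 1]))
    elif receptor == "nmda":
        peak = float(np.mean(_window(sweep, uncage_time_s, 20.0, 50.0)))
    else:
        raise ValueError(f"unknown receptor {receptor!r}")
    return abs(peak - base)


def measure_uepsc_averaged(sweeps: list[Sweep], uncage_time_s: float,
                           receptor: str = "ampa") -> float:
    """Average >=1 repetitions sample-wise before measuring (the standard
    >=3-repetition protocol); repetition order does not matter."""
    if not sweeps:
        raise ValueError("no sweeps given")
    ref = sweeps[0]
    mean = np.mean([s.samples for s in sweeps], axis=0)
    avg = Sweep(dt=ref.dt, samples=mean, stimulus=ref.stimulus,
                mode=ref.mode, markers=list(ref.markers), holding=ref.holding)
    return measure_uepsc(avg, uncage_time_s, receptor=receptor)


def measure_uepsp(sweep: Sweep, onset_s: float,
                  window_ms: float = 20.0) -> float:
    """uEPSP peak amplitude (mV) over the 20 ms after photolysis onset."""
    base, _ = baseline_stats(sweep, onset_s)
    seg = _window(sweep, onset_s, 0.0, window_ms)
    return float(np.max(seg) - base)


# ---------------------------------------------------------------------------
# classification and ratios
# ---------------------------------------------------------------------------

def classify_spine(ampa_amp: float, nmda_amp: float, noise_sd: float,
                   floor_mult: float = NOISE_FLOOR_SD) -> str:
    """silent: no AMPA current but clear NMDA current; unresponsive spines
    (both below the noise floor) are excluded from ratio statistics."""
    floor = floor_mult * noise_sd
    if ampa_amp >= floor:
        return "responsive"
    if nmda_amp >= floor:
        return "silent"
    return "unresponsive"


def nmda_ampa_ratio(spines: list[SpineResult],
                    noise_sd: float | None = None,
                    floor_mult: float = NOISE_FLOOR_SD):
    """Per-spine NMDA/AMPA ratios plus the population regression slope.

    The population slope regresses NMDA on AMPA amplitude through the
    origin over responsive spines.  Spines with AMPA at/below the noise
    floor are excluded from per-spine ratios.  Returns
    (ratios: dict spine_id -> ratio, slope).
    """
    ratios: dict[str, float] = {}
    xs, ys = [], []
    floor = floor_mult * noise_sd if noise_sd is not None else 0.0
    for sp in spines:
        if sp.ampa_amp_pa is None or sp.nmda_amp_pa is None:
            continue
        if sp.call == "silent" or sp.call == "unresponsive":
            continue
        if sp.ampa_amp_pa <= floor:
            continue
        ratios[sp.spine_id] = sp.nmda_amp_pa / sp.ampa_amp_pa
        xs.append(sp.ampa_amp_pa)
        ys.append(sp.nmda_amp_pa)
    slope = None
    if xs:
        x = np.asarray(xs)
        y = np.asarray(ys)
        slope = float(np.sum(x * y) / np.sum(x * x))  # through origin
    return ratios, slope


# ---------------------------------------------------------------------------
# multi-spine summation
# ---------------------------------------------------------------------------

def _first_marker(sweep: Sweep, prefix: str = "uncage") -> float:
    times = [t for lab, t in sweep.markers if lab.startswith(prefix)]
    if not times:
        raise ValueError("ensemble sweep has no uncaging markers")
    return min(times)


def summation_analysis(ensemble_sweeps: dict[int, list[Sweep]],
                       single_uepsps_mv: list[float],
                       silent_flags: list[bool] | None = None,
                       window_ms: float = 20.0) -> EnsembleResult:
    """Near-simultaneous summation analysis.

    ``ensemble_sweeps`` maps spine count -> repetitions of the
    near-simultaneous sweep; ``single_uepsps_mv`` are the single-spine
    uEPSP amplitudes in uncaging order (used for the expected linear sum).
    Counts whose sweeps fire an AP are excluded from the slope fits (the
    AP truncates the subthreshold peak) but kept for spines-to-AP.

    Slopes: ``normalized_slope`` from regressing observed/first-uEPSP on
    spine count; ``linearity_slope`` from regressing observed on expected
    sum through the origin.
    """
    res = EnsembleResult()
    expected_cum = np.cumsum(single_uepsps_mv)
    for count in sorted(ensemble_sweeps):
        reps = ensemble_sweeps[count]
        fired = any(detect_aps(sw) for sw in reps)
        sub = [sw for sw in reps if not detect_aps(sw)]
        obs = None
        if sub:
            onset = _first_marker(sub[0])
            mean = np.mean([s.samples for s in sub], axis=0)
            avg = Sweep(dt=sub[0].dt, samples=mean, stimulus=sub[0].stimulus,
                        mode=sub[0].mode, markers=list(sub[0].markers),
                        holding=sub[0].holding)
            obs = measure_uepsp(avg, onset, window_ms)
        res.counts.append(count)
        res.ap_fired.append(fired)
        res.observed_mv.append(obs if obs is not None else np.nan)
        res.expected_mv.append(float(expected_cum[count - 1])
                               if count <= len(expected_cum) else np.nan)
    first = None
    for c, o in zip(res.counts, res.observed_mv):
        if c == 1 and np.isfinite(o):
            first = o
    res.normalized = [o / first if first else np.nan for o in res.observed_mv]
    fired_counts = [c for c, f in zip(res.counts, res.ap_fired) if f]
    if fired_counts:
        res.spines_to_ap = min(fired_counts)
    else:
        res.spines_to_ap = max(res.counts) if res.counts else None
        res.ap_censored = True
    # slope fits over subthreshold, finite points
    ok = [i for i, (f, o) in enumerate(zip(res.ap_fired, res.observed_mv))
          if not f and np.isfinite(o)]
    if len(ok) >= 2 and first:
        cnt = np.array([res.counts[i] for i in ok], dtype=float)
        nrm = np.array([res.normalized[i] for i in ok])
        res.normalized_slope = float(np.polyfit(cnt, nrm, 1)[0])
        exp = np.array([res.expected_mv[i] for i in ok])
        obs = np.array([res.observed_mv[i] for i in ok])
        fin = np.isfinite(exp)
        if fin.sum() >= 2 and np.sum(exp[fin] ** 2) > 0:
            res.linearity_slope = float(
                np.sum(exp[fin] * obs[fin]) / np.sum(exp[fin] ** 2))
    return res


# ---------------------------------------------------------------------------
# EPSP decay vs summation
# ---------------------------------------------------------------------------

def fit_epsp_decay(sweep: Sweep, onset_s: float,
                   window_ms: float = 20.0,
                   fit_ms: float = 150.0) -> tuple[float, float]:
    """Single-exponential decay constant (ms) fitted from the EPSP peak
    back to baseline.  Returns (tau_ms, r_squared)."""
    base, _ = baseline_stats(sweep, onset_s)
    i_on = int(round(onset_s / sweep.dt))
    npk = int(round(window_ms / 1000.0 / sweep.dt))
    seg = sweep.samples[i_on:i_on + npk]
    ipk = i_on + int(np.argmax(seg))
    nfit = int(round(fit_ms / 1000.0 / sweep.dt))
    tail = sweep.samples[ipk:ipk + nfit] - base
    t = np.arange(len(tail)) * sweep.dt * 1000.0
    a0 = max(tail[0], 1e-9)

    def model(t, a, tau):
        return a * np.exp(-t / tau)

    popt, _ = curve_fit(model, t, tail, p0=[a0, 30.0],
                        bounds=([0.0, 0.1], [np.inf, 5000.0]), maxfev=10000)
    resid = tail - model(t, *popt)
    ss_tot = float(np.sum((tail - tail.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return float(popt[1]), r2


def decay_vs_summation(ensemble_sweeps: dict[int, list[Sweep]],
                       normalized: dict[int, float],
                       r2_floor: float = 0.5):
    """Per-count EPSP decay constants and the log-linear trend.

    Returns (decays: dict count -> (tau_ms, flagged), trend_slope) where
    the trend is the least-squares slope of log(tau) on the normalized
    summation.  Points with fit R^2 below ``r2_floor`` are flagged and
    excluded from the trend.
    """
    decays: dict[int, tuple[float, bool]] = {}
    xs, ys = [], []
    for count, reps in sorted(ensemble_sweeps.items()):
        sub = [sw for sw in reps if not detect_aps(sw)]
        if not sub:
            continue
        onset = _first_marker(sub[0])
        mean = np.mean([s.samples for s in sub], axis=0)
        avg = Sweep(dt=sub[0].dt, samples=mean, stimulus=sub[0].stimulus,
                    mode=sub[0].mode, markers=list(sub[0].markers),
                    holding=sub[0].holding)
        tau, r2 = fit_epsp_decay(avg, onset)
        flagged = r2 < r2_floor
        decays[count] = (tau, flagged)
        if not flagged and count in normalized and np.isfinite(normalized[count]):
            xs.append(normalized[count])
            ys.append(np.log(tau))
    trend = float(np.polyfit(xs, ys, 1)[0]) if len(xs) >= 2 else None
    return decays, trend


# ---------------------------------------------------------------------------
# afferent train spike probability
# ---------------------------------------------------------------------------

def train_spike_probability(trial_sweeps: list[Sweep],
                            frequency_hz: float,
                            expected_trials: int = 10) -> TrainResult:
    """P_spike = fraction of trials with >=1 AP during the train window."""
    import warnings

    if len(trial_sweeps) < expected_trials:
        warnings.warn(
            f"only {len(trial_sweeps)} trials (expected {expected_trials}); "
            "P_spike computed on available trials", stacklevel=2)
    n_spk = 0
    for sw in trial_sweeps:
        stim_times = [t for lab, t in sw.markers if lab == "stim"]
        t0 = min(stim_times) if stim_times else 0.0
        t1 = (max(stim_times) + 0.2) if stim_times else sw.duration
        aps = [a for a in detect_aps(sw) if t0 <= a.time_s <= t1]
        if aps:
            n_spk += 1
    return TrainResult(frequency_hz=frequency_hz,
                       p_spike=n_spk / len(trial_sweeps) if trial_sweeps else 0.0,
                       n_trials=len(trial_sweeps))
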