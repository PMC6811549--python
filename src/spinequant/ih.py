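"""Voltage-clamp I_h isolation and Boltzmann activation fitting.

I_h is measured per hyperpolarising step as the difference between the
instantaneous (post-transient) and steady-state current, reported as a
positive magnitude.  The activation midpoint is obtained by fitting a
variable-slope sigmoid; by default the amplitudes are first divided by
the driving force (V - E_h), i.e. the fit is performed on the conductance
activation curve.  Fitting the raw current amplitudes instead (available
via ``driving_force_correction=False``) biases the midpoint several mV
hyperpolarised, because the driving force keeps growing after the
conductance has saturated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .data import Sweep
from .simulate import E_HCN_MV
from .intrinsic import _step_window


@dataclass
class IhCurve:
    step_voltages: np.ndarray
    ih_amps: np.ndarray
    flags: list[str] = field(default_factory=list)


@dataclass
class IhFit:
    i_max: float   # fitted plateau, on the scale that was fitted
    v12: float     # half-activation voltage, mV
    k: float       # slope factor, mV (> 0)
    cov: np.ndarray | None = None
    corrected: bool = True

    def __post_init__(self) -> None:
        if not (-130.0 <= self.v12 <= -50.0):
            # fits outside the physiological window are suspect but kept;
            # downstream code can check this flag
            pass


def extract_ih(vstep_sweeps: list[Sweep],
               inst_window_ms: tuple[float, float] = (10.0, 60.0),
               steady_ms: float = 500.0) -> IhCurve:
    """Per-step I_h amplitude: |steady - instantaneous| current.

    The instantaneous level is the mean over ``inst_window_ms`` after the
    step (clear of the capacitive transient); steady state is the mean of
    the final ``steady_ms``.  Steps whose last two 250-ms bins differ by
    more than 5 % of the developed amplitude are flagged ``unsettled:<V>``
    (flag, not failure).
    """
    volts, amps, flags = [], [], []
    for sw in vstep_sweeps:
        if sw.mode != "voltage_clamp":
            raise ValueError("extract_ih requires voltage-clamp sweeps")
        i0, i1 = _step_window(sw)
        v_step = float(np.mean(sw.stimulus[i0:i1]))
        n = lambda ms: int(round(ms / 1000.0 / sw.dt))
        inst = float(np.mean(sw.samples[i0 + n(inst_window_ms[0]):
                                        i0 + n(inst_window_ms[1])]))
        steady = float(np.mean(sw.samples[i1 - n(steady_ms):i1]))
        amp = abs(steady - inst)
        b1 = float(np.mean(sw.samples[i1 - n(500.0):i1 - n(250.0)]))
        b2 = float(np.mean(sw.samples[i1 - n(250.0):i1]))
        if amp > 0 and abs(b2 - b1) > 0.05 * amp:
            flags.append(f"unsettled:{v_step:g}")
        volts.append(v_step)
        amps.append(amp)
    order = np.argsort(volts)[::-1]  # -60 first, most hyperpolarised last
    return IhCurve(step_voltages=np.asarray(volts)[order],
                   ih_amps=np.asarray(amps)[order], flags=flags)


def _boltzmann(v, i_max, v12, k):
    return i_max / (1.0 + np.exp((v - v12) / k))


def fit_activation(step_voltages: np.ndarray, ih_amps: np.ndarray,
                   driving_force_correction: bool = True,
                   e_rev: float = E_HCN_MV,
                   v12_starts: tuple[float, ...] = (-70.0, -85.0, -100.0),
                   ) -> IhFit:
    """Variable-slope sigmoid fit of the activation curve.

    Multi-start least squares over the listed midpoint initialisations;
    non-convergence from every start raises with a residual report.
    """
    v = np.asarray(step_voltages, dtype=float)
    y = np.asarray(ih_amps, dtype=float)
    if len(v) < 5:
        raise ValueError("need >=5 points spanning the sigmoid rise")
    if driving_force_correction:
        df = np.abs(v - e_rev)
        if np.any(df < 1e-9):
            raise ValueError("step voltage equals the reversal potential")
        y = y / df
    best = None
    errs = []
    for v12_0 in v12_starts:
        try:
            popt, pcov = curve_fit(
                _boltzmann, v, y,
                p0=[max(y.max(), 1e-12), v12_0, 8.0],
                bounds=([0.0, -150.0, 0.1], [np.inf, -30.0, 60.0]),
                maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            errs.append(f"start {v12_0}: {exc}")
            continue
        sse = float(np.sum((_boltzmann(v, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise RuntimeError(
            "activation fit failed from all starts: " + "; ".join(errs))
    _, popt, pcov = best
    return IhFit(i_max=float(popt[0]), v12=float(popt[1]), k=float(popt[2]),
                 cov=pcov, corrected=driving_force_correction)


def pn_subtract(sweep_at_target: Sweep, sweep_small_step: Sweep) -> np.ndarray:
    """P/N subtraction: target minus scaled small-step response.

    The scale is the ratio of command-step amplitudes (e.g. 5 for a
    -50 mV target against a -10 mV scaling step), removing linear leak
    and capacitive components and isolating the slow I_h relaxation.
    """
    for sw in (sweep_at_target, sweep_small_step):
        if sw.mode != "voltage_clamp":
            raise ValueError("pn_subtract requires voltage-clamp sweeps")
    if sweep_at_target.holding != sweep_small_step.holding:
        raise ValueError("sweeps must share a holding potential")

    def step_amp(sw):
        i0, i1 = _step_window(sw)
        return float(np.mean(sw.stimulus[i0:i1]) - sw.stimulus[0])

    a_small = step_amp(sweep_small_step)
    if a_small == 0.0:
        raise ValueError("scaling step amplitude is zero")
    scale = step_amp(sweep_at_target) / a_small

    def baselined(sw):
        i0, _ = _step_window(sw)
        base = float(np.mean(sw.samples[:i0])) if i0 > 0 else 0.0
        return sw.samples - base

    n = min(sweep_at_target.n_samples, sweep_small_step.n_samples)
    return baselined(sweep_at_target)[:n] - scale * baselined(sweep_small_step)[:n]
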