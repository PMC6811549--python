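"""Linearised resonant membrane: an R-C membrane in parallel with a
phenomenological inductive branch (R_L in series with L), the standard
small-signal equivalent of a slow hyperpolarisation-activated conductance.

Closed-form impedance:

    Z(w) = 1 / ( 1/R + j w C + 1/(R_L + j w L) )

``design_resonant_membrane`` solves for L so the impedance magnitude
peaks at a requested frequency, giving an analytic ground truth against
which the chirp + FFT impedance pipeline can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import brentq

from .data import Sweep


@dataclass
class ResonantMembrane:
    r_ohm: float
    c_farad: float
    rl_ohm: float
    l_henry: float

    def impedance(self, f_hz: np.ndarray) -> np.ndarray:
        """Complex impedance (Ohm) at the given frequencies."""
        w = 2 * np.pi * np.asarray(f_hz, dtype=float)
        return 1.0 / (1.0 / self.r_ohm + 1j * w * self.c_farad
                      + 1.0 / (self.rl_ohm + 1j * w * self.l_henry))

    def peak_frequency(self, f_lo: float = 0.05, f_hi: float = 40.0,
                       n: int = 40001) -> float:
        f = np.logspace(np.log10(f_lo), np.log10(f_hi), n)
        return float(f[np.argmax(np.abs(self.impedance(f)))])


def design_resonant_membrane(f_res_hz: float,
                             r_mohm: float = 250.0,
                             c_pf: float = 400.0,
                             rl_mohm: float | None = None) -> ResonantMembrane:
    """Choose the branch inductance so |Z| peaks at ``f_res_hz``.

    The peak frequency is monotone decreasing in the branch time constant
    L/R_L over the useful range; the root is bracketed by a log-spaced
    scan and polished with Brent's method.
    """
    R = r_mohm * 1e6
    C = c_pf * 1e-12
    RL = (rl_mohm * 1e6) if rl_mohm is not None else R

    def gap(tau):
        return ResonantMembrane(R, C, RL, RL * tau).peak_frequency() - f_res_hz

    taus = np.logspace(-3, 2.5, 120)
    vals = np.array([gap(t) for t in taus])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if sign_change.size == 0:
        raise ValueError(
            f"no branch time constant places the peak at {f_res_hz} Hz "
            f"for R={r_mohm} MOhm, C={c_pf} pF")
    i = sign_change[-1]
    tau = brentq(gap, taus[i], taus[i + 1], xtol=1e-9)
    return ResonantMembrane(R, C, RL, RL * tau)


def simulate_chirp(membrane: ResonantMembrane,
                   f0_hz: float = 0.2, f1_hz: float = 20.0,
                   amplitude_pa: float = 50.0, duration_s: float = 20.0,
                   fs_hz: float = 20_000.0,
                   v_rest_mv: float = -60.0) -> Sweep:
    """Simulate the chirp protocol on the linear membrane (exact linear
    state-space integration) and return a current-clamp sweep."""
    R, C, RL, L = (membrane.r_ohm, membrane.c_farad,
                   membrane.rl_ohm, membrane.l_henry)
    A = np.array([[-1.0 / (R * C), -1.0 / C], [1.0 / L, -RL / L]])
    B = np.array([[1.0 / C], [0.0]])
    sys = signal.StateSpace(A, B, np.array([[1.0, 0.0]]), np.array([[0.0]]))
    t = np.arange(0.0, duration_s, 1.0 / fs_hz)
    i_amp = amplitude_pa * 1e-12
    i_t = i_amp * np.sin(2 * np.pi * (f0_hz * t
                                      + (f1_hz - f0_hz) * t * t / (2 * duration_s)))
    _, v, _ = signal.lsim(sys, i_t, t)
    return Sweep(dt=1.0 / fs_hz,
                 samples=v * 1e3 + v_rest_mv,       # V -> mV around rest
                 stimulus=i_t * 1e12,               # A -> pA
                 mode="current_clamp",
                 holding=v_rest_mv)
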