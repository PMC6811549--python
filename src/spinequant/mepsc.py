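"""Moving-template miniature-EPSC detection and event statistics.

The detector slides a template event across the sweep; at each offset it
least-squares fits scale and offset of the template and scores the fit as
scale / SD(residual) (the classic sliding-template criterion).  Candidate
events exceeding the criterion threshold (default 3) are then filtered by
an amplitude floor of 3x the SD of the 5-ms preceding baseline and a
refractory minimum inter-event interval (7.5 ms at -70 mV, 25 ms at
+40 mV), keeping the higher-criterion event of any conflicting pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .data import Sweep

CRITERION_DEFAULT = 3.0
AMPLITUDE_FLOOR_SD = 3.0
BASELINE_MS = 5.0
REFRACTORY_NEG_MS = 7.5   # events at -70 mV
REFRACTORY_POS_MS = 25.0  # events at +40 mV


@dataclass
class EventTemplate:
    """Tri-exponential event shape: rise * weighted double-exp decay.

    T(t) = (1 - exp(-t/rise)) * (w*exp(-t/decay1) + (1-w)*exp(-t/decay2)),
    normalised to unit peak and signed by ``polarity`` (-1 for inward
    currents at -70 mV, +1 for outward at +40 mV).
    """

    rise_ms: float = 0.5
    decay1_ms: float = 4.0
    decay2_ms: float = 12.0
    w1: float = 0.8
    duration_ms: float = 30.0
    polarity: int = -1

    def __post_init__(self) -> None:
        if not (self.rise_ms < self.decay1_ms < self.decay2_ms):
            raise ValueError("require rise < decay1 < decay2")
        if not (0.0 <= self.w1 <= 1.0):
            raise ValueError("w1 must lie in [0, 1]")

    def waveform(self, dt_s: float) -> np.ndarray:
        t = np.arange(0.0, self.duration_ms, dt_s * 1000.0)
        shape = _tri_exp(t, self.rise_ms, self.decay1_ms, self.decay2_ms,
                         self.w1)
        return self.polarity * shape / np.max(shape)


@dataclass
class EventList:
    times_s: np.ndarray
    amplitudes_pa: np.ndarray
    scores: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times_s)


def _tri_exp(t_ms, rise, d1, d2, w):
    return (1.0 - np.exp(-t_ms / rise)) * (
        w * np.exp(-t_ms / d1) + (1.0 - w) * np.exp(-t_ms / d2))


DEFAULT_NEG = EventTemplate()
DEFAULT_POS = EventTemplate(rise_ms=1.5, decay1_ms=20.0, decay2_ms=60.0,
                            w1=0.7, duration_ms=120.0, polarity=+1)


def build_template(exemplars: list[np.ndarray], dt_s: float,
                   polarity: int = -1,
                   duration_ms: float | None = None) -> EventTemplate:
    """Fit the tri-exponential to the mean of >=5 aligned exemplar events.

    Falls back to the configured default kinetics (with a warning) if the
    fit diverges.  Single-exponential exemplars are handled by the w -> 1
    limit of the nested model.
    """
    if len(exemplars) < 5:
        raise ValueError("need >=5 aligned exemplar events")
    n = min(len(e) for e in exemplars)
    mean = np.mean([np.asarray(e[:n], dtype=float) for e in exemplars], axis=0)
    mean = mean - mean[0]
    y = polarity * mean
    peak = np.max(np.abs(y))
    if peak <= 0:
        raise ValueError("exemplars have zero amplitude")
    y = y / peak
    t = np.arange(n) * dt_s * 1000.0
    dur = duration_ms if duration_ms is not None else t[-1]

    def model(t, rise, d1, d2, w, a):
        return a * _tri_exp(t, rise, d1, d2, w)

    best = None
    for p0 in ([0.5, 3.0, 12.0, 0.8, 1.0], [1.0, 8.0, 40.0, 0.6, 1.0]):
        try:
            popt, _ = curve_fit(
                model, t, y, p0=p0,
                bounds=([0.05, 0.1, 0.2, 0.0, 0.0],
                        [20.0, 200.0, 1000.0, 1.0, 10.0]),
                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        warnings.warn("template fit diverged; using default kinetics",
                      stacklevel=2)
        return EventTemplate(polarity=polarity) if polarity < 0 else DEFAULT_POS
    rise, d1, d2, w, _ = best[1]
    if d1 > d2:  # enforce the tau ordering by swapping the labelled pair
        d1, d2, w = d2, d1, 1.0 - w
    d1 = max(d1, rise * 1.001)
    d2 = max(d2, d1 * 1.001)
    return EventTemplate(rise_ms=float(rise), decay1_ms=float(d1),
                         decay2_ms=float(d2), w1=float(w),
                         duration_ms=float(dur), polarity=polarity)


def _sliding_fit(y: np.ndarray, tpl: np.ndarray):
    """Vectorised sliding least-squares scale/offset template fit.

    Returns (scale, criterion) arrays of length len(y) - len(tpl) + 1.
    """
    from scipy.signal import oaconvolve

    n = len(tpl)
    sum_t = float(np.sum(tpl))
    sum_t2 = float(np.sum(tpl * tpl))
    ones = np.ones(n)
    sum_y = oaconvolve(y, ones, mode="valid")
    sum_y2 = oaconvolve(y * y, ones, mode="valid")
    sum_ty = oaconvolve(y, tpl[::-1], mode="valid")
    denom = n * sum_t2 - sum_t ** 2
    scale = (n * sum_ty - sum_t * sum_y) / denom
    offset = (sum_y - scale * sum_t) / n
    sse = (sum_y2 + scale ** 2 * sum_t2 + n * offset ** 2
           - 2.0 * scale * sum_ty - 2.0 * offset * sum_y
           + 2.0 * scale * offset * sum_t)
    sse = np.maximum(sse, 0.0)
    sd = np.sqrt(sse / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = np.where(sd > 0, scale / sd, 0.0)
    return scale, crit


def detect_events(sweep: Sweep, template: EventTemplate | None = None,
                  criterion_threshold: float = CRITERION_DEFAULT,
                  refractory_ms: float | None = None,
                  amplitude_floor_sd: float = AMPLITUDE_FLOOR_SD) -> EventList:
    """Moving-template event detection on a voltage-clamp sweep."""
    if template is None:
        template = DEFAULT_NEG if sweep.holding < 0 else DEFAULT_POS
    if refractory_ms is None:
        refractory_ms = (REFRACTORY_NEG_MS if template.polarity < 0
                         else REFRACTORY_POS_MS)
    tpl = template.waveform(sweep.dt)
    y = sweep.samples
    if len(tpl) > len(y):
        raise ValueError("template longer than sweep")
    scale, crit = _sliding_fit(y, tpl)
    above = crit > criterion_threshold
    # candidate = local criterion maximum within each contiguous run
    cands: list[int] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            cands.append(i + int(np.argmax(crit[i:j])))
            i = j
        else:
            i += 1
    nb = int(round(BASELINE_MS / 1000.0 / sweep.dt))
    kept: list[tuple[int, float, float]] = []
    for idx in cands:
        amp = abs(scale[idx])  # template has unit peak
        b0 = max(idx - nb, 0)
        if idx - b0 < 2:
            continue
        base_sd = float(np.std(y[b0:idx]))
        if amp <= amplitude_floor_sd * base_sd:
            continue
        kept.append((idx, amp, float(crit[idx])))
    # refractory: greedy by criterion, suppress closer events
    refr = refractory_ms / 1000.0
    kept.sort(key=lambda e: -e[2])
    final: list[tuple[int, float, float]] = []
    for idx, amp, c in kept:
        t = idx * sweep.dt
        if all(abs(t - f[0] * sweep.dt) >= refr for f in final):
            final.append((idx, amp, c))
    final.sort(key=lambda e: e[0])
    return EventList(
        times_s=np.array([f[0] * sweep.dt for f in final]),
        amplitudes_pa=np.array([f[1] for f in final]),
        scores=np.array([f[2] for f in final]),
        meta=dict(criterion_threshold=criterion_threshold,
                  refractory_ms=refractory_ms,
                  amplitude_floor_sd=amplitude_floor_sd,
                  template=template.__dict__.copy()))


def event_stats(events: EventList, duration_s: float):
    """Amplitude mean/median (pA) and frequency (Hz).

    Zero events give frequency 0 and missing (None) amplitude summaries.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    freq = len(events) / duration_s
    if len(events) == 0:
        return dict(n=0, frequency_hz=0.0, amp_mean_pa=None,
                    amp_median_pa=None)
    return dict(n=len(events), frequency_hz=freq,
                amp_mean_pa=float(np.mean(events.amplitudes_pa)),
                amp_median_pa=float(np.median(events.amplitudes_pa)))
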