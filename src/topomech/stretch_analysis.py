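"""Analysis of optical-trap DNA stretching traces.

Covers both acquisition modes of the stretching assay: constant-velocity
pulling (loop-rupture force peaks, loop sizes, compaction extension at a
reference force, tether breakage force) and constant-force clamping
(tether-survival kinetics with a double-exponential fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import brentq, curve_fit
from scipy.signal import find_peaks

from .polymer_mechanics import (
    DsDnaElasticity,
    ForceExtensionTrace,
    contour_length_from_point,
)

__all__ = [
    "RuptureEvent",
    "SurvivalModel",
    "decimate_and_filter",
    "detect_ruptures",
    "loop_size_of_event",
    "extension_at_reference_force",
    "tether_breakage_force",
    "fit_survival",
    "kaplan_meier",
]

#: force-peak selection bounds, pN: peaks must rise above 1 pN and stay at
#: or below 60 pN to exclude the overstretching transition
MIN_PEAK_FORCE_PN = 1.0
MAX_PEAK_FORCE_PN = 60.0


@dataclass
class RuptureEvent:
    """A single loop-disruption force peak in a constant-velocity trace."""

    peak_index: int
    peak_time: float  # s
    peak_force: float  # pN
    released_bp: float | None = None
    contour_before: float | None = None  # bp
    contour_after: float | None = None  # bp
    truncated: bool = False  # post-event window cut short (tether break)


@dataclass
class SurvivalModel:
    """Double-exponential tether survival S(t) = a1 e^{-t/tau1} + a2 e^{-t/tau2}."""

    amplitude_1: float
    tau_1: float  # s
    amplitude_2: float
    tau_2: float  # s
    t_half: float  # s
    covariance: np.ndarray | None = field(default=None, repr=False)

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        return (self.amplitude_1 * np.exp(-t / self.tau_1)
                + self.amplitude_2 * np.exp(-t / self.tau_2))


def decimate_and_filter(trace: ForceExtensionTrace, target_rate: float = 1000.0,
                        window: float = 0.025) -> ForceExtensionTrace:
    """Block-average to ``target_rate`` then boxcar-smooth over ``window``.

    Mirrors the instrument pipeline: acquisition at 10 kHz decimated by
    averaging to 1 kHz, then a 25 ms sliding-window low-pass before peak
    detection.  Trailing samples that do not fill a block are dropped.
    """
    if trace.acquisition_rate < target_rate:
        raise ValueError("acquisition_rate below target_rate")
    factor = int(round(trace.acquisition_rate / target_rate))
    n = (len(trace) // factor) * factor

    def block(x):
        return x[:n].reshape(-1, factor).mean(axis=1)

    time = block(trace.time)
    force = block(trace.force)
    ext = block(trace.extension)
    n_win = int(round(window * target_rate))
    if n_win < 2:
        raise ValueError("smoothing window shorter than 2 samples")
    force = uniform_filter1d(force, n_win, mode="nearest")
    ext = uniform_filter1d(ext, n_win, mode="nearest")
    return ForceExtensionTrace(time, force, ext, target_rate,
                               metadata=dict(trace.metadata, filtered=True))


def detect_ruptures(trace: ForceExtensionTrace,
                    min_peak_force: float = MIN_PEAK_FORCE_PN,
                    max_peak_force: float = MAX_PEAK_FORCE_PN,
                    min_drop: float = 1.0,
                    drop_window: float = 0.100,
                    min_extension_gain: float = 10.0) -> list[RuptureEvent]:
    """Identify loop-disruption force peaks in a filtered trace.

    A rupture is a local force maximum above ``min_peak_force`` (measured
    as prominence over the local pre-peak minimum) and at most
    ``max_peak_force``, followed within ``drop_window`` seconds by a
    force drop of at least ``min_drop`` pN together with an extension
    gain of at least ``min_extension_gain`` nm.  Events are returned in
    time order.
    """
    n_win = int(round(drop_window * trace.acquisition_rate))
    if len(trace) <= n_win or n_win < 1:
        raise ValueError("trace shorter than the detection window")
    force = trace.force
    peaks, _ = find_peaks(force, prominence=min_drop, distance=max(1, n_win // 2))
    events: list[RuptureEvent] = []
    for p in peaks:
        fp = force[p]
        if not (fp > min_peak_force and fp <= max_peak_force):
            continue
        stop = min(len(force), p + 1 + n_win)
        seg = force[p + 1:stop]
        if len(seg) == 0 or fp - np.min(seg) < min_drop:
            continue
        trough = p + 1 + int(np.argmin(seg))
        if trace.extension[trough] - trace.extension[p] < min_extension_gain:
            continue
        events.append(RuptureEvent(peak_index=int(p),
                                   peak_time=float(trace.time[p]),
                                   peak_force=float(fp)))
    return events


def loop_size_of_event(trace: ForceExtensionTrace, event: RuptureEvent,
                       elasticity: DsDnaElasticity = DsDnaElasticity(),
                       window: float = 0.050,
                       guard: float = 0.030) -> RuptureEvent:
    """Loop size (bp released) of one rupture event.

    The contour length is computed pointwise from (force, extension)
    over a ``window`` on each side of the peak, excluding ``guard``
    around the drop (wide enough to clear the 25 ms low-pass smear);
    the released size is the difference of the medians.
    If the post-event window is truncated by the end of the trace (or a
    tether break drops the force below the inversion cutoff), the event
    is flagged and the size omitted.
    """
    rate = trace.acquisition_rate
    n_win = max(1, int(round(window * rate)))
    n_guard = max(1, int(round(guard * rate)))
    p = event.peak_index
    pre = slice(max(0, p - n_guard - n_win), max(0, p - n_guard))
    post = slice(p + n_guard, p + n_guard + n_win)
    truncated = post.stop > len(trace) or pre.start >= pre.stop

    def median_contour(sl):
        bp, ok = contour_length_from_point(trace.force[sl], trace.extension[sl],
                                           elasticity)
        bp = np.asarray(bp)[np.asarray(ok)]
        return float(np.median(bp)) if len(bp) else math.nan

    before = median_contour(pre)
    after = median_contour(post) if not truncated else math.nan
    if truncated or math.isnan(before) or math.isnan(after):
        return replace(event, truncated=True, contour_before=before)
    return replace(event, contour_before=before, contour_after=after,
                   released_bp=after - before)


def extension_at_reference_force(trace: ForceExtensionTrace,
                                 f_ref: float = 0.5,
                                 smooth_window: float = 0.25) -> float:
    """Extension (nm) interpolated at the first upward crossing of ``f_ref``.

    The compaction metric reads the DNA extension at 0.5 pN during the
    initial low-force stretch.  The force is boxcar-smoothed over
    ``smooth_window`` seconds first, so the crossing reflects the mean
    force rather than the first favourable noise excursion.
    """
    if f_ref <= 0:
        raise ValueError("f_ref must be > 0")
    n_win = max(1, int(round(smooth_window * trace.acquisition_rate)))
    f = uniform_filter1d(trace.force, n_win, mode="nearest")
    above = f >= f_ref
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if len(idx) == 0:
        raise ValueError(f"force never crosses {f_ref} pN upward")
    i = int(idx[0])
    w = (f_ref - f[i]) / (f[i + 1] - f[i])
    return float((1 - w) * trace.extension[i] + w * trace.extension[i + 1])


def tether_breakage_force(trace: ForceExtensionTrace,
                          escape_force: float = 110.0,
                          zero_tension: float = 0.5,
                          min_preload: float = 5.0) -> tuple[float, bool]:
    """Breakage force of a constant-velocity trace, with censoring.

    Returns ``(force_pN, censored)``.  A break is a collapse of the force
    to the zero-tension baseline after the trace has reached at least
    ``min_preload``; the reported force is the maximum over the few
    samples immediately preceding the collapse.  If the trace instead
    reaches the trap escape force first, or never breaks, the result is a
    censored lower bound.
    """
    f = trace.force
    loaded = np.flatnonzero(f >= min_preload)
    if len(loaded):
        start = loaded[0]
        collapsed = np.flatnonzero(f[start:] < zero_tension)
        if len(collapsed):
            i = start + collapsed[0]
            # look back past the low-pass smear of the collapse edge
            lo = max(0, i - max(2, int(0.05 * trace.acquisition_rate)))
            force_at_break = float(np.max(f[lo:i])) if i > lo else float(f[max(i - 1, 0)])
            if force_at_break >= escape_force:
                return escape_force, True
            return force_at_break, False
    peak = float(np.max(f)) if len(f) else 0.0
    if peak >= escape_force:
        return escape_force, True
    return peak, True  # censored at trace end


# ---------------------------------------------------------------------------
# Tether survival kinetics
# ---------------------------------------------------------------------------

def kaplan_meier(lifetimes, censored=None):
    """Product-limit survival estimate; censored tethers stay in the
    at-risk set until their censoring time.  Returns (times, survival)."""
    t = np.asarray(lifetimes, dtype=float)
    c = np.zeros(len(t), bool) if censored is None else np.asarray(censored, bool)
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    n_at_risk = len(t)
    times, surv = [0.0], [1.0]
    s = 1.0
    for ti, ci in zip(t, c):
        if not ci:
            s *= (n_at_risk - 1) / n_at_risk
            times.append(ti)
            surv.append(s)
        n_at_risk -= 1
    return np.asarray(times), np.asarray(surv)


def _mixture_survival(t, a1, tau1, tau2):
    return a1 * np.exp(-t / tau1) + (1.0 - a1) * np.exp(-t / tau2)


def fit_survival(lifetimes, censored=None, p0=None) -> SurvivalModel:
    """Fit a double-exponential survival law to pooled tether lifetimes.

    The empirical survival curve (product-limit, censoring-aware) is fit
    by nonlinear least squares with S(t) = a·e^{-t/τ1} + (1-a)·e^{-t/τ2},
    matching how the plotted remaining-tether fraction is fitted; the
    half-life t_1/2 solves S(t) = 1/2 numerically.
    """
    t = np.asarray(lifetimes, dtype=float)
    c = np.zeros(len(t), bool) if censored is None else np.asarray(censored, bool)
    n_events = int((~c).sum())
    if n_events < 10:
        raise ValueError("need at least 10 uncensored lifetimes")
    if np.ptp(t[~c]) == 0:
        raise ValueError("degenerate data: all lifetimes identical")
    times, surv = kaplan_meier(t, c)
    med = float(np.median(t[~c]))
    if p0 is None:
        p0 = (0.5, max(med / math.log(2.0) / 4.0, 1e-6), med / math.log(2.0) * 4.0)
    try:
        popt, pcov = curve_fit(_mixture_survival, times, surv, p0=p0,
                               bounds=([0.0, 1e-9, 1e-9], [1.0, np.inf, np.inf]),
                               maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"survival fit did not converge: {exc}") from exc
    a1, tau1, tau2 = popt
    if tau1 > tau2:  # report the fast phase first
        a1, tau1, tau2 = 1.0 - a1, tau2, tau1
        # covariance loses its parameter order under the swap; keep raw
    hi = 10.0 * max(tau1, tau2)
    t_half = brentq(lambda x: _mixture_survival(x, a1, tau1, tau2) - 0.5, 0.0, hi)
    return SurvivalModel(amplitude_1=float(a1), tau_1=float(tau1),
                         amplitude_2=float(1.0 - a1), tau_2=float(tau2),
                         t_half=float(t_half), covariance=pcov)
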