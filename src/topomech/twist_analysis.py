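"""Magnetic-tweezers supercoil-relaxation analysis.

A torsionally constrained DNA tether held at low force (0.22 pN) shortens
linearly with applied magnet turns once plectonemes form; the
extension-versus-turns relation is the "hat curve".  During enzymatic
relaxation the extension grows back, and converting extension to the turn
state through the hat curve yields turns-relaxed versus time.  This module
fits hat curves, converts extension to turns, detects pauses by dwell-time
analysis, and computes pause-free rates, pause frequencies (with
censoring), mean relaxation rates and trapped-supercoil sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .polymer_mechanics import (
    DsDnaElasticity,
    wlc_fractional_extension,
)

__all__ = [
    "TwistTrace",
    "HatCurveModel",
    "PauseState",
    "fit_hat_curve",
    "turns_from_extension",
    "sg_smooth",
    "relaxation_window",
    "detect_pauses",
    "pause_free_rate",
    "pause_frequency",
    "mean_relaxation_rate",
    "trapped_loop_size",
]

#: magnet force of the twisting assay, pN
DEFAULT_TWIST_FORCE_PN = 0.22
#: turns relaxed assigned to pause-free traces (pre-buckling bound)
DEFAULT_CENSOR_TURNS = 30.0


@dataclass
class TwistTrace:
    """Extension/applied-turns time series from a magnetic-tweezers run."""

    time: np.ndarray  # s
    extension: np.ndarray  # nm
    applied_turns: np.ndarray  # turns (magnet setting per sample)
    acquisition_rate: float = 10.0  # Hz
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.applied_turns = np.asarray(self.applied_turns, dtype=float)
        if not (len(self.time) == len(self.extension) == len(self.applied_turns)):
            raise ValueError("time, extension and applied_turns must match in length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class HatCurveModel:
    """Piecewise extension-versus-turns model: quadratic cap + linear flanks.

    For turns n beyond the buckling points the extension falls linearly
    (plectoneme growth); within ``half_width`` of the centre the two
    flanks are joined by a quadratic cap with matching slopes.
    """

    center_turn: float
    plateau_extension: float  # nm
    half_width: float  # turns between centre and each buckling point
    slope_left: float  # nm/turn, > 0 (extension rises toward the centre)
    slope_right: float  # nm/turn, < 0
    residual: float = 0.0  # rms fit residual, nm

    def __post_init__(self) -> None:
        if self.plateau_extension <= 0:
            raise ValueError("plateau_extension must be > 0")
        if not (self.slope_left > 0 > self.slope_right):
            raise ValueError("flank slopes must have opposite signs")

    @property
    def buckling_left(self) -> float:
        return self.center_turn - self.half_width

    @property
    def buckling_right(self) -> float:
        return self.center_turn + self.half_width

    def extension_at(self, turns):
        return _hat_model(np.asarray(turns, dtype=float), self.center_turn,
                          self.plateau_extension, self.half_width,
                          self.slope_left, -self.slope_right)

    def turns_at(self, extension, branch: str):
        """Inverse mapping on one flank ('plus' = right, 'minus' = left).

        Extensions above the plateau are clipped to the branch buckling
        point.  Returns (turns, clipped flag array).
        """
        e = np.asarray(extension, dtype=float)
        n0, p, w = self.center_turn, self.plateau_extension, self.half_width
        s = -self.slope_right if branch == "plus" else self.slope_left
        if branch not in ("plus", "minus"):
            raise ValueError("branch must be 'plus' or 'minus'")
        e_buckle = p - 0.5 * s * w  # extension at the buckling point
        clipped = e > p
        e_c = np.minimum(e, p)
        # |n - n0|: invert the quadratic cap above e_buckle, the flank below
        n_off = np.where(e_c >= e_buckle,
                         w * np.sqrt(np.maximum(2.0 * (p - e_c) / (s * w), 0.0)),
                         w + (e_buckle - e_c) / s)
        turns = n0 + n_off if branch == "plus" else n0 - n_off
        return turns, clipped


def _hat_model(n, n0, p, w, sl, sr):
    """Continuous hat: quadratic cap of half-width w, linear flanks.

    sl, sr are the positive magnitudes of the left/right flank slopes.
    The cap e(n) = p - s/(2w)·(n-n0)² matches value and slope at n0 ± w.
    """
    d = n - n0
    left_cap = p - sl / (2.0 * w) * d ** 2
    right_cap = p - sr / (2.0 * w) * d ** 2
    left_flank = p - 0.5 * sl * w - sl * (-d - w)
    right_flank = p - 0.5 * sr * w - sr * (d - w)
    out = np.where(d < -w, left_flank, np.where(d <= 0, left_cap,
                   np.where(d <= w, right_cap, right_flank)))
    return out


def fit_hat_curve(turns, extension) -> HatCurveModel:
    """Least-squares multi-piece fit of the extension-versus-turns relation.

    Requires data on both flanks (turns below and above the centre with
    extension clearly off the plateau); raises otherwise.
    """
    n = np.asarray(turns, dtype=float)
    e = np.asarray(extension, dtype=float)
    if np.ptp(e) < 1e-9:
        raise ValueError("extension does not vary with turns; no flanks to fit")
    p0_center = float(n[np.argmax(e)])
    p0_plateau = float(np.max(e))
    span = max(np.ptp(n) / 4.0, 1.0)
    # rough flank slopes from the extreme thirds
    lo = n < np.percentile(n, 25)
    hi = n > np.percentile(n, 75)
    if not (lo.any() and hi.any()):
        raise ValueError("hat-curve data must span both flanks")
    sl0 = abs(np.polyfit(n[lo], e[lo], 1)[0]) or 10.0
    sr0 = abs(np.polyfit(n[hi], e[hi], 1)[0]) or 10.0
    if sl0 < 1e-9 or sr0 < 1e-9:
        raise ValueError("one-sided or flankless hat-curve data")
    popt, _ = curve_fit(_hat_model, n, e,
                        p0=(p0_center, p0_plateau, span / 2.0, sl0, sr0),
                        bounds=([np.min(n), 0.0, 1e-3, 1e-3, 1e-3],
                                [np.max(n), np.inf, np.ptp(n), np.inf, np.inf]),
                        maxfev=20000)
    n0, p, w, sl, sr = popt
    resid = float(np.sqrt(np.mean((e - _hat_model(n, *popt)) ** 2)))
    return HatCurveModel(center_turn=float(n0), plateau_extension=float(p),
                         half_width=float(w), slope_left=float(sl),
                         slope_right=float(-sr), residual=resid)


def turns_from_extension(trace: TwistTrace, hat: HatCurveModel, branch: str,
                         initial_turns: float | None = None):
    """Turns relaxed over time, deduced from extension through the hat curve.

    ``branch`` declares which flank the applied turns sit on ('plus' for
    positive supercoiling, 'minus' for negative).  Turns relaxed are
    measured from the initial applied turn state (default: the first
    sample of ``applied_turns``) and are non-decreasing up to noise.
    Returns ``(turns_relaxed, clipped)``.
    """
    if initial_turns is None:
        initial_turns = float(trace.applied_turns[0])
    state, clipped = hat.turns_at(trace.extension, branch)
    sign = 1.0 if branch == "minus" else -1.0
    relaxed = sign * (state - initial_turns)
    return relaxed, clipped


def sg_smooth(series, time_constant: float = 30.0, rate: float = 10.0,
              order: int = 2):
    """Savitzky–Golay low-pass: local polynomial regression of the given
    order over a ``time_constant`` window (301 points at 10 Hz, 30 s)."""
    x = np.asarray(series, dtype=float)
    n_win = int(round(time_constant * rate))
    n_win += 1 - n_win % 2  # odd
    n_win = max(n_win, order + 2 + (order % 2))
    if len(x) < n_win:
        raise ValueError("series shorter than the filter window")
    return savgol_filter(x, n_win, order, mode="interp")


def relaxation_window(turns_relaxed, limit: float = DEFAULT_CENSOR_TURNS) -> int:
    """Index ending the analyzable relaxation region.

    Beyond ~30 turns relaxed (of the 40 applied) the tether leaves the
    plectonemic flank and enters the pre-buckling cap of the hat curve,
    where extension no longer reads out turns; dwell analysis past that
    point would report the relaxed end state as a spurious pause.
    Returns the index of the first sample at or beyond ``limit`` (the
    series length if never reached).
    """
    x = np.asarray(turns_relaxed, dtype=float)
    beyond = np.flatnonzero(x >= limit)
    return int(beyond[0]) if len(beyond) else len(x)


@dataclass
class PauseState:
    """A pausing state: a turn level with a notable dwell."""

    turn_level: float  # turns relaxed at the pause
    start: float  # s
    duration: float  # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


def detect_pauses(turn_series, time, bin_width: float = 0.2,
                  dwell_threshold: float = 2.0,
                  assign_radius: float = 0.4,
                  min_duration: float = 2.0,
                  min_resolvable: float = 12.0) -> list[PauseState]:
    """Dwell-time pause detection on a smoothed turns-relaxed series.

    The series is binned in ``bin_width``-turn intervals and the dwell
    time per bin computed; clusters of adjacent bins with more than
    ``dwell_threshold`` seconds per bin become single pausing states.
    Each state is mapped back to the time domain by assigning samples
    within ``assign_radius`` turns of its level, then the level and
    duration are refined by averaging the assigned samples.

    ``min_duration`` is the hard detection floor (2 s per the dwell
    criterion).  ``min_resolvable`` additionally drops states shorter
    than the resolution of the upstream low-pass: a 2nd-order filter of
    window W smears the entry into and exit from a pause into satellite
    dwell peaks lasting up to ~0.4 W, so with the default 30 s filter
    states shorter than 12 s cannot be distinguished from filter edges.
    Set it to 0 to recover the bare dwell criterion.
    """
    x = np.asarray(turn_series, dtype=float)
    t = np.asarray(time, dtype=float)
    if len(x) != len(t) or len(x) < 2:
        raise ValueError("turn series and time must match and hold >= 2 samples")
    dt = float(np.median(np.diff(t)))
    lo = np.floor(x.min() / bin_width) * bin_width
    nbins = max(1, int(np.ceil((x.max() - lo) / bin_width)))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(x, bins=edges)
    dwell = counts * dt
    hot = dwell > dwell_threshold
    # candidate levels: dwell-weighted centres of hot-bin clusters
    candidates: list[tuple[float, float]] = []  # (level, total dwell)
    i = 0
    while i < nbins:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < nbins and hot[j + 1]:
            j += 1
        centers = 0.5 * (edges[i:j + 1] + edges[i + 1:j + 2])
        w = dwell[i:j + 1]
        candidates.append((float(np.average(centers, weights=w)),
                           float(w.sum())))
        i = j + 1
    # clusters whose assignment windows would overlap are one state: the
    # low-pass filter smears the approach to a pause into satellite
    # dwell peaks that cannot be resolved as separate levels
    merged: list[tuple[float, float]] = []
    for level, w in candidates:
        if merged and level - merged[-1][0] <= 2.0 * assign_radius:
            l0, w0 = merged[-1]
            merged[-1] = ((l0 * w0 + level * w) / (w0 + w), w0 + w)
        else:
            merged.append((level, w))
    floor = max(min_duration, min_resolvable)
    pauses: list[PauseState] = []
    for level, _ in merged:
        sel = np.abs(x - level) <= assign_radius
        if sel.any():
            level_refined = float(np.mean(x[sel]))
            duration = float(sel.sum() * dt)
            start = float(t[np.flatnonzero(sel)[0]])
            if duration > floor:
                pauses.append(PauseState(turn_level=level_refined,
                                         start=start, duration=duration))
    return pauses


def pause_free_rate(trace: TwistTrace, turns_relaxed, pauses,
                    filter_constant: float = 5.0,
                    rate_bin: float = 0.5) -> float:
    """Median instantaneous rate (turns/s) over the first activity burst.

    The instantaneous rate is the slope of a rolling linear fit over a
    ``filter_constant`` window of the raw turns-relaxed series (the
    sliding-window filter and the linear fit in one operation).  Rates
    are binned by 0.5 turns of progress and the median of the bin
    medians over the first burst (onset to first pause, or the whole
    trace without pauses) is returned.
    """
    x = np.asarray(turns_relaxed, dtype=float)
    t = trace.time
    dt = float(np.median(np.diff(t)))
    n_win = max(3, int(round(filter_constant / dt)) | 1)
    if len(x) < n_win:
        raise ValueError("trace shorter than the rate filter window")
    # the 5 s sliding-window filter and the linear fit are one operation:
    # a rolling first-order polynomial fit (Savitzky-Golay, order 1)
    x_f = savgol_filter(x, n_win, 1, mode="interp")
    rate = savgol_filter(x, n_win, 1, deriv=1, delta=dt, mode="interp")
    if pauses:
        stop_t = min(p.start for p in pauses)
        m = t < stop_t
        # drop the half-window next to the pause, where the rolling fit
        # already averages in the paused plateau
        trimmed = m & (t < stop_t - filter_constant / 2.0)
        if trimmed.sum() >= n_win:
            m = trimmed
    else:
        m = np.ones(len(t), dtype=bool)
    if m.sum() < 2:
        raise ValueError("no burst before the first pause")
    xb, rb = x_f[m], rate[m]
    lo = np.floor(xb.min() / rate_bin) * rate_bin
    nb = max(1, int(np.ceil((xb.max() - lo) / rate_bin)))
    med = []
    for b in range(nb):
        sel = (xb >= lo + b * rate_bin) & (xb < lo + (b + 1) * rate_bin)
        if sel.any():
            med.append(np.median(rb[sel]))
    return float(np.median(med))


def pause_frequency(first_pause_turns, censored=None,
                    censor_turns: float = DEFAULT_CENSOR_TURNS):
    """Pause frequency (per turn) from turns relaxed before the first pause.

    Traces without a detected pause contribute the censoring bound
    (default ~30 turns, the pre-buckling range of the 12.7-kb tether at
    0.22 pN).  The cumulative fraction of traces still pause-free after
    n turns is fitted with a single exponential exp(-n/n0); the
    frequency is 1/n0.  Returns ``(frequency, all_censored_flag)``.
    """
    x = np.asarray(first_pause_turns, dtype=float)
    if censored is None:
        censored = np.zeros(len(x), dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    if len(x) < 10:
        raise ValueError("need at least 10 traces")
    x = np.where(censored, censor_turns, x)
    all_censored = bool(censored.all())
    if all_censored:
        return 1.0 / censor_turns, True  # upper bound
    # survival-style cumulative histogram: fraction with first pause > n.
    # Below the censor bound the censored traces simply remain at risk,
    # so the curve is exact there; the cliff at the bound is not fitted.
    xs = np.sort(x)
    n_grid = np.concatenate([[0.0], xs])
    frac = 1.0 - np.arange(len(n_grid)) / len(xs)
    keep = n_grid < censor_turns

    def expdec(n, n0):
        return np.exp(-n / n0)

    popt, _ = curve_fit(expdec, n_grid[keep], frac[keep],
                        p0=(max(np.mean(x), 1e-3),),
                        bounds=(1e-6, np.inf), maxfev=10000)
    freq = 1.0 / float(popt[0])
    return freq, False


def mean_relaxation_rate(trace: TwistTrace, turns_relaxed,
                         target_turns: float | None = None,
                         tolerance: float = 0.5):
    """Overall relaxation rate (turns/s) including pauses.

    Total turns relaxed divided by the time from relaxation onset (first
    sample) to first reaching ``target_turns`` (default: the initial
    applied turns), or to the trace end if the tether never fully
    relaxes.  Returns ``(rate, completed)``.
    """
    x = np.asarray(turns_relaxed, dtype=float)
    t = trace.time
    if target_turns is None:
        target_turns = abs(float(trace.applied_turns[0]))
    done = np.flatnonzero(x >= target_turns - tolerance)
    if len(done):
        i = int(done[0])
        elapsed = t[i] - t[0]
        total = x[i]
        completed = True
    else:
        elapsed = t[-1] - t[0]
        total = max(float(x[-1]), 0.0)
        completed = False
    if elapsed <= 0:
        return 0.0, completed
    return float(total / elapsed), completed


def trapped_loop_size(hat_before: HatCurveModel, hat_after: HatCurveModel,
                      force: float = DEFAULT_TWIST_FORCE_PN,
                      elasticity: DsDnaElasticity = DsDnaElasticity(),
                      noise_floor: float = 10.0):
    """Size (bp) of a trapped supercoiled loop from the hat-height drop.

    The plateau-extension reduction is converted to base pairs through
    the WLC fractional extension at the holding force:
    bp = Δext / (rise × x/L(F)).  Returns ``(bp, consistent)`` where
    ``consistent`` is False if the plateau instead rose by more than the
    noise floor (nm).
    """
    d_ext = hat_before.plateau_extension - hat_after.plateau_extension
    frac = wlc_fractional_extension(force, elasticity)
    bp = d_ext / (elasticity.rise_per_bp * frac)
    consistent = d_ext >= -noise_floor
    return float(bp), bool(consistent)
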